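"""End-to-end orchestration: load/align inputs, build fused similarities,
denoise the association matrix, factorize, and score all pairs.

Configuration is a flat, namespaced YAML mapping (e.g. ``scmf.theta: 4``);
every CLI flag overrides its config key.  A JSON run report captures every
effective parameter plus convergence diagnostics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, skf
from . import lrr as lrr_mod
from . import scmf as scmf_mod
from .lrr import LRRParams
from .scmf import SCMFParams
from .data_model import (
    AssociationDataset,
    ScoreMatrix,
    SimilarityMatrix,
    align,
    load_association_edges,
    load_similarity_matrix,
    save_scores,
)
from .disease_semantics import SemanticParams, build_semantic_similarity, load_dag_corpus
from .gip import GIPParams, gip_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "scores_for_training_matrix",
    "run_predict",
    "run_evaluate",
    "run_grid",
]


@dataclass
class PipelineConfig:
    association_path: str | None = None
    mirna_similarity_path: str | None = None
    dag_edges_path: str | None = None
    dag_roster_path: str | None = None
    output_dir: str = "mirlink_out"
    seed: int = 0

    semantic: SemanticParams = field(default_factory=SemanticParams)
    gip_mirna: GIPParams = field(default_factory=GIPParams)
    gip_disease: GIPParams = field(default_factory=GIPParams)
    fusion_mirna: skf.FusionParams = field(default_factory=skf.FusionParams)
    fusion_disease: skf.FusionParams = field(default_factory=skf.FusionParams)
    # phi=0.4 keeps the outlier matrix active; at phi=1 the L2,1 penalty
    # shrinks X to near zero and the denoising step degenerates to A* ~ A
    lrr: LRRParams = field(default_factory=lambda: LRRParams(phi=0.4))
    scmf: SCMFParams = field(default_factory=SCMFParams)

    skip_md: bool = False          # ablation: use A directly instead of A* = A Y*
    clip_a_star: bool = False      # optionally clip the denoised matrix to [0, 1]
    protocol: str = "5cv"
    repeats: int = 5
    n_folds: int = 5
    local_diseases: list[str] | None = None

    _SECTIONS = {
        "semantic": SemanticParams,
        "gip_mirna": GIPParams,
        "gip_disease": GIPParams,
        "fusion_mirna": skf.FusionParams,
        "fusion_disease": skf.FusionParams,
        "lrr": LRRParams,
        "scmf": SCMFParams,
    }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        cfg = cls()
        cfg.update(mapping)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def update(self, mapping: dict) -> None:
        """Apply flat ``section.key`` (or top-level) overrides in place."""
        for key, value in mapping.items():
            if value is None:
                continue
            if "." in key:
                section, attr = key.split(".", 1)
                if section not in self._SECTIONS:
                    raise KeyError(f"unknown config section {section!r}")
                params = getattr(self, section)
                if not hasattr(params, attr):
                    raise KeyError(f"unknown config key {key!r}")
                setattr(params, attr, value)
                params.__post_init__()
            else:
                if not hasattr(self, key) or key.startswith("_"):
                    raise KeyError(f"unknown config key {key!r}")
                setattr(self, key, value)
        self.scmf.seed = self.seed

    def to_dict(self) -> dict:
        out: dict = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out


def _fused_similarities(
    A_train: np.ndarray,
    sm_functional: SimilarityMatrix | None,
    sd_semantic: SimilarityMatrix | None,
    config: PipelineConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse each entity class's precomputed similarity with the GIP kernel
    computed from the (possibly masked) training matrix.  When a precomputed
    input is missing the GIP kernel stands alone."""
    sm_gip = gip_kernel(A_train, config.gip_mirna)
    sd_gip = gip_kernel(A_train.T, config.gip_disease)
    if sm_functional is not None:
        SM = skf.fused_similarity(
            SimilarityMatrix(sm_gip.ids, sm_functional.S), sm_gip, config.fusion_mirna
        ).S
    else:
        SM = sm_gip.S
    if sd_semantic is not None:
        SD = skf.fused_similarity(
            SimilarityMatrix(sd_gip.ids, sd_semantic.S), sd_gip, config.fusion_disease
        ).S
    else:
        SD = sd_gip.S
    return SM, SD


def scores_for_training_matrix(
    A_train: np.ndarray,
    sm_functional: SimilarityMatrix | None,
    sd_semantic: SimilarityMatrix | None,
    config: PipelineConfig,
    diagnostics: dict | None = None,
) -> np.ndarray:
    """Core scoring path used by both prediction and cross-validation."""
    A_train = np.asarray(A_train, dtype=float)
    SM, SD = _fused_similarities(A_train, sm_functional, sd_semantic, config)

    if config.skip_md:
        A_star = A_train.copy()
    else:
        res = lrr_mod.ialm_lrr(A_train, config.lrr)
        A_star = A_train @ res.Y
        if diagnostics is not None:
            diagnostics["lrr"] = {
                "iterations": res.iterations,
                "r1": res.r1,
                "r2": res.r2,
                "converged": res.converged,
            }
    if config.clip_a_star:
        A_star = np.clip(A_star, 0.0, 1.0)

    params = dataclasses.replace(config.scmf)
    max_rank = min(A_train.shape)
    if params.rank > max_rank:
        logger.warning("scmf rank %d clamped to %d", params.rank, max_rank)
        params.rank = max_rank
    model = scmf_mod.fit_scmf(A_star, SM, SD, params)
    if diagnostics is not None:
        diagnostics["scmf"] = {
            "sweeps": model.sweeps,
            "converged": model.converged,
            "objective": model.objective_trace[-1],
        }
    return model.U @ model.V.T


def _load_inputs(config: PipelineConfig):
    if config.association_path is None:
        raise ValueError("association_path is required")
    dataset = load_association_edges(config.association_path)
    sm = None
    if config.mirna_similarity_path:
        sm = load_similarity_matrix(config.mirna_similarity_path)
    sd = None
    if config.dag_edges_path and config.dag_roster_path:
        corpus = load_dag_corpus(config.dag_edges_path, config.dag_roster_path)
        sd = build_semantic_similarity(corpus, config.semantic, disease_ids=None)
    if sm is not None and sd is not None:
        dataset, sm, sd = align(dataset, sm, sd)
    elif sm is not None:
        dataset, sm, _ = align(dataset, sm, SimilarityMatrix(dataset.disease_ids, np.eye(dataset.nd)))
    elif sd is not None:
        dataset, _, sd = align(dataset, SimilarityMatrix(dataset.mirna_ids, np.eye(dataset.nm)), sd)
    return dataset, sm, sd


def run_predict(config: PipelineConfig) -> ScoreMatrix:
    """Full flow: load/align, fuse similarities, denoise, factorize, write artifacts."""
    t0 = time.time()
    dataset, sm, sd = _load_inputs(config)
    diagnostics: dict = {}
    scores = scores_for_training_matrix(dataset.A, sm, sd, config, diagnostics=diagnostics)
    result = ScoreMatrix(dataset.mirna_ids, dataset.disease_ids, scores)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_scores(result, out / "scores.tsv")
    report = {
        "config": config.to_dict(),
        "diagnostics": diagnostics,
        "nm": dataset.nm,
        "nd": dataset.nd,
        "runtime_seconds": time.time() - t0,
    }
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    logger.info("run_predict: wrote %s in %.1fs", out / "scores.tsv", report["runtime_seconds"])
    return result


def run_evaluate(config: PipelineConfig, protocol: str | None = None) -> evaluation.CVResult:
    """Dispatch a cross-validation protocol with per-fold recomputation."""
    dataset, sm, sd = _load_inputs(config)
    return evaluate_in_memory(dataset, sm, sd, config, protocol)


def evaluate_in_memory(
    dataset: AssociationDataset,
    sm: SimilarityMatrix | None,
    sd: SimilarityMatrix | None,
    config: PipelineConfig,
    protocol: str | None = None,
) -> evaluation.CVResult:
    protocol = protocol or config.protocol
    if protocol == "5cv":
        result = evaluation.five_fold_cv(
            dataset, sm, sd, config,
            repeats=config.repeats, seed=config.seed, n_folds=config.n_folds,
        )
    elif protocol == "global-loocv":
        result = evaluation.global_loocv(dataset, sm, sd, config)
    elif protocol == "local-loocv":
        result = evaluation.local_loocv(dataset, sm, sd, config, diseases=config.local_diseases)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"cv_{protocol}.json", "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    if result.roc is not None:
        with open(out / f"roc_{protocol}.tsv", "w", encoding="utf-8") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in zip(*result.roc):
                fh.write(f"{x:.6g}\t{y:.6g}\n")
    return result


def run_grid(
    dataset: AssociationDataset,
    sm: SimilarityMatrix | None,
    sd: SimilarityMatrix | None,
    config: PipelineConfig,
    thetas: list[float],
    sigmas: list[float],
) -> np.ndarray:
    """AUC table over a (theta, sigma) grid using the k-fold protocol."""
    import copy

    table = np.zeros((len(thetas), len(sigmas)))
    for a, theta in enumerate(thetas):
        for b, sigma in enumerate(sigmas):
            cfg = copy.deepcopy(config)
            cfg.scmf.theta = float(theta)
            cfg.scmf.sigma = float(sigma)
            res = evaluation.five_fold_cv(
                dataset, sm, sd, cfg,
                repeats=config.repeats, seed=config.seed, n_folds=config.n_folds,
            )
            table[a, b] = res.mean_auc
            logger.info("grid theta=%g sigma=%g -> AUC %.4f", theta, sigma, res.mean_auc)
    return table
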