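"""Disease semantic similarity from MeSH-style ancestor DAGs.

Two per-ancestor contribution models are supported: a depth-decay model
(each step toward the root multiplies the contribution by a factor delta)
and an information-content model (rarer terms contribute more, via the
negative natural log of their corpus frequency).  Pairwise similarity sums
shared-ancestor contributions and normalizes by the two semantic values;
the final matrix averages the two models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseDAGCorpus",
    "SemanticParams",
    "contribution_model1",
    "contribution_model2",
    "semantic_value",
    "semantic_similarity_pair",
    "build_semantic_similarity",
    "load_dag_corpus",
    "save_dag_corpus",
]


@dataclass
class SemanticParams:
    """delta: per-edge decay factor of the depth model, in (0, 1]."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.delta <= 1.0):
            raise ValueError("delta must lie in (0, 1]")


@dataclass
class DiseaseDAGCorpus:
    """Per-disease ancestor DAGs.

    ``dag[D]`` maps each term in T(D) (the disease plus all of its ancestors)
    to its set of parent terms within T(D).  ``universe_size`` is the disease
    count used as the denominator of the information-content model.
    """

    diseases: list[str]
    dag: dict[str, dict[str, set[str]]]
    universe_size: int = 0

    def __post_init__(self) -> None:
        if self.universe_size == 0:
            self.universe_size = len(self.diseases)
        for disease in self.diseases:
            if disease not in self.dag:
                continue
            nodes = self.dag[disease]
            if disease not in nodes:
                raise ValueError(f"DAG of {disease!r} does not contain the disease itself")
            for term, parents in nodes.items():
                missing = parents - set(nodes)
                if missing:
                    raise ValueError(f"DAG of {disease!r}: parents {missing} of {term!r} are not nodes")

    def terms(self, disease: str) -> set[str]:
        return set(self.dag[disease]) if disease in self.dag else set()


def _children_map(nodes: dict[str, set[str]]) -> dict[str, set[str]]:
    children: dict[str, set[str]] = {t: set() for t in nodes}
    for term, parents in nodes.items():
        for p in parents:
            children[p].add(term)
    return children


def contribution_model1(
    corpus: DiseaseDAGCorpus, D: str, params: SemanticParams | None = None
) -> dict[str, float]:
    """Depth-decay contribution of every term in T(D).

    The disease itself scores 1; every other term scores the maximum over its
    children (within the DAG) of delta times the child's score.  Computed by
    dynamic programming upward from D; cycles are rejected.
    """
    params = params or SemanticParams()
    if D not in corpus.dag:
        raise KeyError(f"disease {D!r} has no DAG in the corpus")
    nodes = corpus.dag[D]
    children = _children_map(nodes)

    scores: dict[str, float] = {}
    in_progress: set[str] = set()

    def score(term: str) -> float:
        if term in scores:
            return scores[term]
        if term in in_progress:
            raise ValueError(f"cycle detected in DAG of {D!r} at term {term!r}")
        in_progress.add(term)
        if term == D:
            val = 1.0
        else:
            kids = children[term]
            if not kids:
                raise ValueError(f"DAG of {D!r}: term {term!r} is not an ancestor of {D!r}")
            val = max(params.delta * score(c) for c in kids)
        in_progress.discard(term)
        scores[term] = val
        return val

    for term in nodes:
        score(term)
    return scores


def contribution_model2(corpus: DiseaseDAGCorpus) -> dict[str, float]:
    """Information-content contribution of every term appearing in the corpus.

    score(t) = -ln(number of DAGs whose node set contains t / universe_size).
    """
    if corpus.universe_size < 1:
        raise ValueError("universe_size must be >= 1")
    counts: dict[str, int] = {}
    for disease in corpus.diseases:
        for term in corpus.terms(disease):
            counts[term] = counts.get(term, 0) + 1
    if not counts:
        raise ValueError("corpus contains no DAG terms")
    return {t: -math.log(c / corpus.universe_size) for t, c in counts.items()}


def semantic_value(contribs: dict[str, float]) -> float:
    """Total semantic value of a disease: the sum of its term contributions."""
    if not contribs:
        raise ValueError("empty contribution map")
    return float(sum(contribs.values()))


def semantic_similarity_pair(
    corpus: DiseaseDAGCorpus,
    d_i: str,
    d_j: str,
    contribs_i: dict[str, float],
    contribs_j: dict[str, float],
    dv_i: float,
    dv_j: float,
) -> float:
    """Shared-ancestor similarity: sum of both contributions over the term
    intersection, divided by the sum of the two semantic values."""
    denom = dv_i + dv_j
    if denom <= 0:
        raise ValueError("zero or negative semantic-value denominator")
    shared = corpus.terms(d_i) & corpus.terms(d_j)
    num = sum(contribs_i[t] + contribs_j[t] for t in shared)
    return float(num / denom)


def build_semantic_similarity(
    corpus: DiseaseDAGCorpus,
    params: SemanticParams | None = None,
    disease_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Average of the two contribution models over all disease pairs.

    Diseases without a DAG get similarity 0 to all others and 1 to self;
    downstream kernel fusion fills those rows in from interaction profiles.
    """
    params = params or SemanticParams()
    ids = list(disease_ids) if disease_ids is not None else list(corpus.diseases)
    n = len(ids)
    if n < 1:
        raise ValueError("no diseases to compare")

    dd2 = contribution_model2(corpus) if any(d in corpus.dag for d in ids) else {}
    c1: dict[str, dict[str, float]] = {}
    c2: dict[str, dict[str, float]] = {}
    dv1: dict[str, float] = {}
    dv2: dict[str, float] = {}
    for d in ids:
        if d not in corpus.dag:
            logger.warning("no DAG for disease %r; semantic similarity set to 0", d)
            continue
        c1[d] = contribution_model1(corpus, d, params)
        dv1[d] = semantic_value(c1[d])
        c2[d] = {t: dd2[t] for t in corpus.terms(d)}
        v2 = sum(c2[d].values())
        dv2[d] = v2

    S = np.eye(n)
    for a in range(n):
        da = ids[a]
        if da not in c1:
            continue
        for b in range(a + 1, n):
            db = ids[b]
            if db not in c1:
                continue
            ss1 = semantic_similarity_pair(corpus, da, db, c1[da], c1[db], dv1[da], dv1[db])
            if dv2[da] + dv2[db] > 0:
                ss2 = semantic_similarity_pair(corpus, da, db, c2[da], c2[db], dv2[da], dv2[db])
            else:
                # both diseases carry zero information content (terms shared by
                # every DAG); fall back on the depth model alone
                ss2 = ss1
            S[a, b] = S[b, a] = (ss1 + ss2) / 2.0
    return SimilarityMatrix(ids, np.clip(S, 0.0, 1.0))


def load_dag_corpus(edges_path: str | Path, roster_path: str | Path) -> DiseaseDAGCorpus:
    """Read a corpus from a global child->parent edge TSV plus a roster file.

    Roster lines are ``disease<TAB>term1<TAB>term2...`` giving each disease's
    node set T(D); the per-disease DAG keeps only edges between those nodes.
    """
    parents_of: dict[str, set[str]] = {}
    with open(edges_path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{edges_path}: line {lineno}: expected child<TAB>parent")
            child, parent = fields[0].strip(), fields[1].strip()
            parents_of.setdefault(child, set()).add(parent)

    diseases: list[str] = []
    dag: dict[str, dict[str, set[str]]] = {}
    with open(roster_path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t") if f.strip()]
            disease = fields[0]
            diseases.append(disease)
            node_set = set(fields[1:]) | {disease}
            dag[disease] = {t: (parents_of.get(t, set()) & node_set) for t in node_set}
    if not diseases:
        raise ValueError(f"{roster_path}: empty DAG roster")
    return DiseaseDAGCorpus(diseases, dag)


def save_dag_corpus(corpus: DiseaseDAGCorpus, edges_path: str | Path, roster_path: str | Path) -> None:
    edges: set[tuple[str, str]] = set()
    for nodes in corpus.dag.values():
        for term, parents in nodes.items():
            for p in parents:
                edges.add((term, p))
    with open(edges_path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(edges):
            fh.write(f"{child}\t{parent}\n")
    with open(roster_path, "w", encoding="utf-8") as fh:
        for d in corpus.diseases:
            terms = sorted(corpus.terms(d))
            fh.write("\t".join([d] + terms) + "\n")
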