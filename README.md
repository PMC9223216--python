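# mirlink

Prediction of miRNA–disease associations from a binary association matrix
plus similarity side-information. The scoring pipeline has three stages:

1. **Low-rank denoising (`mirlink.lrr`)** — decompose the association matrix
   as `A = A·Y + X` with a nuclear-norm penalty on the self-expression
   matrix `Y` and an L2,1 (column-sparse) penalty on the outlier matrix `X`,
   solved by inexact augmented Lagrange multipliers; the denoised matrix is
   `A* = A·Y`.
2. **Similarity kernel fusion (`mirlink.skf`)** — for each entity class,
   fuse a precomputed similarity (miRNA functional similarity from a file;
   disease semantic similarity from DAGs, `mirlink.disease_semantics`) with
   a Gaussian interaction-profile kernel (`mirlink.gip`) by cross-diffusion,
   finishing with a neighbor-agreement weight mask.
3. **Similarity-constrained matrix factorization (`mirlink.scmf`)** —
   factorize `A*` with L2 and graph-smoothness penalties tied to the fused
   kernels, using exact per-row Gauss–Seidel updates; predictions are
   `U·Vᵀ`.

Evaluation protocols (`mirlink.evaluation`): repeated 5-fold CV over known
pairs, global leave-one-out, and per-disease (local) leave-one-out, all with
per-fold refitting — interaction-profile kernels are recomputed from the
masked training matrix only. A seeded synthetic generator
(`mirlink.synthetic`) plants low-rank structure with configurable density
and flip noise, plus consistent similarity inputs, so everything runs
without downloads.

## CLI

```sh
# write a synthetic dataset in the standard input formats
mirlink generate --nm 120 --nd 80 --rank 5 --density 0.05 --noise-rate 0.1 \
    --seed 7 --output-dir data

# score all pairs
mirlink predict --association data/associations.tsv \
    --mirna-similarity data/mirna_similarity.tsv \
    --dag-edges data/dag_edges.tsv --dag-roster data/dag_roster.tsv \
    --output-dir out

# rank miRNAs for one disease
mirlink top-k --scores out/scores.tsv --disease d0003 -k 30

# cross-validate (5cv | global-loocv | local-loocv)
mirlink evaluate --association data/associations.tsv \
    --mirna-similarity data/mirna_similarity.tsv \
    --protocol 5cv --repeats 5 --seed 1 --output-dir eval

# hyperparameter grid over the L2 weight (theta) and smoothness weight (sigma)
mirlink grid --association data/associations.tsv --theta-grid 0.25,1,4 \
    --sigma-grid 0.5,1,2 --output-dir grid
```

All file formats are UTF-8 TSV: two-column edge lists for associations,
labeled square matrices for similarities and scores, child/parent edge +
roster files for disease DAGs. `#` lines are comments. Configuration can
also be given as a flat YAML file (`--config`), e.g. `scmf.theta: 4`;
CLI flags override config keys. `--skip-md` ablates the denoising stage.

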