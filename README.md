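# pseudopath

Pseudo developmental time for single-cell RNA-seq via a consensus
asymmetric Hamiltonian-path algorithm, with downstream gene-dynamics
analysis, quiescent-cell (G0) detection, cycle–differentiation coupling
coordinates, and trajectory evaluation metrics.

## Who this is for

Computational biologists ordering cells along a (mostly) linear
differentiation process — e.g. quiescent neural stem cells (qNSC) →
activated NSC (aNSC) → neural progenitors (NPC) — from a snapshot
expression matrix, who then want to know *which genes switch on or off*
along that axis, *which cells have exited the cycle*, and *how good* the
ordering is against known stage labels.

## The method

Let `X` be the `N × M` matrix of log₂(TPM+1) expression over a few hundred
development-associated genes (user-supplied gene sets, filtered by the
per-gene dispersion ratio `disp_j = var_j / μ_j ≥ 10`). For every
granularity `k = 3 … N`:

1. cells are cut into `k` groups by average-linkage hierarchical clustering
   on the double-centered Spearman distance `D(x_i, x_j) = (1 − ρ_s)/2`;
2. an **open Hamiltonian path** over the `k` cluster centroids is sought
   under the *directed* Kullback–Leibler cost
   `d_KL(x_i‖x_j) = Σ_m p_im ln(p_im/p_jm)` (profiles pseudocount-smoothed
   and normalized to the simplex) — the asymmetry encodes that
   differentiation is directional;
3. the path is solved by a modified arbitrary-insertion heuristic
   (endpoint-spread seeding, directed insertion costs, 10 restarts) and
   projected to per-cell scores in [0, 1].

The `k = 3…7` score vectors are merged into a **reference** by
exhaustively searching all 2⁵ = 32 keep/reflect orientation assignments for
the one maximizing the sum of the C(5,2) = 10 pairwise Spearman
correlations; the `k = 7…N` vectors are then oriented against the running
reference and averaged. Sorting the final min-max-scaled vector gives the
consensus ordering. The same path family is accumulated into an `N × N`
transition matrix whose PCA embedding distinguishes linear from branched
development.

Downstream: genes are ranked against pseudotime by distance correlation
(dCor) and the maximal information coefficient (MIC), both in [0, 1]
(keep if ≥ 0.5 by default); significant genes are segmented into hidden
on/off states by a univariate Gaussian HMM (Baum–Welch transitions,
Viterbi decoding) and clustered into modules; G0-like cells are detected
as the k-means (k = 5) cluster that is significantly lowest (P < 0.001,
every test) in all six cell-cycle phase scores (G1, S, G1/S, G2, M, G2/M);
orderings are scored with CI, BI, Kendall tau-b, and POS.

## Worked example

```python
import pandas as pd
from pseudopath import simulate_linear
from pseudopath.cli import RunConfig, run_pipeline

fx = simulate_linear(seed=7)                # 150 cells, 3 stages, 300 genes
fx.expr.write_tsv("expression.tsv")
pd.DataFrame({"cell_id": fx.expr.cell_ids,
              "stage": [f"s{v}" for v in fx.true_stage.stages]}
             ).to_csv("labels.tsv", sep="\t", index=False, header=False)

res = run_pipeline(RunConfig(
    expr_path="expression.tsv", out_dir="out", already_log=True,
    skip_dispersion=True, seed=7,
    labels_path="labels.tsv", stage_order=["s0", "s1", "s2"],
))
ev = res["evaluation"]
print(f"CI={ev.ci:.3f} BI={ev.bi:.3f} KC={ev.kc:.3f} POS={ev.pos:.3f}")
print("kept genes:", sum(g.kept for g in res["gene_scores"]))
```

prints

```
CI=0.932 BI=0.998 KC=0.817 POS=0.997
kept genes: 180
```

i.e. the consensus ordering is almost perfectly stage-contiguous (CI) and
stage-sorted (BI, POS); KC sits at 0.817 against a tau-b ceiling of 0.819
for 150 cells in three balanced tied stages; 180 of 300 genes pass the
dCor/MIC ≥ 0.5 screen (the fixture plants 60% informative genes). The
output directory contains `pseudotime.tsv`, `transition_matrix.tsv`,
`embedding.tsv`, `gene_scores.tsv`, `gene_states.tsv`, `modules.tsv`, and
`evaluation.tsv`.

The same pipeline is exposed as a CLI:

```sh
pseudopath simulate --out fixture/
pseudopath run --expr fixture/expression.tsv --already-log --skip-dispersion \
    --labels fixture/labels.tsv --stage-order s0,s1,s2 --out out/
pseudopath evaluate --pseudotime out/pseudotime.tsv \
    --labels fixture/labels.tsv --stage-order s0,s1,s2
```

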