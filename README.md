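# simplexdec

Fully unsupervised deconvolution of bulk tissue expression: given only a
non-negative genes × samples expression matrix **X**, `simplexdec`
recovers the number of constituent cell types *K*, the sample-wise
proportion matrix **A**, the cell-type-specific expression matrix **S**,
and the marker genes defining each cell type. No reference signatures,
marker lists, or cell counts are required.

## Who this is for

Bulk transcriptomics (and, in principle, any linearly mixed omics
signal) measures a weighted average over the cell types present in each
sample. Supervised deconvolution tools need reference profiles that are
often unreliable or unavailable for a given tissue, condition, or
platform. `simplexdec` is for researchers who want composition and
cell-type-specific expression estimates *from the bulk data alone*.

## The model and the geometry

The package assumes the linear mixing model

```
X = S · Aᵀ,      X[g, n] = Σₖ S[g, k] · A[n, k]
```

with **S** ≥ 0 (genes × K) and **A** row-stochastic (samples × K, each
sample's proportions summing to 1). Dividing each gene row of **X** by
its own sum projects the genes onto the standard simplex in sample
space. Under the model, every projected gene is a convex combination of
the K column-normalized columns of **A** — so the point cloud is a
(rotated, compressed) K-vertex simplex, genes expressed in exactly one
cell type (markers) sit at its vertices, and the vertices *are* the
columns of **A** up to positive scaling. Deconvolution therefore
reduces to vertex hunting:

1. **Radius-fixed clustering (RFC)** — deterministic, fixed-angular-
   radius clustering finds tight, dense marker-candidate clusters and
   flags outliers; the number of clusters is an output, not an input.
2. **Linear-programming vertex detection** — for each cluster center
   x_j, the LP `min s_j s.t. Σ s_i x_i = x_j, Σ s_i = 1, s ≥ 0` gives a
   *vertex margin*: zero for interior clusters, positive for hull
   vertices. One small LP per cluster replaces an exact convex-hull
   computation.
3. **Floating search + MDL** — sequential forward/backward floating
   searches find the best K-vertex simplex for each K (scored by a
   non-negative-least-squares cone-fit error), and a two-part minimum
   description length criterion picks the optimal K.

**A** is then recovered from the selected vertices (scales fixed by row-
stochasticity), **S** by per-gene NNLS against **A**, and the members of
the vertex clusters are reported as markers.

## Worked example

Simulate a designed benchmark mixture — 3 cell types, 3000 genes, 12
samples, 50 designated markers per type, no noise — then deconvolve it
blind and score the result:

```sh
simplexdec simulate --K 3 --genes 3000 --samples 12 \
    --markers-per-type 50 --seed 1 --out demo/truth
simplexdec deconvolve --input demo/truth/expr.tsv \
    --radius 1e-3 --k-min 2 --k-max 8 --out demo/run
simplexdec evaluate --result demo/run --truth demo/truth
```

The evaluation prints:

```
         metric        value
     selected_K 3.000000e+00
         true_K 3.000000e+00
        K_match 1.000000e+00
         rmse_A 2.373779e-16
precision_type1 1.000000e+00
   recall_type1 1.000000e+00
precision_type2 1.000000e+00
   recall_type2 1.000000e+00
precision_type3 1.000000e+00
   recall_type3 1.000000e+00
```

MDL selected K = 3 (the truth), the recovered proportion matrix matches
the ground truth to machine precision (RMSE ≈ 2.4·10⁻¹⁶ after column
matching), and every designated marker was recovered with no false
positives. `demo/run/model_trace.tsv` records the per-K survey — here
the K = 3 simplex reconstructs the scatter essentially exactly
(cone-fit error ~ 10⁻³¹) while K = 2 cannot:

```
K  reconstruction_error   mdl                 vertex_cluster_ids
2  2.596931980437606      -97398.04169181404  2;3
3  8.372958974813176e-31  -450021.75081763254 1;2;3
```

`demo/run/A.tsv` holds the estimated proportions per sample (rows sum
to 1), `S.tsv` the per-gene cell-type expression signatures, and
`markers.tsv` the marker table with each gene's angle to its vertex.

The same pipeline is available as a library:

```python
from simplexdec import DeconvolutionConfig, run_pipeline, load_expression
X = load_expression("demo/truth/expr.tsv")
result = run_pipeline(X, DeconvolutionConfig(radius=1e-3, K_min=2, K_max=8))
result.A, result.S, result.markers, result.trace.selected_K
```

The cluster radius should be on the order of the angular spread of
marker genes: tight (~10⁻³ rad) for clean designed mixtures, wider (the
0.06 rad default) for noisy data. See `docs/methods.md`.

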