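# Methods

## Model and assumptions

`simplexdec` fits the noiseless linear mixing model X = S·Aᵀ with
X ∈ ℝ^{G×N} the observed bulk matrix (G genes, N samples), S ≥ 0 the
cell-type expression signatures (G × K) and A the sample-wise
proportions (N × K, rows on the probability simplex). The method is
identifiable under the separability (pure-gene) condition: every cell
type has at least one marker gene expressed in that type only. Then the
row-normalized gene cloud is a K-vertex simplex whose vertices are the
column-normalized columns of A, markers sit exactly at the vertices,
and recovery of (A, S) is exact up to column permutation. All input
must be linear-scale and non-negative; log-transformed data breaks
additivity, so a heuristic (`detect_scale`: max entry < 50) warns but
never transforms — silent exponentiation would corrupt counts.

Gene vectors are normalized by their row sum (L1), not L2, so the
scatter lies on the standard simplex and convex-combination geometry
holds exactly. All-zero genes are dropped with a logged reason;
negative entries are fatal (an upstream processing bug, not data).

## Pipeline stages and parameters

**Gene filtering** (`min_peak`, default 0 — no filtering): keeps genes
whose peak expression reaches the threshold. The default is
conservative because any filtering choice interacts with marker
discovery; the CLI exposes the flag.

**Radius-fixed clustering** (`radius`, default 0.06 rad;
`min_members`, default 25). Distance is angular: arccos of the cosine
similarity, making the criterion a true metric ball and scale-free.
Every remaining gene seeds a candidate ball; the largest ball wins
(ties: smaller mean member angle, then lowest seed row), its center is
recomputed once as the normalized member mean with members re-collected
around it, and its members are removed. Exactly one recentering pass is
used: repeated recentering can oscillate and would break the uniqueness
of the extraction sequence. In the pathological case where recentering
shrinks the ball below `min_members`, the original seed ball and seed
center are kept so every reported cluster honours its own radius bound.
The number of clusters is an output. The final cluster list is ordered
by (size desc, mean angle asc, first member row asc); under exact size
ties the last tie-break depends on row order, so cell-type column order
(not content) can change when input rows are permuted.

*Choosing `radius`*: it should match the angular spread of marker genes
around their vertex. With ~5% multiplicative noise, markers scatter
roughly 0.03–0.08 rad from their vertex, and the 0.06 default captures
most of them. On noise-free designed mixtures markers coincide at the
vertex to float precision, and a tight radius (we use 1e-3 rad in the
validation studies) excludes near-vertex bystander genes that any wide
ball would sweep in; this is what makes exact marker precision/recall
and machine-precision recovery of A attainable there. The pairwise
angle computation is exact and O(G²); adequate to a few times 10⁴ genes.

**LP vertex detection** (`lp_tolerance`, default 1e-2). The margin LP
for center x_j runs over *all* centers including x_j itself, so it is
always feasible (s_j = 1) and the margin is the minimal self-weight;
margins above the tolerance declare vertices. 1e-2 absorbs the small
positive margins noise induces on interior clusters; the oracle
cross-checks use 1e-6. Solved with scipy's HiGHS; the per-cluster
problems are independent and solved in fixed order, so results never
depend on scheduling. An exact Quickhull-based hull (after SVD
reduction to the cloud's intrinsic dimension) is retained purely as a
small-instance test oracle — it scales poorly with sample dimension and
is not the production path.

**Floating search.** For each K, the best K-subset of vertex candidates
minimizes the cone-fit error Σᵢ wᵢ·‖cᵢ − Vᵀbᵢ‖², bᵢ ≥ 0 — the weighted
"unexplainable portion" of each cluster center under the candidate
simplex — with wᵢ the cluster sizes. During the search the error is
evaluated over cluster centers only (cheap); the gene-level error is
computed once per final per-K model for MDL, keeping MDL data-faithful.
Two passes share a table of the best subset found at every size: SFFS
grows from the empty set with conditional exclusions, SBFS shrinks from
the full candidate set — ranking removals by a one-NNLS-per-candidate
"unexplainable portion" proxy rather than refitting every reduced
subset — with conditional re-inclusions. A conditional exchange
refinement then applies improving single and pair member-for-outsider
swaps at the target size; pair exchanges connect local optima that
single replacements cannot, and in our checks make the search match
exhaustive enumeration on instances with ≤ 15 candidates in ≥ 99.7% of
(instance, K) pairs (100% on the validation families reported by
`scripts/acceptance.py`). Each K's search is additionally seeded with
the best (K−1)-subset plus its best extension, which guarantees the
per-K error is non-increasing in K. NNLS uses scipy's active-set
solver with a bounded-variable (BVLS) fallback for the rare
near-collinear designs where the active-set method stalls.

**MDL selection of K.** The two-part code

```
MDL(K) = (L/2)·ln(RSS/L) + (P/2)·ln(L)
L = G_retained · N,   P = N·(K−1) + K·G_retained
```

combines a Gaussian residual code (RSS = unit-weight gene-level
cone-fit error, floored at L·1e-12 to avoid ln 0 on noise-free data)
with a parameter code counting the free entries of a row-stochastic A
and a full S. Ties break toward smaller K (parsimony). No AIC/BIC
alternatives are offered.

**Optional cluster merging** (`--merge`; `merge_angle` defaults to
radius/2). Single-linkage merging of clusters whose centers lie within
the merge angle, before the search; lowers search burden and the risk
of ill-conditioned simplexes from split clusters. When the scatter is
available the merged center is recomputed exactly as the normalized
mean of member points; the angle-only fallback uses the size-weighted
normalized mean of the constituent centers.

**A and S estimation.** The selected normalized vertices are the
columns of A up to positive per-column scales; the scales are the least
squares solution of "rows of Vᵀ·diag(c) sum to 1", with negative
ripples clipped and rows renormalized. Collinear vertex matrices (rank
< K) are an error. S is estimated by independent per-gene NNLS against
A over *all* input genes, including filtered ones, so the output has
one row per input gene. Cell types are ordered by descending vertex
cluster size.

## Synthetic data: what it emulates and what it does not

The generator emulates designed-mixture benchmarks: K types with
`markers_per_type` designated markers (log-normal magnitude, meanlog 3,
sdlog 1, times an `expr_scale` fold-change of 5, in exactly one
column), remaining genes dense with K independent log-normal values,
proportions i.i.d. symmetric Dirichlet(α = 1) across samples (or an
explicit design table), and either multiplicative log-normal or
additive Gaussian noise. All draws flow through `numpy.random.default_rng`
(PCG64), so a seed pins fixtures bit-for-bit across platforms.

Defaults for the validation studies: the noise-free identifiability
study uses K = 3, G = 3000, N = 12, 50 markers/type (a designed
benchmark scale at which the O(G²) clustering and per-gene NNLS run in
seconds); the noisy model-order study uses K = 4, G = 2000, N = 12,
50 markers/type, σ = 0.05 multiplicative noise, 20 seeds.

What the generator does **not** emulate: between-sample library-size
variation (assumed normalized upstream), correlated gene-gene noise,
cell-type expression profiles that are themselves correlated across
types, batch effects, or count discreteness. Passing tests on these
fixtures therefore demonstrate the geometric machinery — identifiability
under separability, correct vertex detection, consistent model-order
selection under entrywise noise — not robustness to every artefact of
real bulk data. One stress option exists (`near-marker` style
contamination can be mimicked by raising marker count and noise), but
real-data validation is the user's burden.

With dense log-normal background genes, a bystander gene occasionally
lies within any fixed angular radius of a vertex; on noise-free data
the tight validation radius makes the expected contamination ≪ 1 gene
per dataset, but it is not identically zero — marker precision is a
statistical, not deterministic, guarantee at wide radii.

## Numerical choices

- LP equality constraints at HiGHS defaults (~1e-9 feasibility);
  margins clipped into [0, 1].
- Hull oracle: SVD rank cut at 1e-10 relative; intrinsic dimensions 0
  and 1 handled directly (coincident points / segment endpoints).
- Floating-search improvement threshold 1e-15 absolute, with iteration
  guards against oscillation.
- All tie-breaks are total orders (error, then index tuples), making
  every stage deterministic; reruns are bit-identical.
- MDL RSS floor L·1e-12; scale-free because RSS enters as RSS/L.

## Known limitations

- O(G²) memory in clustering (~72 MB at G = 3000 doubles) limits the
  gene count per run; pre-filtering (`min_peak`) is the intended
  mitigation for whole-array inputs.
- The floating search is a heuristic; optimality versus exhaustive
  enumeration is empirical (measured by the acceptance script), not
  guaranteed.
- `radius` and `min_members` remain user-set hyperparameters; no
  automatic calibration is attempted.
- No semi-supervised mode, confidence intervals, batch correction, or
  between-sample normalization.
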