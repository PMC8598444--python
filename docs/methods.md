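# Methods

## Model and statistic

The data model is a d-dimensional lattice (d = 2 or 3) in which each position
either manifests exactly one non-empty *trait combination* — a subset of a
fixed set of t binary traits — or is empty (`None`). Empty covers both "no
spot measured here" and "no trait above threshold": the statistic only ever
counts entries that manifest at least one trait, so the two cases are
operationally identical.

**HTI** of a collection of occupied entries with combination proportions
`p_c` is `−Σ p_c log_C p_c`, Shannon entropy in base `C`. The base makes the
index scale-free in the number of combinations: HTI ∈ [0, 1] with 1 attained
only by the uniform distribution over all `C` combinations. Degenerate cases
are pinned to 0: a single occupied entry, a single positive category, or
C = 1.

**HTA** applies a grid of region size `s` (scalar, broadcast to all axes, or
per-axis for anisotropic grids such as `(8, 8, 1)` vs `(8, 8, 3)` on image
stacks), computes HTI per region, and averages with weights `n_r/n`. Grid
anchoring is at index 0 on every axis; when `s` does not divide the matrix
extent the trailing regions are simply smaller — they are retained, because
dropping occupied entries would bias `n`. Only all-empty regions are
discarded. A region size exceeding the matrix extent is clamped to one region
on that axis, with a warning.

Two conventions for `C` are exposed. `observed` (default) counts the
distinct combinations actually present; it is the convention under which the
deterministic balanced construction attains HTA exactly 1. `full` uses
`2^t − 1`, the cardinality of all non-empty subsets, which is the natural
choice when comparing samples with different observed censuses over the same
trait panel.

## Trait calling

`binarize_median` calls a trait *present* at a spot when its value is
strictly greater than that trait's median over all spots. Ties at the median
are therefore absent — the literal reading of "above the median" — and the
call depends only on ranks, so it is invariant to monotone transforms of a
trait column (log-normalization, CPM scaling, ...). A fixed threshold can be
substituted per trait. Spot coordinates are taken as integer lattice indices
(origin shifted to the per-axis minimum); no geometric re-gridding of
platform-specific spot layouts is attempted.

`resize_nearest` harmonizes label maps of different extents using the
pixel-centre nearest-neighbour mapping `src = floor((i + 0.5)·n_in/n_out)`.
Nearest-neighbour is the only resampling that cannot invent labels, which is
what keeps resized maps valid combination matrices.

## Null model and inference

The null hypothesis is spatial exchangeability of the observed combinations:
labels are rearranged uniformly over the occupied positions, preserving both
the label frequencies and the occupancy mask. Combinations are permuted as
units (not individual traits) so the sample's combination census is invariant
under the null.

Because the mask is fixed, the partition and its weights `w_r = n_r/n` are
identical across permutations. The per-region null moments (μ_r, σ_r) of the
region HTI are estimated from `n_permutations` (default 1000) independent
permutations; permutation i draws from a child stream spawned from
`(seed, i)`, so results are reproducible and order-independent. The
population-form (divide-by-N) standard deviation is used; at 1000 draws the
difference from the sample form is far below Monte-Carlo noise. The
standardized statistic is

    z = (HTA − Σ w_r μ_r) / sqrt(Σ w_r² σ_r²),

treating region HTIs as independent across regions (cross-region covariance
induced by sampling without replacement is ignored; it is O(1/n) for the
region sizes of interest). `p_homogeneity = Φ(z)` tests the lower tail,
`p_heterogeneity = 1 − Φ(z)` the upper, and the overall test doubles the
smaller value (capped at 1). The normal approximation rests on the Lyapunov
CLT and needs enough regions: below R = 30 a warning is emitted but results
are still returned. Regions with a single occupied entry have HTI pinned at
0 under every permutation (μ_r = σ_r = 0); their count is surfaced in the
result bundle because a growing proportion of such regions undermines the
variance growth the CLT argument needs. A rank-based empirical p-value is
available (`empirical_p_values`) as a cross-check; the CLT path is the
primary output because it resolves p-values far beyond the 1/(n_perm+1)
resolution floor.

**Exact moments.** For small regions the null moments under a uniform
cell-state model can be computed exactly: each cell of the region
independently takes one of `2^t` states (every trait present independently
with probability ½, including the empty state), empty cells are excluded
from the counts, the log base is `C = 2^t − 1`, and moments are conditioned
on the region containing at least one occupied cell. For two traits this
yields per-region HTI moments (0.5731, 0.3096) for 2×2 regions and
(0.8334, 0.1698) for 3×3 — 0.57/0.31 and 0.83/0.17 at two decimals. The
implementation aggregates configurations by their state-count vector with
exact multinomial weights, which is algebraically identical to iterating all
`(2^t)^cells` configurations (the test suite keeps a literal brute-force
enumerator as an independent oracle); the capacity guard is nevertheless
expressed in `(2^t)^cells` ≤ 10^7 and steers larger problems to the
permutation estimator. Note the two nulls differ: the permutation null
conditions on the observed census and mask, the cell model does not; on
dense, balanced data they coincide approximately and the `exact` toggle in
the pipeline applies the cell model uniformly across equal-occupancy regions.

## Synthetic data generator

The generators produce the constructions under which every statistical claim
of the package is tested, without external data:

- `random_uniform_map(shape, n_traits, p_present)` — each trait present
  i.i.d. per position; defaults `(32, 32)`, t = 2, p = 0.5, the canonical
  null-map condition. Expected occupied fraction `1 − (1−p)^t` (0.75 at the
  defaults).
- `region_homogeneous_map` / `region_heterogeneous_map` — deterministic
  extremes at a construction region size: every region pure (HTA = 0) or
  every region exactly balanced (HTA = 1). Both use mutually exclusive
  single-trait combinations (C = 2 by default) so exact balance is achievable
  in 64-cell regions; within-region label arrangement is row-major cycling,
  immaterial because HTA depends only on counts.
- `layered_z_map` — a 3D volume with one combination per z-layer: regions
  confined to a layer are pure, regions spanning all layers are balanced.
- `from_permuted` — a null replicate of any map by label permutation.

What the generators do *not* emulate: platform spot geometry (hexagonal
lattices, spot dropout correlated with tissue morphology), spatially
correlated expression noise, and library-size effects. Passing tests on
these maps therefore validate the statistic, its null model and its
calibration — not robustness to platform artefacts, which enter upstream of
this package's input contract (a called label matrix or a preprocessed spot
table).

## Calibration and verified properties

The test suite verifies, at the defaults above (problem sizes chosen to keep
the full suite under a minute of compute):

- exact enumeration reproduces the reference null moments to two decimals,
  and matches a 10^5-draw Monte-Carlo estimate within 3 standard errors;
- type-I error of the doubled one-sided p-value at α = 0.05 over 200 null
  maps (region size 8, 1000 permutations) lies within 3 binomial standard
  errors of 0.05 — the measured rate in development runs was 0.025;
- HTA(2) ≤ HTA(8) ≤ HTA(16) on 100 random fully occupied maps, without
  exception;
- p-values from 100 vs 1000 permutations agree within one order of magnitude
  on a strongly structured map (p ≈ 10⁻⁶ scale). At vastly smaller p the
  comparison is meaningless: log-p scales with z², so a few percent of
  Monte-Carlo error in σ_r alone moves hundreds of orders of magnitude.

One asymmetry is worth knowing: at the deterministic upper bound HTA = 1 the
permutation-null HTI distribution is itself concentrated near 1 and bounded
above, so the upper-tail CLT p-value is small (~10⁻³) but far less extreme
than the lower-tail p of the pure construction (~10⁻²⁰⁰). The rank-based
cross-check confirms no permutation attains the optimum.

## Numerical choices and edge cases

- Entropy terms use the convention `0·log 0 = 0`; proportions are exact
  ratios of integer counts.
- All-empty matrices, all-zero count vectors, and `C` smaller than the number
  of positive categories raise `InputError`; a degenerate null variance
  (single observed combination) raises `InferenceError` rather than emitting
  z = ±∞.
- Result JSON is serialized with sorted keys and no timestamps, so identical
  configurations and seeds produce byte-identical outputs.
- In multi-size runs each region size uses its own permutation stream
  (derived from the user seed and the size index): region structure changes
  the null, so permutations are not shared.

## Limitations

- The CLT p-value degrades for very few regions (coarse grids); the R < 30
  warning flags this, and the empirical permutation p-value is the fallback.
- The permutation null is global: it cannot express locality-preserving
  alternatives (e.g. "mixing at short range only"), and a sample that is
  heterogeneous at every scale is its own null.
- Continuous trait levels are reduced to presence/absence before the
  statistic; graded heterogeneity is invisible.
- `c_mode="full"` is capped at 16 traits (65,535 combinations); beyond that,
  aggregate traits into meta-traits upstream.
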