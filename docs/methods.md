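# Methods

## Pseudotime-informed NMF

The expression matrix Y (genes × cells, non-negative, typically
log-normalized) is transposed internally and approximated as Yᵀ ≈ A X
with A ≥ 0 (cells × r temporal patterns) and X ≥ 0 (r × genes gene
loadings). In piNMF mode the patterns are constrained to the span of a
clamped B-spline basis with non-negative coefficients, A = Φ Cᵀ, C ≥ 0.
Non-negativity of the coefficients is a sufficient (not necessary)
condition for non-negative patterns, chosen because it keeps every block
subproblem a non-negative least-squares problem. stdNMF uses the same
solver with a free A, so any difference between the two modes is
attributable to the temporal constraint alone.

**Spline basis.** Degree 3, 4 interior knots by default, giving
K = n_knots + degree + 1 = 8 basis functions. "Knots" counts interior
breakpoints; the boundary knots are repeated degree + 1 times (clamped).
Interior knots sit at pseudotime quantiles rather than uniform
positions so that each inter-knot interval holds a comparable number of
cells; this keeps the basis well-conditioned when cells crowd one end of
the trajectory. Rows of Φ sum to one (partition of unity), and fitting
requires at least K distinct pseudotime values.

**Solver.** HALS block-coordinate descent. Rows of X and free columns
of A have closed-form non-negative updates; each spline-coefficient row
of C is an exact K-dimensional NNLS solved in Cholesky coordinates of
ΦᵀΦ. Every update is an exact constrained block minimizer, so the
squared-Frobenius objective never increases; the trace is recorded per
sweep. Convergence is declared when the relative objective decrease
falls below `tol` (default 1e-10) or after `max_iter` (default 10⁴)
sweeps. Initialization is elementwise uniform(0, 1] with seed =
base_seed + replicate index; all randomness in the package flows from
explicit seeds and reruns are bitwise reproducible. After convergence
each pattern column is rescaled to unit maximum with the inverse scale
on the matching row of X, which fixes the scale indeterminacy of NMF
without changing A X.

A block can collapse to exactly zero (a "dead" component), a known
behavior of exact HALS when the rank exceeds the structure the data
supports. Dead components are kept in the replicate (the factor shapes
stay fixed) but excluded from consensus pooling: as all-zero vectors
among L2-normalized ones they would otherwise form a spurious,
perfectly tight cluster and inflate the stability score at
over-specified ranks. This is degenerate-component handling; the
optional outlier filtering of far-from-centroid components is available
separately and off by default.

**Consensus.** The r gene-coefficient rows of every replicate are
L2-normalized, pooled and clustered by K-means (k = r, Euclidean,
n_init = 10, fixed seed). Consensus gene loadings are the cluster
centroids; the temporal factor is then refit once by convex non-negative
least squares against the fixed consensus loadings (under the spline
constraint in piNMF mode). Stability is the silhouette of the clustered
component vectors; error is ‖Yᵀ − A X‖_F. Programs are reported in
order of the pseudotime at which their pattern peaks. Clustering in
gene-coefficient space rather than pattern space is a design choice:
gene loadings are the branch-independent identity of a program, while
patterns are tied to the particular cell sample.

**Rank selection.** `rank_sweep` reports silhouette, consensus error
and best-replicate error across candidate ranks. On data with
sequentially activated programs, under-factorizations are themselves
highly stable — at rank 2 every restart finds the same early/late
split, so the silhouette there is ≈ 1. The planted rank appears instead
as the local silhouette maximum above rank 2 (the first rank where all
true programs separate without splitting; rank true−1 is consistently
the least stable) together with the flattening of the reconstruction
error beyond it. Rank choice should therefore balance stability and
error rather than take the global silhouette argmax; the diagnostics
table contains everything needed for that judgement.

**Gene modules.** Each gene's expression is z-scored across the
analyzed cells and regressed (OLS, with intercept) on the r min-max
scaled activation columns; two-sided t-tests per coefficient are
BH-corrected jointly across all gene × program tests, and membership
requires q < alpha (default 0.05) with a positive coefficient. Genes
with zero variance are excluded and reported. Fits are per branch (root
cells plus one branch), mirroring separate analyses of each
differentiation path; `module_overlap` compares two assignments after
pattern-correlation matching and reports the asymmetric percentage of
the reference module recovered.

## Synthetic bifurcating data

The generator plants r = 4 temporal programs on pseudotime uniform in
[0, 1]: a decreasing sigmoid (root identity), an increasing sigmoid
(terminal identity) and bump-shaped transient programs in between
(Gaussian, σ = 0.16; sigmoid steepness 0.09). Curve widths are chosen so
the planted patterns are representable by the default 4-knot cubic
basis — the noiseless fit is then an internal consistency check of the
model class rather than a spline-approximation benchmark. Cells carry
one of two branch labels; programs peaking after the bifurcation point
(0.5) are shifted and damped on the second branch, so branches share
early programs and diverge late. Genes load on one program
(Gamma(2, 1) + 0.2), 10% on two; expression is loadings × patterns
under multiplicative lognormal noise (default sd 0.8 on the log scale,
CV ≈ 0.95, comparable to log-normalized single-cell variability) and
Bernoulli dropout (default rate 0.2, an explicit and controllable
replacement for simulator-specific dropout parameterizations). Defaults
are 1000 cells × 2000 genes.

What the simulator does not emulate: count-level sampling
(overdispersion, library-size variation), batch effects, correlated
noise between genes, doublets, or graded branch assignment around the
bifurcation. Passing recovery tests therefore demonstrates correctness
of the estimator under its own model with realistic marginal noise, not
robustness to every artifact of real single-cell data.

The toy genome generator emits peaks, derived variants (frequencies
drawn above/below the 0.9 threshold, archaic-state flags), archaic
lineage-specific derived positions at a configurable density, target
region sets, random motifs and a reference sequence consistent with the
variants' ancestral alleles. It computes the exact set of regulatory
islands implied by the definition with a deliberately naive brute-force
scan that shares no code with the production caller, so the caller can
be validated against it by set equality.

## Regulatory islands

Coordinates are 0-based half-open everywhere; variant tables use
1-based positions converted on load. The atlas keeps each reference
peak covered at least `min_frac` (default 0.5) of its length by the
union of at least one support set, and appends X/Y peaks from dedicated
sources verbatim (flagged), for reference sets lacking sex chromosomes.
A variant qualifies for an island when frequency ≥ 0.9 (inclusive),
archaic state is ancestral (missing genotypes are conservatively
non-qualifying), the variant itself lies inside an atlas peak (a peak
merely overlapping the window does not qualify), and its centered
window [pos − 1500, pos + 1500) fits inside the chromosome — windows
truncated by chromosome ends are rejected since the definition requires
the full 3 kb — and contains no archaic-derived position. Overlapping
windows merge with pooled member variants, hence "at least" 3 kb.

Gene linkage builds basal-plus-extension regulatory domains: basal =
5 kb upstream / 1 kb downstream of the TSS (strand-aware; unknown
strand treated as '+'), extended in each direction to the nearest
neighboring basal-domain edge, capped at 1 Mb; when neighboring basal
domains overlap, the extension contributes nothing beyond the basal
domain. Curated domains, when supplied, replace the computed domain for
their genes.

The permutation test counts query regions overlapping at least one
target region and redraws each query uniformly on its own chromosome
with its own length (lengths and per-chromosome counts preserved;
overlaps among placed regions allowed — the simplest exchangeable
null). The empirical p-value uses the +1 correction,
p = (1 + #extreme)/(1 + n_perm), so it is never zero. Because the
statistic is a count, p-values are discrete; calibration to a uniform
distribution is expected (and tested) only when the statistic takes
many values, i.e. with enough query regions relative to target
coverage.

## TF binding effects

Motif matrices (JASPAR- or HOCOMOCO-style text, counts or frequencies)
are regularized with a per-position pseudocount of 0.8 split evenly
across bases and renormalized. The match score of an L-mer is the sum
of per-position probabilities, min-max scaled so the consensus scores
exactly 1 and the anti-consensus 0; a constant-score (uniform) motif
scores 1 by convention and is never significant. Match significance is
the exact tail probability of the scaled score for a random background
L-mer (uniform background by default), computed by convolving the
per-position score distributions on a grid of 1e-4 of the score range;
the accumulated rounding is at most half a bin per position. For each
variant, every motif is scanned at all offsets covering the variant on
both strands; the placement maximizing the better allele's score is
kept, an effect is emitted when that allele's p-value passes the
threshold (default 1e-4), one best effect per TF and variant survives
(redundant motifs dropped, ties broken toward larger |Δ|), and BH
correction is applied jointly across the emitted motif × variant tests.
Effects with |Δ| = |alt − ref| in the top quartile are "strong"; a TF
is classed increased/reduced/both by the signs of its strong effects,
with a frequency score of strong over total hits.

## Problem sizes in the test suite

The suite exercises the full-scale synthetic benchmark (1000 × 2000)
where the check is about that scale — noiseless reconstruction,
100-replicate consensus recovery, rank sweeps — and smaller instances
(200–300 cells, 400–600 genes, 15–20 replicates) for multi-seed
comparisons, which we verified behave identically in the quantities
tested. Solver cross-checks against the multiplicative-update oracle
use rank 2 with best-of-restarts objectives on both sides because NMF
has genuine local optima: at higher ranks two correct solvers can
converge to different optima from the same initialization, making
single-run objective comparison ill-posed.

## Known limitations

- The spline constraint assumes programs vary smoothly in pseudotime;
  truly discontinuous switches are blurred to the knot resolution.
- Consensus K-means assumes roughly balanced, convex component clusters;
  rare alternative local optima are averaged into centroids rather than
  reported as separate solutions.
- The OLS module assignment inherits collinearity of temporally
  overlapping activations: power drops as programs overlap, so module
  recall depends on cell count.
- The island caller treats archaic states as given; it does not model
  genotype uncertainty or recompute allele frequencies.
- PWM scoring is the scaled probability-sum score described above;
  numerical agreement with any particular external motif-disruption
  tool's internal score is not claimed.
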