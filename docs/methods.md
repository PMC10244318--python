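# Methods

## Implicit correlation-matrix PCA

Let `X` be the symmetric contact matrix of one chromosome (only the upper
triangle is stored; counts are non-negative, integer for raw maps). After
removing zero-variance rows/columns, each column is standardized with the
population (divide-by-n) standard deviation, and the correlation matrix is
`A = YᵀY` with no `1/n` factor. Both conventions only rescale eigenvalues; the
eigenvectors — the object of interest — are unchanged. With this convention a
pair of perfectly correlated columns contributes eigenvalue mass proportional
to the retained dimension n.

`A` is never formed. Writing `Y = XS − 1rᵀ` (`S = diag(1/σᵢ)`, `rᵢ = cᵢ/σᵢ`),

```
Yx  = (XS)x − (r·x)·1
Ax  = Yᵀ(Yx) = S Xᵀ(Yx) − (c∘S)·Σ(Yx)
```

so each product costs `O(nnz(X))` plus `O(n)` vector work.

**Zero-variance filter.** Removing a row can make another column constant
within the retained submatrix, so the filter is iterated to a fixed point;
column statistics are those of the final square submatrix. A column counts as
constant when its variance is below `1e−12` of its mean square (pure
floating-point rounding). Fewer than two surviving columns is a degenerate
matrix and an error. Excluded bins reappear in all outputs as missing (NaN)
markers.

**Eigensolve.** Power iteration from a seeded standard-normal start vector,
renormalized every step; `λ` is estimated as `‖Ax‖` for unit `x` and the stop
rule is relative residual `‖Ax − λx‖/λ < tol` (default `1e−8`, max 10,000
iterations; non-convergence is flagged, never silent). Deflation
re-orthogonalizes the iterate against *all* previously found eigenvectors at
every step — a numerically robust superset of the single-projection recurrence
— so floating-point drift back into converged directions cannot accumulate.
In a degenerate trailing subspace the eigenvalue estimate still converges even
when the direction does not; both are reported separately (`value_converged`
vs `converged`). When the iterate's residual reaches tolerance inside a
degenerate subspace the vector *is* an exact eigenvector and is reported as
converged; the accompanying error bound is what signals degeneracy. The bound
`‖v − v₁‖ ≤ ‖Av − λ₁v‖ / |λ₁ − λ₂|` is reported whenever `λ₁ > λ₂` (relative
gap above `1e−12`); an exactly degenerate top of the spectrum raises a
dedicated signal instead of returning a number.

Up to four components are exposed — compartment analysis uses the first
principal component, and no analysis in the package consumes more than four.

## Distance normalization modes

The analysed matrix may be, per bin pair at separation `d` with per-distance
mean `e(d)` (zeros included in the mean):

* `raw` — counts as stored;
* `oe` — `obs / e(d)`;
* `pearson` — `(obs − e(d)) / √e(d)` (default for compartment calling).

Pearson residuals variance-stabilize Poisson counts, so every cell enters the
correlation with comparable noise. The subtracted term depends only on `d`,
i.e. it is a symmetric Toeplitz matrix; its matrix–vector product is evaluated
by FFT in `O(n log n)`, and its contribution to column means/variances comes
from two more Toeplitz products. The matrix therefore never densifies and the
`O(n + nnz)` memory contract holds in every mode. The variance filter always
acts on the sparse part, so bins without informative contacts stay excluded.

The default was chosen by measurement on synthetic plaid maps at realistic
desk-scale depth (2,000 bins, 5×10⁵ contacts, enrichment 1.5): PC1 of the
plain O/E correlation recovers ~93.6% of planted compartment signs — a
property of the estimator, confirmed identical with a dense eigensolver —
while PC1 of the Pearson-residual correlation recovers ~99%. `oe` and `raw`
remain available; on distance-decay-free block matrices all modes agree.

## Compartment tracks, intervals, elements

Eigenvector sign is arbitrary per solve, so tracks are oriented against an
activity reference (each chromosome independently, same reference): flipped
when the Pearson correlation over non-missing bins is negative; A is positive
thereafter. A constant reference cannot orient and raises an error.

Compartment intervals are maximal runs of ≥2 consecutive same-sign bins.
Single-bin runs, exact zeros, and missing bins belong to no interval and
terminate runs; intervals are never merged across gaps. Interval sizes are in
bp; the median is the standard order statistic (mean of the central pair for
even counts).

Elements are assigned by the eigenvector value at the bin containing their
midpoint (optionally the mean over covered bins): A if positive, B if below
`−|b_threshold|`, otherwise unassigned. The default threshold 0 reproduces
plain sign assignment; the stringent promoter setting uses 0.001, placing
weakly negative bins in a dead zone rather than in B.

## Gene concordance, profiles, pausing

TSS and TTS are the strand-aware gene ends; each is assigned by plain
eigenvector sign. Genes whose TSS is not in A are excluded from concordance
(the discordance question is conditioned on an active start); TSS-in-A genes
are A/A (TTS in A) or A/B (TTS in B, "discordant"). Discordance fractions per
gene-size class report NaN, not 0, for empty classes.

The TSS-anchored profile averages the eigenvector at fixed distances
downstream of each TSS (strand-aware), each gene contributing only up to its
own TTS so post-gene chromatin never enters the average; the design choice
here is truncation at the TTS rather than a fixed window, because the profile
is meant to describe gene-body compartmentalization. The crossing distance is
the first linearly interpolated zero of the mean profile; a profile that never
crosses reports none.

Pausing index: signal density (units per kb) in the TSS ±250 bp window over
the density in the gene body from 500 bp past the TSS to the TTS (the 3′ end
is included; only the 5′ exclusion is applied). Densities are
length-normalized so library-size factors cancel in the ratio; a silent body
with an active promoter gives an infinite index, a fully silent gene an
undefined one. Pausing tertiles rank genes ≥20 kb by promoter-minus-body
density difference and split the ranks into three equal groups (elongating /
mid / paused), ties broken by stable input order; densities (not raw sums) are
used in the difference, consistent with the index definition.

## Loop radial decay

For each loop, the cells at Manhattan distance `r` from the central
anchor-pair cell form ring `r`; ring means are averaged with equal weight per
loop (not per cell), and absent sparse entries count as true zero-contact
observations. Profiles are normalized to the ring-0 mean; loops with zero
central signal have undefined ratios and are dropped. Windows must fit inside
the matrix and off the diagonal.

Two decay summaries are reported, because both appear in fine-scale loop
analyses: the mean number of kb between successive linearly-interpolated
crossings of the 90%, 80%, … thresholds, and a compounding %/kb rate
`100·(1 − e^slope)` from a least-squares fit of log-ratio vs kb over positive
rings. A profile that never loses 10% is flagged `insufficient_decay` with
rate 0. AUC uses composite Simpson's rule on ratio-vs-kb; an odd interval
count gets a trapezoid tail on the final interval (recorded in the CLI output
metadata). Per-loop AUCs are ranked into five groups of sizes differing by at
most one (quintile 1 = most punctate, 5 = most diffuse); ranking can first be
normalized by the diagonal-decay AUC when loops from maps with different
polymer decays are pooled. The diagonal decay itself — mean count vs
separation normalized to separation 0 — serves as the polymer reference and
feeds the same rate/AUC machinery.

## QC metrics

Coverage: fraction of eligible bin pairs (diagonal included; unmappable bins
excluded from numerator and denominator; optionally restricted to a maximum
separation) with at least one read. Noise: per-row lag-1 Pearson
autocorrelation of the O/E map over a region, averaged over rows with
computable ACF (≥3 entries, nonzero variance), reported as
`(mean ACF − 1)·(−1)` — 0 for smooth rows, 1 for independent noise, 2 for
strict alternation. Subsampling is exact without-replacement sampling of the
contact multiset (multivariate hypergeometric over entries), so a requested
depth is hit exactly and repeated subsampling nests consistently in
expectation.

## Synthetic data: what it emulates and what it does not

The plaid generator draws alternating A/B runs (uniform 4–100 bins at 500 bp:
2–50 kb intervals), sets expected counts to a polymer-like decay
`(d+1)^(−α)` (α = 1 by default; a generic contact-decay exponent, chosen once)
times a same-compartment enrichment (default 1.5), scales expectations to a
target total (default 5×10⁵), and Poisson-samples each upper-triangle cell.
Poisson-per-cell (rather than one multinomial draw) composes cleanly with the
hypergeometric subsampler and differs negligibly at fixture scale. The loop
generator adds Poisson signal `intensity · (1 − rate/100)^(d_kb)` over each
anchor window (diffuse default 6 %/kb; punctate 20–28 %/kb); the `ladder_loops`
helper places anchors with pairwise-disjoint windows so planted decay can be
recovered without cross-contamination between loop tails. The gene generator
lays out genes with planted A→B transition distances (normal, mean 42 kb, sd
8 kb; optionally coupled to pausing class) and a two-level
promoter/body nascent-signal track with class-ordered promoter-minus-body
differences.

These fixtures contain no balancing biases, no TADs, no replication-timing or
copy-number structure, no mappability gaps unless planted, and Poisson (not
overdispersed) counts. Passing tests therefore demonstrate correctness of the
algorithms and their stated statistical behavior under the generative model —
not robustness to every artifact of real Hi-C libraries.

## Study conditions used by the validation suite

* Eigensolver oracle: 50 random sparse symmetric matrices, n ≤ 300, upper-
  triangle density ≤ 0.1, top-4 eigenpairs vs a dense correlation
  eigendecomposition applying the identical variance filter.
* Compartment recovery: the plaid defaults above. Interval recovery is scored
  as boundary recovery — both boundaries of a planted ≥2-bin interval
  reproduced within ±1 bin by same-label called intervals. (Requiring one
  single called interval to match both endpoints is inconsistent with any
  per-bin error rate the sign-agreement check itself tolerates: isolated
  flipped bins split long runs without moving their outer boundaries.)
* Depth sweep: subsampled depths 1–100% of a deep plaid map (2×10⁷
  contacts), 5 seeds, median. The base map is saturated so the smallest
  depth still carries signal — subsamples below the detection threshold have
  noise-floor eigenvector correlations whose ordering is undefined.
* Loop decay: 200 loops per class on a 1-kb ladder, window radius 15 bins,
  center intensity 80.
* Noise-vs-depth: a denser map (400 bins, 2×10⁶ contacts ≈ 25 counts/cell),
  where row smoothness is measurable at full depth; at 0.25 counts/cell the
  lag-1 ACF of any subsample is ≈0 and the depth gradient is undefined.
* Gene crossing: 480 genes of 84–300 kb, so every gene can express its
  planted transition and the planted mean among profiled (discordant) genes
  is the nominal 42 kb; with short genes included, truncation at gene ends
  biases the planted mean itself. Pausing tertiles use the default mixed-size
  set (25–250 kb, 120 genes).

## Known limitations

* Power iteration converges slowly when `λ₁/λ₂ → 1`; the solver reports
  non-convergence honestly but offers no Krylov acceleration.
* Intervals are never merged across single-bin interruptions; at shallow
  depth long compartment intervals fragment rather than smooth.
* The pausing index depends on the exact promoter-window and body-exclusion
  constants; alternative conventions (e.g. TSS-to-+250-only windows) are not
  exposed.
* Inter-chromosomal (trans) compartment calling is not implemented; all
  analyses are intra-chromosomal.
* Coverage and noise metrics assume a single chromosome per matrix; genome-
  wide aggregation is left to the caller.
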