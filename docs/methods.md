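# Methods

## Model and hypothesis

The data are an n × q matrix x, modelled as matrix-normal with independent
rows: `X ~ MN(μ, I_n, σ²I_q)` (spherical case) or `MN(μ, I_n, Σ)` with a
known positive-definite feature covariance Σ. After running k-means with K
clusters, the null hypothesis for a chosen pair of estimated clusters C1,
C2 is that their population means are equal, encoded by the contrast
ν ∈ ℝⁿ with entries 1/|C1| on C1, −1/|C2| on C2, zero elsewhere, and tested
through the statistic `‖xᵀν‖₂` (centroid distance), distributed as
`(σ‖ν‖₂)·χ_q` under the null.

Because the pair was chosen by clustering the same data, the test must be
conditional to be valid. We condition on the *entire clustering path* — the
K sampled initial centroid indices, the initial nearest-centroid
assignment, and every assignment row of the Lloyd iteration up to the
final iteration T — together with the sufficient-statistic directions that
eliminate nuisance parameters. Conditioning on the full path (rather than
only on the final partition) is what makes the event computationally
tractable: the final-partition-only event would require enumerating the
intermediate assignments that could have produced it.

## The clustering run

Lloyd's algorithm is implemented exactly in the form the conditioning event
references: uniform sampling of K data rows as initial centroids, squared
Euclidean nearest-centroid assignment with ties broken toward the lowest
cluster index, within-cluster-mean updates, iterated until the assignments
repeat or `max_iter` (default 300) is reached. The tie-break rule is
arbitrary under the continuous model (ties have probability zero) but must
be identical everywhere the assignment rule is re-evaluated — in the oracle
re-clustering checks it is the same `argmin`.

An empty cluster aborts the run with an error rather than re-seeding: the
centroid-mean weights are undefined for an empty cluster, so the selective
machinery cannot proceed. A run that hits the iteration cap without
stabilizing still defines a valid conditioning event (the p-value
conditions on the realized iterations 0..T, whatever T is) and is flagged
`converged=False` in results.

## The truncation set

Fixing everything orthogonal to the contrast, the conditional distribution
of the statistic lives on a one-parameter family of datasets
`x'(φ)_i = base_i + φ·s_i·v`, where `base = Π_ν⊥ x` is the projection of
the data onto the orthogonal complement of ν, `s = ν/‖ν‖₂²`, and v is the
unit vector along the observed centroid difference `xᵀν`. At
`φ_obs = ‖xᵀν‖₂` the family reproduces x exactly. `base` is written as
`Π_ν⊥ x` rather than the equivalent "subtract the observed component along
v" form because the same expression remains correct in the
known-covariance extension, where v is not the direction of `xᵀν`.

For affine rows, squared distances between two perturbed rows, and between
a perturbed row and a fixed convex combination of perturbed rows, are
quadratic polynomials in φ with closed-form coefficients. The conditioning
event is then

* iteration 0: for every observation i and competitor k, the distance to
  the perturbed row at the originally sampled index of i's assigned initial
  centroid is ≤ the distance to the perturbed row at competitor k's index;
* iteration t ≥ 1: the same comparison against centroids formed with the
  *original run's* assignment weights at iteration t−1 applied to the
  perturbed rows.

Each comparison is a difference of two quadratics — still a quadratic
inequality `aφ² + bφ + c ≤ 0`. There are n·K·(T+1) of them (the k =
assigned-cluster ones are identically zero and are skipped). The feasible
set of each is a union of at most two intervals; the intersection of the
family is computed as the complement of the union of the per-constraint
violation intervals, which needs a single sort of the O(nKT) endpoints.
The set is finally intersected with [0, ∞), the support of the scaled-χ
reference distribution. The observed statistic is always a member; the
implementation verifies this and aborts on numerically degenerate inputs
(e.g. exact ties) rather than returning a wrong region.

Numerical choices: all inequalities are non-strict, so finite interval
endpoints are attained; every constraint is normalized to unit maximum
coefficient magnitude before classification, with coefficients below
1e−10 treated as zero; a convex constraint whose discriminant is a small
negative number is clamped to a double root (it must hold at φ_obs, so the
true solution set is nonempty); interval endpoints are merged within the
same 1e−10 tolerance.

## The p-value

The selective p-value is `P(φ ≥ φ_obs, φ ∈ S) / P(φ ∈ S)` for
`φ ~ (σ‖ν‖₂)·χ_q` and truncation set S. Each interval's mass is a
difference of survival functions, accumulated in log space
(`logsf(lo) + log1p(−exp(logsf(hi) − logsf(lo)))`, combined with
`logsumexp`), so regions far in the tail — where both numerator and
denominator underflow as plain doubles — still yield an accurate ratio.
Where scipy's log-survival itself underflows (χ arguments beyond ≈38), the
leading term of the upper-incomplete-gamma expansion
`sf(x) ≈ x^{q−2}e^{−x²/2}/(2^{q/2−1}Γ(q/2))` takes over. If the region
still carries no resolvable mass (an empty or degenerate region), the
package raises an error pointing at the rejection-sampling estimator
rather than returning 0/0.

The naive p-value is the unconditional tail `P(φ ≥ φ_obs)` of the same
scaled χ distribution; it is reported alongside for comparison but is not
a valid test after clustering.

## Extensions

**Known covariance.** Two procedures are provided, which test different
events and are both legitimate; the choice belongs to the analyst. (1)
*Whiten first*: transform rows by the inverse symmetric square root
`Σ^{−1/2}` and run the spherical test with σ = 1 on the transformed data —
the clustering is then of the whitened data. (2) *Condition directly*:
cluster the raw data; the statistic becomes `‖Σ^{−1/2}xᵀν‖₂` with reference
scale `‖ν‖₂`, and the perturbation direction in data space is
`Σ^{1/2}·dir(Σ^{−1/2}xᵀν)` — the rows remain affine in φ, so the same
truncation machinery applies with no modification beyond the direction
argument (the closed-form leading coefficient simply acquires a
`‖direction‖²` factor). With Σ = σ²I the direct procedure reduces exactly
to the spherical test: identical trace and identical p-values, with the
truncation set expressed in whitened units (scaled by 1/σ); this reduction
is verified numerically in the tests.

**Unknown σ.** The plug-in p-value keeps the truncation set unchanged (the
set does not involve σ) and replaces the reference scale by an estimate:
either the median-based estimator — subtract each column's median, take
the overall median of the squared residuals, normalize by the χ²₁ median
(evaluated from the quantile function at run time, never hard-coded) —
which is consistent when the mean structure is sparse; or the
column-mean-centered RMS with divisor nq − q, which is upward-biased in
the presence of real clusters and hence conservative.

**Estimated covariance.** For data with correlated features and no known
Σ, a ridge-regularized whitening transform `U(Λ + λI)^{−1/2}Uᵀ` from the
eigendecomposition of the sample covariance (default λ = 0.01, sample
covariance with divisor n−1) is provided as a preprocessing operation; the
downstream test then treats the transformed features as spherical, which
is an approximation, not an exact guarantee.

## Synthetic data and what the experiments show

The global-null generator draws i.i.d. Normal(0, σ²) entries — the regime
in which *any* estimated cluster pair satisfies the null, so rejection
rates estimate the selective Type I error. The alternative generator
places three equal-sized clusters at the vertices of an equilateral
triangle with side δ: means `(−δ/2, 0, …)`, `(0, …, 0, √3·δ/2)`,
`(δ/2, 0, …)`. The middle cluster's mean magnitude `√3·δ/2` on a
coordinate orthogonal to the first is the unique choice making all three
pairwise mean distances equal δ. Experiments report, per replicate, all
four p-values (naive, known-σ selective, and the two plug-ins) computed on
one uniformly random cluster pair sharing a single truncation set (the set
is σ-free); replicates aborted by an empty cluster are redrawn and
counted. Detection probability is the fraction of replicates in which both
tested clusters exactly equal true clusters (set equality, not
containment); conditional power is the rejection rate among those
replicates and is reported as missing when none detected.

The generators emulate the homoscedastic Gaussian model the theory
assumes. They do not emulate count-valued, heteroscedastic, or correlated
real data (e.g. raw scRNA-seq counts), so passing calibration tests here
demonstrates correctness of the method under its model, not robustness
beyond it.

Default experiment sizes are desk-scale — 500 replicates at n = 50, q = 2
for calibration and 2,000 replicates per δ at n = 150, q = 10 for power —
chosen so the full suite runs in minutes on one core; larger designs are a
config change. At these sizes the 3-binomial-SE acceptance band around the
nominal level is ±0.029 at α = 0.05.

## Validation strategy

Two brute-force oracles, deliberately independent of the analytic path,
back every core computation: a grid oracle that re-runs the
assignment/update recursion on the perturbed data and checks each
assignment row against the trace, and a rejection sampler that estimates
the p-value by drawing φ from the unconditional scaled χ and keeping draws
whose re-clustering reproduces the path. The tests require exact
truncation-set agreement away from interval endpoints and p-value
agreement within Monte Carlo error, plus closed-form coefficient fidelity
at 1e−8 relative accuracy.

## Known limitations

* The conditioning is on the full iteration path, which is finer than the
  final partition alone; p-values are exactly valid but can be more
  variable (less powerful) than the coarser — and intractable —
  final-partition conditioning would give.
* One run, one initialization: restarts or k-means++ would change the
  conditioning event and are not supported.
* Exact distance ties (zero-probability under the model, possible in
  quantized real data) abort rather than silently choosing a region.
* The plug-in tests are asymptotically, not exactly, calibrated; the
  sample-RMS variant is conservative under strong separation.
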