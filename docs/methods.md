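# Methods

## Decision model

A cell's stimulus discrimination is modeled as a binary hypothesis test
on a scalar response level x (e.g. nuclear NF-κB, arbitrary units): H0 =
stimulus low, H1 = stimulus high, with conditional densities p(x|H0),
p(x|H1) and priors P(H0), P(H1) (default 1/2 each, modeling absent prior
knowledge; configurable everywhere).  The Bayes-optimal rule decides H1
where P(H1)p(x|H1) > P(H0)p(x|H0); ties decide H0 (a measure-zero
convention fixed for reproducibility).  False alarm and miss
probabilities are the H0 mass of the decide-H1 region and the H1 mass of
its complement; the overall error is P_e = P(H0)P_FA + P(H1)P_M.

### Gaussian single-threshold treatment

With Gaussian models, equating the prior-weighted log-densities gives a
quadratic in x.  The package solves it analytically:

- **Equal variances.**  The quadratic coefficient vanishes; the linear
  equation is solved directly, giving the midpoint shifted by
  σ² ln γ / (μ1 − μ0) with γ = P(H0)/P(H1).  This branch is taken when
  the variances agree to 1e-12 relative, for numerical robustness.
- **Unequal variances.**  Up to two real roots exist.  The
  single-threshold treatment returns the root strictly between the two
  means — the density crossing at which P_e is locally (and, over any
  grid between the tails, globally) minimal — and computes
  P_FA = Q((x_th − μ0)/σ0), P_M = Q((μ1 − x_th)/σ1).  The returned
  threshold is verified to equate the prior-weighted densities to 1e-9
  relative.
- **Exact region.**  When σ0 ≠ σ1 the true decide-H1 region is an
  interval or the complement of one.  `decide_h1_region` derives it from
  the roots of the log-likelihood-ratio quadratic and
  `exact_region_error_probabilities` integrates it exactly via Gaussian
  CDFs.  This is implemented in closed form rather than by quadrature —
  exact and fast — with numerical quadrature kept as an independent
  oracle in the test suite.

Orientation convention: hypotheses are labeled so μ1 ≥ μ0.  The pipeline
relabels violating inputs with a logged warning; the low-level
`error_probabilities` raises instead, telling the caller to relabel.

Degenerate geometry: when the fitted distributions are nearly identical
(or a narrow distribution sits inside a broad one near the same mean),
no density crossing exists strictly between the means and a
single-threshold treatment is undefined.  `ml_threshold` refuses with an
explanation; the pipeline then falls back to the exact-region analysis,
which correctly reports P_e ≈ 0.5 for indistinguishable conditions.

### Variance estimator

Condition fits use the unbiased (n−1) sample variance.  At the intended
sample sizes ("hundreds of cells" per condition) the biased and unbiased
estimates differ well below the second decimal of any reported
probability; the choice is fixed purely for reproducibility.

### Joint early/late analysis

Per hypothesis, the (early, late) response pair is modeled as a
bivariate Gaussian built from the two univariate condition fits plus a
correlation ρ.  The correlation source precedence is: an explicit
user-supplied value; otherwise a per-dose Pearson estimate from cells
measured at both time points (requiring ≥3 paired cells); otherwise an
error instructing the user to supply it.  Error probabilities are
estimated by Monte Carlo: draw from each hypothesis' model and count
density-comparison verdicts.  Defaults: 10^6 samples (binomial standard
error ≈ 5e-4 near p = 0.25, below two-decimal precision), mandatory
seed, batched evaluation (250k per batch) to bound memory.  Results
carry sqrt(p(1−p)/n) standard errors and the full provenance (models, ρ
and its source, seed, n).  The decision boundary is never extracted as a
curve for computation — the region is evaluated directly by density
comparison — but a grid utility is provided for contour plots.

Because the early/late correlation is often not identifiable from
unpaired data, `rho_sensitivity` sweeps an assumed ρ (applied to both
hypotheses) across a grid and reports P_FA/P_M/P_e at each value.

### Empirical (distribution-free) mode

Histograms use Freedman–Diaconis binning by default (any
`numpy.histogram_bin_edges` policy is accepted and recorded in the
model).  Thresholds inside bins split the bin mass by linear
interpolation, removing bin-width discontinuities.  The empirical
threshold minimizes the prior-weighted error over all edges of the two
histograms rebinned onto their common (union) grid, ties going to the
lowest edge; disjoint supports yield a separating edge with zero error,
logged because any edge in the gap is equivalent.  When raw samples are
available, thresholds and tail fractions are computed from the samples
directly (candidate cuts at the pooled sample values), avoiding binning
loss entirely; histogram mode exists for pre-binned input.

### Radar reference

The constant-signal-in-noise scenario (amplitude A, noise sd σ, N
samples, sample-mean detector) serves as a pedagogical API and analytic
oracle: the likelihood-ratio test reduces to comparing the sample mean
with A/2, and P_FA = Q(√N·x̄_th/σ), P_M = Q(√N·(A−x̄_th)/σ).  Its Monte
Carlo check exploits that the sample mean is Gaussian with sd σ/√N, so
trials are drawn directly at that scale.

## Synthetic data generator

`generate_dataset` draws long-format tables (cell_id, genotype,
dose_ng_ml, time_min, response) from fully specified per-condition
Gaussians, with correlated per-cell draws at the two time points of each
dose, deterministically under a fixed seed.  The packaged
`tnf_nfkb_scenario` fixture emulates the qualitative structure of
single-cell TNF→NF-κB dose-response data:

- six doses from 0.0021 to 8 ng/mL at 30 min and 4 h;
- early means rising from 0.25 to 0.75 (sd 0.12–0.18), saturating near
  3 ng/mL — early low/high distributions are well separated;
- late means compressed to 0.30–0.55 (sd 0.15–0.20), reflecting
  negative-feedback attenuation of the high-dose response — late
  distributions overlap heavily, so late-only decisions err more;
- an "A20KO" variant with an elevated, broadened low-dose response
  (mean 0.40, sd 0.20 at 30 min) and uniformly elevated late means,
  modeling lost feedback; analyzed with the wild-type threshold, since a
  deficient cell has no way to know its threshold is stale.  For the
  4-hour deficient analysis the default fixed threshold is the
  wild-type 4-hour optimal one (parallel to the early analysis); the
  wild-type 30-minute threshold can be selected instead via
  `fixed_value`.
- per-dose early/late correlations 0.30–0.50, and 500 cells per
  condition ("hundreds of cells") by default.

All fixture means, variances and correlations are synthetic values
chosen once for these qualitative properties; they are not measurements,
and numbers computed from the fixture characterize the fixture, not any
real pathway.  What the fixture's passing tests do show: the estimators
recover known parameters at realistic sample sizes, the closed forms
agree with independent numerical oracles, and the pipeline reproduces
the expected orderings (early < late error; deficient > wild-type
error).  What they do not show: behavior under non-Gaussian response
distributions, dose-dependent non-Gaussian noise, measurement outliers,
or batch effects — real data should be checked against the empirical
mode before trusting Gaussian fits.

## Numerical choices

- Q function via `scipy.special.ndtr` (complement form), exact to
  double precision over the tested range.
- Quadratic roots via the explicit formula; the equal-variance branch
  avoids catastrophic cancellation when σ0 ≈ σ1.
- Bisection/quadrature appear only as test oracles (tolerances 1e-10 in
  x, 1e-8 in probability).
- Monte-Carlo determinism: `numpy.random.default_rng` seeded per call,
  with independent spawned substreams for the two hypotheses; no global
  state.
- Histogram mass renormalized after counting so the sum-to-1 invariant
  holds to 1e-12 exactly.
- Problem sizes used by the shipped validation suites: 500 random model
  pairs against 2000-point grids for threshold optimality; 10^6
  Monte-Carlo samples against ~1400² quadrature grids for the bivariate
  checks; 20 random scenarios at 10^4 cells for parameter recovery —
  sizes at which the statistical tolerances (3 standard errors, 0.01
  absolute) are meaningful.

## Known limitations

- Only two hypotheses (one dose pair) per analysis; multi-dose studies
  are handled as sweeps of pairwise analyses against a reference dose.
- Only two time points in the joint analysis; the machinery would
  generalize but is deliberately not exposed.
- The MATLAB adapter requires an explicit field mapping (variable name →
  dose/time/genotype) because `.mat` archives carry no standard
  condition metadata; it never guesses.
- The empirical mode's threshold search is O(total sample count) per
  pair, fine at single-cell scales.
- The joint analysis assumes the same ρ-structure family (bivariate
  Gaussian) under both hypotheses; copulas or non-Gaussian joints are
  out of scope.
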