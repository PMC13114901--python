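# Methods

## The analysis

The package operationalizes a cross-sectional association study between
DNA-methylation–derived biological age and cumulative physical
performance in adults beyond young adulthood. Its pieces are:

1. a **cumulative physical-performance score** (0–12) summarizing six
   motor tests against normative cutoffs;
2. **methylation matrix preprocessing** (beta/M values, detection-p
   probe QC, quantile normalization, global mean methylation);
3. **linear epigenetic clocks** mapping a beta matrix to biological age,
   and the per-subject delta Δ = chronological − DNAm age;
4. **association statistics**: tie-aware Spearman correlations (overall
   and within tertiles), and a per-CpG regression scan with FDR control;
5. a **synthetic cohort generator** supplying all inputs with known
   ground truth.

## Performance scoring

Every motor test is performed twice; the arithmetic mean of the two
trials is the analysis value. Gait speed is divided by body height
before normative comparison, so gait cutoffs are in m/s per m of height.
Five tests (gait, grip, single-limb stance, 30-s chair stand, 2-min
step) are rated against a normative table of (test, sex, age-band)
cutoff pairs: value < lower → 0, lower ≤ value ≤ upper → 1,
value > upper → 2. Values exactly at a cutoff rate "within" so the
three categories partition the axis. Age bands are whole-year closed
intervals matched by age at last birthday (floor). The dual-task
component is rated by the percent gait-speed reduction relative to the
subject's own usual pace — > 25% → 0, 10–25% (closed interval) → 1,
< 10% → 2 — computed after trial averaging; a small epsilon (1e-9 on
the percent scale) keeps speeds landing exactly on a boundary in the
closed middle category despite floating-point division. Single-limb
stance values are capped at 30 s by the test protocol and the cap is
enforced at record validation. Missing trials are a hard error naming
the participant and test; no imputation is attempted, matching a
complete-case analysis.

## Methylation preprocessing

Betas are β = meth/(meth + unmeth + offset) with offset 100 by
convention; M = log₂(β/(1−β)) after clipping β into [0.001, 0.999],
which keeps M finite and the transform invertible on the interior.
Detection p is the upper-tail normal probability of a probe's intensity
under the background distribution estimated from negative-control
probes. A probe is removed when the fraction of samples with p > 0.01
exceeds `max_fail_fraction` (default 0: one failing sample drops the
probe — the strictest reading; configurable). Quantile normalization is
plain (unstratified): every sample's sorted vector is replaced by the
rank-wise mean of all sorted vectors; within-sample ties receive the
mean of the reference values at their tied ranks, so ties stay tied and
the operation is idempotent. Probe-type–stratified normalization would
require array annotation and is deliberately not implemented. Global
mean methylation is the per-sample mean beta over QC-passing probes,
computed on normalized betas by default for cross-sample comparability;
the pipeline also reports the raw-beta version since either order is
defensible.

## Clocks and calibration

A clock is (intercept, CpG → weight map, calibration). The linear
predictor for a sample is intercept + Σ wⱼβⱼ. Calibration `identity`
reads the predictor as years; `log_linear` applies

    age(lp) = (A + 1)·exp(lp) − 1      if lp < 0
            = (A + 1)·lp + A           otherwise

with adult-age knot A (default 20 years), the exact inverse of the
log-below/linear-above age transform used by several published
blood/skin clocks; it is continuous and strictly increasing. Clock CpGs
absent from the matrix raise an error by default; a `mean_impute`
policy (β = 0.5, count logged) exists for exploratory runs. Published
coefficient sets can be supplied in the same CSV + JSON-sidecar format;
nothing in the package depends on any particular published clock. The
delta is defined as chronological − DNAm age, so a positive delta means
the subject appears biologically younger. Because "±" dispersion
accompanying a mean delta is ambiguous in small cohorts, summaries emit
both the sample SD (ddof 1) and the SEM, labeled. Age-acceleration
residuals (regressing DNAm age on chronological age) are out of scope;
raw deltas are reported.

## Association statistics

Spearman's ρ is the Pearson correlation of mid-ranks. The two-sided p
uses t = ρ√((n−2)/(1−ρ²)) on n−2 df; for n < 10 or |ρ| = 1 the t
formula degenerates, so a permutation p is substituted — exact
enumeration of all n! orderings for n ≤ 7, otherwise 10,000 Monte-Carlo
permutations from a fixed internal seed (results are deterministic;
the +1/(N+1) correction keeps p > 0). Constant input is an error
rather than a NaN.

Chronological age tertiles use fixed boundaries — ≤ 55, 56–64, ≥ 65 —
reflecting conventional pre-older / transition / older adulthood
thresholds; empty groups are allowed. Clock-age tertiles are built by
ranking: base group sizes differ by at most one (larger groups first),
and when a run of tied values straddles a cut the entire run moves to
the later (higher-value) group, so a tie never splits. With all values
tied, everyone lands in group 3 and a warning is emitted. Stratified
correlations run Spearman within each group; groups with n < 3 are
reported as undefined, not fatal.

The DMP scan fits, per CpG, ordinary least squares of the M-value on a
continuous phenotype with intercept (vectorized closed form), t on n−2
df, two-sided p, and Benjamini–Hochberg step-up q across all CpGs in
the input matrix (the multiple-testing family is everything passing
QC). Significance is q < 0.01. M-values are the default regression
scale; a beta-scale scan is available by passing betas. A CpG fitting
perfectly (zero residual) reports t = ±∞ and p = 0; a constant CpG
reports t = 0.

## The synthetic cohort

The generator emulates the study conditions the analysis assumes: by
default 24 participants with age drawn from a truncated normal, mean
58.67 and SD 9.22 on [35, 70], 62.5% female. Each motor test follows a
linear-in-age mean, `baseline + slope·(age − 35)`, truncated to the
test's physical range, with two i.i.d. Gaussian trials per subject —
the simplest model consistent with monotone age-related decline. The
default baselines and slopes were set so the cohort means at the mean
age land near typical values for this population (gait 1.26 m/s ≈ 0.74
height-adjusted, grip 30.8 kgF, SLS 22.4 s under the 30-s cap, 14.3
chair stands, 63 steps). Dual-task gait speed is the normal-pace trial
scaled by 1 − cost/100, with the percent cost drawn per subject from
normal(15.47, 17.94) truncated at zero; the cost is independent of age.
Sex affects only height (and hence height-adjusted gait) and normative
lookup, not methylation.

Normative cutoffs are derived from the generative model itself: per
test × age-band × sex, mean ∓ k·sd at the band midpoint (k = 0.5
default). The default band structure is a single broad adult band
(35–74): anchoring cutoffs at the mid-adult mean leaves the age-related
decline visible in the composite score, which is the regime the
association analysis is designed to detect. Finer (e.g. decadal) bands
progressively age-normalize the score away — with a bounded age range
they can even invert the apparent trend, because everyone in the last
band sits below its midpoint — so band structure is an explicit
argument rather than a hidden constant.

Methylation: β = clip(aⱼ + bⱼ·age + ε, 0.001, 0.999) with
ε ~ N(0, sd). Fifty of 200 CpGs (defaults) are "clock" CpGs whose
slopes bⱼ have magnitude uniform in [0.002, 0.006] per year with random
sign; the rest are flat. Each CpG's level is anchored at the age-range
midpoint with enough margin that the noise-free trajectory never clips
inside the cohort age range. The returned clock definition has weights
wⱼ = 1/(n·bⱼ) and intercept −Σ aⱼ/(n·bⱼ), which makes it the exact
inverse of the noise-free generative model: applied to noise-free
betas it returns every true age to floating-point precision, and
estimation error grows monotonically with the beta noise. If noise is
so large that clipping saturates most of the matrix, a warning is
raised.

What the generator does **not** emulate: raw array intensities and
probe chemistry, batch effects, blood cell-type composition,
probe-type-specific distributions, nonlinear or accelerating functional
decline, and intra-subject trial learning effects (the two trials are
exchangeable). Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and its statistical contracts under a clean
linear-Gaussian world, not robustness to the artifacts of real array
data.

## Problem sizes and numerical choices

The test suite runs the heavier simulations at deliberately modest
sizes chosen once as part of the study design: structure recovery at
n = 200 participants, category coverage at n = 2000, clock recovery at
n = 50 with 50 clock CpGs, and FDR null control at 1000 CpGs × 24
samples × 100 seeds. Tolerances: rank-correlation oracle agreement to
1e-12, OLS t-statistics to 1e-9, quantile-normalization invariants to
1e-12, noise-free clock inversion to 1e-6 years. All randomness flows
from explicit integer seeds; the end-to-end pipeline writes a manifest
(seed, flags, per-stage counts) and reruns are byte-identical.

## Known limitations

- Published per-p-value agreement with any particular statistics
  package is not attempted; small-sample Spearman p-values depend on
  the method (exact, t, permutation) and ties.
- The bundled example clock-age table is rounded to whole years, so
  mean deltas computed from it differ from values computed on unrounded
  estimates; only ordinal statements (which clock has the largest mean
  delta) are stable under rounding, and that is all the package asserts.
- Quantile normalization is unstratified; results on real EPIC arrays
  will differ from probe-type-stratified pipelines.
- The DMP scan fits no covariates (sex, cell composition); it is the
  minimal continuous-phenotype regression.
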