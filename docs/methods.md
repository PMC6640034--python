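# Methods

## Model

Two-sample MR treats each instrument SNP j as a natural experiment. The
generative model underlying both the estimators and the synthetic-data
module is linear on the summary-statistic scale:

    Γ_j = θ·γ_j + α_j

where γ_j is the SNP's effect on the exposure (per allele, exposure in SD
units), Γ_j its effect on the outcome (log-odds), θ the causal effect of
interest (log-odds per SD of exposure) and α_j a direct (horizontally
pleiotropic) effect that bypasses the exposure. Observed effects β̂_xj,
β̂_yj are the true effects plus independent sampling noise with known
standard errors; the two samples do not overlap, so the noises are
independent between exposure and outcome.

* With α_j ≡ 0, every Wald ratio β̂_yj/β̂_xj estimates θ and IVW is the
  efficient fixed-effect combination.
* With directional pleiotropy (E[α] ≠ 0), IVW is biased by
  Σw_jγ_jα_j / Σw_jγ_j²; MR-Egger absorbs E[α] into its intercept and its
  slope remains consistent for θ provided instrument strength is
  independent of the pleiotropic effects (InSIDE) and the γ_j are measured
  essentially without error (see Limitations).

## Pipeline stages and defaults

| Parameter | Default | Meaning |
|---|---|---|
| `p_threshold` | 5×10⁻⁸ | genome-wide significance for candidate instruments |
| `maf_threshold` | 0.3 | folded MAF min(f, 1−f) must strictly exceed this |
| `clump_r2` | 0.2 | known r² above this links variants into one clump |
| `proxy_r2` | 0.8 | minimum r² (strict) for a proxy replacing a missing SNP |
| `palindrome_window` | 0.08 | drop palindromic SNPs with folded EAF within this of 0.5 |
| `ci_level` | 0.95 | all confidence intervals |
| `alpha` | 0.05 | significance level (power module) |
| `case_fraction` | 0.314 | outcome-study case fraction (17 008 / 54 162) |

The MAF filter can be applied to the reported effect-allele frequency
instead of the folded MAF (`maf_on="eaf"`): published instrument tables
are not always explicit about which convention their frequency column
follows, and the packaged table itself contains folded MAFs below 0.3.

Clumping acts only on *known* r²: a pair absent from the LD table is
treated as independent (absence of evidence of linkage is not linkage),
and the package never computes LD from genotypes. Within a clump the
index SNP is the largest |β|; ties break by smaller p, then variant ID, so
the result is a deterministic function of the input set regardless of
input order.

Palindromic (A/T, C/G) variants cannot be strand-resolved from alleles
alone; they are oriented by requiring the effect-allele frequency to fall
on the same side of 0.5 in both studies. The ambiguity window is a safety
margin: within `palindrome_window` of 0.5 (strictly) the comparison is
considered uninformative and the variant is dropped. Setting the window
to 0 disables it, reproducing a purely frequency-based rule.

## Estimators

* Wald ratio: β̂_y/β̂_x with first-order delta SE σ_y/|β̂_x|; the
  exposure-side term (β̂_y²σ_x²/β̂_x⁴ under the radical) is neglected, the
  usual convention when instruments pass genome-wide significance.
* IVW is fixed-effect by default; `random_effects=True` applies
  multiplicative overdispersion max(1, RSS/(m−1)) to the SE. With the 2–4
  instruments typical of cytokine exposures a random-effects variance is
  barely estimable, hence the fixed-effect default. Inference is normal.
* MR-Egger requires m ≥ 3 (two parameters plus at least one residual
  degree of freedom). Exposure effects are oriented non-negative before
  fitting; this is the standard convention, fixing the intercept's sign
  (its magnitude is orientation-invariant). Inference uses the
  residual-scaled WLS covariance with t(m−2).
* A single-instrument IVW is computed in ratio form so that it equals the
  Wald ratio bit-for-bit.

The odds-ratio columns are exp-transforms of the log-odds estimate and CI
bounds; both scales are always emitted.

## Power

The Wald statistic of the IVW estimate is approximately N(√λ, 1) with
λ = n·R²·(log OR)²·K(1−K); two-sided power follows directly and equals α
at OR = 1. `min_sample_size` inverts the power curve for the required
noncentrality (Brent root-finding on the monotone gap) and settles the
integer boundary exactly, so `mr_power(min_sample_size(target)) ≥ target`
while one participant fewer falls short. The approximation treats the
instrument R² as known and the outcome model as a score test on the
log-odds scale — the same regime as the rest of the package.

## Synthetic data

The generator emulates exactly what the estimators consume, and nothing
more: m independent biallelic SNPs, EAF ~ U(0.1, 0.9), true exposure
effects rescaled so the total variance explained Σ2γ_j²f_j(1−f_j) hits a
target (default 0.03, matching the biomarker instrument sets), pleiotropy
α_j ~ N(μ_α, σ_α²) with a configurable correlation to instrument strength
(0 ⇒ InSIDE holds), and observation noise with the standard
summary-statistic SEs: se_x = 1/√(2n_x f(1−f)) for a unit-variance trait
and se_y = 1/√(2n_y K(1−K) f(1−f)) for a log-odds coefficient. Default
sample sizes (n_x = 12 000; n_y = 54 162, K = 0.314) mirror the motivating
cytokine GWAS and the Alzheimer's case-control meta-analysis.

Two deliberate modelling choices:

* Effects are coded for the exposure-increasing allele (γ_j ≥ 0), with
  relative strengths U(0.5, 1.5) before rescaling. Directional pleiotropy
  is only well defined relative to a fixed allele orientation — under a
  random orientation its oriented mean is zero by symmetry — and
  instruments represent SNPs that passed a significance threshold, whose
  effects are bounded away from zero by selection. Allele-coding
  corruptions (swaps, strand flips) then exercise sign handling
  explicitly, with every applied corruption recorded in the returned
  truth object so round-trip tests can assert exact recovery.
* Outcome statistics are generated directly on the log-odds scale from
  the linear model rather than by simulating individual-level case-control
  data. The estimators only ever see summary statistics, so the
  logistic-approximation error is irrelevant to testing their algebra;
  consequently the generator validates estimator correctness, not the
  adequacy of the log-linear approximation to real case-control sampling,
  nor realistic LD structure (only injected satellite blocks), winner's
  curse, or sample overlap.

A single RNG stream per `simulate` call, seeded from the config, draws in
a fixed order (frequencies, alleles, γ, pleiotropy, noise, satellites,
corruptions), making every dataset reproducible from its config alone.

## Numerical choices

* p-values are clipped into (0, 1] (floor 5×10⁻³²⁴) so the record contract
  holds under extreme test statistics; an SE of exactly 0 (possible only
  in degenerate exact-fit inputs) yields p at the floor rather than a
  division error.
* Summary-statistic TSV/CSV round-trips are lossless: writers use
  shortest-repr float formatting and readers parse with round-trip float
  precision, so persisted intermediates reproduce downstream estimates
  bit-for-bit.
* Clump clustering is union-find over the known-r² graph; for small
  instrument sets this is verified in tests against independent
  connected-component enumeration.
* Monte-Carlo suites use 1000 replicates at m = 10–20 SNPs (seconds of
  runtime); recovery is judged against three Monte-Carlo standard errors
  of the replicate mean.

## Known limitations

* **Weak-instrument attenuation.** Measurement error in β̂_x biases
  ratio-based estimators toward the null (regression dilution). At the
  motivating study's scale — total R² ≈ 3% split over 10–20 SNPs with an
  exposure GWAS of ~12 000 — the per-SNP F statistic is ≈ 18–36. IVW is
  attenuated by roughly R²/(R² + m/n_x), under 3% here, which Monte-Carlo
  runs show to be comparable to its Monte-Carlo error at 1000 replicates.
  MR-Egger is far more sensitive: its dilution is governed by the weighted
  *variance* of the instrument strengths (the I²_GX statistic), which at
  these conditions is ≈ 0.6, attenuating the slope by ~40% and pushing
  the displaced signal into the intercept. This is a property of the
  estimator at this instrument strength, not of the implementation: the
  same code matches a generic WLS oracle to 10⁻¹⁰ and recovers slope and
  intercept within Monte-Carlo error when the exposure study is large
  (NOME effectively satisfied). Practitioners should check I²_GX before
  trusting Egger point estimates from weak instruments; SIMEX-style
  corrections are out of scope here.
* The Wald/IVW delta-method SE ignores exposure-side uncertainty, which
  is anticonservative for borderline instruments.
* Proxy substitution assumes the proxy tags the index SNP's signal with
  the same effect orientation; r² carries no sign information, so a proxy
  in strong LD but opposite phase would be mis-signed. Real analyses
  should confirm phase from a reference panel, which this package does not
  consume.
* No liftover: positions are opaque 1-based integers taken verbatim from
  their sources, and are never used computationally.
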