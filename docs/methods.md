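# Methods

This note documents the models, numerical choices and known limitations
of `neurocvr`, in the order the pipeline runs.

## Cerebrovascular risk score

The score is a sum of seven components (range 0–9). All clinical
thresholds are inclusive: measured hypertension requires *both* the
averaged systolic and diastolic readings to reach 140/90 mmHg (a single
reading is used as-is when only one exists); the WHO waist-to-hip
cut-offs are 0.90 (men) and 0.85 (women); the pack-year band [10, 50]
is closed at both ends. Pack-years are (cigarettes/day ÷ 20) × years
smoked, with the exposure window ending at the quit age for ex-smokers
and the scan age for current smokers — ending the window at quit age is
the whole of the "gave up smoking" adjustment; no extra multiplier is
applied because none is specified anywhere authoritative, and the hook
(`Thresholds`, `smoking_points`) is the place to add one. Ex-smokers
without a cigarettes-per-day count (only collected for people who smoked
on most or all days) cannot accrue pack-years and score 0. Measured
hypertension and antihypertensive use are independent components, so a
treated-but-uncontrolled participant collects both points; this
sum-score semantics is deliberate and configurable only by editing the
breakdown. Missing components contribute 0 and are flagged
(`CvrBreakdown.missing`); `on_missing="propagate"` raises instead. A
fully missing record has no score.

## Preprocessing

Reaction-time trials are kept when 50 ms ≤ t ≤ 2000 ms (inclusive;
faster responses are anticipations, slower ones outlived the stimulus).
A participant whose twelve trials are all excluded has a missing
cognitive score. Pairs-matching errors are used as recorded — a count
has no trial filter. Every analysis variable is normalised as
(x − median)/(1.4826 × MAD); the 1.4826 constant makes the scale
estimate consistent with a normal SD and can be set to 1. A zero MAD is
an error naming the column, never a silent pass-through. Total WMH
volume is cube-root transformed before normalisation. Confound
residualisation is ordinary least squares with an intercept; it is
idempotent and leaves residuals orthogonal to every confound column.
The model matrix negates mean reaction time and error counts so the
executive-function (EF) latent is oriented "higher = better", which
makes the network → EF paths positive; a raw orientation is available by
building the matrix by hand.

## Structural-equation engine

Models are held in RAM form: directed coefficients (paths and loadings)
in an asymmetric matrix A, variances/covariances in a symmetric S, and
the implied covariance of the p observed variables
Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ. Identification uses a unit-loading marker
per latent (first indicator fixed to 1); standardised output is
invariant to that convention.

**Estimation.** Covariance ML minimises
F = log|Σ| + tr(SΣ⁻¹) − log|S| − p with analytic gradients
(∂F = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)∂Σ]), L-BFGS-B under variance bounds, then
Newton polishing until the gradient norm falls below 1e−8; three
jittered restarts precede a convergence error. Optimisation runs on the
correlation scale for conditioning and estimates are mapped back, which
leaves F, χ² and the standardised solution untouched. The sample
covariance uses the ML (1/n) denominator so that FIML on complete data
reproduces covariance-ML estimates to machine-level agreement; the test
statistic is reported as χ² = (n−1)·F (the usual Wishart-flavoured
statistic; the two conventions differ only in O(1/n) scaling of the
statistic, not the estimates). Variances are bounded below at 1e−6; an
estimate on that bound is a Heywood case and raises a warning, never a
silent absolute value.

**FIML.** Under missing-at-random data the casewise Gaussian
log-likelihood is accumulated per missingness pattern with free observed
means; the saturated log-likelihood for the χ² comes from an EM fit of
the unstructured mean/covariance, and the independence baseline from
per-variable Gaussian MLEs on each variable's observed cases.

**Fit indices.** CFI = 1 − max(χ²ₘ−dfₘ,0)/max(χ²₀−df₀, χ²ₘ−dfₘ, 0),
TLI = (χ²₀/df₀ − χ²ₘ/dfₘ)/(χ²₀/df₀ − 1),
RMSEA = √(max(χ²ₘ−dfₘ,0)/(dfₘ(n−1))). CFI/TLI are clipped to [0, 1]
for reporting; RMSEA is flagged undefined at df = 0. The ML baseline is
the independence model, whose ML solution is diag(S) in closed form.

**The full structural model** has 13 observed variables, three latents,
10 directed paths, the age↔CVR covariance and two correlated-residual
pairs among the grey-matter indicators (angular gyrus↔precuneus and
superior frontal↔frontal pole by default): 36 free parameters, df = 55.
Correlated-residual pairs are configuration, not search — modification-
index discovery is out of scope, and the defaults are restricted to the
grey-matter block on the structural-covariance argument that those
regions participate in other networks. There are no direct
age/CVR/WMH → EF paths, which is exactly why constraining either
network latent removes four free parameters (three incoming paths plus
one outgoing). Alternative structures load from JSON/YAML specs.

**Effects.** Semi-partial correlation residualises the control out of
the *predictor* only (the WMH side), matching the question "how much of
the lesion–cognition association runs through the network". Mediation
uses closed-form least-squares paths (a; b and c′ from the two-predictor
normal equations) and a percentile bootstrap over case resampling with a
mandatory seed; c_total = c′ + a·b holds to numerical precision on
complete data.

## Window statistics

Sliding windows are contiguous quantile intervals holding a fraction
`frac` (default 10%) of the sorted sample, stepped by 1 percentile — 91
overlapping windows at the defaults. The step is a package choice (the
window width is standard; the literature's dense-slide behaviour pins
the step). Ties are broken by a stable sort on (x, original index);
window centres are window-median x; the band is the per-window
SD/√count. "Gaussian kernel of 10" is interpreted as σ = 10 in
window-index units with edge renormalisation (weights always sum to 1,
so constants are preserved and the smoothed curve never leaves the data
range); an FWHM reading is available via `mode="fwhm"`. Fixed binning
uses ten 16-mmHg bins anchored at min(x) floored to a bin multiple;
empty bins are flagged and excluded, never interpolated. Age
deconfounding assigns participants to ten age-quantile bins (count
configurable; ten is a package default — the bin count is not specified
anywhere) and removes each bin's mean, which makes the correlation of
two residualised vectors a bin-fixed-effects partial correlation.

## Association

Pearson intervals use the Fisher-z closed form
tanh(atanh r ± z₁₋α/₂/√(n−3)) — the upstream interval construction is
unknown and slightly wider, so magnitudes match but interval widths are
a convention here. The two-sample comparison is
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with two-sided normal
p-values throughout; the study-wide significance threshold is p < 0.001.
The risk-factor regression uses the eight-covariate set (waist-hip
ratio, smoking status coded 0/1/2, cholesterol medication, BP
medication, diabetes, APOE ε4 count, age, Townsend deprivation) with
listwise deletion, standardised betas via z-scored variables, and
VIFⱼ = 1/(1−R²ⱼ) from auxiliary regressions.

## Synthetic cohort generator

The generator is the package's study-conditions module: its defaults
*are* the population being emulated, and they are not tuned per-test.

**Ages** come from a truncated normal on [44, 73] whose parent
parameters (≈ N(66.16, 10.74²)) are solved numerically so the
*post-truncation* mean and SD hit 62 and 7 — plain truncation of
N(62, 7²) would undershoot both.

**Risk factors.** Underlying systolic pressure is 137 + 7·z_age + 13·ε
mmHg (two readings add 4-mmHg measurement noise each); diastolic shares
the systolic residual with correlation 0.55. Medication, diabetes and
smoking are probit assignments whose thresholds enforce the marginal
prevalences exactly (22% BP-medicated, 21% cholesterol-medicated, 5%
diabetic, 22% ever-smokers) and whose shared age slope (0.1943) was
calibrated once, by a deterministic 2-million-draw run frozen into the
module, so the population correlation between age and the resulting CVR
score is 0.25. The medication probit also loads on the systolic
residual (treatment tracks established hypertension). The APOE
distribution is 76% ε3/3, 17% ε3/ε4, 2% ε2/ε4, 1% ε4/4, with the
remaining 4% on ε2-containing non-ε4 genotypes (zero score points).
The CVR score entering the structural equations is the actual rule-based
score computed from these raw fields — risk scoring sits inside the
generative loop — standardised by the frozen population moments
(1.537/1.104).

**Structural core.** On standardised scales: Age, CVR → WMH (0.35,
0.13); Age, CVR, WMH → GM (−0.45, −0.07, −0.10); Age, CVR, WMH → WM
(−0.35, −0.01, −0.20); GM, WM → EF (0.32, 0.34). The WMH→GM and
WMH→WM values are package assumptions (the source coefficients for
those two arrows are not available to pin; WMH→WM is set stronger,
consistent with the observation that the CVR→WM path only loses
significance because the WMH→WM path is present). Residual variances
are solved sequentially so every structural variable has unit variance;
inadmissible coefficient sets raise a positive-definiteness error.

**Raw-scale indicators.** Mappings are chosen so the pipeline's
transforms recover *linear* indicators, keeping the injected
standardised coefficients exactly recoverable: WMH volume is the cube of
a Gaussian (15 + 3.8·z on the cube-root scale, in mm^(1/3)), so the
cube-root transform normalises it exactly; the six grey-matter volumes
and two NODDI indices are linear-Gaussian with standardised loadings
0.7 (GM, residual covariance 0.15 for the two correlated pairs) and
±0.8 (ICVF +, OD −). Reaction-time trials are log-normal
(trial σ = 0.18) around a participant mean *linear* in the latent score
(555 − 90·0.49·EF ms plus unique noise), with 2% anticipation and 1.2%
lapse contaminants that the trial filter removes; the between-person
unique SD is solved in closed form so that the trial-level noise and the
filtering's effective trial count are *budgeted inside* the indicator
uniqueness — the standardised loading of the filtered mean RT is 0.49
by construction, not approximately. Pairs errors follow a Poisson-gamma
law (mean 4, overdispersion 0.5) with the count mean linear in EF and
the overdispersion budgeted the same way, giving a 0.25 loading.

**Blood-pressure channel.** To reproduce the sliding-window phenomenology
(graded EF decline with SBP off medication; a plateau below 140 mmHg on
it), EF receives a direct SBP term: −0.16 × standardised SBP in the
unmedicated stratum and −0.10 × standardised max(SBP − 140, 0) in the
medicated stratum. The term is orthogonalised (in-cohort OLS) against
age, the measured-hypertension point and the medication flag before
being injected into the EF *residual* budget, so it cannot leak into any
structural covariance the SEM models — the window curves show the
pattern while every ground-truth path stays exactly recoverable. The
magnitude of the window-curve association measured on factor scores is
attenuated relative to the latent-level strength (factor-score
determinacy is well below 1 with two cognitive indicators); the
generator emulates the *pattern*, not the printed correlation
magnitudes.

**Missingness** is injected per-cell with probability proportional to
exp(0.4·z_age), normalised to the requested average rate — missing at
random given observed age — over the imaging and cognitive columns.

**What passing tests do and do not show.** The generator produces
linear-Gaussian structure (plus the designed count/log-normal
measurement laws) with exact marginals; real cohorts have selection
effects, non-Gaussian tails, genotype–behaviour interactions and
confounding the generator does not emulate. Recovery of the injected
coefficients validates the estimator and pipeline plumbing, not the
substantive claims on real data.

## Problem sizes and test budgets

The law-of-large-numbers check of the implied covariance runs at
n = 400,000 (elementwise tolerance 0.01, Monte-Carlo error ≈ 0.002);
parameter-recovery checks use n = 20,000 cohorts; the full recovery
acceptance check runs 50 seeded replicates (≈ 30 s total — each
generate+fit cycle takes well under a second). At n = 20,000 the
per-replicate sampling SD of the standardised WM→EF path and EF→RT
loading is 0.016–0.018: with only two cognitive indicators at loadings
0.49/0.25 the EF latent is weakly measured, and this is the
information bound of the efficient estimator, so individual replicates
land outside ±0.02 roughly a quarter of the time even though the means
across replicates sit within ±0.007 of the injected truth. The
50-replicate tolerance check documents this; the averaged-recovery test
is the meaningful unbiasedness check.

## Known limitations

- WLSMV/robust estimators, ordinal indicators, multi-group models and
  modification indices are out of scope; correlated residuals are
  declared, not searched.
- FIML gradients are finite-difference; with many distinct missingness
  patterns (every cell independently missing across many columns) the
  fit is correspondingly slower.
- The changepoint at 140 mmHg is descriptive (a generator design and a
  window-curve observation), not formally estimated.
- Mediation assumes linear homoscedastic relations; the bootstrap is
  percentile-only (no BCa).
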