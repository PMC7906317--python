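# Methods

## The problem

Observational studies repeatedly associate low serum 25-hydroxyvitamin D
(25OHD) with autoimmune disease, but confounding (latitude, ethnicity, time
spent outdoors) and reverse causation make those associations hard to
interpret. Two-sample Mendelian randomization (MR) sidesteps both by using
genetic variants as instruments: variant–exposure effects from one GWAS
(25OHD, standardized natural-log scale, n ≈ 443,734) are combined with
variant–outcome effects from an independent case-control GWAS (type 1
diabetes, 9,358 cases / 15,705 controls) to estimate the causal effect of the
exposure on the outcome.

This package implements that full inference chain — harmonization, instrument
selection, four estimators, heterogeneity and MR-PRESSO diagnostics,
confounder-screen sensitivity sets, power, unit conversion — and a
summary-level simulator so every step is testable against known ground truth.

## Model

For instrument j, let β̂_Xj (SE se_Xj) be its per-allele effect on the
standardized log exposure and β̂_Yj (SE se_Yj) its log-odds effect on the
outcome, both on a shared effect allele. Under the instrumental-variable
assumptions each Wald ratio

    θ̂_j = β̂_Yj / β̂_Xj ,   se_j = se_Yj / |β̂_Xj|   (first-order delta method)

estimates the causal log-odds per 1 SD increase of the exposure. The
estimators pool these ratios under progressively weaker assumptions:

* **IVW** — θ̂ = Σ w_j θ̂_j / Σ w_j with w_j = se_j⁻²; fixed-effects SE
  (Σw)^(−1/2). The *random-effects* model multiplies the SE by the
  overdispersion φ̂ = max(1, √(Q/(J−1))), Q = Σ w_j (θ̂_j − θ̂)² (Cochran's
  heterogeneity statistic). φ̂ is floored at 1: underdispersion never tightens
  the interval. Optional *penalized* weights multiply w_j once by
  min(1, 20·p_j), where p_j is the upper χ²₁ tail of instrument j's Q
  contribution, then recompute; this softens the influence of heterogeneous
  ratios without iterating.
* **MR-Egger** — after orienting every instrument so β̂_Xj > 0, a 1/se_Yj²-
  weighted regression of β̂_Yj on β̂_Xj *with a free intercept*. The slope is a
  pleiotropy-robust causal estimate under InSIDE (instrument strength
  independent of direct effects); the intercept estimates the average
  directional pleiotropic effect. Both SEs are scaled by
  φ̂ = max(1, √(RSS_w/(J−2))). I²_GX = (Q_GX − (J−1))/Q_GX, with Q_GX the
  1/se_X²-weighted dispersion statistic of the exposure effects, gauges
  regression dilution (values near 1: the NOME approximation is benign).
* **Weighted median** — order the ratios; at sorted position j the cumulative
  standardized weight is s_j = (Σ_{i≤j} w_i − w_j/2)/Σw; the estimate
  interpolates θ(s) at s = 0.5. Consistent while valid instruments carry more
  than half the total weight.
* **Mode-based estimate (MBE)** — the argmax of a normal-kernel density of the
  ratios with modified-Silverman bandwidth
  h = φ · 0.9 · min(SD, MAD/0.6745) · J^(−1/5); "simple" weighting (unit
  kernels) and φ = 1 is the headline configuration. Consistent when the
  largest homogeneous cluster of instruments is valid, even if a majority are
  pleiotropic. The argmax is located on a 10,001-point grid and refined with
  bounded scalar minimization, so it agrees with a 1e-4 brute-force grid.

Weighted-median and MBE standard errors come from a seeded parametric
bootstrap (default 10,000 draws): β̂_X and β̂_Y are redrawn from normal
distributions at their observed values and SEs, the estimator recomputed, and
the SD of the replicates taken. All intervals use the normal 1.96 quantile —
at J = 69 the t correction is negligible.

Estimates are reported both as θ (log-odds per 1 SD *increase*) and as an
odds ratio per 1 SD *decrease*, exp(−θ), with the interval reflected — the
natural scale for a hypothesized harm of low 25OHD.

### MR-PRESSO

Leave-one-out IVW slopes θ̂₋j define residuals r_j = β̂_Yj − θ̂₋j β̂_Xj and the
observed RSS = Σ r_j². A parametric null redraws β̂*_X ~ N(β̂_X, se_X²) and
β̂*_Y ~ N(θ̂₋j β̂_Xj, se_Y²) and recomputes its own leave-one-out RSS per
replicate. The global p is the plus-one-corrected Monte-Carlo tail
probability of the observed RSS (so it is never exactly 0; 10,000 draws by
default). The outlier test compares each r_j² against its simulated
distribution, Bonferroni-adjusts across instruments, and flags variants at
α = 0.05; IVW is then recomputed without them. The distortion test contrasts
the estimate change after outlier removal with the changes produced by
removing random subsets of the same size. The leave-one-out estimator inside
PRESSO is fixed-effects IVW — it defines the residuals, not the inference.

### Instrument selection and the confounder screen

Candidates must associate with the exposure at p < 6.6 × 10⁻⁹ and have
MAF ≥ 0.5%. The variance a variant explains in the standardized exposure is
2β²f(1−f); set totals simply add (instruments are conditionally independent
by construction of the source GWAS — no LD pruning is done here). Instruments
missing from the outcome GWAS are replaced by LD proxies with r² > 0.7 from a
precomputed lookup table; the best qualifying proxy wins (ties: smaller
outcome p, then lexicographic ID), and proxy effects are used as-is, with no
r² attenuation correction. A proxy must carry records in *both* studies,
since pairing the original's exposure effect with the proxy's outcome effect
cannot be allele-harmonized; otherwise the instrument is reported unresolved.

The confounder screen consumes a phenome-scan export (variant, trait,
category, p). Associations at p < α/J (the exact Bonferroni quotient — 0.05/69
= 7.25 × 10⁻⁴, not its rounded display) are kept, de-duplicated on
(variant, trait) across studies, and tallied per category; each sensitivity
analysis excludes one category's variants (plus a proxies-only exclusion) and
recomputes everything, including the set's r² total. The 14-name category
vocabulary ships as a config file and is deliberately an *input*: mapping
individual traits to categories is curation, not computation.

### Harmonization

Outcome records are oriented onto the exposure's effect allele: identical
labels copy through; swapped labels negate the effect and reflect the
frequency; labels matching only after strand complement are complemented
first (every such variant is logged — multi-cohort exports mix strands).
Palindromic variants (A/T, G/C) cannot distinguish swap from complement by
labels, so they are kept only when both effect-allele frequencies fall on the
same side of 0.5 *and* outside 0.5 ± 0.08 (window configurable); anything
else is dropped as ambiguous. This conservative frequency rule is standard
practice; harmonization is involutive and estimates are invariant to the
incoming allele-coding signs (property-tested).

### Power and units

For a case-control outcome with N subjects, case fraction K, instrument
variance explained R² and detectable odds ratio OR, the approximate power of
the two-sided α-level IVW test is

    power = Φ( |ln OR| · √(N R² K(1−K)) − z_{1−α/2} ),

the one-sided rejection approximation (the symmetric lower tail is ignored;
at OR = 1 the formula correctly returns α/2). With N = 25,063, K = 0.373,
R² = 0.031: 79.7% power at OR 1.23 and 99.5% at OR 1.4. (The source GWAS
sample size is printed inconsistently in places as 24,063; the power
calculation uses 25,063 = 9,358 + 15,705.)

Because the exposure is a standardized *log* concentration, 1 SD corresponds
to different absolute changes at different baselines: Δ = baseline·(e^σ − 1).
σ is calibrated from a single anchor pair — a 40.9 nmol/l change at a
70 nmol/l baseline gives σ = ln(110.9/70) ≈ 0.460 — which then implies
29.2 nmol/l at 50 (insufficiency) and 14.6 nmol/l at 25 (deficiency); the
three published conversions are mutually consistent under this one σ.

## The synthetic-data generator

`simulate_two_sample` emulates the two-sample design at summary level — no
individual genotypes, which keeps the generator exact and fast and matches
what the estimators actually consume:

* EAFs uniform on (0.05, 0.5); per-variant variance-explained shares uniform
  on (0.5, 2), normalized so Σ 2β²f(1−f) equals the 3.1% target *exactly*.
  Bounding the share keeps every instrument genuinely genome-wide significant
  at n = 443,734 (per-variant association χ² = n × variance explained ≥ ~57),
  matching the premise of an already-selected panel.
* se_X = 1/√(2f(1−f)·n) for the standardized exposure; the outcome is
  log-odds with the case-control effective-sample-size approximation
  se_Y = 1/√(2f(1−f)·n_case n_ctrl/n_tot).
* True outcome effects θβ_X + α with α from: none; balanced N(0, σ²);
  directional N(μ, σ²) independent of β_X (InSIDE holds); or an
  InSIDE-violating model correlating α with instrument strength (corr ρ).
* Observed effects add N(0, se²) noise; a configurable fraction of variants
  has its allele coding flipped identically in both studies (betas negated,
  frequency reflected) so the pipeline's orientation handling is exercised.
* Same seed ⇒ bit-identical output; the truth record retains θ, every α_j and
  the realized r².

What it deliberately does **not** model: LD between instruments (the real
panel is conditionally independent), winner's curse in the exposure effects,
sample overlap between the two GWAS, and non-normal effect-size noise.
Passing calibration tests therefore demonstrate correctness of the estimators
under the stated sampling model, not robustness to those additional
real-data pathologies.

## Measured operating characteristics

Computed by the test suite and `scripts/acceptance.py` at J = 69, GWAS-scale
SEs (nothing below is asserted that the code does not recompute):

* IVW-random two-sided size at α = 0.05 under θ = 0: ≈ 0.044 (1,000
  replicates).
* 95% CI coverage at θ = 0.2 (500 replicates): IVW ≈ 0.95, Egger ≈ 0.95,
  weighted median ≈ 0.98, MBE ≈ 1.00.
* Under directional pleiotropy (μ = 0.002, InSIDE) with a null causal
  effect: the Egger intercept averages ≈ 0.002 (recovering μ), the Egger
  slope stays centred on 0, and IVW is biased upward by ≈ μ/E[β_X].
* MR-PRESSO flags a planted 10-SE outlier in ≈ 95–100% of runs and false-flags
  ≈ 0.03 variants per null run (Bonferroni keeps the family-wise rate ≤ α).

The MBE interval is markedly conservative here, and structurally so: with no
true heterogeneity, the spread of the observed ratios is pure sampling noise,
and a parametric bootstrap centred on those noisy observations carries ~√2
times the true ratio dispersion. Linear pooling (IVW) is immune — its SE
depends only on the redrawn noise — but the mode's sampling variability
scales with the local density of ratios, so its bootstrap SE runs ~1.4× the
empirical sampling SD (a normal-scaled MAD of the bootstrap distribution was
measured and is no tighter). This conservativeness is inherited from the
published bootstrap-SE mode estimator, not an implementation artifact; users
comparing MBE intervals with the other methods should expect them to be wide
in low-heterogeneity regimes.

## Numerical and design choices

* Exact Bonferroni quotient α/J, never its rounded display.
* Wald ratio with β̂_X = 0 is an error naming the variant, not a silent drop.
* All-identical ratios give the MBE a zero bandwidth: the common value is
  returned with SE 0 and a warning. If only the MAD is zero (ties at the
  median — e.g. ratios {0,0,0,0.5}), the bandwidth scale falls back to the
  smallest *positive* of {SD, MAD/0.6745} so the density stays non-degenerate.
* Egger requires J ≥ 3 and non-constant β_X (singular design is an explicit
  error); the two-parameter fit itself is closed-form weighted least squares,
  cross-checked against statsmodels WLS in the tests.
* Monte-Carlo p-values all carry the plus-one correction.
* Pipeline seeds for the bootstrap/PRESSO stages are derived from the run
  seed and the *content* (sorted variant IDs) of each instrument set, so
  analyses over identical instruments are bit-identical — e.g. excluding an
  empty category reproduces the full analysis exactly — and the whole bundle
  is byte-reproducible for a fixed config.
* Penalized weighting is exposed as a flag but off for headline runs; whether
  the original analysis applied it to all estimators is ambiguous, so the
  default reproduces the plain versions.
* Problem sizes in the shipped studies: 1,000 null replicates for test size,
  500 for coverage and pleiotropy recovery (bootstraps at 200 draws there),
  200 PRESSO runs at 1,000 simulations each; the analysis drivers use
  reduced rehearsal sizes and the library defaults stay at 10,000.

## Known limitations

Linear effects only (no non-linear MR), no multivariable MR, no Steiger
direction filtering, no correlated-instrument power variant, no live LD or
phenome-scan queries (the package consumes their tabular exports). Findings
on synthetic panels quantify estimator behaviour under the generator's
assumptions; transfer to any particular real dataset depends on those
assumptions holding there.
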