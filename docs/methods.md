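# Methods

This note documents the statistical model behind `medimr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a user auditing results
should know about.

## The two-sample MR model

A SNP j with per-allele effect β_exp,j on the exposure (SE se_exp,j) and
β_out,j on the outcome (SE se_out,j, log-odds for a binary outcome) yields a
Wald ratio r_j = β_out,j / β_exp,j estimating the causal effect θ, valid
when the SNP is a true instrument: associated with the exposure, independent
of confounders, and affecting the outcome only through the exposure. With k
instruments:

* **IVW**: β̂ = Σ w_j r_j / Σ w_j, w_j = 1/se(r_j)², algebraically the
  weighted least-squares slope of β_out on β_exp through the origin with
  weights 1/se_out². Fixed-effect SE is (Σ w_j)^{-1/2}; the default
  *multiplicative random-effects* model inflates it by max(1, √(Q/(k−1)))
  where Q is Cochran's Q, so heterogeneity can widen but never narrow the
  interval. The truncation makes the default test conservative under exact
  homogeneity (empirically ~3.5% rejection at the 5% level); calibration
  statements about the IVW test therefore refer to the correctly specified
  fixed-effect model, which is exact under the null.
* **MR-Egger**: weighted regression of β_out on β_exp with a free intercept,
  weights 1/se_out², after flipping rows so every β_exp ≥ 0 (without a fixed
  orientation the intercept is not identified). The slope estimates θ under
  the InSIDE assumption; the intercept estimates the mean directional
  pleiotropic effect per exposure-increasing allele. SEs are scaled by
  max(1, σ̂), the multiplicative random-effects convention.
* **Weighted median**: the ratio at which cumulative normalized
  inverse-variance weight crosses 0.5 (linear interpolation between the
  bracketing order statistics); consistent while valid instruments carry
  more than half the weight. SE by seeded parametric bootstrap of the
  ratios.
* **Simple/weighted mode**: the maximizer of a Gaussian kernel density over
  the ratios (weights equal or 1/se(r_j)²), bandwidth
  φ·0.9·min(sd, 1.4826·mad)·k^{−1/5} with φ = 1 by default; consistent under
  the plurality-valid assumption. The mode is located on a 512-point grid
  over the ratio range; with zero spread the estimate is the ratio carrying
  the most weight. SE by the same bootstrap.

Wald-ratio SEs use the first-order delta approximation se_out/|β_exp|,
the dominant convention; a second-order option adding the exposure-side
term is available but off by default. p-values use the normal reference by
default (`df_mode="t"` switches to t with k−1, Egger k−2 df); ORs and 95%
CIs use exp(β ± 1.96·se).

## Instrument selection

Candidates require exposure p < 1e-5 (strict inequality; the relaxed
threshold conventional for molecular traits where genome-wide-significant
hits are scarce), then greedy LD clumping: repeatedly promote the remaining
candidate with the smallest p-value and remove candidates on the same
chromosome within ±10,000 kb with r² ≥ 0.001 against it. The window is
two-sided, matching common clumping tools; LD comes from a caller-supplied
correlation matrix (the generator emits one; a plink-style table can be
loaded), never from a remote panel. Instruments then need F ≥ 10, with
R² = 2·MAF·(1−MAF)·β² and F = R²(N−2)/(1−R²); per-SNP N is used when
present, the study-level default otherwise. Ties are always broken by
(p-value, SNP id), making every stage deterministic; audit trails satisfy
|input| = |retained| + |excluded| at each stage.

## Harmonization

Outcome effects are re-expressed for the exposure's effect allele: identical
allele pairs copy, swapped pairs negate. Palindromic SNPs (A/T, C/G) cannot
be strand-resolved from alleles alone; we drop them when the exposure MAF is
≥ 0.42 (or unknown) and otherwise orient by allele-frequency concordance.
The 0.42 cut-off and the frequency-based orientation are standard practice
but conventions nonetheless — the threshold is configurable. Non-palindromic
pairs matching neither orientation are reported as `allele_mismatch`; no
complement-strand rescue is attempted.

## Sensitivity diagnostics

Cochran's Q uses the fixed-effect IVW center (the standard definition) even
when the main fit is random-effects; Q = Σ w_j (r_j − β̂)², df = k−1.
Leave-one-out refits IVW k times. The PRESSO-style test is a
re-implementation from the method's published description, simplified: the
observed residual sum Σ w_j (r_j − β̂_loo(j))² is compared against n_sim
(default 1000) parametric simulations of the ratios around their
leave-one-out fits; per-SNP outlier p-values are simulation tail
probabilities with add-one smoothing ((count+1)/(n_sim+1), never exactly 0),
Bonferroni-corrected by k; the distortion test compares the post-removal
estimate against removal of random same-size subsets. There is no
two-parameter global search as in the original software. Note the smoothing
floor implies outlier detection requires n_sim > k/α (e.g. > 600 at k = 30,
α = 0.05). Degenerate exact fits (zero residual variance in Egger) report
NA p-values with a `degenerate_fit` flag rather than infinite statistics.

## Two-step mediation

α = IVW(exposure→outcome), β₁ = IVW(exposure→mediator) on the exposure's
instruments; β₂ = IVW(mediator→outcome) on the mediator's instruments after
removing any with exposure p < 1e-5. This instrument-exclusion rule is our
operationalization of "conditioning on the exposure" in the mediator→outcome
leg; multivariable MR is deliberately out of scope, and the choice matters:
with mediator instruments that are also exposure instruments, β₂ would be
confounded by the direct path. β₃ = β₁·β₂ and the proportion mediated β₃/α
hold as exact identities in every report; the proportion is not truncated to
[0, 1], and a sign disagreement between β₃ and α is flagged
(`opposite_sign_proportion`) rather than hidden. Inference for β₃ is a
parametric bootstrap — each leg's outcome-side betas resampled from
Normal(β, se), leg estimates recomputed, percentile CI and an add-one
smoothed sign-flip p-value over (default) 1000 replicates. Resampling
summary statistics is the only bootstrap available without individual-level
data; it captures estimation noise in both legs but not instrument-selection
variability.

## Screening, tiers, reverse MR

Each exposure in a screen runs the full pipeline independently; failures
(e.g. no instruments) yield a row with a reason and never abort the screen.
Tiers follow method agreement at α = 0.05: *none* unless the primary IVW
test is significant; *inclusion* if IVW alone is; *strong* for 2–3
significant methods; *very strong* for ≥4. NA p-values count as
non-significant. BH-FDR q-values over the screen's IVW p-values are always
reported; tiering uses raw p-values by default (a config switch re-tiers on
q-values). Because the five methods are computed from the same Wald ratios
they are strongly positively correlated: in a screen with many null
exposures, a null whose IVW p-value fluctuates below 0.05 frequently drags a
second method with it, so occasional spurious *strong* rows are expected
under raw-p tiering — the FDR column is provided exactly for this. Reverse
MR reruns the pipeline with roles swapped (instruments selected from the
outcome at the same 1e-5 default); a forward finding is labelled
`unidirectional` when the reverse IVW p ≥ 0.05 and `reverse_untestable` when
the outcome has no instruments. Per-exposure bootstrap seeds derive from the
screen seed and the exposure id, so output is invariant to input order, and
identical config + seed reproduces screen tables and mediation reports
byte-for-byte.

## The synthetic generator

Summary statistics are simulated directly on the beta/SE scale — no
genotypes. Per-SNP SEs use 1/√(2·MAF·(1−MAF)·N) for a standardized trait;
binary-outcome betas are treated as log-odds with the same approximation
(no prevalence/ascertainment modelling). EAFs are uniform on [0.05, 0.95];
allele pairs are drawn with transition-heavy weights including ~10%
palindromic pairs so the ambiguity rule is exercised. Instrument effects
γ_j ~ N(0, 0.08²) with the default exposure N = 20,000 give typical
instrument |z| ≈ 7, so the strongest instruments comfortably clear p < 1e-5
(about half of a panel's instruments survive selection, as in real molecular
GWAS); `gamma_sign="positive"` folds the effects for scenarios that need a
defined effect direction. Default sample sizes (exposure/mediator 20,000;
outcome 315,000) mirror the scale of protein/metabolite GWAS against a
biobank case-control outcome. The mediator and outcome can carry their own
instrument sets (`n_mediator_instruments`, `n_outcome_instruments`) — needed
for a mediator→outcome leg that survives exposure-instrument exclusion and
for reverse-MR scenarios. Pleiotropic direct effects α_j are balanced
(zero-mean) or directional; directional means are planted relative to the
exposure-increasing allele, because a constant mean on arbitrarily labelled
alleles cancels under the Egger orientation convention and is undetectable
by construction. Gross outliers add ±`outlier_effect` (default
10·pleiotropy_sd) to chosen instruments. LD is equicorrelated within
consecutive blocks: true marginal effects are smeared by the block
correlation matrix and noise is correlated accordingly, and the generator
emits the implied block-diagonal LD matrix. The direct effect θ and
mediation path β₁·β₂ combine to a total exposure→outcome effect
θ + β₁·β₂, exactly, in the ground-truth record.

What the generator does **not** emulate: realistic allele-frequency spectra,
fine-scale LD, case-control ascertainment, sample overlap between studies,
population stratification, or winner's-curse from discovery-replication
designs. Passing tests therefore demonstrate correctness of the estimators
and pipeline under the stated sampling model, not robustness to those
real-data complications.

## Monte-Carlo test design and known calibration limits

Simulation-backed tests use seeded replicate sets sized to run on one CPU in
seconds to a couple of minutes (e.g. 1000 replicates for IVW type-I error,
100–200 for recovery checks, 40–120 for power/robustness rates); tolerances
follow the binomial or Monte-Carlo noise at those sizes. Recovery checks
compare the replicate mean against the planted value within three SDs of the
replicate estimate distribution. Two deliberate scenario choices deserve
emphasis:

* **Egger intercept calibration.** The intercept test is nominally
  calibrated when the 1/se_out² weights match the residual variance. With
  balanced pleiotropic variance comparable to the outcome sampling variance
  the weights are misspecified (the pleiotropic component is constant across
  SNPs while se_out varies with allele frequency) and the test becomes
  anti-conservative — we measure ~7.5% rejection at the 5% level with
  pleiotropy SD 0.005 against outcome-effect SEs of 0.0025–0.006. This is a
  property of MR-Egger weighting generally, not of this implementation.
  Calibration tests therefore use pleiotropy SD 0.001 (well below the
  sampling SEs), and users should treat borderline intercept p-values with
  caution when Cochran's Q indicates substantial heterogeneity.
* **Small systematic biases.** With noisy exposure effects the Egger
  orientation flip occasionally mis-signs weak instruments, attenuating the
  recovered directional intercept by a few percent; the weighted median
  under heavy one-sided contamination carries a finite-sample quantile shift
  of order the ratio SE. Both effects are small relative to replicate spread
  at the tested sizes and vanish as instruments strengthen; they are why
  recovery is asserted against the replicate SD rather than the SD of the
  mean.

## Defaults at a glance

| Parameter | Default | Meaning |
| --- | --- | --- |
| `pval_threshold` | 1e-5 | instrument selection p-value (strict <) |
| `window_kb`, `r2_max` | 10,000 kb, 0.001 | clumping window and r² cut |
| `f_min` | 10 | weak-instrument F cut (F ≥ 10 kept) |
| `palindromic_maf` | 0.42 | ambiguity cut for A/T, C/G SNPs |
| `ivw_model` | random_multiplicative | SE never below fixed-effect |
| `alpha_sig` | 0.05 | significance level for tiers/diagnostics |
| `n_boot` | 1000 | bootstrap replicates (median/mode SE, mediation CI) |
| `presso_n_sim` | 1000 | PRESSO null simulations |
| `mediator_exclusion_pval` | 1e-5 | exposure-association cut in the β₂ leg |

All bootstrap/simulation functions require an explicit seed; there is no
hidden global RNG state anywhere in the package.
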