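# Methods

## Design overview

The pipeline mirrors a summary-statistics MR workflow. Individual-level
data (real or synthetic) enter per-cohort association fits; each fit is
reduced to a cohort summary row (N, estimate, SE, p, direction); rows are
combined across cohorts; and the combined instrument-exposure and
instrument-outcome pairs feed the Wald-ratio and verdict layer. The
packaged fixtures are the per-cohort rows of the four published
score-association tables, so the entire meta-analytic layer can be
exercised — and its headline numbers recomputed — without any
individual-level data at all.

## Scale conventions

25(OH)D is analysed on the natural-log nmol/L scale throughout; all
"beta" values for the vitamin-D trait are ln-nmol/L per allele or per SD
of score. T2D effects are ln-odds-ratios. Printed odds ratios are
converted to ln-OR on ingest (with a provenance flag so files round-trip
on the OR scale), and SEs absent from a table are reconstructed from the
95% CI as `(t(hi) − t(lo)) / (2·1.959964)` with `t = ln` on the OR scale.
The quantile is fixed at 1.959964 rather than 1.96: the difference is far
below printed precision, but pinning it makes CI↔SE round trips
deterministic.

A reporting quirk is preserved deliberately: headline vitamin-D effects
multiply the ln-scale beta by 100 and label the result nmol/L (−0.042 →
"−4.2 nmol/L"). `headline_scale()` returns both that convention and the
exact percent change `100·(exp(β)−1)` so reports can show either.

## Meta-analysis schemes and why two coexist

The estimate columns of the published tables pool by fixed-effect
inverse-variance weighting (IVW); the Z columns are reproduced exactly by
**unweighted** Stouffer combination `Z = Σz_i/√k` of the per-cohort
`z_i = sign_i · Φ⁻¹(1 − p_i/2)` — not by √N weighting, and not by a Wald
Z on the pooled estimate. This was verified numerically against every
printed combined Z before the scheme was frozen (8-cohort disease score:
11.864 vs printed 11.86; the √N-weighted variant gives 12.13). Both Z
schemes are exposed; table reproduction defaults to Stouffer for Z and
IVW for estimates. Heterogeneity (Cochran's Q, I², χ² p) is always
reported but never switches the model: pooling is fixed-effect only,
matching the source analysis.

One transcribed meta row is internally inconsistent: the disease score on
25(OH)D prints (β = −0.0002, SE = 0.0001, Z = −0.212), which implies
β/SE = −2, and recomputation from its own cohort rows gives Z = +0.212.
The fixture keeps the printed values verbatim; `reproduce-tables` prints
the recomputed and printed rows side by side and flags the disagreement.
Nothing quantitative is anchored to that row.

Tail handling: Z from p uses the inverse-normal quantile (scipy `ndtri`
under the hood), accurate to ≥ 6 significant digits down to p ≈ 1e-300 —
the smallest printed cohort p is 3.0e-39, well inside that range — and p
from Z uses `erfc(|z|/√2)`, never `1 − CDF`, so nothing underflows before
|Z| ≈ 38; beyond that p is floored at the smallest positive double to
keep it in (0, 1].

## Allele scores

Scores follow PLINK `--score` semantics with `--score-no-mean-imputation`
as the default: a missing genotype contributes zero to the weighted sum
rather than its frequency-expected dosage `2·EAF` (the alternative is
available). SUM and AVERAGE modes are both retained: after
standardization they coincide on complete data, but missingness breaks
the equivalence, which is exactly when the choice matters. Scores are
standardized to mean 0, SD 1 over non-missing entries, so score-on-outcome
effects read per SD of score — the scale on which the published table
magnitudes are interpreted. Weights are fixed external constants from
published GWAS, not re-estimated in the analysis cohort, avoiding
winner's-curse circularity; `score_weights_from_results` exists for
explicit in-sample sensitivity runs.

## Association fits

statsmodels OLS and Logit supply the numerics behind the module surface.
Conventions: effect-allele dosage coding 0/1/2; complete-case analysis
(missing outcome or missing term value drops the sample, and `n` in every
result counts analysed samples exactly); Wald normal z and two-sided p
(not likelihood-ratio), so Z, p and direction are mutually consistent as
in the printed tables; direction for z = 0 is "+" (arbitrary, documented
tie-break). T2D is included as a covariate in score-on-25(OH)D fits,
matching the source covariate list; BMI is included by default in all
fits (one description of the per-SNP 25(OH)D analysis omits it, but the
main model statement includes it — the covariate list is caller-controlled
either way). Logistic fits converge on relative log-likelihood change
< 1e-8 within 50 Newton iterations; perfect separation is converted to a
typed, catchable error rather than a crash; designs with condition number
above 1e8 record a collinearity warning in the result.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any particular study population:

- **Genotypes**: independent Hardy-Weinberg draws (Binomial(2, q)) at the
  six instrument SNPs. European effect-allele frequencies are fixed
  values inside the reported 0.22–0.32 band (GC 0.28, CYP2R1 0.32, DHCR7
  0.23, IGF2BP2 0.30, TCF7L2 0.30, KCNQ1 0.22); the South Asian preset
  changes only GC to the reported 0.73. No linkage disequilibrium is
  simulated (the instruments are reported to be in linkage equilibrium,
  r² = 0.001).
- **25(OH)D**: generated on the natural-log scale,
  `ln V = baseline + Σβ_j g_j + covariate terms + ε`, `ε ~ N(0, 0.5)`,
  then exponentiated for storage. The residual SD of 0.5 ln-units
  corresponds to the ~50% coefficient of variation visible in the cohort
  descriptive statistics; baselines of 4.0 (≈ 55 nmol/L, European) and
  3.58 (≈ 36 nmol/L, South Asian) reproduce the reported separation of
  cohort means. Preset per-allele slopes: GC −0.091, CYP2R1 −0.039,
  DHCR7 −0.042.
- **T2D**: logistic, `logit P = intercept + Σ lnOR_j g_j + pleiotropy +
  covariate terms [+ causal slope · ln V]`. Preset per-allele ORs: 1.12
  (IGF2BP2), 1.25 (TCF7L2), 1.49 (KCNQ1); the DHCR7→T2D configuration
  uses OR 1.05. A logistic (rather than threshold-liability) disease
  model was chosen because the instruments are defined on the OR scale.
  The intercept is calibrated in closed form (mean-covariate plug-in) to
  a ~10% case fraction; logistic non-collapsibility leaves the realised
  fraction slightly above the target, which is immaterial here.
- **Covariates**: age ~ N(52, 13²) years, sex ~ Bernoulli(0.5),
  BMI ~ N(26.5, 4.8²) kg/m², loosely calibrated to the combined
  descriptive rows; small default effects on both traits (e.g. BMI −0.01
  per kg/m² on ln 25(OH)D, +0.08 on the T2D logit) make covariate
  adjustment non-trivial in tests. UV index, when enabled, is a plain
  Normal per-sample covariate added to the ln-25(OH)D predictor; its
  meteorological derivation is out of scope.
- **Causal paths**: `FORWARD_CAUSAL` sets the 25(OH)D→T2D slope to −0.5
  ln-OR per ln-nmol/L; `REVERSE_CAUSAL` shifts ln 25(OH)D by −0.10 in
  cases. The two are mutually exclusive per run so the generative causal
  direction is never ambiguous; T2D is drawn before 25(OH)D under the
  reverse path and after it under the forward path. Missing dosages
  contribute zero to linear predictors.
- **Determinism**: one seed drives a single `numpy` Generator through
  genotypes and phenotypes; identical parameters and seed give
  bit-identical cohort files.

What the generator does **not** emulate — and what passing tests
therefore do not certify about real data: population stratification and
ancestry admixture, relatedness (one contributing study is a sib-pair
design), LD between instruments, genotyping error, assay differences in
25(OH)D between laboratories, and selection into case-control sampling.

## MR layer

The Wald ratio `β_IV = β_GY/β_GX` with first-order delta SE
`|β_IV|·√(SE_GY²/β_GY² + SE_GX²/β_GX²)` (falling back to `SE_GY/|β_GX|`
when `β_GY = 0`) is the minimal formalization of the qualitative causal
arithmetic in the source analysis — e.g. DHCR7's per-allele −0.042
ln-nmol/L on 25(OH)D and ln(1.05) on T2D give −1.16 ln-OR per ln-nmol/L —
and is labeled an extension in reports. Per-instrument ratios are
first-class alongside the composite because the key finding is
instrument-specific (the synthesis-pathway SNP carries the signal; the
transport and metabolism SNPs do not). No MR-Egger or weighted-median
estimators: with three instruments per direction they are not
identified in any useful sense; pleiotropy sensitivity is delegated to
the simulation scenarios instead.

Verdicts per direction use the Bonferroni-corrected threshold
α = 0.05/8 = 0.0063 (eight tested variables: six SNPs plus the two
traits): SUPPORTED needs instrument-exposure **and** instrument-outcome
p < α; a valid instrument with a null outcome arm is NOT_SUPPORTED; an
instrument that fails on its own exposure renders the direction
INCONCLUSIVE. The composite score decides the direction verdict;
individual instruments that pass both arms are listed in the notes.

A scale caveat for the reverse arm: with a binary mediating trait, the
reverse Wald ratio (score→25(OH)D over score→T2D ln-OR) is attenuated
relative to the generative case shift — a ln-OR of liability is not a
unit change in disease probability — so the reverse analysis is read
directionally (is there any effect?), not as an unbiased magnitude. This
matches how the reverse question is posed qualitatively in the source
design. The preset reverse shift (−0.10 ln-units) is also below detection
power at 50k samples; the verdict-recovery test therefore drives the
direction logic with a stronger configured shift while the preset stays
at the descriptive value.

## Problem sizes in tests and the acceptance script

Desk-scale recomputations (pooled ORs/betas, combined Zs) run on the
8- and 6-row fixture tables in milliseconds. Simulation-based recovery
uses 20 cohorts of 50,000 samples per quantity — enough that the Monte
Carlo SE of the 20-seed mean (~0.0008 ln-units for the GC slope, ~0.6
percentage points for the DHCR7 odds increase) sits inside the stated
recovery bands. The end-to-end forward-causal test uses one cohort of
200,000 samples, sized by a power calculation so the score-on-disease arm
clears the corrected threshold reliably; the null-uniformity check uses
1,000 SNPs at n = 600, where each per-SNP fit is exact enough for a
Kolmogorov–Smirnov uniformity test.

## Known limitations

- Fixed-effect pooling only; substantial I² between cohorts is reported
  but does not trigger a random-effects model.
- The fixtures transcribe printed values at 2–3 significant digits;
  recomputed pooled quantities inherit that precision (e.g. the pooled
  OR recomputes to 1.249 against a printed 1.24 because the largest
  cohort's CI is printed to only three digits).
- Instruments are taken as pre-harmonized; no strand/allele-flip
  reconciliation across files.
- No mixed-model support for related samples.
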