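# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, and what the synthetic
data can and cannot demonstrate.

## Cohort model and eligibility

A cohort is a subject-level table (one row per survey participant) with
demographics, anthropometrics, fasting labs, viral-hepatitis serology,
an ultrasound steatosis grade (`none/mild/moderate/severe/ungradable/
missing`), and the survey-design variables stratum, PSU and weight.
Missing optional values are explicit (`NaN`/`NA`) and survive the CSV
round-trip as empty cells; they are never coerced to zero. Listwise
deletion happens in the eligibility stage, not in the reader, so the
same file can be analysed under different completeness requirements.

Eligibility retains subjects aged 20–74 inclusive with a gradable
ultrasound and no competing cause of steatosis. Exclusion reasons are
evaluated in a fixed order (age, ultrasound, hepatitis B, hepatitis C,
transferrin saturation > 50, excessive alcohol, steatogenic medication,
listwise missingness) and each subject is tallied once under its first
matching reason, so the tally partitions the input and renders as a
flow diagram. Decisions worth noting:

* chronic hepatitis B/C require **both** markers positive (HBsAg and
  anti-HBc; HCV antibody and RNA); missing serology counts as negative
  with a logged warning, because exclusion demands positive evidence;
* the alcohol limit is strict ("more than" 2 drinks/day for men, 1 for
  women, computed as days/year × drinks/day ÷ 365), so exactly 2.0 or
  1.0 is not excessive;
* transferrin saturation is excluded strictly above 50%;
* age bounds are inclusive at both ends.

## Scores and classification

HOMA-IR uses the Matthews formula `glucose[mg/dL] × insulin[µU/mL] / 405`.
Insulin enters the fat-score linear predictor in µU/mL (= mU/L), the
units of its derivation cohort; helpers convert pmol/L insulin (÷ 6.0)
and mmol/L glucose (× 18.0).

Two diabetes definitions are deliberately distinct and both kept: the
Gholam score's (prior diagnosis or fasting glucose **>** 126 mg/dL) and
the fat score's (diagnosis, fasting glucose **≥** 126, or 2-h glucose
≥ 200). Metabolic syndrome is ≥ 3 of 5 criteria (waist > 94/80 cm
m/f strictly, triglycerides ≥ 150, HDL < 40/50 m/f, blood pressure,
glucose ≥ 100 or treated hyperglycemia); the blood-pressure criterion
defaults to `SBP ≥ 130 AND DBP ≥ 85` (or treated), with OR available by
config since the conventional "≥130/85" notation is ambiguous. In the
vectorized path, "treated for hyperglycemia" is proxied by the diabetes
diagnosis flag, the only treatment indicator the data model carries.

The fat-score cutoff comparison is inclusive (≥ 2.122), mirroring the
Gholam rule's explicit "≥"; it is a config flag. All cutoffs,
coefficients and category boundaries live in one versioned
`ScoreConfig` (YAML round-trip), the single source of truth.

Covariate categories resolve ambiguous printed boundaries with fixed
half-open conventions, tested case by case: cholesterol normal ≤ 200 /
elevated (200, 240) / high ≥ 240 mg/dL; CRP normal < 0.3 / mild
[0.3, 1] / significant > 1 mg/dL; C-peptide low < 0.26 / normal
[0.26, 1.03] / high > 1.03 nmol/L; HEI poor < 50 / needs improvement
[50, 80] / good > 80; waist-to-hip at risk at ≥ 0.85 (women) / ≥ 0.90
(men) — the Methods-text orientation of the cutoffs, which the
descriptive text elsewhere swaps; age 20–34 / 35–49 / 50–64 / 65+ (the
4-level split; 3-level analyses can merge the top two).

Classification: NAFLD iff ultrasound grade is moderate or severe; each
method's NASH flag is NAFLD ∧ score-positive; `all3 = hair ∧ gholam ∧
lfs`, `any1 = hair ∨ gholam ∨ lfs`. A positive score without NAFLD
never labels NASH. Labels per method are nash / simple_nafld /
normal_mild.

## Screening composition

`net_serial` and `net_parallel` fold the pairwise identities
associatively over k ≥ 2 tests: serial `SE = ∏SEᵢ`,
`SP = 1 − ∏(1−SPᵢ)`; parallel mirrored. Independence between tests is
assumed — a documented limitation, since scores sharing inputs (AST
appears in two) are positively correlated in practice, which would pull
the true net values toward the single-method ones. A Monte-Carlo test
(10⁶ subjects per arm) verifies the algebra under independence. One
published endpoint (97% parallel net sensitivity) is not reachable from
the published single-method inputs — the high-sensitivity fat-score
variant gives ≈ 99.7% — so only the 98% endpoint from the
lower-sensitivity variant is asserted.

## Survey estimation

All estimators assume a stratified design whose first-stage clusters
(PSUs) are independent within strata, with ≥ 2 PSUs per stratum
(enforced at construction); degrees of freedom are `#PSUs − #strata`.
Variances come from Taylor linearization: per-subject linearized
contributions are totalled per PSU and their between-PSU scatter
estimated per stratum.

* **Prevalence** — Hájek ratio `Σwᵢyᵢ/Σwᵢ`; 95% CI built on the logit
  scale with a t quantile and back-transformed (stays inside [0, 1];
  degenerate p ∈ {0, 1} collapses the CI to a point). The logit scale
  was chosen over plain Wald because survey prevalences here are small.
* **Direct standardization** — `Σ_g std(g) · prevalence(g)` over the
  four age groups. Two standards are bundled: the 2000 US standard
  million and the 1990 census distribution, both renormalized to ages
  20–74.
* **Chi-square** — Pearson statistic on the weighted proportions scaled
  by the subject count, divided by the first-order Rao–Scott mean
  generalized design effect (trace formula over linearized cell and
  marginal variances), referred to χ² on (R−1)(C−1) df. With
  `design_correction=False` (equal weights) it is exactly the classical
  Pearson statistic; a simulation test shows the correction restores
  near-nominal size when both variables share cluster-level random
  effects. Empty rows/columns after weighting are collapsed with a
  warning.
* **Multinomial logit** — baseline-category model (reference:
  normal/mild) maximizing the weighted pseudo-likelihood `Σwᵢ log pᵢ(yᵢ)`
  by Newton–Raphson with step-halving, converged at gradient max-norm
  1e-8 (cap 100 iterations, error on non-convergence); |coefficient| >
  15 triggers a separation warning. Covariance is the design sandwich
  `H⁻¹GH⁻¹` with PSU-linearized score totals; CIs use the t quantile at
  the design df. With equal weights the coefficients agree with the
  ordinary MLE to ≈ 1e-6 (verified against an independent
  implementation). Unadjusted ORs come from single-covariate refits on
  the same listwise-deleted subjects as the adjusted model. No
  multiple-testing adjustment is applied (two-sided α = 0.05),
  matching common practice for descriptive survey tables.

## Synthetic cohort generator

The generator is first-class, tested code; it emulates the structure
the estimators assume.

* **Latent liver state** — exact three-category multinomial logit in
  the configured covariate indicators: NASH-vs-normal log odds equal
  the configured `log(OR)`; simple-NAFLD-vs-normal gets half that log
  odds (a plausible monotone gradient); intercepts are solved
  numerically so marginal class frequencies hit `latent_prevalence`.
  Because the fitted model can be exactly the generating model,
  parameter-recovery tests are sharp. Defaults: prevalence (0.80,
  0.12, 0.08) and a Mexican-American vs White OR of 1.6, the magnitudes
  a US population cohort of this era suggests.
* **Labs** — conditionally log-normal (insulin, transaminases,
  triglycerides, CRP) or Gaussian (glucose, pressures, waist, HDL) per
  latent class, with class shifts sized so each score's sensitivity and
  specificity against the latent label are strictly inside (0, 1) —
  scores are informative but imperfect, as in real data.
* **Ultrasound** — moderate/severe for latent NAFLD/NASH, none/mild
  for normal, flipped across the NAFLD boundary at a misgrading rate
  (default 0.02).
* **Design** — configurable strata × PSUs (defaults 14 × 2, an
  NHANES-like public-use layout), every cell guaranteed non-empty;
  weights i.i.d. log-normal normalized to mean 1 with configurable CV
  (default 0.5) — strictly positive, non-informative by construction.
* **Exclusions and missingness** — states that trigger eligibility
  exclusions are injected only via explicit contamination rates
  (defaults between 0.004 and 0.03 per reason, so a 10,000-subject run
  loses roughly 10% before listwise deletion); natural draws never
  cross those thresholds, so a zero-contamination configuration passes
  the screen untouched. Optional covariates go missing independently at
  `missingness_rate` (default 0.02).

What passing tests on this generator do **not** show: robustness to
informative weights (weights correlated with outcomes), to
within-cluster outcome correlation beyond what covariates induce, to
correlated score errors, to measurement error in labs, or to real
NHANES variable quirks. The generator is a correctness harness, not a
population model.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 1,000–50,000 subjects and up to
100 seeded replicates — sizes at which binomial/asymptotic tolerances
(3 SE bands, 90–99% coverage windows) are meaningful while the whole
suite stays fast. Monte-Carlo checks of the composition algebra use 10⁶
subjects per arm. All randomness flows from explicit integer seeds
(numpy `default_rng`); reruns with the same config and seed are
byte-identical. Newton fits start from zero coefficients; the softmax
subtracts its row max before exponentiation; likelihood terms are
floored at 1e-300 before logging.

## Known limitations

* Serial/parallel net performance assumes independent tests (above).
* The first-order Rao–Scott correction matches the mean of the
  eigenvalue distribution only; second-order (Satterthwaite) matching
  is not implemented.
* The weighted multinomial treats weights as fixed design weights;
  replicate-weight (jackknife/BRR) variance is not implemented.
* No imputation: the pipeline is listwise-deletion only, as configured
  through `required_fields`.
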