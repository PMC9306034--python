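# Methods

This note documents the models and procedures behind `peslink`, the
assumptions they make, and the choices taken where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The linkage problem

An anonymous inpatient-experience survey carries no patient identifier,
only routinely recorded attributes of the rated admission. The
admissions register carries the same ten attributes per episode plus a
pseudo patient ID. Deterministic linkage declares a survey row linked
when **exactly one** episode row agrees with it on all ten fields —
age (years), sex, residence district, admission source, admission month,
discharge month, admission specialty, discharge specialty, discharge
hospital and length of stay (nights). Equality is exact after
canonicalization: no fuzzy tolerance on age or length of stay, no
probabilistic (Fellegi–Sunter) scoring, no blocking heuristics. A survey
key hitting several episodes (one-to-many, 1:M) is set aside — a unique
person cannot be established — and a key hitting none is unmatched.

Two policy details the survey-side classification cannot express:

* **Reverse multiplicity.** If one episode is the unique candidate of
  two or more survey rows, one person would have to be several
  respondents. All involved survey rows are demoted to 1:M, and the
  demotions are logged separately so their effect is auditable. (On the
  synthetic data, where each surveyed patient contributes one survey
  row copied from a real episode, demotions essentially never fire.)
* **1:M rows stay in the diagnostics denominator** but are excluded
  from every outcome analysis.

## Outcomes

The outcome is patient-level and binary: any admission whose admission
month equals the calendar month following the **discharge** month of the
index admission (the survey samples discharges, so readmission after
discharge is the construct; a December index looks into January of the
next year). The data carry months only, so 28/30-day windows are
impossible by construction; this is a documented limitation of the
monthly design, not of the implementation. Flags are classified by
admission source — A&E (unplanned) and outpatient referral (planned) —
and may overlap when a patient re-enters through both routes. Sources
other than those two count toward the any-department flag only; per-source
counts are exposed so users can audit the overlap. The outcome scan runs
over the **unfiltered** admissions table, because the linkage-candidate
filter (discharges October–December) would hide January readmissions.

Covariate bins: age 45–54 / 55–64 / 65–74 / 75+; length of stay 1–3 /
4–7 / 8+ days (the bins must partition, so a 7-night stay is in the
middle bin); discharge specialty grouped Medicine / Surgery / Oncology /
Others via a configurable dictionary (geriatrics, cardiac care and
infectious disease fold into Medicine; the eight minor specialties into
Others).

## Statistical layer

* **Crude odds ratios** use the Woolf construction: OR = ad/bc with
  SE(log OR) = √(1/a + 1/b + 1/c + 1/d) and CI = exp(log OR ± 1.96·SE).
  Hand-derivation from the published descriptive cells reproduces the
  published intervals exactly, which is why no exact or profile CI is
  offered. Zero cells raise an error unless the Haldane–Anscombe +0.5
  correction is explicitly requested (and is then flagged in the output).
* **Pearson χ²** is Σ(O−E)²/E with margin-product expectations and
  df = (r−1)(c−1), deliberately without continuity correction (the
  published length-of-stay statistic, 27.5, is only reproduced without
  it); the tail probability comes from `scipy.stats.chi2`.
* **Linkage-bias diagnostics** compare an evaluative score between
  matched and non-uniquely-matched respondents via a 2×k table and the
  same χ². The 5-level quality rating uses its native levels (df 4). The
  binning of the 0–10 experience score is not determined by the emulated
  study's reported shape beyond df = 6, so it is configurable; the
  default splits at {≤4, 5, 6, 7, 8, 9, 10} (7 categories, df 6).
* **Logistic regression** is fitted by Newton/IRLS, initialised at zero,
  converging when the relative log-likelihood change drops below 1e-10
  (max 100 iterations). The covariance is the inverse observed
  information; Wald 95% intervals are exp(β ± 1.96·SE). Reference levels
  are fixed: male, age 45–54, LOS 1–3 nights, no CSSA, Others specialty,
  low evaluative score (quality below "good"; experience score < 8, the
  published median). Perfect separation (diverging linear predictor with
  error-free classification, or |β| > 30) raises an error instead of
  reporting estimates; rank-deficient designs raise an error naming the
  collinear columns. Because which pseudo-R² the emulated study reported
  is not stated, both McFadden (1 − ℓ/ℓ₀) and Nagelkerke are always
  reported. The statistic weights per working-response iteration are
  floored at 1e-10 to keep the normal equations solvable near the
  boundary.

Two identities anchor the implementation and are asserted in tests: a
single-binary-covariate logistic fit reproduces the crude OR and Woolf CI
of the underlying 2×2 table to at least six significant figures, and the
2×2 Pearson χ² equals the squared two-proportion z statistic.

## The synthetic cohort generator

The generator emulates the study conditions end to end: ~10 000 patients,
seven hospital clusters, eighteen residence districts, survey window
October–December 2013 with a January 2014 look-ahead month, survey
sampling fraction 0.33, CSSA welfare prevalence 0.13, male fraction
0.526, a 45+ age component with median ≈ 65 and IQR ≈ 56–76 plus a ~22%
younger component (so the age-45 filter has work to do), a geometric
length-of-stay distribution (p = 0.20), and a two-response experience
model — a shared standard-normal latent drives both the 5-level quality
rating (marginal 77.5% in the top two levels) and the 0–10 score
(Gaussian with mean 8.10, SD 1.53, correlation 0.6, rounded and censored
to the scale).

**Outcome models.** Surveyed patients' episode histories realise three
configured logistic models over the model covariates (sex, age band, LOS
band, CSSA, specialty group, high quality rating). The A&E and
outpatient flags are drawn from their own models; a residual
"other-source" probability is chosen per patient so that the union
matches the any-department model wherever feasible. This mirrors the
overlap structure of real source-specific counts and keeps all three
models simultaneously (A&E and outpatient: exactly) true, so parameter
recovery is well-posed. Slope defaults are the published adjusted odds
ratios; the intercepts are calibrated so the model-implied *marginal*
rates under the default covariate mix equal the published readmission
rates (23.8% any, 8.3% A&E, 16.7% planned) — the published intercepts
and published marginal rates cannot both hold under any covariate mix
near the published margins, and the marginal rates are the
better-determined quantity.

**Key density.** With ten exactly matching fields, a realistic
one-to-many share requires the admissions table to be much denser than
the surveyed patients' own trajectories. Non-surveyed patients therefore
carry a heavier background admission process (1 + Poisson(4.5) episodes
across the window), emulating the heavy-utiliser tail of an elderly
admissions extract. Background patients never enter the survey, so they
add key collisions without touching the outcome models. Identifier
distributions (district decay 0.55ᵏ→0.45ᵏ per rank, district-to-cluster
hospital loyalty 0.97, concentrated specialty codes, A&E-heavy sources,
front-loaded admission months) were tuned once, by brute-force
key-frequency counting at n = 10 000, to put the 1:M share in the
0.25–0.45 band; the realised share is ~26–28% across seeds.

**What the generator does not emulate, and what that means for tests.**
Keys are copied from the generating episode, so they are never
corrupted: the synthetic unmatched fraction is zero and the matching
rate (~73%) exceeds the ~62% of real data, where transcription
discordance (e.g. survey age recorded at interview rather than at
admission) creates unmatched rows. Tests that need unmatched cases
perturb keys explicitly. Telephone non-response, item-level
questionnaire structure, diagnosis-code realism and day-level timing are
out of scope. The realised share of experience scores ≥ 8 is ~0.65
rather than the published 0.746: a censored Gaussian cannot match the
published mean, SD and tail share simultaneously, and the moments were
kept. Consequently, passing tests demonstrate correctness of the
machinery and recoverability of the generating models — not that the
generator reproduces every marginal of the real cohort.

**Determinism.** All randomness flows from the single config seed
through named `numpy` child streams (population, admissions row order,
survey row order); identical config + seed reproduces every emitted file
byte for byte. Survey IDs are salted hashes of the pseudo ID, which
keeps the ground-truth oracle reconstructible without leaking a linkable
identifier into the survey schema.

## Pipeline sizes and runtime

Default problem sizes were chosen so a full run stays interactive on one
CPU: 10 000 patients ≈ 40 000 episodes generate in ~4 s, and the whole
pipeline (generation through model tables) completes in seconds. The
test suite uses a 10 000-patient cohort for calibration checks, a
400-patient cohort (≤ 200 eligible survey rows) for quadratic-oracle
comparisons, and n = 5000 simulated observations for the 3-SE
parameter-recovery check.

## Known limitations

* Monthly resolution only; no 28/30-day readmission definitions.
* The any-department generator model is exact only where the
  source-model union does not already exceed it (the residual
  probability is clipped at zero); empirically the discrepancy between
  realised and model-implied any-department rates stays within binomial
  error, which the suite asserts.
* Exact-equality linkage is brittle to any identifier discordance; the
  package deliberately offers no fuzzy fallback, matching the method it
  implements.
* The 1:M mechanism (which identifier drives collisions) is a modelling
  choice exposed through the config, not an estimate from real data.
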