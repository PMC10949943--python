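# Methods

## Scores

**Revised Tokuhashi score (RTS).** Six parameters, each a small ordinal
lookup: general condition (Karnofsky bands 10–40 / 50–70 / 80–100 % → 0/1/2
points), extraspinal bone metastasis foci (≥3 / 1–2 / 0 → 0/1/2), vertebral
body metastases (same bands), internal-organ metastases (nonremovable /
removable / none → 0/1/2), primary site (six groups, 0–5 points: lung-type
primaries 0 … thyroid/breast/prostate/carcinoid 5), and palsy (Frankel A–B /
C–D / E → 0/1/2). Total 0–15, banded 0–8 / 9–11 / 12–15 into low / moderate /
good life-expectancy categories (< 6 months / ≥ 6 months / ≥ 1 year).

**Modified Bauer score.** A count (0–4) of favorable criteria: no visceral
metastases, primary not lung cancer, favorable primary (breast, renal,
lymphoma, myeloma), single skeletal metastasis. Lung and favorable primaries
are mutually exclusive by construction and the validator enforces it.

**NESMS.** Three components: modified Bauer ≥ 3 (2 points in the printed
component table, 0 otherwise), independent ambulation (1 point), serum
albumin ≥ 3.5 g/dl inclusive (1 point). The published score ranges 0–3,
yet the printed 2-point Bauer weighting makes the raw maximum 4. We honor
both printed artifacts: the default `two_point_clamped` weighting keeps the
2-point lookup and clamps the total at 3; an alternative `one_point`
weighting assigns 1 point, giving a 0–3 raw sum with no clamping. Which
convention the original analysis used is not resolvable from the published
description; the choice is exposed as `bauer_weighting` everywhere a score
is computed.

**Combined score.** `combined = clamp(RTS + a, 0, 17)` with adjustment
a = −2, −1, +1, +2 for NESMS 0, 1, 2, 3. The lower clamp only engages for
RTS 0–1 with NESMS 0–1 and never changes the (low) band. Bands are closed
intervals 0–8 / 9–12 / 13–17 → low / moderate / good, with predicted
survival < 6 months / ≥ 6 months / ≥ 1 year. The combination is monotone
non-decreasing in both arguments (checked exhaustively in the tests).

## Synthetic cohorts

The patient-level data behind the combined score's published evaluation are
not available, so the generator builds cohorts that match the published
*structure* and nothing more:

- **Categorical marginals.** Defaults are the published counts for a
  64-patient cohort (e.g. extraspinal foci 4/19/41 across ≥3 / 1–2 / 0;
  primary-site groups 27/2/0/18/2/15), plus the cancer-type mix, sex split
  and age moments (mean 64.8, SD 13.3 years, clipped to 18–99).
  `exact_counts` mode permutes each column's exact counts so every seed
  reproduces the marginals exactly; `multinomial` mode samples each column
  i.i.d. from the normalised counts and supports any n.
- **Independence.** Only marginals are published, so columns are sampled
  independently; no correlation between, say, performance status and palsy
  is modelled. This is the generator's most consequential simplification:
  real cohorts correlate these strongly, so absolute accuracy and R² levels
  measured on synthetic cohorts characterise the pipeline, not the clinical
  scores. A joint-structure hook (user-supplied sampler) is the natural
  extension point.
- **Derived consistency.** Each record's Bauer flags are deterministic
  functions of its sampled categories: visceral metastases ⇔ organ
  metastases present; lung flag ⇔ the lung-type primary group; favorable
  flag ⇔ the kidney/uterus or thyroid/breast/prostate groups (disjoint from
  lung, so the exclusivity invariant always holds); single skeletal
  metastasis ⇔ no extraspinal foci and 1–2 vertebral lesions. Every
  generated record therefore passes the scoring validators.
- **Unpublished component marginals.** Ambulatory independence and albumin
  distributions are not reported anywhere we can cite. Defaults:
  P(independent) = 0.906, mirroring the incomplete-palsy fraction as the
  closest printed analogue, and P(albumin ≥ 3.5) = 0.5 with a half-normal
  spread of 0.4 g/dl on either side of the threshold. Both are `CohortSpec`
  fields and should be treated as assumptions, not measurements.

**Survival model.** Survival in stratum s (the patient's NESMS total) is
piecewise exponential with constant hazards on [0, 6), [6, 12) and
[12, horizon) months, inverted in closed form from the published mortality
fractions (m6, m12, m_overall) per stratum — e.g. 27 % / 48 % / 60 % for
NESMS 2:

- λ₁ = −ln(1 − m6)/6
- λ₂ = [ln(1 − m6) − ln(1 − m12)]/6
- λ₃ = [ln(1 − m12) − ln(1 − m_overall)]/(horizon − 12)

A mortality of 100 % (the NESMS-0 stratum at one year) has no finite-hazard
representation, so fractions are capped at 1 − ε with ε = 0.001 (12-month
survival 0.1 %, clinically indistinguishable from certain death). "Overall"
mortality carries no stated time point; we read it at a configurable
horizon, default 24 months, used only for the tail hazard. Sampling is by
inverse transform on the cumulative hazard; draws beyond the horizon are
administratively censored there (the only censoring mechanism modelled —
the real cohort's follow-up pattern is unknown). One master seed drives the
generator; covariates use one sub-stream and each patient's survival draw
its own deterministically spawned sub-stream, so cohorts are byte-identical
across runs and independent of draw order. Day-denominated inputs convert
at 30.4375 days/month.

## Validation

**Band accuracy.** Each prognosis band makes a falsifiable claim: low —
death before 6 months; moderate — survival ≥ 6 months; good — survival ≥ 12
months. A patient is graded only against their own band's claim (a good-band
patient surviving 13 months is one accurate case, not two). Right-censoring
makes some claims undecidable: a record censored before its band's threshold
is excluded from numerator and denominator under the default `exclude`
policy; `count_as_accurate` / `count_as_inaccurate` bound the answer from
both sides, and reports carry all three tables. A record censored at or
after the threshold is known to have survived past it and is graded
normally. Accuracies are emitted at full precision plus 1- and 2-decimal
roundings.

**Kaplan–Meier.** A from-scratch product-limit estimator: at each distinct
death time t, S ← S·(1 − d_t/n_t); censored times shrink the risk set
without a step, and deaths precede censorings at tied times (the standard
convention). The implementation is cross-checked against `lifelines` to
10⁻¹² on random fixtures in the test suite; `lifelines` is a test-only
dependency.

**Score-vs-survival regression.** OLS of observed survival months on the
score (via `statsmodels`), reporting slope, intercept, R² and the 95 %
confidence band for the conditional mean at each distinct score value
(prediction intervals behind a flag). Observed time enters regardless of
event status — the convention the published scatter analyses follow — which
biases fits downward when censoring is heavy; reports should be read with
that caveat. Fits require ≥ 3 distinct score values. `compare_scores` runs
the fit for the RTS and the combined score on the same cohort and reports
the R² difference alongside both bands' accuracy tables.

## Numerical and scale choices

- Exhaustive checks enumerate all 3·3·3·3·6·3 = 1,458 RTS input
  combinations and all 64 (RTS, NESMS) pairs; they run in well under a
  second.
- Calibration recovery simulates 50,000 draws per stratum (binomial
  standard error ≈ 0.2 % at the published fractions); distributional checks
  use 20,000 draws against a Dvoretzky–Kiefer–Wolfowitz band at α = 10⁻⁶.
- The end-to-end ordering property (good-band 12-month survival strictly
  above the low band's) uses a 10,000-patient multinomial cohort — large
  enough that the ordering induced by the NESMS-dependent survival model is
  deterministic in practice.
- Empty patient groups yield empty Kaplan–Meier estimates with a warning
  rather than an error; zero-patient accuracy rows report NaN percent
  (serialised as null).

## Limitations

- The published accuracy percentages and R² values (and the 27/24/13 band
  sizes) belong to an unpublished 64-patient cohort and cannot be
  reproduced; the pipeline reproduces the *machinery*, and the test suite
  verifies it on synthetic data whose generating process is known.
- Synthetic survival depends on covariates only through the NESMS stratum;
  RTS components carry no independent survival signal beyond their overlap
  with NESMS inputs, so synthetic R² values are not calibrated to clinical
  reality.
- No treatment effects, cancer-type-specific survival, or informative
  censoring are modelled.
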