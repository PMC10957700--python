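# Methods

## Model structure

The model compares two LVO-detection strategies for suspected acute
ischemic stroke patients presenting within 6 h at an EVT-capable centre:
NCCT + CTA + CTP (the observed arm) versus NCCT + CTA (the simulated
counterfactual). It has two stages.

**Short-term (90 days).** Every patient enters with an observed 90-day mRS
under EVT. In the control arm, each patient's occlusion is missed with the
occlusion-site-specific sensitivity difference of adding CTP (defaults
ICA 8%, M1 16%, M2 16%; independent Bernoulli draws). A missed patient
forgoes EVT; their counterfactual 90-day mRS is obtained by removing the
EVT common odds ratio (median 1.67) from their stratum's empirical
cumulative mRS distribution: `C'(k) = expit(logit(C(k)) − ln OR)` per
cutpoint. Two choices here are deliberate:

- *Case fatality is held fixed by default* (`evt_affects_mortality=False`):
  the odds shift acts on cutpoints mRS ≤ 0…4 only and displaced mass
  accumulates in mRS 5. The pivotal EVT trial evidence behind the OR shows
  a functional-outcome shift without a mortality effect, and treating the
  death cutpoint as shiftable would make the counterfactual arm die ~10 pp
  more at 90 days, which flips the sign of the long-run cost comparison
  (death is the cheapest state in the cost tables). The full six-cutpoint
  shift remains available as an option.
- *Rank-preserving coupling*: each patient carries a latent uniform,
  re-anchored inside their observed cell of the treated CDF and pushed
  through the inverse shifted CDF. The coupled counterfactual is never
  better than the observed outcome, and Monte-Carlo noise in paired
  differences is much reduced. The coupled marginal equals the shifted
  distribution exactly (verified by simulation in the tests).

**Long-term (yearly cycles to 5 or 10 years).** Each year, in order:
a death trial with probability `min(1, q(age, sex, year) · HR_mort(mRS))`,
HRs 1.54/2.17/3.18/4.55/6.55 for mRS 0–1/2/3/4/5; then a recurrent-stroke
trial with probability `min(1, baseline(years since stroke) ·
HR_rec(age, mRS))`. A recurrence redraws the state from the stratum's
no-EVT distribution truncated to states at or above the current one
(function never improves; drawing mRS 6 is a fatal recurrence). Death
trials precede recurrence trials so a fatal recurrence is not counted
twice. States are recorded end-of-cycle without half-cycle correction;
ages and calendar years advance with the cycle. Both arms of one run
consume identical per-patient event uniforms (common random numbers), so
paired differences isolate the arm effect; a non-missed patient has
exactly zero outcome difference.

## Economics

Per LVO patient and arm, discounted at 1.5%/yr (costs) and 4%/yr (QALYs),
year 1 undiscounted, simulation start 2022:

- **Acute bundle, year 0** (undiscounted): CTP arm
  `(CTP + EVT + IVT·1{ivt}) × 1.42`; control arm the same without CTP, and
  without EVT when missed (IVT is given in both arms — thrombolysis
  precedes LVO confirmation). The shared NCCT + CTA cost cancels between
  arms. The 42% uplift is the Dutch hospital-overhead convention; a config
  switch exempts CTP (whether the listed prices already include overhead
  is ambiguous in the source material).
- **Screening, year 0**: `(NNI − 1) × CTP price × overhead` per detected
  LVO — the expected cost of CTP-screening the suspected-stroke patients
  without an EVT-eligible occlusion; the index patient's own CTP sits in
  the acute bundle, so total CTP spend per LVO is NNI × price either way.
  Screened non-LVO patients have no simulated health consequences.
- **Follow-up costs**: per-mRS yearly cost tables for year 1, year 2, and
  year 3 onward, inflated once from their 2015 reference year to 2022
  (×1.149 at the fixture rates) and held in constant 2022 euros. Year 1 is
  keyed to the 90-day mRS, all later years to the 18-month mRS (the state
  entering year 2). The anchored cost is charged irrespective of simulated
  death after the anchor: the per-state yearly costs are population
  averages over patients observed in that early state — including those
  who subsequently died, which is why the mRS-6 columns are near zero
  (€423/€374) with sd far above the mean — so zeroing costs at a simulated
  death would double-count mortality's cost reduction.
- **QALYs**: utility of the state entering each year (0.94/0.80/0.68/
  0.39/0.24/0 for mRS 0–1 … 6); the dead accrue nothing. The dying year
  grants the full entering-state utility (no half-cycle correction),
  symmetric across arms.
- **NMB** `= WTP·ΔQALY − ΔCosts` at WTP €80,000/QALY, exact per patient
  and per PSA replicate by construction. Negative ΔCosts means the CTP
  strategy saves money.

## Analyses

- **Baseline**: all uncertainty distributions collapsed to their central
  values; cohort-mean ΔQALY, ΔCosts, NMB averaged over 8 paired simulation
  repetitions (distinct event streams, common random numbers within each)
  to shrink the Monte-Carlo error of the mean at n = 701 — the estimand is
  unchanged.
- **One-way (tornado)**: each positive scalar input at 0.9× and 1.1× with
  identical seeds, ranked by NMB swing; utilities are clipped at 1.
  Screening economics (NNI, sensitivity differences) and the EVT effect
  are excluded by convention. On default runs the good-outcome utilities
  (mRS 0–3) and the CTP/EVT prices dominate the ranking.
- **PSA**: per replicate, the cohort is bootstrapped with replacement
  (whole patients, stratum labels preserved), one parameter set is drawn —
  EVT OR and mortality HRs log-normal (HR CIs are unpublished; a stand-in
  ×1.3 multiplicative 95% CI is used), a common log-normal factor
  (σ = 0.15) on the recurrence HRs, gamma yearly costs, beta utilities
  sorted to keep the mRS ordering, death utility fixed at 0 — then arms
  are rebuilt and simulated. Replicate sub-streams derive from the master
  seed by replicate index only, so scenario cells sharing horizon, offset
  and OR reuse identical draws and ΔQALY is exactly invariant to NNI.
- **Scenario grid**: horizon {5, 10} × NNI {4.3, 8.3} × sensitivity-offset
  {−8 … +8 pp, floored at 0} (× optional OR variants 1.37/1.67/1.97/2.49),
  one PSA per cell; the ICER-plane export gives per-replicate (ΔQALY,
  ΔCosts) per occlusion stratum (excluding screening costs) and pooled
  (including them).

## Synthetic cohort

The generator emulates the registry the evaluation was built on: strata
weights 168/367/166 (ICA/M1/M2); per-stratum 90-day mRS from the observed
counts (denominator 645 with known outcome); age truncated-normal
(71.5, 13.5) on [18, 100] with per-stratum shifts −2/0/+1 years,
reproducing median 72 and IQR ≈ [62, 81]; sex and IVT independent
Bernoulli (0.556, 0.673); mRS and age independent within stratum (their
joint distribution is unpublished). It does **not** emulate NIHSS,
ASPECTS, collaterals, perfusion volumes, workflow times, or any
correlation between age, severity and outcome — so passing tests show the
pipeline reproduces the published *distributional* conditions, not that
it would reproduce patient-level structure in real data.

## Stand-in fixtures

Three inputs of the original evaluation are not published and ship as
clearly labelled synthetic stand-ins, each overridable by CSV or config:

- **Life table**: Gompertz–Makeham `q(age) = min(1, 2·10⁻⁴ + b·1.1^age)`
  with `b` calibrated per sex so remaining life expectancy at 72 is 14 y
  (female) / 12 y (male) in 2022, and a 0.5%/yr mortality improvement
  across calendar years.
- **Recurrence**: baseline annual probability 0.04 in year 1 declining to
  0.02 by year 5 (then constant); HRs stepped 1.0/1.4/2.0 by mRS band
  (0–1/2–3/4–5) times a mild age factor 0.9/1.0/1.1 (<65/65–74/≥75).
- **Inflation**: 2%/yr historical (2016–2022), 2.5%/yr forecast.

## Numerical and degenerate-input conventions

Degenerate CDF cutpoints (0 or 1) map to themselves under the odds shift;
the shifted CDF is re-monotonized against floating error. CI↔σ conversion
uses 1.959964. A recurrence truncation with no mass at or above the
current state leaves the state unchanged. Life-table lookups clamp age to
the covered range with a logged warning. Beta fits with infeasible
variance degrade to a point mass with a warning. Every stage derives its
random stream from `SeedSequence(seed, spawn_key=(stage, …))`, so reusing
one integer seed across stages cannot correlate their draws.

## Agreement with the published evaluation, and limits

With the default (published) parameters the model reproduces the
QALY-scale results closely: baseline 5-year ΔQALY ≈ 0.045–0.049, 10-year
PSA median ΔQALY ≈ 0.072–0.076, and the 10-year PSA median NMB within
~20%. Cost-scale differences (ΔCosts) are reproduced in sign-structure
(savings grow with horizon and sensitivity difference, ΔQALY invariant to
NNI) but sit €1,000–2,000 per LVO patient above the published medians:
ΔCosts is a small difference of ~€5,000-scale components, and its level is
first-order sensitive to the unpublished inputs replaced by stand-ins
(the early-year per-state cost gap, the overhead convention for acute
prices). Problem sizes used throughout — a 701-patient cohort, 8 baseline
repetitions, 1000 PSA replicates — are the package's defaults and run in
well under a minute.

Known limitations: no false-positive/futile-transfer pathway (assumed
negligible), no CTP contrast/radiation harms, healthcare-payer perspective
only (no indirect costs), integer-year cycles without half-cycle
correction, and utilities taken as given parameters rather than estimated
from individual quality-of-life data.
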