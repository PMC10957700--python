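# ctp-cea

Health-economic microsimulation of CT-perfusion (CTP) based screening for
endovascular-treatment-eligible large vessel occlusion (LVO) in acute
ischemic stroke.

## The question

Adding CTP to the standard NCCT + CTA imaging workup raises the
sensitivity of LVO detection — by roughly 8 percentage points for
ICA/ICA-terminus occlusions and 16 points for M1/M2 occlusions in reader
studies — so more patients receive endovascular treatment (EVT). But every
detected LVO comes with an NNI (number needed to image) of 4.3–8.3
CTP-screened suspected-stroke patients whose scans cost money and change
nothing. Is CTP-based LVO screening worth it to a healthcare payer?

The package answers this with a patient-level Markov model. A cohort of
EVT-treated LVO patients with observed 90-day modified Rankin Scale (mRS)
outcomes is compared with a counterfactual NCCT + CTA arm in which a
stratum-specific fraction of occlusions is missed. A missed patient forgoes
EVT, and their 90-day mRS distribution is shifted by removing the EVT
treatment effect — a common (proportional) odds ratio, OR = 1.67
(95% CI 1.21–2.30) — from the cutpoints of the cumulative mRS
distribution, holding 90-day case fatality fixed; a rank-preserving latent
uniform couples each patient's counterfactual outcome to their observed
one. Yearly mRS trajectories then evolve to a 5- or 10-year horizon under
an age/sex/calendar-year life table multiplied by mRS-specific mortality
hazard ratios (1.54–6.55) and a recurrent-stroke process that can only
worsen function.

Outcomes per LVO patient are discounted QALYs (4%/yr) and costs (1.5%/yr):
acute bundles (CTP €251.40, EVT €9,924.50, IVT €950.82, plus a 42% hospital
overhead), NNI-scaled screening costs, and per-mRS yearly follow-up costs
keyed to the 90-day (year 1) and 18-month (later years) state. The primary
outcome is the net monetary benefit at a willingness to pay of
€80,000/QALY:

```
NMB = WTP · (QALY_CTP − QALY_control) − (Costs_CTP − Costs_control)
```

Because the study cohort is not public, a first-class synthetic-cohort
generator emulates its descriptive statistics (strata 168/367/166 for
ICA/M1/M2, the per-stratum 90-day mRS distributions, median age 72,
55.6% male, 67.3% IVT), and all analyses — mean-input baseline, ±10%
one-way tornado, 1000-replicate probabilistic sensitivity analysis (PSA)
with bootstrap cohorts and log-normal/gamma/beta parameter uncertainty,
and a scenario grid over horizon × NNI × sensitivity difference × EVT
effect — run on synthetic or user-supplied cohorts.

## Worked example

```python
from ctp_cea import ModelParameters, run_baseline, run_psa, synthesize_cohort

params = ModelParameters()                      # published defaults
cohort = synthesize_cohort(n=701, seed=1)

base = run_baseline(cohort, params, horizon=5, nni=8.3, seed=1, reps=8)
print(base.delta_qalys, base.delta_costs, base.nmb)
# 0.0451  1567.27  2040.06

psa = run_psa(cohort, params, n_reps=1000, horizon=10, nni=8.3, seed=1)
print(psa.summary())
# ΔCosts median  -495  (IQR -3046; 1734)
# ΔQALY  median 0.076  (IQR 0.056; 0.099)
# NMB    median  6900  (IQR 3347; 10641),  fraction cost-effective 0.911
```

Reading: at the conservative NNI of 8.3 and a 5-year horizon, CTP-based
screening buys 0.045 QALYs per LVO patient for about €1,600 extra — cost-
effective (positive NMB) at €80,000/QALY. Over 10 years the follow-up-care
savings of better functional outcomes overtake the screening and EVT
costs: the PSA median ΔCosts turns negative (a saving), the median NMB is
≈ €6,900 per LVO patient, and 91% of PSA replicates are cost-effective.

The same analyses are available from the shell:

```bash
ctp-cea synthesize --n 701 --seed 1 --outdir out
ctp-cea baseline  --seed 1 --outdir out
ctp-cea psa       --seed 1 --horizon 10 --reps 1000 --outdir out
ctp-cea tornado   --seed 1 --outdir out
ctp-cea scenarios --seed 1 --reps 200 --outdir out
```

Each command writes CSV/JSON artifacts plus a `manifest.json` (command,
config hash, seed, outputs) from which the run can be reproduced exactly.
Parameters are overridden with a flat YAML file via `--config`; life
table, inflation, and recurrence fixtures can be replaced by CSVs
(`life_table_csv`, `inflation_csv`, `recurrence_csv` keys).

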