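"""Discounted costs, QALYs, and incremental outcomes per LVO patient.

Accounting conventions:

- Acute and screening costs fall at year 0 and are not discounted; the
  simulation starts in 2022 and the first cycle carries discount factor 1.
- Follow-up year ``t`` (t = 1..horizon) accrues QALYs for the state
  occupied at its start (the 90-day state for year 1); the dead accrue
  nothing.
- Follow-up costs are anchored: year 1 is keyed to the 90-day mRS and
  every later year to the 18-month mRS (the state entering year 2), year 2
  using the second-year table and later years the steady-state table. The
  anchored cost is charged irrespective of simulated death after the
  anchor, because the per-state yearly cost estimates are population
  averages over patients in that early state - including those who
  subsequently died (the near-zero mRS-6 columns) - so zeroing costs at a
  simulated death would count mortality's cost reduction twice.
- The mRS-6 (death) cost is charged once, in the first year keyed to the
  dead state; afterwards the dead contribute neither costs nor QALYs.
- The CTP arm carries the index patient's own CTP inside the acute bundle
  and ``(NNI - 1)`` additional screening CTPs per detected LVO; the NCCT+CTA
  bundle is identical across arms and differenced out.
- Net monetary benefit: ``NMB = WTP * dQALY - dCosts`` at WTP eur 80,000
  per QALY; positive ΔCosts means the CTP strategy is more expensive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import InflationSeries, ModelParameters


@dataclass(frozen=True)
class EconomicResult:
    patient_id: int
    arm: str
    discounted_costs: float
    discounted_qalys: float


@dataclass(frozen=True)
class DeltaOutcome:
    """Per-patient incremental outcome (CTP arm minus control arm)."""

    delta_costs: float
    delta_qalys: float
    nmb: float


def discount_factor(year_index: int, rate: float):
    """Present-value multiplier ``(1 + rate)^(-year_index)``; the first year
    (index 0) is undiscounted."""
    if np.any(np.asarray(rate) <= -1):
        raise ValueError("discount rate must exceed -1")
    if np.any(np.asarray(year_index) < 0):
        raise ValueError("year index must be non-negative")
    return (1.0 + rate) ** (-np.asarray(year_index, dtype=float))


def inflate_cost(
    cost: float, from_year: int, to_year: int, series: InflationSeries
) -> float:
    """Carry a cost between calendar years with compound annual inflation."""
    return cost * series.factor(from_year, to_year)


def acute_cost(ivt: bool, params: ModelParameters, arm: str, missed: bool = False):
    """Acute-care bundle at year 0, with the hospital overhead uplift.

    CTP arm: CTP + EVT (+ IVT); control arm: EVT (+ IVT) when detected,
    IVT only when the occlusion was missed (thrombolysis is assumed given
    in both arms). The shared NCCT+CTA bundle cancels between arms and is
    included only via ``cost_ncct_cta`` (default 0).
    """
    ivt_c = np.asarray(ivt, dtype=float) * params.cost_ivt
    ctp_ovh = params.overhead_factor if params.overhead_applies_to_ctp else 1.0
    if arm == "ctp":
        base = (params.cost_ncct_cta + params.cost_evt + ivt_c) * params.overhead_factor
        return base + params.cost_ctp * ctp_ovh
    missed = np.asarray(missed)
    evt = np.where(missed, 0.0, params.cost_evt)
    return (params.cost_ncct_cta + evt + ivt_c) * params.overhead_factor


def screening_cost_per_lvo(nni: float, cost_ctp: float, overhead_factor: float) -> float:
    """Cost of the ``NNI - 1`` non-LVO screening CTPs attributed to each
    detected LVO patient (the index CTP sits in the acute bundle)."""
    if nni < 1:
        raise ValueError("number needed to image must be >= 1")
    return (nni - 1.0) * cost_ctp * overhead_factor


def annual_cost(mrs: int, year_index: int, cost_tables: np.ndarray) -> float:
    """Mean follow-up cost for the given mRS state in simulation year
    ``year_index`` (1-based); ``cost_tables`` is the (3, 7) band table."""
    if not 1 <= int(year_index):
        raise ValueError("year_index is 1-based")
    band = min(int(year_index), 3) - 1
    return float(cost_tables[band, int(mrs)])


def annual_qaly(mrs: int, utilities: np.ndarray) -> float:
    """Utility weight of one full year in the given state (0 for death)."""
    return float(utilities[int(mrs)])


def accumulate_states(
    states: np.ndarray,
    acute: np.ndarray,
    screening: float,
    params: ModelParameters,
    utilities: np.ndarray | None = None,
    cost_tables: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised accumulation over an (n, horizon+1) state matrix.

    Returns per-patient (discounted costs, discounted QALYs). ``utilities``
    and ``cost_tables`` default to the parameter means (PSA passes draws).
    """
    if utilities is None:
        utilities = params.utility_by_state()
    if cost_tables is None:
        cost_tables = params.cost_tables_by_state()
    n, width = states.shape
    horizon = width - 1
    costs = np.asarray(acute, dtype=float) + screening
    qalys = np.zeros(n)
    for t in range(1, horizon + 1):
        entering = states[:, t - 1]
        band = min(t, 3) - 1
        cost_state = entering if t == 1 else states[:, 1]
        year_cost = cost_tables[band][cost_state]
        costs = costs + year_cost * discount_factor(t - 1, params.discount_rate_cost)
        qalys = qalys + utilities[entering] * discount_factor(
            t - 1, params.discount_rate_qaly
        )
    return costs, qalys


def accumulate(
    trajectory,
    params: ModelParameters,
    ivt: bool = False,
    missed: bool = False,
    nni: float | None = None,
) -> EconomicResult:
    """Single-trajectory wrapper over :func:`accumulate_states`."""
    states = np.asarray(trajectory.mrs_by_year)[None, :]
    arm = "ctp" if trajectory.arm == "ctp" else "control"
    acute = np.atleast_1d(acute_cost(ivt, params, arm, missed))
    screening = 0.0
    if arm == "ctp":
        nni = params.nni if nni is None else nni
        ctp_ovh = params.overhead_factor if params.overhead_applies_to_ctp else 1.0
        screening = screening_cost_per_lvo(nni, params.cost_ctp, ctp_ovh)
    costs, qalys = accumulate_states(states, acute, screening, params)
    return EconomicResult(
        trajectory.patient_id, trajectory.arm, float(costs[0]), float(qalys[0])
    )


def delta_outcomes(
    treated: pd.DataFrame, control: pd.DataFrame, wtp: float
) -> tuple[pd.DataFrame, dict]:
    """Pair per-patient results by id and compute ΔCosts, ΔQALY and NMB.

    Inputs are frames with columns ``id, costs, qalys``. Returns the
    per-patient frame and a summary dict of medians and interquartile
    ranges, with the fraction of patients with positive NMB.
    """
    merged = treated.merge(control, on="id", suffixes=("_ctp", "_control"))
    if len(merged) != len(treated) or len(merged) != len(control):
        raise ValueError("treated and control results must pair one-to-one by id")
    out = pd.DataFrame(
        {
            "id": merged["id"],
            "delta_costs": merged["costs_ctp"] - merged["costs_control"],
            "delta_qalys": merged["qalys_ctp"] - merged["qalys_control"],
        }
    )
    out["nmb"] = wtp * out["delta_qalys"] - out["delta_costs"]
    summary = summarize_deltas(out, wtp)
    return out, summary


def summarize_deltas(deltas: pd.DataFrame, wtp: float) -> dict:
    def _med_iqr(s: pd.Series) -> dict:
        return {
            "median": float(s.median()),
            "iqr": (float(s.quantile(0.25)), float(s.quantile(0.75))),
            "mean": float(s.mean()),
        }

    return {
        "wtp": wtp,
        "delta_costs": _med_iqr(deltas["delta_costs"]),
        "delta_qalys": _med_iqr(deltas["delta_qalys"]),
        "nmb": _med_iqr(deltas["nmb"]),
        "fraction_positive_nmb": float((deltas["nmb"] > 0).mean()),
    }
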