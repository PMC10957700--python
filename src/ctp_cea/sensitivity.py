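"""One-way (tornado), probabilistic, and scenario sensitivity analyses.

The probabilistic sensitivity analysis (PSA) repeats the full pipeline per
replicate: bootstrap the cohort with replacement, draw one parameter set
from the uncertainty distributions (log-normal ratios, gamma costs, beta
utilities), rebuild the counterfactual arm, simulate, and record the
cohort-mean ΔCosts, ΔQALY and NMB. Replicate sub-streams are derived from
the master seed by index only, so scenario-grid cells that share horizon,
sensitivity offset and EVT effect reuse identical draws - which makes
ΔQALY exactly invariant to the number needed to image, as screening
touches costs alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seeding import PSA, rng_for
from .cohort import Cohort
from .engine import run_baseline, simulate_arms
from .parameters import (
    MRS_LEVELS,
    OCCLUSIONS,
    ModelParameters,
)

#: EVT common-OR variants: baseline and the reported lower/upper alternatives
OR_EVT_VARIANTS = (
    (1.37, 0.91, 2.00),
    (1.67, 1.21, 2.30),
    (1.97, 1.51, 2.60),
    (2.49, 1.76, 3.53),
)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    nmb_low: float
    nmb_high: float

    @property
    def swing(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def one_way_sensitivity(
    cohort: Cohort,
    params: ModelParameters,
    parameters: Optional[Sequence[str]] = None,
    horizon: Optional[int] = None,
    nni: Optional[float] = None,
    seed: int = 0,
    reps: int = 4,
) -> pd.DataFrame:
    """±10% one-way analysis of the scalar inputs, ranked by NMB swing.

    Each parameter is set to 0.9x and 1.1x its mean with everything else
    (including all random streams) held fixed; screening economics (NNI,
    sensitivity differences) and the EVT effect are excluded by convention.
    Returns a frame sorted by descending swing with the baseline NMB
    attached in ``attrs``.
    """
    if parameters is None:
        parameters = params.scalar_names()
    base = run_baseline(cohort, params, horizon=horizon, nni=nni, seed=seed, reps=reps)
    entries = []
    for name in parameters:
        lo = run_baseline(
            cohort, params.with_scaled(name, 0.9),
            horizon=horizon, nni=nni, seed=seed, reps=reps,
        ).nmb
        hi = run_baseline(
            cohort, params.with_scaled(name, 1.1),
            horizon=horizon, nni=nni, seed=seed, reps=reps,
        ).nmb
        entries.append(TornadoEntry(name, lo, hi))
    df = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "nmb_low": [e.nmb_low for e in entries],
            "nmb_high": [e.nmb_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    ).sort_values("swing", ascending=False, ignore_index=True)
    df.attrs["nmb_baseline"] = base.nmb
    return df


def draw_psa_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> ModelParameters:
    """One parameter set sampled from the uncertainty distributions.

    Ratios (EVT OR, mortality HRs, a common recurrence-HR factor) are drawn
    log-normal, yearly costs gamma, utilities beta with the draws sorted to
    keep the utility ordering monotone in mRS (death stays at 0). Prices,
    NNI, sensitivity differences and rates are fixed by design.
    """
    data = params.model_dump()

    d = float(params.or_evt_spec().rvs(rng))
    data["or_evt"] = (d, d, d)

    for level, spec in params.hr_mortality_specs().items():
        data["hr_mortality"][level] = float(spec.rvs(rng))

    rec_factor = float(np.exp(rng.normal(0.0, params.hr_recurrence_sigma)))
    for band in data["hr_recurrence_mrs"]:
        data["hr_recurrence_mrs"][band] *= rec_factor

    for table, specs in params.cost_specs().items():
        for level, spec in specs.items():
            sd = data[table][level][1]
            data[table][level] = (float(spec.rvs(rng)), sd)

    util_specs = params.utility_specs()
    draws = [float(util_specs[l].rvs(rng)) for l in MRS_LEVELS[:-1]]
    for level, value in zip(MRS_LEVELS[:-1], sorted(draws, reverse=True)):
        data["utilities"][level] = (value, data["utilities"][level][1])

    return ModelParameters(**data)


@dataclass
class PSAResult:
    """Replicate-level PSA outcomes with summaries."""

    replicates: pd.DataFrame  # rep, delta_costs, delta_qalys, nmb
    icer_plane: pd.DataFrame  # rep, group, delta_costs, delta_qalys
    horizon: int
    nni: float
    seed: int

    @property
    def fraction_cost_effective(self) -> float:
        return float((self.replicates["nmb"] > 0).mean())

    def summary(self) -> dict:
        def _med_iqr(s: pd.Series) -> dict:
            return {
                "median": float(s.median()),
                "iqr": (float(s.quantile(0.25)), float(s.quantile(0.75))),
            }

        return {
            "n_reps": len(self.replicates),
            "horizon_years": self.horizon,
            "nni": self.nni,
            "delta_costs": _med_iqr(self.replicates["delta_costs"]),
            "delta_qalys": _med_iqr(self.replicates["delta_qalys"]),
            "nmb": _med_iqr(self.replicates["nmb"]),
            "fraction_cost_effective": self.fraction_cost_effective,
        }


def _bootstrap(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    idx = rng.integers(0, len(cohort), len(cohort))
    frame = cohort.frame.iloc[idx].reset_index(drop=True).copy()
    frame["id"] = np.arange(len(frame))
    return Cohort(frame, provenance="bootstrap", seed=cohort.seed)


def run_psa(
    cohort: Cohort,
    params: ModelParameters,
    n_reps: Optional[int] = None,
    horizon: Optional[int] = None,
    nni: Optional[float] = None,
    seed: int = 0,
) -> PSAResult:
    """Probabilistic sensitivity analysis with cohort bootstrap.

    Per replicate: resample patients with replacement (preserving stratum
    labels), draw a parameter set, rebuild both arms and simulate with
    common random numbers, and keep the cohort-mean incremental outcomes.
    Fully reproducible from ``seed``.
    """
    n_reps = params.n_psa if n_reps is None else n_reps
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    horizon = params.horizon_years if horizon is None else horizon
    nni = params.nni if nni is None else nni
    wtp = params.wtp

    rows, plane = [], []
    ctp_ovh = params.overhead_factor if params.overhead_applies_to_ctp else 1.0
    screening = (nni - 1.0) * params.cost_ctp * ctp_ovh
    index_ctp = params.cost_ctp * ctp_ovh
    for rep in range(n_reps):
        rng = rng_for(seed, PSA, rep)
        boot = _bootstrap(cohort, rng)
        drawn = draw_psa_parameters(params, rng)
        res = simulate_arms(boot, drawn, rng, horizon=horizon, nni=nni)
        dc, dq = res.mean_delta_costs, res.mean_delta_qalys
        rows.append((rep, dc, dq, wtp * dq - dc))

        per = res.per_patient
        occ = boot.frame["occlusion"].to_numpy()
        for group in OCCLUSIONS:
            sel = per[occ == group]
            if len(sel):
                # stratum panels exclude the CTP screening burden (index CTP
                # plus the NNI - 1 extra screens), which is pooled-level
                plane.append(
                    (
                        rep,
                        group,
                        float(sel["delta_costs"].mean()) - screening - index_ctp,
                        float(sel["delta_qalys"].mean()),
                    )
                )
        plane.append((rep, "pooled", dc, dq))

    replicates = pd.DataFrame(
        rows, columns=["rep", "delta_costs", "delta_qalys", "nmb"]
    )
    icer = pd.DataFrame(plane, columns=["rep", "group", "delta_costs", "delta_qalys"])
    return PSAResult(replicates, icer, horizon, nni, seed)


def _offset_sens(params: ModelParameters, offset: float) -> dict[str, float]:
    return {
        occ: float(np.clip(p + offset, 0.0, 1.0))
        for occ, p in params.sens_diff.items()
    }


def scenario_grid(
    cohort: Cohort,
    params: ModelParameters,
    horizons: Sequence[int] = (10, 5),
    nni_values: Sequence[float] = (4.3, 8.3),
    sens_offsets: Sequence[float] = (0.08, 0.04, 0.0, -0.04, -0.08),
    or_variants: Optional[Sequence[tuple[float, float, float]]] = None,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Dedicated PSA over horizon x NNI x sensitivity offset (x EVT OR).

    Offsets are percentage-point shifts applied to every occlusion site's
    baseline sensitivity difference, floored at zero. Cells sharing every
    setting except NNI reuse identical replicate draws. Returns one row per
    cell with medians, interquartile ranges, and the cost-effective
    fraction.
    """
    if or_variants is None:
        or_variants = [params.or_evt]
    rows = []
    for horizon in horizons:
        for nni in nni_values:
            for offset in sens_offsets:
                for orv in or_variants:
                    p = params.model_copy(
                        update={
                            "sens_diff": _offset_sens(params, offset),
                            "or_evt": tuple(orv),
                        }
                    )
                    res = run_psa(
                        cohort, p, n_reps=n_reps, horizon=horizon, nni=nni, seed=seed
                    )
                    s = res.summary()
                    rows.append(
                        {
                            "horizon_years": horizon,
                            "nni": nni,
                            "sens_offset_pp": round(100 * offset, 1),
                            "or_evt": orv[0],
                            "delta_costs_median": s["delta_costs"]["median"],
                            "delta_costs_q25": s["delta_costs"]["iqr"][0],
                            "delta_costs_q75": s["delta_costs"]["iqr"][1],
                            "delta_qalys_median": s["delta_qalys"]["median"],
                            "delta_qalys_q25": s["delta_qalys"]["iqr"][0],
                            "delta_qalys_q75": s["delta_qalys"]["iqr"][1],
                            "nmb_median": s["nmb"]["median"],
                            "nmb_q25": s["nmb"]["iqr"][0],
                            "nmb_q75": s["nmb"]["iqr"][1],
                            "fraction_cost_effective": s["fraction_cost_effective"],
                        }
                    )
    return pd.DataFrame(rows)
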