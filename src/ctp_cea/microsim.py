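"""Yearly mRS trajectory microsimulation from 90 days to the horizon.

Each patient enters the long-term model in their arm-specific 90-day mRS
state. Every subsequent year, in order: a death trial with probability
``q(age, sex, calendar year) * HR_mortality(mRS)``, then a recurrent-stroke
trial with probability ``baseline(years since stroke) * HR_recurrence(age,
mRS)``; a recurrence redistributes the patient within the stratum's no-EVT
90-day distribution truncated to states at or above the current one (a
recurrent stroke never improves function; drawing mRS 6 represents a fatal
recurrence). States are recorded at the end of each cycle, without
half-cycle correction; death (mRS 6) is absorbing.

Common random numbers: the same per-patient stream of event uniforms is
used in both arms, so paired differences isolate the arm effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._seeding import SIMULATION, rng_for
from .cohort import Cohort
from .counterfactual import shift_distribution_by_or, stratum_distributions
from .parameters import LifeTable, ModelParameters, OCCLUSIONS


@dataclass
class Trajectory:
    """One simulated patient-arm path; entry 0 is the 90-day state."""

    patient_id: int
    arm: str
    mrs_by_year: np.ndarray
    death_year: Optional[int]
    recurrence_years: list[int]

    def __post_init__(self):
        states = np.asarray(self.mrs_by_year)
        if self.death_year is not None and not np.all(
            states[self.death_year:] == 6
        ):
            raise ValueError("states after death must all be 6")


def annual_death_prob(
    age, sex, calendar_year: int, mrs, life_table: LifeTable, hr_mortality: np.ndarray
) -> np.ndarray:
    """``min(1, q(age, sex, year) * HR(mRS))`` for living states, vectorised."""
    mrs = np.asarray(mrs)
    if np.any(mrs > 5):
        raise ValueError("death probability is defined for states 0..5 only")
    q = life_table.q(age, sex, calendar_year)
    return np.minimum(1.0, q * np.asarray(hr_mortality)[mrs])


def annual_recurrence_prob(
    years_since_stroke: int, age, mrs, params: ModelParameters
) -> np.ndarray:
    """``min(1, baseline(years since stroke) * HR_recurrence(age, mRS))``."""
    base = params.recurrence_baseline_at(years_since_stroke)
    return np.minimum(1.0, base * params.hr_recurrence(age, mrs))


def apply_recurrence(
    current_mrs: np.ndarray, no_evt_cdf: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Redistribute within the no-EVT distribution truncated to
    ``[current, 6]`` via inverse-CDF sampling; never improves the state.

    ``no_evt_cdf`` is either a single 7-point CDF or one row per patient.
    A degenerate truncation (no mass at or above the current state) leaves
    the state unchanged.
    """
    current = np.atleast_1d(np.asarray(current_mrs, dtype=int))
    u = np.atleast_1d(np.asarray(u, dtype=float))
    cdf = np.asarray(no_evt_cdf, dtype=float)
    if cdf.ndim == 1:
        cdf = np.broadcast_to(cdf, (current.size, 7))
    lower = np.where(
        current > 0, np.take_along_axis(cdf, (current - 1)[:, None], 1)[:, 0], 0.0
    )
    tail = 1.0 - lower
    ok = tail > 1e-12
    target = lower + u * tail
    new = (cdf < target[:, None]).sum(axis=1).clip(0, 6)
    new = np.where(ok, np.maximum(new, current), current)
    return new


def _simulate_states(
    mrs0: np.ndarray,
    ages: np.ndarray,
    sex_codes: np.ndarray,
    occ_idx: np.ndarray,
    no_evt_cdfs: np.ndarray,  # (3, 7) per-stratum no-EVT CDFs
    params: ModelParameters,
    horizon: int,
    u_death: np.ndarray,
    u_rec: np.ndarray,
    u_redist: np.ndarray,
) -> np.ndarray:
    """Vectorised engine; returns the (n, horizon+1) state matrix."""
    n = mrs0.size
    states = np.empty((n, horizon + 1), dtype=int)
    states[:, 0] = mrs0
    state = mrs0.copy()
    hr_mort = params.hr_mortality_by_state()
    patient_cdfs = no_evt_cdfs[occ_idx]
    for t in range(1, horizon + 1):
        alive = state < 6
        if alive.any():
            q = annual_death_prob(
                ages + t,
                sex_codes,
                params.start_year + t,
                np.where(alive, state, 0),
                params.life_table,
                hr_mort,
            )
            dies = alive & (u_death[:, t - 1] < q)
            state = np.where(dies, 6, state)
            alive = state < 6
            p_rec = annual_recurrence_prob(
                t, ages + t, np.where(alive, state, 0), params
            )
            recurs = alive & (u_rec[:, t - 1] < p_rec)
            if recurs.any():
                state[recurs] = apply_recurrence(
                    state[recurs], patient_cdfs[recurs], u_redist[recurs, t - 1]
                )
        states[:, t] = state
    return states


def draw_event_uniforms(n: int, horizon: int, rng: np.random.Generator):
    """One (death, recurrence, redistribution) uniform stream per patient-year;
    reused across arms for common random numbers."""
    u = rng.random((3, n, horizon))
    return u[0], u[1], u[2]


def simulate_trajectory(
    patient,
    mrs90: int,
    params: ModelParameters,
    rng: np.random.Generator,
    horizon: Optional[int] = None,
    no_evt_dist: Optional[np.ndarray] = None,
    arm: str = "ctp",
) -> Trajectory:
    """Single-patient convenience wrapper over the vectorised engine."""
    horizon = params.horizon_years if horizon is None else horizon
    if no_evt_dist is None:
        dist = np.zeros(7)
        dist[mrs90] = 1.0
    else:
        dist = np.asarray(no_evt_dist, dtype=float)
    cdf = np.cumsum(dist)
    cdf[-1] = 1.0
    ud, ur, ux = draw_event_uniforms(1, horizon, rng)
    states = _simulate_states(
        np.array([mrs90]),
        np.array([patient.age]),
        np.array([0 if patient.sex == "male" else 1]),
        np.array([0]),
        np.broadcast_to(cdf, (3, 7)).copy(),
        params,
        horizon,
        ud,
        ur,
        ux,
    )[0]
    return _trajectory_from_states(patient.id, arm, states)


def _trajectory_from_states(pid: int, arm: str, states: np.ndarray) -> Trajectory:
    dead = np.flatnonzero(states == 6)
    death_year = int(dead[0]) if dead.size else None
    rec_years = [
        int(t)
        for t in range(1, states.size)
        if states[t] > states[t - 1] and states[t] < 6
    ]
    return Trajectory(pid, arm, states, death_year, rec_years)


def simulate_cohort(
    cohort: Cohort,
    arms: pd.DataFrame,
    params: ModelParameters,
    seed: int | np.random.Generator = 0,
    horizon: Optional[int] = None,
    strata_dists: Optional[dict[str, np.ndarray]] = None,
) -> dict[str, np.ndarray]:
    """Simulate both arms with common random numbers.

    Returns ``{"ctp": states, "control": states}`` with one
    ``(n, horizon+1)`` integer state matrix per arm, row-aligned with the
    cohort frame.
    """
    horizon = params.horizon_years if horizon is None else horizon
    rng = rng_for(seed, SIMULATION)
    if strata_dists is None:
        strata_dists = stratum_distributions(cohort)
    preserve = not params.evt_affects_mortality
    no_evt = np.stack(
        [
            np.cumsum(
                shift_distribution_by_or(
                    strata_dists[occ], params.or_evt[0], preserve_death=preserve
                )
            )
            for occ in OCCLUSIONS
        ]
    )
    no_evt[:, -1] = 1.0

    ages = cohort.frame["age"].to_numpy()
    sexes = cohort.sex_codes()
    occ_idx = cohort.occlusion_codes()
    n = len(cohort)
    ud, ur, ux = draw_event_uniforms(n, horizon, rng)

    out = {}
    for arm, col in (("ctp", "mrs90_treated"), ("control", "mrs90_control")):
        out[arm] = _simulate_states(
            arms[col].to_numpy(dtype=int),
            ages,
            sexes,
            occ_idx,
            no_evt,
            params,
            horizon,
            ud,
            ur,
            ux,
        )
    return out


def trajectories_to_frame(
    states_by_arm: dict[str, np.ndarray], ids: np.ndarray
) -> pd.DataFrame:
    """Long-format (id, arm, year, mrs) export of simulated state matrices."""
    frames = []
    for arm, states in states_by_arm.items():
        n, h = states.shape
        frames.append(
            pd.DataFrame(
                {
                    "id": np.repeat(ids, h),
                    "arm": arm,
                    "year": np.tile(np.arange(h), n),
                    "mrs": states.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
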