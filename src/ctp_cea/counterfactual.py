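"""Construction of the NCCT+CTA control arm.

Under standard NCCT+CTA screening a fraction of EVT-eligible occlusions is
missed; the miss probability is the occlusion-site-specific sensitivity
difference of adding CTP. A missed patient does not receive EVT, and their
observed (treated) 90-day mRS is replaced by a counterfactual no-EVT
outcome obtained by removing the EVT treatment effect - a common
(proportional) odds ratio - from the patient's stratum-level 90-day mRS
distribution.

Two shift variants are provided. The default holds the 90-day case
fatality fixed (the odds shift acts on cutpoints mRS<=0..4 only), because
the pivotal randomised evidence for EVT shows a functional-outcome shift
without a mortality effect; displaced probability mass then accumulates in
mRS 5. Setting ``evt_affects_mortality=True`` shifts all six cutpoints.

The counterfactual outcome is realised with a rank-preserving coupling:
the patient's latent uniform is re-anchored inside their observed mRS cell
of the treated CDF and pushed through the inverse CDF of the shifted
distribution, so that removing EVT can never improve the coupled outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeding import ARMS, rng_for
from .cohort import Cohort
from .parameters import OCCLUSIONS, ModelParameters


@dataclass(frozen=True)
class ArmAssignment:
    """Control-arm outcome for one patient."""

    patient_id: int
    missed: bool
    mrs90_treated: int
    mrs90_control: int

    def __post_init__(self):
        if not self.missed and self.mrs90_control != self.mrs90_treated:
            raise ValueError("detected patients keep their treated 90-day mRS")


def shift_distribution_by_or(
    dist: np.ndarray, or_evt: float, preserve_death: bool = True
) -> np.ndarray:
    """Remove a common odds-ratio treatment effect from a 7-cell mRS simplex.

    For each shifted cutpoint k, ``C'(k) = expit(logit(C(k)) - ln(or_evt))``
    where ``C(k) = P(mRS <= k)`` of the treated distribution; the returned
    vector is the first difference of ``C'``. Degenerate cutpoints (0 or 1)
    map to themselves. With ``preserve_death`` (default) the death cutpoint
    ``C(5)`` is left unchanged.
    """
    p = np.asarray(dist, dtype=float)
    if p.shape != (7,):
        raise ValueError("mRS distribution must have 7 cells")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("mRS distribution must be a probability simplex")
    if or_evt <= 0:
        raise ValueError("odds ratio must be positive")
    cum = np.cumsum(p)
    cum[-1] = 1.0
    shifted = shifted_cdf(cum, or_evt, preserve_death)
    out = np.diff(np.concatenate(([0.0], shifted)))
    return np.clip(out, 0.0, 1.0)


def shifted_cdf(cum: np.ndarray, or_evt: float, preserve_death: bool = True) -> np.ndarray:
    """Cutpoint-wise odds division of a 7-point mRS CDF (last entry is 1)."""
    shifted = cum.copy()
    last = 4 if preserve_death else 5
    for k in range(last + 1):
        c = cum[k]
        if c <= 0.0 or c >= 1.0:
            continue  # degenerate cutpoint maps to itself
        odds = c / (1.0 - c) / or_evt
        shifted[k] = odds / (1.0 + odds)
    # guard against floating non-monotonicity at degenerate cutpoints
    return np.maximum.accumulate(shifted)


def counterfactual_mrs(
    mrs_treated: np.ndarray,
    latent_u: np.ndarray,
    treated_dist: np.ndarray,
    or_evt: float,
    preserve_death: bool = True,
) -> np.ndarray:
    """Rank-preserving no-EVT 90-day mRS for patients of one stratum.

    The latent uniform is re-anchored to the observed cell,
    ``u = C(m-1) + latent_u * (C(m) - C(m-1))``, and evaluated through the
    inverse CDF of the shifted distribution. Because the shifted CDF is
    pointwise below the treated CDF the coupled outcome satisfies
    ``counterfactual >= treated``.
    """
    mrs_treated = np.atleast_1d(np.asarray(mrs_treated, dtype=int))
    latent_u = np.atleast_1d(np.asarray(latent_u, dtype=float))
    p = np.asarray(treated_dist, dtype=float)
    cum = np.cumsum(p)
    cum[-1] = 1.0
    lower = np.concatenate(([0.0], cum))[mrs_treated]
    upper = cum[mrs_treated]
    u = lower + latent_u * (upper - lower)
    shifted = shifted_cdf(cum, or_evt, preserve_death)
    return np.searchsorted(shifted, u, side="right").clip(0, 6)


def stratum_distributions(cohort: Cohort) -> dict[str, np.ndarray]:
    """Empirical per-occlusion treated 90-day mRS distributions of a cohort.

    A stratum absent from the cohort falls back to the pooled distribution.
    """
    df = cohort.frame
    pooled = np.bincount(df["mrs90_treated"], minlength=7).astype(float)
    pooled /= pooled.sum()
    out = {}
    for occ in OCCLUSIONS:
        sub = df.loc[df["occlusion"] == occ, "mrs90_treated"]
        if len(sub) == 0:
            out[occ] = pooled
        else:
            counts = np.bincount(sub, minlength=7).astype(float)
            out[occ] = counts / counts.sum()
    return out


def select_missed(
    cohort: Cohort, sens_diff: dict[str, float], seed: int | np.random.Generator = 0
) -> set[int]:
    """Patients whose LVO is missed without CTP: independent Bernoulli draws
    with the stratum-specific sensitivity difference as probability."""
    for occ, p in sens_diff.items():
        if not 0 <= p <= 1:
            raise ValueError(f"sens_diff[{occ}]={p} outside [0, 1]")
    rng = rng_for(seed, ARMS)
    probs = cohort.frame["occlusion"].map(sens_diff).to_numpy(dtype=float)
    mask = rng.random(len(cohort)) < probs
    return set(cohort.frame.loc[mask, "id"].tolist())


def build_arms(
    cohort: Cohort,
    params: ModelParameters,
    seed: int | np.random.Generator = 0,
    strata_dists: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assign both arms: columns ``id, occlusion, missed, mrs90_treated,
    mrs90_control``.

    The treated (CTP) arm keeps the observed 90-day mRS for everyone; in the
    control arm, missed patients receive the coupled counterfactual no-EVT
    outcome. Patients screened with CTP but without an LVO contribute
    screening costs only and are not simulated.
    """
    rng = rng_for(seed, ARMS)
    if strata_dists is None:
        strata_dists = stratum_distributions(cohort)
    df = cohort.frame
    probs = params.sens_by_occlusion(cohort.occlusion_codes())
    missed = rng.random(len(df)) < probs

    or_med = params.or_evt[0]
    preserve = not params.evt_affects_mortality
    control = df["mrs90_treated"].to_numpy().copy()
    for occ in OCCLUSIONS:
        sel = missed & (df["occlusion"] == occ).to_numpy()
        if sel.any():
            control[sel] = counterfactual_mrs(
                df.loc[sel, "mrs90_treated"].to_numpy(),
                df.loc[sel, "latent_u"].to_numpy(),
                strata_dists[occ],
                or_med,
                preserve_death=preserve,
            )
    return pd.DataFrame(
        {
            "id": df["id"].to_numpy(),
            "occlusion": df["occlusion"].to_numpy(),
            "missed": missed,
            "mrs90_treated": df["mrs90_treated"].to_numpy(),
            "mrs90_control": control,
        }
    )


def arms_to_csv(arms: pd.DataFrame, path) -> None:
    arms.to_csv(path, index=False)
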