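"""Synthetic LVO patient cohorts and cohort CSV I/O.

The generator emulates the descriptive statistics of a Dutch registry of
701 EVT-treated patients with an anterior-circulation large vessel
occlusion: occlusion-site strata ICA/M1/M2 of 168/367/166 patients,
per-stratum 90-day mRS distributions (known for 645 of 701 patients),
median age 72 (IQR 62-81), 55.6% male, and 67.3% IVT administration. The
study cohort itself is not public, so every downstream stage runs on these
synthetic cohorts (or on any cohort supplied as CSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._seeding import COHORT, COHORT_IO, rng_for
from .parameters import OCCLUSIONS

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: registry stratum sizes (ICA includes ICA-terminus)
STRATUM_COUNTS = {"ICA": 168, "M1": 367, "M2": 166}

#: 90-day mRS counts per stratum among patients with a known outcome
MRS90_COUNTS = {
    "ICA": [7, 21, 35, 20, 20, 11, 38],
    "M1": [28, 61, 87, 35, 43, 20, 65],
    "M2": [12, 33, 32, 14, 13, 11, 39],
}

COHORT_COLUMNS = ["id", "age", "sex", "occlusion", "mrs90_treated", "ivt", "latent_u"]


@dataclass
class Patient:
    """One LVO patient as observed under CTP-augmented screening.

    ``latent_u`` is the patient's uniform deviate used for the
    rank-preserving counterfactual mapping of the no-EVT 90-day mRS.
    """

    id: int
    age: int
    sex: str
    occlusion: str
    mrs90_treated: int
    ivt: bool
    latent_u: float

    def __post_init__(self):
        if not 18 <= self.age <= 110:
            raise ValueError(f"patient {self.id}: age {self.age} outside [18, 110]")
        if self.sex not in SEXES:
            raise ValueError(f"patient {self.id}: sex must be one of {SEXES}")
        if self.occlusion not in OCCLUSIONS:
            raise ValueError(
                f"patient {self.id}: occlusion must be one of {OCCLUSIONS}"
            )
        if self.mrs90_treated not in range(7):
            raise ValueError(f"patient {self.id}: mrs90_treated must be in 0..6")
        if not 0 < self.latent_u < 1:
            raise ValueError(f"patient {self.id}: latent_u must lie in (0, 1)")


@dataclass
class CohortSpec:
    """Sampling distributions for a synthetic cohort.

    Ages follow a truncated normal, calibrated so that the sample median is
    ~72 with IQR ~[62, 81]; small per-stratum location shifts mimic the
    registry's stratum medians (70/72/73 for ICA/M1/M2). mRS and age are
    drawn independently within a stratum.
    """

    strata_weights: dict[str, float]
    mrs90_dist_by_stratum: dict[str, np.ndarray]
    age_mean: float = 71.5
    age_sd: float = 13.5
    age_bounds: tuple[int, int] = (18, 100)
    age_shift_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"ICA": -2.0, "M1": 0.0, "M2": 1.0}
    )
    male_fraction: float = 0.556
    ivt_fraction: float = 0.673

    def __post_init__(self):
        w = np.array([self.strata_weights[o] for o in OCCLUSIONS])
        if np.any(w < 0):
            raise ValueError("strata weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("strata weights must sum to 1")
        for occ in OCCLUSIONS:
            p = np.asarray(self.mrs90_dist_by_stratum[occ], dtype=float)
            if p.shape != (7,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"mrs90 distribution for {occ} is not a 7-simplex")
        for frac in (self.male_fraction, self.ivt_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    @classmethod
    def default(cls) -> "CohortSpec":
        total = sum(STRATUM_COUNTS.values())
        weights = {o: STRATUM_COUNTS[o] / total for o in OCCLUSIONS}
        dists = {
            o: np.asarray(MRS90_COUNTS[o], dtype=float) / sum(MRS90_COUNTS[o])
            for o in OCCLUSIONS
        }
        return cls(strata_weights=weights, mrs90_dist_by_stratum=dists)


@dataclass
class Cohort:
    """Ordered collection of patients with provenance metadata."""

    frame: pd.DataFrame
    provenance: str = "synthetic"
    seed: Optional[int] = None

    def __post_init__(self):
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns {missing}")
        if self.frame["id"].duplicated().any():
            raise ValueError("patient ids must be unique")
        self.frame = self.frame[COHORT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[Patient]:
        for row in self.frame.itertuples(index=False):
            yield Patient(
                id=int(row.id),
                age=int(row.age),
                sex=str(row.sex),
                occlusion=str(row.occlusion),
                mrs90_treated=int(row.mrs90_treated),
                ivt=bool(row.ivt),
                latent_u=float(row.latent_u),
            )

    def occlusion_codes(self) -> np.ndarray:
        mapping = {o: i for i, o in enumerate(OCCLUSIONS)}
        return self.frame["occlusion"].map(mapping).to_numpy()

    def sex_codes(self) -> np.ndarray:
        return (self.frame["sex"] == "female").astype(int).to_numpy()


def synthesize_cohort(
    spec: Optional[CohortSpec] = None, n: int = 701, seed: int = 0
) -> Cohort:
    """Draw a synthetic cohort of ``n`` patients, reproducible from ``seed``."""
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    if spec is None:
        spec = CohortSpec.default()
    rng = rng_for(seed, COHORT)

    weights = np.array([spec.strata_weights[o] for o in OCCLUSIONS])
    occ_idx = rng.choice(len(OCCLUSIONS), size=n, p=weights / weights.sum())

    mrs = np.zeros(n, dtype=int)
    for i, occ in enumerate(OCCLUSIONS):
        mask = occ_idx == i
        if mask.any():
            mrs[mask] = rng.choice(7, size=mask.sum(), p=spec.mrs90_dist_by_stratum[occ])

    shifts = np.array([spec.age_shift_by_stratum[o] for o in OCCLUSIONS])
    loc = spec.age_mean + shifts[occ_idx]
    lo, hi = spec.age_bounds
    a = (lo - loc) / spec.age_sd
    b = (hi - loc) / spec.age_sd
    if n:
        ages = truncnorm.rvs(a, b, loc=loc, scale=spec.age_sd, random_state=rng)
    else:
        ages = np.empty(0)
    ages = np.clip(np.rint(ages), lo, hi).astype(int)

    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    ivt = rng.random(n) < spec.ivt_fraction
    latent_u = rng.random(n)
    latent_u = np.clip(latent_u, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))

    frame = pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "age": ages,
            "sex": sex,
            "occlusion": np.array(OCCLUSIONS)[occ_idx] if n else np.empty(0, dtype=object),
            "mrs90_treated": mrs,
            "ivt": ivt,
            "latent_u": latent_u,
        }
    )
    return Cohort(frame, provenance="synthetic", seed=seed)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    df = cohort.frame.copy()
    df["ivt"] = df["ivt"].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


def read_cohort(path: str | Path, seed: Optional[int] = None) -> Cohort:
    """Read a cohort CSV; rows with a missing 90-day mRS are dropped.

    A missing ``latent_u`` column is replaced by freshly drawn uniforms
    (seeded by ``seed`` when given) with a warning, since the counterfactual
    coupling needs one deviate per patient.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["id", "age", "sex", "occlusion", "mrs90_treated", "ivt"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV missing columns {missing_cols}")

    blank = df["mrs90_treated"].str.strip() == ""
    if blank.any():
        logger.warning(
            "dropped %d of %d rows with missing 90-day mRS", blank.sum(), len(df)
        )
        df = df[~blank]

    def _col(name, caster):
        out = []
        for idx, raw in zip(df.index, df[name]):
            try:
                out.append(caster(raw))
            except (ValueError, KeyError) as exc:
                raise ValueError(
                    f"malformed value {raw!r} for {name} on line {idx + 2} of {path}"
                ) from exc
        return out

    bool_map = {"true": True, "false": False, "1": True, "0": False}
    frame = pd.DataFrame(
        {
            "id": _col("id", int),
            "age": _col("age", int),
            "sex": _col("sex", str),
            "occlusion": _col("occlusion", str),
            "mrs90_treated": _col("mrs90_treated", int),
            "ivt": _col("ivt", lambda v: bool_map[str(v).strip().lower()]),
        }
    )
    if "latent_u" in df.columns and (df["latent_u"].str.strip() != "").all():
        frame["latent_u"] = _col("latent_u", float)
    else:
        logger.warning("latent_u column missing; drawing fresh uniform deviates")
        rng = rng_for(seed, COHORT_IO)
        u = rng.random(len(frame))
        frame["latent_u"] = np.clip(u, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))

    cohort = Cohort(frame, provenance="file", seed=seed)
    for patient in cohort:  # row-level invariant check
        pass
    return cohort


@dataclass
class CohortSummary:
    """Descriptive statistics of a cohort, mirroring a registry table."""

    n: int
    mrs_table: pd.DataFrame  # index mrs 0..6; count/pct per stratum and total
    stratum_counts: pd.Series
    age_median: float
    age_iqr: tuple[float, float]
    male_pct: float
    ivt_pct: float

    def to_text(self) -> str:
        lines = [
            f"n = {self.n}",
            f"age median (IQR): {self.age_median:.0f} "
            f"({self.age_iqr[0]:.0f}; {self.age_iqr[1]:.0f})",
            f"male: {self.male_pct:.1f}%   IVT: {self.ivt_pct:.1f}%",
            "occlusion strata: "
            + ", ".join(f"{o}={int(self.stratum_counts[o])}" for o in OCCLUSIONS),
            "",
            self.mrs_table.to_string(float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Counts and percentages by stratum and 90-day mRS, plus demographics."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    df = cohort.frame
    counts = (
        df.groupby(["mrs90_treated", "occlusion"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=range(7), columns=list(OCCLUSIONS), fill_value=0)
    counts["total"] = counts.sum(axis=1)
    pct = 100 * counts / counts.sum(axis=0)
    table = pd.concat({"count": counts, "pct": pct}, axis=1)
    ages = df["age"]
    return CohortSummary(
        n=len(df),
        mrs_table=table,
        stratum_counts=df["occlusion"].value_counts().reindex(OCCLUSIONS, fill_value=0),
        age_median=float(ages.median()),
        age_iqr=(float(ages.quantile(0.25)), float(ages.quantile(0.75))),
        male_pct=100 * float((df["sex"] == "male").mean()),
        ivt_pct=100 * float(df["ivt"].mean()),
    )
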