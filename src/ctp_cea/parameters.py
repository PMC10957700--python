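"""Model parameters, uncertainty distributions, and demographic fixtures.

Everything the simulation consumes is collected in :class:`ModelParameters`:
acute-care prices, per-mRS yearly follow-up costs and utilities, hazard
ratios for excess mortality and stroke recurrence, screening economics
(number needed to image, occlusion-specific sensitivity differences of
CTP-augmented detection), discounting and inflation conventions, and the
uncertainty-distribution metadata used by the probabilistic sensitivity
analysis.

Three demographic inputs are not parameters in the usual sense and ship as
generated stand-in fixtures with CSV overrides: an age/sex/calendar-year
life table (Gompertz-Makeham, calibrated on remaining life expectancy at
age 72), an annual inflation series, and a baseline stroke-recurrence
probability by years since the index stroke.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: two-sided 97.5% normal quantile used for CI <-> sigma conversion.
Z975 = 1.959964

#: mRS levels as stored in per-level tables; 0 and 1 share one level.
MRS_LEVELS = ("mrs01", "mrs2", "mrs3", "mrs4", "mrs5", "mrs6")

#: index into a per-level 6-vector for each mRS state 0..6
_STATE_TO_LEVEL = np.array([0, 0, 1, 2, 3, 4, 5])

OCCLUSIONS = ("ICA", "M1", "M2")


# ---------------------------------------------------------------------------
# Uncertainty distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted parametric uncertainty distribution for one model input.

    Families mirror the usual cost-effectiveness conventions: log-normal for
    ratios (odds/hazard ratios), gamma for costs, beta for utilities, and a
    degenerate ``fixed`` point mass for inputs without sampling uncertainty.

    Parameters by family:

    - ``lognormal``: ``(mu, sigma)`` on the log scale
    - ``gamma``: ``(shape, scale)``
    - ``beta``: ``(alpha, beta)``
    - ``fixed``: ``(value,)``
    """

    family: Literal["lognormal", "gamma", "beta", "fixed"]
    params: tuple

    def rvs(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        """Draw from the distribution with ``rng``; ``fixed`` consumes no draws."""
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size)
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size)
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        value = self.params[0]
        return value if size is None else np.full(size, value)

    def mean(self) -> float:
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        return self.params[0]

    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.params[0])
        if self.family == "fixed":
            return self.params[0]
        raise NotImplementedError(f"median not defined here for {self.family}")


def lognormal_from_ci(median: float, ci_low: float, ci_high: float) -> DistributionSpec:
    """Log-normal from a reported median and 95% CI.

    ``mu = ln(median)``; ``sigma = (ln(ci_high) - ln(ci_low)) / (2 * 1.959964)``.
    """
    if median <= 0 or ci_low <= 0 or ci_high <= 0:
        raise ValueError("lognormal_from_ci requires positive median and CI bounds")
    if not (ci_low <= median <= ci_high):
        raise ValueError(f"CI ({ci_low}, {ci_high}) must bracket the median {median}")
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2 * Z975)
    return DistributionSpec("lognormal", (math.log(median), sigma))


def gamma_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Gamma by method of moments: shape ``(mean/sd)^2``, scale ``sd^2/mean``."""
    if mean <= 0:
        raise ValueError("gamma_from_mean_sd requires mean > 0")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec("fixed", (mean,))
    return DistributionSpec("gamma", ((mean / sd) ** 2, sd**2 / mean))


def beta_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Beta by method of moments; infeasible variance degrades to a point mass.

    ``alpha = mean * (mean(1-mean)/sd^2 - 1)`` and the mirrored ``beta``. When
    ``sd^2 >= mean(1-mean)`` (method of moments infeasible) or the mean sits on
    the support boundary, a point mass at the mean is returned with a warning.
    """
    if not 0 <= mean <= 1:
        raise ValueError("beta_from_mean_sd requires mean in [0, 1]")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec("fixed", (mean,))
    feasible = mean not in (0.0, 1.0) and sd**2 < mean * (1 - mean)
    if not feasible:
        if mean not in (0.0, 1.0):
            warnings.warn(
                f"beta variance {sd ** 2:.4g} infeasible for mean {mean}; "
                "using point mass",
                stacklevel=2,
            )
        return DistributionSpec("fixed", (mean,))
    nu = mean * (1 - mean) / sd**2 - 1
    return DistributionSpec("beta", (mean * nu, (1 - mean) * nu))


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


class LifeTable:
    """Annual death probability ``q(age, sex, calendar_year)``.

    Two backings: a parametric Gompertz-Makeham law with a yearly mortality
    improvement factor (the shipped stand-in), or an explicit grid loaded from
    a ``age,sex,year,qx`` CSV (e.g. a national actuarial table). Ages and
    years outside the covered range are clamped with a logged warning.
    """

    def __init__(
        self,
        ages: np.ndarray,
        qx_by_sex: dict[str, np.ndarray],
        ref_year: int = 2022,
        improvement: float = 0.0,
        qx_by_sex_year: Optional[dict[tuple[str, int], np.ndarray]] = None,
    ):
        self.ages = np.asarray(ages, dtype=int)
        self.qx_by_sex = {k: np.asarray(v, dtype=float) for k, v in qx_by_sex.items()}
        self.ref_year = ref_year
        self.improvement = improvement
        self.qx_by_sex_year = qx_by_sex_year
        self._years = (
            sorted({y for (_, y) in qx_by_sex_year}) if qx_by_sex_year else None
        )
        self._warned_clamp = False

    def q(self, age, sex, year) -> np.ndarray:
        """Vectorised annual death probability; ``sex`` is 'male'/'female' or
        an integer array (0=male, 1=female)."""
        age = np.asarray(age)
        lo, hi = self.ages[0], self.ages[-1]
        if np.any(age > hi) or np.any(age < lo):
            if not self._warned_clamp:
                logger.warning(
                    "age outside life table range [%d, %d]; clamping", lo, hi
                )
                self._warned_clamp = True
        idx = np.clip(age, lo, hi) - lo
        sex_arr = self._sex_labels(sex, age.shape if age.shape else None)
        if self.qx_by_sex_year is not None:
            yr = int(np.clip(year, self._years[0], self._years[-1]))
            q = np.where(
                sex_arr == 0,
                self.qx_by_sex_year[("male", yr)][idx],
                self.qx_by_sex_year[("female", yr)][idx],
            )
            return q
        q = np.where(
            sex_arr == 0, self.qx_by_sex["male"][idx], self.qx_by_sex["female"][idx]
        )
        factor = (1.0 - self.improvement) ** (int(year) - self.ref_year)
        return np.minimum(1.0, q * factor)

    @staticmethod
    def _sex_labels(sex, shape):
        if isinstance(sex, str):
            code = 0 if sex == "male" else 1
            return np.full(shape, code) if shape else np.asarray(code)
        return np.asarray(sex)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"life table fixture not found: {path}")
        df = pd.read_csv(path)
        required = {"age", "sex", "year", "qx"}
        if not required.issubset(df.columns):
            raise ValueError(f"life table CSV must have columns {sorted(required)}")
        ages = np.arange(df["age"].min(), df["age"].max() + 1)
        grid: dict[tuple[str, int], np.ndarray] = {}
        for (sex, year), sub in df.groupby(["sex", "year"]):
            sub = sub.set_index("age")["qx"].reindex(ages).ffill().bfill()
            grid[(sex, int(year))] = sub.to_numpy(dtype=float)
        any_year = sorted({y for (_, y) in grid})[0]
        return cls(
            ages,
            {
                "male": grid.get(("male", any_year), np.zeros_like(ages, dtype=float)),
                "female": grid.get(
                    ("female", any_year), np.zeros_like(ages, dtype=float)
                ),
            },
            qx_by_sex_year=grid,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in ("male", "female"):
            q = self.q(self.ages, sex, self.ref_year)
            rows.append(
                pd.DataFrame(
                    {"age": self.ages, "sex": sex, "year": self.ref_year, "qx": q}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _gompertz_makeham_q(ages, makeham_a, b, c):
    return np.minimum(1.0, makeham_a + b * c**ages)


def life_expectancy(table: LifeTable, age: int, sex: str, year: int) -> float:
    """Curtate life expectancy plus half a year, from the table's hazards."""
    ages = np.arange(age, table.ages[-1] + 1)
    q = np.asarray([float(table.q(a, sex, year)) for a in ages])
    surv = np.cumprod(1 - q)
    return float(surv.sum()) + 0.5


@lru_cache(maxsize=8)
def default_life_table(
    le_female: float = 14.0,
    le_male: float = 12.0,
    at_age: int = 72,
    makeham_a: float = 2e-4,
    gompertz_c: float = 1.1,
    ref_year: int = 2022,
    improvement: float = 0.005,
) -> LifeTable:
    """Stand-in Dutch-style life table from a Gompertz-Makeham law.

    ``q(age) = min(1, a + b * c^age)`` with ``b`` calibrated per sex so that
    remaining life expectancy at ``at_age`` in ``ref_year`` hits the target
    (14 y female / 12 y male by default). A mild annual mortality improvement
    applies across calendar years. This is a documented synthetic stand-in
    for a national actuarial table; pass a real table via ``life_table_csv``.
    """
    ages = np.arange(0, 121)

    def _le_given_b(b):
        q = _gompertz_makeham_q(np.arange(at_age, 121), makeham_a, b, gompertz_c)
        return float(np.cumprod(1 - q).sum()) + 0.5

    qx = {}
    for sex, target in (("male", le_male), ("female", le_female)):
        b = brentq(lambda x: _le_given_b(10**x) - target, -9, -2, xtol=1e-12)
        qx[sex] = _gompertz_makeham_q(ages, makeham_a, 10**b, gompertz_c)
    return LifeTable(ages, qx, ref_year=ref_year, improvement=improvement)


# ---------------------------------------------------------------------------
# Inflation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InflationSeries:
    """Annual inflation fractions by calendar year (historical + forecast)."""

    rates: dict[int, float]

    def factor(self, from_year: int, to_year: int) -> float:
        """Compound factor over years in ``(from_year, to_year]``; symmetric
        deflation when ``to_year < from_year``."""
        if to_year >= from_year:
            years = range(from_year + 1, to_year + 1)
            invert = False
        else:
            years = range(to_year + 1, from_year + 1)
            invert = True
        f = 1.0
        for y in years:
            if y not in self.rates:
                raise KeyError(f"inflation series does not cover year {y}")
            f *= 1.0 + self.rates[y]
        return 1.0 / f if invert else f

    @classmethod
    def default(cls, historical: float = 0.02, forecast: float = 0.025) -> "InflationSeries":
        """Dutch-style stand-in: ~2%/yr through 2022, 2.5%/yr forecast."""
        rates = {y: historical for y in range(2016, 2023)}
        rates.update({y: forecast for y in range(2023, 2046)})
        return cls(rates)

    @classmethod
    def from_csv(cls, path: str | Path) -> "InflationSeries":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"inflation fixture not found: {path}")
        df = pd.read_csv(path)
        if not {"year", "rate"}.issubset(df.columns):
            raise ValueError("inflation CSV must have columns year,rate")
        return cls({int(r.year): float(r.rate) for r in df.itertuples()})


def read_recurrence_csv(path: str | Path) -> list[float]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recurrence fixture not found: {path}")
    df = pd.read_csv(path)
    if not {"years_since", "prob"}.issubset(df.columns):
        raise ValueError("recurrence CSV must have columns years_since,prob")
    return df.sort_values("years_since")["prob"].astype(float).tolist()


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------


class ModelParameters(BaseModel):
    """All model inputs with their uncertainty metadata.

    Per-level tables are keyed ``mrs01, mrs2, ..., mrs6`` (mRS 0 and 1 share
    one level throughout). ``(mean, sd)`` pairs feed the PSA distributions;
    the deterministic baseline uses the means (the median for ratios).
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # economics conventions
    wtp: float = 80_000.0
    horizon_years: int = 5
    start_year: int = 2022
    cost_reference_year: int = 2015
    discount_rate_qaly: float = 0.04
    discount_rate_cost: float = 0.015
    overhead_factor: float = 1.42
    overhead_applies_to_ctp: bool = True

    # screening economics
    nni: float = 8.3
    sens_diff: dict[str, float] = {"ICA": 0.08, "M1": 0.16, "M2": 0.16}

    # treatment effect: (median, ci_low, ci_high) of the common OR for EVT
    or_evt: tuple[float, float, float] = (1.67, 1.21, 2.30)
    #: whether the EVT odds shift also moves the death cutpoint P(mRS<=5).
    evt_affects_mortality: bool = False

    # acute prices (euro)
    cost_evt: float = 9_924.50
    cost_ivt: float = 950.82
    cost_ctp: float = 251.40
    cost_ncct_cta: float = 0.0

    # per-level (mean, sd) tables
    utilities: dict[str, tuple[float, float]] = {
        "mrs01": (0.94, 0.09),
        "mrs2": (0.80, 0.17),
        "mrs3": (0.68, 0.24),
        "mrs4": (0.39, 0.26),
        "mrs5": (0.24, 0.25),
        "mrs6": (0.0, 0.01),
    }
    costs_y1: dict[str, tuple[float, float]] = {
        "mrs01": (33_402, 31_930),
        "mrs2": (52_804, 23_571),
        "mrs3": (82_452, 35_333),
        "mrs4": (112_414, 35_786),
        "mrs5": (96_640, 30_463),
        "mrs6": (21_112, 17_350),
    }
    costs_y2: dict[str, tuple[float, float]] = {
        "mrs01": (5_934, 15_918),
        "mrs2": (8_543, 14_844),
        "mrs3": (19_235, 15_999),
        "mrs4": (43_193, 45_640),
        "mrs5": (56_425, 24_252),
        "mrs6": (423, 3_196),
    }
    costs_y3plus: dict[str, tuple[float, float]] = {
        "mrs01": (3_633, 9_087),
        "mrs2": (7_318, 13_770),
        "mrs3": (16_276, 11_753),
        "mrs4": (31_037, 19_928),
        "mrs5": (54_997, 24_874),
        "mrs6": (374, 3_118),
    }

    # excess mortality (state 6 is absorbing, no HR)
    hr_mortality: dict[str, float] = {
        "mrs01": 1.54,
        "mrs2": 2.17,
        "mrs3": 3.18,
        "mrs4": 4.55,
        "mrs5": 6.55,
    }
    #: stand-in multiplicative 95% CI half-width for the mortality HRs
    hr_mortality_ci_factor: float = 1.3

    # recurrence: baseline by years since index stroke (last value carried
    # forward), times an age-band x mRS-band hazard ratio (stand-ins).
    recurrence_baseline: list[float] = [0.04, 0.035, 0.03, 0.025, 0.02]
    hr_recurrence_mrs: dict[str, float] = {"mrs01": 1.0, "mrs23": 1.4, "mrs45": 2.0}
    hr_recurrence_age_edges: tuple[int, int] = (65, 75)
    hr_recurrence_age_factors: tuple[float, float, float] = (0.9, 1.0, 1.1)
    hr_recurrence_sigma: float = 0.15

    n_psa: int = 1000

    # optional fixture overrides
    life_table_csv: Optional[str] = None
    inflation_csv: Optional[str] = None
    recurrence_csv: Optional[str] = None

    # ---------------- validation ----------------

    @field_validator("discount_rate_qaly", "discount_rate_cost")
    @classmethod
    def _rate_valid(cls, v):
        if not 0 <= v <= 1:
            raise ValueError(f"discount rate {v} outside [0, 1]")
        return v

    @field_validator("cost_evt", "cost_ivt", "cost_ctp", "cost_ncct_cta")
    @classmethod
    def _cost_nonneg(cls, v):
        if v < 0:
            raise ValueError("costs must be non-negative")
        return v

    @field_validator("sens_diff")
    @classmethod
    def _sens_valid(cls, v):
        for occ, p in v.items():
            if occ not in OCCLUSIONS:
                raise ValueError(f"unknown occlusion site {occ!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"sens_diff[{occ}]={p} outside [0, 1]")
        return v

    @field_validator("utilities")
    @classmethod
    def _utilities_valid(cls, v):
        for level, (mean, sd) in v.items():
            if not -0.1 <= mean <= 1:
                raise ValueError(f"utilities[{level}] mean {mean} outside [-0.1, 1]")
            if sd < 0:
                raise ValueError("utility sd must be non-negative")
        if v.get("mrs6", (0.0, 0.0))[0] != 0.0:
            raise ValueError("utilities[mrs6] mean must be 0 (death)")
        return v

    @field_validator("costs_y1", "costs_y2", "costs_y3plus")
    @classmethod
    def _costs_valid(cls, v):
        for level, (mean, sd) in v.items():
            if mean < 0 or sd < 0:
                raise ValueError(f"cost table entry {level} must be non-negative")
        return v

    @field_validator("hr_mortality", "hr_recurrence_mrs")
    @classmethod
    def _hr_valid(cls, v):
        for level, hr in v.items():
            if hr < 0:
                raise ValueError(f"hazard ratio {level} must be non-negative")
        return v

    @field_validator("recurrence_baseline")
    @classmethod
    def _recurrence_valid(cls, v):
        if not v:
            raise ValueError("recurrence_baseline must be non-empty")
        for p in v:
            if not 0 <= p <= 1:
                raise ValueError("recurrence probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _or_valid(self):
        med, lo, hi = self.or_evt
        if not (0 < lo <= med <= hi):
            raise ValueError(f"or_evt (median, lo, hi) = {self.or_evt} invalid")
        return self

    # ---------------- derived state vectors ----------------

    def _level_vector(self, table: dict[str, tuple[float, float]], which=0) -> np.ndarray:
        vals = np.array([table[l][which] for l in MRS_LEVELS], dtype=float)
        return vals[_STATE_TO_LEVEL]

    def utility_by_state(self) -> np.ndarray:
        """Mean utility per mRS state 0..6 (state 6 fixed at 0)."""
        return self._level_vector(self.utilities)

    def hr_mortality_by_state(self) -> np.ndarray:
        """Mortality HR per mRS state 0..6 (state 6 unused, set to 0)."""
        vals = [self.hr_mortality[l] for l in MRS_LEVELS[:-1]] + [0.0]
        return np.asarray(vals, dtype=float)[_STATE_TO_LEVEL]

    def cost_tables_by_state(self, inflate: bool = True) -> np.ndarray:
        """(3, 7) mean yearly follow-up cost per [year-band, mRS state].

        Bands are year 1, year 2, year 3 onward. When ``inflate`` is true,
        values are carried from the cost reference year to the simulation
        start year with the inflation series (constant start-year euros
        thereafter).
        """
        raw = np.stack(
            [
                self._level_vector(self.costs_y1),
                self._level_vector(self.costs_y2),
                self._level_vector(self.costs_y3plus),
            ]
        )
        if inflate:
            raw = raw * self.inflation.factor(self.cost_reference_year, self.start_year)
        return raw

    def hr_recurrence(self, age, mrs) -> np.ndarray:
        """Recurrence HR for (age, current mRS state), vectorised."""
        age = np.asarray(age)
        mrs = np.asarray(mrs)
        mrs_factor = np.select(
            [mrs <= 1, mrs <= 3],
            [self.hr_recurrence_mrs["mrs01"], self.hr_recurrence_mrs["mrs23"]],
            default=self.hr_recurrence_mrs["mrs45"],
        )
        e0, e1 = self.hr_recurrence_age_edges
        f = self.hr_recurrence_age_factors
        age_factor = np.select([age < e0, age < e1], [f[0], f[1]], default=f[2])
        return mrs_factor * age_factor

    def recurrence_baseline_at(self, years_since: int) -> float:
        """Baseline recurrence probability; the last value carries forward."""
        if years_since < 1:
            raise ValueError("years_since_stroke must be >= 1")
        idx = min(years_since, len(self.recurrence_baseline)) - 1
        return self.recurrence_baseline[idx]

    def sens_by_occlusion(self, occ_codes: np.ndarray) -> np.ndarray:
        """Missed-LVO probability per patient from integer occlusion codes."""
        table = np.array([self.sens_diff[o] for o in OCCLUSIONS])
        return table[np.asarray(occ_codes)]

    # ---------------- PSA distribution specs ----------------

    def or_evt_spec(self) -> DistributionSpec:
        return lognormal_from_ci(*self.or_evt)

    def hr_mortality_specs(self) -> dict[str, DistributionSpec]:
        f = self.hr_mortality_ci_factor
        return {
            level: lognormal_from_ci(hr, hr / f, hr * f)
            for level, hr in self.hr_mortality.items()
        }

    def cost_specs(self) -> dict[str, dict[str, DistributionSpec]]:
        out = {}
        for name, table in (
            ("costs_y1", self.costs_y1),
            ("costs_y2", self.costs_y2),
            ("costs_y3plus", self.costs_y3plus),
        ):
            out[name] = {l: gamma_from_mean_sd(m, s) for l, (m, s) in table.items()}
        return out

    def utility_specs(self) -> dict[str, DistributionSpec]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return {
                l: beta_from_mean_sd(m, s) for l, (m, s) in self.utilities.items()
            }

    # ---------------- fixtures ----------------

    @property
    def life_table(self) -> LifeTable:
        if not hasattr(self, "_life_table"):
            object.__setattr__(
                self,
                "_life_table",
                LifeTable.from_csv(self.life_table_csv)
                if self.life_table_csv
                else default_life_table(),
            )
        return self._life_table

    @property
    def inflation(self) -> InflationSeries:
        if not hasattr(self, "_inflation"):
            object.__setattr__(
                self,
                "_inflation",
                InflationSeries.from_csv(self.inflation_csv)
                if self.inflation_csv
                else InflationSeries.default(),
            )
        return self._inflation

    @model_validator(mode="after")
    def _load_recurrence_csv(self):
        if self.recurrence_csv and not getattr(self, "_recurrence_loaded", False):
            object.__setattr__(self, "_recurrence_loaded", True)
            self.recurrence_baseline = read_recurrence_csv(self.recurrence_csv)
        return self

    # ---------------- scalar access for one-way sensitivity ----------------

    def scalar_names(self) -> list[str]:
        """Dotted names of the positive scalars eligible for one-way analysis."""
        names = ["cost_ctp", "cost_evt", "cost_ivt",
                 "discount_rate_qaly", "discount_rate_cost"]
        names += [f"utilities.{l}" for l in MRS_LEVELS[:-1]]
        for table in ("costs_y1", "costs_y2", "costs_y3plus"):
            names += [f"{table}.{l}" for l in MRS_LEVELS]
        names += [f"hr_mortality.{l}" for l in MRS_LEVELS[:-1]]
        return names

    def with_scaled(self, name: str, factor: float) -> "ModelParameters":
        """Copy with the named scalar mean multiplied by ``factor``.

        Utilities are clipped to their feasible upper bound of 1, so a +10%
        perturbation of a utility near 1 saturates (standard practice in
        one-way sensitivity analyses).
        """
        data = self.model_dump()
        if "." in name:
            table, level = name.split(".", 1)
            if table not in data or level not in data[table]:
                raise KeyError(f"unknown scalar parameter {name!r}")
            entry = data[table][level]
            if isinstance(entry, (tuple, list)):
                scaled = entry[0] * factor
                if table == "utilities":
                    scaled = min(scaled, 1.0)
                data[table][level] = (scaled, entry[1])
            else:
                data[table][level] = entry * factor
        else:
            if name not in data or not isinstance(data[name], (int, float)):
                raise KeyError(f"unknown scalar parameter {name!r}")
            data[name] = data[name] * factor
        if name == "utilities.mrs6":
            raise KeyError("the death utility is fixed at 0")
        return ModelParameters(**data)

    # ---------------- I/O ----------------

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_parameters(config_path: str | Path | None = None, **overrides) -> ModelParameters:
    """Load parameters from a flat YAML config; omitted keys take defaults.

    Unknown keys are rejected. Fixture CSV paths referenced by the config are
    resolved eagerly so a missing file fails at load with the named path.
    """
    data: dict = {}
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a YAML mapping of parameter names")
        data.update(loaded)
    data.update(overrides)
    params = ModelParameters(**data)
    # touch fixtures so missing files surface now, naming the path
    _ = params.life_table
    _ = params.inflation
    return params
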