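"""Screening economics: number needed to image, detection-sensitivity
evidence, and national-scale extrapolation.

The number needed to image (NNI) is the expected count of suspected-stroke
patients screened with CTP per detected EVT-eligible large vessel
occlusion: the reciprocal of the product of the acute-ischemic-stroke
share among suspected strokes and the LVO share among AIS. Published
prevalence data bound it between roughly 4.3 (optimistic: high AIS and LVO
shares) and 8.3 (conservative: 50% AIS, 24% LVO).

The sensitivity difference of adding CTP to NCCT+CTA is taken from reader
studies, computed relative to the CTP-augmented protocol:
``(sens_with_ctp - sens_without) / sens_with_ctp``.
"""

from __future__ import annotations

import pandas as pd

#: reader studies of LVO-detection sensitivity with and without CTP (%).
#: Where a study reported several raters, the lowest- and highest-gain
#: raters appear as separate rows.
READER_STUDIES = pd.DataFrame(
    [
        ("olive_gadea_2017", "ICA", 223, 91.7, 100.0),
        ("olive_gadea_2017", "M1", 373, 84.4, 100.0),
        ("bathla_2019_low", "M2", 462, 78.0, 91.0),
        ("bathla_2019_high", "M2", 462, 76.0, 93.0),
        ("hopyan_2010", "any", 191, 69.5, 55.4 + 69.5),
        ("becks_2019_low", "proximal", 363, 89.0, 89.0),
        ("becks_2019_high", "proximal", 363, 94.0, 100.0),
    ],
    columns=["study", "occlusion", "n", "sens_ncct_cta", "sens_with_ctp"],
)

#: suspected-stroke final diagnoses: (region/source, year, AIS, TIA-or-mimic)
SUSPECTED_STROKE_COUNTS = pd.DataFrame(
    [
        ("presto_rotterdam", 2018, 522, 445),
        ("amsterdam_ambulance", 2019, 623, 634),
        ("amsterdam_ambulance", 2020, 712, 704),
        ("amsterdam_ambulance", 2021, 853, 643),
        ("amsterdam_ambulance", 2022, 797, 591),
    ],
    columns=["source", "year", "n_ais", "n_other"],
)

#: approximate yearly national EVT volume in the Netherlands
NATIONAL_EVT_PER_YEAR = 2350


def number_needed_to_image(ais_fraction: float, lvo_given_ais_fraction: float) -> float:
    """CTPs acquired per detected EVT-eligible LVO: ``1 / (p_AIS * p_LVO|AIS)``."""
    if not 0 < ais_fraction <= 1 or not 0 < lvo_given_ais_fraction <= 1:
        raise ValueError("prevalence fractions must lie in (0, 1]")
    return 1.0 / (ais_fraction * lvo_given_ais_fraction)


def ais_share_percent(n_ais: int, n_other: int) -> float:
    """Share of acute ischemic stroke among suspected strokes, in percent."""
    if n_ais < 0 or n_other < 0 or n_ais + n_other == 0:
        raise ValueError("counts must be non-negative with a positive total")
    return 100.0 * n_ais / (n_ais + n_other)


def sensitivity_difference_percent(sens_with_ctp: float, sens_without: float) -> float:
    """Relative sensitivity gain of adding CTP, as a percentage of the
    CTP-augmented sensitivity (inputs in percent)."""
    if sens_with_ctp <= 0:
        raise ValueError("CTP-augmented sensitivity must be positive")
    if sens_without < 0 or sens_without > sens_with_ctp:
        raise ValueError("sensitivity without CTP must lie in [0, sens_with_ctp]")
    return 100.0 * (sens_with_ctp - sens_without) / sens_with_ctp


def national_annual_impact(
    delta_qalys_per_patient: float,
    delta_costs_per_patient: float,
    evt_per_year: int = NATIONAL_EVT_PER_YEAR,
) -> dict:
    """Scale per-LVO-patient incremental outcomes to a yearly national volume.

    Returns QALYs gained per year and million euros saved per year (positive
    savings mean the CTP strategy is cheaper).
    """
    return {
        "qalys_gained": evt_per_year * delta_qalys_per_patient,
        "million_eur_saved": evt_per_year * (-delta_costs_per_patient) / 1e6,
        "evt_per_year": evt_per_year,
    }
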