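"""QALY and direct-cost payoffs for each person-year.

Baseline utility starts at 1 at birth and falls linearly to the sex-specific
age-18 value, then follows the adult tariff table.  Labelled person-years
lose utility for time spent at each control level and per exacerbation
(pro-rated by event duration), and accrue direct costs per control-time and
per event.  Unlabelled person-years accrue baseline utility and zero
asthma cost.
"""

from __future__ import annotations

import numpy as np

from .params_io import FEMALE, PayoffTable


def baseline_utility(sex, age, table: PayoffTable):
    """Baseline QALY weight by sex and completed age.

    Age 0 -> 1 exactly; ages 1-17 interpolate linearly towards the age-18
    value; ages >= 18 use the adult table, clamped at its oldest entry.
    """
    sex = np.asarray(sex)
    age = np.asarray(age)
    if (age < 0).any():
        raise ValueError("age must be non-negative")
    u18 = np.where(sex == FEMALE, table.utility_at_18_female, table.utility_at_18_male)
    child = 1.0 + (u18 - 1.0) * (np.minimum(age, 18) / 18.0)
    adult_f = np.asarray(table.adult_utility_female)
    adult_m = np.asarray(table.adult_utility_male)
    idx_f = np.clip(age - 18, 0, len(adult_f) - 1).astype(int)
    idx_m = np.clip(age - 18, 0, len(adult_m) - 1).astype(int)
    adult = np.where(sex == FEMALE, adult_f[idx_f], adult_m[idx_m])
    out = np.where(age < 18, child, adult)
    return float(out) if out.ndim == 0 else out


def control_disutility(ct, table: PayoffTable):
    """Annual disutility from asthma control: control-time-weighted tariffs.

    ``ct`` is (..., 3) ordered (UC, PC, WC); a full uncontrolled year costs
    0.10, partially controlled 0.09, well-controlled 0.06 QALYs.
    """
    ct = np.asarray(ct, dtype=float)
    du = np.asarray(table.control_disutility)
    out = ct @ du
    return float(out) if out.ndim == 0 else out


def exacerbation_disutility(counts, table: PayoffTable):
    """Annual disutility from exacerbations.

    Each event of severity j contributes (full-year disutility_j) x
    (duration_j in weeks)/52; counts is (..., 4) ordered mild, moderate,
    severe, very severe.
    """
    counts = np.asarray(counts, dtype=float)
    per_event = np.asarray(table.exac_disutility) * np.asarray(
        table.exac_duration_weeks
    ) / 52.0
    out = counts @ per_event
    return float(out) if out.ndim == 0 else out


def person_year_utility(sex, age, has_label, ct, counts, table: PayoffTable):
    """Utility accrued this person-year, floored at 0.

    Unlabelled: the baseline weight.  Labelled: baseline minus control and
    exacerbation disutilities.
    """
    base = baseline_utility(sex, age, table)
    has_label = np.asarray(has_label)
    loss = control_disutility(ct, table) + exacerbation_disutility(counts, table)
    out = np.where(has_label, np.maximum(0.0, base - loss), base)
    return float(out) if out.ndim == 0 else out


def person_year_cost(has_label, ct, counts, table: PayoffTable):
    """Direct asthma cost this person-year (0 if unlabelled)."""
    has_label = np.asarray(has_label)
    ct = np.asarray(ct, dtype=float)
    counts = np.asarray(counts, dtype=float)
    cost = ct @ np.asarray(table.control_cost) + counts @ np.asarray(table.exac_cost)
    out = np.where(has_label, cost, 0.0)
    return float(out) if out.ndim == 0 else out
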