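"""Asthma occurrence: prevalence at entry, annual incidence, reassessment.

The model tracks *labelled* (diagnosed) asthma.  Entrants (initial
population and immigrants) receive a label from the prevalence equation;
unlabelled residents can gain one each cycle from the incidence equation;
labelled residents are reassessed each cycle and keep the label with a
(calibrated) probability — losing it returns them to the susceptible pool.

Both occurrence equations are logistic regressions in calendar year, sex and
age with risk-factor log-odds-ratio add-ons for family history (FHA) and
infant antibiotics (IAE).  No label is ever assigned below the minimum
asthma age (default 3).  Calendar year is clamped into
[year_clamp_low, stabilisation_year] before entering either equation, so
rates are flat outside that window.

Polynomial coding (documented in the schema): year enters as
(year - 2010)/10 and age as (age - 40)/40, as raw centred powers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .params_io import (
    EffectCoefficients,
    OccurrenceCoefficients,
    OCC_AGE_CENTER,
    OCC_AGE_SCALE,
    OCC_YEAR_CENTER,
    OCC_YEAR_SCALE,
)


def _clamp_year(year, coeffs: OccurrenceCoefficients, stabilisation_year: int):
    return np.clip(np.asarray(year, dtype=float), coeffs.year_clamp_low, stabilisation_year)


def fha_log_or(fha, age, effects: EffectCoefficients, target: str):
    """Log odds ratio contributed by family history of asthma.

    Zero unless the flag is set and age >= 3; then b0 + b1*(min(age, 5) - 3)
    for the chosen equation (``target`` in {"prev", "inc"}).
    """
    b0, b1 = effects.fha_prev if target == "prev" else effects.fha_inc
    fha = np.asarray(fha, dtype=float)
    age = np.asarray(age, dtype=float)
    active = (fha > 0) & (age >= effects.fha_age_floor)
    ramp = np.minimum(age, effects.fha_age_cap) - effects.fha_age_floor
    out = np.where(active, b0 + b1 * ramp, 0.0)
    return float(out) if out.ndim == 0 else out


def iae_log_or(dose, age, effects: EffectCoefficients, target: str):
    """Log odds ratio contributed by infant antibiotic courses.

    Zero outside ages 3-7 or with zero courses; inside the window
    b0 + b1*(age - 3) + b2*min(dose, 3).
    """
    b0, b1, b2 = effects.iae_prev if target == "prev" else effects.iae_inc
    dose = np.asarray(dose, dtype=float)
    age = np.asarray(age, dtype=float)
    lo, hi = effects.iae_age_window
    active = (dose > 0) & (age >= lo) & (age <= hi)
    out = np.where(
        active, b0 + b1 * (age - lo) + b2 * np.minimum(dose, effects.iae_dose_cap), 0.0
    )
    return float(out) if out.ndim == 0 else out


def _poly_terms_prev(yc: np.ndarray, ac: np.ndarray) -> np.ndarray:
    """The 17 per-sex prevalence terms: year, year^2, age..age^5,
    year*age..year*age^5, year^2*age..year^2*age^5 (in that order)."""
    apows = [ac**k for k in range(1, 6)]
    cols = [yc, yc**2] + apows
    cols += [yc * a for a in apows]
    cols += [yc**2 * a for a in apows]
    return np.stack(cols, axis=-1)


def prevalence_linear_predictor(year, sex, age, coeffs: OccurrenceCoefficients,
                                stabilisation_year: int = 2025):
    """Base (risk-factor-free) logit of prevalence."""
    year = _clamp_year(year, coeffs, stabilisation_year)
    sex = np.asarray(sex)
    age = np.asarray(age, dtype=float)
    yc = (year - OCC_YEAR_CENTER) / OCC_YEAR_SCALE
    ac = (age - OCC_AGE_CENTER) / OCC_AGE_SCALE
    yc, ac = np.broadcast_arrays(yc, ac)
    terms = _poly_terms_prev(yc, ac)
    beta = np.asarray(coeffs.prev_beta).reshape(2, 17)
    return coeffs.prev_intercept + np.einsum("...k,...k->...", terms, beta[sex])


def incidence_linear_predictor(year, sex, age, coeffs: OccurrenceCoefficients,
                               stabilisation_year: int = 2025):
    """Base (risk-factor-free) logit of annual incidence."""
    year = _clamp_year(year, coeffs, stabilisation_year)
    sex = np.asarray(sex)
    age = np.asarray(age, dtype=float)
    yc = (year - OCC_YEAR_CENTER) / OCC_YEAR_SCALE
    ac = (age - OCC_AGE_CENTER) / OCC_AGE_SCALE
    terms = np.stack([ac**k for k in range(1, 6)], axis=-1)
    beta = np.asarray(coeffs.inc_beta).reshape(2, 5)
    return (
        coeffs.inc_intercept
        + coeffs.inc_year_slope * yc
        + np.einsum("...k,...k->...", terms, beta[sex])
    )


def prevalence_probability(
    year,
    sex,
    age,
    fha,
    iae,
    coeffs: OccurrenceCoefficients,
    effects: EffectCoefficients,
    min_asthma_age: int = 3,
    stabilisation_year: int = 2025,
    offset=0.0,
):
    """Probability an entrant of the given profile carries an asthma label.

    Inverse-logit of the base linear predictor plus risk-factor log-ORs plus
    an additive calibration ``offset``; exactly 0 below ``min_asthma_age``.
    """
    eta = prevalence_linear_predictor(year, sex, age, coeffs, stabilisation_year)
    eta = eta + fha_log_or(fha, age, effects, "prev")
    eta = eta + iae_log_or(iae, age, effects, "prev") + offset
    p = expit(eta)
    out = np.where(np.asarray(age) < min_asthma_age, 0.0, p)
    return float(out) if out.ndim == 0 else out


def incidence_probability(
    year,
    sex,
    age,
    fha,
    iae,
    coeffs: OccurrenceCoefficients,
    effects: EffectCoefficients,
    min_asthma_age: int = 3,
    stabilisation_year: int = 2025,
    offset=0.0,
):
    """Probability an unlabelled individual gains a label this cycle."""
    eta = incidence_linear_predictor(year, sex, age, coeffs, stabilisation_year)
    eta = eta + fha_log_or(fha, age, effects, "inc")
    eta = eta + iae_log_or(iae, age, effects, "inc") + offset
    p = expit(eta)
    out = np.where(np.asarray(age) < min_asthma_age, 0.0, p)
    return float(out) if out.ndim == 0 else out


def reassess_label(keep_p, rng: np.random.Generator, size: int | None = None):
    """Bernoulli label retention: True keeps the label, False is remission.

    Remitted individuals re-enter the susceptible pool; onset age and the
    person-level control intercept are retained in history by the caller.
    """
    keep_p = np.asarray(keep_p, dtype=float)
    if ((keep_p < 0) | (keep_p > 1)).any():
        raise ValueError("keep probabilities must lie in [0, 1]")
    if size is None and keep_p.ndim == 0:
        return bool(rng.random() < keep_p)
    return rng.random(size if size is not None else keep_p.shape) < keep_p
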