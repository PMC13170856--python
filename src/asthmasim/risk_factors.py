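"""Risk-factor assignment: family history of asthma and infant antibiotics.

Both factors are set once per individual at entry.  Family history at birth
is a single Bernoulli probability shared by everyone regardless of year and
sex (trend data support treating it as stable).  Infant antibiotic exposure
is the number of antibiotic courses in the first year of life, drawn from a
negative binomial whose log-mean declines over calendar time with a slope
change after the knot year; the mean is floored so extrapolation far into
the future never drops below 50 courses per 1,000 infants.
"""

from __future__ import annotations

import numpy as np

from .params_io import AntibioticModel


def assign_family_history(p: float, rng: np.random.Generator, size: int | None = None):
    """Bernoulli(p) family-history flag(s), independent of everything else."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("family-history probability must lie in [0, 1]")
    if size is None:
        return bool(rng.random() < p)
    return rng.random(size) < p


def antibiotic_mean(sex, year, model: AntibioticModel):
    """Floored mean courses of infant antibiotics for a (sex, birth-year).

    exp of a linear predictor in sex (male = 1) and centred calendar year,
    with post-knot intercept and slope shifts; never below ``mean_floor``.
    Accepts scalars or arrays.
    """
    sex = np.asarray(sex)
    year = np.asarray(year)
    post = (year > model.knot_year).astype(float)
    yc = year - model.year_center
    eta = (
        model.beta0
        + model.beta1_sex * sex
        + model.beta2_post2005 * post
        + model.beta3_year * yc
        + model.beta4_post2005_year * post * yc
    )
    mean = np.maximum(model.mean_floor, np.exp(eta))
    return float(mean) if mean.ndim == 0 else mean


def sample_antibiotic_courses(
    mean, theta: float, rng: np.random.Generator, size: int | None = None
):
    """Negative-binomial draw(s) with the given mean and dispersion.

    Parameterised so that variance = mean + mean^2 / theta; numpy's
    ``negative_binomial(n, p)`` is used with n = theta, p = theta/(theta+mean).
    """
    if theta <= 0:
        raise ValueError("dispersion theta must be positive")
    mean = np.asarray(mean, dtype=float)
    if (mean <= 0).any():
        raise ValueError("negative-binomial mean must be positive")
    p = theta / (theta + mean)
    if size is None and mean.ndim == 0:
        return int(rng.negative_binomial(theta, float(p)))
    return rng.negative_binomial(theta, p, size=size if size is not None else mean.shape)
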