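"""Asthma outcomes for labelled person-years: control, exacerbations, severity.

Control is a three-level state (1 = uncontrolled, 2 = partially controlled,
3 = well-controlled).  A proportional-odds model with a person-level random
intercept yields, for each labelled person-year, the expected fraction of
the year spent at each level; the intercept is drawn once at first
labelling and persists for life (a latent severity trait).  Exacerbation
counts are Poisson with a log-mean linear in the control-time fractions,
and each count is split across four severity levels (mild, moderate,
severe, very severe) by a Dirichlet-multinomial in which a history of very
severe events inflates the very severe probability.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.special import expit

from .params_io import (
    ControlModel,
    ExacerbationModel,
    SeverityModel,
    OCC_AGE_CENTER,
    OCC_AGE_SCALE,
)


class ControlTime(NamedTuple):
    """Fractions of a year spent at each control level; sums to 1."""

    uc: float
    pc: float
    wc: float


def draw_control_intercept(
    sigma: float, rng: np.random.Generator, size: int | None = None
):
    """Person-level Normal(0, sigma^2) intercept, drawn once at first label."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if size is None:
        return float(rng.normal(0.0, sigma))
    return rng.normal(0.0, sigma, size)


def control_linear_predictor(sex, age, intercept, model: ControlModel):
    """eta = intercept + per-sex (age, age^2) fixed effects, age coded
    (age - 40)/40."""
    sex = np.asarray(sex)
    ac = (np.asarray(age, dtype=float) - OCC_AGE_CENTER) / OCC_AGE_SCALE
    fe = np.asarray(model.fixed_effects).reshape(2, 2)
    terms = np.stack([ac, ac**2], axis=-1)
    return np.asarray(intercept, dtype=float) + np.einsum(
        "...k,...k->...", terms, fe[sex]
    )


def control_proportions(sex, age, intercept, model: ControlModel):
    """Expected fraction of the year at each control level (UC, PC, WC).

    Cumulative logits: P(level <= j) = invlogit(theta_j - eta).  Returns an
    array of shape (..., 3) ordered (uncontrolled, partial, well); the three
    components sum to 1 by construction.
    """
    eta = control_linear_predictor(sex, age, intercept, model)
    c1 = expit(model.theta1 - eta)
    c2 = expit(model.theta2 - eta)
    return np.stack([c1, c2 - c1, 1.0 - c2], axis=-1)


def exacerbation_mean(ct, offset, model: ExacerbationModel):
    """Annual Poisson mean: exp(offset + ct . per-level log rates).

    ``ct`` is (..., 3) ordered (UC, PC, WC).  With zero offset the mean is a
    log-convex combination of the per-level rates, so it always lies between
    the well-controlled and uncontrolled rates.
    """
    ct = np.asarray(ct, dtype=float)
    log_rates = np.array([model.log_rate_uc, model.log_rate_pc, model.log_rate_wc])
    out = np.exp(np.asarray(offset, dtype=float) + ct @ log_rates)
    return float(out) if out.ndim == 0 else out


def sample_exacerbations(mean, rng: np.random.Generator):
    """Poisson draw(s) of the annual exacerbation count."""
    mean = np.asarray(mean, dtype=float)
    if (mean < 0).any():
        raise ValueError("exacerbation mean must be non-negative")
    out = rng.poisson(mean)
    return int(out) if out.ndim == 0 else out


def severity_weights(
    model: SeverityModel,
    very_severe_history,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Per-person-year severity probability vector(s), shape (..., 4).

    Drawn from Dirichlet(alpha); for anyone with past very severe events the
    fourth component is multiplied by (1 + gamma)^min(history, cap) and the
    vector renormalised.  (The inflation form is this package's documented
    construction; gamma = 0 disables it.)
    """
    history = np.asarray(very_severe_history)
    if (history < 0).any():
        raise ValueError("very-severe history must be non-negative")
    n = size if size is not None else (history.shape[0] if history.ndim else None)
    alpha = np.asarray(model.alpha, dtype=float)
    w = rng.dirichlet(alpha, size=n)
    factor = (1.0 + model.history_inflation_gamma) ** np.minimum(
        history, model.history_cap
    )
    w = np.array(w, copy=True)
    w[..., 3] = w[..., 3] * factor
    return w / w.sum(axis=-1, keepdims=True)


def sample_severity_counts(n, w, rng: np.random.Generator):
    """Multinomial severity split(s) of ``n`` exacerbations; rows sum to n.

    The caller increments the individual's very-severe history by the fourth
    component.
    """
    n = np.asarray(n)
    w = np.asarray(w, dtype=float)
    if (n < 0).any():
        raise ValueError("exacerbation count must be non-negative")
    if w.ndim == 1:
        return rng.multinomial(int(n), w)
    # vectorised: one multinomial per row
    out = np.zeros(w.shape, dtype=np.int64)
    nz = np.flatnonzero(np.asarray(n) > 0)
    for i in nz:
        out[i] = rng.multinomial(int(n[i]), w[i])
    return out
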