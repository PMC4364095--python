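"""Weibull distribution primitives in the rate (proportional-hazards) parameterization.

Throughout the package the Weibull density is written

    f(t) = lam * rho * t**(rho - 1) * exp(-lam * t**rho),   t > 0,

with *scale* ``lam > 0`` and *shape* ``rho > 0``.  Note that ``lam`` here is a
rate-like parameter (it multiplies ``t**rho``), not the "characteristic life"
scale of the reliability literature; the hazard is ``lam * rho * t**(rho-1)``
so covariates entering ``lam`` multiplicatively act proportionally on the
hazard.  ``rho < 1`` gives a decreasing hazard, ``rho = 1`` the exponential
(constant-hazard) special case, and ``rho > 1`` an increasing hazard.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

__all__ = [
    "weibull_logpdf",
    "weibull_logsurv",
    "weibull_loghazard",
    "weibull_moments",
    "linear_predictor",
    "sample_weibull_time",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~(arr > 0)):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def weibull_logpdf(t, scale, shape):
    """Log density ``log lam + log rho + (rho-1) log t - lam t**rho``.

    Parameters
    ----------
    t : float or array
        Event time, strictly positive.
    scale : float or array
        Rate parameter ``lam > 0``.
    shape : float or array
        Shape parameter ``rho > 0``.
    """
    _check_positive(t=t, scale=scale, shape=shape)
    t = np.asarray(t, dtype=float)
    return np.log(scale) + np.log(shape) + (shape - 1.0) * np.log(t) - scale * t**shape


def weibull_logsurv(t, scale, shape):
    """Log survival ``-lam * t**rho``; equals 0 at ``t = 0``."""
    _check_positive(scale=scale, shape=shape)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return -scale * t**shape


def weibull_loghazard(t, scale, shape):
    """Log hazard ``log lam + log rho + (rho-1) log t``."""
    _check_positive(t=t, scale=scale, shape=shape)
    t = np.asarray(t, dtype=float)
    return np.log(scale) + np.log(shape) + (shape - 1.0) * np.log(t)


def weibull_moments(scale, shape):
    """Closed-form mean and variance of the Weibull distribution.

    mean = lam**(-1/rho) * Gamma(1 + 1/rho)
    var  = lam**(-2/rho) * (Gamma(1 + 2/rho) - Gamma(1 + 1/rho)**2)
    """
    _check_positive(scale=scale, shape=shape)
    g1 = _gamma(1.0 + 1.0 / shape)
    g2 = _gamma(1.0 + 2.0 / shape)
    mean = scale ** (-1.0 / shape) * g1
    var = scale ** (-2.0 / shape) * (g2 - g1**2)
    return mean, var


def linear_predictor(x, beta0, beta, offset=0.0):
    """Scale parameter ``exp(beta0 + beta . x + offset)``.

    ``x`` and ``beta`` are name-aligned mappings (dict or :class:`pandas.Series`);
    the exponential link enforces positivity of the scale.  ``offset`` carries
    random-effect contributions (subject frailty, subject-by-type frailty).
    """
    x = pd.Series(x, dtype=float)
    beta = pd.Series(beta, dtype=float)
    if set(x.index) != set(beta.index):
        missing = set(beta.index) ^ set(x.index)
        raise KeyError(f"covariate/coefficient name mismatch: {sorted(missing)}")
    eta = beta0 + float((beta * x.reindex(beta.index)).sum()) + offset
    return float(np.exp(eta))


def sample_weibull_time(scale, shape, u):
    """Invert the survival function: the ``t`` with ``S(t) = u``.

    Returns ``(-log u / lam)**(1/rho)`` for ``u`` strictly in (0, 1).  Used by
    the cohort simulator via inverse-transform sampling (``u ~ Uniform(0,1)``).
    """
    _check_positive(scale=scale, shape=shape)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly in (0, 1)")
    return (-np.log(u) / scale) ** (1.0 / shape)
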