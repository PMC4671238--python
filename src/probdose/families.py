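"""Dose-response model families.

Pure model functions only: continuous medians f(d, theta) and quantal
probabilities P(d, theta). Fitting lives in :mod:`probdose.models`.

Continuous families follow the PROAST parameterizations and are interpreted
as the median response of a lognormally distributed individual response:

* ``exponential``: f(d) = a * exp(b * d**g)          theta = (a, b, g)
* ``hill``:        f(d) = a * (1 + (c - 1) * d**g / (b**g + d**g))
                                                     theta = (a, b, c, g)

Quantal families give the probability of the discrete outcome.  All but the
plain logistic use the independent-background form
P(d) = c + (1 - c) * F(d) with F(0) = 0:

* ``logistic``:     P(d) = expit(a + b d)            theta = (a, b)
* ``log_logistic``: F(d) = expit(a + b ln d)         theta = (c, a, b)
* ``log_probit``:   F(d) = Phi(a + b ln d)           theta = (c, a, b)
* ``weibull``:      F(d) = 1 - exp(-b d**k)          theta = (c, b, k)
* ``gamma``:        F(d) = GammaCDF(b d; k)          theta = (c, b, k)
* ``multistage``:   F(d) = 1 - exp(-q1 d - q2 d^2)   theta = (c, q1, q2)

The multistage is second-degree with nonnegative coefficients.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .errors import UnknownFamilyError

CONTINUOUS_FAMILIES = ("exponential", "hill")
QUANTAL_FAMILIES = (
    "logistic",
    "log_logistic",
    "log_probit",
    "weibull",
    "gamma",
    "multistage",
)

#: number of free parameters of the mean/probability function (excluding the
#: residual log-SD of continuous fits, which is profiled out)
N_PARAMS = {
    "exponential": 3,
    "hill": 4,
    "logistic": 2,
    "log_logistic": 3,
    "log_probit": 3,
    "weibull": 3,
    "gamma": 3,
    "multistage": 3,
}


def continuous_median(family: str, theta, dose):
    """Median response f(dose, theta) of a continuous family."""
    d = np.asarray(dose, dtype=float)
    th = np.asarray(theta, dtype=float)
    if family == "exponential":
        a, b, g = th
        return a * np.exp(b * np.power(d, g))
    if family == "hill":
        a, b, c, g = th
        dg = np.power(d, g)
        return a * (1.0 + (c - 1.0) * dg / (b**g + dg))
    raise UnknownFamilyError(family)


def quantal_probability(family: str, theta, dose):
    """Outcome probability P(dose, theta) of a quantal family."""
    d = np.asarray(dose, dtype=float)
    th = np.asarray(theta, dtype=float)
    if family == "logistic":
        a, b = th
        return special.expit(a + b * d)

    if family not in QUANTAL_FAMILIES:
        raise UnknownFamilyError(family)
    c = th[0]
    with np.errstate(divide="ignore"):
        logd = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), -np.inf)
    if family == "log_logistic":
        _, a, b = th
        f = np.where(d > 0, special.expit(a + b * logd), 0.0)
    elif family == "log_probit":
        _, a, b = th
        f = np.where(d > 0, stats.norm.cdf(a + b * logd), 0.0)
    elif family == "weibull":
        _, b, k = th
        f = -np.expm1(-b * np.power(d, k))
    elif family == "gamma":
        _, b, k = th
        f = special.gammainc(k, b * d)
    else:  # multistage, degree 2
        _, q1, q2 = th
        f = -np.expm1(-(q1 * d + q2 * d * d))
    return c + (1.0 - c) * f


def extra_risk(family: str, theta, dose):
    """Extra risk (P(d) - P(0)) / (1 - P(0)).

    For the independent-background families this reduces to F(d) exactly; the
    general form also covers the plain logistic, whose background lives in the
    intercept.
    """
    p0 = quantal_probability(family, theta, 0.0)
    p = quantal_probability(family, theta, dose)
    return (p - p0) / (1.0 - p0)
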