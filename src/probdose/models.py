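"""Maximum-likelihood fitting of dose-response models and BMD computation.

Continuous endpoints are fitted on the log scale: group summaries (mean, SD)
are converted to log-scale sufficient statistics and the model median is
fitted under a lognormal likelihood with a common log-SD across dose groups
(profiled out analytically). Quantal endpoints are fitted under the binomial
likelihood.

Goodness of fit is a likelihood-ratio test against the saturated model
(group-specific means / incidences); a model is *accepted* for pooling when
its p-value exceeds 0.05.

The benchmark dose is the dose at which the fitted curve reaches the
benchmark response implied by the endpoint class: a relative change of M* in
the median response (continuous), an extra risk of M* (stochastic quantal),
or a 50% incidence (deterministic quantal, where the quantal response tracks
an underlying continuous response crossing a severity cut point).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from . import families
from .data_io import Direction, DoseResponseDataset, EndpointClass, EndpointSpec
from .errors import (
    BMDRangeError,
    DatasetValidationError,
    FitError,
    UnknownFamilyError,
)

GOF_THRESHOLD = 0.05


@dataclass
class ModelFit:
    """A fitted dose-response model and its screening status."""

    family: str
    theta: np.ndarray
    loglik: float
    gof_p: float
    accepted: bool
    endpoint_kind: str  # "continuous" | "quantal"
    background: float
    n_params: int
    max_dose: float
    sigma_log: float | None = None  # residual log-SD (continuous only)
    at_boundary: bool = False
    converged: bool = True


# ---------------------------------------------------------------------------
# continuous fitting
# ---------------------------------------------------------------------------


def _log_stats(dataset: DoseResponseDataset):
    """Per-group log-scale statistics from arithmetic mean and SD."""
    mean = np.array([g.mean for g in dataset.groups])
    sd = np.array([g.sd for g in dataset.groups])
    n = dataset.ns.astype(float)
    s2 = np.log1p((sd / mean) ** 2)  # log-scale sample variance
    m = np.log(mean) - 0.5 * s2  # log-scale sample mean
    return m, s2, n


def _profile_nll_continuous(logf, m, s2, n):
    """Negative profile log-likelihood given model log-medians ``logf``."""
    if not np.all(np.isfinite(logf)):
        return np.inf
    ntot = n.sum()
    sse = np.sum(n * (m - logf) ** 2) + np.sum((n - 1.0) * s2)
    sigma2 = sse / ntot
    if sigma2 <= 0:
        sigma2 = 1e-300
    return 0.5 * ntot * (np.log(2.0 * np.pi * sigma2) + 1.0)


_POWER_BOUNDS = (0.25, 6.0)


def _fit_exponential(m, s2, n, doses):
    """Exponential family a*exp(b*d**g): (ln a, b) are linear in the
    log-median for fixed g, so only the power g needs a numeric search."""

    def sse_given_g(g):
        t = np.power(doses, g)
        # weighted least squares of m on (1, t) with weights n
        w = n
        sw = w.sum()
        tbar = np.sum(w * t) / sw
        mbar = np.sum(w * m) / sw
        stt = np.sum(w * (t - tbar) ** 2)
        if stt <= 0:
            return np.inf, (mbar, 0.0)
        b = np.sum(w * (t - tbar) * (m - mbar)) / stt
        la = mbar - b * tbar
        rss = np.sum(w * (m - la - b * t) ** 2)
        return rss, (la, b)

    grid = np.linspace(_POWER_BOUNDS[0], _POWER_BOUNDS[1], 24)
    rss_grid = np.array([sse_given_g(g)[0] for g in grid])
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: sse_given_g(g)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    g = float(res.x)
    _, (la, b) = sse_given_g(g)
    theta = np.array([np.exp(la), b, g])
    boundary = min(g - _POWER_BOUNDS[0], _POWER_BOUNDS[1] - g) < 1e-4
    return theta, boundary


def _fit_hill(m, s2, n, doses, theta_start=None):
    """Hill family a*(1 + (c-1)*d**g/(b**g + d**g)); ln a profiled."""
    dmax = doses.max()
    pos = doses > 0
    w = n

    def nll(x):
        lb, lc, g = x
        b = np.exp(lb) * dmax
        c = np.exp(lc)
        dg = np.power(doses, g)
        h = 1.0 + (c - 1.0) * dg / (b**g + dg)
        if np.any(h <= 0) or not np.all(np.isfinite(h)):
            return np.inf
        logh = np.log(h)
        la = np.sum(w * (m - logh)) / w.sum()
        return _profile_nll_continuous(la + logh, m, s2, n)

    # crude fold-change start from the top dose group
    top_ratio = np.exp(m[-1] - m[0]) if pos.any() else 1.0
    lc0 = np.log(np.clip(top_ratio, 1e-3, 1e3))
    starts = [
        (np.log(0.5), lc0, 1.0),
        (np.log(0.2), lc0, 1.0),
        (np.log(1.0), lc0, 2.0),
        (np.log(0.5), lc0, 0.5),
        (np.log(0.1), lc0, 3.0),
    ]
    bounds = [(-8.0, 5.0), (-8.0, 8.0), _POWER_BOUNDS]
    if theta_start is not None:
        _, b0, c0, g0 = np.asarray(theta_start, dtype=float)
        x0 = np.array([np.log(b0 / dmax), np.log(c0), g0])
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts = [np.clip(x0, lo + 1e-8, hi - 1e-8)]
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lb, lc, g = best.x
    theta = np.array([0.0, np.exp(lb) * dmax, np.exp(lc), g])
    dg = np.power(doses, g)
    h = 1.0 + (np.exp(lc) - 1.0) * dg / (theta[1] ** g + dg)
    la = np.sum(w * (m - np.log(h))) / w.sum()
    theta[0] = np.exp(la)
    boundary = any(
        min(x - lo, hi - x) < 1e-4 for x, (lo, hi) in zip(best.x, bounds)
    )
    return theta, boundary


def fit_continuous(
    dataset: DoseResponseDataset, family: str, theta_start=None
) -> ModelFit:
    """Fit a continuous family by lognormal ML on group summaries.

    ``theta_start`` seeds the Hill optimizer with a single starting point
    (bootstrap refits); the exponential family profiles down to a 1-D search
    and ignores it.
    """
    if dataset.kind != "continuous":
        raise DatasetValidationError("fit_continuous requires a continuous dataset")
    if not dataset.has_control:
        raise DatasetValidationError(
            "continuous percent-change analysis requires a dose-0 control group"
        )
    if family not in families.CONTINUOUS_FAMILIES:
        raise UnknownFamilyError(family)
    n_par = families.N_PARAMS[family]
    if len(dataset.groups) < n_par:
        raise FitError(
            f"{family}: {len(dataset.groups)} groups < {n_par} parameters"
        )
    m, s2, n = _log_stats(dataset)
    doses = dataset.doses
    if family == "exponential":
        theta, boundary = _fit_exponential(m, s2, n, doses)
    else:
        theta, boundary = _fit_hill(m, s2, n, doses, theta_start=theta_start)
    logf = np.log(families.continuous_median(family, theta, doses))
    nll = _profile_nll_continuous(logf, m, s2, n)
    if not np.isfinite(nll):
        raise FitError(f"{family}: non-finite likelihood at optimum")
    ntot = n.sum()
    sse = np.sum(n * (m - logf) ** 2) + np.sum((n - 1.0) * s2)
    fit = ModelFit(
        family=family,
        theta=theta,
        loglik=-nll,
        gof_p=np.nan,
        accepted=False,
        endpoint_kind="continuous",
        background=float(families.continuous_median(family, theta, 0.0)),
        n_params=n_par,
        max_dose=float(doses.max()),
        sigma_log=float(np.sqrt(sse / ntot)),
        at_boundary=boundary,
    )
    p = gof_pvalue(fit, dataset)
    return replace(fit, gof_p=p, accepted=p > GOF_THRESHOLD)


# ---------------------------------------------------------------------------
# quantal fitting
# ---------------------------------------------------------------------------

# optimizer parameterizations use doses scaled by the maximum tested dose so
# that bounds and starting points are design-independent; _unscale maps the
# fitted parameters back to native dose units.

_CLIP = 1e-9


def _quantal_setup(family: str, y, n, u):
    """Return (nll, starts, bounds, unpack) in scaled-dose space."""
    rates = y / n
    c0 = float(np.clip(rates.min(), 1e-3, 0.5))

    def make_nll(unpack):
        def nll(x):
            theta = unpack(x)
            p = families.quantal_probability(family, theta, u)
            p = np.clip(p, _CLIP, 1.0 - _CLIP)
            return -np.sum(y * np.log(p) + (n - y) * np.log1p(-p))

        return nll

    if family == "logistic":
        a0 = float(np.log(c0 / (1 - c0)))
        unpack = lambda x: np.array([x[0], x[1]])
        bounds = [(-30.0, 30.0), (1e-9, 300.0)]
        starts = [(a0, b) for b in (0.3, 1.0, 3.0, 10.0, 30.0)]
    elif family in ("log_logistic", "log_probit"):
        unpack = lambda x: np.array([x[0], x[1], x[2]])
        bounds = [(0.0, 0.999), (-30.0, 30.0), (1e-6, 30.0)]
        starts = [
            (c0, 0.0, 1.0),
            (c0, 1.0, 1.0),
            (c0, -1.0, 1.0),
            (c0, 0.0, 2.0),
            (c0, 0.0, 0.5),
        ]
    elif family in ("weibull", "gamma"):
        unpack = lambda x: np.array([x[0], np.exp(x[1]), np.exp(x[2])])
        bounds = [(0.0, 0.999), (-20.0, 8.0), (np.log(0.05), np.log(18.0))]
        starts = [
            (c0, 0.0, 0.0),
            (c0, np.log(0.3), 0.0),
            (c0, np.log(3.0), 0.0),
            (c0, 0.0, np.log(2.0)),
            (c0, 0.0, np.log(0.5)),
        ]
    elif family == "multistage":
        unpack = lambda x: np.array([x[0], x[1], x[2]])
        bounds = [(0.0, 0.999), (0.0, 60.0), (0.0, 60.0)]
        starts = [
            (c0, 0.5, 0.0),
            (c0, 2.0, 0.0),
            (c0, 0.0, 1.0),
            (c0, 1.0, 1.0),
            (c0, 0.1, 0.1),
        ]
    else:
        raise UnknownFamilyError(family)
    return make_nll(unpack), starts, bounds, unpack


def _unscale_theta(family: str, theta, dmax: float):
    """Map parameters fitted on d/dmax back to native dose units."""
    theta = np.array(theta, dtype=float)
    if family == "logistic":
        theta[1] /= dmax
    elif family in ("log_logistic", "log_probit"):
        theta[1] -= theta[2] * np.log(dmax)
    elif family == "weibull":
        theta[1] /= dmax ** theta[2]
    elif family == "gamma":
        theta[1] /= dmax
    elif family == "multistage":
        theta[1] /= dmax
        theta[2] /= dmax**2
    return theta


def fit_quantal(
    dataset: DoseResponseDataset, family: str, theta_start=None
) -> ModelFit:
    """Fit a quantal family by binomial ML.

    ``theta_start`` (native units) replaces the default deterministic start
    grid; bootstrap refits pass the original estimate for speed and to keep
    refits in the same likelihood basin.
    """
    if dataset.kind != "quantal":
        raise DatasetValidationError("fit_quantal requires a quantal dataset")
    if family not in families.QUANTAL_FAMILIES:
        raise UnknownFamilyError(family)
    doses = dataset.doses
    dmax = float(doses.max())
    u = doses / dmax
    y = np.array([g.affected for g in dataset.groups], dtype=float)
    n = dataset.ns.astype(float)
    nll, starts, bounds, unpack = _quantal_setup(family, y, n, u)
    if theta_start is not None:
        starts = [_pack_start(family, theta_start, dmax, bounds)]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"{family}: optimizer failed")
    theta = _unscale_theta(family, unpack(best.x), dmax)
    boundary = any(
        min(x - lo, hi - x) < 1e-6 for x, (lo, hi) in zip(best.x, bounds)
    )
    n_par = families.N_PARAMS[family]
    fit = ModelFit(
        family=family,
        theta=theta,
        loglik=-float(best.fun),
        gof_p=np.nan,
        accepted=False,
        endpoint_kind="quantal",
        background=float(families.quantal_probability(family, theta, 0.0)),
        n_params=n_par,
        max_dose=dmax,
        at_boundary=boundary,
    )
    p = gof_pvalue(fit, dataset)
    return replace(fit, gof_p=p, accepted=p > GOF_THRESHOLD)


def _pack_start(family, theta, dmax, bounds):
    """Native-units theta -> optimizer coordinates, clipped into bounds."""
    theta = np.array(theta, dtype=float)
    if family == "logistic":
        x = np.array([theta[0], theta[1] * dmax])
    elif family in ("log_logistic", "log_probit"):
        x = np.array([theta[0], theta[1] + theta[2] * np.log(dmax), theta[2]])
    elif family == "weibull":
        x = np.array(
            [theta[0], np.log(max(theta[1] * dmax ** theta[2], 1e-12)),
             np.log(theta[2])]
        )
    elif family == "gamma":
        x = np.array([theta[0], np.log(max(theta[1] * dmax, 1e-12)), np.log(theta[2])])
    else:  # multistage
        x = np.array([theta[0], theta[1] * dmax, theta[2] * dmax**2])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    eps = 1e-8 * np.maximum(1.0, np.abs(hi - lo))
    return np.clip(x, lo + eps, hi - eps)


# ---------------------------------------------------------------------------
# goodness of fit, prediction, BMD
# ---------------------------------------------------------------------------


def gof_pvalue(fit: ModelFit, dataset: DoseResponseDataset) -> float:
    """Likelihood-ratio p-value against the saturated model.

    Chi-square with df = (#groups) - (#free parameters); returns 1.0 when the
    fit is saturated (df <= 0).
    """
    g = len(dataset.groups)
    df = g - fit.n_params
    if df <= 0:
        return 1.0
    if fit.endpoint_kind == "quantal":
        y = np.array([gr.affected for gr in dataset.groups], dtype=float)
        n = dataset.ns.astype(float)
        rates = np.clip(y / n, _CLIP, 1 - _CLIP)
        ll_sat = float(np.sum(y * np.log(rates) + (n - y) * np.log1p(-rates)))
        deviance = 2.0 * (ll_sat - fit.loglik)
    else:
        m, s2, n = _log_stats(dataset)
        ntot = n.sum()
        sse_sat = np.sum((n - 1.0) * s2)
        sigma2_sat = max(sse_sat / ntot, 1e-300)
        ll_sat = -0.5 * ntot * (np.log(2.0 * np.pi * sigma2_sat) + 1.0)
        deviance = 2.0 * (ll_sat - fit.loglik)
    deviance = max(float(deviance), 0.0)
    return float(stats.chi2.sf(deviance, df))


def predict(fit: ModelFit, dose):
    """Model value at dose: median response (continuous) or probability."""
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be nonnegative")
    if fit.endpoint_kind == "continuous":
        out = families.continuous_median(fit.family, fit.theta, dose_arr)
    else:
        out = families.quantal_probability(fit.family, fit.theta, dose_arr)
    return float(out) if np.isscalar(dose) or dose_arr.ndim == 0 else out


def _smallest_root(func, dmax: float) -> float:
    """Smallest dose in (0, 10*dmax] where ``func`` crosses zero from below."""
    upper = 10.0 * dmax
    grid = np.concatenate([[0.0], np.geomspace(dmax * 1e-8, upper, 240)])
    vals = np.asarray(func(grid), dtype=float)
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        raise BMDRangeError(
            "benchmark response not reached within 10x the maximum tested dose"
        )
    i = int(crossings[0])
    lo, hi = grid[i], grid[i + 1]
    if lo == 0.0:
        lo = dmax * 1e-12
        if func(lo) * func(hi) > 0:
            return float(optimize.brentq(func, 0.0, hi, xtol=1e-300, rtol=8.9e-16))
    return float(optimize.brentq(func, lo, hi, xtol=1e-300, rtol=8.9e-16))


def bmd_from_fit(fit: ModelFit, spec: EndpointSpec) -> float:
    """Benchmark dose at the benchmark response implied by the endpoint class.

    continuous: smallest d with |f(d) - f(0)| / f(0) = M*;
    stochastic quantal: extra risk (P(d) - P(0)) / (1 - P(0)) = M*;
    deterministic quantal: d with P(d) = 0.5 (the ED50).
    """
    ec = EndpointClass(spec.endpoint_class)
    if ec is EndpointClass.CONTINUOUS:
        if fit.endpoint_kind != "continuous":
            raise DatasetValidationError("continuous endpoint needs a continuous fit")
        f0 = predict(fit, 0.0)
        mstar = float(spec.critical_effect_size)
        direction = spec.direction
        if direction is Direction.AUTO:
            trend = predict(fit, fit.max_dose) - f0
            direction = Direction.INCREASE if trend >= 0 else Direction.DECREASE
        target = f0 * (1.0 + mstar) if direction is Direction.INCREASE else f0 * (
            1.0 - mstar
        )
        return _smallest_root(lambda d: predict(fit, d) - target, fit.max_dose)
    if fit.endpoint_kind != "quantal":
        raise DatasetValidationError("quantal endpoint needs a quantal fit")
    if ec is EndpointClass.STOCHASTIC_QUANTAL:
        mstar = float(spec.critical_effect_size)
        return _smallest_root(
            lambda d: families.extra_risk(fit.family, fit.theta, d) - mstar,
            fit.max_dose,
        )
    # deterministic quantal: ED50 on the observed incidence scale
    if fit.background >= 0.5:
        raise BMDRangeError("background incidence at or above 50%; ED50 undefined")
    return _smallest_root(lambda d: predict(fit, d) - 0.5, fit.max_dose)
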