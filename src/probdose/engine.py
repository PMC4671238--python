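"""Hierarchical Monte Carlo combination of uncertainty and variability.

One joint uncertainty draw ``j`` pairs a bootstrap BMD sample AD_M*[j] with
draws of DAF, AHU, OU and sigma_H. Uncertainty is evaluated first:

    HD_median[j] = AD_M*[j] * DAF[j] / (AHU[j] * OU[j])

then variability, through the human variability factor at the target
incidence I*:

    HD_MI[j] = HD_median[j] * exp(z_I* * sigma_H[j])

The resulting cloud is the uncertainty distribution of the target human dose
HD_M^I; its lower (1 - confidence) quantile is the probabilistic RfD.

For stochastic quantal endpoints the expected *population* incidence at a
human dose requires integrating the individual probability of effect over
the lognormal population of equipotent doses — a nested Monte Carlo with an
inner standard-normal sample per uncertainty draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import families as _fam
from ._random import substream
from .adjustments import hv_factor, z_score
from .bmd import summarize_percentiles
from .errors import ConfigError


@dataclass(frozen=True)
class ProtectionGoal:
    """Risk-management choices: effect size M*, incidence I*, confidence."""

    m_star: float | str | None
    i_star: float
    confidence: float = 0.95

    def __post_init__(self):
        if not 0.0 < self.i_star <= 0.5:
            raise ConfigError(f"target incidence must be in (0, 0.5], got {self.i_star}")
        if not 0.5 <= self.confidence < 1.0:
            raise ConfigError(f"confidence must be in [0.5, 1), got {self.confidence}")


@dataclass
class HDMIResult:
    """Uncertainty sample sets for HD_median and HD_M^I plus summaries."""

    hd_median_samples: np.ndarray
    hd_mi_samples: np.ndarray
    summary: tuple  # (p5, p50, p95) of hd_mi_samples
    probabilistic_rfd: float
    goal: ProtectionGoal
    n_mc: int
    seed: int | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class IncidenceCurve:
    """Percentile bands of incidence (or population extra risk) vs dose."""

    doses: np.ndarray
    p5: np.ndarray
    p50: np.ndarray
    p95: np.ndarray
    interpretation: str  # "deterministic_quantal_or_continuous" | "stochastic_population"


def _aligned(*arrays) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=float) for a in arrays]
    n = {a.shape for a in out}
    if len(n) != 1 or out[0].ndim != 1:
        raise ValueError(f"sample arrays must be 1-D of equal length, got shapes {n}")
    return out


def hd_median_samples(ad, daf, ahu, ou) -> np.ndarray:
    """Elementwise HD for the median human: AD * DAF / (AHU * OU)."""
    ad, daf, ahu, ou = _aligned(ad, daf, ahu, ou)
    return ad * daf / (ahu * ou)


def hd_mi_samples(ad, daf, ahu, ou, sigma_h, goal: ProtectionGoal, seed=None,
                  provenance=None) -> HDMIResult:
    """Uncertainty distribution of the target human dose HD_M^I."""
    ad, daf, ahu, ou, sigma_h = _aligned(ad, daf, ahu, ou, sigma_h)
    hdm = ad * daf / (ahu * ou)
    hdmi = hdm * hv_factor(sigma_h, goal.i_star)
    summary = tuple(summarize_percentiles(hdmi, (0.05, 0.50, 0.95)))
    rfd = summarize_percentiles(hdmi, (1.0 - goal.confidence,))[0]
    return HDMIResult(
        hd_median_samples=hdm,
        hd_mi_samples=hdmi,
        summary=summary,
        probabilistic_rfd=rfd,
        goal=goal,
        n_mc=hdm.size,
        seed=seed,
        provenance=dict(provenance or {}),
    )


def incidence_curve(hd_median, sigma_h, doses) -> IncidenceCurve:
    """Incidence of effects >= M* versus dose, with uncertainty bands.

    Per uncertainty draw the incidence at dose d is
    Phi((ln d - ln HD_median) / sigma_H); the bands are pointwise 5th/50th/
    95th percentiles across draws. sigma_H = 0 degenerates to a step at
    HD_median.
    """
    hd_median, sigma_h = _aligned(hd_median, sigma_h)
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("dose grid must be strictly positive")
    log_hd = np.log(hd_median)
    p5 = np.empty(doses.size)
    p50 = np.empty(doses.size)
    p95 = np.empty(doses.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, d in enumerate(doses):
            z = (np.log(d) - log_hd) / sigma_h
            z = np.where(sigma_h == 0.0, np.sign(np.log(d) - log_hd) * np.inf, z)
            inc = stats.norm.cdf(z)
            p5[i], p50[i], p95[i] = np.quantile(inc, (0.05, 0.50, 0.95))
    return IncidenceCurve(
        doses=doses, p5=p5, p50=p50, p95=p95,
        interpretation="deterministic_quantal_or_continuous",
    )


def population_incidence_stochastic(
    theta_samples,
    family: str,
    daf,
    ahu,
    ou,
    sigma_h,
    doses,
    n_inner: int = 10_000,
    seed: int = 0,
) -> IncidenceCurve:
    """Expected population extra risk vs dose for a stochastic quantal endpoint.

    Per uncertainty draw j (a bootstrap parameter vector theta[j] paired with
    DAF/AHU/OU/sigma_H draws), a human population of ``n_inner`` standard-
    normal z-scores is generated and the individual extra risk is averaged at
    the back-transformed animal-equivalent dose

        exp(z * sigma_H[j]) * dose * AHU[j] * OU[j] / DAF[j].

    The average individual probability equals the expected population
    incidence; extra risk over the model background keeps the magnitude on
    the same effect-metric scale as the AD analysis.
    """
    daf, ahu, ou, sigma_h = _aligned(daf, ahu, ou, sigma_h)
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be nonnegative")
    if n_inner < 100:
        raise ValueError("n_inner < 100 gives an unconverged inner average")
    n_j = daf.size
    if len(theta_samples) != n_j:
        raise ValueError("theta_samples must align with the adjustment draws")
    if isinstance(family, str):
        labels = [family] * n_j
    else:
        labels = list(family)
        if len(labels) != n_j:
            raise ValueError("family labels must align with the adjustment draws")
    rng = substream(seed, "inner_z")
    z = rng.standard_normal(n_inner)
    incid = np.empty((n_j, doses.size))
    for j in range(n_j):
        shift = np.exp(z * sigma_h[j]) * ahu[j] * ou[j] / daf[j]  # (n_inner,)
        ad_equiv = shift[:, None] * doses[None, :]
        er = _fam.extra_risk(labels[j], theta_samples[j], ad_equiv)
        incid[j] = er.mean(axis=0)
    p5, p50, p95 = np.quantile(incid, (0.05, 0.50, 0.95), axis=0)
    return IncidenceCurve(
        doses=doses, p5=p5, p50=p50, p95=p95, interpretation="stochastic_population"
    )
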