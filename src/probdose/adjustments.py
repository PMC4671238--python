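"""Interspecies adjustment and human-variability distributions.

Three multiplicative factors carry the animal BMD to the median human
(all on the mg/kg BW-day scale):

* **DAF** — dosimetric adjustment factor for generic physiology. Oral:
  ``(BW_animal / BW_human) ** (1 - alpha)`` with the allometric power alpha
  uncertain (default Normal(0.7, 0.024)). Inhalation: a user-supplied
  RDDR/RGDR point value times a lognormal residual ``exp(eps_DAF)``.
* **AHU** — animal-to-human uncertainty: chemical-specific toxicokinetic/
  toxicodynamic deviation beyond the DAF, lognormal with geometric mean
  equal to the CSAF/DDEF point value (default 1) and default GSD 2.0.
* **OU** — other, study-specific uncertainties (duration, route, pattern),
  a product of independent lognormal components; an empty list means OU = 1.

Human variability in equipotent dose is lognormal with log-SD sigma_H; the
factor separating the sensitive (incidence-I) individual from the median is
``HV_I = exp(z_I * sigma_H)``. sigma_H is itself uncertain, lognormal with
default GM 0.746 and GSD 1.59 (from meta-analyses of human toxicokinetic and
toxicodynamic variability data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._random import as_generator
from .errors import ConfigError

Z_90 = stats.norm.ppf(0.95)  # 1.6449: z-points of a (p5, p95) interval


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution given by geometric mean and geometric SD."""

    gm: float
    gsd: float

    def __post_init__(self):
        if self.gm <= 0:
            raise ConfigError(f"geometric mean must be positive, got {self.gm}")
        if self.gsd < 1.0:
            raise ConfigError(f"geometric SD must be >= 1, got {self.gsd}")

    @property
    def sigma_log(self) -> float:
        return float(np.log(self.gsd))

    def sample(self, n: int, rng) -> np.ndarray:
        return self.gm * np.exp(rng.normal(0.0, self.sigma_log, size=n))

    def quantile(self, p) -> float:
        return float(self.gm * np.exp(stats.norm.ppf(p) * self.sigma_log))

    @classmethod
    def from_interval(cls, gm: float, p5: float, p95: float) -> "LognormalSpec":
        """Build from 5th/95th percentiles of the multiplicative deviation
        (e.g., 'three times lower to three times higher' -> p5=1/3, p95=3)."""
        if not 0 < p5 <= p95:
            raise ConfigError("need 0 < p5 <= p95")
        gsd = float(np.exp(np.log(p95 / p5) / (2.0 * Z_90)))
        return cls(gm=gm, gsd=gsd)


@dataclass(frozen=True)
class OUComponent:
    """One study-condition adjustment: point value times lognormal spread."""

    point: float
    gsd: float = 1.0

    def __post_init__(self):
        if self.point <= 0:
            raise ConfigError("OU point adjustment must be positive")
        if self.gsd < 1.0:
            raise ConfigError("OU GSD must be >= 1")


@dataclass
class AdjustmentConfig:
    """All Step-2 adjustment distributions for one assessment."""

    route: str = "oral"  # "oral" | "inhalation"
    bw_animal: float = 0.496  # kg
    bw_human: float = 70.0  # kg
    alpha_mean: float = 0.7
    alpha_sd: float = 0.024
    rddr_rgdr: float | None = None  # inhalation only
    sigma_daf: float | None = None  # log-SD of eps_DAF (inhalation)
    csaf_ddef: float = 1.0
    sigma_ahu: float = float(np.log(2.0))  # log-SD of eps_AHU (GSD 2.0)
    ou_components: list = field(default_factory=list)

    def __post_init__(self):
        if self.route not in ("oral", "inhalation"):
            raise ConfigError(f"route must be 'oral' or 'inhalation', got {self.route!r}")
        if self.bw_animal <= 0 or self.bw_human <= 0:
            raise ConfigError("body weights must be positive")
        if self.bw_animal >= self.bw_human:
            warnings.warn(
                "animal body weight >= human body weight; the DAF is intended "
                "for animal-to-human extrapolation"
            )
        if self.alpha_sd < 0 or (self.sigma_daf is not None and self.sigma_daf < 0):
            raise ConfigError("spread parameters must be nonnegative")
        if self.sigma_ahu < 0:
            raise ConfigError("sigma_AHU must be nonnegative")
        if self.csaf_ddef <= 0:
            raise ConfigError("CSAF/DDEF must be positive")
        self.ou_components = [
            c if isinstance(c, OUComponent) else OUComponent(*c)
            for c in self.ou_components
        ]


@dataclass(frozen=True)
class VariabilitySpec:
    """Uncertainty distribution of the human log-SD sigma_H.

    Either a lognormal (gm, gsd) or a fixed value (gsd = 1).
    """

    gm: float = 0.746
    gsd: float = 1.59

    def __post_init__(self):
        if self.gm < 0:
            raise ConfigError("sigma_H must be nonnegative")
        if self.gsd < 1.0:
            raise ConfigError("sigma_H GSD must be >= 1")

    @classmethod
    def fixed(cls, value: float) -> "VariabilitySpec":
        return cls(gm=value, gsd=1.0)


# ---------------------------------------------------------------------------
# point evaluations
# ---------------------------------------------------------------------------


def daf_oral(bw_animal: float, bw_human: float, alpha) -> float | np.ndarray:
    """Oral dosimetric adjustment factor (BW_animal/BW_human)**(1 - alpha)."""
    if bw_animal <= 0 or bw_human <= 0:
        raise ConfigError("body weights must be positive")
    return (bw_animal / bw_human) ** (1.0 - np.asarray(alpha, dtype=float))


def z_score(incidence: float) -> float:
    """Standard normal quantile of an incidence in (0, 1)."""
    incidence = float(incidence)
    if not 0.0 < incidence < 1.0:
        raise ValueError(f"incidence must be in (0, 1), got {incidence}")
    return float(stats.norm.ppf(incidence))


def hv_factor(sigma_h, incidence: float):
    """Human variability factor exp(z_I * sigma_H).

    Below the median (I < 0.5) this is < 1: the sensitive individual's
    equipotent dose lies below the median individual's.
    """
    sigma = np.asarray(sigma_h, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma_H must be nonnegative")
    out = np.exp(z_score(incidence) * sigma)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_daf(config: AdjustmentConfig, n: int, seed) -> np.ndarray:
    """Draws of the DAF: oral with random alpha, or RDDR/RGDR with residual."""
    rng = as_generator(seed)
    if config.route == "oral":
        alpha = rng.normal(config.alpha_mean, config.alpha_sd, size=n)
        return np.asarray(daf_oral(config.bw_animal, config.bw_human, alpha))
    if config.rddr_rgdr is None:
        raise ConfigError("inhalation route requires an RDDR/RGDR value")
    if config.sigma_daf is None:
        raise ConfigError(
            "inhalation route requires sigma_daf (no default is shipped; it "
            "must come from propagated dosimetry uncertainty or expert judgment)"
        )
    return config.rddr_rgdr * np.exp(rng.normal(0.0, config.sigma_daf, size=n))


def sample_ahu(config: AdjustmentConfig, n: int, seed) -> np.ndarray:
    """Draws of AHU = (CSAF or DDEF) * exp(eps_AHU)."""
    rng = as_generator(seed)
    return config.csaf_ddef * np.exp(rng.normal(0.0, config.sigma_ahu, size=n))


def sample_ou(config: AdjustmentConfig, n: int, seed) -> np.ndarray:
    """Draws of OU: product of independent lognormal components (or all 1)."""
    rng = as_generator(seed)
    out = np.ones(n)
    for comp in config.ou_components:
        out *= comp.point * np.exp(rng.normal(0.0, np.log(comp.gsd), size=n))
    return out


def sample_sigma_h(spec: VariabilitySpec, n: int, seed) -> np.ndarray:
    """Draws of the human variability log-SD sigma_H."""
    rng = as_generator(seed)
    if spec.gsd == 1.0:
        return np.full(n, spec.gm, dtype=float)
    return spec.gm * np.exp(rng.normal(0.0, np.log(spec.gsd), size=n))
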