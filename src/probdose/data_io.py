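"""Dose-response datasets: reading, validation, synthesis, and quantization.

Datasets are small summary tables, one row per dose group.  Continuous
endpoints carry (dose, n, mean, sd); quantal endpoints carry
(dose, n, affected).  Files are comma-separated with a header row and doses
in mg/kg BW-day unless stated otherwise.

The module also provides the construction linking the two endpoint kinds:
any continuous individual-level dataset can be *quantized* at a cut point,
turning it into a (deterministic) quantal dataset whose 50% effective dose
estimates the dose at which the median continuous response crosses the cut
point.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import families
from ._random import as_generator
from .errors import (
    AffectedExceedsGroupError,
    DatasetValidationError,
    EndpointSpecError,
    MissingColumnError,
    MixedGroupKindError,
    NonIncreasingDoseError,
    NonNumericCellError,
    TooFewGroupsError,
    UnknownFamilyError,
)

DEFAULT_DOSE_UNIT = "mg/kg BW-day"


class EndpointClass(str, enum.Enum):
    CONTINUOUS = "continuous"
    DETERMINISTIC_QUANTAL = "deterministic_quantal"
    STOCHASTIC_QUANTAL = "stochastic_quantal"


class EffectMetric(str, enum.Enum):
    PERCENT_CHANGE = "percent_change"
    SEVERITY_CATEGORY = "severity_category"
    EXTRA_RISK = "extra_risk"


class Direction(str, enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    AUTO = "auto"


#: endpoint class -> the effect metric that defines toxicological equivalence
METRIC_FOR_CLASS = {
    EndpointClass.CONTINUOUS: EffectMetric.PERCENT_CHANGE,
    EndpointClass.DETERMINISTIC_QUANTAL: EffectMetric.SEVERITY_CATEGORY,
    EndpointClass.STOCHASTIC_QUANTAL: EffectMetric.EXTRA_RISK,
}


@dataclass(frozen=True)
class ContinuousGroup:
    dose: float
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class QuantalGroup:
    dose: float
    n: int
    affected: int


@dataclass
class DoseResponseDataset:
    """Ordered dose groups of one kind plus endpoint metadata."""

    endpoint_name: str
    groups: list
    dose_unit: str = DEFAULT_DOSE_UNIT

    def __post_init__(self):
        self.groups = sorted(self.groups, key=lambda g: g.dose)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if len(self.groups) < 3:
            raise TooFewGroupsError(
                f"{self.endpoint_name!r}: {len(self.groups)} dose groups; "
                "at least 3 are required for model fitting"
            )
        kinds = {type(g) for g in self.groups}
        if len(kinds) > 1:
            raise MixedGroupKindError(
                f"{self.endpoint_name!r}: continuous and quantal groups mixed"
            )
        doses = self.doses
        if np.any(np.diff(doses) <= 0):
            raise NonIncreasingDoseError(
                f"{self.endpoint_name!r}: non-increasing doses {doses.tolist()}"
            )
        if doses[0] < 0:
            raise DatasetValidationError(
                f"{self.endpoint_name!r}: negative dose {doses[0]}"
            )
        for g in self.groups:
            if g.n <= 0:
                raise DatasetValidationError(
                    f"{self.endpoint_name!r}: non-positive group size at dose {g.dose}"
                )
            if isinstance(g, QuantalGroup):
                if not 0 <= g.affected <= g.n:
                    raise AffectedExceedsGroupError(
                        f"{self.endpoint_name!r}: affected={g.affected} outside "
                        f"[0, n={g.n}] at dose {g.dose}"
                    )
            else:
                if g.mean <= 0:
                    raise DatasetValidationError(
                        f"{self.endpoint_name!r}: non-positive mean at dose {g.dose}"
                    )
                if g.sd <= 0:
                    raise DatasetValidationError(
                        f"{self.endpoint_name!r}: non-positive sd at dose {g.dose}"
                    )

    # -- accessors --------------------------------------------------------
    @property
    def kind(self) -> str:
        return "quantal" if isinstance(self.groups[0], QuantalGroup) else "continuous"

    @property
    def doses(self) -> np.ndarray:
        return np.array([g.dose for g in self.groups], dtype=float)

    @property
    def ns(self) -> np.ndarray:
        return np.array([g.n for g in self.groups], dtype=int)

    @property
    def has_control(self) -> bool:
        return self.groups[0].dose == 0.0

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "quantal":
            return pd.DataFrame(
                {
                    "dose": self.doses,
                    "n": self.ns,
                    "affected": [g.affected for g in self.groups],
                }
            )
        return pd.DataFrame(
            {
                "dose": self.doses,
                "n": self.ns,
                "mean": [g.mean for g in self.groups],
                "sd": [g.sd for g in self.groups],
            }
        )


@dataclass(frozen=True)
class EndpointSpec:
    """What is being protected against: endpoint class, metric, effect size.

    ``critical_effect_size`` (M*) is a fraction for percent-change and
    extra-risk metrics; for severity-category endpoints the analysis targets
    the 50% incidence of the reported category and M* is the category label
    (or None).
    """

    endpoint_class: EndpointClass
    critical_effect_size: float | str | None = None
    effect_metric: EffectMetric | None = None
    direction: Direction = Direction.AUTO

    def __post_init__(self):
        ec = EndpointClass(self.endpoint_class)
        object.__setattr__(self, "endpoint_class", ec)
        metric = self.effect_metric
        implied = METRIC_FOR_CLASS[ec]
        if metric is None:
            metric = implied
        else:
            metric = EffectMetric(metric)
            if metric is not implied:
                raise EndpointSpecError(
                    f"endpoint class {ec.value} implies metric {implied.value}, "
                    f"got {metric.value}"
                )
        object.__setattr__(self, "effect_metric", metric)
        object.__setattr__(self, "direction", Direction(self.direction))
        m = self.critical_effect_size
        if metric in (EffectMetric.PERCENT_CHANGE, EffectMetric.EXTRA_RISK):
            if not isinstance(m, (int, float)) or not 0.0 < float(m) < 1.0:
                raise EndpointSpecError(
                    f"critical effect size must be a fraction in (0, 1) for "
                    f"{metric.value}; got {m!r}"
                )
            object.__setattr__(self, "critical_effect_size", float(m))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_REQUIRED = {"continuous": ("dose", "n", "mean", "sd"), "quantal": ("dose", "n", "affected")}


def read_dataset(path, kind: str, endpoint_name: str | None = None) -> DoseResponseDataset:
    """Read a CSV dose-response summary table and validate it.

    ``kind`` is ``"continuous"`` or ``"quantal"``; the required columns are
    dose,n,mean,sd and dose,n,affected respectively. Extra columns ignored.
    """
    if kind not in _REQUIRED:
        raise ValueError(f"kind must be 'continuous' or 'quantal', got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path.name}: missing column(s) {missing}")
    for col in _REQUIRED[kind]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df[col][coerced.isna()].iloc[0]
            raise NonNumericCellError(f"{path.name}: non-numeric {col!r} value {bad!r}")
        df[col] = coerced
    name = endpoint_name or path.stem
    if kind == "quantal":
        groups = [
            QuantalGroup(float(r.dose), int(r.n), int(r.affected)) for r in df.itertuples()
        ]
    else:
        groups = [
            ContinuousGroup(float(r.dose), int(r.n), float(r.mean), float(r.sd))
            for r in df.itertuples()
        ]
    return DoseResponseDataset(endpoint_name=name, groups=groups)


def write_dataset(dataset: DoseResponseDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


_EXAMPLES = {
    "rat_body_weight": ("continuous", "rat_body_weight.csv"),
    "mouse_forestomach_tumors": ("quantal", "mouse_forestomach_tumors.csv"),
}


def load_example(name: str, directory=".") -> DoseResponseDataset:
    """Load one of the two worked-example datasets, if the user supplies it.

    The rat body-weight and mouse forestomach-tumor tables are distributed
    with the PROAST software examples and are not bundled here. Place them as
    ``rat_body_weight.csv`` (columns dose,n,mean,sd) or
    ``mouse_forestomach_tumors.csv`` (columns dose,n,affected) in
    ``directory``; doses in mg/kg BW-day.
    """
    if name not in _EXAMPLES:
        raise KeyError(f"unknown example {name!r}; known: {sorted(_EXAMPLES)}")
    kind, fname = _EXAMPLES[name]
    path = Path(directory) / fname
    if not path.exists():
        raise FileNotFoundError(
            f"example dataset file {path} not found. Export the corresponding "
            f"PROAST example table to CSV with columns "
            f"{','.join(_REQUIRED[kind])} (doses in mg/kg BW-day) and place it "
            f"at that path."
        )
    return read_dataset(path, kind, endpoint_name=name)


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------


def simulate_continuous_individuals(
    family: str,
    params: Sequence[float],
    doses: Sequence[float],
    n_per_group: int,
    cv: float,
    seed,
) -> list[tuple[float, np.ndarray]]:
    """Individual lognormal responses around the model median at each dose.

    Individuals at dose d are lognormal with median f(d, params) and log-SD
    ln(1 + cv), where cv is the within-group geometric coefficient of
    variation (the exact lognormal relation sqrt(ln(1+cv^2)) agrees to second
    order; the simpler form is used throughout).
    """
    if family not in families.CONTINUOUS_FAMILIES:
        raise UnknownFamilyError(family)
    if cv <= 0:
        raise ValueError("cv must be positive")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    rng = as_generator(seed)
    sigma = np.log1p(cv)
    out = []
    for d in doses:
        median = float(families.continuous_median(family, params, d))
        if not np.isfinite(median) or median <= 0:
            raise ValueError(f"non-finite or non-positive model median at dose {d}")
        values = median * np.exp(rng.normal(0.0, sigma, size=n_per_group))
        out.append((float(d), values))
    return out


def simulate_continuous_dataset(
    family: str,
    params: Sequence[float],
    doses: Sequence[float],
    n_per_group: int,
    cv: float,
    seed,
    endpoint_name: str = "simulated_continuous",
) -> DoseResponseDataset:
    """Summary dataset (group means and SDs) of simulated individuals."""
    individuals = simulate_continuous_individuals(
        family, params, doses, n_per_group, cv, seed
    )
    groups = []
    for d, values in individuals:
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        groups.append(
            ContinuousGroup(d, len(values), float(np.mean(values)), max(sd, 1e-300))
        )
    return DoseResponseDataset(endpoint_name=endpoint_name, groups=groups)


def simulate_quantal_dataset(
    family: str,
    params: Sequence[float],
    doses: Sequence[float],
    n_per_group: int,
    seed,
    endpoint_name: str = "simulated_quantal",
) -> DoseResponseDataset:
    """Binomial counts from the family's probability model at each dose."""
    if family not in families.QUANTAL_FAMILIES:
        raise UnknownFamilyError(family)
    rng = as_generator(seed)
    p = np.asarray(families.quantal_probability(family, params, list(doses)), dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError(f"model probabilities outside [0, 1]: {p.tolist()}")
    groups = [
        QuantalGroup(float(d), int(n_per_group), int(rng.binomial(n_per_group, pi)))
        for d, pi in zip(doses, p)
    ]
    return DoseResponseDataset(endpoint_name=endpoint_name, groups=groups)


def quantize_continuous(
    individual_responses: Iterable[tuple[float, float]] | list[tuple[float, np.ndarray]],
    cutpoint: float,
    direction: Direction | str,
    endpoint_name: str = "quantized",
) -> DoseResponseDataset:
    """Dichotomize individual continuous responses at a cut point.

    ``individual_responses`` is either a flat iterable of (dose, value) pairs
    or a list of (dose, array-of-values) as produced by
    :func:`simulate_continuous_individuals`. Per dose, ``affected`` counts the
    individuals beyond the cut point in the adverse direction.
    """
    direction = Direction(direction)
    if direction is Direction.AUTO:
        raise ValueError("quantize_continuous requires an explicit direction")
    by_dose: dict[float, list[float]] = {}
    for dose, value in individual_responses:
        vals = np.atleast_1d(np.asarray(value, dtype=float))
        by_dose.setdefault(float(dose), []).extend(vals.tolist())
    if not by_dose:
        raise DatasetValidationError("no individual responses supplied")
    groups = []
    for dose in sorted(by_dose):
        values = np.asarray(by_dose[dose])
        if values.size == 0:
            raise DatasetValidationError(f"empty dose group at dose {dose}")
        if direction is Direction.INCREASE:
            affected = int(np.sum(values > cutpoint))
        else:
            affected = int(np.sum(values < cutpoint))
        groups.append(QuantalGroup(dose, int(values.size), affected))
    return DoseResponseDataset(endpoint_name=endpoint_name, groups=groups)
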