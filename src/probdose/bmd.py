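"""Benchmark-dose uncertainty by parametric bootstrap with model pooling.

Each candidate family is fitted to the observed data and screened by
goodness of fit (p > 0.05). For every accepted family, datasets are
re-simulated from its fitted sampling model (binomial counts for quantal
data; lognormal group summaries for continuous data), the same family is
refitted, and the BMD recomputed. The per-model BMD clouds are pooled with
equal weight — each model contributes the same number of samples — yielding
the uncertainty distribution of the animal dose AD_M* at the critical effect
size.

Failed refits (non-convergence, benchmark response out of range) are dropped
and counted, never retried; a failure fraction above 20% is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import families as _fam
from ._random import as_generator, substream
from .data_io import (
    ContinuousGroup,
    DoseResponseDataset,
    EndpointSpec,
    QuantalGroup,
)
from .errors import AllModelsRejectedError, BMDRangeError, FitError, ProbdoseError
from .models import ModelFit, bmd_from_fit, fit_continuous, fit_quantal

DEFAULT_N_BOOT = 1000  # bootstrap samples per accepted model

DEFAULT_FAMILIES = {
    "continuous": list(_fam.CONTINUOUS_FAMILIES),
    "quantal": list(_fam.QUANTAL_FAMILIES),
}


@dataclass
class ADDistribution:
    """Pooled bootstrap sample set for the animal benchmark dose."""

    samples: np.ndarray  # positive doses, mg/kg-day
    model_labels: np.ndarray  # per-sample family id
    thetas: list  # per-sample fitted parameter vectors
    n_boot_per_model: int
    seed: int | None
    summary: tuple  # (p5, p50, p95)
    fits: dict = field(default_factory=dict)  # family -> ModelFit on observed data
    n_failed: dict = field(default_factory=dict)
    high_failure: bool = False

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.size and (not np.all(np.isfinite(s)) or np.any(s <= 0)):
            raise ValueError("AD samples must be finite and positive")


def summarize_percentiles(samples, probs) -> list[float]:
    """Empirical quantiles (linear interpolation); ``probs`` are fractions."""
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("no samples")
    return [float(q) for q in np.quantile(s, list(probs))]


def resample_to(samples, n_out: int, seed) -> np.ndarray:
    """Draw ``n_out`` samples with replacement (uniform weights)."""
    s = np.asarray(samples)
    if s.size == 0:
        raise ValueError("no samples")
    rng = as_generator(seed)
    return s[rng.integers(0, s.size, size=int(n_out))]


def _equalized_indices(per_model_samples: dict, rng) -> dict:
    """Per-family index arrays giving each accepted model equal representation:
    families short of the maximum count are resampled up with replacement."""
    if not per_model_samples:
        raise ValueError("no model samples to pool")
    sizes = {k: len(v) for k, v in per_model_samples.items()}
    if min(sizes.values()) == 0:
        raise ValueError("empty sample array for model(s) "
                         f"{[k for k, s in sizes.items() if s == 0]}")
    n_max = max(sizes.values())
    out = {}
    for fam in sorted(per_model_samples):
        n = sizes[fam]
        if n == n_max:
            out[fam] = np.arange(n)
        else:
            out[fam] = rng.integers(0, n, size=n_max)
    return out


def pool_models(per_model_samples: dict, seed=0) -> np.ndarray:
    """Equal-weight pooling of per-model BMD samples into one array."""
    rng = as_generator(seed)
    idx = _equalized_indices(per_model_samples, rng)
    return np.concatenate(
        [np.asarray(per_model_samples[fam], dtype=float)[idx[fam]]
         for fam in sorted(per_model_samples)]
    )


# ---------------------------------------------------------------------------
# parametric resimulation of datasets from a fit
# ---------------------------------------------------------------------------


def _simulate_quantal_rows(fit: ModelFit, dataset: DoseResponseDataset, n_boot, rng):
    phat = np.clip(
        _fam.quantal_probability(fit.family, fit.theta, dataset.doses), 0.0, 1.0
    )
    ns = dataset.ns
    counts = rng.binomial(ns[None, :], phat[None, :], size=(n_boot, len(ns)))
    doses = dataset.doses
    for row in counts:
        yield DoseResponseDataset(
            endpoint_name=dataset.endpoint_name,
            groups=[QuantalGroup(float(d), int(n), int(y))
                    for d, n, y in zip(doses, ns, row)],
            dose_unit=dataset.dose_unit,
        )


def _simulate_continuous_rows(fit: ModelFit, dataset: DoseResponseDataset, n_boot, rng):
    """Resample sufficient statistics: group log-mean ~ N(log f, sigma^2/n),
    group log-variance ~ sigma^2 * chi2_{n-1} / (n-1)."""
    doses = dataset.doses
    ns = dataset.ns.astype(float)
    logf = np.log(_fam.continuous_median(fit.family, fit.theta, doses))
    sigma2 = fit.sigma_log**2
    for _ in range(n_boot):
        m = rng.normal(logf, np.sqrt(sigma2 / ns))
        s2 = sigma2 * rng.chisquare(ns - 1.0) / (ns - 1.0)
        mean = np.exp(m + 0.5 * s2)
        sd = mean * np.sqrt(np.expm1(s2))
        yield DoseResponseDataset(
            endpoint_name=dataset.endpoint_name,
            groups=[ContinuousGroup(float(d), int(n), float(mu), float(max(s, 1e-300)))
                    for d, n, mu, s in zip(doses, dataset.ns, mean, sd)],
            dose_unit=dataset.dose_unit,
        )


def bootstrap_ad_samples(
    dataset: DoseResponseDataset,
    spec: EndpointSpec,
    families: list[str] | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> ADDistribution:
    """Pooled parametric-bootstrap distribution of the BMD at BMR = M*."""
    if families is None:
        families = DEFAULT_FAMILIES[dataset.kind]
    fit_fn = fit_quantal if dataset.kind == "quantal" else fit_continuous
    fits = {}
    for fam in families:
        try:
            fits[fam] = fit_fn(dataset, fam)
        except (FitError, BMDRangeError) as exc:
            warnings.warn(f"{fam}: fit failed on observed data ({exc})")
    accepted = {fam: f for fam, f in fits.items() if f.accepted}
    if not accepted:
        raise AllModelsRejectedError(
            "all models rejected by the goodness-of-fit screen (p <= 0.05): "
            + ", ".join(f"{fam} p={f.gof_p:.3g}" for fam, f in fits.items())
        )
    rng = substream(seed, "bootstrap")
    per_model_bmd: dict[str, list] = {}
    per_model_theta: dict[str, list] = {}
    n_failed: dict[str, int] = {}
    sim_fn = (
        _simulate_quantal_rows if dataset.kind == "quantal" else _simulate_continuous_rows
    )
    for fam in sorted(accepted):
        fit = accepted[fam]
        bmds, thetas, failed = [], [], 0
        for boot_ds in sim_fn(fit, dataset, n_boot, rng):
            try:
                refit = fit_fn(boot_ds, fam, fit.theta)
                bmd = bmd_from_fit(refit, spec)
                if not np.isfinite(bmd) or bmd <= 0:
                    raise BMDRangeError("non-finite bootstrap BMD")
            except ProbdoseError:
                failed += 1
                continue
            bmds.append(bmd)
            thetas.append(refit.theta)
        per_model_bmd[fam] = bmds
        per_model_theta[fam] = thetas
        n_failed[fam] = failed
    high_failure = any(
        n_failed[fam] > 0.2 * n_boot for fam in per_model_bmd
    )
    if high_failure:
        warnings.warn(
            "more than 20% of bootstrap refits failed for at least one model: "
            f"{n_failed}"
        )
    idx = _equalized_indices(per_model_bmd, rng)
    samples, labels, thetas = [], [], []
    for fam in sorted(per_model_bmd):
        arr = np.asarray(per_model_bmd[fam], dtype=float)
        th = per_model_theta[fam]
        for i in idx[fam]:
            thetas.append(th[int(i)])
        samples.append(arr[idx[fam]])
        labels.append(np.full(len(idx[fam]), fam, dtype=object))
    samples = np.concatenate(samples)
    return ADDistribution(
        samples=samples,
        model_labels=np.concatenate(labels),
        thetas=thetas,
        n_boot_per_model=n_boot,
        seed=seed,
        summary=tuple(summarize_percentiles(samples, (0.05, 0.50, 0.95))),
        fits=fits,
        n_failed=n_failed,
        high_failure=high_failure,
    )
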