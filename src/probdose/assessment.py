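"""Assessment orchestration, deterministic comparators, and reporting.

`run_assessment` wires the three steps together: bootstrap the animal BMD
(Step 1), sample the interspecies adjustment distributions (Step 2), apply
uncertain human variability at the target incidence (Step 3), and derive the
probabilistic RfD. Deterministic comparators — the BMDL/100 reference dose
and, for stochastic quantal endpoints, linear extrapolation from the
allometrically scaled BMDL10 — are reported alongside.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._random import substream
from .adjustments import sample_ahu, sample_daf, sample_ou, sample_sigma_h
from .bmd import ADDistribution, bootstrap_ad_samples, summarize_percentiles
from .config import AssessmentConfig, load_config
from .data_io import EndpointClass, EndpointSpec, read_dataset
from .engine import (
    HDMIResult,
    IncidenceCurve,
    hd_mi_samples,
    incidence_curve,
    population_incidence_stochastic,
)
from .errors import BMDRangeError, ConfigError, ProbdoseError
from .models import ModelFit, bmd_from_fit

log = logging.getLogger("probdose")

LINEAR_EXTRAPOLATION_INCIDENCES = (0.05, 0.01, 0.001, 0.0001)


def deterministic_rfd(bmdl: float, uf: float = 100.0) -> float:
    """Traditional reference dose: BMDL divided by a composite factor."""
    if bmdl <= 0 or uf <= 0:
        raise ValueError("bmdl and uf must be positive")
    return bmdl / uf


def linear_extrapolation_dose(
    bmdl10: float, bw_animal: float, bw_human: float, incidence: float
) -> float:
    """Low-dose linear extrapolation from the allometrically scaled BMDL10.

    The point of departure is the BMDL at 10% extra risk scaled to a human
    equivalent dose by (BW_animal / BW_human)**0.25; doses below it scale
    linearly with the target incidence.
    """
    if bmdl10 <= 0 or bw_animal <= 0 or bw_human <= 0:
        raise ValueError("bmdl10 and body weights must be positive")
    if not 0.0 < incidence <= 0.10:
        raise ValueError(
            "linear extrapolation applies below the 10% point of departure; "
            f"got incidence {incidence}"
        )
    hed = bmdl10 * (bw_animal / bw_human) ** 0.25
    return hed * (incidence / 0.10)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report convention)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


@dataclass
class AssessmentReport:
    """All sample sets and summaries of one probabilistic assessment."""

    dataset_name: str
    endpoint: EndpointSpec
    ad: ADDistribution
    hdmi: HDMIResult
    comparators: dict
    config: AssessmentConfig
    seed: int
    n_mc: int
    version: str = __version__
    population_curve: IncidenceCurve | None = None
    incidence_bands: IncidenceCurve | None = None

    def intervals(self) -> dict:
        """(p5, p95) intervals recomputed from the stored samples."""
        out = {
            "AD_M*": tuple(summarize_percentiles(self.ad.samples, (0.05, 0.95))),
            "HD_M*": tuple(
                summarize_percentiles(self.hdmi.hd_median_samples, (0.05, 0.95))
            ),
            "HD_M^I": tuple(
                summarize_percentiles(self.hdmi.hd_mi_samples, (0.05, 0.95))
            ),
        }
        return out

    def to_frame(self, sig: int = 2) -> pd.DataFrame:
        rows = []
        for label, (p5, p95) in self.intervals().items():
            rows.append(
                {"quantity": label, "p5": round_sig(p5, sig), "p95": round_sig(p95, sig)}
            )
        rows.append(
            {
                "quantity": f"probabilistic RfD (I*={self.hdmi.goal.i_star:g}, "
                f"{self.hdmi.goal.confidence:.0%} confidence)",
                "p5": round_sig(self.hdmi.probabilistic_rfd, sig),
                "p95": np.nan,
            }
        )
        for label, value in self.comparators.items():
            rows.append({"quantity": label, "p5": round_sig(value, sig), "p95": np.nan})
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        goal = self.hdmi.goal
        lines = [
            f"probdose {self.version} assessment of {self.dataset_name!r}",
            f"endpoint class: {self.endpoint.endpoint_class.value}; "
            f"effect metric: {self.endpoint.effect_metric.value}; "
            f"M* = {self.endpoint.critical_effect_size}",
            f"protection goal: I* = {goal.i_star:g}, confidence = {goal.confidence:.0%}",
            f"accepted models: "
            + ", ".join(sorted({f for f in self.ad.model_labels})),
            f"seed = {self.seed}; n_boot = {self.ad.n_boot_per_model} per model; "
            f"n_mc = {self.n_mc}",
            "",
            self.to_frame().to_string(index=False),
            "",
            "intervals are (5th, 95th) percentiles in mg/kg BW-day, "
            "rounded to 2 significant figures",
        ]
        return "\n".join(lines)

    def write(self, out_dir, include_samples: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "report.csv", index=False)
        (out / "report.txt").write_text(self.to_text() + "\n")
        manifest = {
            "version": self.version,
            "dataset": self.dataset_name,
            "seed": self.seed,
            "n_mc": self.n_mc,
            "n_boot_per_model": self.ad.n_boot_per_model,
            "bootstrap_failures": {k: int(v) for k, v in self.ad.n_failed.items()},
            "config": self.config.raw,
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
        if include_samples:
            pd.DataFrame(
                {
                    "ad": np.asarray(
                        self.ad.samples, dtype=float
                    ),
                    "model": self.ad.model_labels,
                }
            ).to_csv(out / "ad_samples.csv", index=False)
            pd.DataFrame(
                {
                    "hd_median": self.hdmi.hd_median_samples,
                    "hd_mi": self.hdmi.hd_mi_samples,
                }
            ).to_csv(out / "hd_samples.csv", index=False)
        if self.population_curve is not None:
            c = self.population_curve
            pd.DataFrame(
                {"dose": c.doses, "p5": c.p5, "p50": c.p50, "p95": c.p95}
            ).to_csv(out / "population_incidence.csv", index=False)


def _bmd_samples_at(ad: ADDistribution, spec: EndpointSpec, max_dose: float):
    """Recompute per-bootstrap-sample BMDs at another benchmark response."""
    out = []
    for fam, theta in zip(ad.model_labels, ad.thetas):
        shell = ModelFit(
            family=str(fam), theta=np.asarray(theta, dtype=float), loglik=np.nan,
            gof_p=np.nan, accepted=True, endpoint_kind="quantal",
            background=np.nan, n_params=0, max_dose=max_dose,
        )
        try:
            out.append(bmd_from_fit(shell, spec))
        except BMDRangeError:
            continue
    return np.asarray(out)


def run_assessment(
    dataset_path,
    config_path,
    seed: int,
    n_mc: int | None = None,
    n_inner: int | None = None,
    population_incidence: bool = False,
    out_dir=None,
) -> AssessmentReport:
    """Execute the full probabilistic assessment on one dataset + config."""
    cfg = config_path if isinstance(config_path, AssessmentConfig) else load_config(
        config_path
    )
    endpoint = cfg.endpoint
    kind = (
        "continuous"
        if endpoint.endpoint_class is EndpointClass.CONTINUOUS
        else "quantal"
    )
    dataset = (
        dataset_path
        if not isinstance(dataset_path, (str, Path))
        else read_dataset(dataset_path, kind)
    )
    n_mc = int(n_mc or cfg.sampling.n_mc)
    n_inner = int(n_inner or cfg.sampling.n_inner)

    log.info("step 1: bootstrap BMD analysis (%s, %d per model)",
             dataset.endpoint_name, cfg.sampling.n_boot)
    try:
        ad = bootstrap_ad_samples(
            dataset, endpoint, families=cfg.families,
            n_boot=cfg.sampling.n_boot, seed=seed,
        )
    except ProbdoseError as exc:
        raise type(exc)(f"step 1 (BMD bootstrap): {exc}") from exc

    log.info("step 2/3: %d MC draws of adjustments and variability", n_mc)
    idx = substream(seed, "resample").integers(0, ad.samples.size, size=n_mc)
    ad_mc = ad.samples[idx]
    daf = sample_daf(cfg.adjustments, n_mc, substream(seed, "daf"))
    ahu = sample_ahu(cfg.adjustments, n_mc, substream(seed, "ahu"))
    ou = sample_ou(cfg.adjustments, n_mc, substream(seed, "ou"))
    sigma_h = sample_sigma_h(cfg.variability, n_mc, substream(seed, "sigma_h"))
    hdmi = hd_mi_samples(
        ad_mc, daf, ahu, ou, sigma_h, cfg.goal, seed=seed,
        provenance={"dataset": dataset.endpoint_name, "config": cfg.raw},
    )

    comparators: dict[str, float] = {}
    ad_p5 = summarize_percentiles(ad.samples, (0.05,))[0]
    comparators["deterministic RfD (BMDL/100)"] = deterministic_rfd(ad_p5)
    if endpoint.endpoint_class is EndpointClass.STOCHASTIC_QUANTAL:
        if endpoint.critical_effect_size == 0.10:
            bmdl10 = ad_p5
        else:
            spec10 = replace(endpoint, critical_effect_size=0.10)
            bmd10 = _bmd_samples_at(ad, spec10, float(dataset.doses.max()))
            bmdl10 = summarize_percentiles(bmd10, (0.05,))[0]
        for inc in LINEAR_EXTRAPOLATION_INCIDENCES:
            comparators[f"linear extrapolation, incidence {inc:g}"] = (
                linear_extrapolation_dose(
                    bmdl10, cfg.adjustments.bw_animal, cfg.adjustments.bw_human, inc
                )
            )

    population_curve = None
    incidence_bands = None
    if population_incidence:
        lo = hdmi.probabilistic_rfd / 30.0
        hi = summarize_percentiles(hdmi.hd_median_samples, (0.95,))[0] * 10.0
        grid = np.geomspace(lo, hi, 25)
        n_outer = min(n_mc, 2000)
        if endpoint.endpoint_class is EndpointClass.STOCHASTIC_QUANTAL:
            thetas = [ad.thetas[int(i)] for i in idx[:n_outer]]
            labels = [str(ad.model_labels[int(i)]) for i in idx[:n_outer]]
            population_curve = population_incidence_stochastic(
                thetas, labels, daf[:n_outer], ahu[:n_outer], ou[:n_outer],
                sigma_h[:n_outer], grid, n_inner=n_inner, seed=seed,
            )
        else:
            incidence_bands = incidence_curve(
                hdmi.hd_median_samples[:n_outer], sigma_h[:n_outer], grid
            )

    report = AssessmentReport(
        dataset_name=dataset.endpoint_name,
        endpoint=endpoint,
        ad=ad,
        hdmi=hdmi,
        comparators=comparators,
        config=cfg,
        seed=int(seed),
        n_mc=n_mc,
        population_curve=population_curve,
        incidence_bands=incidence_bands,
    )
    if out_dir is not None:
        report.write(out_dir)
        log.info("report written to %s", out_dir)
    return report


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
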