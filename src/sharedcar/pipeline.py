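"""End-to-end orchestration: simulate, fit, diagnose, summarise.

A study run is fully described by a :class:`RunConfig` (paths, variant,
chain schedule, optional sub-cohort filter and hyperparameter overrides,
master seed) and is deterministic given the seed.  Every run writes a
manifest recording the configuration hash and SHA-256 checksums of all
outputs, so a replay can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import (
    FitReport,
    dic,
    gelman_rubin_table,
    ppc_coverage,
    relative_weights,
    summarize_effects,
)
from .inference import McmcSettings, run_mcmc
from .model import Hyperparameters, ModelSpec, VARIANTS
from .spatial_graph import read_adjacency
from .summaries import shared_effect_summary, treatment_specific_summary
from .synthetic import TREATMENTS, CohortTable, default_schema

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "compare_variants", "SENSITIVITY_PRESETS"]

#: hyperparameter overrides of the published sensitivity analyses: two
#: alternative Gamma hyperpriors for the precisions of the fixed effects and
#: CAR fields, and a less informative log-weight prior (precision 2.9)
SENSITIVITY_PRESETS: dict[str, dict] = {
    "gamma_0.5_0.5": {"fe_shape": 0.5, "fe_rate": 0.5, "car_shape": 0.5, "car_rate": 0.5},
    "gamma_0.5_0.05": {"fe_shape": 0.5, "fe_rate": 0.05, "car_shape": 0.5, "car_rate": 0.05},
    "logdelta_prec_2.9": {"logdelta_prec": 2.9},
}


@dataclass
class RunConfig:
    cohort: str
    adjacency: str
    output_dir: str
    variant: str = "A0"
    mcmc: dict = field(default_factory=dict)
    subcohort: dict | None = None  # {"covariate": ..., "value": ...}
    hyper_overrides: dict = field(default_factory=dict)
    seed: int = 0
    overwrite: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"invalid variant {self.variant!r}")
        if self.subcohort is not None and set(self.subcohort) != {"covariate", "value"}:
            raise ValueError("subcohort filter needs 'covariate' and 'value' keys")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def settings(self) -> McmcSettings:
        base = {"seed": self.seed}
        base.update(self.mcmc)
        return McmcSettings(**base)

    def model_spec(self) -> ModelSpec:
        hyper = Hyperparameters(**self.hyper_overrides) if self.hyper_overrides else None
        return ModelSpec.from_variant(self.variant, hyper=hyper)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def cohort_hash(cohort: CohortTable) -> str:
    csv = cohort.df.to_csv(index=False, lineterminator="\n")
    return hashlib.sha256(csv.encode()).hexdigest()


def run_study(config: RunConfig) -> dict:
    """Fit, diagnose and summarise one model run; returns the manifest.

    Artefacts written to ``output_dir``: posterior samples (per-parameter
    CSV), fit report (JSON), effect and relative-weight tables, per-area
    spatial summaries, Gelman-Rubin table and a checksummed manifest.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"{out} exists and is not empty; set overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    logger.info("loading cohort %s and adjacency %s", config.cohort, config.adjacency)
    cohort = CohortTable.read_csv(config.cohort)
    graph = read_adjacency(config.adjacency)
    cohort.validate_against(graph)
    schema = default_schema()

    drop: tuple[str, ...] = ()
    if config.subcohort is not None:
        cov, val = config.subcohort["covariate"], config.subcohort["value"]
        cohort = cohort.subset(cov, val)
        drop = (cov,)  # sub-cohort analyses are not adjusted for the filter variable
        logger.info("sub-cohort %s=%s: %d individuals, dropping %s from design",
                    cov, val, len(cohort), cov)

    spec = config.model_spec()
    settings = config.settings()
    logger.info(
        "fitting variant %s: %d chains x %d iterations (burn-in %d, thin %d), "
        "%d retained per chain / %d pooled",
        spec.variant, settings.n_chains, settings.n_iterations, settings.burn_in,
        settings.thin, settings.retained_per_chain, settings.retained_total,
    )
    samples = run_mcmc(spec, cohort, graph, settings, schema=schema, drop=drop)

    residual = max(
        float(np.abs(samples.stacked("log_delta").sum(axis=1)).max())
        if "log_delta" in samples.draws else 0.0,
        float(np.abs(samples.stacked("phi").mean(axis=1)).max())
        if "phi" in samples.draws else 0.0,
    )
    logger.info("max constraint residual over retained draws: %.3g", residual)

    samples.to_dir(out / "samples")

    dic_val, dbar, pd_val = dic(samples, spec, cohort, graph, schema=schema, drop=drop)
    ppc = ppc_coverage(samples, spec, cohort, graph, schema=schema, drop=drop,
                       seed=config.seed)
    gr = gelman_rubin_table(samples)
    report = FitReport(
        dic=dic_val, dbar=dbar, pd=pd_val, ppc=ppc,
        rhat_max=float(gr["rhat"].max()), variant=spec.variant,
        cohort_hash=cohort_hash(cohort),
    )
    with open(out / "fit_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    gr.to_csv(out / "gelman_rubin.csv", index=False, lineterminator="\n")
    summarize_effects(samples).to_csv(out / "effects.csv", index=False, lineterminator="\n")
    if "log_delta" in samples.draws:
        relative_weights(samples).to_csv(
            out / "relative_weights.csv", index=False, lineterminator="\n"
        )
    if "phi" in samples.draws:
        shared_effect_summary(samples).to_csv(
            out / "shared_effect.csv", index=False, lineterminator="\n"
        )
    if "u" in samples.draws or "s" in samples.draws:
        for k, treat in enumerate(TREATMENTS):
            treatment_specific_summary(samples, k).to_csv(
                out / f"specific_effect_{treat}.csv", index=False, lineterminator="\n"
            )

    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "retained_per_chain": settings.retained_per_chain,
        "retained_total": settings.retained_total,
        "max_constraint_residual": residual,
        "checksums": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("run complete: %d artefact files in %s", len(files), out)
    return manifest


def compare_variants(reports: list[FitReport]) -> pd.DataFrame:
    """Rank fit reports by DIC (ascending; smaller is better fit).

    All reports must come from the same cohort; ``delta_dic`` is the gap to
    the best model.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    hashes = {r.cohort_hash for r in reports}
    if len(hashes) > 1:
        raise ValueError("reports were fit on different cohorts")
    df = pd.DataFrame([r.to_dict() for r in reports])
    df = df.sort_values("dic", kind="stable").reset_index(drop=True)
    df["delta_dic"] = df["dic"] - df["dic"].iloc[0]
    return df[["variant", "dic", "dbar", "pd", "ppc", "rhat_max", "delta_dic", "cohort_hash"]]
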