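"""Config-driven end-to-end runs: simulate/load -> screen -> intersect ->
refine, with TSV report export and a manifest sufficient to reproduce
every output byte-identically.

A single config file (YAML or JSON) declares either file-backed cohorts
(paths + column maps + ELN dialect) or a simulation recipe, plus endpoint,
ROC horizon, gate thresholds, confounder list and refinement mapping.
Outputs are written all-or-nothing: the report lands in a temporary
directory that is atomically renamed on success, so an aborted run never
leaves partial output under the target path.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Cohort,
    CohortError,
    dichotomize,
    harmonize,
    load_clinical,
    load_expression,
    write_clinical,
    write_expression,
)
from .refine import DEFAULT_MAPPING, evaluate_stratification, refine_risk
from .screen import (
    DEFAULT_CONFOUNDERS,
    DEFAULT_HORIZON,
    GateThresholds,
    ScreenSummary,
    intersect_cohorts,
    screen_cohort,
)
from .simulate import InteractionSpec, SimulationConfig, generate_multi_cohort

logger = logging.getLogger("survscreen")

FLOAT_FMT = "%.10g"  # fixed text formatting => byte-stable TSV exports


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    endpoint: str = "OS"
    horizon: float = DEFAULT_HORIZON
    gates: GateThresholds = field(default_factory=GateThresholds)
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS
    cutpoint_band: tuple[float, float] = (0.10, 0.90)
    #: file-backed cohorts: list of {name, expression, clinical, column_map}
    cohorts: list[dict] = field(default_factory=list)
    #: simulation recipe (mutually exclusive with ``cohorts``)
    simulate: dict | None = None
    refinement: dict = field(default_factory=lambda: {"base_column": "eln", "mapping": "default"})

    def __post_init__(self):
        if self.endpoint not in ("OS", "DFS", "EFS"):
            raise ConfigError(f"unknown endpoint {self.endpoint!r}")
        if self.horizon <= 0:
            raise ConfigError("horizon must be positive")
        if not (0 <= self.cutpoint_band[0] < self.cutpoint_band[1] <= 1):
            raise ConfigError(f"invalid cutpoint band {self.cutpoint_band}")
        if bool(self.cohorts) == bool(self.simulate):
            raise ConfigError("config must declare exactly one of 'cohorts' or 'simulate'")
        for decl in self.cohorts:
            for key in ("name", "expression", "clinical", "column_map"):
                if key not in decl:
                    raise ConfigError(f"cohort declaration missing {key!r}: {decl}")
            for key in ("expression", "clinical"):
                if not Path(decl[key]).exists():
                    raise ConfigError(f"declared path does not exist: {decl[key]}")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "endpoint": self.endpoint,
            "horizon": self.horizon,
            "gates": dataclasses.asdict(self.gates),
            "confounders": list(self.confounders),
            "cutpoint_band": list(self.cutpoint_band),
            "refinement": self.refinement,
        }
        if self.simulate is not None:
            d["simulate"] = self.simulate
        if self.cohorts:
            d["cohorts"] = self.cohorts
        return d


def load_config(path) -> RunConfig:
    """Load and validate a run config from a YAML/JSON file.

    A manifest written by a previous run is also accepted (its embedded
    config is used), which makes manifest-driven re-runs first-class.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")
    if "config" in raw and "version" in raw:  # manifest from a previous run
        raw = raw["config"]
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    gates = GateThresholds(**raw.get("gates", {}))
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        endpoint=raw.get("endpoint", "OS"),
        horizon=float(raw.get("horizon", DEFAULT_HORIZON)),
        gates=gates,
        confounders=tuple(raw.get("confounders", DEFAULT_CONFOUNDERS)),
        cutpoint_band=tuple(raw.get("cutpoint_band", (0.10, 0.90))),
        cohorts=list(raw.get("cohorts", [])),
        simulate=raw.get("simulate"),
        refinement=raw.get("refinement", {"base_column": "eln", "mapping": "default"}),
    )


# ---------------------------------------------------------------------------
# cohort acquisition


def _sim_configs(spec: dict) -> list[SimulationConfig]:
    common = {
        "n_genes": int(spec.get("n_genes", 200)),
        "planted": {int(k): float(v) for k, v in spec.get("planted", {}).items()},
        "censoring": float(spec.get("censoring", 0.35)),
    }
    if "confounder_effects" in spec:
        common["confounder_effects"] = {
            k: float(v) for k, v in spec["confounder_effects"].items()
        }
    if "interaction" in spec:
        common["interaction"] = InteractionSpec(**spec["interaction"])
    out = []
    for decl in spec.get("cohorts", [{"name": "sim", "n_samples": 100}]):
        out.append(
            SimulationConfig(
                name=str(decl["name"]), n_samples=int(decl["n_samples"]), **common
            )
        )
    return out


def acquire_cohorts(config: RunConfig):
    """Load file-backed cohorts or simulate per the config; validates first."""
    if config.simulate is not None:
        pairs = generate_multi_cohort(_sim_configs(config.simulate), config.seed)
        return [c for c, _ in pairs], [t for _, t in pairs]
    cohorts = []
    for decl in config.cohorts:
        expr = load_expression(decl["expression"])
        clin = load_clinical(decl["clinical"], decl["column_map"])
        cohorts.append(harmonize(expr, clin, decl["name"]))
    return cohorts, None


# ---------------------------------------------------------------------------
# report tables


def screen_ledger(results) -> pd.DataFrame:
    """Flat per-gene ledger for one cohort's screen."""
    rows = []
    for r in results:
        row = {"gene_id": r.gene_id, "cohort": r.cohort}
        if r.cutpoint is not None:
            c = r.cutpoint
            row.update(cutpoint=c.cutpoint, auc=c.auc, sensitivity=c.sensitivity,
                       specificity=c.specificity, n_high=c.n_high, n_low=c.n_low)
        if r.univariate is not None:
            row.update(uni_hr=float(r.univariate.hazard_ratios[0]),
                       uni_p=float(r.univariate.p_values[0]))
        if r.multivariate is not None:
            row.update(multi_hr=float(r.multivariate.hazard_ratios[0]),
                       multi_p=float(r.multivariate.p_values[0]))
        for gate, ok in r.gates.items():
            row[gate] = ok
        row["passed"] = r.passed
        row["direction"] = r.direction or ""
        row["failure_reason"] = r.failure_reason or ""
        rows.append(row)
    return pd.DataFrame(rows)


def km_table(curve, group: str) -> pd.DataFrame:
    return pd.DataFrame(
        {"group": group, "time": curve.event_times, "survival": curve.survival,
         "at_risk": curve.at_risk, "events": curve.events}
    )


def forest_table(summary: ScreenSummary) -> pd.DataFrame:
    """HR + 95% CI per covariate of every intersection gene's adjusted fit."""
    rows = []
    for gene in summary.intersection:
        for cname, res in summary.results.items():
            fit = res[gene].multivariate
            if fit is None:
                continue
            ci = fit.confidence_intervals()
            for j, cov in enumerate(fit.covariates):
                rows.append({
                    "gene_id": gene, "cohort": cname, "covariate": cov,
                    "hr": float(fit.hazard_ratios[j]), "ci_low": float(ci[j, 0]),
                    "ci_high": float(ci[j, 1]), "p_value": float(fit.p_values[j]),
                })
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# pipeline


def run_screen_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the full screen end to end and write the report bundle.

    Loads/harmonizes (or simulates) every cohort, screens all genes per
    cohort, intersects across cohorts, evaluates marker-based risk
    refinement for each intersection gene, and writes per-cohort ledgers,
    the intersection table, KM tables, a forest-plot table and a manifest.
    Outputs appear atomically under ``out_dir``; an empty intersection
    still produces a complete report.
    """
    out_dir = Path(out_dir)
    cohorts, truths = acquire_cohorts(config)

    per_cohort = {}
    for cohort in cohorts:
        per_cohort[cohort.name] = screen_cohort(
            cohort, confounders=config.confounders, thresholds=config.gates,
            horizon=config.horizon, endpoint=config.endpoint, band=config.cutpoint_band,
        )
    summary = intersect_cohorts(per_cohort)

    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=out_dir.name + ".partial.", dir=out_dir.parent))
    try:
        for cohort in cohorts:
            _write_tsv(screen_ledger(per_cohort[cohort.name]),
                       staging / f"screen_{cohort.name}.tsv")
        inter = pd.DataFrame(
            {"gene_id": summary.intersection,
             "direction": [summary.directions[g] for g in summary.intersection]}
        )
        _write_tsv(inter, staging / "intersection.tsv")
        _write_tsv(forest_table(summary), staging / "forest.tsv")

        km_rows, refine_rows = [], []
        for gene in summary.intersection:
            for cohort in cohorts:
                res = summary.results[cohort.name][gene]
                if res.cutpoint is None:
                    continue
                marker = pd.Series(cohort.expression.gene(gene), index=cohort.sample_ids)
                labels = dichotomize(marker, res.cutpoint.cutpoint, gene)
                lo = config.endpoint.lower()
                surv = cohort.clinical.data[[f"{lo}_time", f"{lo}_event"]].dropna()
                for level in ("high", "low"):
                    m = labels.labels.loc[surv.index] == level
                    if m.sum() == 0:
                        continue
                    from .survival import km_estimate

                    curve = km_estimate(surv.loc[m, f"{lo}_time"], surv.loc[m, f"{lo}_event"])
                    t = km_table(curve, level)
                    t.insert(0, "cohort", cohort.name)
                    t.insert(0, "gene_id", gene)
                    km_rows.append(t)
                # refinement against the base risk system, when available
                base_col = config.refinement.get("base_column", "eln")
                if base_col in cohort.clinical.data.columns:
                    mapping = config.refinement.get("mapping", "default")
                    mapping = DEFAULT_MAPPING if mapping == "default" else {
                        (k.split("|")[0], k.split("|")[1]): v for k, v in mapping.items()
                    }
                    try:
                        refined = refine_risk(cohort.clinical.data[base_col], labels, mapping)
                        comp = evaluate_stratification(
                            cohort, cohort.clinical.data[base_col],
                            refined.assignments, endpoint=config.endpoint,
                        )
                        refine_rows.append({
                            "gene_id": gene, "cohort": cohort.name,
                            "base_logrank": comp.base.logrank.statistic,
                            "base_p": comp.base.logrank.p_value,
                            "refined_logrank": comp.refined.logrank.statistic,
                            "refined_p": comp.refined.logrank.p_value,
                            "n": comp.n,
                        })
                    except (CohortError, ValueError) as exc:
                        logger.warning("refinement skipped for %s/%s: %s",
                                       cohort.name, gene, exc)
        km_all = (pd.concat(km_rows, ignore_index=True) if km_rows
                  else pd.DataFrame(columns=["gene_id", "cohort", "group", "time",
                                             "survival", "at_risk", "events"]))
        _write_tsv(km_all, staging / "km_curves.tsv")
        _write_tsv(pd.DataFrame(refine_rows, columns=["gene_id", "cohort", "base_logrank",
                                                      "base_p", "refined_logrank",
                                                      "refined_p", "n"]),
                   staging / "refinement.tsv")

        if truths is not None:
            for cohort, truth in zip(cohorts, truths):
                _write_tsv(truth.to_frame(), staging / f"ground_truth_{cohort.name}.tsv")
                write_expression(cohort.expression, staging / f"expression_{cohort.name}.tsv")
                write_clinical(cohort.clinical, staging / f"clinical_{cohort.name}.tsv")

        manifest = {
            "package": "survscreen",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": sorted(p.name for p in staging.iterdir()) + ["manifest.json"],
        }
        with open(staging / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(staging, out_dir)
    except BaseException:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    logger.info("report written to %s (%d intersection genes)",
                out_dir, len(summary.intersection))
    return out_dir
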