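"""Orchestration: simulate -> preprocess -> analyse -> report.

A pipeline run is fully described by a :class:`PipelineConfig` (either a
simulation block or a path to an existing dataset, plus the validity rule,
aggregation mode and model options) and a seed.  The same config + seed
always produces a byte-identical report bundle; the manifest records the
seed, a hash of the canonical config and the package version so every
number in the reports is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

import codawork
from codawork.models import fit_model1, fit_pivot_models, fit_vca, predict_composition_curve
from codawork.preprocess import ValidityRule, complete_case_filter, preprocess
from codawork.reports import (
    model1_table,
    pivot_table,
    summarise_composition,
    summarise_determinants,
    vca_table,
)
from codawork.simulate import (
    DETERMINANTS,
    SimulationConfig,
    generate_dataset,
    read_dataset,
    write_dataset,
)

logger = logging.getLogger("codawork.pipeline")

REPORT_FILES = (
    "descriptives.csv",
    "composition_summary.csv",
    "variance_components.csv",
    "model1_associations.csv",
    "pivot_associations.csv",
    "ternary_curves.csv",
)


class PipelineConfigError(ValueError):
    """Raised when a pipeline configuration is unusable."""


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    #: simulation settings (dict for SimulationConfig), or None to read data
    simulation: dict | None = None
    #: directory holding workers.csv / days.csv, or None to simulate
    dataset: str | None = None
    min_work_hours: float = 4.0
    aggregation: str = "geometric"
    #: significance level selecting determinants for prediction curves
    curve_alpha: float = 0.05
    out_dir: str = "codawork_out"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None and self.dataset is None:
            raise PipelineConfigError(
                "config must provide either a 'simulation' block or a 'dataset' path"
            )
        if self.simulation is not None and self.dataset is not None:
            raise PipelineConfigError("provide 'simulation' or 'dataset', not both")
        if self.aggregation not in ("geometric", "arithmetic"):
            raise PipelineConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.min_work_hours <= 0:
            raise PipelineConfigError("min_work_hours must be positive")
        if self.dataset is not None and not Path(self.dataset).exists():
            raise PipelineConfigError(f"dataset path {self.dataset!r} does not exist")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.canonical_json().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns a summary dict (the manifest contents).  On stage failure the
    partially written outputs are removed and a :class:`PipelineStageError`
    naming the stage is raised.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
        logger.info("wrote %s (%d rows)", path, len(df))

    stage = "configure"
    try:
        # ---- data -------------------------------------------------------
        stage = "simulate" if config.simulation is not None else "load"
        if config.simulation is not None:
            sim = SimulationConfig.from_dict({**config.simulation, "seed": config.seed})
            workers, days = generate_dataset(sim)
            write_dataset(workers, days, out / "dataset")
            written += [out / "dataset" / "workers.csv", out / "dataset" / "days.csv"]
            logger.info(
                "simulated %d workers / %d teams / %d institutions, %d day records",
                len(workers), workers["team_id"].nunique(),
                workers["institution_id"].nunique(), len(days),
            )
        else:
            workers, days = read_dataset(config.dataset)
            logger.info("loaded %d workers, %d day records from %s", len(workers), len(days), config.dataset)

        # ---- preprocess -------------------------------------------------
        stage = "preprocess"
        analysis, plog = preprocess(
            workers, days, ValidityRule(config.min_work_hours), config.aggregation
        )
        analysis.to_csv(out / "analysis_workers.csv", index=False)
        written.append(out / "analysis_workers.csv")
        logger.info(
            "validity filter: %d/%d days kept; %d/%d workers with >=1 valid day",
            plog["n_days_valid"], plog["n_days_in"],
            plog["n_workers_valid"], plog["n_workers_in"],
        )

        # ---- descriptives ----------------------------------------------
        stage = "describe"
        emit("descriptives.csv", summarise_determinants(analysis))
        emit("composition_summary.csv", summarise_composition(analysis))

        # ---- variance components ---------------------------------------
        stage = "variance_components"
        vd = fit_vca(analysis)
        emit("variance_components.csv", vca_table(vd))

        # ---- association models ----------------------------------------
        stage = "association_models"
        complete, dropped = complete_case_filter(analysis, DETERMINANTS)
        logger.info(
            "complete-case: %d/%d workers retained (missing per determinant: %s)",
            len(complete), len(analysis), dropped,
        )
        m1 = fit_model1(complete)
        emit("model1_associations.csv", model1_table(m1))
        pivots = fit_pivot_models(complete)
        emit("pivot_associations.csv", pivot_table(pivots))

        # ---- prediction curves ------------------------------------------
        stage = "prediction_curves"
        significant = [
            det
            for det, row in m1.table.iterrows()
            if row["p_joint"] < config.curve_alpha and det in m1.observed_ranges
        ]
        if significant:
            curves = pd.concat(
                [predict_composition_curve(m1, det) for det in significant],
                ignore_index=True,
            )
        else:
            curves = pd.DataFrame(columns=["determinant", "value", "sb", "lpa", "mvpa"])
        emit("ternary_curves.csv", curves)

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        manifest = {
            "package": "codawork",
            "version": codawork.__version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "config": json.loads(config.canonical_json()),
            "n_workers_analysis": int(len(analysis)),
            "n_workers_complete_case": int(len(complete)),
            "n_teams": int(analysis["team_id"].nunique()),
            "n_institutions": int(analysis["institution_id"].nunique()),
            "attrition": {**plog, "missing_per_determinant": dropped},
            "variance_contributions_pct": {k: round(v, 3) for k, v in vd.contributions.items()},
            "significant_determinants": significant,
            "outputs": [p.name for p in written],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(out / "manifest.json")
        _write_text_summary(out, manifest, vd, m1, pivots)
        return manifest
    except PipelineConfigError:
        raise
    except Exception as exc:  # remove partial bundle, then surface the stage
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc


def _write_text_summary(out: Path, manifest, vd, m1, pivots) -> None:
    lines = [
        f"codawork {manifest['version']}  (seed {manifest['seed']}, config {manifest['config_hash']})",
        "",
        f"Workers analysed: {manifest['n_workers_analysis']} "
        f"({manifest['n_workers_complete_case']} complete-case) in "
        f"{manifest['n_teams']} teams / {manifest['n_institutions']} institutions",
        "",
        "Variance contributions to physical-behaviour composition (ilr scale):",
    ]
    for lvl in ("worker", "team", "institution"):
        lines.append(f"  {lvl:<12} {vd.estimates[lvl]:.4f}  ({vd.contributions[lvl]:.1f}%)")
    lines.append("")
    sig = manifest["significant_determinants"]
    lines.append(
        "Determinants jointly associated with the composition (p < 0.05): "
        + (", ".join(sig) if sig else "none")
    )
    for det in sig:
        for part, fit in pivots.items():
            row = fit.table.loc[det]
            lines.append(
                f"  {det}: {row['percent_change']:+.1f}% {part.upper()} per unit (p={row['p']:.3f})"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
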