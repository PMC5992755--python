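"""End-to-end pipeline: curate -> deconvolve -> (validate) -> associate.

Given file paths for the reference panel, marker list, bulk matrix, and
metadata, the pipeline curates the panel, estimates proportions, optionally
runs a scaled chimeric validation, and fits the configured association
contrasts.  Every run writes a manifest (package version, seed, a hash of
the configuration, and SHA-256 checksums of all inputs and outputs) so that
identical configuration and inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .containers import MarkerPanel, ReferencePanel
from .deconv import deconvolve
from .exceptions import ConfigurationError
from .io import (
    read_expression,
    read_markers,
    read_metadata,
    write_proportions,
)
from .panel import loocv_curate
from .validate import build_chimeric_design, run_chimeric_validation
from .assoc import adjust_pvalues, fit_association

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    panel_expression: str
    panel_labels: str  # CSV with sample_id, cell_type
    markers: str
    bulk: str
    metadata: str
    output_dir: str
    engine: str = "ssnmf"
    curation_threshold: float = 0.80
    curation_max_rounds: int = 10
    run_validation: bool = False
    validation_distributions: int = 8
    validation_repeats: int = 3
    contrasts: Sequence[str] = ("status",)
    covariates: Sequence[str] = ()
    seed: int = 42
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if not 0 < self.curation_threshold < 1:
            raise ConfigurationError(
                f"curation_threshold must be in (0, 1), got {self.curation_threshold}"
            )
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")
        for name in ("panel_expression", "panel_labels", "markers", "bulk", "metadata"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise ConfigurationError(f"{name} path does not exist: {path}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure propagates with the stage recorded in the log, leaving
    partial outputs in place.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    logging.getLogger().addHandler(handler)

    inputs = {
        name: str(getattr(config, name))
        for name in ("panel_expression", "panel_labels", "markers", "bulk", "metadata")
    }
    manifest = {
        "package": "cortexmix",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in inputs.items()},
        "outputs": {},
    }

    stage = "load"
    try:
        markers = read_markers(config.markers)
        panel_expr = read_expression(config.panel_expression)
        labels = pd.read_csv(config.panel_labels)
        label_map = dict(zip(labels["sample_id"], labels["cell_type"]))
        panel = ReferencePanel(expression=panel_expr, labels=label_map)
        bulk = read_expression(config.bulk)
        metadata = read_metadata(config.metadata)

        stage = "curate"
        curated, report = loocv_curate(
            panel,
            markers,
            engine=config.engine,
            threshold=config.curation_threshold,
            max_rounds=config.curation_max_rounds,
        )
        report.rounds.to_csv(out / "curation_report.csv", index=False)
        logger.info(
            "curation kept %d/%d samples in %d round(s)",
            len(curated.sample_ids), len(panel.sample_ids), report.rounds_run,
        )

        stage = "deconvolve"
        result = deconvolve(bulk, curated, markers, engine=config.engine)
        write_proportions(result.proportions, out / "proportions.tsv")
        with open(out / "deconvolution.json", "w") as fh:
            json.dump(
                {
                    "engine": result.engine,
                    "iterations": result.iterations,
                    "converged": result.converged,
                    "final_objective": result.objective_trace[-1] if result.objective_trace else None,
                },
                fh,
                indent=2,
            )

        if config.run_validation:
            stage = "validate"
            design = build_chimeric_design(
                n_distributions=config.validation_distributions,
                repeats=config.validation_repeats,
                seed=config.seed,
            )
            evaluation = run_chimeric_validation(
                curated, markers, design, engine=config.engine, seed=config.seed
            )
            evaluation.per_task.to_csv(out / "validation_per_task.csv")
            with open(out / "validation.json", "w") as fh:
                json.dump({"pooled_rmse": evaluation.rmse, "n_tasks": len(evaluation.per_task)}, fh, indent=2)
            logger.info("chimeric validation pooled RMSE %.4f", evaluation.rmse)

        stage = "associate"
        results = []
        for predictor in config.contrasts:
            for cell_type in result.proportions.columns:
                results.append(
                    fit_association(
                        result.proportions,
                        metadata,
                        cell_type,
                        predictor,
                        covariates=config.covariates,
                    )
                )
        table = adjust_pvalues(results)
        table.to_csv(out / "associations.csv", index=False)
    except Exception:
        logger.exception("pipeline failed in stage %r; partial outputs kept in %s", stage, out)
        logging.getLogger().removeHandler(handler)
        handler.close()
        raise

    for produced in sorted(out.iterdir()):
        if produced.name not in ("manifest.json", "run.log"):
            manifest["outputs"][produced.name] = _sha256(produced)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logging.getLogger().removeHandler(handler)
    handler.close()
    return out
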