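"""Config-driven end-to-end analysis pipeline.

Stages mirror the analysis workflow: obtain records (read a survey CSV or
simulate one) -> score -> aggregate per category -> rates and AWAG
segmentation -> optional regression battery -> write a report bundle
(rates JSON/CSV, matrix figure data, regression table, reproducibility
manifest).  All outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .awag import build_matrix_figure, compute_rates, aggregate_category
from .regression import battery_to_frame, run_table4_battery
from .survey_io import (
    OVERALL,
    Category,
    ServiceCatalog,
    default_catalog,
    read_survey_csv,
    write_survey_csv,
)
from .synthetic import GeneratorConfig, generate_survey

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "category_rate_table"]

log = logging.getLogger("awagkit")

CATEGORY_ORDER = (
    OVERALL,
    Category.INFORMATION_BASED.value,
    Category.TREATMENT_INTERMEDIARY.value,
    Category.TREATMENT.value,
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Exactly one of ``input_path`` / ``simulate`` must be set."""

    output_dir: str | Path = "awag_output"
    input_path: str | Path | None = None
    simulate: GeneratorConfig | None = None
    reference_income: float | None = None
    run_regression: bool = True
    render_figure: bool = False
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be given")
        if self.simulate is not None and self.seed is not None:
            self.simulate.seed = self.seed

    def to_dict(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "input_path": None if self.input_path is None else str(self.input_path),
            "simulate": None
            if self.simulate is None
            else _jsonable(dataclasses.asdict(self.simulate)),
            "reference_income": self.reference_income,
            "run_regression": self.run_regression,
            "render_figure": self.render_figure,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def category_rate_table(records, catalog: ServiceCatalog):
    """CategoryRates for overall + each catalog category, in report order."""
    rates = []
    for cat in CATEGORY_ORDER:
        if cat != OVERALL and cat not in [c.value for c in catalog.categories()]:
            continue
        awa = aggregate_category(records, catalog, cat)
        rates.append(compute_rates(awa, cat))
    return rates


def run_pipeline(config: PipelineConfig, catalog: ServiceCatalog | None = None) -> dict:
    """Run all stages and write the report bundle; returns a manifest dict
    with output paths and headline numbers."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    catalog = catalog or default_catalog()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: acquire records
    ground_truth = None
    if config.simulate is not None:
        log.info("simulating %d respondents (seed=%s)", config.simulate.n,
                 config.simulate.seed)
        try:
            records, ground_truth = generate_survey(config.simulate, catalog)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        write_survey_csv(records, outdir / "survey.csv", catalog)
        _dump_json(ground_truth, outdir / "ground_truth.json")
    else:
        try:
            records, diagnostics = read_survey_csv(config.input_path, catalog)
        except Exception as exc:
            raise PipelineError("read", str(exc)) from exc
        if diagnostics:
            log.warning("%d rows rejected during read", len(diagnostics))
            _dump_json(
                [{"row": i, "reason": m} for i, m in diagnostics],
                outdir / "rejected_rows.json",
            )
    if not records:
        raise PipelineError("read", "no valid respondent records")

    # ---- stage: rates + segmentation
    try:
        rates = category_rate_table(records, catalog)
    except Exception as exc:
        raise PipelineError("rates", str(exc)) from exc
    rate_rows = [r.rounded() for r in rates]
    _dump_json(rate_rows, outdir / "rates.json")
    pd.DataFrame(rate_rows).to_csv(outdir / "rates.csv", index=False)

    fig_data = build_matrix_figure(rates)
    (outdir / "matrix_figure.json").write_text(fig_data.to_json() + "\n")
    if config.render_figure:
        from .awag import render_matrix_figure

        render_matrix_figure(fig_data, str(outdir / "matrix_figure.png"))

    # ---- stage: regression battery
    regression_summary = None
    if config.run_regression:
        try:
            battery = run_table4_battery(
                records, catalog, reference_income=config.reference_income
            )
        except Exception as exc:
            raise PipelineError("regression", str(exc)) from exc
        table = battery_to_frame(battery)
        table.to_csv(outdir / "regression.csv", index=False)
        _dump_json(
            [
                {
                    "outcome": r.outcome,
                    "category": r.category,
                    "n_used": r.n_used,
                    "n_clusters": r.n_clusters,
                    "converged": r.converged,
                    "error": r.error,
                    "terms": list(r.terms),
                }
                for r in battery
            ],
            outdir / "regression.json",
        )
        regression_summary = {
            "n_models": len(battery),
            "n_converged": sum(r.converged for r in battery),
        }

    # ---- stage: manifest
    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "awagkit_version": __version__,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "seed": config.seed if config.seed is not None else (
            config.simulate.seed if config.simulate else None
        ),
        "n_records": len(records),
        "rates": {r["category"]: r for r in rate_rows},
        "regression": regression_summary,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
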