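"""End-to-end pipeline: simulate → trends → fit → explain → index → export.

A :class:`PipelineConfig` (YAML-serialisable) fixes every seed and
setting; :func:`run_pipeline` executes the stages, writes each artifact
as deterministic CSV/JSON, and returns a manifest mapping artifact names
to SHA-256 content hashes — identical config and seeds give identical
hashes, which is the reproducibility contract for the whole analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import attribution, prediction, simulate, svi, trends
from .panel import RATE_BINS, SVI_BINS, CountyPanel, export_choropleth, read_panel, write_panel

log = logging.getLogger("countysvi")


class PipelineConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    seed: int = 0
    panel_path: str | None = None  # read an existing panel CSV …
    simulate_enabled: bool = True  # … or generate one
    artifacts_dir: str = "artifacts"
    n_counties: int = 3140
    years: tuple[int, ...] = tuple(range(2010, 2020))
    sigma_eps: float = 0.05
    trend: float = 0.0
    base_rate: float = 15.0
    beta: dict[str, float] | None = None
    target: str = "count"
    grid: dict[str, tuple] | None = None
    cv_folds: int = 10
    test_fraction: float = 0.2
    background_size: int = 100
    svi_p: int = 5
    svi_weights: dict[str, float] | None = None
    trend_thresholds: tuple[float, ...] = (10.0, 50.0)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.simulate_enabled and not self.panel_path:
            raise PipelineConfigError("no input: set panel_path or enable simulation")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        d["trend_thresholds"] = list(self.trend_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        if "trend_thresholds" in d:
            d["trend_thresholds"] = tuple(d["trend_thresholds"])
        if d.get("grid"):
            d["grid"] = {k: tuple(v) for k, v in d["grid"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    manifest: dict[str, str]  # artifact name -> sha256
    panel: CountyPanel
    model: prediction.GradientBoostedCountyModel
    report: attribution.ImportanceReport
    svi_table: svi.SviTable
    trend: trends.TrendSummary


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                record = {"stage": name, "error": type(exc).__name__, "message": str(exc)}
                log.error("stage failed: %s", json.dumps(record))
                raise

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the artifact manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.artifacts_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    @_stage("input")
    def _input() -> CountyPanel:
        if config.panel_path:
            return read_panel(config.panel_path)
        cfg = simulate.SyntheticConfig(
            n_counties=config.n_counties,
            years=config.years,
            seed=config.seed,
            beta=config.beta,
            base_rate=config.base_rate,
            sigma_eps=config.sigma_eps,
            trend=config.trend,
        )
        panel, truth = simulate.generate_panel(cfg)
        write_panel(panel, out / "panel.csv")
        simulate.write_truth(truth, out / "planted_truth.json")
        return panel

    panel = _input()

    @_stage("trends")
    def _trends() -> trends.TrendSummary:
        summary = trends.trend_summary(panel, thresholds=config.trend_thresholds)
        summary.to_frame().to_csv(out / "trend_summary.csv", index=False, float_format="%.10g")
        rates = trends.average_rates(panel)
        export_choropleth(rates, bins=RATE_BINS).to_csv(out / "rate_choropleth.csv")
        return summary

    tsum = _trends()

    @_stage("fit")
    def _fit():
        spec = prediction.ModelSpec(
            target=config.target,
            grid=config.grid or dict(prediction.DEFAULT_GRID),
            cv_folds=config.cv_folds,
            test_fraction=config.test_fraction,
            split_seed=config.seed,
        )
        design = prediction.make_design(panel, spec)
        model = prediction.fit(design, spec)
        log.info(
            "chosen hyperparameters: %s (cv R²=%.4f, test R²=%.4f)",
            model.best_params_,
            model.r2_cv_,
            model.r2_test_,
        )
        (out / "model.json").write_text(
            json.dumps(
                {
                    "best_params": model.best_params_,
                    "r2_train": model.r2_train_,
                    "r2_cv": model.r2_cv_,
                    "r2_test": model.r2_test_,
                    "test_fips": model.test_fips_,
                    "target": spec.target,
                },
                indent=1,
                sort_keys=True,
            )
        )
        return design, model

    design, model = _fit()

    @_stage("attribute")
    def _attribute():
        att = attribution.explain(
            model, design, background_size=config.background_size, seed=config.seed
        )
        report = attribution.importance(att, design)
        report.to_frame().to_csv(out / "importance.csv", index=False, float_format="%.10g")
        return att, report

    att, report = _attribute()

    @_stage("svi")
    def _svi() -> svi.SviTable:
        index = svi.VulnerabilityIndex(p=config.svi_p, weights=config.svi_weights)
        table = index.fit(report).transform(design)
        table.to_csv(out / "svi_table.csv")
        export_choropleth(
            dict(table.table["svi"]), bins=SVI_BINS
        ).to_csv(out / "svi_choropleth.csv")
        return table

    svi_table = _svi()

    for artifact in sorted(out.iterdir()):
        if artifact.is_file() and artifact.name != "manifest.json":
            manifest[artifact.name] = _sha256(artifact)
    manifest_payload = {"artifacts": manifest, "config": config.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest_payload, indent=1, sort_keys=True))

    return PipelineResult(
        manifest=manifest,
        panel=panel,
        model=model,
        report=report,
        svi_table=svi_table,
        trend=tsum,
    )
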