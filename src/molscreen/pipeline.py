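"""Pipeline configuration and the high-level stage functions the CLI wraps.

A single YAML file configures all stages (generation, training, screening,
validation); every stage writes a provenance record — the full effective
config, seeds, and package version — next to its outputs so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ensemble import EnsembleScreener, ScreeningConfig, write_screen_outputs
from .evaluation import balanced_resampling_validation, evaluate_model_on_test
from .model import AffinityModel, AffinityResults, ModelConfig, SplitConfig, split_dataset
from .records import LabeledDataset
from .chem_io import read_molecule_table
from .synthetic import SyntheticSpec, generate_study, write_study

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass
class PipelineConfig:
    """Everything one study run needs; defaults mirror the reference design
    (1000 balanced repetitions; thresholds 0.5-0.95; 70/10/20 split;
    1024/1024/512 head trained 100 epochs at lr 0.001, batch 128)."""

    workdir: str = "molscreen_run"
    seed: int = 0
    scale: float = 1.0
    n_reps: int = 1000
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    model: ModelConfig = field(default_factory=ModelConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    def __post_init__(self):
        self.thresholds = tuple(float(t) for t in self.thresholds)
        # one global seed cascades into stage seeds unless overridden
        if self.model.seed == 0:
            self.model.seed = self.seed
        if self.split.seed == 0:
            self.split.seed = self.seed
        if self.synthetic.seed == 0:
            self.synthetic.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        for key, klass in (
            ("model", ModelConfig), ("split", SplitConfig),
            ("screening", ScreeningConfig), ("synthetic", SyntheticSpec),
        ):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = klass(**kw[key])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    def effective_spec(self) -> SyntheticSpec:
        return self.synthetic if self.scale == 1.0 else self.synthetic.scaled(self.scale)

    def write_provenance(self, outdir: Path, stage: str) -> None:
        record = {"stage": stage, "version": __version__, "config": self.to_dict()}
        (outdir / f"provenance_{stage}.json").write_text(
            json.dumps(record, indent=1, default=str)
        )


def _workdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.workdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def run_generate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate the synthetic study populations and write them as CSVs."""
    out = _workdir(cfg)
    study = generate_study(cfg.effective_spec())
    paths = write_study(study, out / "data")
    cfg.write_provenance(out, "generate")
    for t, ds in study.training.items():
        logger.info("training set %s: %d molecules", t, len(ds))
    logger.info("screen library: %d molecules", len(study.screen))
    return paths


def _load_training(cfg: PipelineConfig) -> dict[str, LabeledDataset]:
    data = _workdir(cfg) / "data"
    out = {}
    for t in cfg.effective_spec().targets:
        path = data / f"train_{t}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing training table: {path} (run `generate` first)")
        records, _ = read_molecule_table(path)
        out[t] = LabeledDataset(records=records, target=t)
    return out


def run_train(cfg: PipelineConfig, verbose: bool = False) -> pd.DataFrame:
    """Fit one model per target; write model archives and the test-metric
    report (one row per target: AUROC, AUPRC, F1)."""
    out = _workdir(cfg)
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    datasets = _load_training(cfg)
    rows = []
    for t, ds in datasets.items():
        train, valid, test = split_dataset(ds, cfg.split)
        results = AffinityModel(train, valid, cfg.model).fit(verbose=verbose)
        results.save(models_dir / f"{t}.molscreen.zip")
        panel = evaluate_model_on_test(results, test, threshold=cfg.screening.threshold)
        rows.append({"target": t, "AUROC": panel.auroc, "AUPRC": panel.auprc,
                     "F1": panel.f1})
        (out / f"loss_{t}.csv").write_text(results.training_history.to_csv(index=False))
    report = pd.DataFrame(rows)
    report.to_csv(out / "test_metrics.csv", index=False)
    cfg.write_provenance(out, "train")
    return report


def _load_models(cfg: PipelineConfig) -> dict[str, AffinityResults]:
    models_dir = _workdir(cfg) / "models"
    out = {}
    for t in cfg.effective_spec().targets:
        path = models_dir / f"{t}.molscreen.zip"
        if not path.exists():
            raise FileNotFoundError(f"missing model archive: {path} (run `train` first)")
        out[t] = AffinityResults.load(path)
    return out


def _load_screen(cfg: PipelineConfig):
    path = _workdir(cfg) / "data" / "screen.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing screen table: {path} (run `generate` first)")
    records, _ = read_molecule_table(path)
    return records


def run_screen(cfg: PipelineConfig) -> pd.DataFrame:
    """Rank the screening library by ensemble score; write CSV + summary."""
    out = _workdir(cfg)
    screener = EnsembleScreener(_load_models(cfg))
    table, rejects = screener.screen(_load_screen(cfg), cfg.screening)
    write_screen_outputs(table, list(cfg.thresholds), out / "screen_ranked.csv",
                         out / "screen_summary.json")
    if rejects:
        pd.DataFrame({"id": [r.id for r in rejects],
                      "smiles": [r.smiles for r in rejects]}
                     ).to_csv(out / "screen_rejects.csv", index=False)
    n_pos_pred = int(table["prediction"].sum()) if not table.empty else 0
    logger.info("screened %d molecules, %d at or above threshold %.2f",
                len(table), n_pos_pred, cfg.screening.threshold)
    cfg.write_provenance(out, "screen")
    return table


def run_validate(cfg: PipelineConfig) -> pd.DataFrame:
    """Balanced-resampling external validation; writes the threshold-sweep
    report (both aggregation variants) and the convergence trace."""
    out = _workdir(cfg)
    screener = EnsembleScreener(_load_models(cfg))
    table, _ = screener.screen(_load_screen(cfg), cfg.screening)
    if "label" not in table.columns:
        raise ValueError("screen table carries no ground-truth labels; cannot validate")
    report = balanced_resampling_validation(
        table, thresholds=list(cfg.thresholds), n_reps=cfg.n_reps, seed=cfg.seed,
    )
    frame = report.to_frame(aggregation="counts")
    frame.to_csv(out / "validation_counts_metrics.csv", index=False)
    report.to_frame(aggregation="metrics").to_csv(
        out / "validation_mean_metrics.csv", index=False)
    report.to_json(out / "validation_trace.json")
    cfg.write_provenance(out, "validate")
    return frame


def run_report(cfg: PipelineConfig) -> str:
    """Collect stage outputs into one human-readable text summary."""
    out = _workdir(cfg)
    parts = []
    for name, path in (("Per-target test metrics", out / "test_metrics.csv"),
                       ("Validation (metrics of averaged counts)",
                        out / "validation_counts_metrics.csv")):
        if path.exists():
            parts.append(f"== {name} ==\n{pd.read_csv(path).to_string(index=False)}")
    summary_path = out / "screen_summary.json"
    if summary_path.exists():
        parts.append(f"== Screen summary ==\n{summary_path.read_text()}")
    text = "\n\n".join(parts) if parts else "no stage outputs found; run the pipeline first"
    (out / "report.txt").write_text(text + "\n")
    return text
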