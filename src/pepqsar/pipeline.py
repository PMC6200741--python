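"""End-to-end pipeline: data -> descriptors -> selection -> nested CV ->
model comparison -> coefficient importance, with every stage artifact
written as CSV into a run directory.

A run is fully determined by its configuration and master seed: rerunning
with the same config produces byte-identical result CSVs. The effective
configuration is serialized verbatim into the output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import descriptors as desc
from . import feature_selection as fs
from . import importance as imp
from . import io as pio
from . import model_eval as me
from . import stats_compare as sc
from . import synthetic as syn

logger = logging.getLogger("pepqsar.pipeline")


class ConfigError(ValueError):
    """Invalid pipeline configuration (detected before any computation)."""


@dataclass
class DatasetConfig:
    """One descriptor/selection configuration to benchmark."""

    label: str
    sets: tuple[str, ...] = ("aac", "dc", "tc")
    fs_k: int | None = 200


@dataclass
class PipelineConfig:
    # input: FASTA + labels, or the synthetic generator when fasta is None
    input_fasta: str | None = None
    input_labels: str | None = None
    synthetic_seed: int = 0
    dataset_configs: list[DatasetConfig] = field(
        default_factory=lambda: [DatasetConfig("AAC_DC_TC_200")]
    )
    pseaac_lambda: int = 3
    pseaac_w: float = 0.05
    learners: tuple[str, ...] = me.FAMILIES
    fast: bool = False
    outer_repeats: int = 5
    outer_folds: int = 10
    seed: int = 0
    fs_mode: str = "fold"
    standardize_mode: str = "fold"
    outdir: str = "pepqsar_run"

    def validate(self) -> None:
        unknown = set(self.learners) - set(me.FAMILIES)
        if unknown:
            raise ConfigError(f"unknown learner families {sorted(unknown)}")
        for dc in self.dataset_configs:
            bad = set(dc.sets) - set(desc.DESCRIPTOR_SETS)
            if bad:
                raise ConfigError(f"dataset {dc.label!r}: unknown descriptor sets {sorted(bad)}")
            if dc.fs_k is not None and dc.fs_k < 1:
                raise ConfigError(f"dataset {dc.label!r}: fs_k must be >= 1")
        if self.fs_mode not in ("fold", "global"):
            raise ConfigError(f"unknown fs_mode {self.fs_mode!r}")
        if self.standardize_mode not in ("fold", "global", "none"):
            raise ConfigError(f"unknown standardize_mode {self.standardize_mode!r}")
        if self.outer_folds < 2 or self.outer_repeats < 1:
            raise ConfigError("need outer_folds >= 2 and outer_repeats >= 1")

    def to_yaml(self, path: Path) -> None:
        d = asdict(self)
        d["dataset_configs"] = [asdict(dc) for dc in self.dataset_configs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["dataset_configs"] = [DatasetConfig(**dc) for dc in d.get("dataset_configs", [])]
        for key in ("learners", "dataset_configs"):
            if key in d and isinstance(d[key], list) and key == "learners":
                d[key] = tuple(d[key])
        if isinstance(d.get("learners"), list):
            d["learners"] = tuple(d["learners"])
        for dc in d["dataset_configs"]:
            dc.sets = tuple(dc.sets)
        return cls(**d)


def _load_or_generate(config: PipelineConfig) -> pio.LabeledDataset:
    if config.input_fasta is not None:
        records = pio.read_fasta(config.input_fasta)
        if config.input_labels is not None:
            labels = pio.read_labels(config.input_labels)
        else:
            labels = pio.labels_from_headers(records)
        dataset = pio.LabeledDataset(records=records, labels=labels)
        dataset, rejected = pio.filter_valid(dataset)
        for pid, reason in rejected:
            logger.warning("dropped record %s: %s", pid, reason)
        return dataset
    gen = syn.paper_like_config(seed=config.synthetic_seed)
    return syn.generate_dataset(gen)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the run-artifact directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log_lines: list[str] = []

    def stage(name: str):
        logger.info("stage: %s", name)
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} stage {name}")

    stage("load/generate")
    dataset = _load_or_generate(config)
    pio.write_fasta(dataset.records, outdir / "dataset.fasta")
    pio.write_labels(dataset.labels, outdir / "labels.csv")
    labels = dataset.label_vector()

    learner_factory = me.make_fast_learners if config.fast else me.make_default_learners
    cv = me.NestedCVConfig(
        outer_folds=config.outer_folds,
        outer_repeats=config.outer_repeats,
        seed=config.seed,
    )

    tables: list[me.ResultTable] = []
    glmnet_artifacts: dict[str, tuple[desc.DescriptorMatrix, desc.DescriptorMatrix]] = {}
    for dcfg in config.dataset_configs:
        stage(f"featurize:{dcfg.label}")
        matrix = desc.featurize_dataset(
            dataset, sets=dcfg.sets,
            pseaac_lambda=config.pseaac_lambda, pseaac_w=config.pseaac_w,
        )
        matrix = desc.remove_zero_features(matrix)

        stage(f"rank:{dcfg.label}")
        ranking = fs.rank_features_ttest(matrix, labels)
        ranking.to_csv(outdir / f"ranking_{dcfg.label}.csv")
        if dcfg.fs_k is not None:
            selected = fs.select_top_k(ranking, matrix, dcfg.fs_k)
            glmnet_artifacts[dcfg.label] = (matrix, selected)

        stage(f"evaluate:{dcfg.label}")
        table = me.run_nested_cv(
            matrix,
            labels,
            learner_factory(matrix.p, families=tuple(config.learners)),
            cv,
            fs_k=dcfg.fs_k,
            fs_mode=config.fs_mode,
            standardize_mode=config.standardize_mode,
            dataset_label=dcfg.label,
        )
        tables.append(table)

    stage("aggregate")
    import pandas as pd

    all_results = pd.concat([t.results for t in tables], ignore_index=True)
    all_results.to_csv(outdir / "results.csv", index=False)
    all_coefs = pd.concat([t.coefficients for t in tables], ignore_index=True)
    all_coefs.to_csv(outdir / "coefficients.csv", index=False)
    summary = pd.concat([me.aggregate(t) for t in tables], ignore_index=True)
    summary.to_csv(outdir / "summary.csv", index=False)

    stage("compare")
    blocks = me.performance_blocks(tables, metric="auc", blocks="repeat")
    report = None
    if blocks.shape[1] >= 2 and blocks.shape[0] >= 2:
        pbm = sc.PerformanceBlockMatrix.from_frame(blocks)
        try:
            report = sc.run_cascade(pbm)
            report.posthoc.to_csv(outdir / "comparison.csv", index=False)
            (outdir / "comparison.txt").write_text(report.summary() + "\n")
        except ValueError as exc:
            logger.warning("comparison skipped: %s", exc)
            log_lines.append(f"comparison skipped: {exc}")

    stage("importance")
    if "GLMNET" in config.learners and not all_coefs.empty:
        table = imp.aggregate_betas(all_coefs)
        table.to_csv(outdir / "importance.csv")
        k = min(40, len(table.entries))
        imp.top_k_report(table, k).to_csv(outdir / "top40.csv", index=False)
        for label, (before, after) in glmnet_artifacts.items():
            imp.descriptor_composition(before, after).to_csv(
                outdir / f"composition_{label}.csv", index=False
            )

    manifest = sorted(p.name for p in outdir.iterdir() if p.name != "run.log")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
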