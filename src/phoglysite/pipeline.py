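"""End-to-end orchestration: simulate/load -> featurize -> clean -> train ->
cross-validate, with stage artifacts, count bookkeeping and one global seed.

The global seed fans out to per-stage seeds by fixed offsets (simulation:
``seed``; fold assignment: ``seed + 1000``) so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evaluation, features, imbalance, model, synthetic
from .io_formats import FeatureTable, write_features

CV_SEED_OFFSET = 1000


@dataclass
class PipelineConfig:
    input_dir: str | Path | None = None
    simulation: synthetic.SimulationConfig | None = None
    f_struct: int = 3
    f_pssm: int = 20
    mirror: str = "exclusive"
    clean: bool = True
    clean_within_folds: bool = False
    target_ratio: float = 2.05
    k0: int | None = None
    k_step: int = 1
    k_max: int | None = None
    standardize_cleaning: bool = True
    requery: str = "original"
    classifier: model.ClassifierConfig = field(
        default_factory=model.ClassifierConfig
    )
    n_folds: int = 10
    stratified: bool = True
    aggregate: str = "mean"
    seed: int = 0


@dataclass
class PipelineResult:
    metrics: evaluation.MetricsReport
    cleaning: imbalance.CleaningReport | None
    features: FeatureTable
    cleaned_features: FeatureTable
    run_log: dict


def load_dataset(config: PipelineConfig) -> synthetic.SyntheticDataset:
    if config.simulation is not None:
        return synthetic.simulate_dataset(config.simulation)
    if config.input_dir is None:
        raise ValueError("config needs either input_dir or simulation")
    return synthetic.read_fixture_tree(config.input_dir)


def run_end_to_end(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run every stage, logging sample counts; optionally write artifacts
    (features CSV, cleaning JSON, model file, metrics JSON, run log)."""
    log: dict = {"stages": []}

    def stage(name: str, **info) -> None:
        log["stages"].append({"stage": name, **info})

    dataset = load_dataset(config)
    n_pos = sum(s.label for s in dataset.sites)
    stage(
        "data",
        n_proteins=len(dataset.proteins),
        n_sites=len(dataset.sites),
        n_pos=n_pos,
        n_neg=len(dataset.sites) - n_pos,
    )

    table = features.featurize_dataset(
        dataset.sites,
        dataset.pssms,
        dataset.structs,
        f_struct=config.f_struct,
        f_pssm=config.f_pssm,
        mirror=config.mirror,
    )
    stage(
        "featurize",
        n_sites=len(table),
        n_pos=table.n_pos,
        n_neg=table.n_neg,
        feature_dimension=table.n_features,
    )

    cleaning_report = None
    cleaned = table

    def _clean(t: FeatureTable) -> tuple[FeatureTable, imbalance.CleaningReport]:
        return imbalance.escalate_k(
            t,
            target_ratio=config.target_ratio,
            k0=config.k0,
            k_step=config.k_step,
            k_max=config.k_max,
            standardize=config.standardize_cleaning,
            requery=config.requery,
        )

    if config.clean and not config.clean_within_folds:
        cleaned, cleaning_report = _clean(table)
        stage(
            "clean",
            k_initial=cleaning_report.k_initial,
            k_final=cleaning_report.k_final,
            n_pos=cleaned.n_pos,
            n_neg=cleaned.n_neg,
            ratio=cleaning_report.ratio_after,
        )

    train_transform = None
    if config.clean and config.clean_within_folds:
        train_transform = lambda t: _clean(t)[0]  # noqa: E731

    metrics_report = evaluation.cross_validate(
        cleaned,
        config=config.classifier,
        n_folds=config.n_folds,
        seed=config.seed + CV_SEED_OFFSET,
        stratified=config.stratified,
        aggregate=config.aggregate,
        train_transform=train_transform,
    )
    stage("cross_validate", n_folds=config.n_folds)

    final_model = model.train(cleaned, config=config.classifier)
    stage("train_final", n_train=len(cleaned))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_features(table, outdir / "features.csv")
        if cleaning_report is not None:
            cleaning_report.to_json(outdir / "cleaning.json")
        metrics_report.to_json(outdir / "metrics.json")
        final_model.save(outdir / "model.joblib")
        (outdir / "run_log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True) + "\n"
        )
    return PipelineResult(
        metrics=metrics_report,
        cleaning=cleaning_report,
        features=table,
        cleaned_features=cleaned,
        run_log=log,
    )


def window_sweep(
    config: PipelineConfig,
    flanks_struct: list[int],
    flanks_pssm: list[int],
) -> pd.DataFrame:
    """Grid evaluation over window flanks with shared folds and seed.

    Returns one row per (f_struct, f_pssm) with the aggregate metrics.
    """
    dataset = load_dataset(config)
    rows = []
    for fs in flanks_struct:
        for fp in flanks_pssm:
            table = features.featurize_dataset(
                dataset.sites,
                dataset.pssms,
                dataset.structs,
                f_struct=fs,
                f_pssm=fp,
                mirror=config.mirror,
            )
            if config.clean:
                table, _ = imbalance.escalate_k(
                    table,
                    target_ratio=config.target_ratio,
                    k0=config.k0,
                    k_step=config.k_step,
                    k_max=config.k_max,
                    standardize=config.standardize_cleaning,
                    requery=config.requery,
                )
            rep = evaluation.cross_validate(
                table,
                config=config.classifier,
                n_folds=config.n_folds,
                seed=config.seed + CV_SEED_OFFSET,
                stratified=config.stratified,
                aggregate=config.aggregate,
            )
            rows.append(
                {
                    "f_struct": fs,
                    "f_pssm": fp,
                    "feature_dimension": table.n_features,
                    **{m: getattr(rep, m) for m in evaluation.METRIC_NAMES},
                }
            )
    return pd.DataFrame(rows)
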