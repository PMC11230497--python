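"""End-to-end workflow: simulate -> omega -> graphs -> train -> statistics.

Every random stage draws from an explicit seed recorded in the output
manifest, so any artifact is reproducible from (inputs, config, seeds).
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

from . import evaluation, exposome, graphs, importance, io, quality, synthetic
from .gcn import TrainingPlan, predict_batch, train_with_grid_search
from .hoi import normalize_omega, omega_matrix

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str | None = None
    output_dir: str = "braingap_out"
    modality: str = "fMRI"
    simulate: bool = True
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    train_fraction: float = 0.8
    n_age_bins: int = 5
    n_augment: int = 500
    plan: TrainingPlan = field(default_factory=TrainingPlan)
    n_permutation_iterations: int = 5000
    n_importance_bootstrap: int = 5000
    run_importance: bool = True
    run_exposome: bool = False
    run_quality: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    """Either simulate a cohort or read fixtures from the input directory."""
    if config.simulate:
        records = synthetic.generate_cohort_table(config.cohort)
        series = [
            synthetic.simulate_subject_timeseries(
                rec, config.cohort, seed=config.cohort.seed + 1000 + k
            )
            for k, rec in enumerate(records)
        ]
        return records, series
    if config.input_dir is None:
        raise FileNotFoundError("input_dir required when simulate is false")
    in_dir = Path(config.input_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {in_dir}")
    cohort_df = io.read_cohort_table(in_dir / "cohort.tsv")
    records, series = [], []
    for row in cohort_df.to_dict("records"):
        rec = synthetic.CohortRecord(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            sex=str(row.get("sex", "F")),
            diagnosis=str(row["diagnosis"]),
            region=str(row.get("region", "nonLAC")),
            country=str(row.get("country", "")),
            scanner=str(row.get("scanner", "scanner0")),
            eyes=str(row.get("eyes", "open")),
            education=float(row.get("education", 12.0)),
            modality=str(row.get("modality", config.modality)),
        )
        path = in_dir / f"{rec.subject_id}_timeseries.tsv"
        series.append(io.read_timeseries_matrix(path, modality=rec.modality))
        records.append(rec)
    return records, series


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write artifacts; returns the in-memory report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True, default=str)
    )
    report: dict = {"config_hash": config.config_hash()}

    records, series = _load_inputs(config)
    logger.info("stage simulate/load: %d subjects", len(records))

    graph_list = []
    for rec, ts in zip(records, series):
        m = normalize_omega(omega_matrix(ts))
        graph_list.append(graphs.build_graph(m, rec))
    graph_list = graphs.filter_invalid(graph_list)
    logger.info("stage omega/graphs: %d graphs after filtering", len(graph_list))

    split = graphs.stratified_split(
        graph_list, config.train_fraction, config.n_age_bins, seed=config.seed
    )
    augmented = graphs.augment_by_interpolation(
        split.train, n_new=config.n_augment, seed=config.seed + 1
    )
    split.train = split.train + augmented
    logger.info(
        "stage split/augment: %d train (+%d augmented) / %d test",
        len(split.train) - len(augmented), len(augmented), len(split.test),
    )

    model = train_with_grid_search(split, config.plan)
    logger.info("stage train: best %s", model.best_hyperparams)

    preds = predict_batch(split.test, model)
    preds = evaluation.compute_bag(preds)
    meta = pd.DataFrame([vars(g.subject_ref) for g in split.test if g.subject_ref])
    preds = preds.merge(
        meta[["subject_id", "diagnosis", "sex", "region", "scanner", "eyes", "education"]],
        on="subject_id", how="left",
    )

    metrics = evaluation.compute_fit_metrics(preds["y"].to_numpy(), preds["y_hat"].to_numpy())
    report["metrics"] = metrics
    report["predictions"] = preds
    report["cv_table"] = model.cv_table
    report["model"] = model

    # group BAG comparisons (each group vs HC)
    stats_rows = []
    hc = preds.loc[preds["diagnosis"] == "HC", "bag"].to_numpy()
    for g in ("MCI", "AD", "bvFTD"):
        other = preds.loc[preds["diagnosis"] == g, "bag"].to_numpy()
        if hc.size and other.size:
            res = evaluation.permutation_group_test(
                other, hc, n_iterations=config.n_permutation_iterations,
                seed=config.seed + 2,
            )
            stats_rows.append(
                {"comparison": f"{g} vs HC", "observed_diff": res.observed_diff,
                 "p_two_sided": res.p_two_sided, "n_iterations": res.n_iterations,
                 "subsample_size": res.subsample_size}
            )
    report["group_tests"] = pd.DataFrame(stats_rows)

    if config.run_importance and split.test:
        table = importance.bootstrap_importance_table(
            model, split.test, unit_kind="node",
            n_bootstrap=config.n_importance_bootstrap, seed=config.seed + 3,
        )
        report["importance"] = table

    if config.run_exposome:
        countries = sorted({rec.country for rec in records} | {"Chile", "USA"})
        expo = synthetic.generate_exposome_table(countries, seed=config.seed)
        country_map = {r.subject_id: r.country for r in records}
        bag_table = preds.assign(country=preds["subject_id"].map(country_map))
        design = exposome.build_design(bag_table, expo)
        _, cv_metrics = exposome.fit_bag_regression(design, seed=config.seed)
        report["exposome_metrics"] = cv_metrics

    if config.run_quality:
        odqs = []
        for rec, ts in zip(records, series):
            if ts.modality == "EEG":
                rep = quality.eeg_odq(ts)
            else:
                rep = quality.fmri_odq(ts)
            odqs.append({"subject_id": rec.subject_id, "odq": rep.odq})
        report["quality"] = pd.DataFrame(odqs)

    tables = {
        k: v for k, v in report.items() if isinstance(v, pd.DataFrame)
    }
    tables["metrics_table"] = pd.DataFrame([dataclasses.asdict(metrics)])
    io.write_report(tables, out, config_hash=report["config_hash"])
    manifest = {
        "config_hash": report["config_hash"],
        "seed": config.seed,
        "n_subjects": len(records),
        "n_graphs": len(graph_list),
        "n_train": len(split.train),
        "n_test": len(split.test),
        "n_augmented": len(augmented),
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
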