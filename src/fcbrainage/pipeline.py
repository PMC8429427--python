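"""End-to-end orchestration: split, preprocess, metrics, rank, fit, predict, infer.

The pipeline enforces the anti-tweaking contract of a brain-age study:
subjects with genetic risk labels never enter the training set, the
validation set comes from a held-out site when one exists, and the model
manifest (``model.json``) is written to disk *before* any test-set file is
opened — test data only ever meet the frozen predictor.  Every stage
writes plain-text artifacts (TSV tables, JSON reports) into the run
directory plus a manifest with per-file checksums, so every number in
``stats_report.json`` is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectome as cn
from . import graphmetrics as gm
from . import padstats as ps
from .model import BrainAgeModel, FrozenBrainAge
from .ranking import (
    FeatureRanking,
    StandardizationStats,
    average_rank,
    rank_by_margin_model,
    rank_by_tree_ensemble,
    standardize,
)

log = logging.getLogger("fcbrainage")

__all__ = [
    "RunConfig",
    "split_cohort",
    "run_pipeline",
    "load_config",
    "accelerated_aging_study",
]


def accelerated_aging_study(
    seed: int,
    dataset_dir,
    out_dir,
    delta_years: float = 8.0,
    n_controls: int = 480,
    n_carriers: int = 30,
    full_grid: bool = False,
):
    """Study design for the planted accelerated-aging experiment.

    Controls span the lifespan over four site draws (three feeding the
    training/test pool, one held out for validation); the carrier group is
    mid-aged (the brain-age model is most sensitive away from the edges of
    the training age range, where regression-to-the-mean flattens
    predictions) and its effective brain age is shifted by ``delta_years``.
    Returns the cohort spec and a matching run configuration.
    """
    from .synth import CohortSpec

    spec = CohortSpec(
        n_subjects_per_group=(n_controls, n_carriers),
        groups=(("control", 0.0), ("carrier", float(delta_years))),
        group_age_ranges=((18.0, 90.0), (25.0, 65.0)),
        site_labels=("siteA", "siteA", "siteA", "siteB"),
        seed=seed,
    )
    config = RunConfig(
        dataset=str(dataset_dir),
        out_dir=str(out_dir),
        validation_site="siteB",
        train_fraction=0.667,
        n_inputs=(5, 10, 15, 20, 25) if full_grid else (5, 10, 15, 20),
        architectures=None if full_grid else ((5,), (5, 2), (10, 5)),
        seed_split=seed + 11,
        seed_ranking=seed + 12,
        seed_nets=seed + 13,
        seed_null=seed + 14,
        seed_metrics=seed + 15,
    )
    return spec, config


@dataclass
class RunConfig:
    dataset: str
    out_dir: str
    scrub_threshold_mm: float = cn.FD_THRESHOLD_MM
    qc_min_fraction: float = cn.QC_MIN_FRACTION
    density: float = gm.DEFAULT_DENSITY
    n_null: int = gm.DEFAULT_N_NULL
    tr_seconds: float = 2.0
    catalog: str | None = None
    control_group: str = "control"
    risk_groups: tuple[str, ...] = ("carrier",)
    validation_site: str | None = None
    train_fraction: float = 0.8
    validation_fraction: float = 0.1
    n_inputs: tuple[int, ...] = (5, 10, 15, 20, 25)
    architectures: tuple[tuple[int, ...], ...] | None = None
    decay: float = 0.01
    n_iterations: int = 3
    with_null: bool = False
    write_connectivity: bool = False
    outlier_k_sd: float = 5.0
    seed_split: int = 1
    seed_ranking: int = 2
    seed_nets: int = 3
    seed_null: int = 4
    seed_metrics: int = 5

    def catalog_obj(self) -> gm.MetricCatalog:
        if self.catalog:
            return gm.MetricCatalog.from_yaml(self.catalog)
        return gm.default_catalog()

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    grid = d.pop("grid", {}) or {}
    seeds = d.pop("seeds", {}) or {}
    kw = dict(d)
    for k, v in grid.items():
        kw[{"n_inputs": "n_inputs", "architectures": "architectures",
            "decay": "decay", "n_iterations": "n_iterations"}[k]] = v
    for k, v in seeds.items():
        kw[f"seed_{k}"] = v
    if kw.get("risk_groups") is not None:
        kw["risk_groups"] = tuple(kw["risk_groups"])
    if kw.get("n_inputs") is not None:
        kw["n_inputs"] = tuple(kw["n_inputs"])
    if kw.get("architectures"):
        kw["architectures"] = tuple(tuple(a) for a in kw["architectures"])
    return RunConfig(**kw)


def split_cohort(participants: pd.DataFrame, config: RunConfig) -> dict[str, list[str]]:
    """Deterministic train/validation/test split.

    Risk-labelled subjects go straight to the test set.  With two or more
    sites, all controls from the (configured or last-sorted) validation
    site form the validation set; the remaining controls are shuffled with
    the split seed and divided train/test by ``train_fraction``.  With a
    single site the validation set is a seeded fraction of controls.
    """
    if "group" not in participants.columns:
        raise ValueError("participants table needs a 'group' column")
    rng = np.random.default_rng(config.seed_split)
    risk = participants[participants["group"].isin(config.risk_groups)]
    controls = participants[~participants["group"].isin(config.risk_groups)]
    sites = sorted(controls["site"].unique())
    if len(sites) >= 2:
        val_site = config.validation_site or sites[-1]
        if val_site not in sites:
            raise ValueError(f"validation site {val_site} absent from controls")
        val = controls[controls["site"] == val_site]
        pool = controls[controls["site"] != val_site]
    else:
        ids = controls["subject_id"].to_numpy()
        n_val = max(1, int(round(config.validation_fraction * len(ids))))
        pick = rng.permutation(len(ids))[:n_val]
        val = controls.iloc[sorted(pick)]
        pool = controls.drop(val.index)
    ids = pool["subject_id"].to_numpy()
    perm = rng.permutation(len(ids))
    n_train = int(round(config.train_fraction * len(ids)))
    train_ids = sorted(ids[perm[:n_train]])
    test_ids = sorted(list(ids[perm[n_train:]]) + list(risk["subject_id"]))
    split = {
        "train": train_ids,
        "validation": sorted(val["subject_id"]),
        "test": test_ids,
    }
    all_ids = split["train"] + split["validation"] + split["test"]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("split produced overlapping subject sets")
    if set(split["train"]) & set(risk["subject_id"]):
        raise ValueError("risk-group subject leaked into the training set")
    return split


# ---------------------------------------------------------------------------
# stages


def _subject_connectivity(
    dataset: Path, sid: str, config: RunConfig
) -> tuple[cn.ConnectivityMatrix | None, dict]:
    ts = cn.load_timeseries(dataset, sid, tr_seconds=config.tr_seconds)
    mask = cn.scrub_frames(ts.fd, threshold_mm=config.scrub_threshold_mm)
    info = {
        "n_frames": int(len(mask)),
        "n_retained": int(mask.sum()),
        "retained_fraction": float(mask.mean()),
    }
    if not cn.qc_retention(mask, min_fraction=config.qc_min_fraction):
        info["qc"] = "fail"
        return None, info
    info["qc"] = "pass"
    return cn.correlation_fisher(ts, mask), info


def _metric_frame(
    cms: list[cn.ConnectivityMatrix],
    mr: cn.MeanRegressionModel,
    config: RunConfig,
    catalog: gm.MetricCatalog,
) -> pd.DataFrame:
    vectors = []
    for cm in cms:
        resid = cn.apply_mean_regression(mr, cm)
        vec = gm.compute_metric_vector(
            resid,
            catalog,
            seed=config.seed_metrics,
            density=config.density,
            n_null=config.n_null,
        )
        vectors.append((vec, cm.n_frames_used))
    frame = gm.vectors_to_frame([v for v, _ in vectors])
    frame["n_frames_used"] = [n for _, n in vectors]
    return frame


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


STAGES = ("connectome", "metrics", "rank", "fit", "predict", "stats")


def run_pipeline(
    config: RunConfig, overwrite: bool = False, stop_after: str | None = None
) -> dict:
    """Execute the study replica; returns the manifest dict.

    ``stop_after`` truncates the run after the named stage (one of
    ``STAGES``); test-set files are only ever opened in the ``predict``
    stage, after ``model.json`` has been written.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    dataset = Path(config.dataset)
    out = config.out
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is non-empty")
    out.mkdir(parents=True, exist_ok=True)
    catalog = config.catalog_obj()

    participants = pd.read_csv(dataset / "participants.tsv", sep="\t")
    participants["subject_id"] = participants["subject_id"].astype(str)
    split = split_cohort(participants, config)
    (out / "split.json").write_text(json.dumps(split, indent=2, sort_keys=True))
    by_id = participants.set_index("subject_id")

    exclusions: dict[str, dict] = {"qc": {}, "outlier": {}}

    def _load_set(ids: list[str]) -> list[cn.ConnectivityMatrix]:
        cms = []
        for sid in ids:
            cm, info = _subject_connectivity(dataset, sid, config)
            if cm is None:
                exclusions["qc"][sid] = info
                log.info("QC fail %s (%.0f%% retained)", sid, 100 * info["retained_fraction"])
            else:
                cms.append(cm)
        return cms

    # --- stages 1-2: connectome + MR (training/validation only) ------------
    log.info("stage connectome: training (%d) + validation (%d)", len(split["train"]), len(split["validation"]))
    train_cms = _load_set(split["train"])
    val_cms = _load_set(split["validation"])
    if len(train_cms) < 3:
        raise RuntimeError("stage connectome: fewer than 3 training subjects survived QC")
    mr = cn.fit_mean_regression(train_cms)
    mr.to_frame().to_csv(out / "mr_model.tsv", sep="\t", index=False, float_format="%.10g")
    if config.write_connectivity:
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for cm in train_cms + val_cms:
            pd.DataFrame(cm.z, index=cm.region_labels, columns=cm.region_labels).to_csv(
                conn_dir / f"{cm.subject_id}_z.tsv", sep="\t", float_format="%.6g"
            )
    if stop_after == "connectome":
        return _finish_manifest(config, out, split, exclusions, None)

    # --- stage 3: graph metrics + outlier rule -----------------------------
    log.info("stage metrics: %d metrics per subject", len(catalog.entries))
    train_metrics = _metric_frame(train_cms, mr, config, catalog)
    val_metrics = _metric_frame(val_cms, mr, config, catalog)
    metric_cols = catalog.names

    def _vectors(frame: pd.DataFrame) -> list[gm.GraphMetricVector]:
        return [
            gm.GraphMetricVector(sid, dict(zip(metric_cols, row)), 0)
            for sid, row in zip(frame.index, frame[metric_cols].to_numpy())
        ]

    rule = gm.OutlierRule.fit(_vectors(train_metrics), k_sd=config.outlier_k_sd)
    keep_train, log_train = gm.exclude_metric_outliers(_vectors(train_metrics), rule)
    keep_val, log_val = gm.exclude_metric_outliers(_vectors(val_metrics), rule)
    exclusions["outlier"].update({**log_train, **log_val})
    train_metrics["excluded"] = [int(s not in keep_train) for s in train_metrics.index]
    val_metrics["excluded"] = [int(s not in keep_val) for s in val_metrics.index]
    catalog.to_yaml(out / "catalog.yaml")
    pd.concat(
        [train_metrics.assign(split="train"), val_metrics.assign(split="validation")]
    ).to_csv(out / "metrics.tsv", sep="\t", index_label="subject_id", float_format="%.10g")
    if stop_after == "metrics":
        return _finish_manifest(config, out, split, exclusions, None)

    Xtr = train_metrics.loc[keep_train, metric_cols]
    age_tr = by_id.loc[keep_train, "age"].to_numpy(dtype=float)
    Xva = val_metrics.loc[keep_val, metric_cols]
    age_va = by_id.loc[keep_val, "age"].to_numpy(dtype=float)

    # --- stage 4: feature ranking (training only) --------------------------
    log.info("stage ranking: n_train=%d", len(Xtr))
    stats = StandardizationStats.fit(Xtr)
    margin_scores, margin_rmse = rank_by_margin_model(
        standardize(Xtr, stats), age_tr, seed=config.seed_ranking
    )
    ens_scores, ens_rmse = rank_by_tree_ensemble(Xtr, age_tr, seed=config.seed_ranking)
    ranking = average_rank(margin_scores, ens_scores)
    ranking.to_tsv(out / "ranking.tsv")
    if stop_after == "rank":
        return _finish_manifest(config, out, split, exclusions, None)

    # --- stage 5: network grid + freeze ------------------------------------
    log.info("stage fit: grid over %s inputs", list(config.n_inputs))
    bam = BrainAgeModel(
        Xtr,
        age_tr,
        Xva,
        age_va,
        feature_order=ranking.ordered_features,
        n_inputs=config.n_inputs,
        architectures=(
            [tuple(a) for a in config.architectures] if config.architectures else None
        ),
        decay=config.decay,
    )
    results = bam.fit(
        seed=config.seed_nets,
        with_null=config.with_null,
        null_seed=config.seed_null,
        n_iterations=config.n_iterations,
    )
    results.selection_grid.table.to_csv(
        out / "grid.tsv", sep="\t", index=False, float_format="%.10g"
    )
    results.save(out / "model.json")  # freeze before any test file is read
    frozen = FrozenBrainAge.load(out / "model.json")
    if stop_after == "fit":
        return _finish_manifest(config, out, split, exclusions, results)

    # --- stage 6: test predictions (frozen model only) ---------------------
    log.info("stage predict: test (%d)", len(split["test"]))
    test_cms = _load_set(split["test"])
    test_metrics = _metric_frame(test_cms, mr, config, catalog)
    keep_test, log_test = gm.exclude_metric_outliers(_vectors(test_metrics), rule)
    exclusions["outlier"].update(log_test)
    test_metrics["excluded"] = [int(s not in keep_test) for s in test_metrics.index]
    Xte = test_metrics.loc[keep_test, metric_cols]
    predicted = frozen.predict(Xte)
    pred_frame = pd.DataFrame(
        {
            "subject_id": keep_test,
            "chronological_age": by_id.loc[keep_test, "age"].to_numpy(dtype=float),
            "predicted_age": predicted,
        }
    )
    pred_frame.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.10g")
    if stop_after == "predict":
        return _finish_manifest(config, out, split, exclusions, results)

    # --- stage 7: PAD inference --------------------------------------------
    log.info("stage stats: %d test subjects", len(pred_frame))
    meta_cols = [c for c in ("group", "site", "amyloid_load", "amyloid_positive", "parental_onset_age") if c in by_id.columns]
    meta = by_id.loc[keep_test, meta_cols].reset_index()
    enriched = pred_frame.merge(meta, on="subject_id")
    enriched = enriched.rename(columns={"group": "group_label"})
    pad = ps.compute_pad(enriched)
    if "parental_onset_age" in pad.frame.columns:
        pad.frame["eyo"] = ps.compute_eyo(
            pad.frame["chronological_age"], pad.frame["parental_onset_age"]
        )
    pad.to_tsv(out / "pad.tsv")

    report: dict = {"contrasts": [], "partial_correlations": [], "rank_tests": []}
    test_rmse = float(np.sqrt(np.mean((pad.frame["pad"]) ** 2)))
    corr = float(np.corrcoef(pad.frame["predicted_age"], pad.frame["chronological_age"])[0, 1]) if len(pad.frame) > 2 else float("nan")
    report["test_performance"] = {
        "n": int(len(pad.frame)),
        "rmse": test_rmse,
        "mae": float(np.mean(np.abs(pad.frame["pad"]))),
        "r": corr,
    }
    report["model"] = {
        "selected_architecture": results.architecture.label(),
        "training_rmse": results.training_rmse,
        "validation_rmse": results.validation_rmse,
        "margin_model_rmse": margin_rmse,
        "ensemble_rmse": ens_rmse,
    }
    present_groups = set(pad.frame["group_label"])
    for gname in config.risk_groups:
        if gname in present_groups and config.control_group in present_groups:
            comp = ps.group_glm(pad, config.control_group, gname)
            report["contrasts"].append(comp.as_dict())
            ctrl = pad.frame[pad.frame.group_label == config.control_group]["pad"]
            risk = pad.frame[pad.frame.group_label == gname]["pad"]
            u, p_u = ps.mann_whitney(ctrl, risk, sided="two")
            report["rank_tests"].append(
                {"groups": [config.control_group, gname], "U": u, "p": p_u, "sided": "two"}
            )
    for col in ("amyloid_load", "eyo"):
        if col in pad.frame.columns and pad.frame[col].notna().sum() >= 5:
            try:
                r, dof, p = ps.partial_correlation(pad, col)
            except ValueError:
                continue
            report["partial_correlations"].append(
                {"x": col, "r": r, "df": dof, "p": p, "covariate": "chronological_age"}
            )
    report["exclusions"] = {
        "qc_failed": sorted(exclusions["qc"]),
        "metric_outliers": {k: v for k, v in sorted(exclusions["outlier"].items())},
    }
    (out / "stats_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return _finish_manifest(config, out, split, exclusions, results)


def _finish_manifest(config, out: Path, split, exclusions, results) -> dict:
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "split_sizes": {k: len(v) for k, v in split.items()},
        "selected_model": results.architecture.label() if results else None,
        "checksums": {
            p.name: _checksum(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
        "exclusion_counts": {
            "qc": len(exclusions["qc"]),
            "outlier": len(exclusions["outlier"]),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
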