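"""End-to-end orchestration: extract -> metrics -> cluster -> PCA ->
cohort analyses -> size model, with a machine-readable run report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_analysis as ca
from . import clustering_pca as cp
from .config import RunConfig
from .dar_extraction import build_dars, dars_to_frames
from .errors import DataError
from .path_metrics import metrics_table
from .track_io import Track, write_table

log = logging.getLogger("darshape")


@dataclass
class RunResult:
    dars: list
    metrics: pd.DataFrame
    matrix: cp.MetricMatrix
    clusterer: cp.WardClusterer
    pca: cp.DarPCA
    summary: pd.DataFrame
    cohort: pd.DataFrame
    contingency: dict
    size_fit: ca.SizeModelFit | None
    report: dict


def frame_to_tracks(tracks_df: pd.DataFrame) -> list[Track]:
    tracks = []
    for ind, g in tracks_df.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp", kind="mergesort")
        tracks.append(Track(str(ind),
                            g[["timestamp", "x", "y", "accuracy_std"]]
                            .reset_index(drop=True)))
    return tracks


def run_all(config: RunConfig, tracks_df: pd.DataFrame, meta_df: pd.DataFrame,
            outdir: str | Path | None = None) -> RunResult:
    """Run the whole analysis on in-memory tables.

    Stages that need structure the data cannot support (a single sex in the
    cohort, say) are recorded as skipped in the report rather than aborting
    the run.
    """
    cfg = config
    report: dict = {"config": cfg.to_dict()}
    if "accuracy_std" not in tracks_df.columns:
        tracks_df = tracks_df.assign(accuracy_std=np.nan)

    tracks = frame_to_tracks(tracks_df)
    dars, extract_report = build_dars(tracks, None, cfg)
    report["extraction"] = {
        k: v for k, v in extract_report.items() if k != "incomplete_nights"}
    report["extraction"]["incomplete_nights"] = len(
        extract_report["incomplete_nights"])
    if not dars:
        raise DataError("no DARs extracted; check thresholds and data span")

    metrics = metrics_table(dars)
    matrix = cp.make_matrix(metrics)
    report["metrics"] = {"rows": len(metrics), "dropped_na": matrix.n_dropped}

    clusterer = cp.WardClusterer(n_clusters=cfg.k, k_max=cfg.k_max).fit(matrix)
    report["clustering"] = {
        "k": cfg.k,
        "suggested_k": clusterer.suggested_k_[:5],
        "wss": {k: round(v, 3) for k, v in clusterer.curves_.wss.items()},
    }

    pca = cp.run_pca(matrix)
    report["pca"] = {
        "variance_fraction": [round(float(v), 4)
                              for v in pca.explained_variance_ratio_],
        "interpretation": pca.interpretation_,
        "pc1_loadings": [round(float(v), 3) for v in pca.loadings_[:, 0]],
    }

    clustered = metrics[metrics["dar_id"].isin(matrix.dar_ids)].reset_index(drop=True)
    summary = cp.summarize_clusters(clusterer.labels_, clustered,
                                    cfg.open_lo_km, cfg.open_hi_km)
    try:
        size = cp.composite_size(clustered, pca)
        report["composite_size_mode"] = "loading_weighted"
    except DataError:
        # PC1 not all-positive (possible on small/degenerate cohorts):
        # fall back to the min-shifted PC1 score
        size = cp.composite_size(clustered, pca, mode="shifted_score")
        report["composite_size_mode"] = "shifted_score"
    clustered = clustered.assign(composite_size=size)

    # start locations from the extracted start points
    dar_frame, _ = dars_to_frames(dars)
    starts = dar_frame[dar_frame["dar_id"].isin(matrix.dar_ids)]
    starts = starts.set_index("dar_id").loc[matrix.dar_ids].reset_index()
    loc_labels = None
    pts = starts[["start_x", "start_y"]].to_numpy(dtype=float)
    if len(pts) >= cfg.kmeans_k and np.isfinite(pts).all():
        loc = ca.StartLocationKMeans(cfg.kmeans_k, n_restarts=cfg.kmeans_restarts,
                                     random_state=cfg.seed).fit(pts)
        loc_labels = loc.labels_
        report["start_locations"] = {"k": cfg.kmeans_k,
                                     "wss": {k: round(v, 1)
                                             for k, v in loc.wss_.items()}}

    cohort = ca.build_cohort(clustered, clusterer.labels_, matrix.dar_ids,
                             meta_df, location_labels=loc_labels)

    contingency = {}
    for grouping in ("sex", "age", "location", "quadrimester"):
        col = ca.GROUPINGS[grouping]
        if col not in cohort.columns or cohort[col].nunique() < 2:
            continue
        tab = ca.distribution_table(cohort, grouping)
        try:
            contingency[grouping] = ca.chi_squared_test(tab.counts)
        except DataError:
            continue
    report["contingency"] = {
        g: {"statistic": round(r.statistic, 3), "dof": r.dof,
            "p_value": float(r.p_value)}
        for g, r in contingency.items()}

    size_fit = None
    model_frame = cohort
    if cfg.exclude_no_flight and "no_flight" in cohort.columns:
        model_frame = cohort[~cohort["no_flight"]]
    try:
        size_fit = ca.fit_size_model(model_frame, "composite_size",
                                     include_date_effect=True)
        report["size_model"] = {
            "fixed_effects": {
                t: {"estimate": round(float(r["estimate"]), 4),
                    "p_value": float(r["pvalue"])}
                for t, r in size_fit.fixed_effects.iterrows()},
            "random_variances": {k: round(v, 5)
                                 for k, v in size_fit.random_variances.items()},
            "aic": round(size_fit.aic, 2),
        }
    except DataError as exc:
        report["size_model"] = {"skipped": str(exc)}
        log.warning("size model skipped: %s", exc)

    result = RunResult(dars, metrics, matrix, clusterer, pca, summary,
                       cohort, contingency, size_fit, report)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(res: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(res.metrics, outdir / "metrics.csv")
    labels = pd.DataFrame({"dar_id": res.matrix.dar_ids,
                           "cluster": res.clusterer.labels_})
    write_table(labels, outdir / "labels.csv")
    curves = pd.DataFrame({
        "k": sorted(res.clusterer.curves_.wss),
        "wss": [res.clusterer.curves_.wss[k]
                for k in sorted(res.clusterer.curves_.wss)],
    })
    curves["s"] = curves["k"].map(res.clusterer.curves_.s)
    curves["f"] = curves["k"].map(res.clusterer.curves_.f)
    write_table(curves, outdir / "wss_curves.csv")
    loadings = pd.DataFrame(
        res.pca.loadings_,
        index=["net_displacement", "max_displacement", "max_diameter",
               "max_width"],
        columns=[f"PC{i + 1}" for i in range(res.pca.loadings_.shape[1])])
    loadings.insert(0, "metric", loadings.index)
    write_table(loadings, outdir / "pca_loadings.csv")
    write_table(res.summary, outdir / "cluster_summary.csv")
    write_table(res.cohort.drop(columns=["birth_or_assignment_date"],
                                errors="ignore"),
                outdir / "cohort.csv")
    if res.size_fit is not None:
        fe = res.size_fit.fixed_effects.copy()
        fe.insert(0, "term", fe.index)
        write_table(fe, outdir / "size_model.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(res.report, fh, indent=2, default=str)
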