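"""Batch execution of the full pipeline with FAIR provenance.

Every file in a batch runs through localize -> filter -> track -> mask ->
length filter -> mobility -> clustering with one frozen
:class:`~sptpalm.params.ParameterSet`.  A stage failure flags the file's
summary row instead of aborting the batch, and the complete parameter
set is embedded verbatim in the results workbook so any number in it can
be traced back to the settings that produced it.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .camera import (
    MovieStack,
    calibrate_camera,
    read_mask,
    read_movie_stack,
    write_localization_table,
)
from .cluster import (
    cluster_dbscan,
    cluster_metrics,
    cluster_nastic,
    cluster_voronoi,
    make_cluster_input,
)
from .localize import filter_localizations, localize_stack
from .mobility import analyze_mobility, write_mobility_table, per_track_mobility
from .params import ParameterSet
from .track import apply_mask, close_gaps, filter_tracks, link_frames, write_tracks

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "file",
    "n_localizations",
    "n_tracks",
    "n_tracks_min_length",
    "D_mean_um2_per_s",
    "peak_logD",
    "mobile_fraction",
    "n_clusters",
    "median_diameter_nm",
    "clustered_fraction",
    "qc_flags",
]


@dataclass
class BatchItem:
    movie_path: str
    dark_path: Optional[str] = None
    mask_path: Optional[str] = None
    frame_interval_s: Optional[float] = None  # per-file override


@dataclass
class BatchResult:
    summary: pd.DataFrame  # one row per input file, input order
    params: ParameterSet
    software_version: str = __version__
    started: str = ""
    finished: str = ""


def _null_row(path: str) -> dict:
    row = {c: None for c in SUMMARY_COLUMNS}
    row["file"] = path
    row["qc_flags"] = ""
    return row


def run_pipeline_single(
    item: BatchItem, params: ParameterSet, out_dir: str | Path | None = None
) -> dict:
    """All pipeline stages for one movie; failures become qc flags."""
    row = _null_row(item.movie_path)
    flags: list[str] = []
    out = Path(out_dir) if out_dir is not None else None
    stem = Path(item.movie_path).stem
    dt = item.frame_interval_s or params.camera.frame_interval_s

    try:
        movie = read_movie_stack(item.movie_path, params.camera.pixel_size_nm, dt)
    except Exception as exc:
        logger.error("read failed for %s: %s", item.movie_path, exc)
        row["qc_flags"] = "read_error"
        return row

    if item.dark_path:
        try:
            dark = read_movie_stack(item.dark_path, params.camera.pixel_size_nm, dt)
            calib = calibrate_camera(dark, params.camera.e_per_adu, params.camera.qe)
        except Exception as exc:
            logger.error("calibration failed for %s: %s", item.dark_path, exc)
            flags.append("calibration_error")
            calib = _scalar_calib(params)
    else:
        calib = _scalar_calib(params)

    logger.info("[%s] localize (params %s)", stem, params.digest())
    try:
        locs = localize_stack(movie, calib, params)
        locs, _ = filter_localizations(locs, params.filter)
    except Exception as exc:
        logger.error("localization failed for %s: %s", item.movie_path, exc)
        row["qc_flags"] = ";".join(flags + ["localization_error"])
        return row
    row["n_localizations"] = len(locs)
    if out is not None:
        write_localization_table(locs, out / f"{stem}_locs.csv")
    if len(locs) == 0:
        row["qc_flags"] = ";".join(flags + ["no_localizations"])
        return row

    if not params.batch.run_tracking:
        row["qc_flags"] = ";".join(flags)
        return row
    logger.info("[%s] track", stem)
    try:
        tracks = close_gaps(link_frames(locs, params.tracking), params.tracking)
        if item.mask_path:
            mask = read_mask(item.mask_path)
            tracks, _ = apply_mask(tracks, mask, params.camera.pixel_size_nm)
        row["n_tracks"] = len(tracks)
        tracks = filter_tracks(tracks, params.tracking)
        row["n_tracks_min_length"] = len(tracks)
        if out is not None:
            write_tracks(tracks, out / f"{stem}_tracks.csv")
    except Exception as exc:
        logger.error("tracking failed for %s: %s", item.movie_path, exc)
        row["qc_flags"] = ";".join(flags + ["tracking_error"])
        return row
    if not tracks:
        row["qc_flags"] = ";".join(flags + ["no_tracks"])
        return row

    if params.batch.run_mobility:
        logger.info("[%s] mobility", stem)
        try:
            summary = analyze_mobility(tracks, dt, params.mobility)
            row["D_mean_um2_per_s"] = summary.D_mean_um2_per_s
            if summary.population is not None:
                row["peak_logD"] = summary.population.peak_logD
                row["mobile_fraction"] = summary.population.mobile_fraction
            if out is not None:
                per_track, _, _, _ = per_track_mobility(
                    tracks, dt, params.mobility.n_fit_points,
                    params.mobility.adj_r2_min, params.mobility.max_lag,
                )
                write_mobility_table(per_track, out / f"{stem}_mobility.csv")
        except Exception as exc:
            logger.error("mobility failed for %s: %s", item.movie_path, exc)
            flags.append("mobility_error")

    if params.batch.run_clustering:
        logger.info("[%s] cluster (%s)", stem, params.clustering.algorithm)
        try:
            cp = params.clustering
            ci = make_cluster_input(locs, tracks, cp.input_mode)
            if cp.algorithm == "dbscan":
                result = cluster_dbscan(ci, cp.dbscan)
            elif cp.algorithm == "voronoi":
                result = cluster_voronoi(ci, cp.voronoi)
            else:
                result = cluster_nastic(ci, cp.nastic, frame_interval_s=dt)
            df_clusters, summ = cluster_metrics(result)
            row["n_clusters"] = summ["n_clusters"]
            row["median_diameter_nm"] = summ["median_diameter_nm"]
            row["clustered_fraction"] = summ["clustered_fraction"]
            if out is not None:
                df_clusters.to_csv(out / f"{stem}_clusters.csv", index=False, float_format="%.10g")
        except Exception as exc:
            logger.error("clustering failed for %s: %s", item.movie_path, exc)
            flags.append("clustering_error")

    row["qc_flags"] = ";".join(flags)
    return row


def _scalar_calib(params: ParameterSet):
    from .camera import CameraCalibration

    return CameraCalibration(
        offset=params.camera.offset_adu,
        variance=0.0,
        e_per_adu=params.camera.e_per_adu,
        qe=params.camera.qe,
    )


def run_batch(
    items: list[BatchItem], params: ParameterSet, out_dir: str | Path | None = None
) -> BatchResult:
    """Apply :func:`run_pipeline_single` to every item with frozen params."""
    if not items:
        raise ValueError("batch needs at least one item")
    started = datetime.datetime.now().isoformat(timespec="seconds")
    rows = [run_pipeline_single(item, params, out_dir) for item in items]
    finished = datetime.datetime.now().isoformat(timespec="seconds")
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return BatchResult(summary=summary, params=params, started=started, finished=finished)


def write_results_workbook(result: BatchResult, path: str | Path) -> None:
    """Single multi-section CSV: parameter dump, then the summary table.

    Numeric summary values are written with 6 significant digits; the
    parameter section is the full JSON parameter set, one key per row.
    """
    lines = ["# sptpalm results workbook v1"]
    lines.append(f"# software_version,{result.software_version}")
    lines.append(f"# started,{result.started}")
    lines.append(f"# finished,{result.finished}")
    lines.append("[parameters]")
    flat = _flatten(json.loads(result.params.to_json()))
    for key in sorted(flat):
        lines.append(f"{key},{json.dumps(flat[key])}")
    lines.append("[summary]")
    df = result.summary.copy()
    for c in df.columns:
        if df[c].dtype.kind == "f" or c not in ("file", "qc_flags"):
            df[c] = df[c].map(lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else (f"{v:.6g}" if isinstance(v, float) else v))
    lines.append(",".join(SUMMARY_COLUMNS))
    for _, r in df.iterrows():
        lines.append(",".join("" if r[c] is None else str(r[c]) for c in SUMMARY_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_results_workbook(path: str | Path) -> tuple[ParameterSet, pd.DataFrame]:
    """Parse a workbook back into (ParameterSet, summary table)."""
    text = Path(path).read_text().splitlines()
    try:
        p_start = text.index("[parameters]")
        s_start = text.index("[summary]")
    except ValueError as exc:
        raise ValueError("not a results workbook: missing sections") from exc
    flat: dict[str, object] = {}
    for line in text[p_start + 1 : s_start]:
        key, val = line.split(",", 1)
        flat[key] = json.loads(val)
    params = ParameterSet.model_validate(_unflatten(flat))
    import io

    summary = pd.read_csv(io.StringIO("\n".join(text[s_start + 1 :])))
    return params, summary


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict[str, object] = {}
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else k
        if isinstance(v, dict):
            out.update(_flatten(v, key))
        else:
            out[key] = v
    return out


def _unflatten(flat: dict) -> dict:
    out: dict = {}
    for key, v in flat.items():
        parts = key.split(".")
        d = out
        for p in parts[:-1]:
            d = d.setdefault(p, {})
        d[parts[-1]] = v
    return out
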