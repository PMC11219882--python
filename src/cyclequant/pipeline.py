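"""End-to-end pipeline: simulate (optional) -> sum -> segment -> track ->
select -> call -> stats, with a JSON run manifest.

The manifest records the config hash, seed, package versions and per-stage
counts (tracks before/after each filter), and carries ``status:
"INCOMPLETE"`` until the run finishes so aborted runs are recognizable.
Outputs are deterministic for a fixed (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, phasecall, segment, select, simulate, tracking
from .config import Construct, PipelineConfig

logger = logging.getLogger(__name__)


def _write_manifest(path: Path, manifest: dict) -> None:
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 venus_path: str | Path | None = None,
                 red_path: str | Path | None = None,
                 labels_path: str | Path | None = None) -> dict:
    """Run every stage and write all outputs plus the run manifest.

    With ``config.simulate`` set, a synthetic movie is generated first (its
    seed is overridden by the pipeline seed); otherwise the two channel
    stacks (and optionally a precomputed label movie) are read from the
    given paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "status": "INCOMPLETE",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "counts": {},
    }
    _write_manifest(outdir / "manifest.json", manifest)
    stage = "setup"
    try:
        # ---- acquire input -------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            sim.seed = config.seed
            lineage = simulate.sample_lineage(sim)
            traces = simulate.reporter_traces(lineage, sim)
            movie = simulate.render_movie(lineage, traces, sim)
            simulate.write_fixture(lineage, traces, movie, sim,
                                   outdir / "synthetic")
            venus, red = movie.venus, movie.red
            manifest["counts"]["simulated_cells"] = int(len(lineage.cells))
            manifest["counts"]["simulated_completed_cycles"] = int(
                lineage.cells["completed"].sum())
        else:
            stage = "read"
            if venus_path is None or red_path is None:
                raise ValueError("without simulate, venus and red stack paths "
                                 "are required")
            venus = io.read_stack(venus_path)
            red = io.read_stack(red_path)

        # ---- segment -------------------------------------------------------
        stage = "segment"
        if labels_path is not None:
            labels = io.read_labels(labels_path)
        else:
            summed = segment.sum_channels((venus, red))
            io.write_stack(outdir / "summed.tif", summed)
            labels = segment.segment_stack(summed,
                                           diameter=config.nucleus_diameter)
        io.write_labels(outdir / "labels.tif", labels)
        manifest["counts"]["frames"] = int(labels.shape[0])

        # ---- track ---------------------------------------------------------
        stage = "track"
        dets = tracking.detections_from_labels(
            labels, venus=venus, red=red, pixel_size_um=config.pixel_size_um)
        tracks = tracking.build_tracks(dets,
                                       frame_interval=config.frame_interval,
                                       max_dist=config.max_link_distance_um)
        tracking.export_track_table(tracks, outdir / "tracks.csv")
        n_all = tracks["track_id"].nunique() if not tracks.empty else 0
        manifest["counts"]["tracks_total"] = int(n_all)

        # ---- select --------------------------------------------------------
        stage = "select"
        kept = select.filter_min_duration(
            tracks, frame_interval=config.frame_interval,
            min_minutes=config.min_track_minutes)
        n_dur = kept["track_id"].nunique() if not kept.empty else 0
        manifest["counts"]["tracks_after_duration_filter"] = int(n_dur)
        manifest["counts"]["tracks_removed_duration"] = int(n_all - n_dur)
        if config.construct is Construct.PIP_H2A:
            kept = select.filter_mitosis_slope(kept, channel="red_max",
                                               thresh=config.slope_threshold)
        n_slope = kept["track_id"].nunique() if not kept.empty else 0
        manifest["counts"]["tracks_after_slope_filter"] = int(n_slope)
        manifest["counts"]["tracks_removed_slope"] = int(n_dur - n_slope)

        # ---- call ----------------------------------------------------------
        stage = "call"
        all_calls: list[phasecall.PhaseCalls] = []
        cycle_ids: list[str] = []
        segments: list[select.CycleSegment] = []
        for tid, g in (kept.groupby("track_id") if not kept.empty else []):
            g = g.sort_values("frame").reset_index(drop=True)
            if len(g) < 5:
                continue
            if config.construct is Construct.PIP_H2A:
                peaks = select.detect_cytokinesis_peaks(
                    g["red_mean"].to_numpy(),
                    prominence_factor=config.peak_prominence_factor,
                    max_width=config.peak_max_width_frames)
                segs = select.extract_full_cycles(
                    g, peaks, frame_interval=config.frame_interval,
                    min_cycle_minutes=config.min_cycle_minutes)
                segments.extend(segs)
                for k, seg in enumerate(segs):
                    if not seg.ok or seg.trace is None:
                        continue
                    calls = phasecall.call_cycle(
                        seg.trace["venus_mean"].to_numpy(), seg.start_frame,
                        config.frame_interval,
                        drop_fraction=config.drop_fraction,
                        rise_window=config.rise_window,
                        rise_margin_fraction=config.rise_margin_fraction,
                        rise_noise_factor=config.rise_noise_factor,
                        smooth_window=config.smooth_window)
                    all_calls.append(calls)
                    cycle_ids.append(f"{tid}:{k}")
            else:
                first = int(g["frame"].iloc[0])
                res = phasecall.call_fucci_cycle(
                    g["venus_mean"].to_numpy(), g["red_mean"].to_numpy(),
                    recording_frames=int(labels.shape[0]),
                    frame_interval=config.frame_interval,
                    min_start_offset_h=config.min_start_offset_h,
                    min_end_offset_h=config.min_end_offset_h,
                    drop_fraction=config.drop_fraction,
                    rise_window=config.rise_window,
                    rise_margin_fraction=config.rise_margin_fraction,
                    rise_noise_factor=config.rise_noise_factor,
                    smooth_window=config.smooth_window)
                if res.calls is not None:
                    # frames within the track are offsets from its first frame
                    c = res.calls
                    for attr in ("start_frame", "g1s_frame", "sg2_frame",
                                 "end_frame"):
                        val = getattr(c, attr)
                        if val is not None:
                            setattr(c, attr, val + first)
                    all_calls.append(c)
                    cycle_ids.append(f"{tid}:0")
        if segments:
            select.segment_report(segments, config.frame_interval).to_csv(
                outdir / "segments.csv", index=False, float_format="%.3f")
        calls_df = phasecall.calls_table(all_calls, cycle_ids)
        calls_df.to_csv(outdir / "phase_calls.csv", index=False,
                        float_format="%.6f")
        manifest["counts"]["cycles_called"] = int(calls_df["flags"].eq("").sum()
                                                  if not calls_df.empty else 0)
        manifest["counts"]["cycles_flagged"] = int(
            (~calls_df["flags"].eq("")).sum() if not calls_df.empty else 0)

        # ---- stats ---------------------------------------------------------
        stage = "stats"
        good = calls_df[calls_df["flags"] == ""]
        if not good.empty:
            from . import stats as qstats
            table = qstats.describe_phases({
                "G1": good["G1_h"].to_numpy(),
                "S": good["S_h"].to_numpy(),
                "G2M": good["G2M_h"].to_numpy(),
                "total": good["total_h"].to_numpy(),
            })
            table.to_csv(outdir / "group_stats.csv", index=False,
                         float_format="%.4f")
        manifest["status"] = "complete"
        _write_manifest(outdir / "manifest.json", manifest)
        return manifest
    except Exception:
        manifest["status"] = "INCOMPLETE"
        manifest["failed_stage"] = stage
        _write_manifest(outdir / "manifest.json", manifest)
        logger.exception("pipeline aborted in stage %s", stage)
        raise


def _versions() -> dict[str, str]:
    import scipy
    import skimage
    import tifffile as tf
    return {
        "cyclequant": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-image": skimage.__version__,
        "tifffile": tf.__version__,
    }
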