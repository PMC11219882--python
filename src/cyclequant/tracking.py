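"""Gap-free nucleus tracking by frame-to-frame linear assignment.

Detections are label-mask regions; consecutive frames are linked by the
optimal one-to-one assignment minimizing total squared displacement, with
an unassignment option costing ``max_dist**2`` per unmatched detection and
links beyond ``max_dist`` forbidden. No gap closing: an unmatched detection
ends its track, and an unclaimed detection starts a new one. At a division
the mother's track simply continues into the nearer daughter; the other
daughter starts a fresh track.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage import measure

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "label", "area_px2",
                 "venus_mean", "venus_max", "red_mean", "red_max"]


def detections_from_labels(label_movie: np.ndarray,
                           venus: np.ndarray | None = None,
                           red: np.ndarray | None = None,
                           pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Measure per-frame detections (centroid, area, channel stats) from labels."""
    rows = []
    for f in range(label_movie.shape[0]):
        lab = label_movie[f]
        for region in measure.regionprops(lab):
            cy, cx = region.centroid
            row = {
                "frame": f, "label": int(region.label),
                "x_um": cx * pixel_size_um, "y_um": cy * pixel_size_um,
                "area_px2": float(region.area),
            }
            mask = lab == region.label
            for name, stack in (("venus", venus), ("red", red)):
                if stack is None:
                    row[f"{name}_mean"] = np.nan
                    row[f"{name}_max"] = np.nan
                else:
                    vals = stack[f][mask]
                    row[f"{name}_mean"] = float(vals.mean())
                    row[f"{name}_max"] = float(vals.max())
            rows.append(row)
    cols = ["frame", "label", "x_um", "y_um", "area_px2",
            "venus_mean", "venus_max", "red_mean", "red_max"]
    return pd.DataFrame(rows, columns=cols)


def link_frames(xy_a: np.ndarray, xy_b: np.ndarray, max_dist: float = 10.0
                ) -> list[tuple[int, int]]:
    """Optimal one-to-one links between two point sets.

    Minimizes total squared displacement plus ``max_dist**2`` per unmatched
    point; links longer than ``max_dist`` are forbidden. Returns (i, j) index
    pairs into ``xy_a`` / ``xy_b``.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    xy_a = np.asarray(xy_a, dtype=float).reshape(-1, 2)
    xy_b = np.asarray(xy_b, dtype=float).reshape(-1, 2)
    n, m = len(xy_a), len(xy_b)
    if n == 0 or m == 0:
        return []
    d2 = ((xy_a[:, None, :] - xy_b[None, :, :]) ** 2).sum(axis=2)
    penalty = max_dist ** 2
    big = 1e12
    # augmented square matrix: top-left real costs, diagonal birth/death blocks
    size = n + m
    cost = np.full((size, size), 0.0)
    cost[:n, :m] = np.where(d2 <= penalty, d2, big)
    cost[:n, m:] = big
    cost[n:, :m] = big
    np.fill_diagonal(cost[:n, m:], penalty)
    np.fill_diagonal(cost[n:, :m], penalty)
    rows, cols = linear_sum_assignment(cost)
    links = []
    for r, c in zip(rows, cols):
        if r < n and c < m and d2[r, c] <= penalty:
            links.append((int(r), int(c)))
    return links


def build_tracks(detections: pd.DataFrame, frame_interval: float = 10.0,
                 max_dist: float = 10.0) -> pd.DataFrame:
    """Assemble a TrackTable by linking consecutive frames.

    ``detections`` must carry frame, label, x_um, y_um (plus any intensity
    columns, which are carried through). Every detection lands in exactly one
    track; frames within a track are strictly consecutive by construction.
    """
    if detections.empty:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    frames = sorted(detections["frame"].unique())
    if any(f2 < f1 for f1, f2 in zip(frames, frames[1:])):
        raise ValueError("frame indices must be monotone")

    det = detections.sort_values(["frame", "label"]).reset_index(drop=True)
    det["track_id"] = -1
    by_frame = {f: g.index.to_numpy() for f, g in det.groupby("frame")}

    next_track = 0
    prev_idx: np.ndarray | None = None
    prev_frame: int | None = None
    for f in frames:
        idx = by_frame[f]
        assigned = np.full(len(idx), -1, dtype=int)
        if prev_idx is not None and f == prev_frame + 1:
            xy_a = det.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            xy_b = det.loc[idx, ["x_um", "y_um"]].to_numpy()
            for i, j in link_frames(xy_a, xy_b, max_dist=max_dist):
                assigned[j] = det.at[prev_idx[i], "track_id"]
        for k, row_i in enumerate(idx):
            if assigned[k] == -1:
                assigned[k] = next_track
                next_track += 1
            det.at[row_i, "track_id"] = assigned[k]
        prev_idx = idx
        prev_frame = f

    cols = ["track_id"] + [c for c in det.columns if c != "track_id"]
    out = det[cols].sort_values(["track_id", "frame"]).reset_index(drop=True)
    out.attrs["frame_interval"] = frame_interval
    return out


def track_durations(tracks: pd.DataFrame, frame_interval: float
                    ) -> pd.Series:
    """Duration in minutes per track id: (n_frames - 1) * interval."""
    if tracks.empty:
        return pd.Series(dtype=float)
    g = tracks.groupby("track_id")["frame"]
    return (g.max() - g.min()) * frame_interval


def validate_track_table(tracks: pd.DataFrame) -> None:
    """Raise if any track contains a frame gap or a duplicated frame."""
    for tid, g in tracks.groupby("track_id"):
        fr = np.sort(g["frame"].to_numpy())
        if len(fr) > 1:
            diffs = np.diff(fr)
            if (diffs == 0).any():
                raise ValueError(f"track {tid} has duplicated frames")
            if (diffs > 1).any():
                bad = int(fr[np.argmax(diffs > 1)])
                raise ValueError(
                    f"track {tid} has a frame gap after frame {bad}; "
                    "gap-free tracks are required")


def export_track_table(tracks: pd.DataFrame, path) -> None:
    missing = [c for c in ("track_id", "frame", "x_um", "y_um")
               if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    tracks.to_csv(path, index=False, float_format="%.6f")


def read_track_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("track_id", "frame", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"track table is missing required column '{col}'")
    validate_track_table(df)
    return df
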