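"""Synthetic dual-reporter time-lapse generator with exported ground truth.

Produces, from a single integer seed: a branching lineage with known
phase-transition frames, per-nucleus noiseless reporter traces, optional
trace-level noise, and rendered 2-channel 16-bit movies with a matching
truth label movie. Every stage of the analysis pipeline can be validated
against the exported truth without any external data.

Trace waveform model (per cell, at frame resolution):

* mVenus: exponential approach to a plateau during G1; exponential decay
  (configured halftime, completing within 30 min) starting at the true
  G1/S frame; floor through S; linear rise from the true S/G2 frame until
  division, capped at the plateau.
* red, histone mode (mScarlet): ``baseline - coupling * venus_norm`` plus a
  single-frame mitotic spike at each daughter's birth frame, guaranteed to
  exceed the per-frame slope-filter threshold and to be the per-cycle
  maximum.
* red, licensing mode (mCherry): zero through G1, linear ramp starting
  ``cherry_onset_delay`` after the true G1/S frame, dropping to zero at
  division (the daughter restarts at zero), i.e. a >=90% single-frame drop.

A cell is alive on frames ``[birth_frame, division_frame - 1]``; its
daughters occupy the division frame. A track that follows a mother into the
nearer daughter therefore sees mitotic red-channel spikes exactly at the
true division frames.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .config import Construct, SimConfig

logger = logging.getLogger(__name__)

_MAX_CELLS = 200_000


def _rng(seed: int, *key) -> np.random.Generator:
    """Named sub-stream generator: deterministic given (seed, key)."""
    parts = [int(seed)] + [zlib.crc32(k.encode()) if isinstance(k, str)
                           else int(k) for k in key]
    return np.random.default_rng(np.random.SeedSequence(parts))


@dataclass
class LineageTruth:
    """Ground-truth lineage, phase boundaries and per-frame positions.

    ``cells`` columns: cell_id, parent_id (-1 for founders), birth_frame,
    g1s_frame, sg2_frame, division_frame (-1 if the cell never divides
    within the movie), completed (full cycle inside the movie), usable
    (phases resolvable at frame resolution).

    ``positions`` columns: cell_id, frame, x_um, y_um, label.
    """

    cells: pd.DataFrame
    positions: pd.DataFrame
    n_frames: int
    frame_interval: float

    def alive_at(self, frame: int) -> pd.DataFrame:
        return self.positions[self.positions["frame"] == frame]

    def completed_cycles(self) -> pd.DataFrame:
        return self.cells[self.cells["completed"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# lineage sampling
# ---------------------------------------------------------------------------

def _draw_phase_durations(rng: np.random.Generator, config: SimConfig
                          ) -> tuple[float, float, float]:
    med = config.effective_medians()
    disp = config.phase_dispersions
    out = []
    for phase in ("G1", "S", "G2M"):
        z = rng.standard_normal()
        out.append(med[phase] * 60.0 * np.exp(disp[phase] * z))  # minutes
    return tuple(out)


def sample_phase_durations(config: SimConfig, n: int,
                           seed: Optional[int] = None) -> pd.DataFrame:
    """n independent (G1, S, G2M) duration draws in hours, as a DataFrame."""
    base = config.seed if seed is None else seed
    rows = [_draw_phase_durations(_rng(base, "phase-draws", i), config)
            for i in range(n)]
    df = pd.DataFrame(rows, columns=["G1", "S", "G2M"]) / 60.0
    return df


def sample_lineage(config: SimConfig) -> LineageTruth:
    """Sample a branching lineage with known phase boundaries.

    Founders start at uniformly random positions within their first cycle
    (so the population is unsynchronized); each cell draws independent
    lognormal (G1, S, G2M) durations; division spawns two daughters until
    the movie ends. Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    if config.n_founders < 1:
        raise ValueError("n_founders must be >= 1 to sample a lineage")
    dt = config.frame_interval
    n_frames = config.n_frames
    total_min = (n_frames - 1) * dt

    rows = []
    # FIFO of (cell_id, parent_id, birth_time_minutes)
    queue: list[tuple[int, int, float]] = []
    next_id = 0
    for _ in range(config.n_founders):
        rng_f = _rng(config.seed, "founder", next_id)
        g1, s, g2m = _draw_phase_durations(rng_f, config)
        u = rng_f.uniform(0.0, g1 + s + g2m)
        queue.append((next_id, -1, -u))
        next_id += 1

    while queue:
        cell_id, parent_id, birth_t = queue.pop(0)
        rng_c = _rng(config.seed, "cycle", cell_id)
        g1, s, g2m = _draw_phase_durations(rng_c, config)
        g1s_t = birth_t + g1
        sg2_t = g1s_t + s
        div_t = sg2_t + g2m

        birth_f = int(round(birth_t / dt))
        g1s_f = int(round(g1s_t / dt))
        sg2_f = int(round(sg2_t / dt))
        div_f = int(round(div_t / dt))

        divides = div_t <= total_min
        usable = (birth_f < g1s_f < sg2_f < div_f) and (div_f - birth_f >= 3)
        completed = divides and birth_f >= 0 and usable
        rows.append({
            "cell_id": cell_id, "parent_id": parent_id,
            "birth_frame": birth_f, "g1s_frame": g1s_f,
            "sg2_frame": sg2_f, "division_frame": div_f if divides else -1,
            "completed": completed, "usable": usable,
        })
        if divides:
            if next_id + 2 > _MAX_CELLS:
                raise RuntimeError("simulation exceeded the cell-count cap")
            queue.append((next_id, cell_id, div_t))
            queue.append((next_id + 1, cell_id, div_t))
            next_id += 2

    cells = pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)
    positions = _simulate_positions(cells, config)
    return LineageTruth(cells=cells, positions=positions,
                        n_frames=n_frames, frame_interval=dt)


def _simulate_positions(cells: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Random-walk motion with pairwise soft repulsion and division placement."""
    h, w = config.image_size
    fw = w * config.pixel_size_um
    fh = h * config.pixel_size_um
    margin = config.nucleus_diameter * config.pixel_size_um / 2.0
    # repulsion equilibrium just under one diameter: keeps the scene packed
    # while guaranteeing overlap never exceeds 30% of a diameter
    min_sep = 0.95 * config.nucleus_diameter * config.pixel_size_um
    n_frames = config.n_frames

    info = {int(r.cell_id): r for r in cells.itertuples()}
    children: dict[int, list[int]] = {}
    for r in cells.itertuples():
        if r.parent_id >= 0:
            children.setdefault(int(r.parent_id), []).append(int(r.cell_id))

    rng_init = _rng(config.seed, "positions-init")
    rng_walk = _rng(config.seed, "positions-walk")

    pos: dict[int, np.ndarray] = {}      # current position of live cells
    out_cell, out_frame, out_x, out_y = [], [], [], []

    def clip(p: np.ndarray) -> np.ndarray:
        q = np.clip(p, [margin, margin], [fw - margin, fh - margin])
        if not np.allclose(q, p):
            logger.debug("centroid clipped to field boundary")
        return q

    for f in range(n_frames):
        # retire cells dividing at this frame, then spawn their daughters
        for cid in sorted(list(pos.keys())):
            r = info[cid]
            if r.division_frame != -1 and f >= r.division_frame:
                mother_p = pos.pop(cid)
                kids = children.get(cid, [])
                theta = rng_walk.uniform(0, 2 * np.pi)
                axis = np.array([np.cos(theta), np.sin(theta)])
                offs = [0.5, -0.5]
                for kid, o in zip(sorted(kids), offs):
                    pos[kid] = clip(mother_p + o * config.division_separation * axis)
        # founders (and any parentless cells) entering the field
        for r in cells.itertuples():
            cid = int(r.cell_id)
            if cid in pos:
                continue
            start = max(r.birth_frame, 0)
            if start == f and r.parent_id == -1:
                pos[cid] = np.array([
                    rng_init.uniform(margin, fw - margin),
                    rng_init.uniform(margin, fh - margin),
                ])
        live = sorted(pos.keys())
        if f > 0:
            steps = rng_walk.normal(0.0, config.motion_sigma, size=(len(live), 2))
            for cid, s in zip(live, steps):
                pos[cid] = clip(pos[cid] + s)
        # two passes of pairwise soft repulsion: nuclei overlap <= 30% diameter
        if live:
            arr = np.array([pos[c] for c in live])
            for _ in range(4):
                diff = arr[None, :, :] - arr[:, None, :]       # j - i
                dist = np.hypot(diff[..., 0], diff[..., 1])
                ii, jj = np.where(np.triu(dist < min_sep, k=1))
                if len(ii) == 0:
                    break
                shift = np.zeros_like(arr)
                for i, j in zip(ii, jj):
                    d = diff[i, j]
                    dd = dist[i, j]
                    if dd < 1e-9:
                        theta = rng_walk.uniform(0, 2 * np.pi)
                        d = np.array([np.cos(theta), np.sin(theta)])
                        dd = 1.0
                    push = (min_sep - dd) / 2.0
                    shift[i] -= d / dd * push
                    shift[j] += d / dd * push
                arr = arr + shift
            for cid, p in zip(live, arr):
                pos[cid] = clip(p)
        for cid in live:
            out_cell.append(cid)
            out_frame.append(f)
            out_x.append(float(pos[cid][0]))
            out_y.append(float(pos[cid][1]))

    positions = pd.DataFrame({
        "cell_id": out_cell, "frame": out_frame,
        "x_um": out_x, "y_um": out_y,
    })
    positions["label"] = positions["cell_id"] + 1
    return positions


# ---------------------------------------------------------------------------
# reporter traces
# ---------------------------------------------------------------------------

def _venus_value(f: int, r, config: SimConfig) -> float:
    dt = config.frame_interval
    lo, hi = config.venus_floor, config.venus_plateau
    g1s = r.g1s_frame
    sg2 = r.sg2_frame
    if f < g1s:
        t = (f - r.birth_frame) * dt
        return lo + (hi - lo) * (1.0 - np.exp(-t / config.venus_rise_tau))
    v_pre = lo + (hi - lo) * (1.0 - np.exp(-((g1s - 1 - r.birth_frame) * dt)
                                           / config.venus_rise_tau))
    if f < sg2:
        decay = 0.5 ** ((f - g1s) * dt / config.venus_decay_halftime)
        return lo + (v_pre - lo) * decay
    return min(hi, lo + config.venus_g2_rise_rate * (f - sg2) * dt)


def _red_value(f: int, r, venus: float, config: SimConfig) -> float:
    dt = config.frame_interval
    if config.construct is Construct.PIP_H2A:
        vnorm = (venus - config.venus_floor) / (
            config.venus_plateau - config.venus_floor)
        val = config.scarlet_baseline - config.scarlet_inverse_coupling * vnorm
        if r.parent_id >= 0 and f == r.birth_frame:
            val += config.scarlet_baseline * (config.scarlet_spike_factor - 1.0)
        return val
    # licensing mode: zero in G1, ramp after onset delay, reset at division
    onset_t = r.g1s_frame * dt + config.cherry_onset_delay
    t = f * dt
    if t <= onset_t:
        return 0.0
    return config.cherry_ramp_rate * (t - onset_t)


def reporter_traces(lineage: LineageTruth, config: SimConfig) -> pd.DataFrame:
    """Noiseless per-cell channel traces at frame resolution.

    Returns a long table with columns cell_id, frame, venus_mean, venus_max,
    red_mean, red_max. Cells flagged unusable (cycle unresolvable at frame
    resolution) are excluded; they remain flagged in ``lineage.cells``.
    """
    last = lineage.n_frames - 1
    rows = []
    for r in lineage.cells.itertuples():
        if not r.usable:
            continue
        end = r.division_frame - 1 if r.division_frame != -1 else last
        end = min(end, last)
        for f in range(max(r.birth_frame, 0), end + 1):
            v = _venus_value(f, r, config)
            red = _red_value(f, r, v, config)
            rows.append((int(r.cell_id), f, v, red))
    df = pd.DataFrame(rows, columns=["cell_id", "frame", "venus_mean", "red_mean"])
    df["venus_max"] = df["venus_mean"] * config.trace_max_factor
    df["red_max"] = df["red_mean"] * config.trace_max_factor
    return df[["cell_id", "frame", "venus_mean", "venus_max",
               "red_mean", "red_max"]]


def apply_trace_noise(traces: pd.DataFrame, config: SimConfig,
                      seed: Optional[int] = None) -> pd.DataFrame:
    """Multiplicative lognormal + additive read noise on every intensity column.

    Trace-level stand-in for full rendering + re-measurement; used where
    rendering whole movies would be needlessly slow.
    """
    rng = _rng(config.seed if seed is None else seed, "trace-noise")
    out = traces.copy()
    for col in ("venus_mean", "venus_max", "red_mean", "red_max"):
        vals = out[col].to_numpy(dtype=float)
        mult = np.exp(rng.normal(0.0, config.noise_mult_sigma, size=len(vals)))
        add = rng.normal(0.0, config.noise_read_sigma, size=len(vals))
        out[col] = np.clip(vals * mult + add, 0.0, None)
    return out


def cycle_trace(lineage: LineageTruth, traces: pd.DataFrame,
                cell_id: int) -> pd.DataFrame:
    """Trace for one completed cycle, spanning birth..division inclusive.

    The division-frame row is taken from the lower-id daughter (which carries
    the mitotic red-channel signature), mirroring what a tracker following
    the mother into the nearer daughter records.
    """
    r = lineage.cells.loc[lineage.cells["cell_id"] == cell_id].iloc[0]
    if not r["completed"]:
        raise ValueError(f"cell {cell_id} did not complete a cycle in the movie")
    own = traces[(traces["cell_id"] == cell_id)
                 & (traces["frame"] < r["division_frame"])]
    kids = lineage.cells[lineage.cells["parent_id"] == cell_id]["cell_id"]
    if len(kids) == 0:
        raise ValueError(f"cell {cell_id} has no recorded daughters")
    kid = int(kids.min())
    kid_row = traces[(traces["cell_id"] == kid)
                     & (traces["frame"] == r["division_frame"])]
    return pd.concat([own, kid_row], ignore_index=True)


def padded_cycle_trace(lineage: LineageTruth, traces: pd.DataFrame,
                       cell_id: int, pad: int = 6) -> pd.DataFrame:
    """Cycle trace with parent/daughter context frames on both sides.

    Mirrors what a tracker following the lineage records around a cycle: up
    to ``pad`` trailing frames of the parent before birth and up to ``pad``
    frames of the lower-id daughter's own trace after division. Both
    cytokinesis spikes are then interior samples, as in a real track.
    """
    r = lineage.cells.loc[lineage.cells["cell_id"] == cell_id].iloc[0]
    core = cycle_trace(lineage, traces, cell_id)
    parts = [core]
    if r["parent_id"] >= 0:
        before = traces[(traces["cell_id"] == r["parent_id"])
                        & (traces["frame"] >= r["birth_frame"] - pad)
                        & (traces["frame"] < r["birth_frame"])]
        parts.insert(0, before)
    kids = lineage.cells[lineage.cells["parent_id"] == cell_id]["cell_id"]
    kid = int(kids.min())
    after = traces[(traces["cell_id"] == kid)
                   & (traces["frame"] > r["division_frame"])
                   & (traces["frame"] <= r["division_frame"] + pad)]
    parts.append(after)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """Rendered movie: two (n_frames, H, W) uint16 channel stacks + truth labels."""
    venus: np.ndarray
    red: np.ndarray
    labels: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval: float = 10.0


def _paint_blob(img: np.ndarray, x: float, y: float, amp: float, sigma: float
                ) -> None:
    h, w = img.shape
    half = int(np.ceil(3 * sigma))
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma ** 2))
    img[y0:y1, x0:x1] += amp * g


def render_movie(lineage: LineageTruth, traces: pd.DataFrame,
                 config: SimConfig) -> FrameStack:
    """Render Gaussian-blob nuclei into 2-channel 16-bit stacks plus labels.

    Blob peak amplitude equals the per-frame mean-trace value; sigma is
    diameter/4. Truth labels paint a disk of the configured diameter at each
    centroid, ties resolved to the nearer centroid. Noise: multiplicative
    lognormal then additive Gaussian read noise, clipped to uint16.
    """
    h, w = config.image_size
    n_frames = lineage.n_frames
    sigma = config.nucleus_diameter / 4.0
    radius = config.nucleus_diameter / 2.0
    rng = _rng(config.seed, "render")

    venus_stack = np.zeros((n_frames, h, w), dtype=np.uint16)
    red_stack = np.zeros((n_frames, h, w), dtype=np.uint16)
    label_stack = np.zeros((n_frames, h, w), dtype=np.uint16)

    tr = traces.set_index(["cell_id", "frame"]).sort_index()
    pos_by_frame = dict(tuple(lineage.positions.groupby("frame")))

    for f in range(n_frames):
        ven = np.full((h, w), float(config.background_level))
        red = np.full((h, w), float(config.background_level))
        dist = np.full((h, w), np.inf)
        lab = np.zeros((h, w), dtype=np.uint16)
        frame_pos = pos_by_frame.get(f)
        if frame_pos is not None:
            for p in frame_pos.itertuples():
                key = (int(p.cell_id), f)
                if key not in tr.index:
                    continue
                row = tr.loc[key]
                x = p.x_um / config.pixel_size_um
                y = p.y_um / config.pixel_size_um
                _paint_blob(ven, x, y, float(row["venus_mean"]), sigma)
                _paint_blob(red, x, y, float(row["red_mean"]), sigma)
                # truth label disk, nearer-centroid tie break
                cx, cy = int(round(x)), int(round(y))
                half = int(np.ceil(radius))
                x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
                y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
                if x0 >= x1 or y0 >= y1:
                    logger.warning("cell %d centroid outside field at frame %d",
                                   p.cell_id, f)
                    continue
                xs = np.arange(x0, x1) - x
                ys = np.arange(y0, y1) - y
                d2 = ys[:, None] ** 2 + xs[None, :] ** 2
                mask = (d2 <= radius ** 2) & (d2 < dist[y0:y1, x0:x1])
                lab[y0:y1, x0:x1][mask] = int(p.label)
                dist[y0:y1, x0:x1][mask] = d2[mask]
        for img, stack in ((ven, venus_stack), (red, red_stack)):
            noisy = img
            if config.noise_mult_sigma > 0:
                noisy = noisy * np.exp(
                    rng.normal(0.0, config.noise_mult_sigma, size=img.shape))
            if config.noise_read_sigma > 0:
                noisy = noisy + rng.normal(0.0, config.noise_read_sigma,
                                           size=img.shape)
            stack[f] = np.clip(noisy, 0, 65535).astype(np.uint16)
        label_stack[f] = lab

    return FrameStack(venus=venus_stack, red=red_stack, labels=label_stack,
                      pixel_size_um=config.pixel_size_um,
                      frame_interval=config.frame_interval)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(lineage: LineageTruth, traces: pd.DataFrame,
                  movie: Optional[FrameStack], config: SimConfig,
                  path: str | Path) -> dict[str, Path]:
    """Write the full synthetic fixture (TIFFs, truth CSVs, config YAML)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    cells = lineage.cells[["cell_id", "parent_id", "birth_frame",
                           "g1s_frame", "sg2_frame", "division_frame"]]
    files["truth_cells"] = path / "truth_cells.csv"
    cells.to_csv(files["truth_cells"], index=False)

    files["truth_positions"] = path / "truth_positions.csv"
    lineage.positions.to_csv(files["truth_positions"], index=False,
                             float_format="%.6f")

    files["traces"] = path / "traces.csv"
    traces.to_csv(files["traces"], index=False, float_format="%.6f")

    files["config"] = path / "sim_config.yaml"
    config.to_yaml(files["config"])

    if movie is not None:
        files["venus"] = path / "venus.tif"
        files["red"] = path / "red.tif"
        files["labels"] = path / "labels.tif"
        tifffile.imwrite(files["venus"], movie.venus, photometric="minisblack")
        tifffile.imwrite(files["red"], movie.red, photometric="minisblack")
        tifffile.imwrite(files["labels"], movie.labels, photometric="minisblack")
    return files


# ---------------------------------------------------------------------------
# snapshot scenes
# ---------------------------------------------------------------------------

def sample_snapshot(config: SimConfig, fractions: dict[str, float], n: int,
                    seed: Optional[int] = None) -> pd.DataFrame:
    """Per-nucleus channel means for a snapshot with a known phase mix.

    ``fractions`` maps {"G1": f1, "S": f2, "G2M": f3} (must sum to 1).
    Returns columns nucleus_id, venus_mean, red_mean, true_class.
    """
    total = sum(fractions.values())
    if not np.isclose(total, 1.0):
        raise ValueError("phase fractions must sum to 1")
    rng = _rng(config.seed if seed is None else seed, "snapshot")
    classes = rng.choice(list(fractions.keys()), size=n,
                         p=[fractions[k] / total for k in fractions])
    hi_v, lo_v = config.venus_plateau, config.venus_floor
    hi_c = config.cherry_ramp_rate * 300.0   # ~5 h into the ramp
    rows = []
    for i, cls in enumerate(classes):
        if cls == "G1":
            v, c = hi_v, 0.0
        elif cls == "S":
            v, c = lo_v, hi_c
        else:  # G2M
            v, c = 0.6 * hi_v, hi_c
        v = max(v * np.exp(rng.normal(0, config.noise_mult_sigma))
                + rng.normal(0, config.noise_read_sigma), 0.0)
        c = max(c * np.exp(rng.normal(0, config.noise_mult_sigma))
                + rng.normal(0, config.noise_read_sigma), 0.0)
        rows.append((i, v, c, cls))
    return pd.DataFrame(rows, columns=["nucleus_id", "venus_mean",
                                       "red_mean", "true_class"])
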