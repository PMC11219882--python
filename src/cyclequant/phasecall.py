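"""Phase-transition calling from reporter traces and snapshot classification.

Rules (operating on percentile-normalized traces, so all calls are invariant
to affine intensity rescaling):

* G1/S — the first frame at which the 3-frame-median-smoothed degron-reporter
  (venus) signal has dropped to half (or less) of its running pre-drop
  maximum.
* S/G2 — the first frame after the lowest maintained level (minimum of the
  rolling median after G1/S) at which the rolling median exceeds that level
  by ``max(0.1 * plateau, 3 * noise_scale)`` and stays above it for three
  consecutive frames.
* Licensing-reporter (cherry) mode — cycle boundaries are rapid (>=50% in
  one frame) cherry drops; cycles starting too close to either end of the
  recording are excluded with a reason rather than mis-called.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

NO_G1S = "NO_G1S"
NO_SG2 = "NO_SG2"
TOO_EARLY = "TOO_EARLY"
TOO_LATE = "TOO_LATE"
NO_END = "NO_END"


@dataclass
class PhaseCalls:
    """Transition frames and derived phase lengths for one full cycle."""
    start_frame: int
    g1s_frame: Optional[int]
    sg2_frame: Optional[int]
    end_frame: int
    g1_h: Optional[float] = None
    s_h: Optional[float] = None
    g2m_h: Optional[float] = None
    total_h: Optional[float] = None
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def normalize_trace(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Percentile normalization to ~[0, 1] plus a noise scale.

    Subtracts the 5th-percentile value and divides by the 95th-5th
    percentile range (a monotone affine map, so ordering is preserved).
    Returns the normalized trace and the median absolute frame-to-frame
    difference of the normalized trace as a noise scale. A constant trace
    maps to zeros with noise 0.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise ValueError("trace too short to normalize (need >= 5 frames)")
    lo, hi = np.percentile(values, [5.0, 95.0])
    span = hi - lo
    if span <= 0:
        return np.zeros_like(values), 0.0
    norm = (values - lo) / span
    noise = float(np.median(np.abs(np.diff(norm))))
    return norm, noise


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def call_g1s(venus: np.ndarray, drop_fraction: float = 0.5,
             smooth_window: int = 3, plateau_min: float = 0.5
             ) -> tuple[Optional[int], float]:
    """First frame where smoothed venus falls to <= (1 - drop) of its plateau.

    The plateau is the running maximum of the smoothed normalized trace, so
    a later G2 re-rise cannot distort the G1 reference. A call requires the
    running maximum to have reached ``plateau_min`` (half the normalized
    range) first — a flat trace never produces a call. Returns
    (frame index into the trace or None, plateau value at the call).
    """
    norm, _ = normalize_trace(venus)
    smoothed = _rolling_median(norm, smooth_window)
    runmax = np.maximum.accumulate(smoothed)
    ok = (runmax >= plateau_min) & (smoothed <= (1.0 - drop_fraction) * runmax)
    hits = np.nonzero(ok)[0]
    if len(hits) == 0:
        return None, float(runmax[-1])
    i = int(hits[0])
    return i, float(runmax[i])


def call_sg2(venus: np.ndarray, g1s_index: int, plateau: float,
             rise_window: int = 3, rise_margin_fraction: float = 0.1,
             rise_noise_factor: float = 3.0, smooth_window: int = 3
             ) -> Optional[int]:
    """First sustained rise above the lowest maintained level after G1/S.

    The lowest maintained level L is the minimum of the rolling median over
    [g1s, end]; the call is the first frame after the argmin where the
    rolling median exceeds L + delta and remains above it for
    ``rise_window`` consecutive frames, with
    delta = max(rise_margin_fraction * plateau, rise_noise_factor * noise).
    Returns a frame index into the trace, or None if no sustained rise.
    """
    norm, noise = normalize_trace(venus)
    if not (0 <= g1s_index < len(norm) - 1):
        return None
    seg = _rolling_median(norm, smooth_window)[g1s_index:]
    level = float(np.min(seg))
    argmin = int(np.argmin(seg))
    delta = max(rise_margin_fraction * plateau, rise_noise_factor * noise)
    above = seg > level + delta
    for i in range(argmin + 1, len(seg) - rise_window + 1):
        if above[i:i + rise_window].all():
            return g1s_index + i
    return None


def phase_lengths(start: int, g1s: int, sg2: int, end: int,
                  frame_interval: float) -> PhaseCalls:
    """Phase lengths in hours from the four boundary frames.

    G1 = g1s - start, S = sg2 - g1s, G2M = end - sg2 (frames x interval);
    the three lengths sum to the total exactly by construction.
    """
    if not (start < g1s < sg2 < end):
        raise ValueError(
            f"phase boundaries must be strictly ordered: "
            f"{start} < {g1s} < {sg2} < {end} fails")
    per_h = frame_interval / 60.0
    return PhaseCalls(
        start_frame=start, g1s_frame=g1s, sg2_frame=sg2, end_frame=end,
        g1_h=(g1s - start) * per_h, s_h=(sg2 - g1s) * per_h,
        g2m_h=(end - sg2) * per_h, total_h=(end - start) * per_h)


def call_cycle(venus: np.ndarray, start_frame: int, frame_interval: float,
               drop_fraction: float = 0.5, rise_window: int = 3,
               rise_margin_fraction: float = 0.1,
               rise_noise_factor: float = 3.0,
               smooth_window: int = 3) -> PhaseCalls:
    """Call both transitions on a venus trace spanning one full cycle.

    ``venus`` covers frames [start, end] of one cytokinesis-bounded cycle;
    ``start_frame`` is the absolute frame of its first sample. Failures are
    recorded as flags, never silently.
    """
    end_frame = start_frame + len(venus) - 1
    calls = PhaseCalls(start_frame=start_frame, g1s_frame=None,
                       sg2_frame=None, end_frame=end_frame)
    g1s_rel, plateau = call_g1s(venus, drop_fraction=drop_fraction,
                                smooth_window=smooth_window)
    if g1s_rel is None:
        calls.flags.append(NO_G1S)
        return calls
    calls.g1s_frame = start_frame + g1s_rel
    sg2_rel = call_sg2(venus, g1s_rel, plateau, rise_window=rise_window,
                       rise_margin_fraction=rise_margin_fraction,
                       rise_noise_factor=rise_noise_factor,
                       smooth_window=smooth_window)
    if sg2_rel is None:
        calls.flags.append(NO_SG2)
        return calls
    calls.sg2_frame = start_frame + sg2_rel
    if not (start_frame < calls.g1s_frame < calls.sg2_frame < end_frame):
        calls.flags.append(NO_SG2)
        return calls
    done = phase_lengths(start_frame, calls.g1s_frame, calls.sg2_frame,
                         end_frame, frame_interval)
    calls.g1_h, calls.s_h = done.g1_h, done.s_h
    calls.g2m_h, calls.total_h = done.g2m_h, done.total_h
    return calls


# ---------------------------------------------------------------------------
# licensing-reporter (cherry) live mode
# ---------------------------------------------------------------------------

def detect_cherry_drops(cherry: np.ndarray, drop_fraction: float = 0.5,
                        floor_fraction: float = 0.2) -> np.ndarray:
    """Frames with a rapid (>= drop_fraction in one frame) cherry decrease.

    Only drops from a substantial level (>= ``floor_fraction`` of the trace
    maximum) count, so noise around zero is ignored.
    """
    cherry = np.asarray(cherry, dtype=float)
    if len(cherry) < 2:
        return np.array([], dtype=int)
    peak = float(cherry.max())
    if peak <= 0:
        return np.array([], dtype=int)
    prev = cherry[:-1]
    cur = cherry[1:]
    hit = (prev >= floor_fraction * peak) & (cur <= (1 - drop_fraction) * prev)
    return (np.nonzero(hit)[0] + 1).astype(int)


@dataclass
class FucciCycleResult:
    calls: Optional[PhaseCalls]
    excluded_reason: Optional[str] = None


def call_fucci_cycle(venus: np.ndarray, cherry: np.ndarray,
                     recording_frames: int, frame_interval: float,
                     start_frame: Optional[int] = None,
                     min_start_offset_h: float = 5.0,
                     min_end_offset_h: float = 20.0,
                     **call_params) -> FucciCycleResult:
    """Call one cycle from aligned venus/cherry traces of a whole recording.

    The cycle starts at the supplied mother-division frame, or at the first
    detected rapid cherry drop. Inclusion windows: the start must be at
    least ``min_start_offset_h`` after the recording start and at least
    ``min_end_offset_h`` before its end; violations are exclusions with a
    reason, not errors. The cycle ends at the next rapid cherry drop.
    """
    venus = np.asarray(venus, dtype=float)
    cherry = np.asarray(cherry, dtype=float)
    if len(venus) != len(cherry):
        raise ValueError("venus and cherry traces must be aligned")
    drops = detect_cherry_drops(cherry)
    if start_frame is None:
        if len(drops) == 0:
            return FucciCycleResult(None, NO_END)
        start_frame = int(drops[0])

    per_h = frame_interval / 60.0
    if start_frame * per_h < min_start_offset_h:
        return FucciCycleResult(None, TOO_EARLY)
    if (recording_frames - 1 - start_frame) * per_h < min_end_offset_h:
        return FucciCycleResult(None, TOO_LATE)

    later = drops[drops > start_frame]
    if len(later) == 0:
        return FucciCycleResult(None, NO_END)
    end_frame = int(later[0])
    calls = call_cycle(venus[start_frame:end_frame + 1], start_frame,
                       frame_interval, **call_params)
    return FucciCycleResult(calls, None)


# ---------------------------------------------------------------------------
# snapshot classification
# ---------------------------------------------------------------------------

SNAPSHOT_CLASSES = ("G1/G0", "S", "G2/M")


def background_model(image: np.ndarray, labels: np.ndarray
                     ) -> tuple[float, float]:
    """(median, MAD) of non-nucleus pixels of one channel image."""
    bg = image[labels == 0].astype(float)
    if bg.size == 0:
        raise ValueError("no background pixels (labels cover the whole frame)")
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med, mad


def classify_snapshot(nuclei: pd.DataFrame,
                      venus_background: tuple[float, float],
                      red_background: tuple[float, float],
                      k: float = 3.0,
                      fold_indeterminate_into_s: bool = False
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify per-nucleus channel means into phase classes and fractions.

    A nucleus is channel-positive iff mean > median + k*MAD of that
    channel's background. venus+/red- -> G1/G0; venus-/red+ -> S;
    venus+/red+ -> G2/M; venus-/red- is indeterminate (the early-S dual-dim
    gap) and reported separately unless folded into S. Fractions are over
    classified nuclei and sum to 1.
    """
    if nuclei.empty:
        return nuclei.assign(phase_class=pd.Series(dtype=object)), {}
    v_med, v_mad = venus_background
    r_med, r_mad = red_background
    v_pos = nuclei["venus_mean"].to_numpy(dtype=float) > v_med + k * v_mad
    r_pos = nuclei["red_mean"].to_numpy(dtype=float) > r_med + k * r_mad
    cls = np.where(v_pos & ~r_pos, "G1/G0",
                   np.where(~v_pos & r_pos, "S",
                            np.where(v_pos & r_pos, "G2/M", "indeterminate")))
    if fold_indeterminate_into_s:
        cls = np.where(cls == "indeterminate", "S", cls)
    out = nuclei.copy()
    out["phase_class"] = cls
    classified = out[out["phase_class"] != "indeterminate"]
    n = len(classified)
    fractions = {c: (float((classified["phase_class"] == c).sum()) / n
                     if n else 0.0)
                 for c in SNAPSHOT_CLASSES}
    fractions["n_classified"] = float(n)
    fractions["n_indeterminate"] = float((out["phase_class"]
                                          == "indeterminate").sum())
    return out, fractions


def calls_table(calls: list[PhaseCalls], ids: Optional[list] = None
                ) -> pd.DataFrame:
    """Flat table of phase calls (flagged cycles included, lengths NaN)."""
    rows = []
    for i, c in enumerate(calls):
        rows.append({
            "cycle_id": ids[i] if ids is not None else i,
            "start_frame": c.start_frame, "g1s_frame": c.g1s_frame,
            "sg2_frame": c.sg2_frame, "end_frame": c.end_frame,
            "G1_h": c.g1_h, "S_h": c.s_h, "G2M_h": c.g2m_h,
            "total_h": c.total_h, "flags": ";".join(c.flags),
        })
    return pd.DataFrame(rows, columns=["cycle_id", "start_frame", "g1s_frame",
                                       "sg2_frame", "end_frame", "G1_h",
                                       "S_h", "G2M_h", "total_h", "flags"])
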