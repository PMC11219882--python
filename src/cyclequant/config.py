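"""Configuration dataclasses for simulation and pipeline runs.

Conventions used throughout the package (the upstream tooling never fixes
them, so they are stated once here):

* coordinates are pixel centers, origin at the top-left corner, ``x``
  rightward and ``y`` downward; physical units are micrometres via
  ``pixel_size_um``;
* frame indices are 0-based;
* a track spanning ``n`` frames has duration ``(n - 1) * frame_interval``
  minutes (closed frame interval).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class Construct(str, enum.Enum):
    """Reporter construct being simulated or analyzed.

    ``PIP_H2A``: degron-tagged mVenus plus a constitutive histone-fused red
    channel (mScarlet) that spikes acutely at mitosis.
    ``PIP_FUCCI``: degron-tagged mVenus plus a licensing-reporter red channel
    (mCherry) that accumulates through S/G2/M and dims rapidly at division.
    """

    PIP_H2A = "PIP_H2A"
    PIP_FUCCI = "PIP_FUCCI"


@dataclass
class SimConfig:
    """All parameters of the synthetic time-lapse generator.

    Phase medians/dispersions parameterize per-phase lognormal duration
    distributions: ``duration = median * exp(sigma * Z)`` with standard
    normal ``Z``, so the configured median is the distribution median
    exactly.
    """

    construct: Construct = Construct.PIP_H2A
    frame_interval: float = 10.0        # minutes
    duration: float = 2880.0            # minutes (48 h)
    image_size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    nucleus_diameter: float = 12.0      # px
    n_founders: int = 30

    # lognormal phase-length model, hours / unitless log-sigma
    phase_medians: dict[str, float] = field(
        default_factory=lambda: {"G1": 8.3, "S": 6.0, "G2M": 2.5}
    )
    phase_dispersions: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.45, "S": 0.12, "G2M": 0.23}
    )

    # mVenus waveform
    venus_plateau: float = 3000.0
    venus_floor: float = 100.0
    venus_rise_tau: float = 30.0        # minutes, G1 re-accumulation
    venus_g2_rise_rate: float = 36.0    # intensity units / minute
    venus_decay_halftime: float = 2.5   # minutes; decay completes within 30 min

    # red channel: constitutive histone mode
    scarlet_baseline: float = 2000.0
    scarlet_spike_factor: float = 2.0
    scarlet_inverse_coupling: float = 500.0

    # red channel: licensing-reporter mode
    cherry_ramp_rate: float = 4.0       # intensity units / minute
    cherry_onset_delay: float = 20.0    # minutes (2 frames at default interval)
    cherry_residual_fraction: float = 0.05

    # motion / geometry
    motion_sigma: float = 0.8           # µm / frame random walk
    division_separation: float = 9.0    # µm between daughter centroids

    # noise / rendering
    noise_read_sigma: float = 30.0
    noise_mult_sigma: float = 0.03
    background_level: float = 200.0
    trace_max_factor: float = 1.6       # per-nucleus max / mean intensity ratio

    # optional per-phase multiplier scenario (e.g. respiration inhibition)
    oligomycin_scenario: Optional[dict[str, float]] = None

    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.construct, str):
            self.construct = Construct(self.construct)
        if isinstance(self.image_size, list):
            self.image_size = tuple(self.image_size)
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def effective_medians(self) -> dict[str, float]:
        """Phase medians with the optional scenario multipliers applied."""
        med = dict(self.phase_medians)
        if self.oligomycin_scenario:
            for phase, mult in self.oligomycin_scenario.items():
                med[phase] = med[phase] * mult
        return med

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0 (degenerate zero-length movie)")
        n_steps = self.duration / self.frame_interval
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("duration must be an integer multiple of frame_interval")
        for name, m in self.phase_medians.items():
            if m <= 0:
                raise ValueError(f"phase median {name} must be > 0")
        for name, s in self.phase_dispersions.items():
            if s < 0:
                raise ValueError(f"phase dispersion {name} must be >= 0")
        if not (self.venus_plateau > self.venus_floor >= 0):
            raise ValueError("require venus_plateau > venus_floor >= 0")
        # decay must fall below 10% of plateau within 30 minutes
        if 0.5 ** (30.0 / self.venus_decay_halftime) >= 0.1:
            raise ValueError(
                "venus_decay_halftime too slow: decay to <10% of plateau "
                "must complete within 30 min"
            )
        n_delay = self.cherry_onset_delay / self.frame_interval
        if not (1.0 - 1e-9 <= n_delay <= 3.0 + 1e-9):
            raise ValueError("cherry_onset_delay must span 1-3 frames")
        if self.n_founders < 0:
            raise ValueError("n_founders must be >= 0")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["construct"] = self.construct.value
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; defaults follow the published protocol."""

    construct: Construct = Construct.PIP_H2A
    frame_interval: float = 10.0        # minutes
    pixel_size_um: float = 1.0
    nucleus_diameter: float = 12.0      # px

    # tracking
    max_link_distance_um: float = 10.0
    # selection
    min_track_minutes: float = 480.0
    slope_threshold: float = 300.0      # |Δ red max| per frame, 16-bit scale
    peak_prominence_factor: float = 3.0  # × MAD of frame-to-frame differences
    peak_max_width_frames: float = 3.0
    min_cycle_minutes: float = 480.0
    # phase calling
    drop_fraction: float = 0.5
    rise_window: int = 3                # frames of sustained exceedance
    rise_margin_fraction: float = 0.1   # of plateau
    rise_noise_factor: float = 3.0
    smooth_window: int = 3
    # inclusion windows for mother-division tracked cycles (licensing mode)
    min_start_offset_h: float = 5.0
    min_end_offset_h: float = 20.0
    # snapshot classification
    snapshot_k: float = 3.0
    fold_indeterminate_into_s: bool = False
    # statistics
    alpha: float = 0.05
    welch: bool = False

    seed: int = 0
    simulate: Optional[SimConfig] = None   # set to run on synthetic input

    def __post_init__(self) -> None:
        if isinstance(self.construct, str):
            self.construct = Construct(self.construct)
        if isinstance(self.simulate, dict):
            self.simulate = SimConfig.from_dict(self.simulate)
        self.validate()

    def validate(self) -> None:
        for name in (
            "frame_interval", "pixel_size_um", "nucleus_diameter",
            "max_link_distance_um", "slope_threshold", "peak_prominence_factor",
            "peak_max_width_frames", "snapshot_k",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must lie in (0, 1)")
        if self.min_track_minutes < 0 or self.min_cycle_minutes < 0:
            raise ValueError("duration bounds must be >= 0")
        if self.rise_window < 1 or self.smooth_window < 1:
            raise ValueError("window sizes must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["construct"] = self.construct.value
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
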