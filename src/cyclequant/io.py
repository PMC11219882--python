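"""TIFF stack and label-movie readers/writers.

All image IO goes through tifffile. Stacks are (frames, H, W) for a single
channel, or (channels, frames, H, W)/(frames, channels, H, W) for 2-channel
input (axis order auto-detected by which axis has length 2). Intensity
stacks must be 16-bit unless conversion is explicitly allowed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


def read_stack(path: str | Path, allow_8bit: bool = False) -> np.ndarray:
    """Read a multi-page TIFF intensity stack as (frames, H, W) uint16.

    A 4D file with one axis of length 2 is returned as
    (2, frames, H, W). 8-bit input is rejected unless ``allow_8bit``,
    in which case it is scaled onto the 16-bit range.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # truncated / non-TIFF input
        raise IOError(f"could not read TIFF stack {path}: {exc}") from exc
    if data.dtype == np.uint8:
        if not allow_8bit:
            raise ValueError(
                f"{path} is 8-bit; expected 16-bit data. Pass allow_8bit=True "
                "to convert (values are scaled by 257 onto the 16-bit range).")
        data = (data.astype(np.uint16)) * 257
    if data.dtype != np.uint16:
        raise ValueError(
            f"{path} has dtype {data.dtype}; expected uint16. Convert the "
            "stack to 16-bit before analysis.")
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim == 4:
        if data.shape[0] == 2:
            pass
        elif data.shape[1] == 2:
            data = np.moveaxis(data, 1, 0)
        else:
            raise ValueError(
                f"{path} is 4D with shape {data.shape}; expected one axis of "
                "length 2 (channels). Split channels into separate files or "
                "reorder axes.")
    elif data.ndim != 3:
        raise ValueError(f"{path} has unsupported dimensionality {data.ndim}")
    return data


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    stack = np.asarray(stack)
    if stack.dtype != np.uint16:
        raise ValueError("intensity stacks are written as uint16")
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def read_labels(path: str | Path) -> np.ndarray:
    """Read an integer label movie as (frames, H, W) int32."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise IOError(f"could not read label TIFF {path}: {exc}") from exc
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path} holds {data.dtype} data; labels must be "
                         "integer-valued")
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path} has unsupported dimensionality {data.ndim}")
    return data.astype(np.int32)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids exceed the 16-bit range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16),
                     photometric="minisblack")
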