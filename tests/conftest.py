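import numpy as np
import pytest

from cyclequant import SimConfig
from cyclequant import simulate as sim


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Small noiseless movie config reused across image-level tests."""
    return SimConfig(n_founders=12, duration=1440, image_size=(256, 256),
                     seed=3, noise_mult_sigma=0.0, noise_read_sigma=0.0)


@pytest.fixture(scope="session")
def small_lineage(small_cfg):
    return sim.sample_lineage(small_cfg)


@pytest.fixture(scope="session")
def small_traces(small_cfg, small_lineage):
    return sim.reporter_traces(small_lineage, small_cfg)


@pytest.fixture(scope="session")
def small_movie(small_cfg, small_lineage, small_traces):
    return sim.render_movie(small_lineage, small_traces, small_cfg)


@pytest.fixture(scope="session")
def trace_cfg() -> SimConfig:
    """Trace-level (never rendered) config with more cycles."""
    return SimConfig(n_founders=20, duration=2160, image_size=(512, 512),
                     seed=7)


@pytest.fixture(scope="session")
def trace_lineage(trace_cfg):
    return sim.sample_lineage(trace_cfg)


@pytest.fixture(scope="session")
def trace_traces(trace_cfg, trace_lineage):
    return sim.reporter_traces(trace_lineage, trace_cfg)


def blob_image(shape, blobs, background=200.0, sigma=3.0):
    """Render Gaussian blobs ((x, y, amplitude)...) onto a background."""
    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for x, y, amp in blobs:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
    return np.clip(img, 0, 65535).astype(np.uint16)
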