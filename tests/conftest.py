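import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hybridpgi.geometry import build_default_setup

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def setup():
    return build_default_setup()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_point_source_cones(source, setup, n, rng,
                            theta_range=(15.0, 55.0)) -> pd.DataFrame:
    """Exact cone events through a point source: apexes uniform in the
    scatter crystals, axes at a random half-angle around the apex->source
    direction (uniform azimuth), so every cone contains the source."""
    boxes = [im.scatter for im in setup.imagers.values()]
    ids = np.array(list(setup.imagers))
    pick = rng.integers(0, len(boxes), n)
    lo = np.array([b.lo for b in boxes])
    hi = np.array([b.hi for b in boxes])
    apex = lo[pick] + rng.random((n, 3)) * (hi[pick] - lo[pick])
    u = np.asarray(source, dtype=float) - apex
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    theta = rng.uniform(np.deg2rad(theta_range[0]),
                        np.deg2rad(theta_range[1]), n)
    h = np.zeros_like(u)
    m = np.abs(u[:, 0]) < 0.9
    h[m, 0] = 1.0
    h[~m, 1] = 1.0
    e1 = np.cross(u, h)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    ax = (np.cos(theta)[:, None] * u
          + np.sin(theta)[:, None] * (np.cos(phi)[:, None] * e1
                                      + np.sin(phi)[:, None] * e2))
    return pd.DataFrame({
        "apex_x": apex[:, 0], "apex_y": apex[:, 1], "apex_z": apex[:, 2],
        "axis_x": ax[:, 0], "axis_y": ax[:, 1], "axis_z": ax[:, 2],
        "half_angle": theta, "e_scatter": 500.0, "e_absorber": 1000.0,
        "imager": ids[pick], "spill_phase": "in",
        "time_ns": np.zeros(n),
    })
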