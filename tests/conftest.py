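import numpy as np
import pytest

from scontrast import Bold4D, MetricMap, contrast_recipe, gen_voxel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_map(values, mask=None, name="test"):
    """3D MetricMap from an array, all-true mask by default."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return MetricMap(values=values, mask=mask, metric_name=name)


def single_voxel_bold(series, tr=2.0):
    """Wrap a 1D series as a one-voxel Bold4D."""
    data = np.asarray(series, dtype=float).reshape(1, 1, 1, -1)
    return Bold4D(data=data, tr=tr, mask=np.ones((1, 1, 1), dtype=bool))


@pytest.fixture
def two_sinusoid_bold():
    """The canonical contrast voxel: amp 1 at 0.05 Hz, 0.5 at 0.15 Hz.

    Exact DFT bins (24 and 72 of 480 s) and midpoint-symmetric phases, so
    the analytic SCM under rv=max is exactly (1/0.5)^2 = 4.
    """
    recipe = contrast_recipe(
        low_amp=1.0, high_amp=0.5, low_freq=0.05, high_freq=0.15, T=240, tr=2.0
    )
    return single_voxel_bold(gen_voxel(recipe, seed=0), tr=2.0)
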