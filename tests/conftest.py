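import numpy as np
import pytest

import spadfuse as sf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """12x12 high-res grid observed by a 4x4 SPAD with moderate defocus."""
    return sf.FusionGeometry(M=12, N=12, m=4, n=4, blur_sigma=2.0)


@pytest.fixture
def identity_geometry():
    """f = 1, no blur, fully active: A is the identity map."""
    return sf.FusionGeometry(
        M=6, N=6, m=6, n=6, blur_sigma=0.0, active_offsets=frozenset({(0, 0)})
    )


def make_lidar_scene(M=12, N=12, tau=6, exposure=5e4):
    """Three-plateau depth scene on a small grid (deterministic)."""
    depth = np.repeat(np.arange(3), N // 3)[None, :].repeat(M, 0)[:, :N] + 1
    return sf.SceneSpec(
        mode="lidar",
        M=M,
        N=N,
        tau=tau,
        bin_width_ps=100.0,
        depth=depth,
        reflectivity=np.ones((M, N)),
        irf_sigma=0.8,
        exposure_scale=exposure,
    )


@pytest.fixture
def lidar_scene():
    return make_lidar_scene()
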