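"""Synthetic scene generation for LIDAR and FLIM sensor-fusion studies.

A :class:`SceneSpec` declares a ground-truth scene; :func:`render_ground_truth`
turns it into a noiseless expected-value transient cube and
:func:`render_measurements` produces the paired sensor measurements:

* ``d`` — the SPAD cube, the forward model ``A_tau`` applied to the truth,
  with Poisson shot noise;
* ``c`` — the CCD image, the *unblurred, unmasked* temporal integral of the
  truth (the CCD has its own focused optical path), also Poisson-noised.

Scene physics:

* LIDAR mode — each pixel returns a Gaussian temporal pulse centred at its
  depth bin (the illumination pulse itself is sub-bin; ``irf_sigma``
  models system jitter), scaled by surface reflectivity.
* FLIM mode — each pixel emits a single-exponential decay with its local
  fluorescence lifetime, convolved with a Gaussian instrument response,
  scaled by fluorophore brightness.

All noise is pure Poisson; SPAD dark counts are folded into
``ambient_rate``.  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import convolve1d

from .forward_model import FusionGeometry, _blur_raw, forward_project_cube
from .reconstruction import temporal_integrate
from .types import HIGH, IntensityImage, TransientCube

__all__ = [
    "SceneSpec",
    "render_ground_truth",
    "add_poisson_noise",
    "render_measurements",
    "preset_scene",
    "preset_scenes",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a ground-truth scene.

    For ``mode="lidar"`` supply ``depth`` (time-bin index per pixel) and
    ``reflectivity``; for ``mode="flim"`` supply ``lifetime_ns`` and
    ``brightness``.  ``exposure_scale`` is the expected total signal count
    in the truth cube (ambient background is added on top of it);
    ``irf_sigma`` is the temporal instrument-response std in bins.
    """

    mode: str
    M: int
    N: int
    tau: int
    bin_width_ps: float
    depth: Optional[np.ndarray] = None
    reflectivity: Optional[np.ndarray] = None
    lifetime_ns: Optional[np.ndarray] = None
    brightness: Optional[np.ndarray] = None
    irf_sigma: float = 1.0
    ambient_rate: float = 0.0
    exposure_scale: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("lidar", "flim"):
            raise ValueError(f"mode must be 'lidar' or 'flim', got {self.mode!r}")
        if self.tau < 1 or self.M < 1 or self.N < 1:
            raise ValueError("M, N, tau must be positive")
        if self.bin_width_ps <= 0 or self.irf_sigma < 0:
            raise ValueError("bin_width_ps must be > 0 and irf_sigma >= 0")
        if self.ambient_rate < 0 or self.exposure_scale <= 0:
            raise ValueError("ambient_rate >= 0 and exposure_scale > 0 required")
        shape = (self.M, self.N)
        if self.mode == "lidar":
            if self.depth is None or self.reflectivity is None:
                raise ValueError("lidar scenes need depth and reflectivity maps")
            depth = np.asarray(self.depth, dtype=int)
            refl = np.asarray(self.reflectivity, dtype=float)
            if depth.shape != shape or refl.shape != shape:
                raise ValueError("depth/reflectivity shapes must be (M, N)")
            if depth.min() < 0 or depth.max() >= self.tau:
                raise ValueError("depth indices must lie in [0, tau)")
            if refl.min() < 0:
                raise ValueError("reflectivity must be nonnegative")
            object.__setattr__(self, "depth", depth)
            object.__setattr__(self, "reflectivity", refl)
        else:
            if self.lifetime_ns is None or self.brightness is None:
                raise ValueError("flim scenes need lifetime and brightness maps")
            lt = np.asarray(self.lifetime_ns, dtype=float)
            br = np.asarray(self.brightness, dtype=float)
            if lt.shape != shape or br.shape != shape:
                raise ValueError("lifetime/brightness shapes must be (M, N)")
            if lt.min() <= 0:
                raise ValueError("lifetimes must be positive")
            if br.min() < 0:
                raise ValueError("brightness must be nonnegative")
            object.__setattr__(self, "lifetime_ns", lt)
            object.__setattr__(self, "brightness", br)

    def with_seed(self, seed: int) -> "SceneSpec":
        return replace(self, seed=seed)


def _irf_kernel(sigma: float) -> np.ndarray:
    radius = max(1, int(np.ceil(4.0 * sigma)))
    taps = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (taps / sigma) ** 2)
    return kernel / kernel.sum()


def render_ground_truth(spec: SceneSpec) -> TransientCube:
    """Noiseless expected-value cube for a scene.

    The signal component is normalized so its total equals
    ``exposure_scale``; ``ambient_rate`` expected background counts per
    voxel are then added uniformly.
    """
    k = np.arange(spec.tau, dtype=float)[:, None, None]
    if spec.mode == "lidar":
        if spec.irf_sigma == 0:
            pulse = (k == spec.depth[None, :, :]).astype(float)
        else:
            pulse = np.exp(-0.5 * ((k - spec.depth[None, :, :]) / spec.irf_sigma) ** 2)
            pulse /= pulse.sum(axis=0, keepdims=True)
        signal = pulse * spec.reflectivity[None, :, :]
    else:
        t_ns = k * spec.bin_width_ps / 1000.0
        signal = np.exp(-t_ns / spec.lifetime_ns[None, :, :])
        if spec.irf_sigma > 0:
            signal = convolve1d(signal, _irf_kernel(spec.irf_sigma), axis=0, mode="constant")
        signal = signal * spec.brightness[None, :, :]
    total = signal.sum()
    if total > 0:
        signal = signal * (spec.exposure_scale / total)
    cube = signal + spec.ambient_rate
    return TransientCube(cube, bin_width=spec.bin_width_ps, grid=HIGH)


def add_poisson_noise(cube: TransientCube, seed: int) -> TransientCube:
    """Independent Poisson draw per voxel; integer-valued, reproducible."""
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(cube.values).astype(float)
    return cube.with_values(noisy)


def render_measurements(
    truth: TransientCube,
    geometry: FusionGeometry,
    seed: int = 0,
    *,
    noise: bool = True,
    share_blur: bool = False,
) -> tuple[TransientCube, IntensityImage]:
    """Simulate the paired (SPAD cube, CCD image) measurement.

    ``d = Poisson(A_tau truth)``; ``c = Poisson(T truth)``.  By default the
    CCD sees the scene through its own focused optics (no blur, no mask);
    ``share_blur=True`` sends the CCD through the defocus blur as well,
    for ablation studies.  SPAD and CCD draws use independent child
    streams of ``seed``.
    """
    if truth.grid != HIGH or truth.spatial_shape != geometry.high_shape:
        raise ValueError("truth cube must live on the geometry's high-res grid")
    d_exp = forward_project_cube(truth, geometry)
    c_vals = temporal_integrate(truth).values
    if share_blur:
        c_vals = np.maximum(_blur_raw(c_vals, geometry), 0.0)
    if noise:
        seq_d, seq_c = np.random.SeedSequence(seed).spawn(2)
        d = TransientCube(
            np.random.default_rng(seq_d).poisson(d_exp.values).astype(float),
            bin_width=d_exp.bin_width,
            grid="low",
        )
        c = IntensityImage(
            np.random.default_rng(seq_c).poisson(c_vals).astype(float), grid=HIGH
        )
        return d, c
    return d_exp, IntensityImage(c_vals, grid=HIGH)


# ---------------------------------------------------------------------------
# Preset scenes

PRESET_NAMES = ("steps", "slant", "letters", "cells")


def _texture(M: int, N: int, amplitude: float = 0.25) -> np.ndarray:
    """Deterministic multiplicative texture so the CCD image carries
    high-frequency structure (what the fusion transfers into the cube)."""
    r = np.arange(M)[:, None]
    c = np.arange(N)[None, :]
    tex = 1.0 + amplitude * np.sin(2 * np.pi * r / 7.0) * np.cos(2 * np.pi * c / 5.0)
    return tex


def _ellipse_mask(M: int, N: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    r = np.arange(M)[:, None]
    c = np.arange(N)[None, :]
    return ((r - cy * M) / (ry * M)) ** 2 + ((c - cx * N) / (rx * N)) ** 2 <= 1.0


def preset_scene(name: str, M: int | None = None, N: int | None = None, tau: int | None = None, seed: int = 0) -> SceneSpec:
    """A named deterministic scene, optionally resized.

    ``steps`` — three depth plateaus with distinct reflectivities
    (cardboard steps); ``slant`` — a linear depth ramp; ``letters`` —
    textured foreground shapes at two distinct depths over a far wall;
    ``cells`` — elliptical cell-like regions of two fluorescence-lifetime
    classes (2 ns and 4 ns) on a dark background.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    if name == "cells":
        M = 48 if M is None else M
        N = 48 if N is None else N
        tau = 75 if tau is None else tau
        lifetime = np.full((M, N), 3.0)
        brightness = np.full((M, N), 0.03)
        blobs = [
            # (cy, cx, ry, rx, lifetime_ns)
            (0.28, 0.30, 0.17, 0.14, 2.0),
            (0.70, 0.68, 0.15, 0.18, 2.0),
            (0.30, 0.72, 0.13, 0.12, 4.0),
            (0.72, 0.26, 0.14, 0.13, 4.0),
        ]
        for cy, cx, ry, rx, lt in blobs:
            mask = _ellipse_mask(M, N, cy, cx, ry, rx)
            lifetime[mask] = lt
            brightness[mask] = 1.0
        brightness *= _texture(M, N, amplitude=0.2)
        return SceneSpec(
            mode="flim",
            M=M,
            N=N,
            tau=tau,
            bin_width_ps=160.0,
            lifetime_ns=lifetime,
            brightness=brightness,
            irf_sigma=1.0,
            ambient_rate=0.0,
            exposure_scale=3e6,
            seed=seed,
        )

    # LIDAR presets
    M = 36 if M is None else M
    N = 36 if N is None else N
    tau = 16 if tau is None else tau
    if name == "steps":
        depth = np.empty((M, N), dtype=int)
        bins = [round(tau * 0.2), round(tau * 0.45), round(tau * 0.7)]
        refl = np.empty((M, N))
        thirds = [slice(0, N // 3), slice(N // 3, 2 * N // 3), slice(2 * N // 3, N)]
        for sl, b, r0 in zip(thirds, bins, (1.0, 0.7, 1.3)):
            depth[:, sl] = b
            refl[:, sl] = r0
    elif name == "slant":
        ramp = np.linspace(2, tau - 3, N)
        depth = np.tile(np.round(ramp).astype(int), (M, 1))
        refl = np.ones((M, N))
    else:  # letters
        depth = np.full((M, N), int(tau * 0.75))
        refl = np.full((M, N), 0.8)
        # blocky "T" in the near plane
        t_rows = slice(int(0.15 * M), int(0.25 * M))
        t_stem_rows = slice(int(0.25 * M), int(0.55 * M))
        t_cols = slice(int(0.10 * N), int(0.40 * N))
        t_stem = slice(int(0.21 * N), int(0.29 * N))
        depth[t_rows, t_cols] = int(tau * 0.2)
        depth[t_stem_rows, t_stem] = int(tau * 0.2)
        refl[t_rows, t_cols] = 1.4
        refl[t_stem_rows, t_stem] = 1.4
        # blocky "L" in the middle plane
        l_col = slice(int(0.60 * N), int(0.68 * N))
        l_rows = slice(int(0.45 * M), int(0.85 * M))
        l_foot_rows = slice(int(0.77 * M), int(0.85 * M))
        l_foot_cols = slice(int(0.60 * N), int(0.88 * N))
        depth[l_rows, l_col] = int(tau * 0.45)
        depth[l_foot_rows, l_foot_cols] = int(tau * 0.45)
        refl[l_rows, l_col] = 1.2
        refl[l_foot_rows, l_foot_cols] = 1.2
    refl = refl * _texture(M, N)
    return SceneSpec(
        mode="lidar",
        M=M,
        N=N,
        tau=tau,
        bin_width_ps=55.0,
        depth=depth,
        reflectivity=refl,
        irf_sigma=1.0,
        ambient_rate=0.0,
        exposure_scale=2e5,
        seed=seed,
    )


def preset_scenes(seed: int = 0) -> dict[str, SceneSpec]:
    """All named presets at their default sizes."""
    return {name: preset_scene(name, seed=seed) for name in PRESET_NAMES}
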