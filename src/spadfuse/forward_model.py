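"""The linear measurement operator A = P . S . B and its adjoint.

A high-resolution frame reaches the SPAD array through three linear stages:

``B`` — Gaussian defocus blur.  The sensor is deliberately placed out of
    focus so that light from every scene point reaches at least one
    photosensitive area despite the array's low fill factor.  ``B`` is a
    separable Gaussian of standard deviation ``blur_sigma`` high-resolution
    (CCD) pixel widths, built from explicit 1-D boundary-aware operator
    matrices so that forward, adjoint and the dense-matrix oracle share one
    definition.  Under the default reflect boundary the kernel matrix is
    exactly symmetric, hence B is self-adjoint.

``S`` — the sparse-sampling mask.  Each low-resolution SPAD pixel covers an
    ``f x f`` block of the high-resolution grid but is photosensitive only
    at the block offsets listed in ``active_offsets``; dead SPAD pixels
    contribute nothing at all.

``P`` — block downsizing.  Each SPAD pixel's output is the *sum* of its
    block (S has already selected the photosensitive sub-pixels, so summing
    preserves photon-count semantics).

``A_tau`` applies A independently to every time bin of a transient cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .types import HIGH, LOW, IntensityImage, TransientCube

__all__ = [
    "FusionGeometry",
    "disc_active_offsets",
    "gaussian_blur",
    "sampling_mask",
    "downsample_sum",
    "upsample_replicate",
    "forward_project_frame",
    "forward_project_cube",
    "adjoint_project_frame",
    "adjoint_project_cube",
    "build_forward_matrix",
]

BOUNDARY_MODES = ("reflect", "constant")

#: Largest high-res pixel count for which an explicit matrix may be built.
MATRIX_GUARD = 10_000


def disc_active_offsets(f: int, radius: float) -> frozenset[tuple[int, int]]:
    """Offsets within a disc of ``radius`` (in high-res pixels) around the
    block centre — models a circular photosensitive area such as a 7 um
    diode on a 50 um pitch."""
    c = (f - 1) / 2.0
    return frozenset(
        (r, q)
        for r in range(f)
        for q in range(f)
        if (r - c) ** 2 + (q - c) ** 2 <= radius**2
    )


@dataclass(frozen=True)
class FusionGeometry:
    """Everything that defines the measurement operator A.

    Parameters
    ----------
    M, N
        High-resolution (CCD) pixel counts, rows and columns.
    m, n
        Low-resolution (SPAD) pixel counts; ``M = f*m`` and ``N = f*n`` for
        a single integer upsampling factor ``f``.
    blur_sigma
        Defocus standard deviation in high-res pixel widths (>= 0).
    active_offsets
        ``(row, col)`` offsets inside each ``f x f`` block that are
        photosensitive.  Default: the single central sub-pixel.
    dead_pixels
        Low-res ``(row, col)`` coordinates whose output is always zero.
    boundary_mode
        Blur edge handling, ``"reflect"`` (default, mass-conserving and
        self-adjoint) or ``"constant"`` (zero padding).
    """

    M: int
    N: int
    m: int
    n: int
    blur_sigma: float = 0.0
    active_offsets: frozenset = field(default=None)  # type: ignore[assignment]
    dead_pixels: frozenset = field(default_factory=frozenset)
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("low-res dimensions must be positive")
        if self.M % self.m or self.N % self.n:
            raise ValueError(
                f"high-res shape ({self.M},{self.N}) must be an integer "
                f"multiple of low-res shape ({self.m},{self.n})"
            )
        if self.M // self.m != self.N // self.n:
            raise ValueError("row and column upsampling factors differ")
        f = self.M // self.m
        offsets = self.active_offsets
        if offsets is None:
            offsets = frozenset({(f // 2, f // 2)})
        offsets = frozenset((int(r), int(c)) for r, c in offsets)
        if not offsets:
            raise ValueError("active_offsets must not be empty")
        for r, c in offsets:
            if not (0 <= r < f and 0 <= c < f):
                raise ValueError(f"active offset {(r, c)} outside [0,{f})^2")
        dead = frozenset((int(r), int(c)) for r, c in self.dead_pixels)
        for r, c in dead:
            if not (0 <= r < self.m and 0 <= c < self.n):
                raise ValueError(f"dead pixel {(r, c)} outside the SPAD grid")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(f"boundary_mode must be one of {BOUNDARY_MODES}")
        object.__setattr__(self, "active_offsets", offsets)
        object.__setattr__(self, "dead_pixels", dead)

    @property
    def f(self) -> int:
        """Integer upsampling factor."""
        return self.M // self.m

    @property
    def high_shape(self) -> tuple[int, int]:
        return (self.M, self.N)

    @property
    def low_shape(self) -> tuple[int, int]:
        return (self.m, self.n)

    def fill_factor(self) -> float:
        """Fraction of the high-res grid that is photosensitive."""
        return float(_mask_array(self).mean())


# ---------------------------------------------------------------------------
# 1-D blur operator matrices

def _reflect_index(j: int, n: int) -> int:
    # scipy-style half-sample symmetric extension: (d c b a | a b c d | d c b a)
    period = 2 * n
    j = j % period
    return j if j < n else period - 1 - j


@lru_cache(maxsize=64)
def _blur_matrix_1d(n: int, sigma: float, mode: str) -> np.ndarray:
    """Dense n x n matrix of a normalized Gaussian (truncated at 4 sigma)
    with the given boundary handling."""
    if sigma == 0:
        return np.eye(n)
    radius = max(1, int(np.ceil(4.0 * sigma)))
    taps = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (taps / sigma) ** 2)
    kernel /= kernel.sum()
    mat = np.zeros((n, n))
    for i in range(n):
        for k, w in zip(taps, kernel):
            j = i + k
            if mode == "reflect":
                mat[i, _reflect_index(j, n)] += w
            elif 0 <= j < n:  # constant: out-of-range taps drop mass
                mat[i, j] += w
    return mat


def _blur_mats(geometry: FusionGeometry) -> tuple[np.ndarray, np.ndarray]:
    return (
        _blur_matrix_1d(geometry.M, float(geometry.blur_sigma), geometry.boundary_mode),
        _blur_matrix_1d(geometry.N, float(geometry.blur_sigma), geometry.boundary_mode),
    )


def _blur_raw(x: np.ndarray, geometry: FusionGeometry, adjoint: bool = False) -> np.ndarray:
    """Apply B (or B^T) to an array of frames with shape (..., M, N)."""
    if geometry.blur_sigma == 0:
        return x
    br, bc = _blur_mats(geometry)
    if adjoint:
        br, bc = br.T, bc.T
    return np.matmul(np.matmul(br, x), bc.T)


@lru_cache(maxsize=64)
def _mask_cached(
    M: int, N: int, m: int, n: int, offsets: frozenset, dead: frozenset
) -> np.ndarray:
    f = M // m
    block = np.zeros((f, f))
    for r, c in offsets:
        block[r, c] = 1.0
    mask = np.tile(block, (m, n))
    for r, c in dead:
        mask[r * f : (r + 1) * f, c * f : (c + 1) * f] = 0.0
    mask.setflags(write=False)
    return mask


def _mask_array(geometry: FusionGeometry) -> np.ndarray:
    return _mask_cached(
        geometry.M,
        geometry.N,
        geometry.m,
        geometry.n,
        geometry.active_offsets,
        geometry.dead_pixels,
    )


def _down_raw(x: np.ndarray, geometry: FusionGeometry) -> np.ndarray:
    m, n, f = geometry.m, geometry.n, geometry.f
    return x.reshape(x.shape[:-2] + (m, f, n, f)).sum(axis=(-3, -1))


def _up_raw(y: np.ndarray, geometry: FusionGeometry) -> np.ndarray:
    f = geometry.f
    return np.repeat(np.repeat(y, f, axis=-2), f, axis=-1)


def _forward_raw(x: np.ndarray, geometry: FusionGeometry) -> np.ndarray:
    """A applied to frames (..., M, N) -> (..., m, n)."""
    return _down_raw(_mask_array(geometry) * _blur_raw(x, geometry), geometry)


def _adjoint_raw(y: np.ndarray, geometry: FusionGeometry) -> np.ndarray:
    """A^T applied to frames (..., m, n) -> (..., M, N)."""
    return _blur_raw(_mask_array(geometry) * _up_raw(y, geometry), geometry, adjoint=True)


# ---------------------------------------------------------------------------
# Public, typed operations

def _require_grid(obj, grid: str, what: str) -> None:
    if obj.grid != grid:
        raise ValueError(f"{what} must be on the {grid!r} grid, got {obj.grid!r}")


def _require_shape(obj, shape: tuple[int, int], what: str) -> None:
    got = obj.values.shape[-2:]
    if got != shape:
        raise ValueError(f"{what} spatial shape {got} does not match geometry {shape}")


def gaussian_blur(image: IntensityImage, geometry: FusionGeometry) -> IntensityImage:
    """Defocus blur B: convolve with a normalized 2-D Gaussian of std
    ``blur_sigma`` high-res pixel widths."""
    _require_grid(image, HIGH, "blur input")
    _require_shape(image, geometry.high_shape, "blur input")
    out = _blur_raw(image.values, geometry)
    return IntensityImage(np.maximum(out, 0.0), grid=HIGH)


def sampling_mask(geometry: FusionGeometry) -> IntensityImage:
    """Sparse-sampling mask S: 1 at photosensitive high-res pixels, with
    dead SPAD pixels' blocks all-zero."""
    return IntensityImage(_mask_array(geometry).copy(), grid=HIGH)


def downsample_sum(image: IntensityImage, geometry: FusionGeometry) -> IntensityImage:
    """Block downsizing P: each low-res pixel is the sum over its f x f
    block; total intensity is conserved exactly."""
    _require_grid(image, HIGH, "downsample input")
    _require_shape(image, geometry.high_shape, "downsample input")
    return IntensityImage(_down_raw(image.values, geometry), grid=LOW)


def upsample_replicate(image: IntensityImage, geometry: FusionGeometry) -> IntensityImage:
    """P^T: replicate each low-res value into its f x f block."""
    _require_grid(image, LOW, "upsample input")
    _require_shape(image, geometry.low_shape, "upsample input")
    return IntensityImage(_up_raw(image.values, geometry), grid=HIGH)


def forward_project_frame(frame: IntensityImage, geometry: FusionGeometry) -> IntensityImage:
    """A = P . S . B applied to one high-res frame."""
    _require_grid(frame, HIGH, "forward input")
    _require_shape(frame, geometry.high_shape, "forward input")
    return IntensityImage(np.maximum(_forward_raw(frame.values, geometry), 0.0), grid=LOW)


def forward_project_cube(cube: TransientCube, geometry: FusionGeometry) -> TransientCube:
    """A_tau: apply A independently to each time bin."""
    _require_grid(cube, HIGH, "forward input")
    _require_shape(cube, geometry.high_shape, "forward input")
    out = np.maximum(_forward_raw(cube.values, geometry), 0.0)
    return TransientCube(out, bin_width=cube.bin_width, grid=LOW)


def adjoint_project_frame(frame: IntensityImage, geometry: FusionGeometry) -> IntensityImage:
    """A^T = B^T . S^T . P^T applied to one low-res frame."""
    _require_grid(frame, LOW, "adjoint input")
    _require_shape(frame, geometry.low_shape, "adjoint input")
    return IntensityImage(np.maximum(_adjoint_raw(frame.values, geometry), 0.0), grid=HIGH)


def adjoint_project_cube(cube: TransientCube, geometry: FusionGeometry) -> TransientCube:
    """A^T applied to each time bin of a low-res cube."""
    _require_grid(cube, LOW, "adjoint input")
    _require_shape(cube, geometry.low_shape, "adjoint input")
    out = np.maximum(_adjoint_raw(cube.values, geometry), 0.0)
    return TransientCube(out, bin_width=cube.bin_width, grid=HIGH)


def build_forward_matrix(geometry: FusionGeometry) -> np.ndarray:
    """Materialize A as an (m*n) x (M*N) dense matrix (testing oracle).

    Vectorization is row-major (C order) within a frame.  Guarded to small
    grids; for cubes, A_tau is block-diagonal with this matrix repeated per
    time bin.
    """
    M, N, m, n = geometry.M, geometry.N, geometry.m, geometry.n
    if M * N > MATRIX_GUARD:
        raise ValueError(
            f"explicit matrix refused: M*N = {M * N} exceeds guard {MATRIX_GUARD}"
        )
    basis = np.zeros((M * N, M, N))
    idx = np.arange(M * N)
    basis[idx, idx // N, idx % N] = 1.0
    cols = _forward_raw(basis, geometry).reshape(M * N, m * n)
    return np.ascontiguousarray(cols.T)
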