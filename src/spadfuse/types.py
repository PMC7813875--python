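"""Core data containers for SPAD/CCD sensor fusion.

Two in-memory objects carry all pixel data through the pipeline:

``IntensityImage``
    A 2-D nonnegative image (photon or camera counts), tagged with the grid
    it lives on — the high-resolution CCD grid or the low-resolution SPAD
    grid.

``TransientCube``
    A time-resolved photon-count volume with axes ``(time bin, row, col)``
    and a time-bin width in picoseconds.  This is the central object: the
    SPAD measurement ``d``, the reconstruction ``i_HR`` and the simulator's
    ground truth are all ``TransientCube`` instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["IntensityImage", "TransientCube", "HIGH", "LOW"]

#: Grid identity tags.
HIGH = "high"
LOW = "low"

_GRIDS = (HIGH, LOW)


def _check_nonnegative(values: np.ndarray, what: str) -> None:
    if values.size and float(values.min()) < 0:
        raise ValueError(f"{what} must be nonnegative (min={values.min()})")


@dataclass(frozen=True)
class IntensityImage:
    """A nonnegative 2-D image on a declared grid.

    Parameters
    ----------
    values
        ``(rows, cols)`` array of nonnegative counts.
    grid
        ``"high"`` for the CCD/reconstruction grid, ``"low"`` for the SPAD
        grid.
    """

    values: np.ndarray
    grid: str = HIGH

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"IntensityImage needs a 2-D array, got shape {values.shape}")
        _check_nonnegative(values, "IntensityImage values")
        if self.grid not in _GRIDS:
            raise ValueError(f"grid must be one of {_GRIDS}, got {self.grid!r}")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total(self) -> float:
        """Total counts in the image."""
        return float(self.values.sum())

    def with_values(self, values: np.ndarray) -> "IntensityImage":
        return replace(self, values=values)


@dataclass(frozen=True)
class TransientCube:
    """A time-resolved photon-count volume.

    Parameters
    ----------
    values
        ``(tau, rows, cols)`` array of nonnegative counts; ``tau`` is the
        number of TCSPC time bins.
    bin_width
        Duration of one time bin in picoseconds.
    grid
        Grid identity, as for :class:`IntensityImage`.
    """

    values: np.ndarray
    bin_width: float = field(default=1.0)
    grid: str = HIGH

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"TransientCube needs a 3-D array, got shape {values.shape}")
        if values.shape[0] < 1:
            raise ValueError("TransientCube needs at least one time bin")
        _check_nonnegative(values, "TransientCube values")
        if not self.bin_width > 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if self.grid not in _GRIDS:
            raise ValueError(f"grid must be one of {_GRIDS}, got {self.grid!r}")
        object.__setattr__(self, "values", values)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def total(self) -> float:
        """Total counts in the cube."""
        return float(self.values.sum())

    def frame(self, k: int) -> IntensityImage:
        """The k-th time bin as an image on the same grid."""
        return IntensityImage(self.values[k], grid=self.grid)

    def with_values(self, values: np.ndarray) -> "TransientCube":
        return replace(self, values=values)
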