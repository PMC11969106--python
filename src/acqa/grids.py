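"""Lattice containers for images, structure masks and dose grids.

All arrays are indexed ``(z, y, x)``: axis 0 runs superior → inferior
(slice index), axis 1 anterior → posterior (rows), axis 2 left → right
(columns).  ``spacing`` and ``origin`` are in millimetres per axis, in the
same ``(z, y, x)`` order, and refer to voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageGrid", "StructureMask", "DoseGrid", "MM3_PER_CM3"]

MM3_PER_CM3 = 1000.0


def _validate_lattice(values: np.ndarray, spacing, origin) -> tuple:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D array, got ndim={values.ndim}")
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must each have 3 components")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacings must be positive, got {spacing}")
    return spacing, origin


@dataclass
class ImageGrid:
    """3-D scalar lattice of Hounsfield units with geometric metadata.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        HU per voxel.  Air is about −1000, water 0, dense bone up to ~3000.
    spacing : (float, float, float)
        Voxel size in mm along (z, y, x).
    origin : (float, float, float)
        Position in mm of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing, self.origin = _validate_lattice(
            self.values, self.spacing, self.origin
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_lattice(self, other) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError("with_values requires the existing lattice shape")
        return replace(self, values=values)


@dataclass
class StructureMask:
    """Boolean lattice aligned with a parent :class:`ImageGrid`.

    ``label`` names the structure's role (body, bolus, target, gap, ...).
    """

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        self.spacing, self.origin = _validate_lattice(
            self.values, self.spacing, self.origin
        )

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_cm3(self) -> float:
        """Structure volume in cm³ (true-voxel count × voxel volume)."""
        return int(np.count_nonzero(self.values)) * self.voxel_volume_mm3 / MM3_PER_CM3

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_lattice(self, other) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray, label: str | None = None) -> "StructureMask":
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError("with_values requires the existing lattice shape")
        return replace(
            self, values=values, label=self.label if label is None else label
        )

    @classmethod
    def like(cls, grid, values: np.ndarray, label: str = "") -> "StructureMask":
        return cls(values=values, spacing=grid.spacing, origin=grid.origin, label=label)


@dataclass
class DoseGrid:
    """3-D dose lattice in Gy, geometrically identical to :class:`ImageGrid`."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing, self.origin = _validate_lattice(
            self.values, self.spacing, self.origin
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def shape(self):
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_lattice(self, other) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("with_values requires the existing lattice shape")
        return replace(self, values=values)
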