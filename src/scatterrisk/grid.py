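"""Regular voxel grids: the universal spatial container.

A :class:`VoxelGrid` is a 3-D scalar field (dose in Gy, mass density in
g/cm^3, a dimensionless uncertainty, or an integer organ label) on a
uniform grid.  Axis order is ``x, y, z`` (index ``[ix, iy, iz]``) and world
coordinates are voxel centers::

    world = origin + (index + 0.5) * spacing        # mm

Grids are written to disk as flat little-endian binary plus a JSON sidecar
describing shape, spacing, origin, dtype and units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["VoxelGrid", "resample_grid", "write_grid", "read_grid"]

_AXIS_ORDER = "xyz"


@dataclass
class VoxelGrid:
    """A scalar field on a regular 3-D grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values.  Must be finite.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm, strictly positive.
    origin : tuple of float
        World position (mm) of the corner of voxel ``(0, 0, 0)``.
    units : str
        Free-text unit declaration ("Gy", "g/cm3", "label", ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = _AXIS_ORDER
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"each dimension must be >= 1, got {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.axis_order != _AXIS_ORDER:
            raise ValueError(f"axis order must be {_AXIS_ORDER!r}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("grid contains non-finite values")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of voxel-center world coordinates."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def world_to_index(self, point: np.ndarray) -> tuple[int, int, int]:
        """Index of the voxel containing a world point (mm)."""
        point = np.asarray(point, dtype=float)
        idx = np.floor((point - np.asarray(self.origin)) / np.asarray(self.spacing))
        idx = idx.astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise ValueError(f"point {point.tolist()} outside grid")
        return tuple(int(i) for i in idx)

    def value_at(self, point: np.ndarray) -> float:
        """Value of the voxel containing a world point."""
        return float(self.values[self.world_to_index(point)])

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "VoxelGrid":
        """New grid with identical geometry and different values."""
        return replace(
            self, values=values, units=self.units if units is None else units
        )


def resample_grid(
    grid: VoxelGrid, new_spacing: tuple[float, float, float], method: str = "average"
) -> VoxelGrid:
    """Downsample a grid by integer factors along each axis.

    ``method="average"`` block-averages (conserves the grid-integrated
    quantity, i.e. sum of value x voxel volume); ``method="nearest"`` picks
    the voxel nearest the block center, and is the only method allowed for
    integer label grids.
    """
    new_spacing = tuple(float(s) for s in new_spacing)
    factors = []
    for ax in range(3):
        f = new_spacing[ax] / grid.spacing[ax]
        fi = round(f)
        if fi < 1 or abs(f - fi) > 1e-9:
            raise ValueError(
                f"new spacing {new_spacing[ax]} is not an integer multiple of "
                f"{grid.spacing[ax]} along axis {ax}"
            )
        if grid.shape[ax] % fi != 0:
            raise ValueError(
                f"grid dimension {grid.shape[ax]} not divisible by factor {fi} "
                f"along axis {ax}"
            )
        factors.append(fi)

    is_label = np.issubdtype(grid.values.dtype, np.integer)
    if method == "average":
        if is_label:
            raise ValueError("averaging applied to a label grid; use method='nearest'")
        nx, ny, nz = (grid.shape[a] // factors[a] for a in range(3))
        blocks = grid.values.reshape(
            nx, factors[0], ny, factors[1], nz, factors[2]
        )
        new_values = blocks.mean(axis=(1, 3, 5))
    elif method == "nearest":
        # voxel nearest the block center: element factors//2 of each block
        off = [f // 2 for f in factors]
        new_values = grid.values[
            off[0] :: factors[0], off[1] :: factors[1], off[2] :: factors[2]
        ].copy()
    else:
        raise ValueError(f"unknown resampling method {method!r}")

    return VoxelGrid(
        values=new_values, spacing=new_spacing, origin=grid.origin, units=grid.units
    )


_DTYPES = {
    "float32": np.dtype("<f4"),
    "float64": np.dtype("<f8"),
    "uint16": np.dtype("<u2"),
    "uint8": np.dtype("u1"),
}


def write_grid(grid: VoxelGrid, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a grid as flat little-endian binary + JSON sidecar.

    Floats are stored as float32 (densities round-trip to <=1e-7 relative),
    integer labels as uint16, masks as uint8.  Returns ``(raw, json)`` paths.
    """
    path_prefix = Path(path_prefix)
    if np.issubdtype(grid.values.dtype, np.integer):
        dtype_name = "uint8" if grid.values.dtype == np.uint8 else "uint16"
    else:
        dtype_name = "float32"
    raw_path = path_prefix.with_suffix(".raw")
    json_path = path_prefix.with_suffix(".json")
    grid.values.astype(_DTYPES[dtype_name]).tofile(raw_path)
    sidecar = {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "axis_order": grid.axis_order,
        "dtype": dtype_name,
        "value_units": grid.units,
        "coordinate_convention": "world = origin + (index + 0.5) * spacing",
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return raw_path, json_path


def read_grid(path_prefix: str | Path) -> VoxelGrid:
    """Read a grid written by :func:`write_grid`."""
    path_prefix = Path(path_prefix)
    sidecar = json.loads(path_prefix.with_suffix(".json").read_text())
    dtype = _DTYPES[sidecar["dtype"]]
    values = np.fromfile(path_prefix.with_suffix(".raw"), dtype=dtype).reshape(
        sidecar["shape"]
    )
    return VoxelGrid(
        values=values,
        spacing=tuple(sidecar["spacing_mm"]),
        origin=tuple(sidecar["origin_mm"]),
        axis_order=sidecar["axis_order"],
        units=sidecar["value_units"],
    )
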