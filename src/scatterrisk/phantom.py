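"""Synthetic segmented voxel phantoms.

A :class:`Phantom` couples a label grid (organ/tissue ids, 0 = exterior
air) with a material table.  Phantoms are built by rasterizing geometric
primitives (ellipsoid, box, cylinder) in list order: later organs
overwrite earlier ones where they overlap, as when painting masks onto a
label map, so every voxel carries exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grid import VoxelGrid, read_grid, write_grid
from .materials import AIR, STANDARD_MATERIALS, Material

__all__ = ["OrganSpec", "PhantomSpec", "Phantom", "build_synthetic_phantom",
           "load_phantom_spec", "save_phantom_spec"]

_SHAPES = ("ellipsoid", "box", "cylinder")


@dataclass
class OrganSpec:
    """One shape primitive in a phantom spec.

    ``half_size_mm`` are semi-axes (ellipsoid), half edge lengths (box) or
    (radius, radius, half-height) for a z-aligned cylinder.
    """

    id: int
    name: str
    shape: str
    center_mm: tuple[float, float, float]
    half_size_mm: tuple[float, float, float]
    material: str | Material = "soft_tissue"

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"organ {self.name!r}: unknown shape {self.shape!r}")
        if self.id <= 0:
            raise ValueError(f"organ {self.name!r}: id must be positive (0 = air)")


@dataclass
class PhantomSpec:
    """Recipe for a synthetic phantom: grid geometry plus organ primitives."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    organs: list[OrganSpec]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = "synthetic"
    seed: int | None = None
    jitter_mm: float = 0.0  # optional random displacement of organ centers

    def __post_init__(self) -> None:
        ids = [o.id for o in self.organs]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate organ ids: {sorted(dup)}")


@dataclass
class Phantom:
    """Segmented voxel phantom: label grid + material table."""

    labels: VoxelGrid
    materials: dict[int, Material]
    organ_names: dict[int, str]
    name: str = "phantom"

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels.values).tolist()) - {0}
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"labels without material: {sorted(missing)}")

    @property
    def organ_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels.values).tolist()) - {0})

    def mask(self, organ_id: int) -> np.ndarray:
        """Boolean mask of one organ (pairwise disjoint by construction)."""
        return self.labels.values == organ_id

    def density_grid(self) -> VoxelGrid:
        """Mass-density grid (g/cm^3); exterior uses air density."""
        dens = np.full(self.labels.shape, AIR.density, dtype=np.float64)
        for oid, mat in self.materials.items():
            dens[self.labels.values == oid] = mat.density
        return self.labels.copy_with(dens, units="g/cm3")

    def organ_centroid(self, organ_id: int) -> np.ndarray:
        """World coordinates (mm) of an organ's voxel centroid."""
        idx = np.argwhere(self.mask(organ_id))
        if idx.size == 0:
            raise ValueError(f"organ {organ_id} has no voxels")
        centers = (idx + 0.5) * np.asarray(self.labels.spacing) + np.asarray(
            self.labels.origin
        )
        return centers.mean(axis=0)

    # -- persistence (internal raw+JSON format + YAML material table) ----

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_grid(self.labels, directory / "labels")
        table = {
            "name": self.name,
            "organs": [
                {
                    "id": oid,
                    "name": self.organ_names.get(oid, f"organ_{oid}"),
                    "material": {
                        "name": mat.name,
                        "density_g_cm3": mat.density,
                        "composition": mat.composition,
                    },
                }
                for oid, mat in sorted(self.materials.items())
            ],
        }
        (directory / "materials.yaml").write_text(yaml.safe_dump(table))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "Phantom":
        directory = Path(directory)
        labels = read_grid(directory / "labels")
        table = yaml.safe_load((directory / "materials.yaml").read_text())
        materials = {}
        names = {}
        for entry in table["organs"]:
            m = entry["material"]
            materials[entry["id"]] = Material(
                m["name"], m["density_g_cm3"], dict(m["composition"])
            )
            names[entry["id"]] = entry["name"]
        return cls(labels=labels, materials=materials, organ_names=names,
                   name=table.get("name", "phantom"))


def _rasterize(organ: OrganSpec, grid: VoxelGrid, center: np.ndarray) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the primitive."""
    x, y, z = grid.voxel_centers()
    u = (x - center[0]) / organ.half_size_mm[0]
    v = (y - center[1]) / organ.half_size_mm[1]
    w = (z - center[2]) / organ.half_size_mm[2]
    if organ.shape == "ellipsoid":
        return u * u + v * v + w * w <= 1.0
    if organ.shape == "box":
        return (np.abs(u) <= 1.0) & (np.abs(v) <= 1.0) & (np.abs(w) <= 1.0)
    # z-aligned cylinder
    return (u * u + v * v <= 1.0) & (np.abs(w) <= 1.0)


def build_synthetic_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a :class:`PhantomSpec` into a :class:`Phantom`.

    Deterministic given (spec, spec.seed).  Later-listed organs overwrite
    earlier ones where primitives overlap.  Raises if any organ ends up
    with zero voxels.
    """
    labels = VoxelGrid(
        values=np.zeros(spec.shape, dtype=np.uint16),
        spacing=spec.spacing_mm,
        origin=spec.origin_mm,
        units="label",
    )
    rng = np.random.default_rng(spec.seed)
    materials: dict[int, Material] = {}
    names: dict[int, str] = {}
    for organ in spec.organs:
        center = np.asarray(organ.center_mm, dtype=float)
        if spec.jitter_mm > 0:
            center = center + rng.normal(0.0, spec.jitter_mm, size=3)
        mask = _rasterize(organ, labels, center)
        labels.values[mask] = organ.id
        mat = (
            organ.material
            if isinstance(organ.material, Material)
            else STANDARD_MATERIALS[organ.material]
        )
        materials[organ.id] = mat
        names[organ.id] = organ.name
    for organ in spec.organs:
        if not np.any(labels.values == organ.id):
            raise ValueError(
                f"organ {organ.name!r} (id {organ.id}) has zero voxels after "
                "rasterization (fully overwritten or outside the grid)"
            )
    return Phantom(labels=labels, materials=materials, organ_names=names,
                   name=spec.name)


# -- YAML round trip for specs -------------------------------------------

def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    doc = {
        "name": spec.name,
        "shape": list(spec.shape),
        "spacing_mm": list(spec.spacing_mm),
        "origin_mm": list(spec.origin_mm),
        "seed": spec.seed,
        "jitter_mm": spec.jitter_mm,
        "organs": [
            {
                "id": o.id,
                "name": o.name,
                "shape": o.shape,
                "center_mm": list(o.center_mm),
                "half_size_mm": list(o.half_size_mm),
                "material": o.material if isinstance(o.material, str) else o.material.name,
            }
            for o in spec.organs
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    organs = [
        OrganSpec(
            id=o["id"],
            name=o["name"],
            shape=o["shape"],
            center_mm=tuple(o["center_mm"]),
            half_size_mm=tuple(o["half_size_mm"]),
            material=o.get("material", "soft_tissue"),
        )
        for o in doc["organs"]
    ]
    return PhantomSpec(
        shape=tuple(doc["shape"]),
        spacing_mm=tuple(doc["spacing_mm"]),
        origin_mm=tuple(doc.get("origin_mm", (0, 0, 0))),
        organs=organs,
        name=doc.get("name", "synthetic"),
        seed=doc.get("seed"),
        jitter_mm=doc.get("jitter_mm", 0.0),
    )
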