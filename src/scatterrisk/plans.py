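"""Beams, treatment plans and transport configuration.

Geometry convention: patient axes x = lateral, y = anterior-posterior,
z = superior-inferior (all mm).  The gantry rotates about z; at gantry
angle g (degrees) the unit vector from the isocenter toward the source is
``(sin g, cos g, 0)`` and the beam axis points the opposite way.  The
rectangular field is defined in the isocenter plane: width w along the
in-plane perpendicular to the beam axis, height h along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .physics import DEFAULT_SPECTRA, Spectrum, monoenergetic_spectrum

__all__ = ["Beam", "Plan", "TransportConfig", "load_plan", "save_plan"]


@dataclass
class Beam:
    """One rectangular treatment beam."""

    energy_label: str = "6MV"
    gantry_deg: float = 0.0
    isocenter_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    field_size_mm: tuple[float, float] = (100.0, 100.0)  # (w in-plane, h along z)
    sad_mm: float = 1000.0
    weight: float = 1.0
    spectrum: Spectrum | None = None  # None -> DEFAULT_SPECTRA[energy_label]
    name: str = ""

    def __post_init__(self) -> None:
        if self.field_size_mm[0] <= 0 or self.field_size_mm[1] <= 0:
            raise ValueError("field size must be > 0")
        if self.sad_mm <= 0:
            raise ValueError("SAD must be > 0")
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")
        if self.spectrum is None:
            if self.energy_label in DEFAULT_SPECTRA:
                self.spectrum = DEFAULT_SPECTRA[self.energy_label]
            elif self.energy_label.endswith("MeV"):
                # monoenergetic mode for oracle tests, e.g. "1.0MeV"
                self.spectrum = monoenergetic_spectrum(float(self.energy_label[:-3]))
            else:
                raise ValueError(
                    f"no spectrum for energy label {self.energy_label!r}; "
                    "pass spectrum= explicitly"
                )

    # -- geometry --------------------------------------------------------

    @property
    def toward_source(self) -> np.ndarray:
        g = np.deg2rad(self.gantry_deg)
        return np.array([np.sin(g), np.cos(g), 0.0])

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the beam axis (source -> isocenter)."""
        return -self.toward_source

    @property
    def source_position_mm(self) -> np.ndarray:
        return np.asarray(self.isocenter_mm, dtype=float) + self.sad_mm * self.toward_source

    @property
    def field_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane unit vectors spanning the field at the isocenter."""
        g = np.deg2rad(self.gantry_deg)
        a = np.array([np.cos(g), -np.sin(g), 0.0])  # width axis
        b = np.array([0.0, 0.0, 1.0])  # height axis (superior-inferior)
        return a, b

    def beam_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Project world points into beam coordinates.

        Returns ``(u, v, zeta)``: lateral offsets in the isocenter plane
        (back-projected along the divergence) and depth coordinate zeta =
        distance along the beam axis past the isocenter (negative =
        upstream).
        """
        p = np.asarray(points, dtype=float) - np.asarray(self.isocenter_mm)
        d = self.direction
        a, b = self.field_axes
        zeta = p @ d
        scale = self.sad_mm / np.maximum(self.sad_mm + zeta, 1e-6)
        u = (p @ a) * scale
        v = (p @ b) * scale
        return u, v, zeta

    def distance_to_field_edge(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) from the projected point to the field rectangle.

        Zero inside the field; Euclidean distance to the rectangle outside,
        measured in the isocenter plane.
        """
        u, v, _ = self.beam_coords(points)
        w, h = self.field_size_mm
        du = np.maximum(np.abs(u) - w / 2.0, 0.0)
        dv = np.maximum(np.abs(v) - h / 2.0, 0.0)
        return np.hypot(du, dv)


@dataclass
class Plan:
    """A treatment plan: beams, prescription and specification point(s)."""

    beams: list[Beam]
    prescription_gy: float = 50.0
    fractions: int = 25
    specification_point_mm: tuple[float, float, float] | None = None
    beam_spec_points_mm: list[tuple[float, float, float]] | None = None
    beam_shares: list[float] | None = None  # prescription share per beam
    name: str = "plan"

    def __post_init__(self) -> None:
        if self.fractions < 1:
            raise ValueError("fractions must be >= 1")
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be > 0")
        if not self.beams:
            raise ValueError("plan needs at least one beam")
        if self.beam_shares is not None and len(self.beam_shares) != len(self.beams):
            raise ValueError("beam_shares length must match beams")

    def spec_point_for_beam(self, i: int) -> np.ndarray:
        if self.beam_spec_points_mm is not None:
            return np.asarray(self.beam_spec_points_mm[i], dtype=float)
        if self.specification_point_mm is not None:
            return np.asarray(self.specification_point_mm, dtype=float)
        return np.asarray(self.beams[i].isocenter_mm, dtype=float)

    def shares(self) -> np.ndarray:
        """Prescription share per beam (default: equal split)."""
        if self.beam_shares is not None:
            s = np.asarray(self.beam_shares, dtype=float)
        else:
            s = np.ones(len(self.beams))
        return s / s.sum()


@dataclass
class TransportConfig:
    """Monte Carlo transport settings (desk-scale defaults)."""

    histories: int = 200_000
    batches: int = 10
    photon_cutoff_kev: float = 10.0
    kerma_approximation: bool = True  # secondary electrons deposited locally
    seed: int | None = None
    track_primaries: bool = False  # record first-interaction depths

    def __post_init__(self) -> None:
        if self.photon_cutoff_kev <= 0:
            raise ValueError("photon cutoff must be > 0")
        if self.batches < 2 or self.histories < self.batches:
            raise ValueError("need histories >= batches >= 2")


# -- YAML plan IO ---------------------------------------------------------

def save_plan(plan: Plan, path: str | Path) -> None:
    doc = {
        "name": plan.name,
        "prescription_gy": plan.prescription_gy,
        "fractions": plan.fractions,
        "specification_point_mm": (
            list(plan.specification_point_mm)
            if plan.specification_point_mm is not None
            else None
        ),
        "beam_shares": list(plan.beam_shares) if plan.beam_shares else None,
        "beams": [
            {
                "name": b.name,
                "energy_label": b.energy_label,
                "gantry_deg": b.gantry_deg,
                "isocenter_mm": list(b.isocenter_mm),
                "field_size_mm": list(b.field_size_mm),
                "sad_mm": b.sad_mm,
                "weight": b.weight,
            }
            for b in plan.beams
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_plan(path: str | Path) -> Plan:
    doc = yaml.safe_load(Path(path).read_text())
    beams = [
        Beam(
            name=b.get("name", ""),
            energy_label=b.get("energy_label", "6MV"),
            gantry_deg=b.get("gantry_deg", 0.0),
            isocenter_mm=tuple(b["isocenter_mm"]),
            field_size_mm=tuple(b.get("field_size_mm", (100.0, 100.0))),
            sad_mm=b.get("sad_mm", 1000.0),
            weight=b.get("weight", 1.0),
        )
        for b in doc["beams"]
    ]
    spec_pt = doc.get("specification_point_mm")
    return Plan(
        beams=beams,
        prescription_gy=doc.get("prescription_gy", 50.0),
        fractions=doc.get("fractions", 25),
        specification_point_mm=tuple(spec_pt) if spec_pt else None,
        beam_shares=doc.get("beam_shares"),
        name=doc.get("name", "plan"),
    )
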