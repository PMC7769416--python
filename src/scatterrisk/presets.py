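"""Shipped default study setup: a simplified female torso phantom and
tangential / nodal breast plans.

The phantom is a desk-scale stand-in for a segmented whole-body reference
model: an elliptical soft-tissue trunk with head-to-pelvis extent and
shape-primitive organs at anatomically ordered axial positions (thyroid
superior, breasts/lungs/heart mid-thorax, stomach/liver upper abdomen,
intestine, bladder/uterus/ovaries pelvic).  Axes: x lateral (+x = patient
left), y anterior-posterior (+y = posterior), z inferior-to-superior.

Plans mirror conventional breast radiotherapy: opposed tangential fields
prescribed 50 Gy in 25 fractions to the breast (whole-breast plan), with
an optional pair of opposed superior nodal fields covering the
subclavicular/internal-mammary region (nodal plan).
"""

from __future__ import annotations

from .phantom import OrganSpec, PhantomSpec
from .plans import Beam, Plan

__all__ = [
    "female_torso_spec",
    "wbrt_plan",
    "wbrt_rnrt_plan",
    "DEFAULT_SITE_MAP",
    "BREAST_CENTER_MM",
    "NODAL_CENTER_MM",
]

# organ ids
BODY, THYROID, LEFT_LUNG, RIGHT_LUNG, HEART, ESOPHAGUS, STOMACH, LIVER, \
    INTESTINE, BLADDER, UTERUS, OVARIES, TARGET_BREAST, CONTRA_BREAST = range(1, 15)

BREAST_CENTER_MM = (170.0, 36.0, 300.0)
NODAL_CENTER_MM = (130.0, 60.0, 392.0)


def female_torso_spec(spacing_mm: float = 4.0) -> PhantomSpec:
    """Simplified segmented torso (left-sided target breast).

    With the default 4 mm spacing the grid is 56 x 36 x 110 voxels
    (224 x 144 x 440 mm).  Organs are listed trunk-first so that interior
    organs paint over it; the breasts are last so they are never
    overwritten.
    """
    s = spacing_mm
    shape = (int(224 / s), int(144 / s), int(440 / s))
    organs = [
        OrganSpec(BODY, "body", "ellipsoid", (112, 72, 220), (100, 65, 230),
                  "soft_tissue"),
        OrganSpec(LEFT_LUNG, "ipsilateral lung", "ellipsoid", (152, 78, 310),
                  (38, 40, 78), "lung"),
        OrganSpec(RIGHT_LUNG, "contralateral lung", "ellipsoid", (72, 78, 310),
                  (38, 40, 78), "lung"),
        OrganSpec(HEART, "heart", "ellipsoid", (98, 78, 288), (33, 30, 33),
                  "muscle"),
        OrganSpec(ESOPHAGUS, "esophagus", "cylinder", (112, 92, 340), (8, 8, 60),
                  "soft_tissue"),
        OrganSpec(THYROID, "thyroid", "ellipsoid", (112, 56, 400), (16, 12, 12),
                  "soft_tissue"),
        OrganSpec(STOMACH, "stomach", "ellipsoid", (86, 76, 228), (34, 27, 25),
                  "soft_tissue"),
        OrganSpec(LIVER, "liver", "ellipsoid", (140, 76, 232), (52, 38, 34),
                  "soft_tissue"),
        OrganSpec(INTESTINE, "large intestine", "ellipsoid", (112, 74, 158),
                  (68, 38, 30), "soft_tissue"),
        OrganSpec(BLADDER, "bladder", "ellipsoid", (112, 66, 58), (24, 24, 20),
                  "soft_tissue"),
        OrganSpec(UTERUS, "uterus", "ellipsoid", (112, 92, 80), (20, 18, 15),
                  "soft_tissue"),
        OrganSpec(OVARIES, "ovaries", "ellipsoid", (112, 80, 96), (30, 10, 8),
                  "soft_tissue"),
        OrganSpec(TARGET_BREAST, "target breast", "ellipsoid", BREAST_CENTER_MM,
                  (40, 32, 40), "breast"),
        OrganSpec(CONTRA_BREAST, "contralateral breast", "ellipsoid",
                  (54, 36, 300), (40, 32, 40), "breast"),
    ]
    return PhantomSpec(
        shape=shape,
        spacing_mm=(s, s, s),
        organs=organs,
        name="female_torso",
    )


def wbrt_plan(prescription_gy: float = 50.0) -> Plan:
    """Whole-breast plan: opposed tangential fields on the target breast."""
    field = (70.0, 100.0)
    beams = [
        Beam(name="tangential_med", energy_label="6MV", gantry_deg=45.0,
             isocenter_mm=BREAST_CENTER_MM, field_size_mm=field),
        Beam(name="tangential_lat", energy_label="6MV", gantry_deg=225.0,
             isocenter_mm=BREAST_CENTER_MM, field_size_mm=field),
    ]
    return Plan(
        beams=beams,
        prescription_gy=prescription_gy,
        fractions=25,
        specification_point_mm=BREAST_CENTER_MM,
        name="wbrt",
    )


def wbrt_rnrt_plan(prescription_gy: float = 50.0) -> Plan:
    """Whole-breast plan plus opposed superior regional-nodal fields.

    Two 50 Gy courses are delivered: ``prescription_gy`` to the breast via
    the tangentials and the same dose to the nodal region via the nodal
    fields, so the plan's total prescription is twice ``prescription_gy``
    split equally over the four beams.
    """
    base = wbrt_plan(prescription_gy)
    nodal = [
        Beam(name="nodal_ant", energy_label="6MV", gantry_deg=0.0,
             isocenter_mm=NODAL_CENTER_MM, field_size_mm=(70.0, 55.0)),
        Beam(name="nodal_post", energy_label="6MV", gantry_deg=180.0,
             isocenter_mm=NODAL_CENTER_MM, field_size_mm=(70.0, 55.0)),
    ]
    return Plan(
        beams=base.beams + nodal,
        prescription_gy=2.0 * prescription_gy,
        fractions=25,
        beam_spec_points_mm=[BREAST_CENTER_MM, BREAST_CENTER_MM,
                             NODAL_CENTER_MM, NODAL_CENTER_MM],
        name="wbrt_rnrt",
    )


#: Phantom organ name -> risk-coefficient site name.
DEFAULT_SITE_MAP: dict[str, str] = {
    "target breast": "breast",
    "contralateral breast": "breast",
    "ipsilateral lung": "lung",
    "contralateral lung": "lung",
    "large intestine": "colon",
    "thyroid": "thyroid",
    "stomach": "stomach",
    "liver": "liver",
    "esophagus": "esophagus",
    "bladder": "bladder",
    "uterus": "uterus",
    "ovaries": "ovary",
}
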