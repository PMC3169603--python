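"""Coordinate conventions and reference-frame transforms for visual-field locations.

All angles follow the mathematical convention: 0 deg points East (rightward on
the screen), positive angles run counterclockwise, and stored angles live in
[0, 360).  Distances are degrees of visual angle (dva).  Compass tags name the
eight canonical directions of an isoeccentric stimulus ring: the four cardinal
points (N, E, S, W) and the four 45-degree intercardinals.

The module also provides the displacement table that underlies the
fixation-shift prediction maps: the retinal eccentricity of every target on
the main 6-degree ring after the fixation dot is displaced 4 degrees toward a
cardinal direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Polar angle (deg) of each canonical compass direction.
COMPASS_ANGLES: dict[str, float] = {
    "E": 0.0,
    "NE": 45.0,
    "N": 90.0,
    "NW": 135.0,
    "W": 180.0,
    "SW": 225.0,
    "S": 270.0,
    "SE": 315.0,
}

#: Canonical tags ordered by increasing polar angle.
CANONICAL_BY_ANGLE: tuple[str, ...] = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")

#: Column order of displacement tables (clockwise from North).
TABLE_LOCATIONS: tuple[str, ...] = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

#: Row order of fixation shifts in displacement tables.
TABLE_SHIFTS: tuple[str, ...] = ("E", "W", "N", "S")

#: Head roll of the tilted posture, CCW-positive as seen by the observer.
#: This roll carries retinal East onto screen North-East, retinal South onto
#: screen South-East -- the operational definition of the tilted condition.
TILTED_HEAD_ROLL_DEG = 45.0

#: Radius (dva) of the main isoeccentric stimulus ring.
MAIN_RING_ECC_DEG = 6.0

#: Magnitude (dva) of the cardinal fixation displacements.
FIXATION_SHIFT_DEG = 4.0

#: Ring radii (dva) of the baseline sessions: five rings probe retinotopic
#: predictions, the 6-degree ring probes head-centric predictions.
RING_ECCENTRICITIES: tuple[float, ...] = (2.0, 4.25, 6.0, 7.21, 9.27, 10.0)

_CANONICAL_TOL_DEG = 1e-6


@dataclass(frozen=True)
class PlanarPoint:
    """A point in the fronto-parallel plane, in dva.

    ``x`` grows to the East (screen right), ``y`` to the North (screen up).
    The origin is contextual: screen/head center for stimulus layouts, the
    current fixation for retinal coordinates.
    """

    x: float
    y: float

    @property
    def norm(self) -> float:
        return math.hypot(self.x, self.y)

    def __sub__(self, other: "PlanarPoint") -> "PlanarPoint":
        return PlanarPoint(self.x - other.x, self.y - other.y)

    def __add__(self, other: "PlanarPoint") -> "PlanarPoint":
        return PlanarPoint(self.x + other.x, self.y + other.y)


ORIGIN = PlanarPoint(0.0, 0.0)


@dataclass(frozen=True)
class FieldLocation:
    """A position in the 2-D visual field.

    ``label`` is a canonical compass tag or ``"custom"``; ``angle_deg`` is the
    polar angle in [0, 360); ``eccentricity_deg`` the radial distance (dva).
    """

    label: str
    angle_deg: float
    eccentricity_deg: float

    def __post_init__(self) -> None:
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity must be non-negative")
        if self.label != "custom" and self.label not in COMPASS_ANGLES:
            raise ValueError(f"unknown compass label {self.label!r}")

    @classmethod
    def compass(cls, label: str, eccentricity_deg: float) -> "FieldLocation":
        """Canonical location from a compass tag."""
        return cls(label, COMPASS_ANGLES[label], eccentricity_deg)

    @classmethod
    def polar(cls, angle_deg: float, eccentricity_deg: float) -> "FieldLocation":
        """Location from polar coordinates; labels exact canonical angles."""
        angle = angle_deg % 360.0
        return cls(_label_for_angle(angle), angle, eccentricity_deg)


def _label_for_angle(angle_deg: float) -> str:
    """Canonical tag when the angle sits (within tolerance) on a 45-deg multiple."""
    nearest = round(angle_deg / 45.0) * 45.0
    if abs(angle_deg - nearest) <= _CANONICAL_TOL_DEG or abs(
        angle_deg - nearest
    ) >= 360.0 - _CANONICAL_TOL_DEG:
        return CANONICAL_BY_ANGLE[int(round(angle_deg / 45.0)) % 8]
    return "custom"


@dataclass(frozen=True)
class FrameConfig:
    """Reference-frame parameters of one viewing condition.

    ``head_roll_deg``: signed roll of the head about the line of sight,
    CCW-positive in screen view, in (-180, 180].  ``fixation_offset``: position
    of the fixation dot relative to screen/head center.  ``display_tilt_deg``:
    reference orientation of the distractor array.
    """

    head_roll_deg: float = 0.0
    fixation_offset: PlanarPoint = ORIGIN
    display_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (-180.0 < self.head_roll_deg <= 180.0):
            raise ValueError("head_roll_deg must lie in (-180, 180]")


def to_cartesian(loc: FieldLocation) -> PlanarPoint:
    """Cartesian coordinates (dva) of a field location."""
    a = math.radians(loc.angle_deg)
    return PlanarPoint(
        loc.eccentricity_deg * math.cos(a), loc.eccentricity_deg * math.sin(a)
    )


def from_cartesian(p: PlanarPoint) -> FieldLocation:
    """Inverse of :func:`to_cartesian`.

    The zero vector maps to angle 0 with label ``"custom"``.
    """
    ecc = p.norm
    if ecc == 0.0:
        return FieldLocation("custom", 0.0, 0.0)
    angle = math.degrees(math.atan2(p.y, p.x)) % 360.0
    return FieldLocation(_label_for_angle(angle), angle, ecc)


def apply_head_roll(loc_retinal: FieldLocation, head_roll_deg: float) -> FieldLocation:
    """Screen location of a direction fixed on the retina under a head roll.

    Rotates the location vector by ``head_roll_deg`` counterclockwise; under
    the tilted posture (:data:`TILTED_HEAD_ROLL_DEG`) retinal E maps to screen
    NE and retinal S to screen SE.
    """
    angle = (loc_retinal.angle_deg + head_roll_deg) % 360.0
    return FieldLocation(_label_for_angle(angle), angle, loc_retinal.eccentricity_deg)


def retinal_displacement(
    target: FieldLocation, fixation_offset: PlanarPoint
) -> tuple[float, float]:
    """(eccentricity, angle) of a screen target relative to a displaced fixation.

    ``target`` is given in screen/head-centered coordinates; the return value
    is the polar form of the vector from the fixation dot to the target.  The
    angle of a target coincident with fixation is 0 by convention.
    """
    v = to_cartesian(target) - fixation_offset
    ecc = v.norm
    angle = 0.0 if ecc == 0.0 else math.degrees(math.atan2(v.y, v.x)) % 360.0
    return ecc, angle


def snap_to_canonical(angle_deg: float) -> str:
    """Canonical compass tag nearest to an angle (mod 360).

    Exact midpoints (22.5 deg from two canonicals) break counterclockwise,
    i.e. toward the larger angle.
    """
    d = (angle_deg % 360.0) / 45.0
    lower = math.floor(d)
    frac = d - lower
    if frac > 0.5 or abs(frac - 0.5) <= 1e-9 / 45.0:
        idx = lower + 1
    else:
        idx = lower
    return CANONICAL_BY_ANGLE[int(idx) % 8]


def _round_half_up_2(x: float) -> float:
    return math.floor(x * 100.0 + 0.5) / 100.0


def table1(
    ring_ecc_deg: float = MAIN_RING_ECC_DEG,
    shift_deg: float = FIXATION_SHIFT_DEG,
) -> pd.DataFrame:
    """Retinal eccentricity of each ring target under each cardinal fixation shift.

    Rows are fixation shifts (E, W, N, S), columns the eight target locations;
    each cell is the distance (dva) from the displaced fixation dot to the
    target, computed from first principles and rounded half-up to 2 decimals.
    """
    data = np.empty((len(TABLE_SHIFTS), len(TABLE_LOCATIONS)))
    for i, shift in enumerate(TABLE_SHIFTS):
        offset = to_cartesian(FieldLocation.compass(shift, shift_deg))
        for j, loc in enumerate(TABLE_LOCATIONS):
            ecc, _ = retinal_displacement(FieldLocation.compass(loc, ring_ecc_deg), offset)
            data[i, j] = _round_half_up_2(ecc)
    return pd.DataFrame(data, index=list(TABLE_SHIFTS), columns=list(TABLE_LOCATIONS))


def shift_offset(shift: str, shift_deg: float = FIXATION_SHIFT_DEG) -> PlanarPoint:
    """Fixation-offset vector for a cardinal shift tag; ``"none"`` is the origin."""
    if shift == "none":
        return ORIGIN
    return to_cartesian(FieldLocation.compass(shift, shift_deg))
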