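"""Vector algebra of astigmatism via Naeser polar values.

A cylinder is a *net astigmatism* ``M @ alpha``: magnitude M (dioptres,
M >= 0) at the steep meridian alpha (degrees, half-open interval [0, 180)).
About a reference meridian ``phi`` it decomposes into two orthogonal polar
values,

    KP(phi)      = M * cos(2 * (alpha - phi))
    KP(phi + 45) = M * sin(2 * (alpha - phi))

which live in double-angle space, where cylinders add linearly.  KP(phi) is
positive for steep meridians near phi and negative near phi + 90;
KP(phi + 45) is positive for counter-clockwise rotation relative to phi.

The difference in astigmatism (DA) between refractive astigmatism (RA) and a
corneal astigmatism (CA) measurement is taken componentwise about the
*variable* reference meridian phi = the steep CA meridian of that eye and
modality, so that KP(phi)_CA = M_CA and KP(phi+45)_CA = 0 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "NetAstigmatism",
    "PolarValues",
    "DAResult",
    "AxisClass",
    "net_to_polar",
    "polar_to_net",
    "compute_da",
    "classify_axis",
    "radius_to_power",
    "normalize_meridian",
    "KERATOMETRIC_INDEX",
]

#: Standard keratometric refractive index used to convert anterior corneal
#: radius to total corneal power.
KERATOMETRIC_INDEX = 1.3375

_TOL = 1e-9


def normalize_meridian(deg: float) -> float:
    """Map an angle in degrees onto the clinical meridian range [0, 180)."""
    m = math.fmod(deg, 180.0)
    if m < 0.0:
        m += 180.0
    # fmod can return 180.0 - eps rounding artefacts; exact 180 wraps to 0
    return 0.0 if m == 180.0 else m


@dataclass(frozen=True)
class NetAstigmatism:
    """A cylinder as magnitude ``M`` (D, >= 0) at steep meridian ``alpha``.

    A zero-magnitude cylinder carries meridian 0 by convention (its direction
    is undefined).
    """

    magnitude: float
    meridian: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude) or self.magnitude < 0.0:
            raise ValueError(f"magnitude must be finite and >= 0, got {self.magnitude}")
        if not math.isfinite(self.meridian) or not (0.0 <= self.meridian < 180.0):
            raise ValueError(
                f"meridian must lie in [0, 180), got {self.meridian}; "
                "use normalize_meridian() first"
            )
        if self.magnitude == 0.0 and self.meridian != 0.0:
            object.__setattr__(self, "meridian", 0.0)

    def rotated(self, offset_deg: float) -> "NetAstigmatism":
        """The same cylinder with its meridian rotated by ``offset_deg``."""
        if self.magnitude == 0.0:
            return self
        return NetAstigmatism(self.magnitude, normalize_meridian(self.meridian + offset_deg))


@dataclass(frozen=True)
class PolarValues:
    """Polar values ``KP(phi)`` and ``KP(phi+45)`` about reference ``phi``."""

    kp_phi: float
    kp_phi45: float
    reference: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.reference < 180.0):
            raise ValueError(f"reference meridian must lie in [0, 180), got {self.reference}")

    @property
    def magnitude(self) -> float:
        return math.hypot(self.kp_phi, self.kp_phi45)


@dataclass(frozen=True)
class DAResult:
    """Per-eye vectorial difference in astigmatism about reference ``phi``.

    ``delta_kp_phi``  : KP(phi)_RA - KP(phi)_CA.  Positive when the corneal
        measurement underestimates the refractive cylinder along phi.
    ``delta_kp_phi45``: KP(phi+45)_RA - KP(phi+45)_CA.  Positive when the RA
        meridian is rotated counter-clockwise relative to phi.
    ``angle`` is the DA meridian *relative to* phi, in [0, 180).
    """

    delta_kp_phi: float
    delta_kp_phi45: float
    magnitude: float
    angle: float
    reference: float

    def __post_init__(self) -> None:
        expected = math.hypot(self.delta_kp_phi, self.delta_kp_phi45)
        if abs(expected - self.magnitude) > 1e-6:
            raise ValueError("magnitude inconsistent with the component pair")


class AxisClass(str, Enum):
    """Clinical orientation class of the steep meridian."""

    WTR = "WTR"
    ATR = "ATR"
    OBLIQUE = "OBLIQUE"


def net_to_polar(net: NetAstigmatism, reference: float) -> PolarValues:
    """Decompose a net cylinder into polar values about ``reference``.

    All trigonometry is in degrees.  The Euclidean norm of the pair equals
    the cylinder magnitude for every choice of reference meridian.
    """
    if not (0.0 <= reference < 180.0):
        raise ValueError(f"reference meridian must lie in [0, 180), got {reference}")
    two_delta = math.radians(2.0 * (net.meridian - reference))
    return PolarValues(
        kp_phi=net.magnitude * math.cos(two_delta),
        kp_phi45=net.magnitude * math.sin(two_delta),
        reference=reference,
    )


def _half_angle(x: float, y: float) -> float:
    """Half of the double-angle direction of (x, y), in [0, 180).

    Equivalent to the printed half-angle arctangent form
    ``arctan((M - x) / y)`` with M = hypot(x, y) wherever that form is
    defined, but total: y = 0 with x < 0 yields 90 exactly.
    """
    if x == 0.0 and y == 0.0:
        return 0.0
    return normalize_meridian(math.degrees(math.atan2(y, x)) / 2.0)


def polar_to_net(pv: PolarValues) -> NetAstigmatism:
    """Reconvert polar values to the net cylinder ``M @ alpha``.

    The meridian is the reference plus the half-angle of the double-angle
    vector, normalized to [0, 180).  A zero-magnitude pair returns
    ``0 @ 0`` (the direction quotient is undefined); this never raises.
    """
    m = pv.magnitude
    if m == 0.0:
        return NetAstigmatism(0.0, 0.0)
    rel = _half_angle(pv.kp_phi, pv.kp_phi45)
    return NetAstigmatism(m, normalize_meridian(pv.reference + rel))


def compute_da(ra: NetAstigmatism, ca: NetAstigmatism) -> DAResult:
    """Difference in astigmatism RA - CA about phi = the steep CA meridian.

    With the variable reference, the corneal cylinder contributes
    ``(M_CA, 0)`` exactly, so ``delta_kp_phi = KP(phi)_RA - M_CA``.  The DA
    angle is reported relative to phi.
    """
    phi = ca.meridian
    ra_pv = net_to_polar(ra, phi)
    dkp = ra_pv.kp_phi - ca.magnitude
    dkp45 = ra_pv.kp_phi45 - 0.0
    return DAResult(
        delta_kp_phi=dkp,
        delta_kp_phi45=dkp45,
        magnitude=math.hypot(dkp, dkp45),
        angle=_half_angle(dkp, dkp45),
        reference=phi,
    )


def classify_axis(meridian: float) -> AxisClass:
    """Clinical orientation class of a steep meridian in degrees.

    With-the-rule (WTR) covers 61-120 inclusive; against-the-rule (ATR)
    covers 151-180 and 0-30; the remainder (31-60, 121-150) is oblique.
    180 normalizes to 0 and is therefore ATR.  The three classes partition
    [0, 180).
    """
    if not (0.0 <= meridian <= 180.0):
        raise ValueError(f"meridian must lie in [0, 180], got {meridian}")
    m = normalize_meridian(meridian)
    if 61.0 <= m <= 120.0:
        return AxisClass.WTR
    if m <= 30.0 or m >= 151.0:
        return AxisClass.ATR
    return AxisClass.OBLIQUE


def radius_to_power(radius_mm: float, index: float = KERATOMETRIC_INDEX) -> float:
    """Convert a corneal radius of curvature (mm) to dioptric power.

    Thin-lens paraxial conversion ``(n - 1) / r`` with r in metres, i.e.
    ``(index - 1) / radius_mm * 1000``.  The default index 1.3375 is the
    standard keratometric index.
    """
    if not (radius_mm > 0.0):
        raise ValueError(f"corneal radius must be positive, got {radius_mm} mm")
    return (index - 1.0) / radius_mm * 1000.0
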