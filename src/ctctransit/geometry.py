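"""Capillary-bifurcation device geometry and laminar hydraulics.

Microfluidic capillary bifurcations are rectangular PDMS channels: a parent
channel splits into two daughter branches d1 and d2. Branch cross-sections are
designed by Murray's law on *effective* (equivalent circular) diameters,

    d0**3 = d1**3 + d2**3,

with the effective diameter of a rectangular channel of width ``a`` and height
``b`` given by the sub-10-micron correction

    de = 1.3 * (a*b)**0.625 / (a + b)**0.25.

At capillary scale the flow is laminar (Re << 1), so the fraction of parent
flow entering each daughter branch is set purely by hydraulic resistance:
branch angles and symmetry do not enter the flow split, which matches the
observation that bifurcation angle and symmetry do not change cell pathing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

from scipy.optimize import brentq

__all__ = [
    "ChannelSegment",
    "BifurcationDevice",
    "PressureHead",
    "Symmetry",
    "Equality",
    "WidthClass",
    "parent_diameter",
    "effective_diameter",
    "width_for_effective_diameter",
    "channel_resistance",
    "flow_split",
    "device_flow_split",
    "build_catalog",
    "get_device",
    "catalog_to_json",
    "catalog_from_json",
]

#: Pa per cm of water column (conventional cmH2O).
CMH2O_TO_PA = 98.0665

#: Default dynamic viscosity, Pa*s (PBS ~ water at room temperature).
DEFAULT_VISCOSITY = 1.0e-3

#: Default channel length, micron, used when device drawings give no length.
#: Flow splits depend only on resistance ratios, so equal lengths make the
#: split a function of cross-sections alone.
DEFAULT_LENGTH_UM = 100.0


class Symmetry(str, Enum):
    symmetric = "symmetric"
    asymmetric = "asymmetric"


class Equality(str, Enum):
    equal = "equal"
    unequal = "unequal"


class WidthClass(str, Enum):
    narrow = "narrow"
    wide = "wide"


@dataclass(frozen=True)
class ChannelSegment:
    """One rectangular channel segment.

    Parameters
    ----------
    width_a, height_b : float
        Cross-section, micron. ``width_a`` is the lithographic (in-plane)
        width; ``height_b`` the wafer-set height.
    length_L : float
        Segment length, micron.
    viscosity_mu : float
        Dynamic viscosity of the carrier fluid, Pa*s.
    """

    width_a: float
    height_b: float
    length_L: float = DEFAULT_LENGTH_UM
    viscosity_mu: float = DEFAULT_VISCOSITY

    def __post_init__(self) -> None:
        for name in ("width_a", "height_b", "length_L", "viscosity_mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def effective_diameter(self) -> float:
        return effective_diameter(self.width_a, self.height_b)

    @property
    def resistance(self) -> float:
        return channel_resistance(self)


@dataclass(frozen=True)
class PressureHead:
    """Driving pressure expressed as a water-column height."""

    height_cmH2O: float

    def __post_init__(self) -> None:
        if self.height_cmH2O < 0:
            raise ValueError("height_cmH2O must be >= 0")

    @property
    def pascals(self) -> float:
        return self.height_cmH2O * CMH2O_TO_PA


#: Physiological capillary pressure used throughout the transit experiments.
PHYSIOLOGICAL_HEAD = PressureHead(30.0)


def parent_diameter(d1: float, d2: float) -> float:
    """Murray's-law parent effective diameter, (d1^3 + d2^3)^(1/3).

    Degenerate single-branch case (one diameter zero) returns the other
    diameter unchanged.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("diameters must be non-negative")
    if d1 == 0 and d2 == 0:
        raise ValueError("at least one daughter diameter must be positive")
    return (d1**3 + d2**3) ** (1.0 / 3.0)


def effective_diameter(a: float, b: float) -> float:
    """Equivalent circular diameter of an a x b rectangular channel.

    Empirical correction for channels below ~10 micron; symmetric in (a, b)
    and homogeneous of degree 1.
    """
    if a <= 0 or b <= 0:
        raise ValueError("channel dimensions must be positive")
    return 1.3 * (a * b) ** 0.625 / (a + b) ** 0.25


def width_for_effective_diameter(de: float, height: float) -> float:
    """Invert the effective-diameter formula for width at fixed height."""
    if de <= 0 or height <= 0:
        raise ValueError("de and height must be positive")
    # de is strictly increasing in a, so bracket and bisect.
    lo, hi = 1e-6, 10.0
    while effective_diameter(hi, height) < de:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for sane inputs
            raise ValueError("effective diameter out of invertible range")
    return brentq(lambda a: effective_diameter(a, height) - de, lo, hi, xtol=1e-12)


# One-term truncation of the exact series solution for pressure-driven laminar
# flow in a rectangular duct.  The tanh factor keeps the truncation within
# ~0.7% of the full series down to square cross-sections; dropping it (the
# bare 1 - 0.63 h/w form) is only valid for shallow channels.
_C1 = 192.0 / math.pi**5


def channel_resistance(seg: ChannelSegment) -> float:
    """Hydraulic resistance of a rectangular duct, Pa*s/um^3.

    Internally orders the cross-section so h = min(a, b), w = max(a, b) and
    evaluates R = 12*mu*L / (w*h^3 * (1 - (192/pi^5)(h/w) tanh(pi*w/(2h)))).
    Strictly decreasing in both cross-section dimensions, linear in length
    and viscosity.
    """
    h = min(seg.width_a, seg.height_b)
    w = max(seg.width_a, seg.height_b)
    shape = 1.0 - _C1 * (h / w) * math.tanh(math.pi * w / (2.0 * h))
    return 12.0 * seg.viscosity_mu * seg.length_L / (w * h**3 * shape)


def flow_split(R1: float, R2: float) -> float:
    """Fraction of parent flow entering branch 2 for branch resistances R1, R2.

    The branches see the same pressure drop, so flow partitions by
    conductance: f2 = (1/R2) / (1/R1 + 1/R2) = R1 / (R1 + R2).
    """
    if R1 <= 0 or R2 <= 0:
        raise ValueError("resistances must be positive")
    return R1 / (R1 + R2)


@dataclass(frozen=True)
class BifurcationDevice:
    """One microfluidic device variant.

    ``code`` follows the catalog nomenclature: first letter E/U for
    equal/unequal daughter widths, second N/W for narrow/wide branch angles,
    third A/S for asymmetric/symmetric branching, with unequal (and some
    equal) codes carrying the daughter widths, e.g. ``UNA_5/9``.
    Non-bifurcating controls (``LINEAR``, ``NONCONSTRICTED``) carry a single
    channel in ``parent`` and no daughters.
    """

    code: str
    parent: ChannelSegment
    daughter1: ChannelSegment | None
    daughter2: ChannelSegment | None
    angle1_deg: float = 0.0
    angle2_deg: float = 0.0
    symmetry: Symmetry = Symmetry.asymmetric
    width_class: WidthClass = WidthClass.narrow
    placeholder_dims: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.bifurcating:
            if self.daughter1.width_a > self.daughter2.width_a + 1e-12:
                raise ValueError("convention: daughter1.width_a <= daughter2.width_a")
            first = self.code[0].upper()
            expected = "E" if self.equality is Equality.equal else "U"
            if first != expected:
                raise ValueError(
                    f"device code {self.code!r} inconsistent with "
                    f"{self.equality.value} daughter widths"
                )

    @property
    def bifurcating(self) -> bool:
        return self.daughter1 is not None and self.daughter2 is not None

    @property
    def equality(self) -> Equality | None:
        if not self.bifurcating:
            return None
        if abs(self.daughter1.width_a - self.daughter2.width_a) <= 1e-9:
            return Equality.equal
        return Equality.unequal

    @property
    def constricted(self) -> bool:
        """Constricted devices (7 um height) force single-file transit."""
        return self.parent.height_b < 10.0

    def flow_split(self) -> float:
        """Fraction of parent flow entering daughter branch 2 (the larger)."""
        return device_flow_split(self)


def device_flow_split(device: BifurcationDevice) -> float:
    if not device.bifurcating:
        raise ValueError(f"device {device.code} does not bifurcate")
    return flow_split(channel_resistance(device.daughter1), channel_resistance(device.daughter2))


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

CONSTRICTED_HEIGHT_UM = 7.0
NONCONSTRICTED_HEIGHT_UM = 20.0

# (code, (w1, w2) daughter widths um, angle class, symmetry, placeholder_dims)
# Daughter widths are parsed from the code where the nomenclature prints them;
# the wide-angle variants' drawings are not reproduced here, so they default
# to the canonical equal (7/7) and unequal (5/9) widths and are flagged as
# placeholders.
_CATALOG_ENTRIES: list[tuple[str, tuple[float, float], WidthClass, Symmetry, bool]] = [
    ("ENA_6.3/6.3", (6.3, 6.3), WidthClass.narrow, Symmetry.asymmetric, False),
    ("ENA_7/7", (7.0, 7.0), WidthClass.narrow, Symmetry.asymmetric, False),
    ("ENA_9/9", (9.0, 9.0), WidthClass.narrow, Symmetry.asymmetric, False),
    ("UNA_5/9", (5.0, 9.0), WidthClass.narrow, Symmetry.asymmetric, False),
    ("UNA_5.5/7", (5.5, 7.0), WidthClass.narrow, Symmetry.asymmetric, False),
    ("UNA_5/7", (5.0, 7.0), WidthClass.narrow, Symmetry.asymmetric, False),
    ("EWA", (7.0, 7.0), WidthClass.wide, Symmetry.asymmetric, True),
    ("EWS", (7.0, 7.0), WidthClass.wide, Symmetry.symmetric, True),
    ("UWA", (5.0, 9.0), WidthClass.wide, Symmetry.asymmetric, True),
    ("UWS", (5.0, 9.0), WidthClass.wide, Symmetry.symmetric, True),
]

_ANGLES = {WidthClass.narrow: 30.0, WidthClass.wide: 60.0}


def _make_bifurcating(
    code: str,
    widths: tuple[float, float],
    width_class: WidthClass,
    symmetry: Symmetry,
    placeholder: bool,
    length_um: float,
    viscosity: float,
) -> BifurcationDevice:
    w1, w2 = sorted(widths)
    h = CONSTRICTED_HEIGHT_UM
    d1 = ChannelSegment(w1, h, length_um, viscosity)
    d2 = ChannelSegment(w2, h, length_um, viscosity)
    de0 = parent_diameter(d1.effective_diameter, d2.effective_diameter)
    parent_width = width_for_effective_diameter(de0, h)
    parent = ChannelSegment(parent_width, h, length_um, viscosity)
    branch_angle = _ANGLES[width_class]
    if symmetry is Symmetry.symmetric:
        angles = (branch_angle, branch_angle)
    else:
        angles = (branch_angle, 0.0)  # one daughter continues straight
    return BifurcationDevice(
        code=code,
        parent=parent,
        daughter1=d1,
        daughter2=d2,
        angle1_deg=angles[0],
        angle2_deg=angles[1],
        symmetry=symmetry,
        width_class=width_class,
        placeholder_dims=placeholder,
    )


def build_catalog(
    length_um: float = DEFAULT_LENGTH_UM,
    viscosity: float = DEFAULT_VISCOSITY,
) -> list[BifurcationDevice]:
    """All named device variants plus the two non-bifurcating controls.

    Parent widths are solved so that the parent's effective diameter obeys
    Murray's law on the daughters' effective diameters. Constricted devices
    have 7 um channel height; the nonconstricted control is 20 um.
    """
    catalog = [
        _make_bifurcating(code, widths, wc, sym, ph, length_um, viscosity)
        for code, widths, wc, sym, ph in _CATALOG_ENTRIES
    ]
    catalog.append(
        BifurcationDevice(
            code="LINEAR",
            parent=ChannelSegment(7.0, CONSTRICTED_HEIGHT_UM, length_um, viscosity),
            daughter1=None,
            daughter2=None,
        )
    )
    catalog.append(
        BifurcationDevice(
            code="NONCONSTRICTED",
            parent=ChannelSegment(20.0, NONCONSTRICTED_HEIGHT_UM, length_um, viscosity),
            daughter1=None,
            daughter2=None,
        )
    )
    return catalog


def get_device(code: str, **kwargs) -> BifurcationDevice:
    """Look a device up by catalog code (case-insensitive)."""
    for dev in build_catalog(**kwargs):
        if dev.code.upper() == code.upper():
            return dev
    known = ", ".join(d.code for d in build_catalog())
    raise KeyError(f"unknown device code {code!r}; known codes: {known}")


def _segment_dict(seg: ChannelSegment | None) -> dict | None:
    return None if seg is None else asdict(seg)


def catalog_to_json(devices: list[BifurcationDevice], path: str | Path) -> None:
    """Write a device list as a JSON array (one object per device)."""
    records = []
    for d in devices:
        records.append(
            {
                "code": d.code,
                "parent": _segment_dict(d.parent),
                "daughter1": _segment_dict(d.daughter1),
                "daughter2": _segment_dict(d.daughter2),
                "angle1_deg": d.angle1_deg,
                "angle2_deg": d.angle2_deg,
                "symmetry": d.symmetry.value,
                "width_class": d.width_class.value,
                "bifurcating": d.bifurcating,
                "equality": d.equality.value if d.equality else None,
                "placeholder_dims": d.placeholder_dims,
            }
        )
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def catalog_from_json(path: str | Path) -> list[BifurcationDevice]:
    records = json.loads(Path(path).read_text())
    devices = []
    for r in records:
        devices.append(
            BifurcationDevice(
                code=r["code"],
                parent=ChannelSegment(**r["parent"]),
                daughter1=ChannelSegment(**r["daughter1"]) if r["daughter1"] else None,
                daughter2=ChannelSegment(**r["daughter2"]) if r["daughter2"] else None,
                angle1_deg=r["angle1_deg"],
                angle2_deg=r["angle2_deg"],
                symmetry=Symmetry(r["symmetry"]),
                width_class=WidthClass(r["width_class"]),
                placeholder_dims=r.get("placeholder_dims", False),
            )
        )
    return devices
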