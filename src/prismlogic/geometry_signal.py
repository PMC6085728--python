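"""Coarse-grained B-form geometry of the prism and the Förster signal model.

Geometry: the prism is two parallel equilateral triangles (side
``0.34 nm/bp * 21 bp = 7.14 nm``) separated by the 10-bp vertical struts
(``3.40 nm``), giving an interior volume of ``(sqrt(3)/4) * side^2 * strut
~ 75 nm^3``.  The dye and quencher sit at the backbone nicks in the
middle of the L/A2 and L/B2 sides, radially offset from the helix axis.

Signal: a ROX fluorophore and a BHQ-2 quencher report the structural
state through point-dipole Förster transfer, ``E = 1/(1+(r/R0)^6)``.
The Förster radius is calibrated so that the closed-state dye-quencher
distance of 5.5 nm corresponds to the measured 37.5 % residual
fluorescence of the intact prism (R0 ~ 5.99 nm, within the literature
range for ROX/BHQ-2).  Opened states are represented by effective
distances rather than explicit coordinates: the opened-lid geometry is
floppy, and only the ordering of the per-state intensities and their
relation to the 0.6 decision threshold carry logical meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .assembly import PrismState
from .errors import ClassificationError, InputError, SpecError

__all__ = [
    "GeometryParams",
    "PrismGeometry",
    "SignalModel",
    "build_geometry",
    "fret_efficiency",
    "invert_fret",
    "nfi",
]


@dataclass(frozen=True)
class GeometryParams:
    """B-form geometry parameters (nm / bp)."""

    rise_per_bp: float = 0.34
    strut_bp: int = 10
    side_bp: int = 21
    helix_radius: float = 1.0
    face_twist_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_per_bp <= 0 or self.strut_bp <= 0 or self.side_bp <= 0:
            raise SpecError("geometry lengths must be positive")
        if self.helix_radius < 0:
            raise SpecError("helix radius must be non-negative")

    @property
    def strut_length(self) -> float:
        return self.rise_per_bp * self.strut_bp

    @property
    def side_length(self) -> float:
        return self.rise_per_bp * self.side_bp


@dataclass(frozen=True)
class PrismGeometry:
    """Vertex and nick coordinates of the closed prism (nm)."""

    params: GeometryParams
    vertices_bottom: np.ndarray  # (3, 3)
    vertices_top: np.ndarray     # (3, 3)
    nick_a: np.ndarray           # (3,)
    nick_b: np.ndarray           # (3,)

    @property
    def strut_length(self) -> float:
        return self.params.strut_length

    @property
    def side_length(self) -> float:
        return self.params.side_length

    @property
    def volume(self) -> float:
        """Interior volume (sqrt(3)/4) * side^2 * height in nm^3."""
        return math.sqrt(3.0) / 4.0 * self.side_length**2 * self.strut_length

    @property
    def nick_distance(self) -> float:
        return float(np.linalg.norm(self.nick_a - self.nick_b))

    def to_xyz(self) -> str:
        """PDB-like xyz records for visualization."""
        rows = []
        labels = ["VA1", "VA2", "VA3", "VB1", "VB2", "VB3", "NKA", "NKB"]
        pts = list(self.vertices_bottom) + list(self.vertices_top) + [self.nick_a, self.nick_b]
        rows.append(str(len(pts)))
        rows.append("prism vertices and nick points (nm)")
        for lab, p in zip(labels, pts):
            rows.append(f"{lab} {p[0]:10.4f} {p[1]:10.4f} {p[2]:10.4f}")
        return "\n".join(rows) + "\n"


def build_geometry(p: GeometryParams = GeometryParams()) -> PrismGeometry:
    """Vertex coordinates of the two faces plus the two nick points.

    The nicks sit at the midpoints of the L/A2 and L/B2 sides (the side
    joining vertices 2 and 3), offset radially outward by the helix
    radius.  With the default eclipsed faces the nick-nick distance
    equals the strut length.
    """
    side = p.side_length
    circum = side / math.sqrt(3.0)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    bottom = np.stack(
        [circum * np.cos(angles), circum * np.sin(angles), np.zeros(3)], axis=1
    )
    twist = math.radians(p.face_twist_deg)
    rot = np.array(
        [
            [math.cos(twist), -math.sin(twist), 0.0],
            [math.sin(twist), math.cos(twist), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    top = bottom @ rot.T
    top = top + np.array([0.0, 0.0, p.strut_length])

    def nick(verts: np.ndarray) -> np.ndarray:
        mid = (verts[1] + verts[2]) / 2.0
        radial = mid - verts.mean(axis=0)
        norm = np.linalg.norm(radial[:2])
        direction = radial / norm if norm > 0 else np.zeros(3)
        return mid + direction * p.helix_radius

    return PrismGeometry(p, bottom, top, nick(bottom), nick(top))


# ---------------------------------------------------------------------------
# Förster transfer
# ---------------------------------------------------------------------------


def fret_efficiency(r: float, r0: float) -> float:
    """Point-dipole Förster efficiency E = 1/(1+(r/R0)^6)."""
    if r0 <= 0:
        raise InputError("Förster radius must be positive")
    if r < 0:
        raise InputError("distance must be non-negative")
    if math.isinf(r):
        return 0.0
    return 1.0 / (1.0 + (r / r0) ** 6)


def invert_fret(e: float, r0: float) -> float:
    """Distance at which the Förster efficiency equals ``e`` (exact
    inverse of :func:`fret_efficiency`)."""
    if r0 <= 0:
        raise InputError("Förster radius must be positive")
    if not 0.0 < e < 1.0:
        raise InputError("efficiency must lie strictly between 0 and 1")
    return r0 * ((1.0 - e) / e) ** (1.0 / 6.0)


@dataclass(frozen=True)
class SignalModel:
    """State -> dye-quencher distance -> normalized fluorescence (NFI).

    ``r0`` defaults to the calibrated value at which the closed-state
    distance and the closed-state residual fluorescence are mutually
    consistent: R0 = r_closed / (residual/(1-residual))^(1/6).
    """

    r_closed: float = 5.5
    r_mono_c3: float = 5.8
    r_opened_lid: float = 12.0
    residual_closed: float = 0.375
    threshold: float = 0.6
    r0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r0 is None:
            e_closed = 1.0 - self.residual_closed
            object.__setattr__(
                self,
                "r0",
                self.r_closed / ((1.0 - e_closed) / e_closed) ** (1.0 / 6.0),
            )
        if self.r0 <= 0:
            raise SpecError("Förster radius must be positive")
        if not (0 < self.r_closed <= self.r_mono_c3 < self.r_opened_lid):
            raise SpecError("state distances must satisfy r_closed <= r_monoC3 < r_opened_lid")
        if not 0 < self.threshold < 1:
            raise SpecError("threshold must lie in (0, 1)")

    def state_distance(self, state: PrismState) -> float:
        """Effective dye-quencher distance for a canonical prism state."""
        if not state.connected:
            return math.inf
        opened = state.opened_edges
        if not opened:
            return self.r_closed
        if opened == frozenset({3}):
            return self.r_mono_c3
        return self.r_opened_lid


def nfi(state: PrismState, model: SignalModel = SignalModel()) -> float:
    """Normalized fluorescence intensity (unquenched prism = 1.0)."""
    if not isinstance(state, PrismState):
        raise ClassificationError(f"cannot compute NFI for {state!r}")
    r = model.state_distance(state)
    return 1.0 - fret_efficiency(r, model.r0)
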