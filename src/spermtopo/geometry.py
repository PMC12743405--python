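"""Nuclear coordinate model for decondensed sperm heads.

The nucleus is treated as an ellipse with a longitudinal axis running from
the basal tail-attachment point to the apex (length ``L``) and a short axis
of length ``l`` at its widest part.  Every FISH signal is reduced to

* an *axial fraction* ``t`` — its signed projection onto the basal→apex
  axis divided by ``L``;
* a *linear zone* — which third of the axis it falls in (``b``/``m``/``a``);
* a *radial position* ``(D/L, H/L)`` — distance to the basal point over
  ``L``, and unsigned perpendicular distance to the axis over ``L``.

``H`` is always folded to be non-negative: a sperm lies flat on the slide
in one of two mirror-image poses, so the sign of the perpendicular offset
carries no information.

Two conventions for ``D`` are supported.  ``euclidean`` takes the literal
point-to-point distance from the signal to the basal point; ``axial`` takes
the projection onto the axis (so that ``D/L`` is exactly the axial
fraction).  Both are exposed because the verbal definition and the stated
maximum of 1.0 pull in different directions; callers must use one mode
consistently for simulation and measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "NucleusGeometry",
    "FishSignal",
    "RadialPosition",
    "LinearZone",
    "ZONES",
    "axial_fraction",
    "linear_zone",
    "radial_position",
    "shape_qc",
    "intercentromere_distance",
    "DEFAULT_SHAPE_BAND",
    "AXIAL_CLAMP_EPS",
]

#: Linear zones in basal→apical order.
ZONES = ("b", "m", "a")

#: Default acceptance band on the L/l shape ratio.  Deliberately permissive:
#: it screens out circular debris and grossly elongated objects rather than
#: enforcing the 1.4–1.5-fold decondensation swelling itself.
DEFAULT_SHAPE_BAND = (1.2, 2.2)

#: Axial fractions within this margin outside [0, 1] are clamped; beyond it
#: the signal is considered mis-assigned.
AXIAL_CLAMP_EPS = 0.02

DMode = Literal["euclidean", "axial"]
LinearZone = Literal["b", "m", "a"]


class InvalidGeometryError(ValueError):
    """Raised for degenerate nucleus geometry (e.g. zero-length axis)."""


@dataclass
class NucleusGeometry:
    """Axis and size of one sperm nucleus.

    Parameters
    ----------
    basal_point, apex_point
        Endpoints of the longitudinal axis in µm; ``basal_point`` is the
        tail-attachment end.
    L
        Longitudinal axis length (µm).  Must equal the distance between the
        endpoints; pass ``L=None`` to derive it.
    l
        Short-axis length at the widest part (µm).
    nucleus_id
        Opaque label joining signals to their nucleus.
    qc_pass
        Shape-QC state; set by :func:`shape_qc`.
    """

    basal_point: tuple[float, float]
    apex_point: tuple[float, float]
    l: float
    L: float | None = None
    nucleus_id: str = ""
    qc_pass: bool = True

    def __post_init__(self) -> None:
        bx, by = self.basal_point
        ax, ay = self.apex_point
        dist = math.hypot(ax - bx, ay - by)
        if self.L is None:
            self.L = dist
        elif not math.isclose(self.L, dist, rel_tol=1e-6, abs_tol=1e-9):
            raise InvalidGeometryError(
                f"L={self.L} inconsistent with axis endpoints (|apex-basal|={dist:.6g})"
            )
        if self.L <= 0:
            raise InvalidGeometryError("longitudinal axis length L must be > 0")
        if self.l <= 0:
            raise InvalidGeometryError("short axis length l must be > 0")
        if self.l > self.L * (1 + 1e-9):
            raise InvalidGeometryError(f"short axis l={self.l} exceeds L={self.L}")

    @property
    def axis_unit(self) -> np.ndarray:
        """Unit vector from basal to apex."""
        v = np.asarray(self.apex_point, float) - np.asarray(self.basal_point, float)
        return v / self.L

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.basal_point, float) + np.asarray(self.apex_point, float)) / 2.0

    @property
    def shape_ratio(self) -> float:
        """Ellipsoidal shape ratio L/l."""
        return self.L / self.l

    def half_width_at(self, t: float) -> float:
        """Half-width of the boundary ellipse at axial fraction ``t`` (µm).

        Zero outside [0, 1].
        """
        u = 2.0 * t - 1.0
        if abs(u) >= 1.0:
            return 0.0
        return (self.l / 2.0) * math.sqrt(1.0 - u * u)

    def contains(self, point: tuple[float, float], tol: float = 1e-9) -> bool:
        """True if ``point`` lies inside (or within ``tol`` of) the ellipse."""
        p = np.asarray(point, float) - self.center
        u = self.axis_unit
        along = float(p @ u)
        perp = float(p @ np.array([-u[1], u[0]]))
        q = (along / (self.L / 2.0)) ** 2 + (perp / (self.l / 2.0)) ** 2
        return q <= 1.0 + tol


@dataclass
class FishSignal:
    """One detected centromere spot: chromosome label plus 2D centroid (µm)."""

    chromosome: str
    centroid: tuple[float, float]
    nucleus_id: str = ""
    channel: str = ""


@dataclass
class RadialPosition:
    """Normalized radial coordinates of one signal.

    ``d_over_l`` is D/L in the configured D-mode; ``h_over_l`` is the
    mirror-folded H/L; ``axial_fraction`` is the signed axial projection
    over L (unclamped).
    """

    d_over_l: float
    h_over_l: float
    axial_fraction: float = field(default=0.0)


def _axis_decompose(
    signal: FishSignal, nucleus: NucleusGeometry
) -> tuple[float, float]:
    """Return (signed axial projection / L, unsigned perpendicular distance µm)."""
    if nucleus.L <= 0:
        raise InvalidGeometryError("degenerate nucleus: L = 0")
    p = np.asarray(signal.centroid, float) - np.asarray(nucleus.basal_point, float)
    u = nucleus.axis_unit
    along = float(p @ u)
    perp = abs(float(p @ np.array([-u[1], u[0]])))
    return along / nucleus.L, perp


def axial_fraction(signal: FishSignal, nucleus: NucleusGeometry) -> float:
    """Signed projection of the signal onto the basal→apex axis, over L.

    0 at the basal point, 1 at the apex.  In-nucleus signals fall within
    a small tolerance of [0, 1].
    """
    t, _ = _axis_decompose(signal, nucleus)
    return t


def linear_zone(
    signal: FishSignal, nucleus: NucleusGeometry, clamp_eps: float = AXIAL_CLAMP_EPS
) -> LinearZone:
    """Assign the signal to the basal/middle/apical third of the axis.

    Thirds are half-open, apex-inclusive: t < 1/3 → ``b``;
    1/3 ≤ t < 2/3 → ``m``; t ≥ 2/3 → ``a``.  The axial fraction is clamped
    to [0, 1] first; values outside [−clamp_eps, 1+clamp_eps] indicate a
    mis-assigned spot and raise.
    """
    t = axial_fraction(signal, nucleus)
    if t < -clamp_eps or t > 1.0 + clamp_eps:
        raise ValueError(
            f"axial fraction {t:.4f} outside [-{clamp_eps}, 1+{clamp_eps}]: "
            "signal not on this nucleus?"
        )
    t = min(max(t, 0.0), 1.0)
    if t < 1.0 / 3.0:
        return "b"
    if t < 2.0 / 3.0:
        return "m"
    return "a"


def zone_of_fraction(t: float) -> LinearZone:
    """Zone for a raw axial fraction (clamped to [0, 1]); same thirds rule."""
    t = min(max(t, 0.0), 1.0)
    if t < 1.0 / 3.0:
        return "b"
    if t < 2.0 / 3.0:
        return "m"
    return "a"


def radial_position(
    signal: FishSignal,
    nucleus: NucleusGeometry,
    d_mode: DMode = "euclidean",
) -> RadialPosition:
    """Compute the normalized (D/L, H/L) coordinates of a signal.

    H is the unsigned perpendicular distance from the signal to the
    basal→apex line.  D is either the Euclidean distance to the basal
    point (``d_mode='euclidean'``) or the axial projection
    (``d_mode='axial'``, in which case D/L equals the axial fraction).
    """
    if d_mode not in ("euclidean", "axial"):
        raise ValueError(f"unknown d_mode: {d_mode!r}")
    t, h_um = _axis_decompose(signal, nucleus)
    if d_mode == "euclidean":
        d_um = math.hypot(
            signal.centroid[0] - nucleus.basal_point[0],
            signal.centroid[1] - nucleus.basal_point[1],
        )
        d_over_l = d_um / nucleus.L
    else:
        d_over_l = t
    return RadialPosition(d_over_l=d_over_l, h_over_l=h_um / nucleus.L, axial_fraction=t)


def shape_qc(
    nucleus: NucleusGeometry, band: tuple[float, float] = DEFAULT_SHAPE_BAND
) -> bool:
    """Pass/fail the nucleus on its L/l shape ratio; updates ``qc_pass``."""
    lo, hi = band
    ok = lo <= nucleus.shape_ratio <= hi
    nucleus.qc_pass = ok
    return ok


def intercentromere_distance(s1: FishSignal, s2: FishSignal) -> float:
    """Euclidean distance (µm) between two signals of the same nucleus."""
    if s1.nucleus_id != s2.nucleus_id:
        raise ValueError(
            f"signals belong to different nuclei: {s1.nucleus_id!r} vs {s2.nucleus_id!r}"
        )
    return math.hypot(
        s1.centroid[0] - s2.centroid[0], s1.centroid[1] - s2.centroid[1]
    )
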