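"""Cross-section geometry: digitized (DM) and contour-gauge (CM) bark fissure indices.

These are the reference methods the bark gauge method is validated against. DM works
on digitized polygons of a cut stem disk (outer bark perimeter and wood surface); CM
works on a contour-gauge trace of the outer bark surface plus three bark-thickness
anchors (start, centre, end of the profile). Both divide the solid bark area by the
idealized bark annulus measured with a diameter tape.

Coordinates are planar cm with arbitrary origin; contours are treated as closed and
normalized counter-clockwise. Self-intersecting polygons are rejected, not repaired.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from shapely.geometry import LineString, Polygon

from .errors import BarkDomainError, ConfigurationError
from .gauge import BFIEstimate, _clamped

__all__ = [
    "BarkProfile",
    "ContourTrace",
    "polygon_area",
    "annulus_area",
    "bfi_dm",
    "bfi_cm",
    "resample_contour",
]

logger = logging.getLogger(__name__)

_AREA_EPS = 1e-12


def _as_polygon(contour) -> Polygon:
    coords = np.asarray(contour, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 3:
        raise BarkDomainError("a contour needs >= 3 (x, y) vertices")
    poly = Polygon(coords)
    if not poly.is_valid:
        raise BarkDomainError("contour is degenerate or self-intersecting; not repaired")
    return poly


def polygon_area(contour) -> float:
    """Absolute enclosed (shoelace) area of a closed polyline, cm^2.

    Orientation-independent; degenerate (collinear) input is a domain error.
    """
    poly = _as_polygon(contour)
    if poly.area <= _AREA_EPS:
        raise BarkDomainError("contour encloses no area (collinear vertices?)")
    return float(poly.area)


def annulus_area(dob: float, dub: float) -> float:
    """Area of the idealized circular bark annulus pi/4 * (DoB^2 - DuB^2), cm^2."""
    if not dob > 0:
        raise BarkDomainError(f"dob must be positive, got {dob}")
    if dub < 0 or dub >= dob:
        raise BarkDomainError(f"need dob > dub >= 0, got dob={dob}, dub={dub}")
    return math.pi / 4.0 * (dob**2 - dub**2)


@dataclass
class BarkProfile:
    """Digitized cross-section: outer bark perimeter and wood surface polygons, cm."""

    outer_contour: np.ndarray
    wood_contour: np.ndarray
    tape_dob: float
    section_id: str = ""

    def __post_init__(self) -> None:
        self.outer_contour = np.asarray(self.outer_contour, dtype=float)
        self.wood_contour = np.asarray(self.wood_contour, dtype=float)
        if not self.tape_dob > 0:
            raise BarkDomainError(f"tape_dob must be positive, got {self.tape_dob}")
        outer = _as_polygon(self.outer_contour)
        wood = _as_polygon(self.wood_contour)
        if outer.area <= _AREA_EPS or wood.area <= _AREA_EPS:
            raise BarkDomainError("contours must enclose non-zero area")
        # wood must sit inside the outer contour; the small buffer tolerates
        # fissures digitized right down to the wood surface (touching floors)
        if not wood.within(outer.buffer(1e-3)):
            raise BarkDomainError("wood_contour must lie inside the outer contour")


def bfi_dm(
    profile: BarkProfile,
    *,
    dub_from: str = "wood_area",
    bt_max: Optional[float] = None,
    clamp: bool = True,
) -> BFIEstimate:
    """Digitized-method BFI: solid bark polygon area over the idealized annulus.

    Numerator: outer polygon area minus wood polygon area. Denominator: annulus
    from the tape-measured DoB and an under-bark diameter taken (by default) as
    the wood polygon's area-equivalent diameter 2*sqrt(A_wood/pi); alternatively
    ``dub_from='bt_max'`` uses tape_dob - 2*bt_max.
    """
    outer_a = polygon_area(profile.outer_contour)
    wood_a = polygon_area(profile.wood_contour)
    solid = outer_a - wood_a
    if solid <= 0:
        raise BarkDomainError("solid bark area is non-positive")
    if dub_from == "wood_area":
        dub = 2.0 * math.sqrt(wood_a / math.pi)
    elif dub_from == "bt_max":
        if bt_max is None:
            raise ConfigurationError("dub_from='bt_max' requires bt_max")
        dub = profile.tape_dob - 2.0 * bt_max
    else:
        raise ConfigurationError(f"unknown dub_from {dub_from!r}")
    value = _clamped(solid / annulus_area(profile.tape_dob, dub), clamp, "DM")
    return BFIEstimate(
        value=value,
        method="DM",
        n_readings=int(np.asarray(profile.outer_contour).shape[0]),
        section_id=profile.section_id,
    )


@dataclass
class ContourTrace:
    """Contour-gauge profile of the outer bark surface with 3 thickness anchors.

    ``profile_points`` are (arc position, height) samples in cm along the outer
    surface; heights are relative to the gauge datum (only differences matter).
    ``anchor_thicknesses`` are bark thicknesses (cm) measured at the start, centre
    and end of the profile; ``arc_span`` is the share of the circumference covered
    in degrees.
    """

    profile_points: np.ndarray
    anchor_thicknesses: np.ndarray
    arc_span: float
    tape_dob: float
    section_id: str = ""

    def __post_init__(self) -> None:
        self.profile_points = np.asarray(self.profile_points, dtype=float)
        self.anchor_thicknesses = np.asarray(self.anchor_thicknesses, dtype=float)
        if self.profile_points.ndim != 2 or self.profile_points.shape[1] != 2:
            raise BarkDomainError("profile_points must be an (n, 2) array of (arc, height)")
        if self.profile_points.shape[0] < 2:
            raise BarkDomainError("need >= 2 profile points")
        if self.anchor_thicknesses.shape != (3,):
            raise BarkDomainError("exactly 3 anchor thicknesses (start, centre, end) required")
        if np.any(self.anchor_thicknesses <= 0):
            raise BarkDomainError("anchor thicknesses must be positive")
        if not 0 < self.arc_span <= 360:
            raise BarkDomainError(f"arc_span must be in (0, 360], got {self.arc_span}")
        if not self.tape_dob > 0:
            raise BarkDomainError(f"tape_dob must be positive, got {self.tape_dob}")


def bfi_cm(trace: ContourTrace, *, clamp: bool = True) -> BFIEstimate:
    """Contour-method BFI: solid bark over the annulus sector covered by the trace.

    The traced heights are mapped to outer radii by anchoring the profile envelope
    (its highest point, a bark ridge) at the tape radius DoB/2. The wood line is
    reconstructed from the three anchors — outer radius minus anchor thickness at
    the start, centre and end of the profile, interpolated linearly in arc
    position between them (the smooth-bole assumption: the wood surface is not
    irregular the way the bark surface is). Solid bark area is the polar area
    between the traced outer radius and the reconstructed wood line; where a
    fissure undercuts the wood line the contribution is truncated at zero with a
    warning. The denominator is the idealized annulus (DuB = tape_dob minus twice
    the mean anchor thickness) scaled to the arc span.
    """
    pts = trace.profile_points[np.argsort(trace.profile_points[:, 0], kind="stable")]
    s, h = pts[:, 0], pts[:, 1]
    if s[-1] <= s[0]:
        raise BarkDomainError("profile arc positions must span a positive range")
    radius = trace.tape_dob / 2.0
    span_rad = math.radians(trace.arc_span)
    # map arc positions linearly onto the stated arc span
    theta = (s - s[0]) / (s[-1] - s[0]) * span_rad
    r_out = radius - (h.max() - h)

    anchors_s = np.array([s[0], 0.5 * (s[0] + s[-1]), s[-1]])
    r_out_at_anchor = np.interp(anchors_s, s, h)
    r_out_at_anchor = radius - (h.max() - r_out_at_anchor)
    r_wood_nodes = r_out_at_anchor - trace.anchor_thicknesses
    r_wood = np.interp(s, anchors_s, r_wood_nodes)

    integrand = r_out**2 - r_wood**2
    if np.any(integrand < 0):
        logger.warning(
            "trace %s: fissure deeper than the reconstructed wood line; truncated at zero",
            trace.section_id or "<unnamed>",
        )
        integrand = np.clip(integrand, 0.0, None)
    solid = 0.5 * float(np.trapezoid(integrand, theta))
    if solid <= 0:
        raise BarkDomainError("solid bark area is non-positive")

    dub = trace.tape_dob - 2.0 * float(trace.anchor_thicknesses.mean())
    if dub < 0:
        raise BarkDomainError("anchor thicknesses exceed the tape radius")
    denom = annulus_area(trace.tape_dob, dub) * trace.arc_span / 360.0
    value = _clamped(solid / denom, clamp, "CM")
    return BFIEstimate(
        value=value,
        method="CM",
        n_readings=int(pts.shape[0]),
        section_id=trace.section_id,
    )


def resample_contour(contour, spacing: float = 0.05) -> np.ndarray:
    """Uniformly resample a closed contour at fixed arc-length spacing (cm).

    Optional smoothing step for noisy digitizations; not applied by default.
    """
    if not spacing > 0:
        raise BarkDomainError(f"spacing must be positive, got {spacing}")
    coords = np.asarray(contour, dtype=float)
    _as_polygon(coords)  # validates
    closed = np.vstack([coords, coords[:1]])
    line = LineString(closed)
    n = max(int(line.length / spacing), 3)
    points = [line.interpolate(i * line.length / n) for i in range(n)]
    return np.array([[p.x, p.y] for p in points])
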