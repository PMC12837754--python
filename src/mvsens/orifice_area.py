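"""Gap-length orifice-area algorithm.

Given the anterior and posterior leaflet free-edge curves (ordered 3D
polylines), the valve is cut by ``n_planes`` equally spaced
cross-sectional planes spanning the commissure-to-commissure direction,
each oriented perpendicular to the local coaptation line.  The local gap
length is the minimum distance between the in-plane intersection point
sets of the two edges (zero if the edges touch or overlap), and the
orifice area is the Riemann sum of the gap lengths times the plane
spacing:

    OA = sum_i g_i * dx.

The local coaptation line is estimated as the midcurve between the two
edges; each plane's normal is the midcurve tangent at the plane's
position (central differences on a resampled midcurve).
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SectionPlane", "GapProfile", "make_section_planes", "plane_gap",
           "gap_length_area"]

#: Gaps below this tolerance (mm) count as leaflet contact.
CONTACT_EPS = 1e-12

#: Resolution of the resampled midcurve used for tangent estimation.
_MIDCURVE_RES = 256


@dataclasses.dataclass(frozen=True)
class SectionPlane:
    """Cross-sectional plane given by a point and a unit normal."""

    point: np.ndarray   # (3,)
    normal: np.ndarray  # (3,), unit length


@dataclasses.dataclass
class GapProfile:
    """Per-plane gap lengths and the resulting orifice area."""

    plane_positions: np.ndarray  # (n_planes,) axial coordinate, mm
    gap_lengths: np.ndarray      # (n_planes,) mm
    plane_spacing: float         # dx, mm
    area: float                  # mm^2

    def to_json(self) -> str:
        return json.dumps(
            {"n_planes": int(len(self.gap_lengths)), "area_mm2": self.area},
            sort_keys=True,
        )


def _resample_polyline(curve: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline at n equally spaced arclength values."""
    curve = np.asarray(curve, float)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0:
        return np.repeat(curve[:1], n, axis=0)
    t /= t[-1]
    ti = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(ti, t, curve[:, k]) for k in range(3)])


def make_section_planes(
    anterior_edge: np.ndarray,
    posterior_edge: np.ndarray,
    n_planes: int = 40,
) -> list[SectionPlane]:
    """Equally spaced cutting planes along the commissural span.

    Planes sit at the midpoints of ``n_planes`` equal cells of the span
    of the midcurve along the commissure-to-commissure axis (the line
    through the midcurve endpoints); each plane's normal is the local
    midcurve tangent.
    """
    ant = np.asarray(anterior_edge, float)
    post = np.asarray(posterior_edge, float)
    if ant.ndim != 2 or post.ndim != 2 or len(ant) == 0 or len(post) == 0:
        raise ValueError("edge curves must be non-empty (k, 3) arrays")
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    a = _resample_polyline(ant, _MIDCURVE_RES)
    b = _resample_polyline(post, _MIDCURVE_RES)
    mid = 0.5 * (a + b)
    axis = mid[-1] - mid[0]
    span = np.linalg.norm(axis)
    if span < 1e-12:
        raise ValueError("degenerate commissural span (zero length)")
    u = axis / span
    # axial coordinate of each midcurve sample
    t = (mid - mid[0]) @ u
    # central-difference tangents of the midcurve
    tan = np.gradient(mid, axis=0)
    norms = np.linalg.norm(tan, axis=1, keepdims=True)
    tan = np.where(norms > 1e-15, tan / np.where(norms == 0, 1, norms), u)
    positions = (np.arange(n_planes) + 0.5) * (t[-1] - t[0]) / n_planes + t[0]
    # midcurve axial coordinate may be non-monotone for convoluted curves;
    # use the first crossing for interpolation
    order = np.argsort(t, kind="stable")
    planes = []
    for pos in positions:
        point = np.array([np.interp(pos, t[order], mid[order, k]) for k in range(3)])
        normal = np.array([np.interp(pos, t[order], tan[order, k]) for k in range(3)])
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 1e-15 else u
        planes.append(SectionPlane(point=point, normal=normal))
    return planes


def _plane_crossings(plane: SectionPlane, curve: np.ndarray) -> np.ndarray:
    """All intersection points of a polyline with a plane.

    Segment-plane crossings with linear interpolation; vertices lying on
    the plane are retained.  Multiple crossings are all kept.
    """
    curve = np.asarray(curve, float)
    sd = (curve - plane.point) @ plane.normal
    pts = [curve[i] for i in np.flatnonzero(np.abs(sd) < 1e-12)]
    s0, s1 = sd[:-1], sd[1:]
    cross = np.flatnonzero((s0 * s1) < 0)
    for i in cross:
        w = s0[i] / (s0[i] - s1[i])
        pts.append(curve[i] + w * (curve[i + 1] - curve[i]))
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


def plane_gap(
    plane: SectionPlane,
    anterior_edge: np.ndarray,
    posterior_edge: np.ndarray,
) -> float:
    """Local gap length (mm): minimum distance between the in-plane
    intersection point sets of the two edges; 0 on contact/overlap."""
    pa = _plane_crossings(plane, np.asarray(anterior_edge, float))
    pb = _plane_crossings(plane, np.asarray(posterior_edge, float))
    if len(pa) == 0 or len(pb) == 0:
        logger.warning("cutting plane misses one leaflet edge; gap counted as 0")
        return 0.0
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    gap = float(d.min())
    return 0.0 if gap < CONTACT_EPS else gap


def gap_length_area(
    anterior_edge: np.ndarray,
    posterior_edge: np.ndarray,
    n_planes: int = 40,
) -> GapProfile:
    """Gap-length orifice area of a leaflet free-edge curve pair."""
    planes = make_section_planes(anterior_edge, posterior_edge, n_planes)
    gaps = np.array([plane_gap(pl, anterior_edge, posterior_edge) for pl in planes])
    # plane spacing: span of the midcurve divided by the plane count
    a = _resample_polyline(np.asarray(anterior_edge, float), 2)
    b = _resample_polyline(np.asarray(posterior_edge, float), 2)
    mid = 0.5 * (a + b)
    span = float(np.linalg.norm(mid[-1] - mid[0]))
    dx = span / n_planes
    positions = (np.arange(n_planes) + 0.5) * dx
    return GapProfile(
        plane_positions=positions,
        gap_lengths=gaps,
        plane_spacing=dx,
        area=float(gaps.sum() * dx),
    )
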