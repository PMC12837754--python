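"""Parametric mitral valve geometry.

The valve is described by 12 geometric parameters. In *normalized* form
(the form in which samples are drawn uniformly) they are:

==========  =========================================  ==========
name        meaning                                    units
==========  =========================================  ==========
AP_D        anteroposterior annular diameter (A2-P2)   mm
IC_D_R      intercommissural diameter / AP_D           --
AL_R        AP_D / anterior leaflet length             --
PL_R        posterior length / (AP_D - AL)             --
CL_R        commissure length / (PL - PH)              --
Ant_Blunt   anterior free-edge bluntness               --
AH          anterior annular saddle height             mm
PH          posterior annular saddle height            mm
D_Shape     anterior annulus D-shaped flattening       --
SF_Shape_R  septal flat width / intercommissural diam  --
Com_Loc     top-down commissure position               --
Com_Cur     commissure free-edge curvature             --
==========  =========================================  ==========

Unnormalization produces the mm-scale *physical* parameter vector
{AP, IC, AL, PL, CL, SF_shape, AH, PH, D_shape, Ant_blunt, Com_loc,
Com_cur} used as the 12-dimensional input of the surrogate model and
the sensitivity analysis:

    AP = AP_D
    IC = IC_D_R * AP
    AL = AP / AL_R
    SF_shape = SF_Shape_R * IC
    PL = PL_R * (AP - AL)
    CL = CL_R * (PL - PH)

Note on AL: the ratio AL_R is tabulated in the range [3.2, 7.2], i.e. it
expresses how many anterior-leaflet lengths fit across the annulus, so
the leaflet length is AP divided by the ratio.  The alternative reading
AL = AL_R * AP would make the anterior leaflet several times longer than
the annulus itself and force PL = PL_R * (AP - AL) < 0, which is
geometrically impossible; see docs/methods.md.

A simplified mid-systole construction maps a physical parameter vector to
per-station leaflet profiles over a commissural coordinate s in [0, 1]
(anterolateral commissure at s=0, posteromedial at s=1):

* chord profile  d(s) -- local anteroposterior width of the annular
  orifice, an ellipse chord modulated by D-shape flattening and a septal
  flat bump,
* anterior profile a(s) = AL * sin(pi s)^(1/Ant_blunt),
* posterior profile p(s) = CL + (PL - CL) * w(s), where w is a smooth
  ramp that is 0 at the commissures and 1 on the central belly, with
  transition midpoint controlled by Com_loc and steepness by Com_cur.

Coordinates: the annular plane is z = 0, the commissure-to-commissure
axis is x (spanning [0, IC]), the anteroposterior axis is y.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParamRange",
    "ValveCurves",
    "InfeasibleGeometryError",
    "NORMALIZED_NAMES",
    "PHYSICAL_NAMES",
    "default_ranges",
    "ranges_as_dict",
    "sample_normalized",
    "unnormalize",
    "sample_physical",
    "chord_profile",
    "anterior_profile",
    "posterior_profile",
    "posterior_ramp",
    "build_valve_curves",
]

#: Column order for normalized parameter tables.
NORMALIZED_NAMES: tuple[str, ...] = (
    "AP_D", "IC_D_R", "AL_R", "PL_R", "CL_R", "Ant_Blunt",
    "AH", "PH", "D_Shape", "SF_Shape_R", "Com_Loc", "Com_Cur",
)

#: Column order for physical (unnormalized, mm-scale) parameter tables.
PHYSICAL_NAMES: tuple[str, ...] = (
    "AP", "IC", "AL", "PL", "CL", "SF_shape",
    "AH", "PH", "D_shape", "Ant_blunt", "Com_loc", "Com_cur",
)


class InfeasibleGeometryError(ValueError):
    """Raised when a parameter vector violates a geometric feasibility
    constraint (currently PL <= PH, which would make CL non-positive)."""


@dataclasses.dataclass(frozen=True)
class ParamRange:
    """Closed sampling interval for one normalized parameter."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lo) or not np.isfinite(self.hi):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.lo > self.hi:
            raise ValueError(
                f"{self.name}: lower bound {self.lo} exceeds upper bound {self.hi}"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


# Physiological sampling ranges of the 12 leaflet/annulus parameters.
_DEFAULT_RANGES: tuple[tuple[str, float, float], ...] = (
    ("AP_D", 24.1, 45.2),
    ("IC_D_R", 0.97, 1.29),
    ("AL_R", 3.2, 7.2),
    ("PL_R", 0.16, 1.0),
    ("CL_R", 0.5, 0.75),
    ("Ant_Blunt", 0.5, 2.05),
    ("AH", 0.3, 0.7),
    ("PH", 1.0, 2.0),
    ("D_Shape", 0.0, 0.038),
    ("SF_Shape_R", 0.01, 0.019),
    ("Com_Loc", 0.26, 0.6),
    ("Com_Cur", 0.2, 0.6),
)


def default_ranges() -> list[ParamRange]:
    """Return the 12 default normalized parameter ranges."""
    return [ParamRange(n, lo, hi) for n, lo, hi in _DEFAULT_RANGES]


def ranges_as_dict(ranges: Iterable[ParamRange] | None = None) -> dict[str, ParamRange]:
    ranges = default_ranges() if ranges is None else list(ranges)
    return {r.name: r for r in ranges}


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_normalized(
    n: int,
    ranges: Sequence[ParamRange] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw ``n`` independent uniform samples of the normalized parameters.

    Each coordinate is uniform on its range.  Returns a DataFrame with the
    columns of :data:`NORMALIZED_NAMES`; reproducible for equal seeds.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ranges = default_ranges() if ranges is None else list(ranges)
    by_name = {r.name: r for r in ranges}
    missing = set(NORMALIZED_NAMES) - set(by_name)
    if missing:
        raise ValueError(f"missing parameter ranges: {sorted(missing)}")
    rng = _as_rng(seed)
    lo = np.array([by_name[c].lo for c in NORMALIZED_NAMES])
    hi = np.array([by_name[c].hi for c in NORMALIZED_NAMES])
    u = rng.random((n, len(NORMALIZED_NAMES)))
    return pd.DataFrame(lo + u * (hi - lo), columns=list(NORMALIZED_NAMES))


def unnormalize(params: pd.DataFrame | Mapping[str, float]) -> pd.DataFrame:
    """Map normalized parameters to the physical (mm-scale) vector.

    Raises :class:`InfeasibleGeometryError` if any row has PL <= PH
    (the commissure length CL = CL_R * (PL - PH) would be non-positive).
    """
    if not isinstance(params, pd.DataFrame):
        params = pd.DataFrame([dict(params)])
    p = params
    ap = p["AP_D"].to_numpy(float)
    ic = p["IC_D_R"].to_numpy(float) * ap
    al = ap / p["AL_R"].to_numpy(float)
    pl = p["PL_R"].to_numpy(float) * (ap - al)
    ph = p["PH"].to_numpy(float)
    bad = pl <= ph
    if np.any(bad):
        idx = np.flatnonzero(bad)
        raise InfeasibleGeometryError(
            f"{bad.sum()} sample(s) have PL <= PH (first offending rows "
            f"{idx[:5].tolist()}); CL would be non-positive"
        )
    cl = p["CL_R"].to_numpy(float) * (pl - ph)
    out = pd.DataFrame(
        {
            "AP": ap,
            "IC": ic,
            "AL": al,
            "PL": pl,
            "CL": cl,
            "SF_shape": p["SF_Shape_R"].to_numpy(float) * ic,
            "AH": p["AH"].to_numpy(float),
            "PH": ph,
            "D_shape": p["D_Shape"].to_numpy(float),
            "Ant_blunt": p["Ant_Blunt"].to_numpy(float),
            "Com_loc": p["Com_Loc"].to_numpy(float),
            "Com_cur": p["Com_Cur"].to_numpy(float),
        }
    )
    out.index = p.index
    return out[list(PHYSICAL_NAMES)]


def sample_physical(
    n: int,
    ranges: Sequence[ParamRange] | None = None,
    seed: int | np.random.Generator = 0,
    max_tries: int = 100,
) -> tuple[pd.DataFrame, int]:
    """Sample exactly ``n`` feasible physical parameter vectors.

    Infeasible draws (PL <= PH) are rejected and resampled.  Returns the
    physical table and the number of rejected draws.  With the default
    ranges no rejection ever occurs (min PL = 2.65 mm > max PH = 2 mm),
    but narrower custom ranges may reject.
    """
    rng = _as_rng(seed)
    kept: list[pd.DataFrame] = []
    n_rejected = 0
    remaining = n
    for _ in range(max_tries):
        if remaining == 0:
            break
        norm = sample_normalized(remaining, ranges, rng)
        pl = norm["PL_R"].to_numpy() * (
            norm["AP_D"].to_numpy() - norm["AP_D"].to_numpy() / norm["AL_R"].to_numpy()
        )
        ok = pl > norm["PH"].to_numpy()
        n_rejected += int((~ok).sum())
        good = norm.loc[ok]
        if len(good):
            kept.append(unnormalize(good))
        remaining = n - sum(len(k) for k in kept)
    else:
        raise InfeasibleGeometryError(
            f"could not draw {n} feasible samples in {max_tries} rounds "
            f"({n_rejected} rejections); check the parameter ranges"
        )
    if not kept:
        return pd.DataFrame(columns=list(PHYSICAL_NAMES)), n_rejected
    out = pd.concat(kept, ignore_index=True)
    return out.iloc[:n].reset_index(drop=True), n_rejected


# ---------------------------------------------------------------------------
# Mid-systole profile construction
# ---------------------------------------------------------------------------

#: Width of the Gaussian septal-flattening bump in commissural coordinate.
SEPTAL_BUMP_WIDTH = 0.2


def _septal_bump(s: np.ndarray) -> np.ndarray:
    """Fixed unit-amplitude bump centered at s = 0.5."""
    return np.exp(-0.5 * ((s - 0.5) / SEPTAL_BUMP_WIDTH) ** 2)


def chord_profile(s, AP, D_shape=0.0, SF_shape=0.0, IC=1.0):
    """Local anteroposterior chord d(s) of the annular orifice (mm).

    An elliptical chord AP * sqrt(1 - (2s-1)^2), reduced uniformly by the
    D-shape flattening and locally (near s=0.5) by the septal flat.
    d(0) = d(1) = 0.
    """
    s = np.asarray(s, dtype=float)
    ell = np.sqrt(np.clip(1.0 - (2.0 * s - 1.0) ** 2, 0.0, None))
    return AP * ell * (1.0 - D_shape) * (1.0 - (SF_shape / IC) * _septal_bump(s))


def anterior_profile(s, AL, Ant_blunt=1.0):
    """Anterior leaflet length profile a(s) = AL * sin(pi s)^(1/Ant_blunt).

    Ant_blunt > 1 flattens (blunts) the free edge; a(0.5) = AL always.
    """
    s = np.asarray(s, dtype=float)
    base = np.clip(np.sin(np.pi * s), 0.0, None)
    return AL * base ** (1.0 / Ant_blunt)


def posterior_ramp(s, Com_loc, Com_cur):
    """Smooth ramp w(s): 0 at the commissures, 1 on the central belly.

    Implemented as a cubic smoothstep on [lo, hi] mirrored about s = 0.5.
    The transition midpoint is Com_loc and the transition half-width
    shrinks as Com_cur grows (steeper commissural free edges).
    """
    s = np.asarray(s, dtype=float)
    half_width = 0.05 / np.clip(Com_cur, 1e-6, None)
    lo = np.clip(Com_loc - half_width, 0.01, 0.47)
    hi = np.clip(Com_loc + half_width, lo + 0.02, 0.5)
    sm = np.where(s <= 0.5, s, 1.0 - s)  # mirror symmetry
    t = np.clip((sm - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclasses.dataclass
class ValveCurves:
    """Mid-systole leaflet profiles sampled at commissural stations.

    ``stations`` are midpoints of ``n_stations`` equal cells of [0, 1], so
    sums over stations approximate integrals with cell width 1/n_stations
    (physical spacing dx = IC / n_stations along the commissural axis).
    """

    stations: np.ndarray          # (m,) commissural coordinate s
    x: np.ndarray                 # (m,) position along commissural axis, mm
    chord: np.ndarray             # (m,) d(s), mm
    anterior: np.ndarray          # (m,) a(s), mm
    posterior: np.ndarray         # (m,) p(s), mm
    annulus_points: np.ndarray    # (2m, 3) anterior rim then posterior rim, mm
    params: pd.Series             # the physical parameters used

    @property
    def dx(self) -> float:
        """Station spacing along the commissural axis (mm)."""
        return float(self.params["IC"]) / len(self.stations)


def build_valve_curves(q: Mapping[str, float] | pd.Series, n_stations: int = 400) -> ValveCurves:
    """Construct the simplified mid-systole valve profiles for one valve.

    ``q`` is a physical parameter vector (keys of :data:`PHYSICAL_NAMES`).
    """
    if n_stations < 3:
        raise ValueError("n_stations must be >= 3")
    q = pd.Series(dict(q), dtype=float)
    s = (np.arange(n_stations) + 0.5) / n_stations
    d = chord_profile(s, q["AP"], q["D_shape"], q["SF_shape"], q["IC"])
    a = anterior_profile(s, q["AL"], q["Ant_blunt"])
    w = posterior_ramp(s, q["Com_loc"], q["Com_cur"])
    p = q["CL"] + (q["PL"] - q["CL"]) * w
    x = s * q["IC"]
    saddle = np.sin(np.pi * s)
    ant_rim = np.column_stack([x, +d / 2.0, q["AH"] * saddle])
    post_rim = np.column_stack([x, -d / 2.0, -q["PH"] * saddle])
    return ValveCurves(
        stations=s,
        x=x,
        chord=d,
        anterior=a,
        posterior=p,
        annulus_points=np.vstack([ant_rim, post_rim]),
        params=q,
    )
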