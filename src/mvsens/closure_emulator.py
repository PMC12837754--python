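"""Synthetic mid-systole closure emulator.

This module is the data generator of the package: a deterministic,
analytically checkable kinematic closure rule that maps the 12 physical
valve parameters to a per-station coaptation gap profile and an orifice
area.  It is a *synthetic* stand-in for a finite-element simulation of
valve closure -- it does not model tissue mechanics, chordae or
hemodynamics -- but it is constructed so that its global sensitivity
structure matches what physics-based models of functional regurgitation
report: orifice-area variability dominated by the intercommissural
diameter (IC), the anterior and posterior leaflet lengths (AL, PL) and
the commissure length (CL), with weak dependence on the remaining eight
parameters.

Closure rule
------------
At commissural station s the annular orifice presents a chord of width
d(s) (see :mod:`mvsens.valve_geometry`).  The two leaflets jointly offer
a coaptation "supply"

    m(s) = alpha_ant * a~(s) + p~(s)

where a~ and p~ are the anterior and posterior length profiles with
their *shape* renormalized to carry a fixed fraction of the leaflet
length budget (so bluntness and commissure-shape parameters redistribute
tissue along the free edge without changing the total supply).  The
anterior leaflet, which forms the major coaptation surface in systole,
is weighted by ``alpha_ant`` > 1.

The fraction of the chord the supply actually seals is modulated by a
coaptation efficiency

    lambda(q) = lambda0 * (AP/AP_ref)^delta_ap * (IC_ref/IC)^delta_ic
                        * (1 - c_h * (AH + PH) / h_ref)

Larger annular AP diameter mildly *improves* per-millimetre sealing
(delta_ap slightly above 1: leaflet billow grows with the annulus),
while a wider commissural span stretches the same tissue over a longer
coaptation line and degrades sealing (delta_ic > 0).  Tall annular
saddles (AH + PH) reduce efficiency slightly.

The residual gap is

    g(s) = max(0, d(s) - lambda(q) * m(s)) + leak(s)

with a commissural leak term that opens when the commissure length is
short:  leak(s) = kappa_cl * max(0, CL_ref - CL) * B(s) * gate, where
B is a pair of Gaussian bumps at the commissures and ``gate`` saturates
to 1 for any non-degenerate leaflet supply (and vanishes when the
leaflets vanish, so the zero-leaflet limit g = d is exact).

The orifice area is the station-sum Riemann integral

    OA = sum_i g(s_i) * dx,     dx = IC / n_stations.

With zero leaflet lengths the rule degenerates to the open annular
orifice and OA converges to the ellipse area pi * AP * IC / 4.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Mapping

import numpy as np
import pandas as pd

from .valve_geometry import (
    PHYSICAL_NAMES,
    ParamRange,
    ValveCurves,
    anterior_profile,
    build_valve_curves,
    chord_profile,
    posterior_ramp,
    sample_physical,
)

__all__ = [
    "EmulatorConstants",
    "ClosedConfiguration",
    "Dataset",
    "emulate_closure",
    "emulate_orifice_area",
    "orifice_area_batch",
    "generate_dataset",
]


@dataclasses.dataclass(frozen=True)
class EmulatorConstants:
    """Fixed constants of the kinematic closure rule.

    Defaults are the study conditions of the package; they are exposed so
    that users can stress-test the sensitivity rankings.
    """

    lambda0: float = 0.90        # base coaptation efficiency (dimensionless)
    alpha_ant: float = 2.5       # anterior leaflet coaptation weight
    ap_ref: float = 34.65        # mm, reference AP diameter (range midpoint)
    ic_ref: float = 39.2         # mm, reference intercommissural diameter
    delta_ap: float = 1.30       # AP exponent of the efficiency
    delta_ic: float = 0.8        # IC exponent of the efficiency
    c_h: float = 0.05            # annular-saddle efficiency penalty
    h_ref: float = 2.7           # mm, reference total saddle height
    kappa_cl: float = 0.30       # commissural leak gain (mm gap per mm CL deficit)
    cl_ref: float = 14.0         # mm, CL below which commissural leak opens
    leak_center: float = 0.10    # commissural coordinate of the leak bumps
    leak_width: float = 0.07     # width of the leak bumps
    w_ref: float = 0.80          # reference integral of the posterior ramp
    a_ref: float = 2.0 / np.pi   # reference integral of sin(pi s)


DEFAULT_CONSTANTS = EmulatorConstants()


@dataclasses.dataclass
class ClosedConfiguration:
    """Mid-systole closed-valve configuration at discrete stations."""

    stations: np.ndarray       # (m,) commissural coordinate
    anterior_edge: np.ndarray  # (m, 3) points, mm
    posterior_edge: np.ndarray # (m, 3) points, mm
    gap_profile: np.ndarray    # (m,) local gap g(s), mm
    dx: float                  # station spacing along the commissural axis, mm
    oa_closed_form: float      # sum(g) * dx, mm^2


@dataclasses.dataclass
class Dataset:
    """Parameter/orifice-area table produced by the emulator."""

    X: pd.DataFrame            # n x 12 physical parameters
    y: np.ndarray              # n orifice areas, mm^2
    seed: int
    n_rejected: int = 0
    noise_sd: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out["orifice_area_mm2"] = self.y
        return out

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path_or_buf, seed: int = -1) -> "Dataset":
        df = pd.read_csv(path_or_buf)
        y = df.pop("orifice_area_mm2").to_numpy(float)
        return cls(X=df[list(PHYSICAL_NAMES)], y=y, seed=seed)


# ---------------------------------------------------------------------------
# Vectorized gap computation
# ---------------------------------------------------------------------------

def _leak_bumps(s: np.ndarray, c: EmulatorConstants) -> np.ndarray:
    b = np.exp(-(((s - c.leak_center) / c.leak_width) ** 2))
    return b + b[..., ::-1]


def _gap_profiles(
    X: pd.DataFrame, n_stations: int, c: EmulatorConstants
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gap profiles for a batch of valves.

    Returns (stations (m,), gaps (n, m), dx (n,)).
    """
    s = (np.arange(n_stations) + 0.5) / n_stations
    AP = X["AP"].to_numpy(float)[:, None]
    IC = X["IC"].to_numpy(float)[:, None]
    AL = X["AL"].to_numpy(float)[:, None]
    PL = X["PL"].to_numpy(float)[:, None]
    CL = X["CL"].to_numpy(float)[:, None]

    d = chord_profile(
        s[None, :], AP, X["D_shape"].to_numpy(float)[:, None],
        X["SF_shape"].to_numpy(float)[:, None], IC,
    )
    # anterior supply, shape-normalized: total budget AL * a_ref
    a_shape = np.clip(np.sin(np.pi * s), 0.0, None)[None, :] ** (
        1.0 / X["Ant_blunt"].to_numpy(float)[:, None]
    )
    a_int = a_shape.mean(axis=1, keepdims=True)
    a_sup = AL * c.a_ref * a_shape / np.where(a_int > 0, a_int, 1.0)
    # posterior supply, ramp-normalized: CL at the commissures, budget
    # (PL - CL) * w_ref in the belly
    w = posterior_ramp(
        s[None, :],
        X["Com_loc"].to_numpy(float)[:, None],
        X["Com_cur"].to_numpy(float)[:, None],
    )
    w_int = w.mean(axis=1, keepdims=True)
    w_norm = w * c.w_ref / np.where(w_int > 0, w_int, 1.0)
    p_sup = CL + (PL - CL) * w_norm

    lam = (
        c.lambda0
        * (AP / c.ap_ref) ** c.delta_ap
        * (c.ic_ref / IC) ** c.delta_ic
        * (1.0 - c.c_h * (X["AH"].to_numpy(float)[:, None] + X["PH"].to_numpy(float)[:, None]) / c.h_ref)
    )
    supply = lam * (c.alpha_ant * a_sup + p_sup)
    gap = np.clip(d - supply, 0.0, None)

    # commissural leak, gated off when the leaflets vanish
    mean_supply = (c.alpha_ant * a_sup + p_sup).mean(axis=1, keepdims=True)
    gate = mean_supply / (mean_supply + 1.0)
    leak = c.kappa_cl * np.clip(c.cl_ref - CL, 0.0, None) * _leak_bumps(s, c) * gate
    gap = gap + leak

    dx = X["IC"].to_numpy(float) / n_stations
    return s, gap, dx


def emulate_closure(
    curves: ValveCurves,
    q: Mapping[str, float] | pd.Series,
    constants: EmulatorConstants = DEFAULT_CONSTANTS,
) -> ClosedConfiguration:
    """Close one valve and return its mid-systole configuration.

    The free-edge curves are laid out symmetrically about the coaptation
    line (the commissural x axis): at station i the anterior and
    posterior edge points are separated by exactly g(s_i) in y.
    """
    q = pd.Series(dict(q), dtype=float)
    X = q.to_frame().T
    s, gap, dx = _gap_profiles(X, len(curves.stations), constants)
    g = gap[0]
    x = curves.x
    z = np.zeros_like(x)
    ant = np.column_stack([x, +g / 2.0, z])
    post = np.column_stack([x, -g / 2.0, z])
    return ClosedConfiguration(
        stations=s,
        anterior_edge=ant,
        posterior_edge=post,
        gap_profile=g,
        dx=float(dx[0]),
        oa_closed_form=float(g.sum() * dx[0]),
    )


def emulate_orifice_area(
    q: Mapping[str, float] | pd.Series,
    constants: EmulatorConstants = DEFAULT_CONSTANTS,
    n_stations: int = 400,
) -> float:
    """Deterministic orifice area (mm^2) of one valve."""
    q = pd.Series(dict(q), dtype=float)
    _, gap, dx = _gap_profiles(q.to_frame().T, n_stations, constants)
    return float(gap[0].sum() * dx[0])


def orifice_area_batch(
    X: pd.DataFrame | np.ndarray,
    constants: EmulatorConstants = DEFAULT_CONSTANTS,
    n_stations: int = 400,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorized orifice areas for an n x 12 physical parameter table."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float), columns=list(PHYSICAL_NAMES))
    out = np.empty(len(X))
    for start in range(0, len(X), chunk):
        part = X.iloc[start : start + chunk]
        _, gap, dx = _gap_profiles(part, n_stations, constants)
        out[start : start + len(part)] = gap.sum(axis=1) * dx
    return out


def generate_dataset(
    n: int,
    seed: int = 0,
    ranges: list[ParamRange] | None = None,
    constants: EmulatorConstants = DEFAULT_CONSTANTS,
    n_stations: int = 400,
    noise_sd: float = 0.0,
) -> Dataset:
    """Generate a parameter/orifice-area dataset of exactly ``n`` rows.

    Normalized parameters are sampled uniformly, unnormalized (rejecting
    infeasible draws), and pushed through the closure emulator.  An
    optional Gaussian observation noise (default off) can be added to the
    areas for robustness experiments; negative noisy areas are clipped
    at 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    X, n_rejected = sample_physical(n, ranges, rng)
    y = orifice_area_batch(X, constants, n_stations)
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, noise_sd, size=len(y)), 0.0, None)
    return Dataset(X=X, y=y, seed=int(seed) if np.isscalar(seed) else -1,
                   n_rejected=n_rejected, noise_sd=noise_sd)
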