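"""First-order Sobol indices and distribution comparison.

The estimator follows the fix-one-dimension Monte-Carlo scheme: for each
input dimension d, draw ``n_outer`` fixed values of that coordinate (the
d-th column of a joint sampler draw); for each fixed value draw
``n_inner`` fresh joint samples, overwrite coordinate d with the fixed
value, evaluate the model and take the inner mean.  The conditional
variance V_d = Var_outer( E_inner[Y | X_d] ) and the first-order index
S_d = V_d / Var(y), with Var(y) estimated from the pooled
n_outer * n_inner * D model evaluations.

Draw order (relied upon by exact-replay cross-checks): one generator is
created from the seed; for each dimension d in order, first one sampler
call of size ``n_outer`` (whose d-th column gives the fixed values),
then ``n_outer`` sampler calls of size ``n_inner``.

Because the joint sampler may induce dependencies between coordinates
(e.g. physical valve parameters obtained by unnormalizing uniform
ratios), overwriting coordinate d breaks that dependency: the scheme is
the literal "repeat the value of that dimension" reading, not a
conditional-distribution decomposition.

The module also provides common-grid histogram density estimation and
the total-variation distance TV(p, q) = 1/2 * integral |p - q| dx used
to compare orifice-area distributions.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SobolResult",
    "DensityEstimate",
    "first_order_indices",
    "rank_parameters",
    "estimate_density",
    "common_grid",
    "total_variation",
]

Sampler = Callable[[int, np.random.Generator], np.ndarray]
Model = Callable[[np.ndarray], np.ndarray]


@dataclasses.dataclass
class SobolResult:
    """Per-dimension first-order Sobol indices.

    ``indices`` are the raw Monte-Carlo estimates (small negatives are
    possible); ``indices_clipped`` clips them at 0 for reporting.
    """

    names: list[str]
    indices: np.ndarray           # raw S_d
    conditional_variances: np.ndarray  # V_d, output units^2
    total_variance: float         # Var(y), output units^2
    n_outer: int
    n_inner: int
    seed: int
    degenerate: bool = False      # Var(y) == 0

    @property
    def indices_clipped(self) -> np.ndarray:
        return np.clip(self.indices, 0.0, None)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "indices": [float(v) for v in self.indices],
            "conditional_variances": [float(v) for v in self.conditional_variances],
            "total_variance": float(self.total_variance),
            "n_outer": self.n_outer,
            "n_inner": self.n_inner,
            "seed": self.seed,
        }


def first_order_indices(
    model: Model,
    sampler: Sampler,
    n_outer: int,
    n_inner: int,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> SobolResult:
    """Estimate first-order Sobol indices of ``model`` by dimension fixing.

    ``model`` maps an (n, D) array to n outputs and must be
    deterministic; ``sampler(n, rng)`` draws an (n, D) array from the
    joint input distribution.
    """
    if n_outer < 2 or n_inner < 2:
        raise ValueError("n_outer and n_inner must be >= 2")
    rng = np.random.default_rng(seed)
    probe = np.asarray(sampler(1, np.random.default_rng(0)))
    ndim = probe.shape[1]
    if names is None:
        names = [f"x{d}" for d in range(ndim)]
    elif len(names) != ndim:
        raise ValueError("names length does not match sampler dimension")

    cond_var = np.empty(ndim)
    pooled_sum = 0.0
    pooled_sumsq = 0.0
    pooled_n = 0
    for d in range(ndim):
        fixed_vals = np.asarray(sampler(n_outer, rng))[:, d]
        inner_means = np.empty(n_outer)
        for i in range(n_outer):
            X = np.asarray(sampler(n_inner, rng), dtype=float).copy()
            X[:, d] = fixed_vals[i]
            y = np.asarray(model(X), dtype=float)
            inner_means[i] = y.mean()
            pooled_sum += y.sum()
            pooled_sumsq += float(y @ y)
            pooled_n += y.size
        cond_var[d] = inner_means.var(ddof=1)

    total_var = (pooled_sumsq - pooled_sum**2 / pooled_n) / (pooled_n - 1)
    if total_var <= 0:
        warnings.warn("model output has zero variance; all Sobol indices set to 0")
        return SobolResult(list(names), np.zeros(ndim), np.zeros(ndim), 0.0,
                           n_outer, n_inner, int(seed), degenerate=True)
    return SobolResult(
        names=list(names),
        indices=cond_var / total_var,
        conditional_variances=cond_var,
        total_variance=float(total_var),
        n_outer=n_outer,
        n_inner=n_inner,
        seed=int(seed),
    )


def rank_parameters(result: SobolResult, k: int) -> list[str]:
    """Top-k parameter names by first-order index (clipped at 0).

    Ties are broken alphabetically.
    """
    if k > len(result.names):
        raise ValueError(f"k={k} exceeds the number of parameters {len(result.names)}")
    order = sorted(zip(result.names, result.indices_clipped), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order[:k]]


# ---------------------------------------------------------------------------
# Densities and total variation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DensityEstimate:
    """Histogram density on a fixed grid."""

    edges: np.ndarray     # (n_bins + 1,)
    density: np.ndarray   # (n_bins,), integrates to 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def common_grid(sample_sets: Sequence[np.ndarray], n_bins: int = 100) -> np.ndarray:
    """Equal-width bin edges spanning the pooled range of all sample sets."""
    lo = min(float(np.min(s)) for s in sample_sets)
    hi = max(float(np.max(s)) for s in sample_sets)
    if hi <= lo:
        hi = lo + 1.0  # all mass at a point: give it one unit-width support
    return np.linspace(lo, hi, n_bins + 1)


def estimate_density(
    samples: np.ndarray,
    edges: np.ndarray | None = None,
    n_bins: int = 100,
) -> DensityEstimate:
    """Normalized histogram density of ``samples`` on a fixed grid.

    If ``edges`` is omitted a grid spanning the sample range is used.
    Samples outside the grid are counted into the nearest edge bin so
    that the density always integrates to 1.
    """
    samples = np.asarray(samples, float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples for a density estimate")
    if edges is None:
        edges = common_grid([samples], n_bins)
    clipped = np.clip(samples, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    return DensityEstimate(edges=np.asarray(edges, float), density=density)


def total_variation(p: DensityEstimate, q: DensityEstimate) -> float:
    """Total-variation distance 1/2 * sum |p_i - q_i| * dx, in [0, 1]."""
    if p.edges.shape != q.edges.shape or not np.allclose(p.edges, q.edges):
        raise ValueError("density estimates are on different grids")
    return float(0.5 * np.abs(p.density - q.density).sum() * p.bin_width)
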