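"""End-to-end experiment orchestration.

The full experiment mirrors a surrogate-based sensitivity study of
mitral valve orifice area:

1. generate ``n_samples`` valves with the closure emulator;
2. over ``n_splits`` random train/test splits, select the GP initial
   length scale by k-fold cross-validation, fit the ARD GP and the
   linear baseline, and record test R^2 / MAPE for both;
3. refit the GP on all samples with the consensus initial length scale;
4. estimate first-order Sobol indices of the GP surrogate by the
   dimension-fixing scheme and rank the parameters;
5. build orifice-area densities for (a) the emulator outputs, (b) the
   GP with all 12 parameters varying and (c) the GP with only the top-k
   parameters varying (the rest fixed at their means), and compute the
   three pairwise total-variation distances.

All randomness flows from one master seed through independent child
seeds per stage, so stages are individually reproducible and the JSON
report is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .closure_emulator import (
    DEFAULT_CONSTANTS,
    Dataset,
    EmulatorConstants,
    generate_dataset,
)
from .gp_surrogate import (
    FitReport,
    TrainedGP,
    cv_init_lengthscale,
    default_init_grid,
    fit_gp,
    fit_linear,
    mape,
    predict_linear,
    predict_mean,
    r_squared,
)
from .sobol_sensitivity import (
    DensityEstimate,
    SobolResult,
    common_grid,
    estimate_density,
    first_order_indices,
    rank_parameters,
    total_variation,
)
from .valve_geometry import (
    PHYSICAL_NAMES,
    ParamRange,
    default_ranges,
    sample_physical,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ReportBundle",
    "run_experiment",
    "fix_noninfluential",
    "physical_means",
    "save_figures",
]


@dataclasses.dataclass
class ExperimentConfig:
    """Settings of the full experiment (defaults are the study protocol)."""

    schema_version: int = 1
    n_samples: int = 440
    n_train: int = 350
    n_test: int = 90
    n_splits: int = 5
    sigma2: float = 1e-4
    cv_folds: int = 5
    cv_factors: tuple[float, ...] = (0.1, 0.316, 1.0, 3.16, 10.0)
    gp_restarts: int = 2
    sobol_n_outer: int = 1000
    sobol_n_inner: int = 1000
    top_k: int = 4
    n_stations: int = 400
    n_planes: int = 40
    n_density: int = 20000
    density_bins: int = 100
    mean_mode: str = "empirical"   # or "midpoint"
    n_mean_samples: int = 100000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n_samples:
            raise ValueError("n_train + n_test must equal n_samples")
        for field in ("n_samples", "n_train", "n_test", "n_splits",
                      "sobol_n_outer", "sobol_n_inner", "top_k",
                      "n_stations", "n_planes", "n_density", "density_bins"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.mean_mode not in ("empirical", "midpoint"):
            raise ValueError("mean_mode must be 'empirical' or 'midpoint'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cv_factors"] = list(self.cv_factors)
        return d

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cv_factors" in raw:
            raw["cv_factors"] = tuple(raw["cv_factors"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class ReportBundle:
    """Everything the experiment produced, serializable to JSON."""

    config: ExperimentConfig
    dataset: Dataset
    fit_reports: list[FitReport]
    mean_metrics: dict[str, float]
    gp_full: TrainedGP
    sobol: SobolResult
    top_parameters: list[str]
    parameter_means: dict[str, float]
    density_edges: np.ndarray
    densities: dict[str, DensityEstimate]   # keys: sim, gp12, gp4
    tv_distances: dict[str, float]          # keys: sim_gp12, sim_gp4, gp4_gp12

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "package_version": __version__,
                "config_hash": self.config.config_hash(),
                "master_seed": self.config.master_seed,
            },
            "config": self.config.to_dict(),
            "dataset": {
                "n": len(self.dataset.y),
                "n_rejected": self.dataset.n_rejected,
                "orifice_area_mean_mm2": float(self.dataset.y.mean()),
                "orifice_area_sd_mm2": float(self.dataset.y.std()),
            },
            "fit_reports": [r.to_dict() for r in self.fit_reports],
            "mean_metrics": {k: float(v) for k, v in self.mean_metrics.items()},
            "gp_lengthscales": self.gp_full.lengthscales.tolist(),
            "sobol": self.sobol.to_dict(),
            "top_parameters": list(self.top_parameters),
            "parameter_means": {k: float(v) for k, v in self.parameter_means.items()},
            "density_edges": self.density_edges.tolist(),
            "densities": {k: v.density.tolist() for k, v in self.densities.items()},
            "tv_distances": {k: float(v) for k, v in self.tv_distances.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def physical_means(
    ranges: Sequence[ParamRange] | None = None,
    mode: str = "empirical",
    n: int = 100000,
    seed: int = 0,
) -> pd.Series:
    """Mean of each physical parameter under the sampling distribution.

    ``empirical``: Monte-Carlo mean of the unnormalized parameters (the
    unnormalization is nonlinear, so this differs from midpoints).
    ``midpoint``: unnormalize the normalized-range midpoints.
    """
    ranges = default_ranges() if ranges is None else list(ranges)
    if mode == "empirical":
        X, _ = sample_physical(n, ranges, seed)
        return X.mean(axis=0)
    if mode == "midpoint":
        from .valve_geometry import unnormalize

        mid = {r.name: 0.5 * (r.lo + r.hi) for r in ranges}
        return unnormalize(mid).iloc[0]
    raise ValueError("mode must be 'empirical' or 'midpoint'")


def fix_noninfluential(
    params_sample: pd.DataFrame,
    top_k_names: Sequence[str],
    means: Mapping[str, float],
) -> pd.DataFrame:
    """Freeze every parameter outside ``top_k_names`` at its mean value."""
    unknown = set(top_k_names) - set(params_sample.columns)
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
    out = params_sample.copy()
    for col in out.columns:
        if col not in top_k_names:
            out[col] = float(means[col])
    return out


def _physical_sampler(ranges):
    def sampler(n: int, rng: np.random.Generator) -> np.ndarray:
        X, _ = sample_physical(n, ranges, rng)
        return X.to_numpy()

    return sampler


def run_experiment(
    cfg: ExperimentConfig,
    ranges: Sequence[ParamRange] | None = None,
    constants: EmulatorConstants = DEFAULT_CONSTANTS,
) -> ReportBundle:
    """Run the full surrogate/sensitivity experiment."""
    ranges = default_ranges() if ranges is None else list(ranges)
    ss = np.random.SeedSequence(cfg.master_seed)
    seeds = ss.generate_state(7)
    s_data, s_split, s_cv, s_gp, s_sobol, s_means, s_density = (int(s) for s in seeds)

    logger.info("stage 1/5: generating %d emulator samples", cfg.n_samples)
    try:
        ds = generate_dataset(cfg.n_samples, seed=s_data, ranges=ranges,
                              constants=constants, n_stations=cfg.n_stations)
    except Exception as exc:
        raise RuntimeError(f"[dataset] generation failed: {exc}") from exc
    X_all = ds.X.to_numpy()
    y_all = ds.y

    logger.info("stage 2/5: %d train/test splits", cfg.n_splits)
    rng_split = np.random.default_rng(s_split)
    reports: list[FitReport] = []
    chosen_inits: list[tuple[float, ...]] = []
    try:
        for split_id in range(cfg.n_splits):
            perm = rng_split.permutation(cfg.n_samples)
            tr, te = perm[: cfg.n_train], perm[cfg.n_train :]
            Xtr, ytr, Xte, yte = X_all[tr], y_all[tr], X_all[te], y_all[te]
            grid = default_init_grid(Xtr, cfg.cv_factors)
            init = cv_init_lengthscale(Xtr, ytr, grid, k_folds=cfg.cv_folds,
                                       seed=s_cv + split_id, sigma2=cfg.sigma2)
            chosen_inits.append(tuple(init))
            gp = fit_gp(Xtr, ytr, init, sigma2=cfg.sigma2,
                        n_restarts=cfg.gp_restarts, seed=s_gp + split_id)
            pred = predict_mean(gp, Xte)
            reports.append(FitReport("gp", split_id, r_squared(yte, pred),
                                     mape(yte, pred)))
            lin = fit_linear(Xtr, ytr)
            lpred = predict_linear(lin, Xte)
            reports.append(FitReport("linear", split_id, r_squared(yte, lpred),
                                     mape(yte, lpred)))
    except Exception as exc:
        raise RuntimeError(f"[splits] fitting failed: {exc}") from exc

    mean_metrics = {
        "gp_r2": float(np.mean([r.r2 for r in reports if r.model == "gp"])),
        "gp_mape": float(np.mean([r.mape for r in reports if r.model == "gp"])),
        "linear_r2": float(np.mean([r.r2 for r in reports if r.model == "linear"])),
        "linear_mape": float(np.mean([r.mape for r in reports if r.model == "linear"])),
    }

    logger.info("stage 3/5: refitting GP on all %d samples", cfg.n_samples)
    # consensus initial length scale: the init chosen most often across
    # splits; ties broken toward the smaller init
    counts = Counter(chosen_inits)
    best_init = np.asarray(
        sorted(counts, key=lambda t: (-counts[t], float(np.mean(np.log(t)))))[0]
    )
    try:
        gp_full = fit_gp(X_all, y_all, best_init, sigma2=cfg.sigma2,
                         n_restarts=cfg.gp_restarts, seed=s_gp + 1000)
    except Exception as exc:
        raise RuntimeError(f"[refit] full-data GP fit failed: {exc}") from exc

    logger.info("stage 4/5: Sobol indices (%d x %d per dimension)",
                cfg.sobol_n_outer, cfg.sobol_n_inner)
    sampler = _physical_sampler(ranges)
    try:
        sobol = first_order_indices(
            model=lambda A: predict_mean(gp_full, A),
            sampler=sampler,
            n_outer=cfg.sobol_n_outer,
            n_inner=cfg.sobol_n_inner,
            seed=s_sobol,
            names=list(PHYSICAL_NAMES),
        )
    except Exception as exc:
        raise RuntimeError(f"[sobol] index estimation failed: {exc}") from exc
    top = rank_parameters(sobol, cfg.top_k)

    logger.info("stage 5/5: densities and total-variation distances")
    try:
        means = physical_means(ranges, cfg.mean_mode, cfg.n_mean_samples, s_means)
        rng_density = np.random.default_rng(s_density)
        X_mc = pd.DataFrame(sampler(cfg.n_density, rng_density),
                            columns=list(PHYSICAL_NAMES))
        y_gp12 = predict_mean(gp_full, X_mc.to_numpy())
        X_mc4 = fix_noninfluential(X_mc, top, means)
        y_gp4 = predict_mean(gp_full, X_mc4.to_numpy())
        edges = common_grid([y_all, y_gp12, y_gp4], cfg.density_bins)
        dens = {
            "sim": estimate_density(y_all, edges),
            "gp12": estimate_density(y_gp12, edges),
            "gp4": estimate_density(y_gp4, edges),
        }
        tv = {
            "sim_gp12": total_variation(dens["sim"], dens["gp12"]),
            "sim_gp4": total_variation(dens["sim"], dens["gp4"]),
            "gp4_gp12": total_variation(dens["gp4"], dens["gp12"]),
        }
    except Exception as exc:
        raise RuntimeError(f"[densities] distribution comparison failed: {exc}") from exc

    return ReportBundle(
        config=cfg,
        dataset=ds,
        fit_reports=reports,
        mean_metrics=mean_metrics,
        gp_full=gp_full,
        sobol=sobol,
        top_parameters=top,
        parameter_means=dict(means),
        density_edges=edges,
        densities=dens,
        tv_distances=tv,
    )


def save_figures(bundle: ReportBundle, outdir) -> list[Path]:
    """Write the Sobol bar chart and the density overlay as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(7, 4))
    order = np.argsort(bundle.sobol.indices_clipped)[::-1]
    names = [bundle.sobol.names[i] for i in order]
    vals = bundle.sobol.indices_clipped[order]
    ax.bar(names, vals, color="steelblue")
    ax.set_ylabel("first-order Sobol index")
    ax.set_title("Orifice-area sensitivity to geometric parameters")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    p = outdir / "sobol_indices.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(7, 4))
    centers = 0.5 * (bundle.density_edges[:-1] + bundle.density_edges[1:])
    labels = {"sim": "emulator", "gp12": "GP (12 params)", "gp4": "GP (top-4 params)"}
    for key, d in bundle.densities.items():
        ax.plot(centers, d.density, label=labels.get(key, key))
    ax.set_xlabel("orifice area (mm$^2$)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    p = outdir / "orifice_area_densities.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths
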