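"""Synthetic tract lattices with the statistical structure the analysis assumes.

The generator emulates a mid-sized, highly segregated US city observed at
census-tract scale (~97 contiguous tracts): a rectangular lattice of unit
squares with queen contiguity, spatially autocorrelated racial composition
producing contiguous Black-majority and White-majority regions, five
socioeconomic covariates correlated with the Black share, and store counts
drawn from the very zero-inflated Poisson BYM model the package fits
(ICAR structured effect, iid heterogeneity, population exposure offset,
excess zeros).  Every latent truth is recorded so that parameter-recovery
tests can close the loop generator -> sampler -> summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .model import AreaTable, make_offset
from .segregation import segregation_features
from .spatial import AreaGraph, adjacency_from_polygons

__all__ = ["SimulationConfig", "simulate_lattice", "simulate_composition",
           "simulate_covariates", "simulate_counts", "simulate_bundle",
           "write_bundle", "Bundle"]

# SES covariate -> (mean %, sd %, sign of correlation with Black share),
# scaled to the percentage ranges typical of a high-poverty urban county.
_SES_SPECS = {
    "pct_poverty": (36.0, 15.0, +1.0),
    "pct_snap": (37.0, 16.0, +1.0),
    "pct_no_vehicle": (26.0, 15.0, +1.0),
    "pct_vacant": (22.0, 10.0, +1.0),
    "pct_college": (9.5, 7.0, -1.0),
}


def _default_beta() -> dict:
    # True log-rate effects: segregation effects echo the directions the
    # analysis is designed to detect (fewer stores with higher Black
    # clustering and segregation, more with White clustering); SES effects
    # are small per-percentage-point slopes.
    return {
        "entropy_score": -0.49,
        "black_cluster_high": -0.14,
        "white_cluster_high": 0.65,
        "pct_asian": 0.02,
        "pct_hispanic": 0.015,
        "pct_poverty": 0.005,
        "pct_snap": -0.01,
        "pct_no_vehicle": 0.005,
        "pct_vacant": -0.005,
        "pct_college": -0.01,
    }


@dataclass
class SimulationConfig:
    """Study-frame defaults for the synthetic city (12 x 8 = 96 tracts)."""

    nrows: int = 12
    ncols: int = 8
    beta0: float = 0.3
    beta: dict = field(default_factory=_default_beta)
    tau_u: float = 4.0
    tau_v: float = 16.0
    pi0: float = 0.2
    pop_range: tuple = (1_000.0, 8_000.0)  # log-uniform per tract
    race_amp: float = 1.8  # amplitude of the smoothed racial latent field
    race_noise: float = 0.6  # iid noise on the latent field
    group_offsets: dict = field(
        default_factory=lambda: {"white": 1.0, "black": 1.2, "asian": -2.2, "hispanic": -0.6}
    )
    ses_race_corr: float = 0.6
    offset_rule: str = "population"
    seed: int = 0

    def __post_init__(self):
        if self.nrows < 2 or self.ncols < 2:
            raise ValueError("lattice must be at least 2 x 2")
        if not (0 <= self.pi0 < 1):
            raise ValueError("pi0 must lie in [0, 1)")
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("precisions must be positive")


def simulate_lattice(config: SimulationConfig):
    """Rectangular grid of unit-square tracts with queen contiguity.

    Returns ``(graph, geometries)`` where geometries maps area id to a
    shapely polygon.  Ids are row-major, zero-padded, so sorted order is
    lattice order.
    """
    geoms = {}
    for r in range(config.nrows):
        for c in range(config.ncols):
            geoms[f"T{r * config.ncols + c:04d}"] = box(c, r, c + 1, r + 1)
    graph = adjacency_from_polygons(geoms)
    return graph, geoms


def icar_sample(graph: AreaGraph, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from the intrinsic CAR law under the sum-to-zero constraint.

    Eigendecomposition of the Laplacian D - A restricted to its non-null
    space: coefficients on eigenvectors with eigenvalue w are
    N(0, 1/(tau w)); null-space (per-component constant) directions are
    fixed at zero, which realises the constraint exactly.
    """
    L = graph.laplacian()
    w, V = np.linalg.eigh(L)
    keep = w > 1e-9
    z = rng.standard_normal(keep.sum())
    return V[:, keep] @ (z / np.sqrt(tau * w[keep]))


def _smooth_field(graph: AreaGraph, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance spatially smooth field (standardised ICAR draw)."""
    f = icar_sample(graph, 1.0, rng)
    s = f.std()
    return f / s if s > 0 else f


def simulate_composition(graph: AreaGraph, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Per-tract population counts for four racial/ethnic groups.

    Latent log-odds per group = group offset + amp * smooth spatial field
    + noise, pushed through a softmax; tract populations are log-uniform
    and group counts multinomial.  At default settings this yields
    contiguous Black-majority and White-majority regions.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    groups = list(config.group_offsets)
    n = graph.n
    latent = np.empty((n, len(groups)))
    for g, name in enumerate(groups):
        field_ = _smooth_field(graph, rng) if config.race_amp > 0 else np.zeros(n)
        latent[:, g] = (
            config.group_offsets[name]
            + config.race_amp * field_
            + config.race_noise * rng.standard_normal(n)
        )
    latent -= latent.max(axis=1, keepdims=True)
    props = np.exp(latent)
    props /= props.sum(axis=1, keepdims=True)
    lo, hi = config.pop_range
    pop = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).round().astype(int)
    counts = np.vstack([rng.multinomial(pop[i], props[i]) for i in range(n)])
    return pd.DataFrame(counts, columns=groups, index=pd.Index(graph.area_ids, name="area_id"))


def simulate_covariates(composition: pd.DataFrame, config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Five SES percentage covariates correlated with the Black share.

    Each covariate is mean + sd * (rho * standardised Black share * sign +
    sqrt(1 - rho^2) * noise), clipped to [0, 100].  At the default
    correlation the model-4 design passes the VIF < 6 screen.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    b = composition["black"].to_numpy(dtype=float) / composition.sum(axis=1).to_numpy(dtype=float)
    bs = (b - b.mean()) / (b.std() if b.std() > 0 else 1.0)
    rho = config.ses_race_corr
    out = {}
    for name, (mu, sd, sign) in _SES_SPECS.items():
        eps = rng.standard_normal(len(b))
        out[name] = np.clip(mu + sd * (sign * rho * bs + np.sqrt(1 - rho**2) * eps), 0.0, 100.0)
    return pd.DataFrame(out, index=composition.index)


def simulate_counts(
    graph: AreaGraph,
    design: pd.DataFrame,
    population,
    config: SimulationConfig,
    rng=None,
) -> tuple:
    """ZIP-BYM store counts given a covariate design; returns (AreaTable, truth).

    u is an exact ICAR draw (sum-to-zero), v iid Normal(0, 1/tau_v);
    log lambda = beta0 + X beta + u + v + offset; y = 0 with probability
    pi0, else Poisson(lambda).  The truth dict records every latent.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    missing = [k for k in config.beta if k not in design.columns]
    if missing:
        raise KeyError(f"design lacks columns for true effects: {missing}")
    n = graph.n
    population = np.asarray(population, dtype=float)
    offset = make_offset(population, config.offset_rule)
    names = list(config.beta)
    X = design[names].to_numpy(dtype=float)
    bvec = np.array([config.beta[k] for k in names])
    u = icar_sample(graph, config.tau_u, rng)
    v = rng.standard_normal(n) / np.sqrt(config.tau_v)
    eta = config.beta0 + X @ bvec + u + v + offset
    lam = np.exp(eta)
    structural_zero = rng.uniform(size=n) < config.pi0
    y = np.where(structural_zero, 0, rng.poisson(lam))
    table = AreaTable(
        area_ids=tuple(graph.area_ids),
        y=y.astype(int),
        population=population,
        covariates=design.copy(),
        offset=offset,
    )
    truth = {
        "beta0": config.beta0,
        "beta": dict(config.beta),
        "u": u,
        "v": v,
        "tau_u": config.tau_u,
        "tau_v": config.tau_v,
        "pi0": config.pi0,
        "lambda": lam,
        "structural_zero": structural_zero,
    }
    return table, truth


@dataclass
class Bundle:
    """Everything one synthetic study needs, in memory."""

    config: SimulationConfig
    graph: AreaGraph
    geometries: dict
    composition: pd.DataFrame
    features: pd.DataFrame
    area_table: AreaTable
    truth: dict


def simulate_bundle(config: SimulationConfig | None = None, seed: int | None = None) -> Bundle:
    """Full generator: lattice -> composition -> segregation features ->
    SES covariates -> ZIP-BYM counts, all from one seed."""
    config = SimulationConfig() if config is None else config
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    graph, geoms = simulate_lattice(config)
    composition = simulate_composition(graph, config, rng)
    features = segregation_features(composition, graph)
    ses = simulate_covariates(composition, config, rng)
    design = pd.concat(
        [features[["entropy_score", "black_cluster_high", "white_cluster_high",
                   "pct_asian", "pct_hispanic"]], ses],
        axis=1,
    )
    population = composition.sum(axis=1).to_numpy(dtype=float)
    table, truth = simulate_counts(graph, design, population, config, rng)
    return Bundle(config, graph, geoms, composition, features, table, truth)


def write_bundle(bundle: Bundle, outdir) -> Path:
    """Write the bundle as plain-text artifacts (tables, GeoJSON, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    area = pd.DataFrame(
        {
            "area_id": bundle.area_table.area_ids,
            "store_count": bundle.area_table.y,
            "population": bundle.area_table.population,
        }
    ).set_index("area_id")
    area = area.join(bundle.composition).join(bundle.area_table.covariates)
    area.to_csv(outdir / "area_table.csv")
    bundle.features.to_csv(outdir / "segregation_features.csv")
    bundle.graph.to_edge_list(outdir / "adjacency.tsv")
    features = [
        {
            "type": "Feature",
            "properties": {"area_id": aid},
            "geometry": mapping(geom),
        }
        for aid, geom in sorted(bundle.geometries.items())
    ]
    with open(outdir / "tracts.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in bundle.truth.items()
    }
    truth["seed"] = bundle.config.seed
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return outdir
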