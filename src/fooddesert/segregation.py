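"""Residential-segregation metrics and multicollinearity screening.

Implements the evenness and clustering measures used as model covariates:

* tract-level racial entropy ``E_i = -Sum_r p_r ln p_r`` and the deviation
  score ``h_i = max(0, (E - E_i)/E)`` against citywide entropy ``E``;
* Theil's multigroup entropy index ``H`` (population-weighted average
  deviation of tract diversity from citywide diversity, in [0, 1]);
* Getis-Ord local G* z-scores on a contiguity graph (binary weights, self
  included), with a sign-based high/low cluster classification;
* variance inflation factors (VIF) for covariate screening.

Natural logarithms are used throughout; ``h_i`` and ``H`` are ratios of
entropies so the choice of base cancels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .spatial import AreaGraph

__all__ = [
    "tract_entropy",
    "entropy_deviation_score",
    "citywide_entropy_index",
    "local_gstar",
    "classify_clusters",
    "compute_vif",
    "segregation_features",
]

_PTOL = 1e-8


def _check_proportions(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative proportion")
    s = p.sum()
    if abs(s - 1.0) > _PTOL:
        raise ValueError(f"proportions sum to {s}, not 1")
    return p


def tract_entropy(proportions) -> float:
    """Shannon entropy -Sum_r p_r ln p_r of one area's group composition.

    Zero-share groups contribute nothing (0 ln 0 := 0).  Maximal, ln R, at
    the uniform composition.
    """
    p = _check_proportions(proportions)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def entropy_deviation_score(tract_proportions, city_proportions) -> float:
    """Per-tract segregation score h_i = max(0, (E - E_i) / E).

    E is the entropy of the citywide composition and E_i the tract's own
    entropy.  0 means the tract is as diverse as the city; 1 means a
    single-group tract.  Tracts *more* diverse than the city are clipped
    to 0 rather than reported as negative.
    """
    E = tract_entropy(city_proportions)
    if E <= 0:
        raise ValueError("citywide entropy is 0 (single-group city); score undefined")
    Ei = tract_entropy(tract_proportions)
    return float(max(0.0, (E - Ei) / E))


def citywide_entropy_index(counts: pd.DataFrame) -> float:
    """Theil's multigroup entropy index H over a table of per-area group counts.

    H = Sum_i t_i (E - E_i) / (E T), with t_i the area population, T the
    total, E_i the area entropy and E the citywide entropy.  0 when every
    area mirrors the city's composition, 1 when every area holds a single
    group.  Zero-population areas are dropped with a warning.
    """
    c = counts.to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("negative group count")
    t = c.sum(axis=1)
    if t.sum() <= 0:
        raise ValueError("zero total population")
    if np.any(t == 0):
        warnings.warn(f"{int((t == 0).sum())} zero-population area(s) dropped from H")
        c = c[t > 0]
        t = t[t > 0]
    city_p = c.sum(axis=0) / t.sum()
    E = tract_entropy(city_p)
    if E <= 0:
        raise ValueError("citywide entropy is 0 (single-group city)")
    P = c / t[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(P > 0, -P * np.log(P), 0.0)
    Ei = ent.sum(axis=1)
    return float((t * (E - Ei)).sum() / (E * t.sum()))


def local_gstar(values, graph: AreaGraph) -> np.ndarray:
    """Getis-Ord G_i* z-scores with binary contiguity weights, self included.

    z_i = (Sum_j w_ij x_j - xbar W_i) / (S sqrt[(n W_i - W_i^2) / (n - 1)])

    with w_ii = 1, w_ij = 1 for graph neighbors, W_i = Sum_j w_ij, xbar and
    S the global mean and (population) standard deviation.  A constant
    surface has no local structure; all z are defined as 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    n = graph.n
    if x.shape != (n,):
        raise ValueError(f"values have shape {x.shape}, expected ({n},)")
    if n < 3:
        raise ValueError("local G* needs at least 3 areas")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    xbar = x.mean()
    S = x.std()  # ddof=0
    if S == 0:
        warnings.warn("constant surface: all G* z-scores set to 0")
        return np.zeros(n)
    # neighbor sums via the edge list, plus self
    wx = x.copy()
    np.add.at(wx, graph.edges[:, 0], x[graph.edges[:, 1]])
    np.add.at(wx, graph.edges[:, 1], x[graph.edges[:, 0]])
    W = graph.degrees + 1.0
    # W_i = n means the neighborhood is the whole study area; numerator and
    # variance both vanish, so the statistic's limit is 0
    spread = np.maximum(n * W - W**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (wx - xbar * W) / (S * np.sqrt(spread / (n - 1)))
    return np.where(spread > 0, z, 0.0)


def classify_clusters(z) -> np.ndarray:
    """High/low cluster label per area by the sign of its G* z-score.

    ``high`` iff z > 0; z = 0 (and any negative z) maps to ``low``.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-score")
    return np.where(z > 0, "high", "low")


def compute_vif(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors: VIF_k = 1 / (1 - R^2_k).

    R^2_k comes from the least-squares regression (with intercept) of
    covariate k on all the others.  A perfectly collinear column yields an
    infinite VIF.  Returns a frame with ``vif`` and a ``flagged`` boolean
    marking VIF >= 6, the conventional screening threshold used here.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 covariates")
    if n <= p:
        raise ValueError("need more rows than covariates")
    if np.any(X.std(axis=0) == 0):
        bad = design.columns[X.std(axis=0) == 0].tolist()
        raise ValueError(f"zero-variance column(s): {bad}")
    vifs = []
    for k in range(p):
        yk = X[:, k]
        Z = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yk, rcond=None)
        resid = yk - Z @ coef
        sst = ((yk - yk.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    out = pd.DataFrame({"vif": vifs}, index=design.columns)
    out["flagged"] = out["vif"] >= 6.0
    return out


def segregation_features(
    composition: pd.DataFrame,
    graph: AreaGraph,
    *,
    white: str = "white",
    black: str = "black",
    asian: str = "asian",
    hispanic: str = "hispanic",
) -> pd.DataFrame:
    """Assemble the per-area segregation covariate block.

    ``composition`` holds group population counts indexed by area id (one
    column per group).  Returns, aligned to ``graph.area_ids``: the entropy
    deviation score, Black/White G* z-scores and high/low cluster labels,
    and percent Asian / percent Hispanic.
    """
    comp = composition.loc[list(graph.area_ids)]
    counts = comp[[white, black, asian, hispanic]].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = [graph.area_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"zero-population area(s): {bad[:5]}")
    props = counts / totals[:, None]
    city = counts.sum(axis=0) / counts.sum()
    h = np.array([entropy_deviation_score(p, city) for p in props])
    z_black = local_gstar(props[:, 1], graph)
    z_white = local_gstar(props[:, 0], graph)
    return pd.DataFrame(
        {
            "entropy_score": h,
            "gstar_z_black": z_black,
            "gstar_z_white": z_white,
            "cluster_black": classify_clusters(z_black),
            "cluster_white": classify_clusters(z_white),
            "black_cluster_high": (z_black > 0).astype(float),
            "white_cluster_high": (z_white > 0).astype(float),
            "pct_asian": 100.0 * props[:, 2],
            "pct_hispanic": 100.0 * props[:, 3],
        },
        index=pd.Index(graph.area_ids, name="area_id"),
    )
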