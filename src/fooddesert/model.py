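"""Zero-inflated Poisson BYM regression: model definition and summaries.

The outcome y_i is the store count in area i, modelled as a zero-inflated
Poisson with log link

    log(lambda_i) = beta_0 + Sum_k beta_k x_ik + u_i + v_i + e_i

where u is an intrinsic CAR (structured) spatial effect on the contiguity
graph, v an iid Normal(0, 1/tau_v) heterogeneity effect and e_i a fixed
log-exposure offset.  A single shared zero-inflation probability pi_0
places extra mass at zero.  Vague priors follow common disease-mapping
practice: Normal(mean 0, precision 0.001) on every coefficient,
Gamma(shape 1, rate 5e-5) on the precisions tau_u and tau_v, and
Normal(0, precision 0.001) on logit(pi_0).

Coefficients are reported as rate ratios RR = exp(beta) with central 95%
credible intervals; an effect is flagged significant when the interval
excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .spatial import AreaGraph, icar_logpdf_unnorm

__all__ = [
    "RACIAL_BLOCK",
    "SES_BLOCK",
    "ModelSpec",
    "Priors",
    "AreaTable",
    "PosteriorSamples",
    "linear_predictor",
    "zip_loglik",
    "log_posterior",
    "summarize_posterior",
    "percent_change",
]

# Covariate blocks mirroring the four nested models: model 1 has no
# covariates, model 2 the racial-segregation block, model 3 the
# socioeconomic block, model 4 their union.
RACIAL_BLOCK = (
    "entropy_score",
    "black_cluster_high",
    "white_cluster_high",
    "pct_asian",
    "pct_hispanic",
)
SES_BLOCK = (
    "pct_poverty",
    "pct_snap",
    "pct_no_vehicle",
    "pct_vacant",
    "pct_college",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the regression, plus likelihood conventions."""

    model_id: int
    covariates: tuple
    offset_rule: str = "population"  # population | log_population | none
    exceedance_threshold: float = 1.0

    @classmethod
    def for_model(cls, model_id: int, **kw) -> "ModelSpec":
        blocks = {
            1: (),
            2: RACIAL_BLOCK,
            3: SES_BLOCK,
            4: RACIAL_BLOCK + SES_BLOCK,
        }
        if model_id not in blocks:
            raise ValueError(f"model_id must be 1-4, got {model_id}")
        return cls(model_id=model_id, covariates=blocks[model_id], **kw)

    @property
    def coef_names(self) -> tuple:
        return ("intercept",) + tuple(self.covariates)


@dataclass(frozen=True)
class Priors:
    """Vague priors on coefficients, precisions and the zero-inflation logit."""

    beta_mean: float = 0.0
    beta_precision: float = 0.001
    tau_shape: float = 1.0
    tau_rate: float = 5e-5
    logit_pi0_mean: float = 0.0
    logit_pi0_precision: float = 0.001

    def __post_init__(self):
        if min(self.beta_precision, self.tau_shape, self.tau_rate, self.logit_pi0_precision) <= 0:
            raise ValueError("precisions, shapes and rates must be positive")


@dataclass
class AreaTable:
    """Per-area outcome, exposure and covariates, aligned to sorted area ids."""

    area_ids: tuple
    y: np.ndarray
    population: np.ndarray
    covariates: pd.DataFrame
    offset: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y)
        self.population = np.asarray(self.population, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        n = len(self.area_ids)
        if not (len(self.y) == len(self.population) == len(self.offset) == n):
            raise ValueError("length mismatch between area_ids and columns")
        if np.any(self.y < 0) or not np.issubdtype(self.y.dtype, np.integer):
            if np.any(self.y != np.floor(self.y)) or np.any(self.y < 0):
                raise ValueError("y must be nonnegative integers")
            self.y = self.y.astype(int)
        if np.any(self.population <= 0):
            raise ValueError("population must be positive")
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite")

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, offset_rule: str = "population") -> "AreaTable":
        """Build from a table indexed (or keyed by column 'area_id') with
        columns ``store_count``, ``population`` and covariates."""
        if "area_id" in df.columns:
            df = df.set_index("area_id")
        df = df.sort_index()
        pop = df["population"].to_numpy(dtype=float)
        offset = make_offset(pop, offset_rule)
        covs = df.drop(columns=["store_count", "population"])
        return cls(
            area_ids=tuple(df.index),
            y=df["store_count"].to_numpy(),
            population=pop,
            covariates=covs,
            offset=offset,
        )

    def design_matrix(self, spec: ModelSpec) -> np.ndarray:
        """Intercept column plus the ModelSpec's covariates, in order."""
        cols = [np.ones(self.n)]
        for name in spec.covariates:
            if name not in self.covariates.columns:
                raise KeyError(f"missing covariate column: {name!r}")
            cols.append(self.covariates[name].to_numpy(dtype=float))
        return np.column_stack(cols)


def make_offset(population, rule: str = "population") -> np.ndarray:
    """Log-exposure offset e_i.

    ``population``: log(pop_i / mean pop) — a population-standardised
    exposure, the default; ``log_population``: log(pop_i); ``none``: 0.
    """
    pop = np.asarray(population, dtype=float)
    if rule == "population":
        return np.log(pop / pop.mean())
    if rule == "log_population":
        return np.log(pop)
    if rule == "none":
        return np.zeros_like(pop)
    raise ValueError(f"unknown offset rule {rule!r}")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, shaped (chains, draws, ...)."""

    coef_names: tuple
    area_ids: tuple
    beta: np.ndarray  # (C, S, p)
    u: np.ndarray  # (C, S, n)
    v: np.ndarray  # (C, S, n)
    tau_u: np.ndarray  # (C, S)
    tau_v: np.ndarray  # (C, S)
    pi0: np.ndarray  # (C, S)
    seed: int = 0
    settings: dict = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        a = getattr(self, name)
        return a.reshape(-1, *a.shape[2:])

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            beta=self.beta,
            u=self.u,
            v=self.v,
            tau_u=self.tau_u,
            tau_v=self.tau_v,
            pi0=self.pi0,
            coef_names=np.array(self.coef_names),
            area_ids=np.array(self.area_ids),
            seed=self.seed,
        )


def linear_predictor(beta, X, u, v, offset) -> np.ndarray:
    """log lambda_i = X beta + u_i + v_i + e_i (X carries the intercept column)."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise ValueError(f"design has {X.shape[1]} columns but beta has {beta.shape[0]}")
    return X @ beta + np.asarray(u) + np.asarray(v) + np.asarray(offset)


def zip_logpmf_terms(y, log_lam, pi0) -> np.ndarray:
    """Per-observation ZIP log-pmf, stable for small probabilities.

    For y=0: log(pi0 + (1-pi0) exp(-lambda)); else log(1-pi0) + Poisson term.
    """
    y = np.asarray(y)
    log_lam = np.asarray(log_lam, dtype=float)
    lam = np.exp(log_lam)
    if pi0 < 0 or pi0 > 1:
        raise ValueError("pi0 must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        lp0 = np.log(pi0) if pi0 > 0 else -np.inf
        lp1 = np.log1p(-pi0) if pi0 < 1 else -np.inf
    pois = y * log_lam - lam - gammaln(y + 1)
    zero_term = np.logaddexp(lp0, lp1 - lam)
    return np.where(y == 0, zero_term, lp1 + pois)


def zip_loglik(y, lam, pi0) -> float:
    """Zero-inflated Poisson log-likelihood Sum_i log[pi0 1{y=0} + (1-pi0) Pois(y_i; lambda_i)]."""
    lam = np.asarray(lam, dtype=float)
    y = np.asarray(y)
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be nonnegative integers")
    out = float(zip_logpmf_terms(y, np.log(lam), pi0).sum())
    return out


@dataclass
class ModelState:
    """One point in parameter space: beta, u, v, tau_u, tau_v, pi0."""

    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float
    pi0: float


def log_posterior(
    state: ModelState,
    data: AreaTable,
    graph: AreaGraph,
    spec: ModelSpec,
    priors: Priors = Priors(),
) -> float:
    """Unnormalized log posterior density of the ZIP-BYM model.

    Returns -inf outside the support (tau <= 0 or pi0 outside (0,1)).
    """
    if state.tau_u <= 0 or state.tau_v <= 0 or not (0 < state.pi0 < 1):
        return -np.inf
    X = data.design_matrix(spec)
    eta = linear_predictor(state.beta, X, state.u, state.v, data.offset)
    ll = float(zip_logpmf_terms(data.y, eta, state.pi0).sum())
    lp = icar_logpdf_unnorm(state.u, graph, state.tau_u)
    n = data.n
    lp += 0.5 * n * np.log(state.tau_v) - 0.5 * state.tau_v * float(state.v @ state.v)
    b = np.asarray(state.beta, dtype=float) - priors.beta_mean
    lp += -0.5 * priors.beta_precision * float(b @ b)
    for tau in (state.tau_u, state.tau_v):
        lp += (priors.tau_shape - 1.0) * np.log(tau) - priors.tau_rate * tau
    psi = np.log(state.pi0) - np.log1p(-state.pi0)
    lp += -0.5 * priors.logit_pi0_precision * (psi - priors.logit_pi0_mean) ** 2
    if not np.isfinite(ll + lp):
        return -np.inf
    return ll + lp


def summarize_posterior(samples: PosteriorSamples, spec: ModelSpec) -> pd.DataFrame:
    """Rate-ratio summary table: posterior mean RR, central 95% CI, significance.

    RR draws are exp(beta); the CI is the 2.5/97.5 percentile interval and
    an effect is significant iff that interval excludes 1.
    """
    if samples.n_draws < 100:
        raise ValueError(f"need >= 100 retained draws, have {samples.n_draws}")
    rr = np.exp(samples.flat("beta"))
    lo, hi = np.percentile(rr, [2.5, 97.5], axis=0)
    mean = rr.mean(axis=0)
    sig = (hi < 1.0) | (lo > 1.0)
    return pd.DataFrame(
        {
            "rr_mean": mean,
            "ci_low": lo,
            "ci_high": hi,
            "significant": sig,
        },
        index=pd.Index(samples.coef_names, name="coefficient"),
    )


def percent_change(rr: float) -> int:
    """Signed percent change implied by a rate ratio: round((rr - 1) * 100).

    0.87 -> -13 (a 13% decrease); 1.92 -> +92 (a 92% increase).
    """
    if rr <= 0:
        raise ValueError("rate ratio must be positive")
    return int(round((rr - 1.0) * 100.0))
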