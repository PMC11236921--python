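"""DIC model comparison and exceedance-probability hotspot classification.

DIC is computed with the conditional-deviance focus (deviance evaluated
given the random effects, the classic BUGS/INLA reporting convention):

    D(theta)  = -2 log ZIP-likelihood at (beta, u, v, pi0)
    Dbar      = posterior mean deviance over retained draws
    D(thetabar) at the posterior means (pi0 averaged on the logit scale)
    pD = Dbar - D(thetabar),   DIC = D(thetabar) + 2 pD = Dbar + pD

Lower DIC is preferred; a gap of at least 3 points against the runner-up
is graded as substantial evidence.

Hotspots are read off the combined spatial effect exp(u_i + v_i): the
exceedance probability p_i = P(exp(u_i + v_i) > c | data) is estimated by
the fraction of retained draws above the threshold (c = 1 by default) and
classified coldspot (p < 0.2), neither (0.2 <= p < 0.8) or hotspot
(p >= 0.8).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import AreaTable, ModelSpec, PosteriorSamples, zip_logpmf_terms

__all__ = [
    "dic",
    "compare_models",
    "exceedance_probability",
    "classify_exceedance",
]


def dic(samples: PosteriorSamples, data: AreaTable, spec: ModelSpec) -> tuple:
    """Conditional-deviance DIC and effective parameter count pD.

    Returns ``(DIC, pD)``.  A negative pD (a known pathology of the
    conditional focus under strong nonlinearity) is reported with a
    warning, not an error.
    """
    if samples.n_draws < 100:
        raise ValueError(f"need >= 100 retained draws, have {samples.n_draws}")
    X = data.design_matrix(spec)
    beta = samples.flat("beta")  # (S, p)
    u = samples.flat("u")
    v = samples.flat("v")
    pi0 = samples.flat("pi0")
    eta = beta @ X.T + u + v + data.offset  # (S, n)
    dev = np.empty(eta.shape[0])
    for s in range(eta.shape[0]):  # loop keeps memory flat for large S
        dev[s] = -2.0 * zip_logpmf_terms(data.y, eta[s], float(pi0[s])).sum()
    dbar = float(dev.mean())
    beta_hat = beta.mean(axis=0)
    u_hat = u.mean(axis=0)
    v_hat = v.mean(axis=0)
    pi0_hat = float(expit(logit(pi0).mean()))
    eta_hat = X @ beta_hat + u_hat + v_hat + data.offset
    d_hat = -2.0 * float(zip_logpmf_terms(data.y, eta_hat, pi0_hat).sum())
    if not np.isfinite(d_hat):
        raise ValueError("non-finite deviance at the posterior mean")
    pd_ = dbar - d_hat
    if pd_ < 0:
        warnings.warn(f"negative pD ({pd_:.3f}): conditional-DIC pathology")
    return d_hat + 2.0 * pd_, pd_


def compare_models(dics: dict, pds: dict | None = None) -> pd.DataFrame:
    """Rank models by DIC (ascending); lowest wins, graded by the 3-point rule.

    ``dics`` maps model label -> DIC.  Returns a table with DIC, pD (if
    given), delta_dic against the best, a ``preferred`` flag and an
    ``evidence`` grade: ``substantial`` when the runner-up trails by at
    least 3 points, ``weak`` otherwise.  Exact ties at the minimum yield
    no preference and a warning.
    """
    if len(dics) < 2:
        raise ValueError("need at least 2 models to compare")
    labels = list(dics)
    vals = np.array([dics[m] for m in labels], dtype=float)
    best = vals.min()
    delta = vals - best
    winners = [m for m, d in zip(labels, delta) if d == 0]
    tie = len(winners) > 1
    if tie:
        warnings.warn(f"DIC tie at the minimum between {winners}; no preference")
    runner_up_gap = np.sort(delta)[1] if not tie else 0.0
    evidence = "substantial" if (not tie and runner_up_gap >= 3.0) else "weak"
    out = pd.DataFrame(
        {
            "dic": vals,
            "delta_dic": delta,
            "preferred": [(d == 0) and not tie for d in delta],
            "evidence": [evidence if d == 0 and not tie else "" for d in delta],
        },
        index=pd.Index(labels, name="model"),
    )
    if pds is not None:
        out.insert(1, "pd", [pds.get(m, np.nan) for m in labels])
    return out.sort_values("dic")


def exceedance_probability(samples: PosteriorSamples, threshold: float = 1.0) -> np.ndarray:
    """Per-area P(exp(u_i + v_i) > c | data), estimated over retained draws.

    The combined spatial effect exp(u + v) is the residual area-level rate
    ratio after the covariates; exceedance of c = 1 marks areas with more
    stores than the covariates explain.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    w = samples.flat("u") + samples.flat("v")
    if w.shape[0] == 0:
        raise ValueError("no retained draws")
    return (w > np.log(threshold)).mean(axis=0)


_CUTS = (0.2, 0.8)


def classify_exceedance(p, cuts: tuple = _CUTS) -> np.ndarray:
    """Map exceedance probabilities to {coldspot, neither, hotspot}.

    coldspot if p < cuts[0]; hotspot if p >= cuts[1]; neither in between
    (half-open boundary convention).  Scalar or array input.
    """
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("exceedance probabilities must lie in [0, 1]")
    lo, hi = cuts
    out = np.full(arr.shape, "neither", dtype=object)
    out[arr < lo] = "coldspot"
    out[arr >= hi] = "hotspot"
    if np.isscalar(p) or np.ndim(p) == 0:
        return out[0]
    return out.astype(str)
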