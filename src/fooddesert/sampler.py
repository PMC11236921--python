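"""Blocked Metropolis-within-Gibbs sampler for the ZIP-BYM spatial regression.

Two reparametrizations make this model tractable for MCMC:

* **ZIP augmentation.**  A latent indicator z_i marks structural zeros,
  drawn each sweep from its exact conditional
  P(z_i = 1 | y_i = 0, rest) = pi0 / (pi0 + (1 - pi0) e^{-lam_i}).
  Conditional on z the count likelihood is plain Poisson on the active
  (z_i = 0) areas and pi0 sees a Bernoulli likelihood through its logit.

* **BYM blocking and collapsing.**  The likelihood only ever sees the
  total spatial effect s = u + v.  In the eigenbasis of the Laplacian
  D - A (computed once) the joint prior of s given the precisions is
  diagonal: along an eigenvector with eigenvalue w > 0 the variance is
  1/(tau_u w) + 1/tau_v, and along the null directions (per-component
  constants, pinned for u by the sum-to-zero constraint) it is 1/tau_v.
  The precisions are therefore updated by Metropolis on the log scale
  against this *marginal* p(s | tau_u, tau_v) — with u integrated out —
  and u is then redrawn exactly from its Gaussian conditional
  u | s, tau_u, tau_v in the same basis (null coordinates zero, which
  realises the per-component sum-to-zero constraint, islands at 0), with
  v = s - u.  Alternating conjugate Gibbs on (tau_u, u) instead is a
  known pathology — the pair is so dependent that tau_u random-walks to
  infinity while u over-smooths — which this partially collapsed scheme
  (valid because u is redrawn after tau) eliminates.

Update scheme per sweep: z (exact conditional) -> beta (random-walk
Metropolis per coordinate; covariate columns centred internally so the
intercept mixes, draws reported on the original scale) -> s (independent
per-site random-walk Metropolis, vectorised; the conditional target
factorises over sites given u) -> tau_u, tau_v (log-scale Metropolis
against the collapsed marginal) -> u | s (exact eigenbasis Gibbs,
v = s - u) -> psi = logit(pi0) (random-walk Metropolis against the
Bernoulli(z) likelihood).

Proposal scales adapt toward ~0.44 acceptance during burn-in and are
frozen afterwards, so the retained chain is a fixed-kernel Markov chain.
All randomness flows from one integer seed via numpy SeedSequence;
identical seeds reproduce draws bit for bit.
"""

from __future__ import annotations

import numpy as np

from .model import (
    AreaTable,
    ModelSpec,
    PosteriorSamples,
    Priors,
)
from .spatial import AreaGraph, icar_energy

__all__ = ["fit_mcmc", "tau_v_gibbs_draw", "tau_u_gibbs_draw"]

_ADAPT_TARGET = 0.44
_ADAPT_EVERY = 50


def tau_v_gibbs_draw(rng, v, priors: Priors) -> float:
    """Exact conjugate draw tau_v | v ~ Gamma(shape + n/2, rate + Sum v^2/2)."""
    v = np.asarray(v, dtype=float)
    shape = priors.tau_shape + 0.5 * v.size
    rate = priors.tau_rate + 0.5 * float(v @ v)
    return rng.gamma(shape, 1.0 / rate)


def tau_u_gibbs_draw(rng, u, graph: AreaGraph, priors: Priors) -> float:
    """Conjugate draw tau_u | u ~ Gamma(shape + rank/2, rate + energy/2).

    rank is the rank of the ICAR precision: n minus the number of
    connected components (islands contribute nothing).
    """
    shape = priors.tau_shape + 0.5 * graph.icar_rank()
    rate = priors.tau_rate + 0.5 * icar_energy(u, graph)
    return rng.gamma(shape, 1.0 / rate)


class _Chain:
    """Single-chain state and update kernels (augmented, blocked ZIP-BYM)."""

    def __init__(self, data: AreaTable, graph: AreaGraph, spec: ModelSpec,
                 priors: Priors, rng: np.random.Generator,
                 prior_only: bool = False):
        self.priors = priors
        self.rng = rng
        self.graph = graph
        self.prior_only = prior_only
        self.n = data.n
        X = data.design_matrix(spec)
        self.col_means = X.mean(axis=0)
        self.col_means[0] = 0.0  # never centre the intercept column
        self.Xc = X - self.col_means
        self.p = X.shape[1]
        self.y = data.y.astype(float)
        self.zero_idx = np.flatnonzero(data.y == 0)
        self.offset = data.offset
        # Laplacian eigenbasis, computed once: the BYM prior for s = u + v
        # is diagonal here (see module docstring)
        w, V = np.linalg.eigh(graph.laplacian())
        self.eigvals = w
        self.eigvecs = V
        self.nonnull = w > 1e-9

        # initial state
        self.beta = np.zeros(self.p)
        self.beta[0] = rng.normal(0.0, 0.1)
        self.u = np.zeros(self.n)
        self.s = np.zeros(self.n)  # total spatial effect u + v
        self.tau_u = 1.0
        self.tau_v = 1.0
        p0 = min(max(float((data.y == 0).mean()), 0.01), 0.95)
        self.psi = float(np.log(p0) - np.log1p(-p0) + rng.normal(0.0, 0.1))
        self.eta = self.Xc @ self.beta + self.s + self.offset
        self.lam = np.exp(self.eta)
        self.z = np.zeros(self.n, dtype=bool)
        self.active = np.zeros(self.n, dtype=bool) if prior_only else ~self.z
        # adaptive scales
        self.s_beta = np.full(self.p, 0.1)
        self.s_s = np.full(self.n, 0.5)
        self.s_psi = 0.5
        self.s_tau = np.array([1.0, 1.0])  # log-scale steps for tau_u, tau_v
        self.acc_beta = np.zeros(self.p)
        self.acc_s = np.zeros(self.n)
        self.acc_psi = 0.0
        self.acc_tau = np.zeros(2)

    @property
    def v(self) -> np.ndarray:
        return self.s - self.u

    # -- update kernels -----------------------------------------------------
    def update_z(self):
        """Exact conditional of the structural-zero indicators."""
        if self.prior_only or self.zero_idx.size == 0:
            return
        pi0 = 1.0 / (1.0 + np.exp(-self.psi))
        lam0 = self.lam[self.zero_idx]
        p_struct = pi0 / (pi0 + (1.0 - pi0) * np.exp(-lam0))
        self.z[self.zero_idx] = self.rng.uniform(size=self.zero_idx.size) < p_struct
        self.active = ~self.z

    def update_beta(self):
        pr = self.priors
        a = self.active

        def ll(eta, lam):
            return float((self.y[a] * eta[a] - lam[a]).sum())

        cur = ll(self.eta, self.lam)
        for k in range(self.p):
            step = self.s_beta[k] * self.rng.normal()
            eta_new = self.eta + self.Xc[:, k] * step
            lam_new = np.exp(eta_new)
            new = ll(eta_new, lam_new)
            b_old = self.beta[k]
            b_new = b_old + step
            dprior = -0.5 * pr.beta_precision * (
                (b_new - pr.beta_mean) ** 2 - (b_old - pr.beta_mean) ** 2
            )
            if np.log(self.rng.uniform()) < new - cur + dprior:
                self.beta[k] = b_new
                self.eta = eta_new
                self.lam = lam_new
                cur = new

                self.acc_beta[k] += 1

    def update_s(self):
        """Vectorised per-site Metropolis on the total spatial effect.

        Given u the conditional target factorises over sites: Poisson
        likelihood (active sites) times the N(u_i, 1/tau_v) prior of
        v_i = s_i - u_i.
        """
        step = self.s_s * self.rng.standard_normal(self.n)
        s_new = self.s + step
        eta_new = self.eta + step
        lam_new = np.exp(eta_new)
        dll = (self.y * step - (lam_new - self.lam)) * self.active
        d = self.s - self.u
        d_new = s_new - self.u
        dlp = dll - 0.5 * self.tau_v * (d_new**2 - d**2)
        accept = np.log(self.rng.uniform(size=self.n)) < dlp
        self.s[accept] = s_new[accept]
        self.eta[accept] = eta_new[accept]
        self.lam[accept] = lam_new[accept]
        self.acc_s[accept] += 1
        # structural-zero sites feel no likelihood: their conditional is the
        # exact prior N(u_i, 1/tau_v) — refresh by Gibbs.  This is what lets
        # a site hop between the "rate ~ 0" and "structural zero"
        # explanations of an observed zero instead of random-walking out.
        inactive = np.flatnonzero(~self.active)
        if inactive.size:
            fresh = self.u[inactive] + self.rng.standard_normal(
                inactive.size
            ) / np.sqrt(self.tau_v)
            delta = fresh - self.s[inactive]
            self.s[inactive] = fresh
            self.eta[inactive] += delta
            self.lam[inactive] = np.exp(self.eta[inactive])

    def _marginal_s_logp(self, tau_u: float, tau_v: float, st: np.ndarray) -> float:
        """log p(s | tau_u, tau_v) with u integrated out, in the eigenbasis.

        Along eigenvalue w > 0 the variance is 1/(tau_u w) + 1/tau_v;
        along the null directions (u constrained to 0) it is 1/tau_v.
        """
        var = np.where(
            self.nonnull, 1.0 / (tau_u * np.maximum(self.eigvals, 1e-12)) + 1.0 / tau_v,
            1.0 / tau_v,
        )
        return float(-0.5 * (np.log(var) + st**2 / var).sum())

    def update_taus(self):
        """Log-scale Metropolis on tau_u, tau_v against the collapsed marginal.

        Target: p(s | taus) Gamma(tau_u) Gamma(tau_v); the log-scale
        proposal contributes a +log tau Jacobian.
        """
        pr = self.priors
        st = self.eigvecs.T @ self.s
        taus = [self.tau_u, self.tau_v]
        for j in range(2):
            cur = taus[j]
            prop = cur * np.exp(self.s_tau[j] * self.rng.normal())
            t_new = taus.copy()
            t_new[j] = prop
            dlp = self._marginal_s_logp(t_new[0], t_new[1], st) - self._marginal_s_logp(
                taus[0], taus[1], st
            )
            # Gamma(shape, rate) prior with the log-proposal Jacobian folded in
            dlp += pr.tau_shape * (np.log(prop) - np.log(cur)) - pr.tau_rate * (prop - cur)
            if np.log(self.rng.uniform()) < dlp:
                taus[j] = prop
                self.acc_tau[j] += 1
        self.tau_u, self.tau_v = taus

    def update_u(self):
        """Exact Gibbs draw of u | s, tau_u, tau_v in the eigenbasis.

        Non-null coordinate k: precision tau_u w_k + tau_v, mean
        tau_v s~_k / (tau_u w_k + tau_v); null coordinates are 0, which
        realises the per-component sum-to-zero constraint (islands at 0).
        """
        st = self.eigvecs.T @ self.s
        prec = self.tau_u * self.eigvals + self.tau_v
        ut = np.where(
            self.nonnull,
            self.tau_v * st / prec + self.rng.standard_normal(self.n) / np.sqrt(prec),
            0.0,
        )
        self.u = self.eigvecs @ ut

    def update_psi(self):
        """RW Metropolis on logit(pi0) against the Bernoulli(z) likelihood."""
        pr = self.priors
        psi_new = self.psi + self.s_psi * self.rng.normal()
        if self.prior_only:
            k1 = k0 = 0.0
        else:
            k1 = float(self.z.sum())
            k0 = float(self.n - k1)

        def bern_ll(psi):
            sp_ = np.logaddexp(0.0, psi)  # k1 log pi0 + k0 log(1-pi0)
            return k1 * (psi - sp_) + k0 * (-sp_)

        dlp = bern_ll(psi_new) - bern_ll(self.psi)
        dlp += -0.5 * pr.logit_pi0_precision * (
            (psi_new - pr.logit_pi0_mean) ** 2 - (self.psi - pr.logit_pi0_mean) ** 2
        )
        if np.log(self.rng.uniform()) < dlp:
            self.psi = psi_new
            self.acc_psi += 1

    def adapt(self, window: int):
        def tune(scale, acc):
            return scale * np.exp(np.clip(acc / window - _ADAPT_TARGET, -0.5, 0.5))

        self.s_beta = tune(self.s_beta, self.acc_beta)
        self.s_s = tune(self.s_s, self.acc_s)
        self.s_psi = float(tune(np.array(self.s_psi), np.array(self.acc_psi)))
        self.s_tau = tune(self.s_tau, self.acc_tau)
        self.acc_beta[:] = 0
        self.acc_s[:] = 0
        self.acc_psi = 0.0
        self.acc_tau[:] = 0

    def sweep(self):
        self.update_z()
        self.update_beta()
        self.update_s()
        self.update_taus()
        self.update_u()
        self.update_psi()

    def report_beta(self) -> np.ndarray:
        """Coefficients on the original (uncentred) covariate scale."""
        b = self.beta.copy()
        b[0] = b[0] - self.col_means[1:] @ b[1:]
        return b


def fit_mcmc(
    data: AreaTable,
    graph: AreaGraph,
    spec: ModelSpec,
    priors: Priors = Priors(),
    n_iter: int = 20_000,
    n_burn: int = 10_000,
    n_chains: int = 4,
    seed: int = 0,
    compute_diagnostics: bool = True,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Fit the ZIP-BYM model by blocked Metropolis-within-Gibbs MCMC.

    Returns retained post-burn-in draws for every chain; u satisfies the
    per-component sum-to-zero constraint in every retained draw.  With
    ``compute_diagnostics`` split-Rhat and bulk effective sample size for
    beta, tau_u, tau_v and pi0 are attached (meaningful with >= 2 chains).
    ``prior_only`` drops the likelihood entirely (prior-recovery checks).
    """
    if not (n_iter > n_burn >= 0):
        raise ValueError("need n_iter > n_burn >= 0")
    if tuple(data.area_ids) != tuple(graph.area_ids):
        raise ValueError("data and graph area ids disagree")
    n_keep = n_iter - n_burn
    chain_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    p = len(spec.coef_names)
    n = data.n
    beta = np.empty((n_chains, n_keep, p))
    u = np.empty((n_chains, n_keep, n))
    v = np.empty((n_chains, n_keep, n))
    tau_u = np.empty((n_chains, n_keep))
    tau_v = np.empty((n_chains, n_keep))
    pi0 = np.empty((n_chains, n_keep))
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        ch = _Chain(data, graph, spec, priors, rng, prior_only=prior_only)
        if not np.all(np.isfinite(ch.lam)):
            raise RuntimeError("non-finite rate at initialization (linear predictor)")
        for it in range(n_iter):
            ch.sweep()
            if it < n_burn and (it + 1) % _ADAPT_EVERY == 0:
                ch.adapt(_ADAPT_EVERY)
            if it >= n_burn:
                k = it - n_burn
                beta[c, k] = ch.report_beta()
                u[c, k] = ch.u
                v[c, k] = ch.v
                tau_u[c, k] = ch.tau_u
                tau_v[c, k] = ch.tau_v
                pi0[c, k] = 1.0 / (1.0 + np.exp(-ch.psi))
    samples = PosteriorSamples(
        coef_names=spec.coef_names,
        area_ids=tuple(data.area_ids),
        beta=beta,
        u=u,
        v=v,
        tau_u=tau_u,
        tau_v=tau_v,
        pi0=pi0,
        seed=seed,
        settings={
            "n_iter": n_iter,
            "n_burn": n_burn,
            "n_chains": n_chains,
            "sampler": "blocked metropolis-within-gibbs (ZIP augmented)",
            "prior_only": prior_only,
        },
    )
    if compute_diagnostics:
        samples.diagnostics = _diagnostics(samples)
    return samples


def _diagnostics(samples: PosteriorSamples):
    """Split-Rhat and bulk ESS for the global parameters, via ArviZ."""
    import warnings

    import pandas as pd

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az
    except ImportError:  # pragma: no cover
        return None
    rows = {}
    scalars = {
        "tau_u": samples.tau_u,
        "tau_v": samples.tau_v,
        "pi0": samples.pi0,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in scalars.items():
            rows[name] = (float(az.rhat(arr.copy())), float(az.ess(arr.copy())))
        for j, cn in enumerate(samples.coef_names):
            arr = samples.beta[:, :, j].copy()
            rows[f"beta[{cn}]"] = (float(az.rhat(arr)), float(az.ess(arr)))
    return pd.DataFrame(rows, index=["rhat", "ess_bulk"]).T
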