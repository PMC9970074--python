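"""Conjugate Gibbs samplers for the Bayesian regressions used in the pipeline.

Two models are implemented:

* :func:`sample_linear` — Gaussian linear regression ``y = X b + e`` with
  independent Normal priors on the coefficients (allowing informative
  per-coefficient means/scales) and a half-Cauchy prior on the residual
  scale, handled through the inverse-gamma auxiliary-variable trick.

* :func:`sample_multilevel` — Gaussian multilevel linear regression with a
  varying intercept and varying slopes per group (physician),

      y_i = x_i' (beta + u_{g(i)}) + e_i,     e_i ~ N(0, sigma^2)
      u_g ~ N(0, Sigma_u)

  Population coefficients get Normal priors; ``Sigma_u`` gets the
  Huang-Wand hierarchical inverse-Wishart prior, which induces half-t
  margins on the random-effect standard deviations and a marginally
  uniform prior on their correlations. All full conditionals are
  conjugate, so sampling is plain Gibbs: no tuning, no divergences.

Chains are run sequentially from independent seeds; draws are returned
per chain so that split R-hat can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "McmcConfig",
    "GibbsDraws",
    "sample_linear",
    "sample_multilevel",
    "split_rhat",
]


@dataclass(frozen=True)
class McmcConfig:
    """MCMC bookkeeping: per-chain iterations, burn-in and thinning.

    Defaults retain ``4 * (8000 - 3000) / 10 = 2000`` posterior draws.
    """

    n_chains: int = 4
    iterations: int = 8000
    burn_in: int = 3000
    thinning: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_retained < 500:
            raise ValueError(
                f"configuration retains only {self.n_retained} draws; "
                "at least 500 are required for stable interval estimates"
            )

    @property
    def per_chain_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.per_chain_retained

    def chain_seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(self.n_chains)


@dataclass
class GibbsDraws:
    """Retained posterior draws, stacked over chains.

    ``beta`` has shape (S, d); ``u`` (S, P, d) when random effects are
    present; ``sigma`` (S,); ``sd_u`` (S, d). ``chain`` labels each of the
    S retained draws with its chain index so per-chain blocks can be
    recovered for convergence diagnostics.
    """

    beta: np.ndarray
    sigma: np.ndarray
    chain: np.ndarray
    u: np.ndarray | None = None
    sd_u: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def by_chain(self, arr: np.ndarray) -> np.ndarray:
        """Reshape (S, ...) draws into (n_chains, S/n_chains, ...)."""
        n_chains = int(self.chain.max()) + 1
        per = self.n_draws // n_chains
        return arr.reshape(n_chains, per, *arr.shape[1:])


def _jittered_cholesky(prec: np.ndarray) -> np.ndarray:
    """Cholesky with a diagonal-jitter retry for near-degenerate precisions
    (e.g. a constant outcome driving the residual variance toward zero)."""
    try:
        return np.linalg.cholesky(prec)
    except np.linalg.LinAlgError:
        scale = np.abs(np.diagonal(prec, axis1=-2, axis2=-1)).max()
        eye = np.eye(prec.shape[-1])
        for exp in range(-10, 1):
            try:
                return np.linalg.cholesky(prec + (10.0**exp) * scale * 1e-6 * eye)
            except np.linalg.LinAlgError:
                continue
        raise


def _wishart_draw(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Wishart(df, scale) sample via the Bartlett decomposition."""
    d = scale.shape[0]
    L = _jittered_cholesky(scale)
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        A[i, :i] = rng.standard_normal(i)
    LA = L @ A
    return LA @ LA.T


def _chol_mvn_draw(rng: np.random.Generator, prec: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Draw from N(prec^{-1} rhs, prec^{-1}) via Cholesky of the precision."""
    L = _jittered_cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(rhs.shape[-1])
    # Solve L' x = z gives covariance prec^{-1}.
    return mean + np.linalg.solve(L.T, z)


def _batched_mvn_draws(
    rng: np.random.Generator, prec: np.ndarray, rhs: np.ndarray
) -> np.ndarray:
    """Batched draws from N(prec_p^{-1} rhs_p, prec_p^{-1}), prec (P,d,d)."""
    L = _jittered_cholesky(prec)
    mean = np.linalg.solve(prec, rhs[..., None])[..., 0]
    z = rng.standard_normal(rhs.shape)
    Lt = np.swapaxes(L, -1, -2)
    return mean + np.linalg.solve(Lt, z[..., None])[..., 0]


def sample_linear(
    y: np.ndarray,
    X: np.ndarray,
    prior_mean: np.ndarray,
    prior_sd: np.ndarray,
    mcmc: McmcConfig,
    resid_scale: float = 10.0,
) -> GibbsDraws:
    """Gibbs sampler for Gaussian linear regression with Normal priors.

    Parameters
    ----------
    prior_mean, prior_sd
        Per-coefficient Normal prior means and standard deviations
        (length d, matching the columns of ``X``); this is how informative
        priors imported from earlier studies enter the model.
    resid_scale
        Scale ``A`` of the half-Cauchy prior on the residual SD.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    prior_mean = np.broadcast_to(np.asarray(prior_mean, float), (d,)).copy()
    prior_prec = 1.0 / np.broadcast_to(np.asarray(prior_sd, float), (d,)) ** 2

    G = X.T @ X
    c = X.T @ y
    yy = float(y @ y)

    per = mcmc.per_chain_retained
    S = mcmc.n_retained
    beta_out = np.empty((S, d))
    sigma_out = np.empty(S)
    chain_out = np.empty(S, dtype=int)

    for ci, ss in enumerate(mcmc.chain_seeds()):
        rng = np.random.default_rng(ss)
        # Ridge initialization keeps the first iterations well-conditioned.
        beta = np.linalg.solve(G + np.diag(prior_prec + 1e-8), c)
        resid = y - X @ beta
        sigma2 = max(float(resid @ resid) / max(n - d, 1), 1e-6)
        xi = 1.0

        kept = 0
        for it in range(mcmc.iterations):
            prec = G / sigma2 + np.diag(prior_prec)
            rhs = c / sigma2 + prior_prec * prior_mean
            beta = _chol_mvn_draw(rng, prec, rhs)

            sse = yy - 2.0 * beta @ c + beta @ G @ beta
            sse = max(sse, 0.0)
            sigma2 = max(1.0 / rng.gamma((n + 1.0) / 2.0, 1.0 / (0.5 * sse + 1.0 / xi)), 1e-12)
            xi = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / sigma2 + 1.0 / resid_scale**2))

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
                idx = ci * per + kept
                beta_out[idx] = beta
                sigma_out[idx] = np.sqrt(sigma2)
                chain_out[idx] = ci
                kept += 1

    return GibbsDraws(beta=beta_out, sigma=sigma_out, chain=chain_out)


def sample_multilevel(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    prior_mean: np.ndarray,
    prior_sd: np.ndarray,
    mcmc: McmcConfig,
    resid_scale: float = 10.0,
    ranef_scale: float = 2.5,
    correlated: bool = True,
    hw_nu: float = 2.0,
) -> GibbsDraws:
    """Gibbs sampler for the varying-intercept, varying-slopes model.

    ``groups`` holds integer group codes 0..P-1 (one physician per code).
    With a single group the model degenerates: random effects are dropped
    and the pooled :func:`sample_linear` posterior is returned with zero
    group deviations, so downstream bookkeeping is unchanged.

    ``correlated=True`` places a Huang-Wand prior on the full random-effect
    covariance (unstructured correlations); ``False`` uses independent
    variances with half-t-type priors, a cheaper option for small samples.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, d = X.shape
    codes, inv = np.unique(groups, return_inverse=True)
    P = codes.size

    if P == 1:
        draws = sample_linear(y, X, prior_mean, prior_sd, mcmc, resid_scale)
        draws.u = np.zeros((draws.n_draws, 1, d))
        draws.sd_u = np.zeros((draws.n_draws, d))
        return draws

    prior_mean = np.broadcast_to(np.asarray(prior_mean, float), (d,)).copy()
    prior_prec = 1.0 / np.broadcast_to(np.asarray(prior_sd, float), (d,)) ** 2

    # Per-group sufficient statistics: iteration cost is independent of n.
    G_p = np.zeros((P, d, d))
    c_p = np.zeros((P, d))
    yy_p = np.zeros(P)
    for p in range(P):
        sel = inv == p
        Xp, yp = X[sel], y[sel]
        G_p[p] = Xp.T @ Xp
        c_p[p] = Xp.T @ yp
        yy_p[p] = yp @ yp
    G = G_p.sum(axis=0)
    c = c_p.sum(axis=0)

    A2 = ranef_scale**2
    per = mcmc.per_chain_retained
    S = mcmc.n_retained
    beta_out = np.empty((S, d))
    u_out = np.empty((S, P, d))
    sigma_out = np.empty(S)
    sd_u_out = np.empty((S, d))
    chain_out = np.empty(S, dtype=int)

    for ci, ss in enumerate(mcmc.chain_seeds()):
        rng = np.random.default_rng(ss)
        beta = np.linalg.solve(G + np.diag(prior_prec + 1e-8), c)
        u = np.zeros((P, d))
        resid = y - X @ beta
        sigma2 = max(float(resid @ resid) / max(n - d, 1), 1e-6)
        xi = 1.0
        Sigma_u = np.eye(d) * 0.1
        a_aux = np.full(d, 1.0)

        kept = 0
        for it in range(mcmc.iterations):
            # beta | u, sigma2
            Gu = np.einsum("pij,pj->i", G_p, u)
            prec = G / sigma2 + np.diag(prior_prec)
            rhs = (c - Gu) / sigma2 + prior_prec * prior_mean
            beta = _chol_mvn_draw(rng, prec, rhs)

            # u_p | beta, Sigma_u, sigma2 (batched over groups)
            Omega = np.linalg.inv(Sigma_u)
            prec_p = G_p / sigma2 + Omega
            rhs_p = (c_p - G_p @ beta) / sigma2
            u = _batched_mvn_draws(rng, prec_p, rhs_p)

            # Sigma_u | u via Huang-Wand hierarchy
            if correlated:
                S_u = u.T @ u
                scale = 2.0 * hw_nu * np.diag(1.0 / a_aux) + S_u
                df = hw_nu + P + d - 1
                inv_scale = np.linalg.inv(scale)
                inv_scale = (inv_scale + inv_scale.T) / 2.0
                W = _wishart_draw(rng, df, inv_scale)
                Sigma_u = np.linalg.inv(W + 1e-10 * np.eye(d))
                Omega_diag = np.diag(np.linalg.inv(Sigma_u))
                a_aux = 1.0 / rng.gamma(
                    (hw_nu + d) / 2.0, 1.0 / (hw_nu * Omega_diag + 1.0 / A2)
                )
                a_aux = np.clip(a_aux, 1e-10, 1e10)
            else:
                ssq = (u**2).sum(axis=0)
                v = 1.0 / rng.gamma(
                    (hw_nu + P) / 2.0, 1.0 / (hw_nu / a_aux + 0.5 * ssq)
                )
                a_aux = 1.0 / rng.gamma(
                    (hw_nu + 1) / 2.0, 1.0 / (hw_nu / v + 1.0 / A2)
                )
                Sigma_u = np.diag(v)

            # sigma2 | beta, u  (SSE from per-group quadratic forms)
            bu = beta[None, :] + u
            sse = float(
                np.sum(
                    yy_p
                    - 2.0 * np.einsum("pi,pi->p", c_p, bu)
                    + np.einsum("pi,pij,pj->p", bu, G_p, bu)
                )
            )
            sse = max(sse, 0.0)
            sigma2 = max(1.0 / rng.gamma((n + 1.0) / 2.0, 1.0 / (0.5 * sse + 1.0 / xi)), 1e-12)
            xi = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / sigma2 + 1.0 / resid_scale**2))

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
                idx = ci * per + kept
                beta_out[idx] = beta
                u_out[idx] = u
                sigma_out[idx] = np.sqrt(sigma2)
                sd_u_out[idx] = np.sqrt(np.diag(Sigma_u))
                chain_out[idx] = ci
                kept += 1

    return GibbsDraws(
        beta=beta_out, sigma=sigma_out, chain=chain_out, u=u_out, sd_u=sd_u_out
    )


def split_rhat(chains: np.ndarray) -> float:
    """Split Gelman-Rubin potential scale reduction for one parameter.

    ``chains`` has shape (n_chains, n_draws). Each chain is split in half,
    and the classic between/within variance ratio is computed over the
    resulting sequences. Zero-variance draws (all sequences constant and
    equal) return exactly 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    m, n = chains.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = seqs.mean(axis=1)
    vars_ = seqs.var(axis=1, ddof=1)
    W = vars_.mean()
    B = half * means.var(ddof=1)
    if W < 1e-300:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))
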