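"""Two-phase mixture model and its EM fit.

Each observed count Y_gi arises from one of two latent phases:

* background (Z_gi = 0): Y ~ ZIP(p0_i, lam_i), a cell-specific zero-inflated
  Poisson — the gene is not actively transcribed and reads are noise;
* active (Z_gi = 1): Y | theta ~ Poisson(theta * S_gi) with the biological
  concentration theta ~ LogNormal(mu_g, sigma2_g) and S_gi the technical
  distortion to be estimated downstream.

The marginal active-phase density is a Poisson-lognormal integral, computed
by Gauss-Hermite quadrature; for large counts the Poisson layer is
negligible and a lognormal density on log Y is used instead. EM alternates
posterior phase probabilities (E-step) with per-gene updates of
(mu_g, sigma2_g, pi_g). The (mu, sigma2) update uses phase-weighted moments
of log counts over cells with Y >= 1; since that is not the exact maximizer
of the Poisson-lognormal likelihood, each gene's candidate update is kept
only if it does not decrease the expected complete-data log-likelihood
(a generalized-EM step), which makes the log-likelihood trace provably
non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .background import BackgroundParams
from .io import CountMatrix

logger = logging.getLogger("sc2pnorm")

APPROX_COUNT = 100  # counts >= this use the lognormal approximation
_GENE_BLOCK = 512   # gene-chunk size for the quadrature arrays


class EMError(RuntimeError):
    """Raised when the mixture cannot be fit at all."""


@dataclass
class TwoPhaseFit:
    """Result of the two-phase EM.

    ``mu``/``sigma2`` are NaN for genes flagged non-estimable (too little
    active-phase mass); those genes keep ``Z_post = 0``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    mu: np.ndarray
    sigma2: np.ndarray
    pi_active: np.ndarray
    Z_post: np.ndarray
    estimable: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    threshold: float = 0.99

    @property
    def n_active_cells(self) -> np.ndarray:
        """Cells called active (Z_post > threshold) per gene."""
        return (self.Z_post > self.threshold).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mu_hat": self.mu,
                "sigma2_hat": self.sigma2,
                "pi_hat": self.pi_active,
                "estimable": self.estimable.astype(int),
            }
        )


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def background_density(y: int, p0: float, lam: float) -> float:
    """ZIP pmf: p0 * 1[y=0] + (1 - p0) * Poisson(y; lam)."""
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must be in [0, 1]")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    base = (1.0 - p0) * poisson.pmf(y, lam)
    return float(base + (p0 if y == 0 else 0.0))


def _agh_logpmf(y: np.ndarray, mu: np.ndarray, sigma2: np.ndarray,
                log_s: np.ndarray, n_nodes: int) -> np.ndarray:
    """Log Poisson-lognormal pmf by adaptive Gauss-Hermite quadrature.

    The integrand Poisson(y; e^{t + log_s}) N(t; mu, sigma2) is strongly
    peaked near t = log(y) - log_s for large y (width ~ 1/sqrt(y)), which a
    fixed quadrature rule centered at the prior mean cannot resolve. The
    rule is therefore centered at the integrand's mode (found by Newton on
    the concave log integrand) with the node spacing matched to its
    curvature — the standard adaptive-GH construction for mixed Poisson
    likelihoods. All inputs broadcast elementwise.
    """
    y = np.asarray(y, dtype=float)
    nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
    # Newton for the mode of h(t) = y(t+log_s) - e^{t+log_s} - (t-mu)^2/(2s2)
    t = np.where(y > 0, np.log(y + 0.5) - log_s, mu)
    for _ in range(40):
        rate = np.exp(np.clip(t + log_s, None, 700.0))
        grad = y - rate - (t - mu) / sigma2
        hess = -rate - 1.0 / sigma2
        step = grad / hess
        t = t - step
        if np.max(np.abs(step)) < 1e-12:
            break
    rate = np.exp(np.clip(t + log_s, None, 700.0))
    sq = 1.0 / np.sqrt(rate + 1.0 / sigma2)  # curvature-matched width
    tk = t[..., None] + np.sqrt(2.0) * sq[..., None] * nodes
    lograte_k = np.clip(tk + log_s[..., None], None, 700.0)
    logf = (
        y[..., None] * lograte_k
        - np.exp(lograte_k)
        - gammaln(y + 1.0)[..., None]
        - 0.5 * np.log(2.0 * np.pi * sigma2)[..., None]
        - (tk - mu[..., None]) ** 2 / (2.0 * sigma2[..., None])
    )
    lse = logsumexp(logf + (np.log(wts) + nodes**2), axis=-1)
    return lse + 0.5 * np.log(2.0) + np.log(sq)


def active_density(
    y: int,
    mu: float,
    sigma2: float,
    log_s: float = 0.0,
    n_nodes: int = 25,
) -> float:
    """Poisson-lognormal pmf by (adaptive) Gauss-Hermite quadrature.

    P(Y = y | active) = ∫ Poisson(y; e^{u + log_s}) N(u; mu, sigma2) du.
    """
    if not np.isfinite([y, mu, sigma2, log_s]).all():
        raise ValueError("non-finite input to active_density")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if n_nodes < 5:
        raise ValueError("n_nodes must be >= 5")
    out = _agh_logpmf(np.array(float(y)), np.array(mu), np.array(sigma2),
                      np.array(log_s), n_nodes)
    return float(np.exp(out))


def _active_logdensity(
    Y: np.ndarray,
    mu: np.ndarray,
    sigma2: np.ndarray,
    log_s: np.ndarray,
    n_nodes: int = 25,
) -> np.ndarray:
    """Vectorized log active density for a (genes x cells) block.

    Adaptive quadrature for Y < APPROX_COUNT; lognormal density of log Y
    (times the 1/Y Jacobian) for larger counts, where Poisson noise is
    negligible.
    """
    out = np.empty(Y.shape, dtype=float)
    for lo in range(0, Y.shape[0], _GENE_BLOCK):
        hi = min(lo + _GENE_BLOCK, Y.shape[0])
        yb = Y[lo:hi]
        mub = np.broadcast_to(mu[lo:hi, None], yb.shape)
        s2b = np.broadcast_to(sigma2[lo:hi, None], yb.shape)
        quad = _agh_logpmf(yb, mub, s2b, log_s[lo:hi], n_nodes)
        m = mu[lo:hi, None] + log_s[lo:hi]
        logy = np.log(np.maximum(yb, 1))
        s2 = sigma2[lo:hi, None]
        ln_approx = (
            -0.5 * np.log(2.0 * np.pi * s2) - (logy - m) ** 2 / (2.0 * s2) - logy
        )
        out[lo:hi] = np.where(yb >= APPROX_COUNT, ln_approx, quad)
    return out


def _background_logdensity(Y: np.ndarray, bg: BackgroundParams) -> np.ndarray:
    """Log ZIP pmf per (gene, cell); cell parameters broadcast over genes."""
    lam = bg.lam[None, :]
    p0 = bg.p0[None, :]
    with np.errstate(divide="ignore"):
        logpois = Y * np.log(lam) - lam - gammaln(Y + 1.0)
        out = np.log1p(-p0) + logpois
        at_zero = np.log(p0 + (1.0 - p0) * np.exp(-lam))
    return np.where(Y == 0, np.broadcast_to(at_zero, Y.shape), out)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def zip_quantile(p0: float, lam: float, q: float = 0.999) -> int:
    """Smallest y with ZIP cdf(y) >= q."""
    if q <= p0:
        return 0
    return int(poisson.ppf((q - p0) / (1.0 - p0), lam))

def init_phase(cm: CountMatrix, bg: BackgroundParams,
               init_tail_prob: float = 0.999) -> np.ndarray:
    """Initial phase indicators: 1 where Y exceeds the cell's ZIP quantile.

    A count that the background could plausibly produce (at or below the
    ``init_tail_prob`` quantile of ZIP(p0_i, lam_i)) starts as background;
    anything larger starts active. Y = 0 is always background-compatible.
    """
    cut = np.array(
        [zip_quantile(bg.p0[i], bg.lam[i], init_tail_prob)
         for i in range(bg.n_cells)]
    )
    return (cm.counts > cut[None, :]).astype(float)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _weighted_moments(
    logY: np.ndarray, Z: np.ndarray, nonzero: np.ndarray,
    sigma2_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene Z-weighted mean/variance of log counts over Y >= 1 cells."""
    W = Z * nonzero
    mass = W.sum(axis=1)
    safe = np.maximum(mass, 1e-300)
    mu = (W * logY).sum(axis=1) / safe
    var = (W * (logY - mu[:, None]) ** 2).sum(axis=1) / safe
    return mu, np.maximum(var, sigma2_floor), mass


def em_fit(
    cm: CountMatrix,
    bg: BackgroundParams,
    log_s: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int | None = None,
    sigma2_floor: float = 0.01,
    min_active_mass: float = 3.0,
    n_nodes: int = 25,
    init_tail_prob: float = 0.999,
) -> TwoPhaseFit:
    """Fit the two-phase mixture by (generalized) EM.

    Parameters
    ----------
    log_s
        Known log technical factors; defaults to zeros (the first pass,
        before normalization factors exist). NaN entries are treated as 0.
    min_active_mass
        Minimum effective number of active cells for a gene's (mu, sigma2)
        to be estimable; below it the gene is flagged, mu is missing and
        the posterior is forced to the background phase.
    seed
        Unused by the deterministic EM; accepted for API uniformity.

    Notes
    -----
    The log-likelihood trace is non-decreasing: the pi update is the exact
    M-step, and the (mu, sigma2) moment update is accepted per gene only if
    it does not lower that gene's expected active-phase log-likelihood.
    """
    del seed  # EM is deterministic given the data
    Y = cm.counts
    G, n = Y.shape
    if log_s is None:
        log_s = np.zeros((G, n))
    log_s = np.nan_to_num(np.asarray(log_s, dtype=float), nan=0.0)

    nonzero = Y >= 1
    with np.errstate(divide="ignore"):
        logY = np.where(nonzero, np.log(np.maximum(Y, 1)), 0.0) - log_s
    log_fb = _background_logdensity(Y, bg)

    Z = init_phase(cm, bg, init_tail_prob)
    mu, sigma2, mass = _weighted_moments(logY, Z, nonzero, sigma2_floor)
    pi = Z.mean(axis=1)
    estimable = mass >= min_active_mass
    if not estimable.any():
        raise EMError("no gene has enough active-phase mass to estimate")
    mu[~estimable] = np.nan
    sigma2[~estimable] = np.nan
    pi[~estimable] = 0.0

    est = np.flatnonzero(estimable)
    Z = np.zeros((G, n))
    loglik_trace: list[float] = []
    converged = False
    it = 0
    log_fa = _active_logdensity(Y[est], mu[est], sigma2[est], log_s[est], n_nodes)

    for it in range(1, max_iter + 1):
        # E-step (estimable genes only; others stay background)
        pi_c = np.clip(pi[est], 1e-12, 1.0 - 1e-12)
        log_num = np.log(pi_c)[:, None] + log_fa
        log_den = np.logaddexp(log_num, np.log1p(-pi_c)[:, None] + log_fb[est])
        Z[est] = np.exp(log_num - log_den)

        loglik = float(log_den.sum() + log_fb[~estimable].sum())
        loglik_trace.append(loglik)

        # M-step
        pi_new = pi.copy()
        pi_new[est] = Z[est].mean(axis=1)
        mu_c, s2_c, mass = _weighted_moments(logY, Z, nonzero, sigma2_floor)

        # generalized-EM guard: keep the moment update only where it does
        # not decrease the expected active-phase log-likelihood
        cand_fa = _active_logdensity(Y[est], mu_c[est], s2_c[est],
                                     log_s[est], n_nodes)
        q_cur = (Z[est] * log_fa).sum(axis=1)
        q_new = (Z[est] * cand_fa).sum(axis=1)
        accept = q_new >= q_cur - 1e-12
        delta_mu = np.zeros(len(est))
        delta_mu[accept] = np.abs(mu_c[est][accept] - mu[est][accept])
        mu[est] = np.where(accept, mu_c[est], mu[est])
        sigma2[est] = np.where(accept, s2_c[est], sigma2[est])
        log_fa = np.where(accept[:, None], cand_fa, log_fa)

        delta = max(
            float(delta_mu.max(initial=0.0)),
            float(np.abs(pi_new[est] - pi[est]).max(initial=0.0)),
        )
        pi = pi_new
        logger.info("EM iter %d: loglik=%.6f max-change=%.3e", it, loglik, delta)
        if delta < tol:
            converged = True
            break

    # final E-step so Z_post reflects the returned parameters
    pi_c = np.clip(pi[est], 1e-12, 1.0 - 1e-12)
    log_num = np.log(pi_c)[:, None] + log_fa
    log_den = np.logaddexp(log_num, np.log1p(-pi_c)[:, None] + log_fb[est])
    Z[est] = np.exp(log_num - log_den)
    loglik_trace.append(float(log_den.sum() + log_fb[~estimable].sum()))

    # genes whose active-phase mass collapsed during EM are flagged last,
    # so the trace above reflects one consistent model throughout
    _, _, mass = _weighted_moments(logY, Z, nonzero, sigma2_floor)
    dead = estimable & (mass < min_active_mass)
    if dead.any():
        logger.info("EM: %d genes below min active mass; flagged",
                    int(dead.sum()))
        estimable = estimable & ~dead
        mu[dead] = np.nan
        sigma2[dead] = np.nan
        pi[dead] = 0.0
        Z[dead] = 0.0

    return TwoPhaseFit(
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        mu=mu,
        sigma2=sigma2,
        pi_active=pi,
        Z_post=Z,
        estimable=estimable,
        loglik_trace=np.array(loglik_trace),
        n_iter=it,
        converged=converged,
    )


def phase_call(fit: TwoPhaseFit, threshold: float = 0.99) -> np.ndarray:
    """Boolean active-phase calls: Z_post strictly greater than threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return fit.Z_post > threshold
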