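"""Per-cell zero-inflated Poisson background estimation.

In the two-phase model a gene that is not actively transcribed in a cell
produces a background count Y ~ ZIP(p0_i, lam_i): a point mass p0 at zero
mixed with Poisson(lam). If N background genes follow Poisson(lam), the
frequency of count value y among them is

    n_y ≈ N exp(-lam) lam^y / y!

so w_y = log(n_y) + log(y!) is linear in y with slope log(lam) and intercept
log(N) - lam. Estimation regresses w_y on y over the low-count window
y in 1..y_max; high counts are contaminated by active-phase observations, so
the regression is robustified with Tukey bisquare IRLS. The excess of
observed zeros over the Poisson prediction then yields p0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import CountMatrix

logger = logging.getLogger("sc2pnorm")

TUKEY_C = 4.685  # standard bisquare tuning constant (95% Gaussian efficiency)


class BackgroundError(RuntimeError):
    """Raised when the low-count window cannot support ZIP estimation."""


@dataclass
class BackgroundParams:
    """Per-cell ZIP background parameters.

    Attributes
    ----------
    p0 : zero-inflation mass per cell, in [0, 1]
    lam : Poisson rate per cell, > 0
    n_bg_hat : implied number of (non-inflated) background genes per cell
    flagged : cells whose own estimate failed and was imputed from the
        cohort median
    fit_range : (y_min, y_max) count window used in the regression
    """

    cell_ids: list[str]
    p0: np.ndarray
    lam: np.ndarray
    n_bg_hat: np.ndarray
    flagged: np.ndarray
    fit_range: tuple[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "p0_hat": self.p0,
                "lam_hat": self.lam,
                "n_bg_hat": self.n_bg_hat,
                "flagged": self.flagged.astype(int),
            }
        )


def logfreq_points(y_counts: np.ndarray, y_max: int = 10) -> pd.DataFrame:
    """Log-frequency points (y, w_y, n_y) for the background regression.

    For each count value y in 1..y_max observed at least once, returns
    w_y = log(n_y) + log(y!). Under a Poisson background these points fall
    on a line with slope log(lambda).
    """
    if y_max < 2:
        raise ValueError("y_max must be >= 2")
    y_counts = np.asarray(y_counts)
    vals, freqs = np.unique(y_counts[(y_counts >= 1) & (y_counts <= y_max)],
                            return_counts=True)
    if len(vals) < 2:
        raise BackgroundError(
            "insufficient low-count support: fewer than 2 distinct count "
            f"values in 1..{y_max}"
        )
    w = np.log(freqs) + gammaln(vals + 1.0)
    return pd.DataFrame({"y": vals.astype(int), "w": w, "n": freqs.astype(int)})


def _wls(y: np.ndarray, w: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of w on y; returns (intercept, slope)."""
    W = weights / weights.sum()
    ybar = float(W @ y)
    wbar = float(W @ w)
    sxx = float(W @ (y - ybar) ** 2)
    if sxx <= 0:
        raise BackgroundError("degenerate abscissae in background regression")
    slope = float(W @ ((y - ybar) * (w - wbar))) / sxx
    return wbar - slope * ybar, slope


def _weighted_median(x: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(weights[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def _robust_line(y: np.ndarray, w: np.ndarray, base_weights: np.ndarray,
                 iters: int) -> tuple[float, float]:
    """Tukey-bisquare IRLS line fit for the log-frequency regression.

    ``base_weights`` are the bin frequencies n_y: each regression point
    summarizes n_y observations and Var(w_y) ~ 1/n_y, so points are
    weighted by n_y and residuals are standardized by sqrt(n_y) before the
    bisquare (tuning constant 4.685) is applied. The scale of the
    standardized residuals is 1 under the model; a frequency-weighted MAD
    is used when it indicates extra dispersion.

    Initialization matters: active-phase contamination inflates the upper
    half of the count window, so a global OLS line can start so far off
    that reweighting never recovers. The slope is therefore initialized
    from the two most-populated bins (the head of the distribution, where
    contamination is negligible) and refined by IRLS over all bins.
    """
    top = np.argsort(base_weights)[-2:]
    y0, w0 = y[top], w[top]
    if y0[0] == y0[1]:
        icept, slope = _wls(y, w, base_weights)
    else:
        slope = float((w0[1] - w0[0]) / (y0[1] - y0[0]))
        icept = float(
            np.average(w - slope * y, weights=base_weights)
        )
    sqn = np.sqrt(base_weights)
    for _ in range(iters):
        resid = w - (icept + slope * y)
        z = resid * sqn
        med = _weighted_median(z, base_weights)
        scale = max(
            1.0,
            _weighted_median(np.abs(z - med), base_weights) / 0.6745,
        )
        u = z / (TUKEY_C * scale)
        biw = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if biw.sum() == 0 or np.count_nonzero(biw) < 2:
            break
        icept, slope = _wls(y, w, base_weights * biw)
    return icept, slope


def _head_window(y: np.ndarray, w: np.ndarray, n: np.ndarray,
                 z_crit: float = 2.5) -> int:
    """Number of leading bins free of detectable phase-II contamination.

    Active-phase leakage only ever adds counts and its share grows with y,
    so the clean region is a prefix of the bins. Starting from the first
    two bins, each next bin is admitted unless its observed log frequency
    exceeds the current line's prediction by more than ``z_crit`` sampling
    standard errors (sd(log n) ~ 1/sqrt(n)); the first significant upward
    break ends the window.
    """
    k = 2
    while k < len(y):
        icept, slope = _wls(y[:k], w[:k], n[:k])
        pred_w = icept + slope * y[k]
        n_pred = np.exp(pred_w - gammaln(y[k] + 1.0))
        se = 1.0 / np.sqrt(max(n_pred, 1.0))
        if (w[k] - pred_w) > z_crit * se:
            break
        k += 1
    return k


def estimate_zip(
    y_counts: np.ndarray,
    y_max: int = 10,
    robust_iters: int = 20,
    robust: bool = True,
) -> tuple[float, float, float]:
    """Estimate (p0, lam, n_bg) for one cell's count vector.

    Fits w_y = c + y log(lam) robustly over y in 1..y_max, then attributes
    the excess of observed zeros over the Poisson prediction to the
    inflation mass. The background population size B satisfies
    B (1 - p0) = N_bg (the Poisson part seen by the regression); p0 and B
    are reconciled with one fixed-point pass starting from B = G.

    Set ``robust=False`` for the plain (frequency-weighted) OLS variant,
    used only as a contrast in robustness checks.
    """
    y_counts = np.asarray(y_counts)
    G = len(y_counts)
    pts = logfreq_points(y_counts, y_max)
    y, w, n = pts["y"].to_numpy(float), pts["w"].to_numpy(), pts["n"].to_numpy(float)
    if robust:
        k = _head_window(y, w, n)
        icept, slope = _robust_line(y[:k], w[:k], n[:k], robust_iters)
    else:
        icept, slope = _wls(y, w, n)
    if not np.isfinite(slope):
        slope = np.nan
    lam = float(np.exp(slope)) if np.isfinite(slope) else np.nan
    if not np.isfinite(lam) or lam <= 0:
        # Poisson ratio fallback: n_2/n_1 = lam/2
        n1 = pts.loc[pts["y"] == 1, "n"]
        n2 = pts.loc[pts["y"] == 2, "n"]
        if len(n1) and len(n2):
            lam = float(2.0 * n2.iloc[0] / n1.iloc[0])
            icept = float(np.log(n1.iloc[0]) - np.log(lam) + lam)
        else:
            raise BackgroundError("insufficient low-count support")
    n_bg = float(np.clip(np.exp(icept + lam), 0.0, G))
    n0 = float(np.sum(y_counts == 0))
    expected_bg_zeros = n_bg * np.exp(-lam)
    # fixed-point pass on the background population size B = n_bg/(1-p0)
    p0 = max(0.0, (n0 - expected_bg_zeros) / G)
    B = n_bg / max(1.0 - p0, 1e-3)
    B = float(np.clip(B, n_bg, G))
    p0 = max(0.0, (n0 - expected_bg_zeros) / max(B, 1.0))
    p0 = float(np.clip(p0, 0.0, 0.999))
    return p0, lam, n_bg


def estimate_background(
    cm: CountMatrix,
    y_max: int = 10,
    robust_iters: int = 20,
) -> BackgroundParams:
    """ZIP background parameters for every cell of a count matrix.

    Cells whose low-count window cannot support the regression are flagged
    and imputed with the cohort median of the successful cells' (p0, lam);
    downstream stages need parameters for every cell. If no cell succeeds a
    hard error is raised.
    """
    n = cm.n_cells
    p0 = np.full(n, np.nan)
    lam = np.full(n, np.nan)
    nbg = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        try:
            p0[i], lam[i], nbg[i] = estimate_zip(cm.counts[:, i], y_max,
                                                 robust_iters)
        except BackgroundError as exc:
            logger.info("cell %s: background estimation failed (%s); "
                        "imputing", cm.cell_ids[i], exc)
            flagged[i] = True
    ok = ~flagged
    if not ok.any():
        raise BackgroundError("background estimation failed for every cell")
    if flagged.any():
        p0[flagged] = np.median(p0[ok])
        lam[flagged] = np.median(lam[ok])
        nbg[flagged] = np.median(nbg[ok])
    return BackgroundParams(
        cell_ids=list(cm.cell_ids),
        p0=p0,
        lam=lam,
        n_bg_hat=nbg,
        flagged=flagged,
        fit_range=(1, y_max),
    )
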