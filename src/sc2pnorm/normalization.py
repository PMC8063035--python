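"""Cell- and gene-specific normalization factors from active-phase residuals.

For genes called active (posterior Z_gi above a high threshold) with Y >= 1,
the residual eps_gi = log Y_gi - mu_g has expectation log S_gi, the log
technical distortion. Within a cell the distortion varies smoothly with the
gene's mean expression, so a robust natural cubic spline f_i is fitted per
cell to the residuals against mu_g, and log S_gi is read off the curve —
by default at the observed log count (f_i(log Y_gi)), optionally at the
gene mean (f_i(mu_g)). The factors are only identified up to a constant, so
they are rescaled to make the mean of S over unmasked genes equal 1 in the
median-depth reference cell. Background entries carry no information about
detection efficiency and stay masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import CountMatrix, LibrarySizes, ValidationError
from .twophase import TwoPhaseFit, phase_call

logger = logging.getLogger("sc2pnorm")

TUKEY_C = 4.685


# ---------------------------------------------------------------------------
# smooth per-cell curves
# ---------------------------------------------------------------------------

class CellCurve:
    """A per-cell smooth bias curve with constant extrapolation.

    ``kind`` is "spline" (natural cubic regression spline given by knots and
    basis coefficients), "constant", or "cohort" (pointwise-median grid of
    other cells' curves, linearly interpolated).
    """

    def __init__(self, kind: str, *, knots: np.ndarray | None = None,
                 coef: np.ndarray | None = None, value: float = 0.0,
                 grid_x: np.ndarray | None = None,
                 grid_y: np.ndarray | None = None,
                 x_range: tuple[float, float] = (0.0, 0.0)):
        self.kind = kind
        self.knots = knots
        self.coef = coef
        self.value = value
        self.grid_x = grid_x
        self.grid_y = grid_y
        self.x_range = x_range

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "constant":
            return np.full(x.shape, self.value)
        lo, hi = self.x_range
        xc = np.clip(x, lo, hi)  # constant extrapolation outside fit range
        if self.kind == "spline":
            return _ns_basis(xc, self.knots) @ self.coef
        if self.kind == "cohort":
            return np.interp(xc, self.grid_x, self.grid_y)
        raise ValueError(f"unknown curve kind {self.kind!r}")

    def shifted(self, c: float) -> "CellCurve":
        """The same curve minus a constant (for reference rescaling)."""
        if self.kind == "constant":
            return CellCurve("constant", value=self.value - c,
                             x_range=self.x_range)
        if self.kind == "spline":
            coef = self.coef.copy()
            coef[0] -= c  # first basis function is the constant 1
            return CellCurve("spline", knots=self.knots, coef=coef,
                             x_range=self.x_range)
        return CellCurve("cohort", grid_x=self.grid_x,
                         grid_y=self.grid_y - c, x_range=self.x_range)


def _ns_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis with K knots -> K columns: 1, x, N_1..N_{K-2}.

    Truncated-power construction; linear beyond the boundary knots (which,
    combined with clipping to the fitted range, yields constant
    extrapolation).
    """
    x = np.asarray(x, dtype=float)
    K = len(knots)
    cols = [np.ones_like(x), x]

    def d(k: int) -> np.ndarray:
        return (
            np.maximum(x - knots[k], 0.0) ** 3
            - np.maximum(x - knots[K - 1], 0.0) ** 3
        ) / (knots[K - 1] - knots[k])

    dlast = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - dlast)
    return np.column_stack(cols)


def _robust_spline(x: np.ndarray, y: np.ndarray, df: int,
                   robust_rounds: int = 3) -> CellCurve:
    """Natural cubic regression spline with bisquare IRLS reweighting."""
    if df >= len(x):
        logger.warning("spline df %d >= %d points; reducing", df, len(x))
        df = max(2, len(x) - 1)
    qs = np.linspace(0.0, 1.0, df)
    knots = np.unique(np.quantile(x, qs))
    if len(knots) < 2 or np.ptp(x) == 0:
        return CellCurve("constant", value=float(np.median(y)),
                         x_range=(float(x.min()), float(x.max())))
    B = _ns_basis(x, knots)
    w = np.ones(len(x))
    coef = np.zeros(B.shape[1])
    for _ in range(robust_rounds + 1):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=None)
        resid = y - B @ coef
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            break
        u = resid / (TUKEY_C * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
    return CellCurve("spline", knots=knots, coef=coef,
                     x_range=(float(x.min()), float(x.max())))


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

@dataclass
class Residuals:
    """Active-phase residuals eps_gi = log Y_gi - mu_g.

    ``eps`` is NaN outside the active set (Z above threshold, Y >= 1, gene
    estimable). ``abscissa`` is mu_g, the x-value the curves are fitted
    against.
    """

    eps: np.ndarray
    abscissa: np.ndarray  # per gene (mu_hat)
    active: np.ndarray    # boolean (gene, cell) mask backing eps
    gene_ids: list[str]
    cell_ids: list[str]

    def cell_points(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.active[:, i]
        return self.abscissa[m], self.eps[m, i]


def compute_residuals(cm: CountMatrix, fit: TwoPhaseFit,
                      threshold: float = 0.99) -> Residuals:
    """Residuals on the active set; genes with missing mu are excluded."""
    active = phase_call(fit, threshold) & (cm.counts >= 1)
    active &= fit.estimable[:, None]
    with np.errstate(divide="ignore"):
        logY = np.where(cm.counts >= 1, np.log(np.maximum(cm.counts, 1)), np.nan)
    eps = np.where(active, logY - fit.mu[:, None], np.nan)
    return Residuals(eps=eps, abscissa=fit.mu, active=active,
                     gene_ids=list(cm.gene_ids), cell_ids=list(cm.cell_ids))


def fit_cell_curve(res: Residuals, cell: str, df: int = 5,
                   robust_rounds: int = 3) -> CellCurve:
    """Robust spline fit of one cell's residuals against mu_g."""
    i = res.cell_ids.index(cell)
    x, y = res.cell_points(i)
    return _robust_spline(x, y, df, robust_rounds)


def fit_curves(res: Residuals, df: int = 5, min_curve_points: int = 50,
               robust_rounds: int = 3) -> tuple[dict[str, CellCurve], np.ndarray]:
    """Fit every cell's curve, with a fallback ladder for data-poor cells.

    Cells with >= ``min_curve_points`` active residuals get a spline; with
    10..min_curve_points-1 a constant at the median residual; with fewer
    than 10 the cohort-median curve (pointwise median of the other cells'
    fitted curves). Returns the curves and a flag vector marking fallbacks.
    """
    n = len(res.cell_ids)
    curves: dict[str, CellCurve] = {}
    flagged = np.zeros(n, dtype=bool)
    needs_cohort: list[str] = []
    for i, cell in enumerate(res.cell_ids):
        x, y = res.cell_points(i)
        if len(x) >= min_curve_points:
            curves[cell] = _robust_spline(x, y, df, robust_rounds)
        elif len(x) >= 10:
            flagged[i] = True
            curves[cell] = CellCurve(
                "constant", value=float(np.median(y)),
                x_range=(float(x.min()), float(x.max())),
            )
        else:
            flagged[i] = True
            needs_cohort.append(cell)
    if needs_cohort:
        donors = [c for c in res.cell_ids if c in curves]
        if not donors:
            raise ValidationError("no cell has enough residuals for a curve")
        xs = res.abscissa[np.isfinite(res.abscissa)]
        grid = np.linspace(float(xs.min()), float(xs.max()), 101)
        med = np.median(np.vstack([curves[c](grid) for c in donors]), axis=0)
        cohort = CellCurve("cohort", grid_x=grid, grid_y=med,
                           x_range=(grid[0], grid[-1]))
        for cell in needs_cohort:
            curves[cell] = cohort
    return curves, flagged


# ---------------------------------------------------------------------------
# normalization factors
# ---------------------------------------------------------------------------

@dataclass
class NormFactorMatrix:
    """Per-(gene, cell) log normalization factors and the per-cell curves.

    ``log_s`` is NaN (masked) where the gene is not called active in the
    cell: the factor is meaningless for background observations.
    """

    log_s: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    curves: dict[str, CellCurve]
    flagged_cells: np.ndarray
    reference_cell: Optional[str] = None

    @property
    def n_active(self) -> np.ndarray:
        """Unmasked (active) entry count per cell."""
        return np.isfinite(self.log_s).sum(axis=0)

    def s_matrix(self) -> np.ndarray:
        return np.exp(self.log_s)

    def curves_frame(self) -> pd.DataFrame:
        """Knots and coefficients, one row per (cell, component)."""
        rows = []
        for cell in self.cell_ids:
            cv = self.curves[cell]
            lo, hi = cv.x_range
            if cv.kind == "spline":
                # basis dimension equals the knot count, so knots and
                # coefficients pair up one-to-one
                for k, (kx, c) in enumerate(zip(cv.knots, cv.coef)):
                    rows.append((cell, "spline", k, float(kx), float(c),
                                 lo, hi))
            elif cv.kind == "constant":
                rows.append((cell, "constant", 0, np.nan, cv.value, lo, hi))
            else:
                for k, (gx, gy) in enumerate(zip(cv.grid_x, cv.grid_y)):
                    rows.append((cell, "cohort", k, float(gx), float(gy),
                                 lo, hi))
        return pd.DataFrame(
            rows, columns=["cell_id", "kind", "idx", "knot_x", "coefficient",
                           "x_min", "x_max"],
        )


def _call_cutoffs(fit: TwoPhaseFit, bg, threshold: float,
                  y_grid_max: int = 60) -> np.ndarray:
    """Smallest count called active, per (gene, cell).

    The posterior phase probability crosses the call threshold at some
    count; below it active observations are censored from the residual
    set. The cutoff is found on a 0..y_grid_max grid (the ZIP background
    is numerically dead well before that for the rates seen in practice);
    entries with no crossing in the grid get +inf (no correction applied).
    """
    from scipy.special import gammaln as _gammaln
    from .twophase import _active_logdensity

    ys = np.arange(0, y_grid_max + 1)
    m = len(ys)
    est = np.flatnonzero(fit.estimable & np.isfinite(fit.mu))
    G = len(fit.gene_ids)
    n = len(fit.cell_ids)
    cutoff = np.full((G, n), np.inf)
    with np.errstate(divide="ignore"):
        logpois = (ys[None, :] * np.log(bg.lam)[:, None] - bg.lam[:, None]
                   - _gammaln(ys + 1.0)[None, :])
        lfb = np.log1p(-bg.p0)[:, None] + logpois
        lfb[:, 0] = np.log(bg.p0 + (1 - bg.p0) * np.exp(-bg.lam))
    # lfb: (n, m); active density per gene over the grid: (len(est), m)
    Yg = np.broadcast_to(ys, (len(est), m))
    lfa = _active_logdensity(Yg, fit.mu[est], fit.sigma2[est],
                             np.zeros((len(est), m)))
    logit_thr = np.log(threshold) - np.log1p(-threshold)
    pi_c = np.clip(fit.pi_active[est], 1e-12, 1 - 1e-12)
    base = np.log(pi_c) - np.log1p(-pi_c)
    for lo in range(0, len(est), 256):
        hi = min(lo + 256, len(est))
        # (block, n, m) posterior log-odds
        lo_odds = (base[lo:hi, None, None] + lfa[lo:hi, None, :]
                   - lfb[None, :, :])
        above = lo_odds > logit_thr
        first = np.where(above.any(axis=2), above.argmax(axis=2), -1)
        blk = cutoff[est[lo:hi]]
        blk[first >= 0] = ys[first[first >= 0]]
        cutoff[est[lo:hi]] = blk
    return cutoff


def debias_residuals(res: Residuals, cm: CountMatrix, fit: TwoPhaseFit,
                     bg, curves: dict[str, CellCurve],
                     threshold: float = 0.99) -> Residuals:
    """Correct residuals for the censoring induced by the active call.

    Conditioning on the active-phase call censors the lower tail of
    low-rate observations: a gene near the call cutoff contributes only
    its larger counts, biasing its residuals upward. The effect is
    material in cells with small S, where the same gene sits closer to
    the cutoff. The bias is removed as the truncated-normal mean shift
    sqrt(v) * phi(a)/(1-Phi(a)) around the current curve, with the
    within-cell residual variance v estimated robustly. (The Poisson
    log-concavity term E[log Y] - log E[Y] ~ -1/(2Y) is deliberately left
    in: it is a count-level distortion that belongs in the factor.)
    One pass, given curves from an initial fit.
    """
    from scipy.stats import norm

    cutoff = _call_cutoffs(fit, bg, threshold)
    eps = res.eps.copy()
    act = res.active
    for i, cell in enumerate(res.cell_ids):
        mask = act[:, i]
        if not mask.any():
            continue
        x = res.abscissa[mask]
        f = curves[cell](x)
        r = eps[mask, i] - f
        v = (1.4826 * np.median(np.abs(r - np.median(r)))) ** 2
        if v <= 0:
            continue
        tau = np.where(np.isfinite(cutoff[mask, i]),
                       np.log(np.maximum(cutoff[mask, i], 0.5)),
                       -np.inf) - res.abscissa[mask]
        alpha = (tau - f) / np.sqrt(v)
        lam = np.zeros_like(alpha)
        rel = alpha > -6.0
        a = np.clip(alpha[rel], -6.0, 4.0)
        lam[rel] = norm.pdf(a) / np.maximum(norm.sf(a), 1e-12)
        eps[mask, i] = eps[mask, i] - np.sqrt(v) * lam
    return Residuals(eps=eps, abscissa=res.abscissa, active=res.active,
                     gene_ids=res.gene_ids, cell_ids=res.cell_ids)


def curves_from_frame(frame: pd.DataFrame) -> dict[str, CellCurve]:
    """Rebuild per-cell curves from their serialized knot/coefficient table."""
    curves: dict[str, CellCurve] = {}
    for cell, sub in frame.groupby("cell_id", sort=False):
        kind = sub["kind"].iloc[0]
        x_range = (float(sub["x_min"].iloc[0]), float(sub["x_max"].iloc[0]))
        sub = sub.sort_values("idx")
        if kind == "constant":
            curves[cell] = CellCurve("constant",
                                     value=float(sub["coefficient"].iloc[0]),
                                     x_range=x_range)
        elif kind == "spline":
            curves[cell] = CellCurve(
                "spline",
                knots=sub["knot_x"].to_numpy(float),
                coef=sub["coefficient"].to_numpy(float),
                x_range=x_range,
            )
        else:
            curves[cell] = CellCurve(
                "cohort",
                grid_x=sub["knot_x"].to_numpy(float),
                grid_y=sub["coefficient"].to_numpy(float),
                x_range=x_range,
            )
    return curves


def eval_log_s(curves: dict[str, CellCurve], cm: CountMatrix,
               active: np.ndarray, mode: str = "at_count",
               fit: TwoPhaseFit | None = None,
               flagged_cells: np.ndarray | None = None) -> NormFactorMatrix:
    """Evaluate log S_gi from the fitted curves (unscaled).

    ``mode="at_count"`` evaluates f_i at the observed log count; ``"at_mu"``
    evaluates at the gene's fitted mean log concentration. Entries outside
    the active set stay masked.
    """
    if mode not in ("at_count", "at_mu"):
        raise ValueError("mode must be 'at_count' or 'at_mu'")
    if mode == "at_mu" and fit is None:
        raise ValueError("mode 'at_mu' requires the two-phase fit")
    G, n = cm.counts.shape
    mask = active & (cm.counts >= 1)
    log_s = np.full((G, n), np.nan)
    for i, cell in enumerate(cm.cell_ids):
        m = mask[:, i]
        if not m.any():
            continue
        if mode == "at_count":
            xs = np.log(cm.counts[m, i])
        else:
            xs = fit.mu[m]
        log_s[m, i] = curves[cell](xs)
    if flagged_cells is None:
        flagged_cells = np.zeros(n, dtype=bool)
    return NormFactorMatrix(log_s=log_s, gene_ids=list(cm.gene_ids),
                            cell_ids=list(cm.cell_ids), curves=dict(curves),
                            flagged_cells=flagged_cells)


def rescale_to_reference(nf: NormFactorMatrix,
                         ls: LibrarySizes) -> NormFactorMatrix:
    """Shift log S so mean S over unmasked genes is 1 in the reference cell.

    Idempotent; if the reference cell has no unmasked entries, the unmasked
    cell with library size nearest the median is used instead (with a
    warning).
    """
    ref = ls.reference_cell
    j = nf.cell_ids.index(ref)
    col = nf.log_s[:, j]
    if not np.isfinite(col).any():
        ok = np.flatnonzero(np.isfinite(nf.log_s).any(axis=0))
        if len(ok) == 0:
            raise ValidationError("all cells fully masked; cannot rescale")
        L = np.asarray(ls.L)
        j = int(ok[np.argmin(np.abs(L[ok] - ls.L0))])
        ref = nf.cell_ids[j]
        logger.warning("reference cell fully masked; using %s instead", ref)
        col = nf.log_s[:, j]
    shift = float(np.log(np.nanmean(np.exp(col))))
    curves = {c: cv.shifted(shift) for c, cv in nf.curves.items()}
    return NormFactorMatrix(log_s=nf.log_s - shift, gene_ids=nf.gene_ids,
                            cell_ids=nf.cell_ids, curves=curves,
                            flagged_cells=nf.flagged_cells,
                            reference_cell=ref)


@dataclass
class AppliedNorm:
    """Result of applying normalization factors to a count matrix."""

    values: np.ndarray
    mode: str
    filter_genes: Optional[list[str]] = None


def apply_normalization(cm: CountMatrix, nf: NormFactorMatrix,
                        mode: str = "offset",
                        min_cells_active: int = 3) -> AppliedNorm:
    """Emit the factors as a model offset or divide them out of the counts.

    Offset mode returns the masked log_s matrix for use as an offset in
    count models (counts themselves untouched). Adjusted mode returns
    Y / S on unmasked entries and raw Y on masked ones, together with the
    recommended gene filter: genes active (unmasked) in at least
    ``min_cells_active`` cells.
    """
    if cm.counts.shape != nf.log_s.shape:
        raise ValidationError("counts and factors have different shapes")
    if mode == "offset":
        return AppliedNorm(values=nf.log_s.copy(), mode="offset")
    if mode != "adjusted":
        raise ValueError("mode must be 'offset' or 'adjusted'")
    unmasked = np.isfinite(nf.log_s)
    vals = cm.counts.astype(float)
    vals[unmasked] = vals[unmasked] / np.exp(nf.log_s[unmasked])
    n_active = unmasked.sum(axis=1)
    keep = [g for g, k in zip(cm.gene_ids, n_active) if k >= min_cells_active]
    return AppliedNorm(values=vals, mode="adjusted", filter_genes=keep)
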