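"""End-to-end convenience wrapper: background -> EM -> curves -> log S."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import BackgroundParams, estimate_background
from .io import CountMatrix, LibrarySizes, library_sizes
from .normalization import (
    NormFactorMatrix,
    apply_normalization,
    compute_residuals,
    debias_residuals,
    eval_log_s,
    fit_curves,
    rescale_to_reference,
)
from .twophase import TwoPhaseFit, em_fit, phase_call


@dataclass
class NormResult:
    """Everything produced by one normalization run."""

    cm: CountMatrix
    ls: LibrarySizes
    bg: BackgroundParams
    fit: TwoPhaseFit
    nf: NormFactorMatrix

    def adjusted(self, min_cells_active: int = 3):
        return apply_normalization(self.cm, self.nf, "adjusted",
                                   min_cells_active)

    def offset(self):
        return apply_normalization(self.cm, self.nf, "offset")


def normalize_counts(
    cm: CountMatrix,
    y_max: int = 10,
    robust_iters: int = 20,
    max_iter: int = 100,
    tol: float = 1e-4,
    threshold: float = 0.99,
    df: int = 5,
    min_curve_points: int = 50,
    eval_mode: str = "at_count",
    seed: int | None = None,
    second_pass: bool = False,
    debias: bool = True,
) -> NormResult:
    """Run the full two-phase normalization on a count matrix.

    ``debias`` applies the one-pass residual correction for Poisson
    log-concavity and active-call truncation before the final curve fit.
    ``second_pass`` refits the mixture once with the estimated offsets
    before re-deriving the factors; off by default (the standard procedure
    is a single pass).
    """
    ls = library_sizes(cm)
    bg = estimate_background(cm, y_max=y_max, robust_iters=robust_iters)
    fit = em_fit(cm, bg, max_iter=max_iter, tol=tol, seed=seed)
    nf = _factors_from_fit(cm, fit, bg, ls, threshold, df, min_curve_points,
                           eval_mode, debias)
    if second_pass:
        fit = em_fit(cm, bg, log_s=nf.log_s, max_iter=max_iter, tol=tol,
                     seed=seed)
        nf = _factors_from_fit(cm, fit, bg, ls, threshold, df,
                               min_curve_points, eval_mode, debias)
    return NormResult(cm=cm, ls=ls, bg=bg, fit=fit, nf=nf)


def _factors_from_fit(cm, fit, bg, ls, threshold, df, min_curve_points,
                      eval_mode, debias) -> NormFactorMatrix:
    res = compute_residuals(cm, fit, threshold)
    curves, flagged = fit_curves(res, df=df,
                                 min_curve_points=min_curve_points)
    if debias:
        res = debias_residuals(res, cm, fit, bg, curves, threshold)
        curves, flagged = fit_curves(res, df=df,
                                     min_curve_points=min_curve_points)
    active = phase_call(fit, threshold)
    nf = eval_log_s(curves, cm, active, mode=eval_mode, fit=fit,
                    flagged_cells=flagged)
    return rescale_to_reference(nf, ls)
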