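"""Evaluation metrics for normalization quality, as tidy tables.

These reproduce the standard assessments for count-depth bias: per-gene
slope/correlation of counts against library size, phase-split MA data,
conditional (detected-only) SD ratios between normalized and raw data, and
stratified two-group log fold changes under unbalanced sequencing depth.
All functions are pure: the same inputs give bit-identical tables.

Log conventions: the package works in natural logs; the count-depth filter
and axes default to log2 (the usual presentation for expression data) with
the base exposed as an option. Fold changes are natural-log by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import CountMatrix, LibrarySizes, ValidationError
from .twophase import TwoPhaseFit, phase_call


def _as_values(mat) -> np.ndarray:
    if isinstance(mat, CountMatrix):
        return mat.counts.astype(float)
    return np.asarray(mat, dtype=float)


# ---------------------------------------------------------------------------
# count-depth relationship
# ---------------------------------------------------------------------------

def count_depth(
    mat,
    ls: LibrarySizes,
    min_mean_log: float = 4.0,
    base: float = 2.0,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Per-gene count-depth slope and correlation with library size.

    For genes whose mean log(Y + pseudo) exceeds ``min_mean_log`` (reliably
    detected genes), the slope of log(Y + pseudo) regressed on log L and the
    Pearson correlation between the gene's values and L are reported. A
    constantly-expressed gene scaling linearly with depth has correlation
    ~1 and slope 1; after good normalization both shrink toward 0.
    Constant genes get a missing correlation.
    """
    V = _as_values(mat)
    if V.shape[1] < 3:
        raise ValidationError("count_depth needs at least 3 cells")
    L = np.asarray(ls.L, dtype=float)
    logV = np.log(V + pseudo) / math.log(base)
    logL = np.log(L) / math.log(base)
    mean_log = logV.mean(axis=1)
    included = mean_log > min_mean_log

    x = logL - logL.mean()
    sxx = float(x @ x)
    if sxx > 0:
        slope = (logV - logV.mean(axis=1, keepdims=True)) @ x / sxx
    else:  # all cells at identical depth: the slope is undefined
        slope = np.full(V.shape[0], np.nan)

    Vc = V - V.mean(axis=1, keepdims=True)
    Lc = L - L.mean()
    denom = np.sqrt((Vc**2).sum(axis=1) * float(Lc @ Lc))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, Vc @ Lc / np.where(denom > 0, denom, 1.0),
                        np.nan)

    gene_ids = (mat.gene_ids if isinstance(mat, CountMatrix)
                else [f"g{k}" for k in range(V.shape[0])])
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_log": mean_log,
            "slope": slope,
            "correlation": corr,
            "included": included,
        }
    )


# ---------------------------------------------------------------------------
# MA data
# ---------------------------------------------------------------------------

def ma_data(cm: CountMatrix, fit: TwoPhaseFit, cell: str,
            threshold: float = 0.99) -> pd.DataFrame:
    """Phase-split MA table for one cell.

    x = mu_g (mean log expression), y = log Y_gi - mu_g (the residual whose
    expectation is log S_gi), phase = active/background by the posterior
    threshold. Genes with Y = 0 in the cell or missing mu are excluded.
    """
    i = fit.cell_ids.index(cell)
    y_col = cm.counts[:, i]
    keep = (y_col >= 1) & np.isfinite(fit.mu)
    calls = phase_call(fit, threshold)[:, i]
    return pd.DataFrame(
        {
            "gene_id": np.asarray(cm.gene_ids)[keep],
            "mean_log_expression": fit.mu[keep],
            "log_ratio": np.log(y_col[keep]) - fit.mu[keep],
            "phase": np.where(calls[keep], "active", "background"),
        }
    )


# ---------------------------------------------------------------------------
# stratified summaries
# ---------------------------------------------------------------------------

@dataclass
class StratifiedSummary:
    """Per-gene statistics binned by mean expression."""

    table: pd.DataFrame
    bin_edges: np.ndarray

    def median_by_stratum(self, column: str) -> pd.Series:
        return self.table.groupby("stratum", observed=True)[column].median()


def _stratify(values: np.ndarray, n_strata: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile bins of mean expression; every gene lands in exactly one."""
    edges = np.quantile(values, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0,
                  len(edges) - 2)
    return idx, edges


def conditional_sd_ratio(
    raw,
    normalized,
    fit: TwoPhaseFit,
    n_strata: int = 4,
    threshold: float = 0.99,
    min_active: int = 3,
) -> StratifiedSummary:
    """SD of detected (active-phase) log expression: normalized vs raw.

    For each gene with at least ``min_active`` active nonzero cells, the SD
    of log values over those cells is computed in the raw and normalized
    matrices, and their ratio reported, stratified by mean active log
    expression. Ratios below 1 mean technical variance was removed; a ratio
    above 1 flags over-normalization (typical for low-expression genes
    under whole-library size factors).
    """
    R = _as_values(raw)
    N = _as_values(normalized)
    if R.shape != N.shape:
        raise ValidationError("raw and normalized shapes differ")
    act = phase_call(fit, threshold) & (R >= 1) & (N > 0)
    n_act = act.sum(axis=1)
    keep = n_act >= min_active

    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.where(act, np.log(np.maximum(R, 1e-300)), np.nan)
        logN = np.where(act, np.log(np.maximum(N, 1e-300)), np.nan)
    sd_raw = np.nanstd(logR[keep], axis=1, ddof=1)
    sd_norm = np.nanstd(logN[keep], axis=1, ddof=1)
    mean_expr = np.nanmean(logR[keep], axis=1)
    ok = sd_raw > 0
    strata, edges = _stratify(mean_expr[ok], n_strata)
    tab = pd.DataFrame(
        {
            "gene_id": np.asarray(fit.gene_ids)[keep][ok],
            "mean_active_log": mean_expr[ok],
            "sd_raw": sd_raw[ok],
            "sd_normalized": sd_norm[ok],
            "ratio": sd_norm[ok] / sd_raw[ok],
            "stratum": strata,
        }
    )
    return StratifiedSummary(tab, edges)


def group_lfc(
    mat,
    groups: np.ndarray,
    fit: TwoPhaseFit,
    n_strata: int = 4,
    threshold: float = 0.99,
    pseudo: float = 1.0,
) -> StratifiedSummary:
    """Two-group log fold changes, stratified by mean expression.

    Reports, per gene, the difference of group means of log(value + pseudo)
    over all cells (``lfc_all``) and over active-phase cells only
    (``lfc_active``; missing when a group has no active cell). Exactly two
    groups with at least 3 cells each are required; for more groups run
    pairwise. Natural-log scale.
    """
    V = _as_values(mat)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValidationError(
            f"group_lfc needs exactly 2 groups, got {len(labels)}; "
            "run pairwise comparisons for more"
        )
    a, b = (groups == labels[0]), (groups == labels[1])
    if a.sum() < 3 or b.sum() < 3:
        raise ValidationError("each group needs at least 3 cells")

    logV = np.log(V + pseudo)
    lfc_all = logV[:, a].mean(axis=1) - logV[:, b].mean(axis=1)

    act = phase_call(fit, threshold)
    wa = act[:, a].astype(float)
    wb = act[:, b].astype(float)
    with np.errstate(invalid="ignore"):
        mean_a = (logV[:, a] * wa).sum(axis=1) / wa.sum(axis=1)
        mean_b = (logV[:, b] * wb).sum(axis=1) / wb.sum(axis=1)
    lfc_active = mean_a - mean_b

    mean_expr = logV.mean(axis=1)
    strata, edges = _stratify(mean_expr, n_strata)
    tab = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "mean_log": mean_expr,
            "lfc_all": lfc_all,
            "lfc_active": lfc_active,
            "stratum": strata,
        }
    )
    return StratifiedSummary(tab, edges)


# ---------------------------------------------------------------------------
# clustering concordance, baseline normalizer, stability utility
# ---------------------------------------------------------------------------

def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same cells."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("partitions have different lengths")
    if a.size < 2:
        raise ValidationError("partitions need at least 2 items")
    return float(adjusted_rand_score(a, b))


def cpm_normalize(cm: CountMatrix, target: float | None = None) -> np.ndarray:
    """Whole-library size-factor baseline: Y_gi scaled by target / L_i.

    ``target`` defaults to the median library size, so values stay on the
    counts scale. This is the naive cell-wise normalization the two-phase
    method improves on; kept as a contrast for the diagnostics.
    """
    L = cm.counts.sum(axis=0).astype(float)
    if target is None:
        target = float(np.median(L))
    return cm.counts * (target / L)[None, :]


def lfc_stability(
    cm: CountMatrix,
    groups: np.ndarray,
    normalizer,
    fit_factory,
    k: int = 5,
    strategy: str = "top_depth",
    seed: int = 0,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Refit-after-dropping-k-cells stability of group log fold changes.

    ``normalizer(cm) -> values`` runs a full normalization pipeline;
    ``fit_factory(cm) -> TwoPhaseFit`` supplies phase calls for the reduced
    data. ``strategy`` picks the removed cells: the k highest-depth cells
    or k at random. Returns per-gene LFC before/after and the change; a
    robust normalization should leave LFCs nearly unchanged.
    """
    if strategy not in ("top_depth", "random"):
        raise ValueError("strategy must be 'top_depth' or 'random'")
    groups = np.asarray(groups)
    L = cm.counts.sum(axis=0)
    if strategy == "top_depth":
        drop = set(np.argsort(L)[-k:].tolist())
    else:
        rng = np.random.default_rng(seed)
        drop = set(rng.choice(cm.n_cells, size=k, replace=False).tolist())
    keep_idx = [i for i in range(cm.n_cells) if i not in drop]

    full = group_lfc(normalizer(cm), groups, fit_factory(cm), pseudo=pseudo)
    sub_cm = cm.subset_cells(keep_idx)
    sub = group_lfc(normalizer(sub_cm), groups[keep_idx],
                    fit_factory(sub_cm), pseudo=pseudo)
    out = full.table[["gene_id", "lfc_all"]].merge(
        sub.table[["gene_id", "lfc_all"]], on="gene_id",
        suffixes=("_full", "_reduced"),
    )
    out["lfc_change"] = out["lfc_all_reduced"] - out["lfc_all_full"]
    return out
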