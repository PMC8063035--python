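"""Data model and file I/O for count matrices and fit results.

The in-memory convention throughout the package is genes x cells: rows are
genes, columns are cells, matching the Y_gi indexing of the two-phase model.
Two on-disk formats are supported for count matrices:

* dense TSV — header row of cell ids, first column of gene ids, integer body;
* Matrix Market coordinate triplets (1-based) with ``genes.txt`` /
  ``cells.txt`` sidecar files, one identifier per line.

All logarithms inside the package are natural logs; diagnostics that present
results in log2 convert at the boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("sc2pnorm")

#: sentinel used for masked (background-phase) normalization factors on disk
NA_SENTINEL = "NA"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed as a count matrix."""


@dataclass
class CountMatrix:
    """Genes x cells matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        2-D integer array, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique row / column identifiers.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be 2-dimensional (genes x cells)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating):
                if not np.all(np.isfinite(self.counts)) or np.any(
                    self.counts != np.floor(self.counts)
                ):
                    raise ValidationError("counts must be integers")
                self.counts = self.counts.astype(np.int64)
            else:
                raise ValidationError("counts must be an integer array")
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError("gene_ids length does not match matrix rows")
        if len(self.cell_ids) != self.counts.shape[1]:
            raise ValidationError("cell_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)

    def subset_cells(self, idx: Iterable[int]) -> "CountMatrix":
        idx = list(idx)
        return CountMatrix(
            self.counts[:, idx],
            list(self.gene_ids),
            [self.cell_ids[i] for i in idx],
        )


@dataclass
class LibrarySizes:
    """Per-cell library sizes plus the median-depth reference cell.

    ``reference_cell`` is the cell whose library size is the median; for an
    even cell count the lower of the two middle values is used, so the
    reference is always an actual cell (the identifiability constraint pins
    the mean normalization factor of that cell to 1). Ties break to the first
    cell in column order.
    """

    L: np.ndarray
    cell_ids: list[str]
    reference_cell: str
    L0: int

    @property
    def reference_index(self) -> int:
        return self.cell_ids.index(self.reference_cell)


@dataclass
class CellMetadata:
    """Cell annotations (group labels etc.) aligned to a CountMatrix."""

    table: pd.DataFrame  # indexed by cell_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate cell ids in metadata")

    @classmethod
    def read(cls, path: str) -> "CellMetadata":
        tab = pd.read_csv(path, sep="\t", dtype={0: str})
        tab = tab.set_index(tab.columns[0])
        return cls(tab)

    def groups_for(self, cell_ids: list[str], column: str = "group") -> np.ndarray:
        missing = set(cell_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"metadata missing cells: {sorted(missing)[:5]}")
        return self.table.loc[cell_ids, column].to_numpy()


def library_sizes(cm: CountMatrix) -> LibrarySizes:
    """Column sums L_i and the median-depth reference cell.

    Raises if every cell is empty (no non-empty cells to normalize against).
    """
    L = cm.counts.sum(axis=0)
    if not np.any(L > 0):
        raise ValidationError("no non-empty cells")
    order = np.argsort(L, kind="stable")
    ref_idx = int(order[(len(L) - 1) // 2])  # lower middle for even counts
    # ties: first cell in column order with the median value
    ref_val = L[ref_idx]
    ref_idx = int(np.flatnonzero(L == ref_val)[0])
    return LibrarySizes(
        L=L.astype(np.int64),
        cell_ids=list(cm.cell_ids),
        reference_cell=cm.cell_ids[ref_idx],
        L0=int(ref_val),
    )


# ---------------------------------------------------------------------------
# count matrix readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str, format: str = "dense-tsv") -> CountMatrix:
    """Read a genes x cells count matrix.

    ``format`` is ``"dense-tsv"`` (header = cell ids, first column = gene
    ids) or ``"matrix-market"`` (coordinate file with ``genes.txt`` and
    ``cells.txt`` sidecars in the same directory).
    """
    if format in ("dense-tsv", "tsv", "dense"):
        return _read_dense(path)
    if format in ("matrix-market", "mtx", "mm"):
        return _read_mtx(path)
    raise ValueError(f"unknown count-matrix format: {format!r}")


def _read_dense(path: str) -> CountMatrix:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: line {i + 2}: entry {raw!r} is not a "
                    "non-negative integer"
                ) from None
            if str(v) != str(raw).strip() and float(raw) != v:
                raise ParseError(
                    f"{path}: line {i + 2}: entry {raw!r} is not an integer"
                )
            values[i, j] = v
    return CountMatrix(values, list(df.index), list(df.columns))


def _read_mtx(path: str) -> CountMatrix:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    d = os.path.dirname(path)
    genes_path = os.path.join(d, "genes.txt")
    cells_path = os.path.join(d, "cells.txt")
    for p in (genes_path, cells_path):
        if not os.path.exists(p):
            raise FileNotFoundError(f"sidecar file not found: {p}")
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    if np.any(dense != np.floor(dense)):
        raise ParseError(f"{path}: non-integer entries in matrix market file")
    genes = _read_id_file(genes_path)
    cells = _read_id_file(cells_path)
    return CountMatrix(dense.astype(np.int64), genes, cells)


def _read_id_file(path: str) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return ids


def write_counts(cm: CountMatrix, path: str, format: str = "dense-tsv") -> None:
    """Write a count matrix in either supported format (inverse of read_counts)."""
    if format in ("dense-tsv", "tsv", "dense"):
        cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format in ("matrix-market", "mtx", "mm"):
        d = os.path.dirname(path) or "."
        os.makedirs(d, exist_ok=True)
        sp = scipy.sparse.coo_matrix(cm.counts)
        scipy.io.mmwrite(path, sp, field="integer")
        _write_id_file(os.path.join(d, "genes.txt"), cm.gene_ids)
        _write_id_file(os.path.join(d, "cells.txt"), cm.cell_ids)
    else:
        raise ValueError(f"unknown count-matrix format: {format!r}")


def _write_id_file(path: str, ids: list[str]) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


# ---------------------------------------------------------------------------
# float matrices with NA masking (Z posterior, log S)
# ---------------------------------------------------------------------------

def write_float_matrix(
    values: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str],
    path: str,
) -> None:
    """Write a float matrix as TSV; NaN entries become the literal "NA".

    Floats are written with 17 significant digits so the round trip is exact
    to 1e-12 relative (in fact bit-exact for finite doubles).
    """
    df = pd.DataFrame(values, index=gene_ids, columns=cell_ids)
    df.to_csv(path, sep="\t", index_label="gene_id", na_rep=NA_SENTINEL,
              float_format="%.17g")


def read_float_matrix(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_SENTINEL],
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(
        df.columns.astype(str)
    )


# ---------------------------------------------------------------------------
# result bundles
# ---------------------------------------------------------------------------

def write_results(fit, nf, outdir: str, cm: Optional[CountMatrix] = None,
                  bg=None, normalized: Optional[np.ndarray] = None) -> None:
    """Serialize a fitted model to ``outdir``.

    Writes the per-gene parameter table, the per-cell background table
    (when ``bg`` is given), the posterior phase matrix, the log S matrix
    (masked entries as "NA"), spline knots/coefficients, and optionally the
    adjusted count matrix. Everything round-trips through the corresponding
    readers.
    """
    if len(fit.gene_ids) == 0:
        raise ValidationError("empty gene set")
    if list(fit.gene_ids) != list(nf.gene_ids) or list(fit.cell_ids) != list(
        nf.cell_ids
    ):
        raise ValidationError("fit and normalization factors must share ids")
    os.makedirs(outdir, exist_ok=True)

    gene_tab = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "mu_hat": fit.mu,
            "sigma2_hat": fit.sigma2,
            "pi_hat": fit.pi_active,
            "n_active_cells": fit.n_active_cells,
            "estimable": fit.estimable.astype(int),
        }
    )
    gene_tab.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False,
                    na_rep=NA_SENTINEL, float_format="%.17g")

    if bg is not None:
        bg.to_frame().to_csv(os.path.join(outdir, "cells.tsv"), sep="\t",
                             index=False, na_rep=NA_SENTINEL,
                             float_format="%.17g")

    write_float_matrix(fit.Z_post, fit.gene_ids, fit.cell_ids,
                       os.path.join(outdir, "z_posterior.tsv"))
    write_float_matrix(nf.log_s, nf.gene_ids, nf.cell_ids,
                       os.path.join(outdir, "log_s.tsv"))
    nf.curves_frame().to_csv(os.path.join(outdir, "curves.tsv"), sep="\t",
                             index=False, float_format="%.17g")
    if cm is not None:
        write_counts(cm, os.path.join(outdir, "counts.tsv"))
    if normalized is not None:
        write_float_matrix(normalized, nf.gene_ids, nf.cell_ids,
                           os.path.join(outdir, "normalized.tsv"))


def read_results(outdir: str):
    """Load a result bundle written by :func:`write_results`.

    Returns (fit, nf, cm, bg); cm and bg are None when not on disk. The
    loaded fit carries no EM trace (it was not serialized).
    """
    from .background import BackgroundParams
    from .normalization import NormFactorMatrix, curves_from_frame
    from .twophase import TwoPhaseFit

    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t",
                        na_values=[NA_SENTINEL], dtype={"gene_id": str},
                        float_precision="round_trip")
    Z, gid, cid = read_float_matrix(os.path.join(outdir, "z_posterior.tsv"))
    log_s, _, _ = read_float_matrix(os.path.join(outdir, "log_s.tsv"))
    fit = TwoPhaseFit(
        gene_ids=gid,
        cell_ids=cid,
        mu=genes["mu_hat"].to_numpy(float),
        sigma2=genes["sigma2_hat"].to_numpy(float),
        pi_active=genes["pi_hat"].to_numpy(float),
        Z_post=Z,
        estimable=genes["estimable"].to_numpy(bool),
        loglik_trace=np.array([]),
        n_iter=0,
        converged=True,
    )
    curves_path = os.path.join(outdir, "curves.tsv")
    curves = {}
    if os.path.exists(curves_path):
        curves = curves_from_frame(
            pd.read_csv(curves_path, sep="\t", dtype={"cell_id": str})
        )
    nf = NormFactorMatrix(log_s=log_s, gene_ids=gid, cell_ids=cid,
                          curves=curves,
                          flagged_cells=np.zeros(len(cid), dtype=bool))
    cm = None
    counts_path = os.path.join(outdir, "counts.tsv")
    if os.path.exists(counts_path):
        cm = read_counts(counts_path, "dense-tsv")
    bg = None
    cells_path = os.path.join(outdir, "cells.tsv")
    if os.path.exists(cells_path):
        tab = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str},
                          float_precision="round_trip")
        bg = BackgroundParams(
            cell_ids=list(tab["cell_id"]),
            p0=tab["p0_hat"].to_numpy(float),
            lam=tab["lam_hat"].to_numpy(float),
            n_bg_hat=tab["n_bg_hat"].to_numpy(float),
            flagged=tab["flagged"].to_numpy(bool),
            fit_range=(1, 10),
        )
    return fit, nf, cm, bg
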