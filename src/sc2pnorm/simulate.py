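"""Generative simulator for two-phase scRNA-seq counts with known truth.

Counts are drawn from the same model the estimators assume: per gene a mean
log concentration mu_g, log-scale dispersion sigma_g and activation
probability pi_g; per cell a ZIP background (p0_i, lam_i); and a technical
distortion S_gi. Three bias models are provided:

* ``none``     — S = 1 everywhere;
* ``cellwise`` — S_gi = s_i, a pure per-cell scale (the assumption behind
  CPM-style size factors);
* ``smooth``   — log S_gi = t_i * q(mu_g) with a per-cell log-depth factor
  t_i and a fixed positive quadratic q, so deeper cells get uniformly
  larger factors but the count-depth slope varies with expression level,
  the signature the normalization is designed to remove.

Reproducibility: one ``numpy.random.default_rng(seed)`` stream (PCG64) with
a frozen draw order — gene mu, gene sigma, gene pi; cell p0, cell lam; the
bias draws; then the Z, active-phase and background matrices, each as a
single full-matrix draw. Identical (config, seed) pairs give bit-identical
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .io import CellMetadata, CountMatrix

import pandas as pd


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the generative model; ranges are sampled uniformly."""

    n_genes: int
    n_cells: int
    mu_range: tuple[float, float] = (math.log(20.0), math.log(200.0))
    sigma_range: tuple[float, float] = (0.4, 0.4)
    pi_range: tuple[float, float] = (0.6, 0.6)
    bg_p0_range: tuple[float, float] = (0.3, 0.3)
    bg_lam_range: tuple[float, float] = (1.0, 1.0)
    bias_model: str = "none"  # none | cellwise | smooth
    bias_params: Optional[dict] = None
    # (n_cells_in_group_A, S multiplier for A, S multiplier for B)
    depth_groups: Optional[tuple[int, float, float]] = None
    # last k genes get pi = 0: pure background, hence zero depth dependence
    n_background_only: int = 0
    # first k genes get mu + de_log_fc in group A (requires depth_groups or
    # a two-group layout via depth_groups with multipliers 1, 1)
    n_de_genes: int = 0
    de_log_fc: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise SimConfigError("n_genes and n_cells must be >= 1")
        for name in ("mu_range", "sigma_range", "pi_range", "bg_p0_range",
                     "bg_lam_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SimConfigError(f"{name} is inverted")
        if not (0 <= self.pi_range[0] and self.pi_range[1] <= 1):
            raise SimConfigError("pi_range must lie in [0, 1]")
        if not (0 <= self.bg_p0_range[0] and self.bg_p0_range[1] <= 1):
            raise SimConfigError("bg_p0_range must lie in [0, 1]")
        if self.bg_lam_range[0] <= 0:
            raise SimConfigError("bg_lam_range must be positive")
        if self.bias_model not in ("none", "cellwise", "smooth"):
            raise SimConfigError(f"unknown bias_model {self.bias_model!r}")
        if self.n_background_only > self.n_genes:
            raise SimConfigError("n_background_only exceeds n_genes")
        if self.n_de_genes and self.depth_groups is None:
            raise SimConfigError("DE genes need a two-group layout "
                                 "(set depth_groups)")
        if self.depth_groups is not None:
            if not (0 < self.depth_groups[0] < self.n_cells):
                raise SimConfigError("group A size out of range")


@dataclass
class SimTruth:
    """A simulated CountMatrix together with every generative quantity."""

    cm: CountMatrix
    mu: np.ndarray
    sigma2: np.ndarray
    pi: np.ndarray
    p0: np.ndarray
    lam: np.ndarray
    Z: np.ndarray
    log_s: np.ndarray
    groups: Optional[np.ndarray]
    de_genes: list[str]
    background_only_genes: list[str]
    config: SimConfig

    def metadata(self) -> Optional[CellMetadata]:
        if self.groups is None:
            return None
        tab = pd.DataFrame({"group": self.groups},
                           index=pd.Index(self.cm.cell_ids, name="cell_id"))
        return CellMetadata(tab)


def _uniform(rng: np.random.Generator, rng_pair, size: int) -> np.ndarray:
    lo, hi = rng_pair
    if lo == hi:
        return np.full(size, float(lo))
    return rng.uniform(lo, hi, size)


def simulate(cfg: SimConfig) -> SimTruth:
    """Draw a count matrix and its ground truth from the two-phase model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G, n = cfg.n_genes, cfg.n_cells

    # 1) gene-level parameters
    mu = _uniform(rng, cfg.mu_range, G)
    sigma = _uniform(rng, cfg.sigma_range, G)
    pi = _uniform(rng, cfg.pi_range, G)
    if cfg.n_background_only:
        pi[G - cfg.n_background_only:] = 0.0

    # 2) cell-level background parameters
    p0 = _uniform(rng, cfg.bg_p0_range, n)
    lam = _uniform(rng, cfg.bg_lam_range, n)

    # 3) technical bias
    params = dict(cfg.bias_params or {})
    if cfg.bias_model == "none":
        log_s = np.zeros((G, n))
    elif cfg.bias_model == "cellwise":
        if "s" in params:
            s = np.asarray(params["s"], dtype=float)
            if len(s) != n:
                raise SimConfigError("bias_params['s'] has wrong length")
        else:
            lo, hi = params.get("s_range", (0.5, 2.0))
            s = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
        log_s = np.broadcast_to(np.log(s)[None, :], (G, n)).copy()
    else:  # smooth
        t = _uniform(rng, params.get("depth_range", (-0.7, 0.7)), n)
        slope = params.get("slope", 0.25)
        curv = params.get("curv", 0.08)
        m0 = 0.5 * (cfg.mu_range[0] + cfg.mu_range[1])
        q = 1.0 + slope * (mu - m0) + curv * (mu - m0) ** 2
        if np.any(q <= 0):
            raise SimConfigError("smooth bias polynomial not positive over "
                                 "the mu range")
        log_s = np.outer(q, t)

    groups = None
    if cfg.depth_groups is not None:
        n_a, m_a, m_b = cfg.depth_groups
        groups = np.array(["A"] * n_a + ["B"] * (n - n_a))
        log_s = log_s + np.where(groups == "A", math.log(m_a),
                                 math.log(m_b))[None, :]

    # genes with pi = 0 never enter the active phase; their "bias" is
    # irrelevant and recorded as 0 so truth comparisons stay meaningful
    if cfg.n_background_only:
        log_s[G - cfg.n_background_only:, :] = 0.0

    # 4) latent phases, 5) active-phase counts, 6) background counts
    Z = (rng.random((G, n)) < pi[:, None]).astype(np.int8)
    mu_eff = np.broadcast_to(mu[:, None], (G, n)).copy()
    if cfg.n_de_genes:
        mu_eff[: cfg.n_de_genes, groups == "A"] += cfg.de_log_fc
    theta = np.exp(mu_eff + sigma[:, None] * rng.standard_normal((G, n)))
    y_active = rng.poisson(theta * np.exp(log_s))
    inflated = rng.random((G, n)) < p0[None, :]
    y_bg = np.where(inflated, 0, rng.poisson(lam[None, :], size=(G, n)))
    Y = np.where(Z == 1, y_active, y_bg)

    cm = CountMatrix(
        Y,
        gene_ids=[f"g{k:05d}" for k in range(G)],
        cell_ids=[f"c{k:04d}" for k in range(n)],
    )
    return SimTruth(
        cm=cm,
        mu=mu,
        sigma2=sigma**2,
        pi=pi,
        p0=p0,
        lam=lam,
        Z=Z,
        log_s=log_s,
        groups=groups,
        de_genes=list(cm.gene_ids[: cfg.n_de_genes]),
        background_only_genes=list(cm.gene_ids[G - cfg.n_background_only:])
        if cfg.n_background_only else [],
        config=cfg,
    )


#: canonical fixture configurations; seeds are part of the definition
FIXTURE_CONFIGS: dict[str, SimConfig] = {
    # pure ZIP background, no active phase: ZIP estimator recovery
    "pure_zip": SimConfig(
        n_genes=20_000, n_cells=5, pi_range=(0.0, 0.0),
        bg_p0_range=(0.3, 0.3), bg_lam_range=(1.0, 1.0), seed=101,
    ),
    # 95% ZIP background plus 5% low-active genes leaking into the
    # low-count window: the robustness stress test for the ZIP regression
    "contaminated": SimConfig(
        n_genes=20_000, n_cells=5, n_background_only=19_000,
        pi_range=(1.0, 1.0), mu_range=(math.log(8.0), math.log(8.0)),
        sigma_range=(0.01, 0.01),
        bg_p0_range=(0.3, 0.3), bg_lam_range=(1.0, 1.0), seed=111,
    ),
    # cleanly separated phases: EM parameter recovery
    "well_separated": SimConfig(
        n_genes=500, n_cells=100, mu_range=(math.log(20.0), math.log(200.0)),
        sigma_range=(0.4, 0.4), pi_range=(0.6, 0.6), seed=202,
    ),
    # pure per-cell scaling: curves should come out constant; gene count at
    # the scale of real non-UMI transcriptomes so per-cell curves rest on
    # thousands of active genes
    "cellwise_bias": SimConfig(
        n_genes=10_000, n_cells=60, bias_model="cellwise",
        bias_params={"s_range": (0.5, 2.0)}, seed=303,
    ),
    # expression-dependent bias plus 15% depth-free (background-only) genes
    "smooth_bias": SimConfig(
        n_genes=3_000, n_cells=80, mu_range=(math.log(10.0), math.log(300.0)),
        bias_model="smooth",
        bias_params={"depth_range": (-0.7, 0.7), "slope": 0.25, "curv": 0.08},
        n_background_only=450, seed=404,
    ),
    # depth effect confined to high-expression genes: low-expression genes
    # have no count-depth dependence, so a whole-library size factor
    # over-normalizes them (the classic failure mode of CPM-style scaling)
    "overnorm": SimConfig(
        n_genes=3_000, n_cells=80, mu_range=(math.log(10.0), math.log(300.0)),
        bias_model="smooth",
        bias_params={"depth_range": (-0.5, 0.5), "slope": 0.588, "curv": 0.0},
        seed=707,
    ),
    # two groups at a 4x depth ratio, zero true DE
    "unbalanced_depth": SimConfig(
        n_genes=3_000, n_cells=120, bias_model="cellwise",
        bias_params={"s_range": (0.8, 1.25)},
        depth_groups=(60, 2.0, 0.5), seed=505,
    ),
    # random cell-wise bias plus 100 genes at a true 2-fold change
    "dge_spike": SimConfig(
        n_genes=2_000, n_cells=120, bias_model="cellwise",
        bias_params={"s_range": (0.5, 2.0)},
        depth_groups=(60, 1.0, 1.0), n_de_genes=100,
        de_log_fc=math.log(2.0), seed=606,
    ),
}


def fixture_suite(names: Optional[list[str]] = None,
                  seed_offset: int = 0) -> dict[str, SimTruth]:
    """Generate the canonical fixtures (optionally a subset).

    ``seed_offset`` is added to each fixture's canonical seed so an entire
    replicate suite can be drawn from one external seed.
    """
    out = {}
    for name, cfg in FIXTURE_CONFIGS.items():
        if names is not None and name not in names:
            continue
        if seed_offset:
            cfg = SimConfig(**{**asdict(cfg), "seed": cfg.seed + seed_offset})
            # asdict deep-copies tuples into lists; restore tuple fields
            for f in ("mu_range", "sigma_range", "pi_range", "bg_p0_range",
                      "bg_lam_range"):
                setattr(cfg, f, tuple(getattr(cfg, f)))
            if cfg.depth_groups is not None:
                cfg.depth_groups = tuple(cfg.depth_groups)
        out[name] = simulate(cfg)
    return out
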