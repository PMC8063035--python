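"""Shared simulation fixtures.

Heavy objects (canonical simulated datasets and full pipeline runs) are
session-scoped so every test module reuses one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import sc2pnorm as sp


@pytest.fixture(scope="session")
def pure_zip():
    return sp.fixture_suite(["pure_zip"])["pure_zip"]


@pytest.fixture(scope="session")
def contaminated():
    return sp.fixture_suite(["contaminated"])["contaminated"]


@pytest.fixture(scope="session")
def well_separated():
    return sp.fixture_suite(["well_separated"])["well_separated"]


@pytest.fixture(scope="session")
def ws_fit(well_separated):
    """Background + EM on the well-separated fixture."""
    bg = sp.estimate_background(well_separated.cm)
    fit = sp.em_fit(well_separated.cm, bg)
    return bg, fit


@pytest.fixture(scope="session")
def cellwise_run():
    fx = sp.fixture_suite(["cellwise_bias"])["cellwise_bias"]
    return fx, sp.normalize_counts(fx.cm)


@pytest.fixture(scope="session")
def smooth_run():
    fx = sp.fixture_suite(["smooth_bias"])["smooth_bias"]
    return fx, sp.normalize_counts(fx.cm)


@pytest.fixture(scope="session")
def unbalanced_run():
    fx = sp.fixture_suite(["unbalanced_depth"])["unbalanced_depth"]
    return fx, sp.normalize_counts(fx.cm)


@pytest.fixture(scope="session")
def dge_run():
    fx = sp.fixture_suite(["dge_spike"])["dge_spike"]
    return fx, sp.normalize_counts(fx.cm)


@pytest.fixture(scope="session")
def overnorm_run():
    fx = sp.fixture_suite(["overnorm"])["overnorm"]
    return fx, sp.normalize_counts(fx.cm)


@pytest.fixture
def tiny_cm():
    """A small two-phase count matrix for structural tests."""
    rng = np.random.default_rng(11)
    counts = rng.poisson(0.8, size=(30, 8))
    counts[:15] = rng.poisson(50.0, size=(15, 8))
    return sp.CountMatrix(counts, [f"g{i}" for i in range(30)],
                          [f"c{i}" for i in range(8)])
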