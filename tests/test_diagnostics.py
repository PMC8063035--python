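"""Diagnostics: count-depth stats, MA data, SD ratios, group LFC, ARI."""

import itertools
import math

import numpy as np
import pytest

import sc2pnorm as sp
from sc2pnorm.io import ValidationError


class TestCountDepth:
    def test_perfectly_depth_tracking_gene(self):
        # Y = round(c * L): correlation ~ 1 and slope ~ 1
        rng = np.random.default_rng(0)
        depth = rng.uniform(0.5, 2.0, 50)
        base = rng.poisson(30.0 * depth, size=(40, 50))
        L = base.sum(axis=0)
        tracking = np.round(0.02 * L).astype(int)  # counts >= 16
        counts = np.vstack([tracking, base])
        cm = sp.CountMatrix(counts, [f"g{i}" for i in range(41)],
                            [f"c{i}" for i in range(50)])
        ls = sp.library_sizes(cm)
        tab = sp.count_depth(cm, ls)
        assert tab.loc[0, "correlation"] > 0.99
        assert tab.loc[0, "slope"] == pytest.approx(1.0, abs=0.1)

    def test_depth_independent_gene_low_correlation(self):
        rng = np.random.default_rng(1)
        n = 200
        indep = rng.poisson(40.0, n)
        scale = rng.uniform(0.5, 2.0, n)
        bulk = rng.poisson(20.0 * scale, size=(60, n))
        cm = sp.CountMatrix(np.vstack([indep, bulk]),
                            [f"g{i}" for i in range(61)],
                            [f"c{i}" for i in range(n)])
        tab = sp.count_depth(cm, sp.library_sizes(cm))
        assert abs(tab.loc[0, "correlation"]) <= 0.15

    def test_constant_gene_correlation_missing(self):
        counts = np.vstack([np.full(5, 20), np.arange(30, 35)])
        cm = sp.CountMatrix(counts, ["const", "var"],
                            [f"c{i}" for i in range(5)])
        tab = sp.count_depth(cm, sp.library_sizes(cm))
        assert np.isnan(tab.loc[0, "correlation"])

    def test_mean_log_filter(self):
        counts = np.vstack([np.full(5, 2), np.full(5, 100)])
        cm = sp.CountMatrix(counts, ["lo", "hi"], [f"c{i}" for i in range(5)])
        tab = sp.count_depth(cm, sp.library_sizes(cm), min_mean_log=4.0)
        assert tab["included"].tolist() == [False, True]

    def test_normalization_reduces_depth_correlation(self, smooth_run):
        fx, run = smooth_run
        adj = run.adjusted().values
        raw = sp.count_depth(fx.cm, run.ls)
        nrm = sp.count_depth(adj, run.ls)
        keep = raw["included"] & np.isfinite(raw["correlation"]) & np.isfinite(
            nrm["correlation"])
        assert (nrm.loc[keep, "correlation"].abs().mean()
                < raw.loc[keep, "correlation"].abs().mean())

    def test_rerun_bit_identical(self, tiny_cm):
        ls = sp.library_sizes(tiny_cm)
        a = sp.count_depth(tiny_cm, ls)
        b = sp.count_depth(tiny_cm, ls)
        assert a.equals(b)


class TestMAData:
    def test_log_ratio_zero_at_mean_count(self, ws_fit, well_separated):
        _, fit = ws_fit
        cm = well_separated.cm
        tab = sp.ma_data(cm, fit, cm.cell_ids[0])
        i = 0
        row = tab.iloc[0]
        g = cm.gene_ids.index(row["gene_id"])
        assert row["log_ratio"] == pytest.approx(
            math.log(cm.counts[g, i]) - fit.mu[g])

    def test_phase_labels_present(self, ws_fit, well_separated):
        _, fit = ws_fit
        tab = sp.ma_data(well_separated.cm, fit, well_separated.cm.cell_ids[0])
        assert set(tab["phase"]) <= {"active", "background"}
        assert (tab["phase"] == "active").any()
        assert (tab["phase"] == "background").any()

    def test_calibrated_cell_centered_at_zero(self, ws_fit, well_separated):
        # true S = 1: active-phase log ratios center on 0
        _, fit = ws_fit
        tab = sp.ma_data(well_separated.cm, fit, well_separated.cm.cell_ids[3])
        act = tab[tab["phase"] == "active"]
        assert abs(act["log_ratio"].median()) < 0.1


class TestConditionalSDRatio:
    def test_identity_normalization_gives_unit_ratio(self, ws_fit,
                                                     well_separated):
        _, fit = ws_fit
        raw = well_separated.cm.counts.astype(float)
        out = sp.conditional_sd_ratio(raw, raw.copy(), fit)
        assert np.allclose(out.table["ratio"], 1.0)

    def test_each_gene_in_exactly_one_stratum(self, ws_fit, well_separated):
        _, fit = ws_fit
        raw = well_separated.cm.counts.astype(float)
        out = sp.conditional_sd_ratio(raw, 2 * raw, fit)
        assert not out.table["gene_id"].duplicated().any()
        assert out.table["stratum"].between(0, 3).all()

    def test_bias_removal_lowers_ratio_in_every_stratum(self, smooth_run):
        fx, run = smooth_run
        out = sp.conditional_sd_ratio(fx.cm, run.adjusted().values, run.fit)
        med = out.median_by_stratum("ratio")
        assert (med < 1.0).all()

    def test_overnormalization_signature(self, overnorm_run):
        """Whole-library scaling inflates the SD of depth-free low genes."""
        fx, run = overnorm_run
        cpm = sp.cpm_normalize(fx.cm)
        out = sp.conditional_sd_ratio(fx.cm, cpm, run.fit)
        med = out.median_by_stratum("ratio")
        assert med.iloc[0] > 1.0  # lowest stratum over-normalized
        ours = sp.conditional_sd_ratio(fx.cm, run.adjusted().values, run.fit)
        assert (ours.median_by_stratum("ratio") < 1.0).all()


class TestGroupLFC:
    def test_identical_groups_zero_lfc(self, ws_fit, well_separated):
        _, fit = ws_fit
        cm = well_separated.cm
        dup = np.hstack([cm.counts, cm.counts])
        fit2 = sp.TwoPhaseFit(
            gene_ids=fit.gene_ids, cell_ids=[f"x{i}" for i in range(200)],
            mu=fit.mu, sigma2=fit.sigma2, pi_active=fit.pi_active,
            Z_post=np.hstack([fit.Z_post, fit.Z_post]),
            estimable=fit.estimable, loglik_trace=fit.loglik_trace,
            n_iter=fit.n_iter, converged=True,
        )
        groups = np.array(["A"] * 100 + ["B"] * 100)
        out = sp.group_lfc(dup.astype(float), groups, fit2)
        assert np.allclose(out.table["lfc_all"], 0.0)

    def test_more_than_two_groups_rejected(self, ws_fit, well_separated):
        _, fit = ws_fit
        groups = np.array(["A", "B", "C"] * 33 + ["A"])
        with pytest.raises(ValidationError, match="pairwise"):
            sp.group_lfc(well_separated.cm.counts.astype(float), groups, fit)

    def test_unbalanced_depth_debiasing(self, unbalanced_run):
        fx, run = unbalanced_run
        raw = sp.group_lfc(fx.cm, fx.groups, run.fit)
        nrm = sp.group_lfc(run.adjusted().values, fx.groups, run.fit)
        assert (raw.median_by_stratum("lfc_all") > 0).all()
        assert nrm.median_by_stratum("lfc_all").abs().max() <= 0.1

    def test_true_fold_change_preserved(self, dge_run):
        fx, run = dge_run
        out = sp.group_lfc(run.adjusted().values, fx.groups, run.fit)
        de = out.table["gene_id"].isin(fx.de_genes)
        med = out.table.loc[de, "lfc_active"].median()
        assert med == pytest.approx(math.log(2.0), abs=0.2)


def brute_force_ari(a, b):
    """Independent ARI oracle: enumerate all item pairs and apply the
    chance-corrected agreement formula directly."""
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    same_a = np.array([a[i] == a[j] for i, j in pairs])
    same_b = np.array([b[i] == b[j] for i, j in pairs])
    n11 = np.sum(same_a & same_b)
    n00 = np.sum(~same_a & ~same_b)
    n10 = np.sum(same_a & ~same_b)
    n01 = np.sum(~same_a & same_b)
    total = len(pairs)
    expected = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / total
    maximum = ((n11 + n10) + (n11 + n01) + (n01 + n00) + (n10 + n00)) / 2
    if maximum == expected:
        return 1.0
    return ((n11 + n00) - expected) / (maximum - expected)


class TestARI:
    def test_identical_partitions(self):
        assert sp.ari([1, 1, 2, 2, 3], [5, 5, 6, 6, 7]) == pytest.approx(1.0)

    def test_singletons_vs_monolith(self):
        assert sp.ari([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1]) == pytest.approx(
            0.0)

    def test_crossed_partition_matches_pair_count_oracle(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert brute_force_ari(a, b) == pytest.approx(-0.5)
        assert sp.ari(a, b) == pytest.approx(-0.5)

    def test_random_partitions_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = rng.integers(0, 3, 12)
            b = rng.integers(0, 4, 12)
            assert sp.ari(a, b) == pytest.approx(brute_force_ari(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            sp.ari([1, 2], [1, 2, 3])


class TestStability:
    def test_drop_cells_changes_lfc_little_with_true_factors(self, dge_run):
        fx, run = dge_run

        def normalizer(cm):
            idx = [fx.cm.cell_ids.index(c) for c in cm.cell_ids]
            return cm.counts / np.exp(fx.log_s[:, idx])

        def fit_factory(cm):
            idx = [fx.cm.cell_ids.index(c) for c in cm.cell_ids]
            return sp.TwoPhaseFit(
                gene_ids=fx.cm.gene_ids, cell_ids=list(cm.cell_ids),
                mu=run.fit.mu, sigma2=run.fit.sigma2,
                pi_active=run.fit.pi_active,
                Z_post=run.fit.Z_post[:, idx],
                estimable=run.fit.estimable,
                loglik_trace=run.fit.loglik_trace, n_iter=1, converged=True,
            )

        out = sp.lfc_stability(fx.cm, fx.groups, normalizer, fit_factory,
                               k=5, strategy="top_depth")
        assert out["lfc_change"].abs().median() < 0.05
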