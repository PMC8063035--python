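"""Residuals, per-cell curves, log S evaluation, rescaling, application."""

import math

import numpy as np
import pytest

import sc2pnorm as sp
from sc2pnorm.normalization import CellCurve, Residuals, _robust_spline


def _residuals_from_points(x, eps_by_cell):
    """Build a Residuals object directly from per-cell point sets."""
    G = len(x)
    cells = [f"c{i}" for i in range(len(eps_by_cell))]
    eps = np.column_stack(eps_by_cell)
    return Residuals(eps=eps, abscissa=np.asarray(x, float),
                     active=np.isfinite(eps),
                     gene_ids=[f"g{i}" for i in range(G)], cell_ids=cells)


class TestComputeResiduals:
    def test_exact_count_gives_zero_residual(self, ws_fit, well_separated):
        _, fit = ws_fit
        cm = well_separated.cm
        res = sp.compute_residuals(cm, fit)
        gi, ci = np.nonzero(res.active)
        vals = np.log(cm.counts[gi, ci]) - fit.mu[gi]
        assert np.allclose(res.eps[gi, ci], vals)

    def test_uncertain_phase_contributes_nothing(self):
        fit = sp.TwoPhaseFit(
            gene_ids=["g0"], cell_ids=["c0", "c1"],
            mu=np.array([2.0]), sigma2=np.array([0.1]),
            pi_active=np.array([0.5]),
            Z_post=np.array([[0.5, 0.5]]), estimable=np.array([True]),
            loglik_trace=np.array([0.0]), n_iter=1, converged=True,
        )
        cm = sp.CountMatrix(np.array([[10, 20]]), ["g0"], ["c0", "c1"])
        res = sp.compute_residuals(cm, fit, threshold=0.99)
        assert not res.active.any()

    def test_known_shift_recovered(self, smooth_run):
        # residual mean tracks the cell's true log bias (up to mu error)
        fx, run = smooth_run
        res = sp.compute_residuals(fx.cm, run.fit)
        i = int(np.argmax(np.abs(fx.log_s[0])))
        m = res.active[:, i]
        est = np.mean(res.eps[m, i])
        true = np.mean(fx.log_s[m, i])
        assert est == pytest.approx(true, abs=0.15)


class TestCellCurves:
    def test_constant_residuals_give_constant_curve(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 8, 200)
        res = _residuals_from_points(x, [np.full(200, 0.7)])
        cv = sp.fit_cell_curve(res, "c0")
        grid = np.array([-5.0, 2.0, 5.0, 8.0, 30.0])  # incl. extrapolation
        assert np.allclose(cv(grid), 0.7, atol=1e-8)

    def test_linear_function_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(2, 8, 500)
        res = _residuals_from_points(x, [0.1 * x + 0.2])
        cv = sp.fit_cell_curve(res, "c0")
        grid = np.linspace(x.min(), x.max(), 40)
        assert np.max(np.abs(cv(grid) - (0.1 * grid + 0.2))) < 1e-3

    def test_smooth_function_recovered_under_noise(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 2 * np.pi, 2_000)
        y = np.sin(x) / 2 + rng.normal(0, 0.1, len(x))
        res = _residuals_from_points(x, [y])
        cv = sp.fit_cell_curve(res, "c0", df=8)
        lo, hi = np.quantile(x, [0.05, 0.95])
        grid = np.linspace(lo, hi, 100)
        assert np.max(np.abs(cv(grid) - np.sin(grid) / 2)) <= 0.1

    def test_df_reduced_when_points_scarce(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        cv = _robust_spline(x, 0.5 * x, df=10)
        assert np.allclose(cv(x), 0.5 * x, atol=1e-6)

    def test_fallback_ladder(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.uniform(2, 8, 200), [5.0] * 3])
        eps_rich = np.concatenate([0.3 * np.ones(200), [np.nan] * 3])
        eps_mid = np.full(203, np.nan)
        eps_mid[:20] = 0.9
        eps_poor = np.full(203, np.nan)
        eps_poor[:2] = 5.0
        res = _residuals_from_points(x, [eps_rich, eps_mid, eps_poor])
        curves, flagged = sp.fit_curves(res, min_curve_points=50)
        assert flagged.tolist() == [False, True, True]
        assert curves["c1"](np.array([4.0]))[0] == pytest.approx(0.9)
        # cohort median ignores the poor cell's own 2 points
        assert curves["c2"](np.array([4.0]))[0] == pytest.approx(0.6, abs=0.1)


class TestEvalLogS:
    def _toy(self):
        cm = sp.CountMatrix(np.array([[10, 0], [20, 30]]), ["g0", "g1"],
                            ["c0", "c1"])
        fit = sp.TwoPhaseFit(
            gene_ids=["g0", "g1"], cell_ids=["c0", "c1"],
            mu=np.array([2.0, 3.0]), sigma2=np.array([0.1, 0.1]),
            pi_active=np.array([0.9, 0.9]),
            Z_post=np.array([[1.0, 0.0], [1.0, 1.0]]),
            estimable=np.array([True, True]),
            loglik_trace=np.array([0.0]), n_iter=1, converged=True,
        )
        return cm, fit

    def test_zero_curve_gives_zero_log_s(self):
        cm, fit = self._toy()
        curves = {c: CellCurve("constant", value=0.0, x_range=(0, 5))
                  for c in cm.cell_ids}
        nf = sp.eval_log_s(curves, cm, sp.phase_call(fit, 0.5), "at_count", fit)
        m = np.isfinite(nf.log_s)
        assert np.all(nf.log_s[m] == 0.0)
        assert not m[0, 1]  # background entry masked

    def test_modes_agree_on_constant_curves(self):
        cm, fit = self._toy()
        curves = {c: CellCurve("constant", value=0.4, x_range=(0, 5))
                  for c in cm.cell_ids}
        a = sp.eval_log_s(curves, cm, sp.phase_call(fit, 0.5), "at_count", fit)
        b = sp.eval_log_s(curves, cm, sp.phase_call(fit, 0.5), "at_mu", fit)
        m = np.isfinite(a.log_s)
        assert np.array_equal(m, np.isfinite(b.log_s))
        assert np.allclose(a.log_s[m], b.log_s[m])
        assert np.allclose(a.log_s[m], 0.4)

    def test_mode_validation(self):
        cm, fit = self._toy()
        with pytest.raises(ValueError):
            sp.eval_log_s({}, cm, np.ones((2, 2), bool), "bogus", fit)


class TestRescaleToReference:
    def _nf(self, log_s, cells):
        return sp.NormFactorMatrix(
            log_s=np.asarray(log_s, float),
            gene_ids=[f"g{i}" for i in range(len(log_s))], cell_ids=cells,
            curves={c: CellCurve("constant", value=0.0, x_range=(0, 1))
                    for c in cells},
            flagged_cells=np.zeros(len(cells), bool),
        )

    def _ls(self, L, cells):
        cm = sp.CountMatrix(np.array(L)[None, :], ["g"], cells)
        return sp.library_sizes(cm)

    def test_reference_mean_halved(self):
        nf = self._nf([[math.log(2.0)], [math.log(2.0)]], ["c0"])
        ls = self._ls([5], ["c0"])
        out = sp.rescale_to_reference(nf, ls)
        assert np.nanmean(np.exp(out.log_s[:, 0])) == pytest.approx(1.0,
                                                                    abs=1e-12)
        assert np.allclose(out.log_s, 0.0)
        # curves shifted consistently
        assert out.curves["c0"](np.array([0.5]))[0] == pytest.approx(
            -math.log(2.0))

    def test_idempotence(self, smooth_run):
        fx, run = smooth_run
        once = run.nf
        twice = sp.rescale_to_reference(once, run.ls)
        m = np.isfinite(once.log_s)
        assert np.allclose(once.log_s[m], twice.log_s[m], atol=1e-12)

    def test_masked_reference_falls_back_with_warning(self):
        log_s = np.array([[0.5, np.nan, 0.2]])
        nf = self._nf(log_s, ["c0", "c1", "c2"])
        ls = self._ls([10, 20, 30], ["c0", "c1", "c2"])  # reference is c1
        assert ls.reference_cell == "c1"
        out = sp.rescale_to_reference(nf, ls)
        assert out.reference_cell in ("c0", "c2")


class TestApplyNormalization:
    def _setup(self, log_s):
        cm = sp.CountMatrix(np.array([[10, 0], [4, 6]]), ["g0", "g1"],
                            ["c0", "c1"])
        nf = sp.NormFactorMatrix(
            log_s=np.asarray(log_s, float), gene_ids=cm.gene_ids,
            cell_ids=cm.cell_ids, curves={}, flagged_cells=np.zeros(2, bool),
        )
        return cm, nf

    def test_identity_factors_return_raw_bitwise(self):
        cm, nf = self._setup([[0.0, np.nan], [0.0, 0.0]])
        out = sp.apply_normalization(cm, nf, "adjusted")
        assert np.array_equal(out.values, cm.counts.astype(float))

    def test_halving(self):
        cm, nf = self._setup([[math.log(2.0), np.nan], [0.0, 0.0]])
        out = sp.apply_normalization(cm, nf, "adjusted")
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_masked_zero_stays_zero(self):
        cm, nf = self._setup([[0.0, np.nan], [0.0, 0.0]])
        out = sp.apply_normalization(cm, nf, "adjusted")
        assert out.values[0, 1] == 0.0

    def test_offset_mode_returns_log_s(self):
        cm, nf = self._setup([[0.1, np.nan], [0.2, 0.3]])
        out = sp.apply_normalization(cm, nf, "offset")
        m = np.isfinite(nf.log_s)
        assert np.array_equal(out.values[m], nf.log_s[m])
        assert out.filter_genes is None

    def test_filter_gene_list(self):
        cm, nf = self._setup([[0.0, np.nan], [0.0, 0.0]])
        out = sp.apply_normalization(cm, nf, "adjusted", min_cells_active=2)
        assert out.filter_genes == ["g1"]


class TestEndToEndRecovery:
    def test_smooth_bias_curves(self, smooth_run):
        """Fitted bias curves track the generative log-bias curves."""
        fx, run = smooth_run
        nf, fit = run.nf, run.fit
        j = nf.cell_ids.index(nf.reference_cell)
        msk = np.isfinite(nf.log_s)
        shift = np.log(np.mean(np.exp(fx.log_s[msk[:, j], j])))
        mu_ok = fit.mu[np.isfinite(fit.mu)]
        grid = np.linspace(*np.quantile(mu_ok, [0.05, 0.95]), 60)
        p = fx.config.bias_params
        m0 = 0.5 * sum(fx.config.mu_range)
        q = 1 + p["slope"] * (grid - m0) + p["curv"] * (grid - m0) ** 2
        q0 = 1 + p["slope"] * (fx.mu[0] - m0) + p["curv"] * (fx.mu[0] - m0) ** 2
        rmses = []
        for i, cell in enumerate(nf.cell_ids):
            if msk[:, i].sum() < 500:
                continue
            t_i = fx.log_s[0, i] / q0
            rmses.append(np.sqrt(np.mean(
                (nf.curves[cell](grid) - (t_i * q - shift)) ** 2)))
        assert len(rmses) > 0
        assert max(rmses) <= 0.1

    def test_background_counts_never_altered(self, smooth_run):
        fx, run = smooth_run
        adj = run.adjusted().values
        masked = ~np.isfinite(run.nf.log_s)
        assert np.array_equal(adj[masked], fx.cm.counts[masked].astype(float))
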