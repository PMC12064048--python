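import numpy as np
import pytest

from sfratios.dfe_models import DFEModel
from sfratios.inference import (
    compare_models,
    estimate_lambda,
    fit,
    fit_fixed_rho,
    lrt_neutral,
    profile_ci,
)
from sfratios.prf_expectations import dfe_bin_expectations, get_grid, neutral_expectations
from sfratios.sfs_core import SFS, fold, make_ratios
from sfratios.simulate import SimConfig, simulate_pair


def expectation_ratios(model, rho, n, theta, folded=True):
    """Noiseless selected/neutral pair: counts set to their expectations."""
    grid_u = get_grid(n, False)
    fg = dfe_bin_expectations(grid_u, model)
    nn = neutral_expectations(n, False)
    sel = SFS(n, fg * rho * theta / 2)
    neu = SFS(n, nn * theta / 2)
    if folded:
        sel, neu = fold(sel), fold(neu)
    return make_ratios(sel, neu)


class TestEstimateLambda:
    def test_worked_example(self):
        # X/Y = 0.2 with rho_hat = 0.35: selected mutations are 75% more
        # likely to go unsampled
        assert estimate_lambda(0.35, X=20.0, Y=100.0) == 1.75

    def test_fully_neutral_case(self):
        assert estimate_lambda(0.2, X=20.0, Y=100.0) == pytest.approx(1.0)

    def test_paired_design(self):
        assert estimate_lambda(2.63, X=500.0, Y=500.0) == pytest.approx(2.63)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            estimate_lambda(1.0, X=0.0, Y=10.0)


class TestFit:
    def test_neutral_recovery(self, grid100f):
        cfg = SimConfig(n=100, theta=500.0, rho=1.0, folded=True, seed=9)
        sel, neu = simulate_pair(cfg)
        res = fit(make_ratios(sel, neu), "fixed", grid=grid100f, n_starts=3, seed=0)
        assert res.rho_hat == pytest.approx(1.0, abs=0.15)
        assert abs(res.model.params["gamma"]) < 1.0
        assert res.aic == pytest.approx(2 * res.K - 2 * res.loglik)

    def test_noiseless_input_recovers_generating_parameters(self, grid100f):
        model = DFEModel("lognormal", {"mu": 1.0, "sigma": 1.0}, m=1.0)
        r = expectation_ratios(model, 0.35, 100, 1e6)
        res = fit(r, "lognormal", m=1.0, grid=grid100f, n_starts=3, seed=1)
        assert res.rho_hat == pytest.approx(0.35, abs=2e-3)
        assert res.model.params["mu"] == pytest.approx(1.0, abs=0.02)
        assert res.model.params["sigma"] == pytest.approx(1.0, abs=0.02)
        assert res.lambda_hat == pytest.approx(res.rho_hat * r.Y / r.X)

    def test_too_few_bins_rejected(self):
        r = make_ratios(SFS(4, [5.0, 2.0, 1.0]), SFS(4, [9.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="3 valid bins"):
            fit(r, "fixed")


class TestFixedRho:
    def test_parameter_count_drops_by_one(self, grid100f):
        cfg = SimConfig(n=100, theta=500.0, rho=1.0, folded=True, seed=10)
        r = make_ratios(*simulate_pair(cfg))
        free = fit(r, "fixed", grid=grid100f, n_starts=2, seed=0)
        pinned = fit_fixed_rho(r, "fixed", 1.0, grid=grid100f, n_starts=2, seed=0)
        assert pinned.K == free.K - 1
        assert pinned.rho_hat == 1.0 and pinned.rho_fixed

    def test_true_rho_transfer_no_worse_than_free_fit(self, grid100f):
        # pinning rho at the truth should not hurt gamma recovery (RMSE
        # over replicates)
        cfg = SimConfig(
            n=100,
            theta=500.0,
            rho=1.0,
            model=DFEModel("fixed", {"gamma": -2.0}),
            folded=True,
            seed=15,
        )
        err_free, err_pinned = [], []
        for rep in range(20):
            r = make_ratios(*simulate_pair(cfg, rep=rep))
            g_free = fit(r, "fixed", grid=grid100f, n_starts=2, seed=rep)
            g_pin = fit_fixed_rho(r, "fixed", 1.0, grid=grid100f, n_starts=2, seed=rep)
            err_free.append(g_free.model.params["gamma"] + 2.0)
            err_pinned.append(g_pin.model.params["gamma"] + 2.0)
        rmse_free = np.sqrt(np.mean(np.square(err_free)))
        rmse_pinned = np.sqrt(np.mean(np.square(err_pinned)))
        assert rmse_pinned <= rmse_free * 1.1

    def test_misspecified_rho_still_converges(self, grid100f):
        # documented behavior: a wildly wrong pinned rho biases the DFE but
        # the optimization itself succeeds
        cfg = SimConfig(n=100, theta=500.0, rho=1.0, folded=True, seed=16)
        r = make_ratios(*simulate_pair(cfg))
        res = fit_fixed_rho(r, "fixed", 10.0, grid=grid100f, n_starts=3, seed=0)
        assert np.isfinite(res.loglik)
        assert res.model.params["gamma"] < -1.0  # forced to absorb the distortion


class TestLRT:
    def test_alternative_never_below_null(self, grid100f):
        for rep in range(3):
            cfg = SimConfig(n=100, theta=500.0, rho=1.0, folded=True, seed=20)
            r = make_ratios(*simulate_pair(cfg, rep=rep))
            res = lrt_neutral(r, grid=grid100f, seed=rep)
            assert res.alt_loglik >= res.null_loglik - 1e-6
            assert res.stat >= 0.0
            assert 0.0 <= res.p_value <= 1.0

    def test_strong_selection_detected(self, grid100f):
        cfg = SimConfig(
            n=100,
            theta=500.0,
            rho=1.0,
            model=DFEModel("fixed", {"gamma": -20.0}),
            folded=True,
            seed=21,
        )
        r = make_ratios(*simulate_pair(cfg))
        res = lrt_neutral(r, grid=grid100f, seed=0)
        assert res.reject_at[0.001]


class TestProfileCI:
    def test_interval_contains_estimate(self, grid100f):
        cfg = SimConfig(n=100, theta=500.0, rho=1.0, folded=True, seed=30)
        r = make_ratios(*simulate_pair(cfg))
        res = fit(r, "fixed", grid=grid100f, n_starts=2, seed=0)
        lo, hi = profile_ci(res, "rho")
        assert lo < res.rho_hat < hi

    def test_width_shrinks_with_data(self, grid100f):
        model = DFEModel("fixed", {"gamma": -1.0})
        widths = []
        for theta in (500.0, 50000.0):
            cfg = SimConfig(n=100, theta=theta, rho=1.0, model=model, folded=True, seed=31)
            r = make_ratios(*simulate_pair(cfg))
            res = fit(r, "fixed", grid=grid100f, n_starts=2, seed=0)
            lo, hi = profile_ci(res, "rho")
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 3


class TestCompareModels:
    def test_single_fit_trivially_ranked(self, grid100f):
        cfg = SimConfig(n=100, theta=500.0, rho=1.0, folded=True, seed=40)
        r = make_ratios(*simulate_pair(cfg))
        res = fit(r, "fixed", grid=grid100f, n_starts=2, seed=0)
        table = compare_models([res])
        assert len(table) == 1 and table["dAIC"].iloc[0] == 0.0

    def test_useless_point_mass_costs_two_aic(self, grid100f):
        # noiseless data without a point mass: adding p+ gains no
        # likelihood, so AIC rises by the 2-per-parameter penalty
        model = DFEModel("lognormal", {"mu": 1.0, "sigma": 1.0}, m=1.0)
        r = expectation_ratios(model, 0.5, 100, 1e6)
        base = fit(r, "lognormal", m=1.0, grid=grid100f, n_starts=2, seed=0)
        with_pp = fit(r, "lognormal", m=1.0, fit_p_plus=True, grid=grid100f, n_starts=2, seed=0)
        assert with_pp.aic - base.aic == pytest.approx(2.0, abs=0.5)

    def test_genuine_point_mass_detected(self, grid100f):
        model = DFEModel("lognormal", {"mu": 2.0, "sigma": 0.8}, m=1.0, p_plus=0.25)
        r = expectation_ratios(model, 0.5, 100, 1e6)
        base = fit(r, "lognormal", m=1.0, grid=grid100f, n_starts=3, seed=0)
        with_pp = fit(r, "lognormal", m=1.0, fit_p_plus=True, grid=grid100f, n_starts=3, seed=0)
        table = compare_models([base, with_pp])
        assert table.iloc[0]["p_plus"] > 0.1  # point-mass model ranks first
        assert with_pp.model.p_plus == pytest.approx(0.25, abs=0.05)

    def test_mixed_datasets_rejected(self, grid100f):
        cfg = SimConfig(n=100, theta=500.0, rho=1.0, folded=True, seed=41)
        r1 = make_ratios(*simulate_pair(cfg, rep=0))
        r2 = make_ratios(*simulate_pair(cfg, rep=1))
        f1 = fit(r1, "fixed", grid=grid100f, n_starts=2, seed=0)
        f2 = fit(r2, "fixed", grid=grid100f, n_starts=2, seed=0)
        with pytest.raises(ValueError, match="different ratio spectra"):
            compare_models([f1, f2])
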