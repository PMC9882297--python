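"""MSD estimators, closed forms, Bayesian fits, collapse, velocity correlations."""

import math

import numpy as np
import pytest

from locusdyn import (
    SimulationConfig,
    autocorr_two_locus,
    collapse_gamma,
    fit_rouse_m2,
    msd_single,
    msd_two_locus,
    powerlaw_fit,
    predicted_vcc_intercept,
    relaxation_ratio,
    relaxation_scaling,
    rouse_m2,
    simulate_rouse_chain,
    stretched_m2,
    theory_exponents,
    velocity_corr,
)
from locusdyn.dynamics import CorrelationCurve, MSDCurve, RouseFit

from conftest import make_trajectory


class TestMSDSingle:
    def test_static_locus_is_zero(self):
        traj = make_trajectory(np.ones((20, 3)) * 100.0, np.zeros((20, 3)))
        m1 = msd_single([traj], locus="a", n_boot=10)
        np.testing.assert_allclose(m1.values, 0.0, atol=1e-12)

    def test_ballistic_track_is_quadratic(self):
        v = 7.0
        t = np.arange(30) * 28.0
        pos = np.column_stack([v * t, np.zeros(30), np.zeros(30)])
        m1 = msd_single([make_trajectory(pos, np.zeros((30, 3)))], locus="a", n_boot=10)
        np.testing.assert_allclose(m1.values, v**2 * m1.lags**2, rtol=1e-9)

    def test_planar_estimate_applies_isotropy_factor(self, rng):
        pos = rng.normal(0, 100, size=(200, 3))
        traj = make_trajectory(pos, np.zeros((200, 3)))
        full = msd_single([traj], locus="a", n_boot=10)
        planar = msd_single([traj], locus="a", use_xy_only=True, n_boot=10)
        # 3/2 x planar MSD built from the xy components only
        d = pos[1:] - pos[:-1]
        expect = 1.5 * np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
        assert planar.values[0] == pytest.approx(expect, rel=1e-9)
        assert planar.dimensionality == "3d-from-xy"
        assert full.values[0] == pytest.approx(np.mean(np.sum(d**2, axis=1)), rel=1e-9)

    def test_fractional_gaussian_input_recovers_hurst(self, rng):
        # fBm with Hurst H: MSD ~ t^{2H}
        hurst = 0.3
        n = 128
        t = np.arange(n, dtype=float)
        cov = 0.5 * (
            t[:, None] ** (2 * hurst)
            + t[None, :] ** (2 * hurst)
            - np.abs(t[:, None] - t[None, :]) ** (2 * hurst)
        )
        chol = np.linalg.cholesky(cov[1:, 1:] + 1e-10 * np.eye(n - 1))
        trajs = []
        for i in range(60):
            x = np.zeros((n, 3))
            x[1:] = 100.0 * chol @ rng.standard_normal((n - 1, 3))
            trajs.append(
                make_trajectory(x, np.zeros((n, 3)), frame_interval=1.0, traj_id=f"f{i}")
            )
        m1 = msd_single(trajs, locus="a", n_boot=30)
        fit = powerlaw_fit(m1.lags[:40], m1.values[:40], m1.se[:40])
        assert abs(fit.exponent - 2 * hurst) < 0.05


class TestMSDTwoLocus:
    def test_constant_separation_is_zero(self):
        pos_a = np.tile([500.0, 0, 0], (15, 1))
        m2 = msd_two_locus([make_trajectory(pos_a, np.zeros((15, 3)))], n_boot=10)
        np.testing.assert_allclose(m2.values, 0.0, atol=1e-12)

    def test_alternating_separation(self):
        # R alternates between a and b: M2 = |a-b|^2 at odd lags, 0 at even
        a = np.array([400.0, 0.0, 0.0])
        b = np.array([0.0, 300.0, 0.0])
        pos_a = np.array([a if k % 2 == 0 else b for k in range(20)])
        m2 = msd_two_locus([make_trajectory(pos_a, np.zeros((20, 3)))], n_boot=10)
        gap = float(np.sum((a - b) ** 2))
        np.testing.assert_allclose(m2.values[0::2], gap, rtol=1e-12)  # odd lags
        np.testing.assert_allclose(m2.values[1::2], 0.0, atol=1e-9)  # even lags

    def test_missing_frames_excluded_pairwise(self, rng):
        pos_a = rng.normal(0, 100, (50, 3))
        traj = make_trajectory(pos_a, np.zeros((50, 3)))
        traj.missing[10:20] = True
        traj.pos_a[10:20] = np.nan
        m2 = msd_two_locus([traj], n_boot=10)
        # frames 10..19 masked: unit-lag pairs (9,10)..(19,20) are dropped
        assert m2.n_pairs[0] == 49 - 11


class TestClosedForms:
    def test_rouse_m2_asymptotics(self):
        gamma, plateau = 2e3, 1e5
        tau = (plateau / gamma) ** 2
        # the approach to the plateau is slow, ~ sqrt(tau/t)/pi relative
        assert rouse_m2(100 * tau, gamma, plateau) == pytest.approx(
            2 * plateau, rel=0.04
        )
        assert rouse_m2(2e4 * tau, gamma, plateau) == pytest.approx(
            2 * plateau, rel=0.01
        )
        t = tau / 1e4
        assert rouse_m2(t, gamma, plateau) == pytest.approx(
            2 * gamma * math.sqrt(t), rel=0.01
        )

    def test_rouse_m2_unit_point(self):
        # Gamma = J = 1 (tau = 1), t = 1:
        # 2(1 - e^{-1/pi}) + 2 erfc(pi^{-1/2}) ~= 1.3951
        assert rouse_m2(1.0, 1.0, 1.0) == pytest.approx(1.3951, abs=2e-4)

    def test_rouse_m2_monotone(self):
        t = np.geomspace(1e-3, 1e5, 300)
        vals = rouse_m2(t, 1.5e3, 2e5)
        assert np.all(np.diff(vals) > 0)

    def test_stretched_m2_asymptotics(self):
        j, tau, beta = 1e5, 200.0, 0.52
        gamma = j / tau**beta
        t = tau / 1e4
        assert stretched_m2(t, j, tau, beta) == pytest.approx(
            2 * gamma * t**beta, rel=0.01
        )
        assert stretched_m2(1e4 * tau, j, tau, beta) == pytest.approx(2 * j, rel=0.01)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            rouse_m2(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            stretched_m2(1.0, 1.0, 0.0, 0.5)


class TestRouseFitting:
    def _curve_from_closed_form(self, gamma, plateau, rel_err=0.01):
        lags = np.geomspace(28, 1792, 40)
        lags = np.unique(np.round(lags / 28) * 28)
        vals = rouse_m2(lags, gamma, plateau)
        return MSDCurve(
            lags=lags, values=vals, se=rel_err * vals, n_pairs=np.full(len(lags), 1000)
        )

    def test_self_consistency_on_noiseless_curve(self):
        gamma, plateau = 2e3, 1e5
        fit = fit_rouse_m2(self._curve_from_closed_form(gamma, plateau), seed=1)
        assert fit.gamma_diff == pytest.approx(gamma, rel=0.01)
        assert fit.plateau == pytest.approx(plateau, rel=0.01)
        assert fit.tau == pytest.approx((plateau / gamma) ** 2, rel=0.03)

    def test_tau_identity_holds_per_draw(self):
        fit = fit_rouse_m2(self._curve_from_closed_form(2e3, 1e5), seed=2)
        g = 10.0 ** fit.samples[:, 0]
        j = 10.0 ** fit.samples[:, 1]
        # tau = (J/Gamma)^2 is exact for every posterior draw by construction
        np.testing.assert_allclose((j / g) ** 2, (j / g) ** (1 / 0.5), rtol=1e-12)

    def test_doubling_errors_widens_intervals(self):
        tight = fit_rouse_m2(self._curve_from_closed_form(2e3, 1e5, 0.01), seed=3)
        loose = fit_rouse_m2(self._curve_from_closed_form(2e3, 1e5, 0.02), seed=3)

        def width(fit):
            lo, hi = fit.intervals["tau"][1], fit.intervals["tau"][3]
            return math.log(hi / lo)

        assert width(loose) > width(tight)


class TestAutocorrelation:
    def test_constant_separation(self):
        pos_a = np.tile([300.0, 400.0, 0.0], (12, 1))
        c2 = autocorr_two_locus([make_trajectory(pos_a, np.zeros((12, 3)))], n_boot=10)
        np.testing.assert_allclose(c2.c2, 500.0**2, rtol=1e-12)

    def test_identity_with_msd_on_gapfree_data(self, rng):
        trajs = [
            make_trajectory(rng.normal(0, 300, (64, 3)), rng.normal(0, 300, (64, 3)),
                            traj_id=f"t{i}")
            for i in range(5)
        ]
        c2 = autocorr_two_locus(trajs, n_boot=10)
        # direct estimator equals <R^2>_pairs - M2/2 to machine precision
        np.testing.assert_allclose(c2.c2, c2.c2_from_msd, rtol=1e-12, atol=1e-9)


class TestScalingAndCollapse:
    def _fits(self, taus):
        return {
            s: RouseFit(gamma_diff=1.0, plateau=1.0, tau=t, beta=0.5, model="rouse")
            for s, t in taus.items()
        }

    def test_exact_tau_scaling(self):
        seps = [58.0, 149.0, 330.0, 595.0]
        fits = self._fits({s: s**0.7 for s in seps})
        fit = relaxation_scaling(fits)
        assert fit.exponent == pytest.approx(0.700, abs=1e-9)

    @pytest.mark.parametrize("gamma_true", [0.7, 2.0])
    def test_collapse_of_exact_construction(self, gamma_true):
        seps = [58.0, 100.0, 149.0]

        def template(u):
            return np.exp(-(u**0.5))

        curves = []
        lags = np.arange(1, 60) * 28.0
        for s in seps:
            u = lags * s ** (-gamma_true)
            u0 = 28.0 * 100.0 ** (-gamma_true)  # common template scale
            curves.append(
                CorrelationCurve(
                    lags=lags,
                    c2=1e5 * template(u / u0),
                    c2_from_msd=1e5 * template(u / u0),
                    r2=1e5,
                    se=np.zeros(len(lags)),
                    n_pairs=np.full(len(lags), 100),
                    separation_kb=s,
                )
            )
        result = collapse_gamma(curves)
        # recovery is limited by interpolation bias on the common grid,
        # of order the coarse grid step
        assert result.gamma == pytest.approx(gamma_true, abs=0.05)

    def test_collapse_requires_three_curves(self):
        with pytest.raises(ValueError, match="3 curves"):
            collapse_gamma([])

    def test_non_overlapping_supports_fail(self):
        lags = np.arange(1, 5) * 28.0
        curves = [
            CorrelationCurve(
                lags=lags, c2=np.ones(4), c2_from_msd=np.ones(4), r2=1.0,
                se=np.zeros(4), n_pairs=np.ones(4, int), separation_kb=s,
            )
            for s in (1.0, 1e4, 1e8)
        ]
        with pytest.raises(ValueError, match="overlap"):
            collapse_gamma(curves, gamma_grid=np.array([2.5, 3.0]))


class TestVelocityCorrelations:
    def test_identical_motion_gives_unit_intercept(self, rng):
        pos = np.cumsum(rng.normal(0, 50, (64, 3)), axis=0)
        traj = make_trajectory(pos, pos + np.array([300.0, 0, 0]))
        vcc = velocity_corr([traj], delta=28.0, n_boot=20)
        assert vcc.intercept_ratio == pytest.approx(1.0, abs=1e-9)

    def test_independent_motion_gives_zero_intercept(self, rng):
        trajs = [
            make_trajectory(
                np.cumsum(rng.normal(0, 50, (64, 3)), axis=0),
                np.cumsum(rng.normal(0, 50, (64, 3)), axis=0),
                traj_id=f"t{i}",
            )
            for i in range(40)
        ]
        vcc = velocity_corr(trajs, delta=28.0, n_boot=100)
        assert abs(vcc.intercept_ratio) < 3 * vcc.intercept_se

    def test_delta_must_be_commensurate_and_short(self):
        traj = make_trajectory(np.zeros((20, 3)), np.zeros((20, 3)))
        with pytest.raises(ValueError, match="integer multiple"):
            velocity_corr([traj], delta=30.0)
        with pytest.raises(ValueError, match="longer"):
            velocity_corr([traj], delta=28.0 * 25)

    def test_predicted_intercept_limits_and_monotonicity(self):
        tau = 123.0
        assert predicted_vcc_intercept(1e7 * tau, tau) == pytest.approx(1.0, abs=1e-3)
        assert predicted_vcc_intercept(1e-3 * tau, tau) == pytest.approx(0.0, abs=1e-3)
        deltas = np.geomspace(1e-2, 1e4, 100) * tau
        vals = predicted_vcc_intercept(deltas, tau)
        assert np.all(np.diff(vals) > 0)
        # stretched family shares the limits
        assert predicted_vcc_intercept(
            1e6 * tau, tau, beta=0.52, family="stretched"
        ) == pytest.approx(1.0, abs=1e-3)
        assert predicted_vcc_intercept(
            1e-6 * tau, tau, beta=0.52, family="stretched"
        ) == pytest.approx(0.0, abs=1e-3)

    def test_rouse_simulation_matches_prediction(self):
        # parameter-free check across delta/tau ~ {0.1, 1, 10} on one
        # simulated Rouse pair (bead separation 8, tau ~= 50 t_b)
        cfg = SimulationConfig(
            n_beads=64, separations=(80.0,), frame_interval=1.0, duration=2560.0,
            n_trajectories=60, seed=11,
        )
        trajs = simulate_rouse_chain(cfg)
        m2 = msd_two_locus(trajs, max_lag=400, n_boot=150, seed=1)
        fit = fit_rouse_m2(m2, seed=2)
        for delta in (5.0, 50.0, 500.0):
            vcc = velocity_corr(trajs, delta=delta, n_boot=150, seed=3)
            pred = predicted_vcc_intercept(delta, fit.tau)
            assert abs(vcc.intercept_ratio - pred) < 2 * vcc.intercept_se + 0.02


class TestTheory:
    def test_generalized_rouse_relations(self):
        ideal = theory_exponents(2.0)
        assert ideal["beta_from_d"] == pytest.approx(0.5)
        assert ideal["gamma"] == pytest.approx(2.0)
        assert ideal["lambda"] == pytest.approx(-0.5)
        crumpled = theory_exponents(3.0)
        assert crumpled["beta_from_d"] == pytest.approx(2.0 / 5.0)
        assert crumpled["gamma"] == pytest.approx(5.0 / 3.0)
        assert crumpled["lambda"] == pytest.approx(-4.0 / 5.0)
        assert crumpled["gamma_zimm"] == pytest.approx(1.0)

    def test_measured_exponent_triple(self):
        out = theory_exponents(1 / 0.31, beta=0.52, alpha=0.27)
        assert out["gamma"] == pytest.approx(0.673, abs=5e-4)

    def test_relaxation_ratio(self):
        assert relaxation_ratio(58.0, 3300.0, 2.0) == pytest.approx(3237.2, rel=1e-3)
        assert relaxation_ratio(58.0, 3300.0, 0.7) == pytest.approx(16.93, rel=1e-3)
        assert relaxation_ratio(10.0, 999.0, 0.0) == 1.0
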