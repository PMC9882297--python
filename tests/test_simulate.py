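"""Synthetic-data generators: polymer physics, state kinetics, measurement."""

import math

import numpy as np
import pytest
from scipy.special import erf

from locusdyn import (
    MeasurementModel,
    SimulationConfig,
    StateKinetics,
    SurrogateConfig,
    apply_measurement,
    equilibrium_chain_distances,
    msd_single,
    overlay_state_process,
    powerlaw_fit,
    sample_gaussian_chain_contacts,
    simulate_rouse_chain,
    simulate_surrogate_pair,
)
from locusdyn.simulate import O_OFF, P_OFF, P_ON, gaussian_contact_probability


class TestRouseChain:
    def test_config_invariants(self):
        with pytest.raises(ValueError, match="dt"):
            SimulationConfig(dt=0.5, bond_relaxation=1.0)
        with pytest.raises(ValueError, match="n_beads"):
            SimulationConfig(n_beads=8, separations=(200.0,))
        with pytest.raises(ValueError, match="integer multiple"):
            SimulationConfig(frame_interval=0.25, dt=0.1)

    def test_noiseless_limit_relaxes_monotonically(self):
        cfg = SimulationConfig(
            n_beads=32, separations=(80.0,), duration=64.0, n_trajectories=40,
            noise_scale=0.0, seed=1,
        )
        trajs = simulate_rouse_chain(cfg)
        r2 = np.mean(
            [np.sum(t.separation_vector() ** 2, axis=1) for t in trajs], axis=0
        )
        # ensemble-mean squared distance is a sum of decaying modes
        assert np.all(np.diff(r2) < 1e-9)
        assert r2[-1] < 0.5 * r2[0]

    def test_dumbbell_is_ornstein_uhlenbeck(self):
        # relative coordinate of a 2-bead chain: per-axis OU with
        # relaxation time t_b / 2
        # fine dt: the Euler scheme's stationary variance is inflated by
        # ~lambda*dt/2, so dt = t_b/100 keeps the discretization bias ~1%
        cfg = SimulationConfig(
            n_beads=2, separations=(10.0,), bond_relaxation=1.0, dt=0.01,
            frame_interval=0.5, duration=320.0, n_trajectories=100, seed=2,
        )
        trajs = simulate_rouse_chain(cfg)
        x = np.array([t.separation_vector()[:, 0] for t in trajs])
        var = x.var()
        assert var == pytest.approx(cfg.bond_scale**2 / 3.0, rel=0.05)
        for lag_frames in (1, 2, 4):
            acfs = np.mean(x[:, lag_frames:] * x[:, :-lag_frames], axis=1) / var
            expected = math.exp(-2.0 * lag_frames * 0.5 / cfg.bond_relaxation)
            se = acfs.std(ddof=1) / math.sqrt(len(acfs))
            assert abs(acfs.mean() - expected) < 3 * se + 0.01

    def test_equilibrium_interbead_distance(self):
        cfg = SimulationConfig(
            n_beads=64, separations=(80.0, 160.0, 320.0), duration=32.0,
            n_trajectories=150, seed=3,
        )
        trajs = simulate_rouse_chain(cfg)
        # <R^2> between beads m apart is m b^2; linear in m with slope b^2
        ms, r2s = [], []
        for s in cfg.separations:
            group = [t for t in trajs if t.separation_kb == s]
            ms.append(group[0].meta["bead_separation"])
            r2s.append(
                np.mean([np.sum(t.separation_vector() ** 2, axis=1) for t in group])
            )
        slope = np.polyfit(ms, r2s, 1)[0]
        assert slope == pytest.approx(cfg.bond_scale**2, rel=0.05)

    def test_central_bead_subdiffusion_exponent(self):
        cfg = SimulationConfig(
            n_beads=64, separations=(80.0,), duration=256.0, n_trajectories=50,
            seed=4,
        )
        trajs = simulate_rouse_chain(cfg)
        m1 = msd_single(trajs, locus="a", n_boot=50)
        fit = powerlaw_fit(m1.lags[1:50], m1.values[1:50], m1.se[1:50])
        assert abs(fit.exponent - 0.5) < 0.05

    def test_unstable_integration_raises(self):
        cfg = SimulationConfig(seed=5, duration=48.0, n_trajectories=2)
        cfg.dt = 1.5  # bypass the config guard to exercise the runtime check
        cfg.frame_interval = 3.0
        with pytest.raises(FloatingPointError):
            simulate_rouse_chain(cfg)

    def test_bit_identical_for_fixed_seed(self):
        cfg = SimulationConfig(
            n_beads=16, separations=(40.0,), duration=16.0, n_trajectories=3, seed=6
        )
        a = simulate_rouse_chain(cfg)
        b = simulate_rouse_chain(cfg)
        np.testing.assert_array_equal(a[0].pos_a, b[0].pos_a)
        np.testing.assert_array_equal(a[-1].pos_b, b[-1].pos_b)


class TestSurrogate:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SurrogateConfig(beta=1.5)
        with pytest.raises(ValueError):
            SurrogateConfig(inv_d=0.0)

    def test_lag_zero_variance_matches_r2(self):
        cfg = SurrogateConfig(seed=1, n_trajectories=200, separations=(149.0,))
        trajs = simulate_surrogate_pair(cfg)
        r2 = np.mean([np.sum(t.separation_vector() ** 2, axis=1) for t in trajs])
        truth = cfg.mean_square_distance(149.0)
        assert r2 == pytest.approx(truth, rel=0.05)

    def test_autocovariance_matches_target(self):
        cfg = SurrogateConfig(seed=2, n_trajectories=300, separations=(190.0,))
        trajs = simulate_surrogate_pair(cfg)
        tau, r2 = cfg.tau(190.0), cfg.mean_square_distance(190.0)
        R = np.array([t.separation_vector() for t in trajs])  # (n, T, 3)
        for lag in range(1, 21):
            emp = np.mean(np.sum(R[:, lag:] * R[:, :-lag], axis=2), axis=1)
            target = r2 * math.exp(-((lag * 28.0 / tau) ** cfg.beta))
            se = emp.std(ddof=1) / math.sqrt(len(emp))
            assert abs(emp.mean() - target) < 4 * se

    def test_markovian_limit_is_ou(self):
        cfg = SurrogateConfig(beta=1.0, seed=3, n_trajectories=300, separations=(149.0,))
        trajs = simulate_surrogate_pair(cfg)
        tau, r2 = cfg.tau(149.0), cfg.mean_square_distance(149.0)
        x = np.array([t.separation_vector()[:, 0] for t in trajs])
        var = x.var()
        assert var == pytest.approx(r2 / 3.0, rel=0.05)
        for lag in (1, 3):
            emp = np.mean(x[:, lag:] * x[:, :-lag]) / var
            assert emp == pytest.approx(math.exp(-lag * 28.0 / tau), abs=0.03)

    def test_single_locus_msd_is_power_law(self):
        # locus positions are built so M1 = Gamma(s) t^beta exactly
        cfg = SurrogateConfig(seed=4, n_trajectories=150, separations=(330.0,))
        trajs = simulate_surrogate_pair(cfg)
        m1 = msd_single(trajs, n_boot=50)
        pred = cfg.diffusivity(330.0) * m1.lags**cfg.beta
        np.testing.assert_allclose(m1.values[:20], pred[:20], rtol=0.1)

    def test_relaxation_exponent_recovery(self):
        # plug-in identity gamma = (2 inv_d - alpha)/beta on generator truth
        cfg = SurrogateConfig(seed=5)
        taus = np.array([cfg.tau(s) for s in cfg.separations])
        fit = powerlaw_fit(np.array(cfg.separations), taus)
        assert fit.exponent == pytest.approx((2 * 0.31 - 0.27) / 0.52, abs=1e-9)

    def test_bit_identical_for_fixed_seed(self):
        cfg = SurrogateConfig(seed=6, n_trajectories=3, separations=(58.0,))
        a = simulate_surrogate_pair(cfg)
        b = simulate_surrogate_pair(cfg)
        np.testing.assert_array_equal(a[1].pos_a, b[1].pos_a)


class TestStateOverlay:
    def _open_trajs(self, n_traj=50, seed=1, s=149.0):
        cfg = SurrogateConfig(seed=seed, n_trajectories=n_traj, separations=(s,))
        return cfg, simulate_surrogate_pair(cfg)

    def test_zero_pairing_rate_keeps_all_open(self):
        _, trajs = self._open_trajs(10)
        kin = StateKinetics(pairing_rate=0.0)
        rng = np.random.default_rng(0)
        out = [overlay_state_process(t, kin, rng) for t in trajs]
        assert all((t.states == O_OFF).all() for t in out)

    def test_detailed_balance_of_transcription_telegraph(self):
        _, trajs = self._open_trajs(80, seed=2)
        kin = StateKinetics(
            pairing_rate=0.05, unpairing_rate=0.0, on_rate=2e-3, off_rate=2e-3
        )
        rng = np.random.default_rng(1)
        out = [overlay_state_process(t, kin, rng) for t in trajs]
        states = np.concatenate([t.states[32:] for t in out])
        paired = states[states != O_OFF]
        frac_on = (paired == P_ON).mean()
        assert frac_on == pytest.approx(0.5, abs=0.05)

    def test_active_dwell_rate_recovered_by_censored_mle(self):
        # ground-truth P_on dwells are geometric with per-frame hazard
        # 1 - exp(-k dt); the censoring-aware exponential MLE on the
        # extracted dwells recovers the discrete hazard rate within 2 SE
        # (naive interior-dwell averages would be length-biased by the
        # finite recording window)
        from locusdyn import exponential_mle, extract_dwells
        from locusdyn.hmm import StatePath

        _, trajs = self._open_trajs(400, seed=3)
        kin = StateKinetics(pairing_rate=0.05, off_rate=4e-3)
        rng = np.random.default_rng(2)
        out = [overlay_state_process(t, kin, rng) for t in trajs]
        paths = [
            StatePath(
                traj_id=t.traj_id, separation_kb=t.separation_kb, states=t.states,
                posteriors=np.zeros((t.n_frames, 3)), missing=t.missing,
                frame_interval=t.frame_interval, log_likelihood=0.0,
            )
            for t in out
        ]
        mle = exponential_mle(extract_dwells(paths), state=P_ON)
        assert mle["n_events"] > 400
        dt = 28.0
        rate_disc = (1.0 - math.exp(-kin.off_rate * dt)) / dt
        se = mle["rate"] / math.sqrt(mle["n_events"])
        assert abs(mle["rate"] - rate_disc) < 2 * se

    def test_no_direct_open_to_on_transitions(self):
        _, trajs = self._open_trajs(50, seed=4)
        kin = StateKinetics(pairing_rate=0.05)
        rng = np.random.default_rng(3)
        out = [overlay_state_process(t, kin, rng) for t in trajs]
        for t in out:
            jumps = set(zip(t.states[:-1], t.states[1:]))
            assert (O_OFF, P_ON) not in jumps and (P_ON, O_OFF) not in jumps

    def test_large_capture_radius_warns(self):
        _, trajs = self._open_trajs(2, seed=5)
        kin = StateKinetics(capture_radius=5000.0, pairing_rate=0.01)
        with pytest.warns(UserWarning, match="proximity"):
            overlay_state_process(trajs[0], kin, np.random.default_rng(0))


class TestMeasurement:
    def test_identity_when_noiseless(self):
        cfg = SurrogateConfig(seed=1, n_trajectories=2, separations=(58.0,))
        traj = simulate_surrogate_pair(cfg)[0]
        model = MeasurementModel(sigma_loc=0.0, missing_prob=0.0)
        out = apply_measurement(traj, model, np.random.default_rng(0))
        np.testing.assert_array_equal(out.pos_a, traj.pos_a)
        np.testing.assert_array_equal(out.missing, traj.missing)

    def test_noise_on_coincident_pair_gives_chi_distance(self, rng):
        # true distance 0, per-locus noise 30 nm/axis: the observed distance
        # is the norm of a 3-D Gaussian with per-axis sd 30*sqrt(2)
        from conftest import make_trajectory

        n = 4000
        traj = make_trajectory(np.zeros((n, 3)), np.zeros((n, 3)))
        model = MeasurementModel(sigma_loc=30.0, missing_prob=0.0)
        out = apply_measurement(traj, model, rng)
        dist = np.linalg.norm(out.pos_a - out.pos_b, axis=1)
        # Monte-Carlo oracle for the same radial distribution
        oracle = np.linalg.norm(
            np.random.default_rng(99).normal(0, 30 * math.sqrt(2), (200000, 3)), axis=1
        )
        se = dist.std(ddof=1) / math.sqrt(n)
        assert abs(dist.mean() - oracle.mean()) < 3 * se

    def test_missing_fraction_binomial(self, rng):
        from conftest import make_trajectory

        n = 5000
        traj = make_trajectory(np.zeros((n, 3)), np.zeros((n, 3)))
        model = MeasurementModel(missing_prob=0.2)
        out = apply_measurement(traj, model, rng)
        frac = out.missing.mean()
        assert abs(frac - 0.2) < 3 * math.sqrt(0.2 * 0.8 / n)

    def test_intensity_follows_state(self, rng):
        from conftest import make_trajectory

        n = 2000
        states = np.zeros(n, dtype=int)
        states[n // 2 :] = P_ON
        traj = make_trajectory(np.zeros((n, 3)), np.zeros((n, 3)), states=states)
        model = MeasurementModel(missing_prob=0.0)
        out = apply_measurement(traj, model, rng)
        assert out.intensity[: n // 2].mean() == pytest.approx(100.0, abs=3.0)
        assert out.intensity[n // 2 :].mean() == pytest.approx(300.0, abs=5.0)


class TestChainStatics:
    def test_contact_probability_closed_form(self):
        # a = 1: P = erf(1) - (2/sqrt(pi)) e^-1 ~= 0.4276
        sigma = 100.0
        rc = sigma * math.sqrt(2.0)
        p = gaussian_contact_probability(rc, sigma)
        assert p == pytest.approx(erf(1) - 2 / math.sqrt(math.pi) * math.exp(-1), abs=1e-12)
        assert p == pytest.approx(0.4276, abs=2e-4)

    def test_monte_carlo_matches_closed_form(self):
        tab = sample_gaussian_chain_contacts(
            [80.0, 320.0], capture_radius=300.0, n_samples=200_000, seed=1
        )
        for _, row in tab.iterrows():
            assert abs(row.p_contact_mc - row.p_contact_closed) < 3 * row.se

    def test_huge_capture_radius_gives_unity(self):
        tab = sample_gaussian_chain_contacts(
            [80.0, 160.0], capture_radius=1e9, n_samples=1000, seed=2
        )
        assert (tab.p_contact_mc == 1.0).all()

    def test_invalid_capture_radius(self):
        with pytest.raises(ValueError):
            sample_gaussian_chain_contacts([80.0], capture_radius=0.0)

    def test_equilibrium_mean_distance_scaling(self):
        tab = equilibrium_chain_distances(96, [8, 16, 32, 64], n_samples=5000, seed=3)
        fit = powerlaw_fit(tab.bead_separation, tab.mean_distance, tab.se)
        assert fit.exponent == pytest.approx(0.5, abs=0.03)
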