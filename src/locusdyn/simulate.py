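"""Synthetic two-locus trajectory generators with known ground truth.

Two generators are provided:

* :func:`simulate_rouse_chain` — overdamped Brownian dynamics of an ideal
  bead-spring (Rouse) chain, the reference polymer model with local
  friction.  It predicts a single-locus MSD exponent beta = 1/2, an
  equilibrium mean-square inter-bead distance <R^2> = m * b^2 for beads m
  apart, and a relaxation-time scaling tau ~ s^2.

* :func:`simulate_surrogate_pair` — a tunable stationary Gaussian-process
  surrogate for the anomalous regime actually measured in embryos: the
  separation vector has autocovariance (<R^2>/3) * exp(-(t/tau)**beta) per
  axis, so the two-locus MSD grows as 2*Gamma*t**beta at short lags and
  plateaus at 2*<R^2>, with tau = (<R^2>/Gamma)**(1/beta).

On top of either, :func:`overlay_state_process` adds the three-state
(O_off/P_off/P_on) pairing/transcription kinetics, and
:func:`apply_measurement` adds localization noise, missing frames, and the
intensity channel.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import erf

from .config import MeasurementModel, SimulationConfig, StateKinetics, SurrogateConfig
from .trajectory import TwoLocusTrajectory

__all__ = [
    "simulate_rouse_chain",
    "simulate_surrogate_pair",
    "overlay_state_process",
    "apply_measurement",
    "sample_gaussian_chain_contacts",
    "equilibrium_chain_distances",
    "O_OFF",
    "P_OFF",
    "P_ON",
]

O_OFF, P_OFF, P_ON = 0, 1, 2


# ---------------------------------------------------------------------------
# Rouse bead-spring chain
# ---------------------------------------------------------------------------


def _equilibrium_chain(n_traj: int, n_beads: int, b: float, rng) -> np.ndarray:
    """Exact Gaussian equilibrium ensemble: iid bond vectors, sd b/sqrt(3)."""
    bonds = rng.normal(0.0, b / math.sqrt(3.0), size=(n_traj, n_beads - 1, 3))
    pos = np.zeros((n_traj, n_beads, 3))
    np.cumsum(bonds, axis=1, out=pos[:, 1:])
    pos -= pos.mean(axis=1, keepdims=True)
    return pos


def simulate_rouse_chain(config: SimulationConfig, rng=None):
    """Brownian dynamics of an ideal bead-spring chain; returns tagged pairs.

    One chain ensemble is simulated and, for every requested genomic
    separation, the pair of beads symmetric about the chain center at the
    corresponding bead separation is recorded per frame.  Ground-truth
    quantities (b, bond relaxation time, theoretical <R^2> and two-locus
    short-time diffusivity) are stored in each trajectory's ``meta``.

    Euler--Maruyama with per-axis drift -(1/t_b) * (graph Laplacian) x and
    noise amplitude sqrt(2 D dt); the config enforces dt <= t_b/10 which
    keeps the scheme stable (stability bound dt < t_b/2).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration / config.frame_interval))
    steps_per_frame = int(round(config.frame_interval / config.dt))
    n_beads = config.n_beads
    b = config.bond_scale
    t_b = config.bond_relaxation
    D = config.diffusivity
    dt = config.dt
    n_traj = config.n_trajectories

    pos = _equilibrium_chain(n_traj, n_beads, b, rng)

    bead_seps = config.bead_separations()
    tag_pairs = []
    for m in bead_seps:
        i0 = (n_beads - m) // 2
        tag_pairs.append((i0, i0 + m))

    out = {
        m: (np.empty((n_traj, n_frames, 3)), np.empty((n_traj, n_frames, 3)))
        for m in bead_seps
    }

    drift_fac = dt / t_b
    noise_amp = config.noise_scale * math.sqrt(2.0 * D * dt)
    for frame in range(n_frames):
        for _ in range(steps_per_frame):
            lap = np.empty_like(pos)
            lap[:, 1:-1] = 2.0 * pos[:, 1:-1] - pos[:, :-2] - pos[:, 2:]
            lap[:, 0] = pos[:, 0] - pos[:, 1]
            lap[:, -1] = pos[:, -1] - pos[:, -2]
            pos -= drift_fac * lap
            if noise_amp > 0.0:
                pos += noise_amp * rng.standard_normal(pos.shape)
        if not np.all(np.isfinite(pos)) or float(np.abs(pos).max()) > 1e9 * b:
            raise FloatingPointError(
                "Rouse integration diverged; reduce dt relative to "
                "bond_relaxation"
            )
        for m, (i, j) in zip(bead_seps, tag_pairs):
            out[m][0][:, frame] = pos[:, i]
            out[m][1][:, frame] = pos[:, j]

    times = np.arange(n_frames) * config.frame_interval
    gamma_single = 2.0 * b**2 / math.sqrt(math.pi * t_b)  # M1 = gamma_single sqrt(t)
    trajectories = []
    for m, s_kb in zip(bead_seps, config.separations):
        pa, pb = out[m]
        for k in range(n_traj):
            trajectories.append(
                TwoLocusTrajectory(
                    traj_id=f"rouse-s{s_kb:g}-{k:04d}",
                    embryo_id="sim",
                    separation_kb=float(s_kb),
                    times=times.copy(),
                    pos_a=pa[k],
                    pos_b=pb[k],
                    intensity=np.zeros(n_frames),
                    missing=np.zeros(n_frames, dtype=bool),
                    frame_interval=config.frame_interval,
                    meta={
                        "generator": "rouse",
                        "bead_separation": m,
                        "true_r2": m * b**2,
                        # M1 = Gamma sqrt(t); M2 = 2 Gamma sqrt(t) for
                        # independently diffusing loci, so the two-locus
                        # diffusivity equals the single-locus one
                        "true_gamma": gamma_single,
                        "true_tau": (m * b**2 / gamma_single) ** 2,
                        "bond_scale": b,
                        "bond_relaxation": t_b,
                    },
                )
            )
    return trajectories


# ---------------------------------------------------------------------------
# Gaussian-process surrogate
# ---------------------------------------------------------------------------


def _cholesky_psd(cov: np.ndarray, what: str) -> np.ndarray:
    jitter = 1e-10 * float(np.max(np.abs(np.diag(cov))) or 1.0)
    for _ in range(6):
        try:
            return sla.cholesky(cov + jitter * np.eye(len(cov)), lower=True)
        except sla.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError(
        f"{what} covariance is not positive definite on the requested frame "
        "grid; shorten the duration or adjust beta/tau"
    )


def simulate_surrogate_pair(config: SurrogateConfig, rng=None):
    """Sample two-locus trajectories from the stationary GP surrogate.

    The separation vector R(t) is exactly stationary with per-axis
    autocovariance (<R^2>(s)/3) * exp(-(t/tau(s))**beta).  When
    ``include_locus_motion`` is set, per-locus positions are synthesized as
    r_A = U + R/2, r_B = U - R/2 with an independent common-mode process U
    chosen so that the single-locus MSD is exactly Gamma(s) * t**beta; this
    makes the velocity cross-correlation intercept obey the increment
    identity Cvv(0)/Cv(0) = 1 - M2(delta) / (2 M1(delta)) by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration / config.frame_interval))
    times = np.arange(n_frames) * config.frame_interval
    trajectories = []
    for s in config.separations:
        r2 = config.mean_square_distance(s)
        gam = config.diffusivity(s)
        tau = config.tau(s)
        lagmat = np.abs(times[:, None] - times[None, :])
        cov_r = (r2 / 3.0) * np.exp(-((lagmat / tau) ** config.beta))
        chol_r = _cholesky_psd(cov_r, f"separation-vector (s={s} kb)")

        chol_u = None
        if config.include_locus_motion:
            # per-axis increment variance of the common-mode process U:
            # psi_u(t) = (Gamma t^beta - M2(t)/4) / 3  with
            # M2(t) = 2 r2 (1 - exp(-(t/tau)^beta))
            def psi_u(t):
                m2 = 2.0 * r2 * (1.0 - np.exp(-((t / tau) ** config.beta)))
                return (gam * t**config.beta - m2 / 4.0) / 3.0

            psi = psi_u(lagmat)
            psi_t = psi_u(times)
            cov_u = 0.5 * (psi_t[:, None] + psi_t[None, :] - psi)
            # U(0) = 0: first row/col are zero; factor the submatrix
            chol_u = _cholesky_psd(cov_u[1:, 1:], f"common-mode (s={s} kb)")

        for k in range(config.n_trajectories):
            z = rng.standard_normal((n_frames, 3))
            R = chol_r @ z
            if chol_u is not None:
                zu = rng.standard_normal((n_frames - 1, 3))
                U = np.zeros((n_frames, 3))
                U[1:] = chol_u @ zu
            else:
                U = np.zeros((n_frames, 3))
            trajectories.append(
                TwoLocusTrajectory(
                    traj_id=f"surr-s{s:g}-{k:04d}",
                    embryo_id="sim",
                    separation_kb=float(s),
                    times=times.copy(),
                    pos_a=U + R / 2.0,
                    pos_b=U - R / 2.0,
                    intensity=np.zeros(n_frames),
                    missing=np.zeros(n_frames, dtype=bool),
                    frame_interval=config.frame_interval,
                    meta={
                        "generator": "surrogate",
                        "true_r2": r2,
                        "true_gamma": gam,
                        "true_tau": tau,
                        "true_beta": config.beta,
                    },
                )
            )
    return trajectories


# ---------------------------------------------------------------------------
# State kinetics overlay
# ---------------------------------------------------------------------------


def overlay_state_process(traj: TwoLocusTrajectory, kinetics: StateKinetics, rng):
    """Overlay the three-state pairing/transcription kinetics on a trajectory.

    The input trajectory provides the open-state (O_off) motion.  Pairing
    (O_off -> P_off) fires with ``kinetics.pairing_rate`` only while the
    instantaneous open-state distance is below the capture radius --
    encounter is limited by the time taken to diffuse into proximity.  While
    paired, the separation vector is replaced by an OU tether around zero
    whose stationary mean distance equals ``tether_center``; the locus
    midpoint keeps following the open-state motion.  P_off <-> P_on is a
    rate telegraph; direct O_off <-> P_on transitions never occur.

    Returns a new trajectory whose ``states`` array is the ground truth.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if traj.states is not None:
        raise ValueError("trajectory already carries a state path")
    dt = traj.frame_interval
    n = traj.n_frames
    R_open = traj.separation_vector()
    mid = 0.5 * (traj.pos_a + traj.pos_b)

    typical = np.sqrt(np.nanmean(np.sum(R_open**2, axis=1)))
    if kinetics.capture_radius > typical:
        warnings.warn(
            "capture radius exceeds the typical inter-locus distance; "
            "pairing is no longer proximity-limited",
            stacklevel=2,
        )

    p_pair = 1.0 - math.exp(-kinetics.pairing_rate * dt)
    sigma = kinetics.tether_sigma
    rho = math.exp(-dt / kinetics.tether_relaxation)

    states = np.empty(n, dtype=int)
    R_out = R_open.copy()
    state = O_OFF
    R_teth = np.zeros(3)
    for k in range(n):
        states[k] = state
        if state != O_OFF:
            R_out[k] = R_teth
        # advance to next frame
        if k == n - 1:
            break
        if state == O_OFF:
            r = np.linalg.norm(R_open[k])
            if np.isfinite(r) and r < kinetics.capture_radius and rng.random() < p_pair:
                state = P_OFF
                R_teth = rng.normal(0.0, sigma, size=3)
            continue
        # paired: evolve the tether and the telegraph
        R_teth = rho * R_teth + math.sqrt(max(0.0, 1 - rho**2)) * sigma * rng.normal(
            0.0, 1.0, size=3
        )
        if state == P_OFF:
            total = kinetics.unpairing_rate + kinetics.on_rate
            if total > 0 and rng.random() < 1.0 - math.exp(-total * dt):
                if rng.random() < kinetics.unpairing_rate / total:
                    state = O_OFF
                else:
                    state = P_ON
        elif state == P_ON:
            if rng.random() < 1.0 - math.exp(-kinetics.off_rate * dt):
                state = P_OFF

    pos_a = mid + R_out / 2.0
    pos_b = mid - R_out / 2.0
    return TwoLocusTrajectory(
        traj_id=traj.traj_id,
        embryo_id=traj.embryo_id,
        separation_kb=traj.separation_kb,
        times=traj.times.copy(),
        pos_a=pos_a,
        pos_b=pos_b,
        intensity=traj.intensity.copy(),
        missing=traj.missing.copy(),
        frame_interval=traj.frame_interval,
        states=states,
        meta=dict(traj.meta),
    )


def apply_measurement(traj: TwoLocusTrajectory, model: MeasurementModel, rng):
    """Apply the measurement model: localization noise, dropouts, intensity.

    Isotropic Gaussian localization noise (sd ``sigma_loc`` per axis) is
    added independently to each locus; frames are masked missing with
    probability ``missing_prob``; the intensity channel is drawn from the
    active distribution on P_on frames and from the background otherwise.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = traj.n_frames
    pos_a = traj.pos_a + rng.normal(0.0, model.sigma_loc, size=(n, 3))
    pos_b = traj.pos_b + rng.normal(0.0, model.sigma_loc, size=(n, 3))
    active = traj.states == P_ON if traj.states is not None else np.zeros(n, bool)
    intensity = np.where(
        active,
        rng.normal(model.active_mean, model.active_sd, size=n),
        rng.normal(model.background_mean, model.background_sd, size=n),
    )
    missing = traj.missing | (rng.random(n) < model.missing_prob)
    return TwoLocusTrajectory(
        traj_id=traj.traj_id,
        embryo_id=traj.embryo_id,
        separation_kb=traj.separation_kb,
        times=traj.times.copy(),
        pos_a=pos_a,
        pos_b=pos_b,
        intensity=intensity,
        missing=missing,
        frame_interval=traj.frame_interval,
        states=None if traj.states is None else traj.states.copy(),
        meta=dict(traj.meta),
    )


# ---------------------------------------------------------------------------
# Equilibrium Gaussian-chain statics
# ---------------------------------------------------------------------------


def gaussian_contact_probability(r_c: float, sigma_axis: float) -> float:
    """Closed-form P(|R| < r_c) for an isotropic 3-D Gaussian vector.

    ``sigma_axis`` is the per-axis standard deviation.  With
    a = r_c / (sigma * sqrt(2)):  P = erf(a) - (2 a / sqrt(pi)) exp(-a^2).
    """
    a = r_c / (sigma_axis * math.sqrt(2.0))
    return float(erf(a) - (2.0 * a / math.sqrt(math.pi)) * math.exp(-(a**2)))


def sample_gaussian_chain_contacts(
    separations_kb,
    capture_radius: float,
    n_samples: int = 100_000,
    seed: int = 0,
    bond_scale: float = 200.0,
    kb_per_bond: float = 10.0,
) -> pd.DataFrame:
    """Monte-Carlo contact frequencies of an ideal (Gaussian) chain.

    For each genomic separation s the end-to-end vector between loci
    m = s / kb_per_bond bonds apart is Gaussian with per-axis variance
    m * b^2 / 3; the contact probability P(|R| < r_c) is estimated by Monte
    Carlo and returned alongside the closed form.  In the small-r_c regime
    P ~ s^(-3/2): the ideal-chain contact exponent f = 3/2.
    """
    if capture_radius <= 0:
        raise ValueError("capture radius must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for s in separations_kb:
        m = s / kb_per_bond
        sigma = bond_scale * math.sqrt(m / 3.0)
        r = np.linalg.norm(rng.normal(0.0, sigma, size=(n_samples, 3)), axis=1)
        hits = int(np.count_nonzero(r < capture_radius))
        p_mc = hits / n_samples
        se = math.sqrt(max(p_mc * (1 - p_mc), 1e-300) / n_samples)
        rows.append(
            {
                "s_kb": s,
                "p_contact_mc": p_mc,
                "p_contact_closed": gaussian_contact_probability(
                    capture_radius, sigma
                ),
                "se": se,
                "n_samples": n_samples,
            }
        )
    return pd.DataFrame(rows)


def equilibrium_chain_distances(
    n_beads: int,
    bead_separations,
    n_samples: int = 20_000,
    bond_scale: float = 200.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean inter-bead distance <R> versus bead separation at equilibrium.

    Draws ``n_samples`` exact Gaussian-chain configurations and measures the
    distance between bead pairs symmetric about the chain center.  For an
    ideal chain <R> ~ m^(1/2), i.e. fractal dimension d = 2.
    """
    rng = np.random.default_rng(seed)
    pos = _equilibrium_chain(n_samples, n_beads, bond_scale, rng)
    rows = []
    for m in bead_separations:
        if m >= n_beads:
            raise ValueError(f"bead separation {m} exceeds chain length")
        i0 = (n_beads - m) // 2
        r = np.linalg.norm(pos[:, i0 + m] - pos[:, i0], axis=1)
        rows.append(
            {
                "bead_separation": m,
                "mean_distance": float(r.mean()),
                "se": float(r.std(ddof=1) / math.sqrt(n_samples)),
                "mean_square_distance": float((r**2).mean()),
            }
        )
    return pd.DataFrame(rows)
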