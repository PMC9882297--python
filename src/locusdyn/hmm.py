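"""Hidden Markov inference of the topological/transcriptional state path.

The latent state at each frame is one of O_off (open, silent), P_off
(paired, silent), P_on (paired, transcribing).  Observations are the
scalar inter-locus distance and the transcription intensity.

Emission model
--------------
* Distance: Maxwell-type radial density — the magnitude of an isotropic
  3-D Gaussian displacement — with a state-specific scale sigma:
  ``p(r) = sqrt(2/pi) * r^2 / sigma^3 * exp(-r^2 / (2 sigma^2))``.
  This has the correct r^2-weighted small-r behavior of 3-D distances.
  The open-state scale exceeds the paired scales (label anchoring).
* Intensity: Gaussian; background component shared by O_off and P_off,
  active component for P_on.

Direct O_off <-> P_on transitions are structurally forbidden (a loop must
form before transcription can start).  Masked frames contribute unit
emission likelihood, i.e. they are marginalized over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import O_OFF, P_OFF, P_ON
from .trajectory import TwoLocusTrajectory, compute_distance

__all__ = [
    "HMMParams",
    "StatePath",
    "fit_hmm",
    "decode_states",
    "state_occupancy",
    "sample_from_hmm",
    "STATE_NAMES",
]

STATE_NAMES = ("O_off", "P_off", "P_on")
N_STATES = 3
_FORBIDDEN = [(O_OFF, P_ON), (P_ON, O_OFF)]


@dataclass
class HMMParams:
    """Parameters of the three-state distance+intensity HMM."""

    startprob: np.ndarray                 # (3,)
    transmat: np.ndarray                  # (3, 3); [O_off, P_on] entries are 0
    sigma: np.ndarray                     # (3,) Maxwell scale per state, nm
    intensity_bg: tuple[float, float]     # mean, sd (shared by O_off, P_off)
    intensity_on: tuple[float, float]     # mean, sd (P_on)
    log_likelihood: float = -np.inf
    converged: bool = False
    n_iter: int = 0
    flags: list = field(default_factory=list)
    loglik_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.startprob = np.asarray(self.startprob, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("transition matrix rows must sum to 1")
        for i, j in _FORBIDDEN:
            if self.transmat[i, j] != 0.0:
                raise ValueError("direct O_off <-> P_on transitions are forbidden")


@dataclass
class StatePath:
    """Decoded state path for one trajectory."""

    traj_id: str
    separation_kb: float
    states: np.ndarray          # (n,) Viterbi path
    posteriors: np.ndarray      # (n, 3) forward-backward marginals
    missing: np.ndarray         # (n,) bool
    frame_interval: float
    log_likelihood: float


def _maxwell_logpdf(r: np.ndarray, sigma: float) -> np.ndarray:
    r = np.maximum(r, 1e-12)
    return (
        0.5 * math.log(2.0 / math.pi)
        + 2.0 * np.log(r)
        - 3.0 * math.log(sigma)
        - r**2 / (2.0 * sigma**2)
    )


def _normal_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    sd = max(sd, 1e-12)
    return -0.5 * math.log(2.0 * math.pi) - math.log(sd) - (x - mean) ** 2 / (
        2.0 * sd**2
    )


def _emission_loglik(r, intensity, missing, params: HMMParams) -> np.ndarray:
    """(n, 3) log emission likelihoods; masked frames contribute 0."""
    n = len(r)
    logb = np.zeros((n, N_STATES))
    obs = ~missing
    bg_m, bg_s = params.intensity_bg
    on_m, on_s = params.intensity_on
    for k in range(N_STATES):
        logb[obs, k] = _maxwell_logpdf(r[obs], params.sigma[k])
    li_bg = _normal_logpdf(intensity[obs], bg_m, bg_s)
    li_on = _normal_logpdf(intensity[obs], on_m, on_s)
    logb[obs, O_OFF] += li_bg
    logb[obs, P_OFF] += li_bg
    logb[obs, P_ON] += li_on
    return logb


def _forward_backward(logb: np.ndarray, params: HMMParams):
    """Scaled forward-backward. Returns (gamma, xi_sum, loglik)."""
    n = len(logb)
    A = params.transmat
    b = np.exp(logb - logb.max(axis=1, keepdims=True))
    logoff = logb.max(axis=1)
    alpha = np.empty((n, N_STATES))
    scale = np.empty(n)
    alpha[0] = params.startprob * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ A) * b[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.empty((n, N_STATES))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((N_STATES, N_STATES))
    for t in range(n - 1):
        xi = (
            alpha[t][:, None]
            * A
            * (b[t + 1] * beta[t + 1])[None, :]
            / scale[t + 1]
        )
        xi_sum += xi
    loglik = float(np.log(scale).sum() + logoff.sum())
    return gamma, xi_sum, loglik


def _viterbi(logb: np.ndarray, params: HMMParams):
    n = len(logb)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transmat)
        logpi = np.log(params.startprob)
    delta = np.empty((n, N_STATES))
    psi = np.zeros((n, N_STATES), dtype=int)
    delta[0] = logpi + logb[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + logA
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(N_STATES)] + logb[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path, float(delta[-1].max())


def _observations(traj: TwoLocusTrajectory):
    dist = compute_distance(traj)
    return dist.distance, traj.intensity, traj.missing


def _init_params(r_all, i_all, rng, jitter: float = 0.0) -> HMMParams:
    """Data-driven initialization.

    The active intensity component is split off by quantiles; frames with
    clearly active intensity are certainly paired, so their distances
    anchor the paired scale directly.  Without enough active frames the
    paired scale falls back to the lower distance tercile (and the open
    scale to the upper tercile).
    """
    i_thresh = np.quantile(i_all, 0.90)
    bg = i_all[i_all < i_thresh]
    on = i_all[i_all >= i_thresh]
    bg_m, bg_s = float(bg.mean()), float(bg.std() + 1e-6)
    on_m, on_s = float(on.mean()), float(on.std() + 1e-6)
    if on_m - bg_m < 2 * bg_s:  # no clear active component; spread the guess
        on_m = bg_m + 5 * bg_s
        on_s = 2 * bg_s
    active = i_all > bg_m + 5.0 * bg_s
    if active.sum() >= 30:  # re-estimate the active component from clear calls
        on_m, on_s = float(i_all[active].mean()), float(i_all[active].std() + 1e-6)
    q1, q2 = np.quantile(r_all, [1.0 / 3.0, 2.0 / 3.0])
    if active.sum() >= 30 and on_m - bg_m >= 2 * bg_s:
        sig_paired = math.sqrt(np.mean(r_all[active] ** 2) / 3.0)
        sig_open = math.sqrt(np.mean(r_all[~active & (r_all >= q1)] ** 2) / 3.0)
    else:
        sig_paired = math.sqrt(np.mean(r_all[r_all <= q1] ** 2) / 3.0)
        sig_open = math.sqrt(np.mean(r_all[r_all >= q2] ** 2) / 3.0)
    sigma = np.array([sig_open, sig_paired, sig_paired * 0.95])
    # sticky defaults: topological states persist for many frames
    A = np.array(
        [
            [0.99, 0.01, 0.0],
            [0.03, 0.94, 0.03],
            [0.0, 0.03, 0.97],
        ]
    )
    startprob = np.array([0.8, 0.1, 0.1])
    if jitter > 0:
        sigma = sigma * np.exp(rng.normal(0.0, jitter, size=3))
        bump = rng.uniform(0.01, 0.10, size=3)
        A = np.array(
            [
                [1 - bump[0], bump[0], 0.0],
                [bump[1] / 2, 1 - bump[1], bump[1] / 2],
                [0.0, bump[2], 1 - bump[2]],
            ]
        )
    return HMMParams(
        startprob=startprob,
        transmat=A,
        sigma=sigma,
        intensity_bg=(bg_m, bg_s),
        intensity_on=(on_m, on_s),
    )


def _em(
    observations,
    params: HMMParams,
    max_iter: int,
    tol: float,
    tie_paired_scales: bool = True,
    fixed_paired_scale: float | None = None,
) -> HMMParams:
    loglik_prev = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        start_acc = np.zeros(N_STATES)
        xi_acc = np.zeros((N_STATES, N_STATES))
        occ_r = np.zeros(N_STATES)      # sum gamma over observed frames
        occ_r2 = np.zeros(N_STATES)     # sum gamma * r^2
        w_bg = w_on = 0.0
        s_bg = s_on = 0.0
        ss_bg = ss_on = 0.0
        total_ll = 0.0
        for r, intensity, missing in observations:
            logb = _emission_loglik(r, intensity, missing, params)
            gamma, xi_sum, ll = _forward_backward(logb, params)
            total_ll += ll
            start_acc += gamma[0]
            xi_acc += xi_sum
            obs = ~missing
            g = gamma[obs]
            ro = r[obs]
            io = intensity[obs]
            occ_r += g.sum(axis=0)
            occ_r2 += (g * ro[:, None] ** 2).sum(axis=0)
            wb = g[:, O_OFF] + g[:, P_OFF]
            wo = g[:, P_ON]
            w_bg += wb.sum()
            w_on += wo.sum()
            s_bg += (wb * io).sum()
            s_on += (wo * io).sum()
            ss_bg += (wb * io**2).sum()
            ss_on += (wo * io**2).sum()

        # M step
        startprob = start_acc / start_acc.sum()
        transmat = xi_acc.copy()
        rowsums = transmat.sum(axis=1, keepdims=True)
        rowsums[rowsums == 0] = 1.0
        transmat /= rowsums
        for i, j in _FORBIDDEN:
            transmat[i, j] = 0.0
        transmat /= transmat.sum(axis=1, keepdims=True)
        sigma = np.sqrt(np.maximum(occ_r2 / np.maximum(occ_r, 1e-12) / 3.0, 1e-6))
        if fixed_paired_scale is not None:
            sigma[P_OFF] = sigma[P_ON] = fixed_paired_scale
        elif tie_paired_scales:
            # paired geometry is transcription-independent: share one scale,
            # anchored by the intensity-identified P_on frames
            paired = math.sqrt(
                max(
                    (occ_r2[P_OFF] + occ_r2[P_ON])
                    / max(occ_r[P_OFF] + occ_r[P_ON], 1e-12)
                    / 3.0,
                    1e-6,
                )
            )
            sigma[P_OFF] = sigma[P_ON] = paired
        bg_m = s_bg / max(w_bg, 1e-12)
        on_m = s_on / max(w_on, 1e-12)
        bg_s = math.sqrt(max(ss_bg / max(w_bg, 1e-12) - bg_m**2, 1e-6))
        on_s = math.sqrt(max(ss_on / max(w_on, 1e-12) - on_m**2, 1e-6))
        params = HMMParams(
            startprob=startprob,
            transmat=transmat,
            sigma=sigma,
            intensity_bg=(bg_m, bg_s),
            intensity_on=(on_m, on_s),
            log_likelihood=total_ll,
            n_iter=it,
        )
        history.append(total_ll)
        params.loglik_history = history
        if total_ll - loglik_prev < tol * abs(total_ll) and it > 1:
            converged = True
            break
        loglik_prev = total_ll

    params.converged = converged
    if not converged:
        params.flags.append("unconverged")
    total_occ = occ_r / max(occ_r.sum(), 1e-300)
    for k in range(N_STATES):
        if total_occ[k] < 1e-6:
            params.flags.append(f"degenerate_state_{STATE_NAMES[k]}")
    if params.sigma[O_OFF] <= max(params.sigma[P_OFF], params.sigma[P_ON]):
        params.flags.append("scale_ordering_violated")
    return params


def fit_hmm(
    trajectories,
    init: HMMParams | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 5,
    seed: int = 0,
    tie_paired_scales: bool = True,
    paired_scale: str | float = "anchored",
) -> HMMParams:
    """Fit the HMM by EM (Baum--Welch) jointly over all trajectories.

    The EM log-likelihood is non-decreasing; convergence is declared when
    the relative change drops below ``tol``.  ``n_restarts`` random
    perturbations of the quantile-split initialization are run (fixed
    seed) and the best likelihood kept.  Label switching is resolved by
    anchoring the open state to the largest distance scale at
    initialization; a final ordering violation is flagged, not silently
    relabeled.
    """
    if len(trajectories) < 10:
        raise ValueError("need at least 10 trajectories to fit the HMM")
    observations = [_observations(t) for t in trajectories]
    observations = [(r, i, m) for r, i, m in observations if (~m).sum() > 0]
    r_all = np.concatenate([r[~m] for r, _, m in observations])
    i_all = np.concatenate([i[~m] for _, i, m in observations])
    rng = np.random.default_rng(seed)
    fixed_scale = None
    if isinstance(paired_scale, (int, float)):
        fixed_scale = float(paired_scale)
    elif paired_scale == "anchored":
        probe = _init_params(r_all, i_all, rng)
        bg_m, bg_s = probe.intensity_bg
        active = i_all > bg_m + 5.0 * bg_s
        if active.sum() >= 30:
            fixed_scale = math.sqrt(np.mean(r_all[active] ** 2) / 3.0)
    elif paired_scale != "free":
        raise ValueError("paired_scale must be 'anchored', 'free', or a number")
    candidates = []
    if init is not None:
        candidates.append(init)
    candidates.append(_init_params(r_all, i_all, rng))
    for _ in range(max(0, n_restarts - 1)):
        candidates.append(_init_params(r_all, i_all, rng, jitter=0.15))
    best = None
    for cand in candidates:
        fitted = _em(observations, cand, max_iter=max_iter, tol=tol,
                     tie_paired_scales=tie_paired_scales,
                     fixed_paired_scale=fixed_scale)
        if best is None or fitted.log_likelihood > best.log_likelihood:
            best = fitted
    return best


def decode_states(traj: TwoLocusTrajectory, params: HMMParams) -> StatePath:
    """Forward-backward posteriors and Viterbi path for one trajectory.

    Downstream kinetics use the Viterbi path (``states``); the posterior
    marginals are returned alongside.  An all-masked trajectory yields an
    empty path with a warning.
    """
    r, intensity, missing = _observations(traj)
    if missing.all():
        import warnings

        warnings.warn(f"trajectory {traj.traj_id} is fully masked", stacklevel=2)
        return StatePath(
            traj_id=traj.traj_id,
            separation_kb=traj.separation_kb,
            states=np.empty(0, dtype=int),
            posteriors=np.empty((0, N_STATES)),
            missing=missing.copy(),
            frame_interval=traj.frame_interval,
            log_likelihood=float("nan"),
        )
    logb = _emission_loglik(r, intensity, missing, params)
    gamma, _, loglik = _forward_backward(logb, params)
    path, _ = _viterbi(logb, params)
    return StatePath(
        traj_id=traj.traj_id,
        separation_kb=traj.separation_kb,
        states=path,
        posteriors=gamma,
        missing=missing.copy(),
        frame_interval=traj.frame_interval,
        log_likelihood=loglik,
    )


def state_occupancy(paths, by_separation: bool = True) -> pd.DataFrame:
    """Frame-weighted state occupancies, optionally per genomic separation.

    Only observed (unmasked) frames count.  Occupancies sum to 1 per row.
    """
    rows = {}
    for path in paths:
        key = path.separation_kb if by_separation else "all"
        counts = rows.setdefault(key, np.zeros(N_STATES))
        obs_states = path.states[~path.missing]
        for k in range(N_STATES):
            counts[k] += int((obs_states == k).sum())
    out = []
    for key in sorted(rows):
        counts = rows[key]
        total = counts.sum()
        frac = counts / total if total > 0 else np.full(N_STATES, np.nan)
        out.append(
            {
                "s_kb": key,
                "p_O_off": frac[O_OFF],
                "p_P_off": frac[P_OFF],
                "p_P_on": frac[P_ON],
                "n_frames": int(total),
            }
        )
    return pd.DataFrame(out)


def sample_from_hmm(
    params: HMMParams,
    n_traj: int,
    n_frames: int,
    frame_interval: float = 28.0,
    separation_kb: float = 149.0,
    seed: int = 0,
):
    """Sample trajectories exactly from the HMM generative model.

    Distances are realized as isotropic 3-D Gaussian separation vectors
    (magnitude is then Maxwell with the state scale); frames are iid given
    the state path.  Useful as a ground-truth oracle for fit/decode tests.
    """
    rng = np.random.default_rng(seed)
    trajs = []
    times = np.arange(n_frames) * frame_interval
    bg_m, bg_s = params.intensity_bg
    on_m, on_s = params.intensity_on
    for k in range(n_traj):
        states = np.empty(n_frames, dtype=int)
        states[0] = rng.choice(N_STATES, p=params.startprob)
        for t in range(1, n_frames):
            states[t] = rng.choice(N_STATES, p=params.transmat[states[t - 1]])
        R = rng.standard_normal((n_frames, 3)) * params.sigma[states][:, None]
        intensity = np.where(
            states == P_ON,
            rng.normal(on_m, on_s, size=n_frames),
            rng.normal(bg_m, bg_s, size=n_frames),
        )
        trajs.append(
            TwoLocusTrajectory(
                traj_id=f"hmm-{k:04d}",
                embryo_id="sim",
                separation_kb=separation_kb,
                times=times.copy(),
                pos_a=R / 2.0,
                pos_b=-R / 2.0,
                intensity=intensity,
                missing=np.zeros(n_frames, dtype=bool),
                frame_interval=frame_interval,
                states=states,
            )
        )
    return trajs
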