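"""MSD and correlation estimation, Rouse fitting, and scaling analysis.

The single-locus MSD is M1(t) = <(r_i(t0+t) - r_i(t0))^2>_{t0} = Gamma t^beta;
the two-locus MSD M2(t) = <(R(t0+t) - R(t0))^2>_{t0} of the separation vector
R = r_A - r_B crosses over from independent diffusion, M2 = 2 Gamma t^beta,
to the plateau 2<R^2> at the relaxation time tau = (<R^2>/Gamma)^(1/beta).

For the ideal (Rouse) chain with beta = 1/2 the full crossover has the closed
form

    M2(t) = 2 Gamma t^(1/2) (1 - exp(-tau/(pi t)))
            + 2 J erfc(sqrt(tau/(pi t))),        tau = (J/Gamma)^2,

where J = <R^2> is the plateau half-value.  Fits are Bayesian (emcee) with a
Gaussian likelihood on log-MSD using bootstrap standard errors.

The generalized Rouse relations link statics and dynamics through the fractal
dimension d: beta = 2/(2+d); the relaxation-time scaling tau ~ s^gamma follows
from Gamma tau^beta ~ s^(2/d) as gamma = (2/d - alpha)/beta where alpha is the
diffusivity scaling exponent Gamma(s) ~ s^alpha; and the two-locus
autocorrelation decays as C2 ~ t^lambda with lambda = 2(1-d)/(2+d) for t >> tau.

The velocity cross-correlation of the two loci, coarse-grained on an interval
delta, has a normalized intercept Cvv(0)/Cv(0) that depends only on delta/tau;
for the Rouse form it equals

    exp(-tau/(pi delta)) - sqrt(tau/delta) * erfc(sqrt(tau/(pi delta))),

which follows from the increment identity Cvv(0) = [2 M1(delta) -
M2(delta)] / (2 delta^2) with M1 = Gamma sqrt(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .kinetics import ScalingFit, powerlaw_fit
from .simulate import O_OFF

__all__ = [
    "MSDCurve",
    "CorrelationCurve",
    "RouseFit",
    "VelocityCorr",
    "msd_single",
    "msd_two_locus",
    "rouse_m2",
    "stretched_m2",
    "fit_rouse_m2",
    "autocorr_two_locus",
    "diffusivity_scaling",
    "relaxation_scaling",
    "collapse_gamma",
    "CollapseResult",
    "velocity_corr",
    "predicted_vcc_intercept",
    "theory_exponents",
    "relaxation_ratio",
]


@dataclass
class MSDCurve:
    """Lag-indexed mean squared displacement with bootstrap uncertainty."""

    lags: np.ndarray            # s, positive increasing
    values: np.ndarray          # nm^2
    se: np.ndarray              # nm^2, bootstrap over trajectories
    n_pairs: np.ndarray         # contributing origin pairs per lag
    dimensionality: str = "3d"  # "3d" or "3d-from-xy"
    separation_kb: float | None = None
    bootstrap: np.ndarray | None = None  # (n_boot, n_lags) replicate curves

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive increasing")


@dataclass
class CorrelationCurve:
    """Two-locus autocorrelation C2(t) = <R(t0) . R(t0+t)>_{t0}."""

    lags: np.ndarray
    c2: np.ndarray                  # direct dot-product estimator
    c2_from_msd: np.ndarray         # <R^2>_pairs - M2/2 on the same origin pairs
    r2: float                       # overall <R^2> normalization
    se: np.ndarray
    n_pairs: np.ndarray
    separation_kb: float | None = None


@dataclass
class RouseFit:
    """Posterior summary of a two-locus MSD fit.

    gamma_diff is the two-locus diffusivity Gamma (nm^2/s^beta), plateau is
    J = <R^2> (nm^2), tau = (J/Gamma)^(1/beta) (s).  Credible intervals are
    16-84% (1 sigma) and 2.5-97.5% (95%) posterior quantiles.
    """

    gamma_diff: float
    plateau: float
    tau: float
    beta: float
    model: str                           # "rouse" or "stretched"
    intervals: dict = field(default_factory=dict)
    converged: bool = True
    samples: np.ndarray | None = None    # posterior draws (n, 2 or 3) in log10


@dataclass
class VelocityCorr:
    """Coarse-grained velocity cross/auto-correlations of the locus pair."""

    delta: float
    lags: np.ndarray
    cross: np.ndarray           # Cvv(delta)(t), nm^2/s^2
    auto: np.ndarray            # Cv(delta)(t), averaged over the two loci
    intercept_ratio: float      # Cvv(0)/Cv(0)
    intercept_se: float
    separation_kb: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.intercept_ratio) and abs(self.intercept_ratio) > 1 + 1e-9:
            raise ValueError("normalized intercept must satisfy |ratio| <= 1")


# ---------------------------------------------------------------------------
# MSD estimation
# ---------------------------------------------------------------------------


def _pairwise_msd(x: np.ndarray, max_lag: int):
    """Time-averaged MSD of one track (n, k) with NaN rows as missing.

    Returns per-lag (sum of squared displacements, pair count).
    """
    n = len(x)
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for lag in range(1, max_lag + 1):
        d = x[lag:] - x[:-lag]
        sq = np.sum(d * d, axis=1)
        ok = np.isfinite(sq)
        sums[lag - 1] = np.nansum(sq[ok])
        counts[lag - 1] = int(ok.sum())
    return sums, counts


def _state_masked(track: np.ndarray, traj, states, which) -> np.ndarray:
    if states is None or which is None:
        return track
    path = states[traj.traj_id] if isinstance(states, dict) else states
    labels = path.states if hasattr(path, "states") else np.asarray(path)
    track = track.copy()
    track[labels != which] = np.nan
    return track


def _aggregate_msd(per_traj, lags, n_boot, seed, dimensionality, factor=1.0):
    sums = np.array([s for s, _ in per_traj])
    counts = np.array([c for _, c in per_traj])
    total_counts = counts.sum(axis=0)
    keep = total_counts > 0
    values = np.full(len(lags), np.nan)
    values[keep] = sums.sum(axis=0)[keep] / total_counts[keep] * factor
    rng = np.random.default_rng(seed)
    n = len(per_traj)
    boots = np.full((n_boot, len(lags)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cs = counts[idx].sum(axis=0)
        ok = cs > 0
        boots[b, ok] = sums[idx].sum(axis=0)[ok] / cs[ok] * factor
    se = np.nanstd(boots, axis=0, ddof=1)
    return MSDCurve(
        lags=lags[keep],
        values=values[keep],
        se=se[keep],
        n_pairs=total_counts[keep],
        dimensionality=dimensionality,
        bootstrap=boots[:, keep],
    )


def msd_single(
    trajectories,
    use_xy_only: bool = False,
    locus: str = "both",
    max_lag: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
    states=None,
    state=None,
) -> MSDCurve:
    """Ensemble single-locus MSD M1(t), time-averaged over all origins.

    Each trajectory's overlapping-origin average is combined across the
    ensemble weighted by pair counts; standard errors are a bootstrap over
    trajectories (nuclei).  With ``use_xy_only`` the 3-D MSD is estimated
    as 3/2 times the planar (xy) MSD, assuming isotropy.  ``states`` (dict
    of StatePath by traj_id, or a single path) with ``state`` restricts
    origins to frames decoded in that state.
    """
    dt = trajectories[0].frame_interval
    n_max = max(t.n_frames for t in trajectories)
    if max_lag is None:
        max_lag = n_max - 1
    max_lag = min(max_lag, n_max - 1)
    axes = slice(0, 2) if use_xy_only else slice(0, 3)
    factor = 1.5 if use_xy_only else 1.0
    per_traj = []
    for traj in trajectories:
        tracks = []
        if locus in ("a", "both"):
            tracks.append(traj.pos_a[:, axes])
        if locus in ("b", "both"):
            tracks.append(traj.pos_b[:, axes])
        s = np.zeros(max_lag)
        c = np.zeros(max_lag, dtype=int)
        for track in tracks:
            track = _state_masked(track, traj, states, state)
            si, ci = _pairwise_msd(track, max_lag)
            s += si
            c += ci
        per_traj.append((s, c))
    lags = np.arange(1, max_lag + 1) * dt
    return _aggregate_msd(
        per_traj, lags, n_boot, seed, "3d-from-xy" if use_xy_only else "3d", factor
    )


def msd_two_locus(
    trajectories,
    max_lag: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
    states=None,
    state=None,
) -> MSDCurve:
    """Two-locus MSD M2(t) of the separation vector R(t) = r_A - r_B."""
    dt = trajectories[0].frame_interval
    n_max = max(t.n_frames for t in trajectories)
    if max_lag is None:
        max_lag = n_max - 1
    max_lag = min(max_lag, n_max - 1)
    per_traj = []
    for traj in trajectories:
        track = _state_masked(traj.separation_vector(), traj, states, state)
        per_traj.append(_pairwise_msd(track, max_lag))
    lags = np.arange(1, max_lag + 1) * dt
    curve = _aggregate_msd(per_traj, lags, n_boot, seed, "3d")
    curve.separation_kb = trajectories[0].separation_kb
    return curve


# ---------------------------------------------------------------------------
# Closed forms and Bayesian fitting
# ---------------------------------------------------------------------------


def rouse_m2(t, gamma_diff: float, plateau: float):
    """Ideal-chain two-locus MSD closed form (beta = 1/2).

    M2(t) = 2 Gamma t^(1/2) (1 - exp(-tau/(pi t))) + 2 J erfc(sqrt(tau/(pi t)))
    with tau = (J/Gamma)^2.  Monotone increasing; -> 2 Gamma sqrt(t) for
    t << tau and -> 2 J for t >> tau.
    """
    if gamma_diff <= 0 or plateau <= 0:
        raise ValueError("Gamma and J must be positive")
    t = np.asarray(t, dtype=float)
    tau = (plateau / gamma_diff) ** 2
    x = tau / (math.pi * t)
    return 2.0 * gamma_diff * np.sqrt(t) * (1.0 - np.exp(-x)) + 2.0 * plateau * erfc(
        np.sqrt(x)
    )


def stretched_m2(t, plateau: float, tau: float, beta: float):
    """Stretched-exponential crossover family M2 = 2 J (1 - exp(-(t/tau)^beta)).

    Shares the Rouse asymptotics (2 Gamma t^beta growth with
    Gamma = J/tau^beta, plateau 2J) and matches the surrogate generator's
    correlation structure exactly.
    """
    if plateau <= 0 or tau <= 0:
        raise ValueError("J and tau must be positive")
    t = np.asarray(t, dtype=float)
    return 2.0 * plateau * (1.0 - np.exp(-((t / tau) ** beta)))


def _moment_guesses(curve: MSDCurve, beta: float):
    j0 = max(float(np.nanmax(curve.values)) / 2.0, 1e-6)
    g0 = max(float(curve.values[0]) / (2.0 * curve.lags[0] ** beta), 1e-12)
    tau0 = (j0 / g0) ** (1.0 / beta)
    return g0, j0, tau0


def fit_rouse_m2(
    curve: MSDCurve,
    model: str = "rouse",
    beta: float = 0.5,
    fit_beta: bool = False,
    n_walkers: int = 24,
    n_steps: int = 1500,
    n_burn: int = 500,
    seed: int = 0,
    fit_range=None,
    n_lags_fit: int = 12,
) -> RouseFit:
    """Bayesian fit of a two-locus MSD curve.

    Likelihood: multivariate Gaussian on log M2 over a log-spaced subset
    of lags (default 12), with the full covariance of log-MSD estimated
    from the curve's bootstrap replicates -- MSD values at different lags
    share trajectories and are strongly correlated, and ignoring this
    yields spuriously narrow posteriors.  Falls back to independent
    per-lag relative errors when no bootstrap replicates are stored.
    Priors: log-uniform over 6 decades centered on moment-based initial
    guesses.  Sampling with emcee; the posterior median and 16-84% /
    2.5-97.5% intervals are reported, with tau = (J/Gamma)^(1/beta)
    derived per draw.

    ``model="rouse"`` fits (Gamma, J) with the ideal-chain closed form
    (beta fixed to 1/2 unless ``fit_beta``); ``model="stretched"`` fits
    (J, tau) of the stretched-exponential family with fixed or free beta.
    """
    import emcee

    keep = np.isfinite(curve.values) & (curve.values > 0) & np.isfinite(curve.se)
    if fit_range is not None:
        keep &= (curve.lags >= fit_range[0]) & (curve.lags <= fit_range[1])
    idx_all = np.nonzero(keep)[0]
    boots = curve.bootstrap
    if boots is not None and len(idx_all) > n_lags_fit:
        # log-spaced lag subset: lags carry largely redundant information
        pick = np.unique(
            np.round(
                np.geomspace(1, len(idx_all), n_lags_fit)
            ).astype(int)
            - 1
        )
        idx = idx_all[pick]
    else:
        idx = idx_all
    t = curve.lags[idx]
    y = curve.values[idx]
    logy = np.log(y)
    rel = np.maximum(curve.se[idx] / y, 1e-4)
    cov_inv = None
    if boots is not None and boots.shape[0] > 3 * len(idx):
        logb = np.log(np.maximum(boots[:, idx], 1e-300))
        ok = np.all(np.isfinite(logb), axis=1)
        cov = np.cov(logb[ok].T)
        cov = np.atleast_2d(cov)
        # small ridge keeps the bootstrap covariance invertible
        cov += np.eye(len(idx)) * (1e-3 * float(np.trace(cov)) / len(idx) + 1e-10)
        cov_inv = np.linalg.inv(cov)

    g0, j0, tau0 = _moment_guesses(curve, beta)
    if model == "rouse":
        if not fit_beta:
            beta = 0.5
        center = np.log10([g0, j0])
    elif model == "stretched":
        center = np.log10([j0, tau0])
    else:
        raise ValueError("model must be 'rouse' or 'stretched'")
    ndim = 2 + int(fit_beta)
    lo = np.concatenate([center - 3.0, [0.05] if fit_beta else []])
    hi = np.concatenate([center + 3.0, [1.0] if fit_beta else []])

    def predict(theta):
        if model == "rouse":
            g, j = 10.0 ** theta[0], 10.0 ** theta[1]
            if fit_beta:
                # generalized: M2 = 2 g t^b below tau, Rouse crossover shape
                b = theta[2]
                tau = (j / g) ** (1.0 / b)
                x = tau / (math.pi * t)
                return 2.0 * g * t**b * (1.0 - np.exp(-x)) + 2.0 * j * erfc(
                    np.sqrt(x)
                )
            return rouse_m2(t, g, j)
        j, tau = 10.0 ** theta[0], 10.0 ** theta[1]
        b = theta[2] if fit_beta else beta
        return stretched_m2(t, j, tau, b)

    def log_prob(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        m = predict(theta)
        if not np.all(np.isfinite(m)) or np.any(m <= 0):
            return -np.inf
        resid = logy - np.log(m)
        if cov_inv is not None:
            return -0.5 * float(resid @ cov_inv @ resid)
        resid = resid / rel
        return -0.5 * float(resid @ resid)

    rng = np.random.default_rng(seed)
    p0 = np.concatenate([center, [beta] if fit_beta else []])
    walkers = p0 + 0.05 * rng.standard_normal((n_walkers, ndim))
    walkers = np.clip(walkers, lo + 1e-6, hi - 1e-6)
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    state = sampler.run_mcmc(walkers, n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    accept = float(np.mean(sampler.acceptance_fraction))
    converged = 0.1 < accept < 0.9

    if model == "rouse":
        g_s = 10.0 ** chain[:, 0]
        j_s = 10.0 ** chain[:, 1]
        b_s = chain[:, 2] if fit_beta else np.full(len(chain), beta)
        tau_s = (j_s / g_s) ** (1.0 / b_s)
    else:
        j_s = 10.0 ** chain[:, 0]
        tau_s = 10.0 ** chain[:, 1]
        b_s = chain[:, 2] if fit_beta else np.full(len(chain), beta)
        g_s = j_s / tau_s**b_s

    def q(a, p):
        return tuple(float(np.quantile(a, x)) for x in p)

    quants = (0.025, 0.16, 0.5, 0.84, 0.975)
    intervals = {
        "gamma_diff": q(g_s, quants),
        "plateau": q(j_s, quants),
        "tau": q(tau_s, quants),
        "beta": q(b_s, quants),
        "acceptance_fraction": accept,
    }
    return RouseFit(
        gamma_diff=float(np.median(g_s)),
        plateau=float(np.median(j_s)),
        tau=float(np.median(tau_s)),
        beta=float(np.median(b_s)),
        model=model,
        intervals=intervals,
        converged=converged,
        samples=chain,
    )


# ---------------------------------------------------------------------------
# Correlation functions
# ---------------------------------------------------------------------------


def autocorr_two_locus(
    trajectories, max_lag: int | None = None, n_boot: int = 200, seed: int = 0,
    states=None, state=None,
) -> CorrelationCurve:
    """Two-locus autocorrelation C2(t) = <R(t0) . R(t0+t)>_{t0}.

    Computed two ways: the direct dot-product estimator, and
    <R^2>_pairs - M2(t)/2 over the same origin pairs.  The two agree to
    machine precision on gap-free data (algebraic identity).
    """
    dt = trajectories[0].frame_interval
    n_max = max(t.n_frames for t in trajectories)
    if max_lag is None:
        max_lag = n_max - 1
    max_lag = min(max_lag, n_max - 1)

    dot_sums = np.zeros((len(trajectories), max_lag))
    sq_sums = np.zeros((len(trajectories), max_lag))  # (|R0|^2+|R1|^2)/2 sums
    counts = np.zeros((len(trajectories), max_lag), dtype=int)
    r2_sum = 0.0
    r2_n = 0
    for i, traj in enumerate(trajectories):
        R = _state_masked(traj.separation_vector(), traj, states, state)
        sq = np.sum(R * R, axis=1)
        ok_frames = np.isfinite(sq)
        r2_sum += np.nansum(sq[ok_frames])
        r2_n += int(ok_frames.sum())
        for lag in range(1, max_lag + 1):
            dots = np.sum(R[lag:] * R[:-lag], axis=1)
            ok = np.isfinite(dots)
            dot_sums[i, lag - 1] = np.nansum(dots[ok])
            sq_sums[i, lag - 1] = 0.5 * np.nansum((sq[lag:] + sq[:-lag])[ok])
            counts[i, lag - 1] = int(ok.sum())

    total = counts.sum(axis=0)
    keep = total > 0
    c2 = dot_sums.sum(axis=0)[keep] / total[keep]
    mean_sq_pairs = sq_sums.sum(axis=0)[keep] / total[keep]
    # M2 on the same pairs: |R1-R0|^2 = |R0|^2+|R1|^2 - 2 R0.R1
    m2_pairs = 2.0 * mean_sq_pairs - 2.0 * c2
    c2_from_msd = mean_sq_pairs - m2_pairs / 2.0

    rng = np.random.default_rng(seed)
    n = len(trajectories)
    boots = np.full((n_boot, int(keep.sum())), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cs = counts[idx].sum(axis=0)[keep]
        ok = cs > 0
        boots[b, ok] = dot_sums[idx].sum(axis=0)[keep][ok] / cs[ok]
    se = np.nanstd(boots, axis=0, ddof=1)

    return CorrelationCurve(
        lags=(np.arange(1, max_lag + 1) * dt)[keep],
        c2=c2,
        c2_from_msd=c2_from_msd,
        r2=r2_sum / max(r2_n, 1),
        se=se,
        n_pairs=total[keep],
        separation_kb=trajectories[0].separation_kb,
    )


# ---------------------------------------------------------------------------
# Scaling with genomic separation
# ---------------------------------------------------------------------------


def _scaling_from_fits(fits_by_s, attr, fit_range) -> ScalingFit:
    s_vals, y, y_err = [], [], []
    for s in sorted(fits_by_s):
        fit = fits_by_s[s]
        s_vals.append(s)
        y.append(getattr(fit, attr))
        iv = fit.intervals.get(attr)
        if iv is not None:
            y_err.append(0.5 * (iv[3] - iv[1]))  # half the 16-84% interval
        else:
            y_err.append(np.nan)
    y_err = None if np.any(~np.isfinite(y_err)) else np.asarray(y_err)
    return powerlaw_fit(np.asarray(s_vals), np.asarray(y), y_err, fit_range)


def diffusivity_scaling(fits_by_s: dict, fit_range=None) -> ScalingFit:
    """Exponent alpha of Gamma(s) ~ s^alpha from per-separation M2 fits."""
    return _scaling_from_fits(fits_by_s, "gamma_diff", fit_range)


def relaxation_scaling(fits_by_s: dict, fit_range=None) -> ScalingFit:
    """Exponent gamma of tau(s) ~ s^gamma from per-separation M2 fits."""
    return _scaling_from_fits(fits_by_s, "tau", fit_range)


@dataclass
class CollapseResult:
    """Best collapse exponent with its score profile."""

    gamma: float
    gamma_se: float
    score: float
    gamma_grid: np.ndarray
    scores: np.ndarray


def _collapse_score(curves, gamma: float, n_grid: int = 60) -> float:
    rescaled = []
    for c in curves:
        u = c.lags * c.separation_kb ** (-gamma)
        v = c.c2 / c.r2
        rescaled.append((np.log(u), v))
    lo = max(lu.min() for lu, _ in rescaled)
    hi = min(lu.max() for lu, _ in rescaled)
    if hi <= lo:
        return float("inf")
    grid = np.linspace(lo, hi, n_grid)
    interp = np.array([np.interp(grid, lu, v) for lu, v in rescaled])
    return float(np.mean(np.var(interp, axis=0)))


def collapse_gamma(curves, gamma_grid=None, refine: bool = True) -> CollapseResult:
    """Data-collapse estimate of the relaxation-time scaling exponent.

    Each normalized correlation curve C2/<R^2> is replotted against the
    rescaled lag t * s^(-gamma); the collapse score is the mean pointwise
    variance across curves on a common grid restricted to the overlap
    region.  The best gamma minimizes the score (coarse grid 0-3 step
    0.05, then local refinement at step 0.005).  The quoted SE is a
    leave-one-curve-out jackknife.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 curves at distinct separations")
    if gamma_grid is None:
        gamma_grid = np.arange(0.0, 3.0 + 1e-9, 0.05)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    scores = np.array([_collapse_score(curves, g) for g in gamma_grid])
    if not np.any(np.isfinite(scores)):
        raise ValueError(
            "rescaled lag supports do not overlap for any candidate gamma; "
            "the curves span incompatible lag ranges"
        )
    best = float(gamma_grid[int(np.argmin(scores))])
    if refine:
        fine = np.arange(best - 0.05, best + 0.05 + 1e-9, 0.005)
        fine = fine[fine >= gamma_grid.min()]
        fine_scores = np.array([_collapse_score(curves, g) for g in fine])
        k = int(np.argmin(fine_scores))
        best, best_score = float(fine[k]), float(fine_scores[k])
    else:
        best_score = float(scores.min())

    # leave-one-curve-out jackknife on the coarse+refined estimate
    jack = []
    for i in range(len(curves)):
        sub = [c for j, c in enumerate(curves) if j != i]
        s_sub = np.array([_collapse_score(sub, g) for g in gamma_grid])
        g0 = float(gamma_grid[int(np.argmin(s_sub))])
        fine = np.arange(g0 - 0.05, g0 + 0.05 + 1e-9, 0.005)
        fine = fine[fine >= gamma_grid.min()]
        fs = np.array([_collapse_score(sub, g) for g in fine])
        jack.append(float(fine[int(np.argmin(fs))]))
    jack = np.asarray(jack)
    m = len(jack)
    se = math.sqrt((m - 1) / m * float(np.sum((jack - jack.mean()) ** 2)))
    return CollapseResult(
        gamma=best,
        gamma_se=se,
        score=best_score,
        gamma_grid=gamma_grid,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# Velocity correlations
# ---------------------------------------------------------------------------


def velocity_corr(
    trajectories,
    delta: float,
    lags=None,
    n_boot: int = 200,
    seed: int = 0,
    states=None,
    state=None,
) -> VelocityCorr:
    """Coarse-grained velocity cross- and auto-correlations of the pair.

    Velocities v(delta)(t) = (x(t+delta) - x(t)) / delta per locus; the
    cross-correlation Cvv(delta)(t) = <v_A(t0) . v_B(t0+t)>_{t0}
    (symmetrized in the loci) and the auto-correlation averaged over loci
    are reported per lag, plus the normalized intercept Cvv(0)/Cv(0) with
    a bootstrap SE over trajectories.  When decoded states are supplied,
    origins are restricted to intervals whose endpoints are in ``state``.
    """
    dt = trajectories[0].frame_interval
    m = int(round(delta / dt))
    if abs(m * dt - delta) > 1e-9:
        raise ValueError("delta must be an integer multiple of the frame interval")
    if m < 1 or m >= min(t.n_frames for t in trajectories):
        raise ValueError("delta is longer than the trajectories")
    if lags is None:
        lags = np.array([0.0])
    lag_frames = [int(round(l / dt)) for l in np.atleast_1d(lags)]

    n = len(trajectories)
    cross_sums = np.zeros((n, len(lag_frames)))
    auto_sums = np.zeros((n, len(lag_frames)))
    cross_counts = np.zeros((n, len(lag_frames)), dtype=int)
    auto_counts = np.zeros((n, len(lag_frames)), dtype=int)
    for i, traj in enumerate(trajectories):
        pa = _state_masked(traj.pos_a, traj, states, state)
        pb = _state_masked(traj.pos_b, traj, states, state)
        va = (pa[m:] - pa[:-m]) / delta
        vb = (pb[m:] - pb[:-m]) / delta
        for j, lf in enumerate(lag_frames):
            if lf >= len(va):
                continue
            a0, b1 = va[: len(va) - lf], vb[lf:]
            b0, a1 = vb[: len(vb) - lf], va[lf:]
            d1 = np.sum(a0 * b1, axis=1)
            d2 = np.sum(b0 * a1, axis=1)
            ok1, ok2 = np.isfinite(d1), np.isfinite(d2)
            cross_sums[i, j] = np.nansum(d1[ok1]) + np.nansum(d2[ok2])
            cross_counts[i, j] = int(ok1.sum() + ok2.sum())
            e1 = np.sum(a0 * a1, axis=1)
            e2 = np.sum(b0 * b1, axis=1)
            ok1, ok2 = np.isfinite(e1), np.isfinite(e2)
            auto_sums[i, j] = np.nansum(e1[ok1]) + np.nansum(e2[ok2])
            auto_counts[i, j] = int(ok1.sum() + ok2.sum())

    def ratio(cs, cc, as_, ac):
        cross = np.where(cc.sum(0) > 0, cs.sum(0) / np.maximum(cc.sum(0), 1), np.nan)
        auto = np.where(ac.sum(0) > 0, as_.sum(0) / np.maximum(ac.sum(0), 1), np.nan)
        return cross, auto

    cross, auto = ratio(cross_sums, cross_counts, auto_sums, auto_counts)
    intercept = float(cross[0] / auto[0]) if auto[0] else float("nan")

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        c, a = ratio(
            cross_sums[idx], cross_counts[idx], auto_sums[idx], auto_counts[idx]
        )
        if np.isfinite(a[0]) and a[0] != 0:
            boots.append(c[0] / a[0])
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")

    return VelocityCorr(
        delta=delta,
        lags=np.atleast_1d(lags).astype(float),
        cross=cross,
        auto=auto,
        intercept_ratio=min(max(intercept, -1.0), 1.0),
        intercept_se=se,
        separation_kb=trajectories[0].separation_kb,
    )


def predicted_vcc_intercept(delta, tau, beta: float = 0.5, family: str = "rouse"):
    """Normalized velocity cross-correlation intercept Cvv(0)/Cv(0).

    Depends only on delta/tau.  From the increment identity
    Cvv(0) = [2 M1(delta) - M2(delta)] / (2 delta^2) with M1 = Gamma t^beta:

    * ``family="rouse"`` (beta = 1/2, ideal-chain closed form):
      exp(-tau/(pi delta)) - sqrt(tau/delta) * erfc(sqrt(tau/(pi delta)))
    * ``family="stretched"`` (generalized crossover, any beta):
      1 - (tau/delta)^beta * (1 - exp(-(delta/tau)^beta))

    Both are monotone increasing in delta/tau with limits 0 and 1.
    """
    delta = np.asarray(delta, dtype=float)
    if family == "rouse":
        x = tau / (math.pi * delta)
        out = np.exp(-x) - np.sqrt(tau / delta) * erfc(np.sqrt(x))
    elif family == "stretched":
        r = (np.asarray(tau) / delta) ** beta
        out = 1.0 - r * (1.0 - np.exp(-1.0 / r))
    else:
        raise ValueError("family must be 'rouse' or 'stretched'")
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Theory
# ---------------------------------------------------------------------------


def theory_exponents(d: float, beta: float | None = None, alpha: float = 0.0) -> dict:
    """Generalized-Rouse exponent relations for fractal dimension d.

    beta_from_d = 2/(2+d) (dynamic exponent from packing);
    gamma = (2/d - alpha)/beta (relaxation-time scaling, from
    Gamma tau^beta ~ s^(2/d) with Gamma ~ s^alpha);
    lam = 2(1-d)/(2+d) (autocorrelation decay C2 ~ t^lam for t >> tau);
    gamma_zimm = 3/d (Zimm model with hydrodynamic coupling: relaxation
    time ~ R^3 ~ s^(3/d), giving gamma = 1 for a compact d = 3 packing).

    If beta is omitted the packing prediction 2/(2+d) is used.  d=2,
    beta=1/2, alpha=0 give the classical Rouse result gamma=2; d=3,
    beta=2/5 give gamma=5/3.
    """
    if d <= 0:
        raise ValueError("fractal dimension must be positive")
    beta_from_d = 2.0 / (2.0 + d)
    b = beta_from_d if beta is None else beta
    if not 0.0 < b < 1.0:
        raise ValueError("beta must lie in (0, 1)")
    return {
        "beta_from_d": beta_from_d,
        "gamma": (2.0 / d - alpha) / b,
        "lambda": 2.0 * (1.0 - d) / (2.0 + d),
        "gamma_zimm": 3.0 / d,
    }


def relaxation_ratio(s1: float, s2: float, gamma: float) -> float:
    """Ratio tau(s2)/tau(s1) = (s2/s1)**gamma for tau ~ s^gamma."""
    if s1 <= 0 or s2 <= 0 or gamma < 0:
        raise ValueError("separations must be positive and gamma >= 0")
    return (s2 / s1) ** gamma
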