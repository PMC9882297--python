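"""Lifetime and pairing-probability statistics from decoded state paths.

Maximal runs of each state become dwell records; runs touching a
trajectory boundary or a masked gap are censored (an unseen state change
cannot be excluded, so gap-interrupted dwells are censored rather than
stitched).  Survival curves use the Kaplan--Meier product-limit estimator
(via lifelines) with Greenwood-variance confidence intervals; lifetimes
are also estimated by censoring-aware exponential maximum likelihood.
Pairing probabilities are frame-weighted and their scaling with genomic
separation is fit by weighted least squares on log-log axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .hmm import STATE_NAMES, StatePath
from .simulate import O_OFF, P_OFF, P_ON

__all__ = [
    "DwellRecord",
    "SurvivalCurve",
    "ScalingFit",
    "extract_dwells",
    "kaplan_meier",
    "exponential_mle",
    "pairing_probability",
    "conditional_on_fraction",
    "powerlaw_fit",
]


@dataclass
class DwellRecord:
    """One maximal run of a state, with boundary/gap censoring flags."""

    state: int
    duration: float           # s, run length * frame interval
    left_censored: bool       # run start touches a boundary or gap
    right_censored: bool      # run end touches a boundary or gap
    traj_id: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("dwell duration must be positive")

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with 95% confidence band."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    median: float
    n_events: int
    n_censored: int


@dataclass
class ScalingFit:
    """Power-law fit y = prefactor * x**exponent on log-log axes."""

    exponent: float
    exponent_se: float
    prefactor: float
    fit_range: tuple[float, float]
    x: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None
    n_points: int


def extract_dwells(paths) -> list[DwellRecord]:
    """Convert decoded state paths into dwell records.

    Each contiguous observed segment (between masked gaps) is scanned for
    maximal state runs; the first/last run of every segment is flagged
    left-/right-censored respectively.
    """
    records: list[DwellRecord] = []
    for path in paths:
        dt = path.frame_interval
        n = len(path.states)
        # contiguous observed segments
        obs = ~path.missing
        k = 0
        while k < n:
            if not obs[k]:
                k += 1
                continue
            seg_start = k
            while k < n and obs[k]:
                k += 1
            seg_end = k  # exclusive
            j = seg_start
            while j < seg_end:
                state = path.states[j]
                run_start = j
                while j < seg_end and path.states[j] == state:
                    j += 1
                records.append(
                    DwellRecord(
                        state=int(state),
                        duration=(j - run_start) * dt,
                        left_censored=run_start == seg_start,
                        right_censored=j == seg_end,
                        traj_id=path.traj_id,
                    )
                )
    return records


def _durations_events(dwells, state):
    sel = [d for d in dwells if d.state == state]
    durations = np.array([d.duration for d in sel])
    events = np.array([not d.censored for d in sel])
    return durations, events


def kaplan_meier(dwells, state: int = P_ON) -> SurvivalCurve:
    """Kaplan--Meier survival curve of the dwell times of one state.

    Censored records enter as right-censored exposure.  The median is the
    earliest time with S(t) <= 0.5.  Requires at least one uncensored
    event.
    """
    durations, events = _durations_events(dwells, state)
    if durations.size == 0 or not events.any():
        raise ValueError(
            f"no uncensored {STATE_NAMES[state]} dwells; survival curve undefined"
        )
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    ci = kmf.confidence_interval_
    lo = ci.iloc[:, 0].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].to_numpy(dtype=float)
    at_risk = np.array(
        [int((durations >= t).sum()) for t in times], dtype=int
    )
    below = np.nonzero(surv <= 0.5 + 1e-12)[0]
    median = float(times[below[0]]) if below.size else float("inf")
    return SurvivalCurve(
        times=times,
        survival=surv,
        ci_lower=lo,
        ci_upper=hi,
        at_risk=at_risk,
        median=median,
        n_events=int(events.sum()),
        n_censored=int((~events).sum()),
    )


def exponential_mle(dwells, state: int = P_ON):
    """Censoring-aware exponential MLE of the dwell rate.

    rate = (#events) / (total exposure including censored durations);
    median = ln 2 / rate.  The 95% CI follows from the Fisher information
    of the log-rate (sd = 1/sqrt(#events)).

    Returns a dict with rate, median and their CIs.
    """
    durations, events = _durations_events(dwells, state)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError(f"no uncensored {STATE_NAMES[state]} dwells; rate undefined")
    exposure = float(durations.sum())
    rate = n_events / exposure
    half = 1.96 / math.sqrt(n_events)
    rate_ci = (rate * math.exp(-half), rate * math.exp(half))
    median = math.log(2.0) / rate
    return {
        "rate": rate,
        "rate_ci": rate_ci,
        "median": median,
        "median_ci": (math.log(2.0) / rate_ci[1], math.log(2.0) / rate_ci[0]),
        "n_events": n_events,
        "exposure": exposure,
    }


def _bootstrap_fraction(numer, denom, n_boot, rng):
    """Bootstrap SE of sum(numer)/sum(denom) resampling trajectories."""
    numer = np.asarray(numer, dtype=float)
    denom = np.asarray(denom, dtype=float)
    n = len(numer)
    if n == 0 or denom.sum() == 0:
        return float("nan")
    idx = rng.integers(0, n, size=(n_boot, n))
    num = numer[idx].sum(axis=1)
    den = denom[idx].sum(axis=1)
    ok = den > 0
    if ok.sum() < 2:
        return float("nan")
    return float(np.std(num[ok] / den[ok], ddof=1))


def pairing_probability(paths, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """P(s): frame-weighted fraction of frames in a paired state, per s.

    Bootstrap errors resample nuclei (trajectories).
    """
    rng = np.random.default_rng(seed)
    by_s: dict[float, list[StatePath]] = {}
    for p in paths:
        by_s.setdefault(p.separation_kb, []).append(p)
    rows = []
    for s in sorted(by_s):
        group = by_s[s]
        paired = [
            float(np.isin(p.states[~p.missing], (P_OFF, P_ON)).sum()) for p in group
        ]
        total = [float((~p.missing).sum()) for p in group]
        tot = sum(total)
        rows.append(
            {
                "s_kb": s,
                "p_paired": sum(paired) / tot if tot else float("nan"),
                "se": _bootstrap_fraction(paired, total, n_boot, rng),
                "n_frames": int(tot),
                "n_trajectories": len(group),
            }
        )
    return pd.DataFrame(rows)


def conditional_on_fraction(paths, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """P_on / (P_on + P_off) restricted to paired frames, per separation.

    Undefined (NaN) where a separation has no paired frames.
    """
    rng = np.random.default_rng(seed)
    by_s: dict[float, list[StatePath]] = {}
    for p in paths:
        by_s.setdefault(p.separation_kb, []).append(p)
    rows = []
    for s in sorted(by_s):
        group = by_s[s]
        on = [float((p.states[~p.missing] == P_ON).sum()) for p in group]
        paired = [
            float(np.isin(p.states[~p.missing], (P_OFF, P_ON)).sum()) for p in group
        ]
        tot = sum(paired)
        rows.append(
            {
                "s_kb": s,
                "on_fraction": sum(on) / tot if tot > 0 else float("nan"),
                "se": _bootstrap_fraction(on, paired, n_boot, rng),
                "n_paired_frames": int(tot),
            }
        )
    return pd.DataFrame(rows)


def powerlaw_fit(x, y, y_err=None, fit_range=None) -> ScalingFit:
    """Weighted least-squares power-law fit on log10-log10 axes.

    Errors enter as relative errors on the log values:
    sigma_log = y_err / (y * ln 10).  With no errors an ordinary
    least-squares fit is used and the exponent SE comes from the residual
    variance (zero for an exact power law).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    err = None if y_err is None else np.asarray(y_err, dtype=float)
    if fit_range is not None:
        lo, hi = fit_range
        keep = (x >= lo) & (x <= hi)
        x, y = x[keep], y[keep]
        if err is not None:
            err = err[keep]
    finite = np.isfinite(x) & np.isfinite(y)
    if err is not None:
        finite &= np.isfinite(err)
    x, y = x[finite], y[finite]
    if err is not None:
        err = err[finite]
    if len(x) < 3:
        raise ValueError("need at least 3 points in the fit range")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive x and y")

    lx = np.log10(x)
    ly = np.log10(y)
    A = np.column_stack([np.ones_like(lx), lx])
    if err is not None:
        sig = err / (y * math.log(10.0))
        sig = np.maximum(sig, 1e-12)
        w = 1.0 / sig**2
    else:
        w = np.ones_like(lx)
    AtW = A.T * w
    cov = np.linalg.inv(AtW @ A)
    coef = cov @ (AtW @ ly)
    if err is None:
        resid = ly - A @ coef
        dof = max(len(x) - 2, 1)
        cov = cov * float(resid @ resid) / dof
    return ScalingFit(
        exponent=float(coef[1]),
        exponent_se=float(math.sqrt(max(cov[1, 1], 0.0))),
        prefactor=float(10.0 ** coef[0]),
        fit_range=(float(x.min()), float(x.max())),
        x=x,
        y=y,
        y_err=err,
        n_points=len(x),
    )
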