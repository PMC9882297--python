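"""Two-locus trajectory container, delimited-text I/O, and preprocessing.

A :class:`TwoLocusTrajectory` holds the time-stamped 3-D positions of the
two labeled loci (nm), the transcription intensity channel (a.u.) and a
per-frame missingness mask on a strictly uniform time grid.  All downstream
stages (state inference, kinetics, dynamics) consume only this type.

File format: comma-separated UTF-8 with header
``embryo,nucleus,frame,t_s,ax,ay,az,bx,by,bz,intensity,s_kb``;
positions in nm, time in s, genomic separation in kb.  Missing frames are
rows with empty position/intensity fields; gaps in the frame index are
re-inserted as masked frames on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TwoLocusTrajectory",
    "DistanceSeries",
    "read_trajectories",
    "write_trajectories",
    "write_state_table",
    "read_state_table",
    "compute_distance",
    "qc_filter",
    "kde_distance_distribution",
]

REQUIRED_COLUMNS = (
    "embryo",
    "nucleus",
    "frame",
    "t_s",
    "ax",
    "ay",
    "az",
    "bx",
    "by",
    "bz",
    "intensity",
    "s_kb",
)


@dataclass
class TwoLocusTrajectory:
    """Paired 3-D positions of two loci with transcription readout.

    Positions are NaN on masked frames; ``missing`` is the authoritative
    mask.  ``states`` optionally carries a per-frame state label
    (0=O_off, 1=P_off, 2=P_on; -1 undefined), used for generator ground
    truth or decoded paths.
    """

    traj_id: str
    embryo_id: str
    separation_kb: float
    times: np.ndarray           # (n,) s, uniform grid
    pos_a: np.ndarray           # (n, 3) nm
    pos_b: np.ndarray           # (n, 3) nm
    intensity: np.ndarray       # (n,) a.u.
    missing: np.ndarray         # (n,) bool
    frame_interval: float       # s
    states: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        self.times = np.asarray(self.times, dtype=float)
        self.pos_a = np.asarray(self.pos_a, dtype=float).reshape(n, 3)
        self.pos_b = np.asarray(self.pos_b, dtype=float).reshape(n, 3)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.separation_kb <= 0:
            raise ValueError("genomic separation must be positive")
        if n > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("time stamps must be strictly increasing")
            if not np.allclose(steps, self.frame_interval, rtol=1e-6, atol=1e-6):
                raise ValueError("time stamps must lie on a uniform grid")
        # masked frames carry no position values
        self.pos_a[self.missing] = np.nan
        self.pos_b[self.missing] = np.nan

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_observed(self) -> int:
        return int((~self.missing).sum())

    def separation_vector(self) -> np.ndarray:
        """R(t) = r_A(t) - r_B(t), shape (n, 3), NaN where masked."""
        return self.pos_a - self.pos_b


@dataclass
class DistanceSeries:
    """Scalar inter-locus distance R(t) = |r_A - r_B| with missing mask."""

    times: np.ndarray
    distance: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        observed = self.distance[~self.missing]
        if np.any(observed < 0):
            raise ValueError("distances must be non-negative")

    def values(self) -> np.ndarray:
        """Observed distances only."""
        return self.distance[~self.missing]


def compute_distance(traj: TwoLocusTrajectory, offset=None) -> DistanceSeries:
    """Euclidean inter-locus distance per frame.

    Parameters
    ----------
    offset
        Optional constant chromatic-offset 3-vector (nm) subtracted from the
        separation vector before taking the norm.  Chromatic and motion
        corrections are inputs here, not computations.
    """
    sep = traj.separation_vector()
    if offset is not None:
        sep = sep - np.asarray(offset, dtype=float).reshape(1, 3)
    dist = np.linalg.norm(sep, axis=1)
    return DistanceSeries(
        times=traj.times.copy(), distance=dist, missing=traj.missing.copy()
    )


def qc_filter(trajectories, min_points: int = 10):
    """Drop trajectories with fewer than ``min_points`` observed frames.

    Returns ``(kept, report)`` where report counts kept/removed.  Idempotent.
    """
    kept = [t for t in trajectories if t.n_observed >= min_points]
    report = {
        "n_input": len(trajectories),
        "n_kept": len(kept),
        "n_removed": len(trajectories) - len(kept),
        "min_points": min_points,
    }
    if not kept:
        warnings.warn("qc_filter removed every trajectory", stacklevel=2)
    return kept, report


def kde_distance_distribution(values, bandwidth: float = 100.0, grid=None):
    """Gaussian kernel density estimate of a distance sample.

    ``bandwidth`` is the kernel standard deviation in nm (default 100 nm).
    Returns ``(grid, density)``; the density integrates to 1 on an
    unbounded grid.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("need at least one finite value")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo = values.min() - 5.0 * bandwidth
        hi = values.max() + 5.0 * bandwidth
        grid = np.linspace(lo, hi, 512)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - values[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (
        values.size * bandwidth * np.sqrt(2.0 * np.pi)
    )
    return grid, density


def _trajectory_frame(traj: TwoLocusTrajectory) -> pd.DataFrame:
    n = traj.n_frames
    return pd.DataFrame(
        {
            "embryo": [traj.embryo_id] * n,
            "nucleus": [traj.traj_id] * n,
            "frame": np.arange(n, dtype=int),
            "t_s": traj.times,
            "ax": traj.pos_a[:, 0],
            "ay": traj.pos_a[:, 1],
            "az": traj.pos_a[:, 2],
            "bx": traj.pos_b[:, 0],
            "by": traj.pos_b[:, 1],
            "bz": traj.pos_b[:, 2],
            "intensity": traj.intensity,
            "s_kb": [traj.separation_kb] * n,
        }
    )


def write_trajectories(trajectories, path) -> None:
    """Write trajectories to one delimited text table (CSV, header row).

    Masked frames are written with empty position/intensity fields so the
    round trip preserves both finite values and masks.
    """
    frames = [_trajectory_frame(t) for t in trajectories]
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False, float_format="%.6f")


def write_state_table(trajectories, path, posteriors=None) -> None:
    """Ground-truth/decoded state sidecar: one row per frame."""
    rows = []
    for traj in trajectories:
        states = traj.states
        if states is None:
            states = np.full(traj.n_frames, -1, dtype=int)
        for k in range(traj.n_frames):
            rows.append(
                {
                    "embryo": traj.embryo_id,
                    "nucleus": traj.traj_id,
                    "frame": k,
                    "state": int(states[k]),
                    "s_kb": traj.separation_kb,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_state_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _check_uniform(times: np.ndarray, group: str) -> float:
    steps = np.diff(times)
    if len(steps) == 0:
        return float("nan")
    dt = np.median(steps)
    bad = np.nonzero(~np.isclose(steps, dt, rtol=1e-6, atol=1e-6))[0]
    if bad.size:
        raise ValueError(
            f"trajectory {group}: non-uniform time grid at rows {bad[:5].tolist()} "
            f"(steps {steps[bad[:5]].tolist()} vs median {dt})"
        )
    return float(dt)


def read_trajectories(path):
    """Read a trajectory table written by :func:`write_trajectories`.

    Gaps in the frame index are inserted as masked frames.  Raises with
    row-level diagnostics on missing columns, non-uniform time grids, or a
    mixed frame interval within one trajectory.
    """
    table = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {missing_cols}")

    trajectories = []
    for (embryo, nucleus), grp in table.groupby(["embryo", "nucleus"], sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"trajectory {embryo}/{nucleus}: duplicate frame indices")
        # infer dt from observed time stamps (frames may be gapped)
        t_obs = grp["t_s"].to_numpy(dtype=float)
        dframes = np.diff(frames)
        if len(frames) > 1:
            dts = np.diff(t_obs) / dframes
            dt = float(np.median(dts))
            bad = np.nonzero(~np.isclose(dts, dt, rtol=1e-6, atol=1e-6))[0]
            if bad.size:
                raise ValueError(
                    f"trajectory {embryo}/{nucleus}: mixed frame interval at "
                    f"rows {bad[:5].tolist()}"
                )
        else:
            dt = float("nan")

        f0, f1 = frames[0], frames[-1]
        n = f1 - f0 + 1
        pos_a = np.full((n, 3), np.nan)
        pos_b = np.full((n, 3), np.nan)
        intensity = np.full(n, np.nan)
        missing = np.ones(n, dtype=bool)
        idx = frames - f0
        pos_a[idx] = grp[["ax", "ay", "az"]].to_numpy(dtype=float)
        pos_b[idx] = grp[["bx", "by", "bz"]].to_numpy(dtype=float)
        intensity[idx] = grp["intensity"].to_numpy(dtype=float)
        # a row whose positions are all empty is a masked frame
        observed = np.isfinite(pos_a).all(axis=1) & np.isfinite(pos_b).all(axis=1)
        missing[idx] = ~observed[idx]
        # anchor times at the first observed frame
        times = t_obs[0] + np.arange(n) * dt if n > 1 else t_obs[:1]
        trajectories.append(
            TwoLocusTrajectory(
                traj_id=str(nucleus),
                embryo_id=str(embryo),
                separation_kb=float(grp["s_kb"].iloc[0]),
                times=times,
                pos_a=pos_a,
                pos_b=pos_b,
                intensity=intensity,
                missing=missing,
                frame_interval=dt if np.isfinite(dt) else 0.0,
            )
        )
    return trajectories
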