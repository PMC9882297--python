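"""End-to-end pipeline: simulate -> infer states -> kinetics -> dynamics ->
report, driven by one :class:`~locusdyn.config.PipelineConfig`.

Every stage writes delimited-text tables into the run directory together
with a config snapshot, and can be re-run from the intermediate tables.
A single global seed deterministically derives per-stage substreams, so a
full run is byte-reproducible and stages can be toggled without changing
the outputs of the others.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig, save_config
from .dynamics import (
    autocorr_two_locus,
    collapse_gamma,
    diffusivity_scaling,
    fit_rouse_m2,
    msd_single,
    msd_two_locus,
    predicted_vcc_intercept,
    relaxation_scaling,
    velocity_corr,
)
from .hmm import StatePath, decode_states, fit_hmm, state_occupancy
from .kinetics import (
    conditional_on_fraction,
    exponential_mle,
    extract_dwells,
    kaplan_meier,
    pairing_probability,
    powerlaw_fit,
)
from .simulate import (
    O_OFF,
    P_ON,
    apply_measurement,
    overlay_state_process,
    simulate_rouse_chain,
    simulate_surrogate_pair,
)
from .trajectory import (
    compute_distance,
    qc_filter,
    read_trajectories,
    write_state_table,
    write_trajectories,
)

__all__ = ["run_pipeline", "make_report", "STAGES"]

STAGES = ("simulate", "infer", "kinetics", "dynamics", "report")

log = logging.getLogger("locusdyn.pipeline")


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence([config.seed, STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _setup_logging(outdir: Path, level: str) -> None:
    log.setLevel(level)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    seed = _stage_seed(config, "simulate")
    rng = np.random.default_rng(seed)
    if config.generator == "surrogate":
        surr = config.surrogate
        surr = type(surr)(**{**surr.__dict__, "seed": seed})
        trajs = simulate_surrogate_pair(surr)
    elif config.generator == "rouse":
        sim = config.simulation
        sim = type(sim)(**{**sim.__dict__, "seed": seed})
        trajs = simulate_rouse_chain(sim)
    else:
        raise ValueError(f"unknown generator {config.generator!r}")
    if config.overlay_states:
        trajs = [overlay_state_process(t, config.kinetics, rng) for t in trajs]
    observed = [apply_measurement(t, config.measurement, rng) for t in trajs]
    write_trajectories(observed, outdir / "trajectories.csv")
    write_state_table(observed, outdir / "true_states.csv")
    log.info("simulate: %d trajectories written", len(observed))


def stage_infer(config: PipelineConfig, outdir: Path) -> None:
    trajs = read_trajectories(outdir / "trajectories.csv")
    trajs, report = qc_filter(trajs, min_points=config.min_points)
    seed = _stage_seed(config, "infer")
    by_s: dict[float, list] = {}
    for t in trajs:
        by_s.setdefault(t.separation_kb, []).append(t)
    rows = []
    params_out = {}
    for s in sorted(by_s):
        params = fit_hmm(
            by_s[s],
            max_iter=config.hmm_max_iter,
            tol=config.hmm_tol,
            n_restarts=config.hmm_restarts,
            seed=seed,
        )
        params_out[s] = {
            "sigma": [float(x) for x in params.sigma],
            "transmat": [[float(x) for x in row] for row in params.transmat],
            "startprob": [float(x) for x in params.startprob],
            "intensity_bg": [float(x) for x in params.intensity_bg],
            "intensity_on": [float(x) for x in params.intensity_on],
            "log_likelihood": float(params.log_likelihood),
            "converged": bool(params.converged),
            "flags": list(params.flags),
        }
        for traj in by_s[s]:
            path = decode_states(traj, params)
            for k in range(len(path.states)):
                rows.append(
                    {
                        "embryo": traj.embryo_id,
                        "nucleus": traj.traj_id,
                        "frame": k,
                        "s_kb": s,
                        "state": int(path.states[k]),
                        "p_O_off": path.posteriors[k, 0],
                        "p_P_off": path.posteriors[k, 1],
                        "p_P_on": path.posteriors[k, 2],
                        "missing": bool(path.missing[k]),
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "decoded_states.csv", index=False)
    with open(outdir / "hmm_params.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"per_separation": params_out, "qc": report}, fh)
    log.info("infer: decoded %d separations", len(by_s))


def _load_paths(outdir: Path) -> list[StatePath]:
    table = pd.read_csv(outdir / "decoded_states.csv")
    dt = _frame_interval(outdir)
    paths = []
    for (_, nucleus), grp in table.groupby(["embryo", "nucleus"], sort=False):
        grp = grp.sort_values("frame")
        paths.append(
            StatePath(
                traj_id=str(nucleus),
                separation_kb=float(grp["s_kb"].iloc[0]),
                states=grp["state"].to_numpy(dtype=int),
                posteriors=grp[["p_O_off", "p_P_off", "p_P_on"]].to_numpy(float),
                missing=grp["missing"].to_numpy(dtype=bool),
                frame_interval=dt,
                log_likelihood=float("nan"),
            )
        )
    return paths


def _frame_interval(outdir: Path) -> float:
    trajs = read_trajectories(outdir / "trajectories.csv")
    return trajs[0].frame_interval


def stage_kinetics(config: PipelineConfig, outdir: Path) -> None:
    seed = _stage_seed(config, "kinetics")
    paths = _load_paths(outdir)
    dwells = extract_dwells(paths)
    pd.DataFrame(
        [
            {
                "state": d.state,
                "duration_s": d.duration,
                "left_censored": d.left_censored,
                "right_censored": d.right_censored,
                "trajectory": d.traj_id,
            }
            for d in dwells
        ]
    ).to_csv(outdir / "dwells.csv", index=False)

    occ = state_occupancy(paths)
    occ.to_csv(outdir / "occupancies.csv", index=False)
    p_s = pairing_probability(paths, n_boot=config.n_bootstrap, seed=seed)
    p_s.to_csv(outdir / "pairing_probability.csv", index=False)
    cond = conditional_on_fraction(paths, n_boot=config.n_bootstrap, seed=seed)
    cond.to_csv(outdir / "conditional_on_fraction.csv", index=False)

    # lifetimes of the transcriptionally active state, per separation and pooled
    rows = []
    by_s: dict[float, list] = {}
    for p in paths:
        by_s.setdefault(p.separation_kb, []).append(p)
    for label, group in [("pooled", paths)] + [(s, g) for s, g in sorted(by_s.items())]:
        sub = extract_dwells(group)
        try:
            km = kaplan_meier(sub, state=P_ON)
            mle = exponential_mle(sub, state=P_ON)
            rows.append(
                {
                    "s_kb": label,
                    "km_median_s": km.median,
                    "mle_median_s": mle["median"],
                    "mle_median_lo": mle["median_ci"][0],
                    "mle_median_hi": mle["median_ci"][1],
                    "n_events": km.n_events,
                    "n_censored": km.n_censored,
                }
            )
        except ValueError:
            rows.append({"s_kb": label, "km_median_s": float("nan")})
    pd.DataFrame(rows).to_csv(outdir / "lifetimes.csv", index=False)

    # P(s) ~ s^-f
    usable = p_s[(p_s["p_paired"] > 0) & np.isfinite(p_s["se"])]
    if len(usable) >= 3:
        fit = powerlaw_fit(
            usable["s_kb"], usable["p_paired"], usable["se"], config.fit_range
        )
        pd.DataFrame(
            [{"f_exponent": -fit.exponent, "f_se": fit.exponent_se,
              "prefactor": fit.prefactor, "n_points": fit.n_points}]
        ).to_csv(outdir / "pairing_scaling.csv", index=False)
    log.info("kinetics: %d dwell records", len(dwells))


def stage_dynamics(config: PipelineConfig, outdir: Path) -> None:
    seed = _stage_seed(config, "dynamics")
    trajs = read_trajectories(outdir / "trajectories.csv")
    trajs, _ = qc_filter(trajs, min_points=config.min_points)
    paths = {p.traj_id: p for p in _load_paths(outdir)}
    by_s: dict[float, list] = {}
    for t in trajs:
        by_s.setdefault(t.separation_kb, []).append(t)

    # snap the velocity coarse-graining interval to the frame grid
    dt = trajs[0].frame_interval
    delta = max(1, round(config.vcc_delta / dt)) * dt

    fits = {}
    curves = []
    msd_rows, fit_rows, vcc_rows = [], [], []
    for s in sorted(by_s):
        group = by_s[s]
        m2 = msd_two_locus(
            group, n_boot=config.n_bootstrap, seed=seed, states=paths, state=O_OFF
        )
        fit = fit_rouse_m2(m2, model=config.m2_model, beta=config.m2_beta, seed=seed)
        fits[s] = fit
        c2 = autocorr_two_locus(
            group, n_boot=config.n_bootstrap, seed=seed, states=paths, state=O_OFF
        )
        curves.append(c2)
        vcc = velocity_corr(
            group,
            delta=delta,
            n_boot=config.n_bootstrap,
            seed=seed,
            states=paths,
            state=O_OFF,
        )
        pred = predicted_vcc_intercept(
            delta, fit.tau, beta=fit.beta, family=config.m2_model
        )
        # prediction band from the tau posterior
        tau_lo, tau_hi = fit.intervals["tau"][1], fit.intervals["tau"][3]
        pred_lo = predicted_vcc_intercept(
            delta, tau_hi, beta=fit.beta, family=config.m2_model
        )
        pred_hi = predicted_vcc_intercept(
            delta, tau_lo, beta=fit.beta, family=config.m2_model
        )
        for lag, val, se_, npair in zip(m2.lags, m2.values, m2.se, m2.n_pairs):
            msd_rows.append(
                {"s_kb": s, "lag_s": lag, "m2_nm2": val, "se": se_, "n_pairs": npair}
            )
        fit_rows.append(
            {
                "s_kb": s,
                "gamma_diff": fit.gamma_diff,
                "plateau_nm2": fit.plateau,
                "tau_s": fit.tau,
                "tau_lo": tau_lo,
                "tau_hi": tau_hi,
                "beta": fit.beta,
                "model": fit.model,
                "converged": fit.converged,
            }
        )
        vcc_rows.append(
            {
                "s_kb": s,
                "delta_s": delta,
                "intercept_ratio": vcc.intercept_ratio,
                "intercept_se": vcc.intercept_se,
                "predicted": pred,
                "predicted_lo": pred_lo,
                "predicted_hi": pred_hi,
            }
        )

    pd.DataFrame(msd_rows).to_csv(outdir / "two_locus_msd.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(outdir / "m2_fits.csv", index=False)
    pd.DataFrame(vcc_rows).to_csv(outdir / "velocity_correlations.csv", index=False)

    alpha_fit = diffusivity_scaling(fits, fit_range=config.fit_range)
    gamma_fit = relaxation_scaling(fits, fit_range=config.fit_range)
    collapse = collapse_gamma(curves)
    corr_rows = []
    for c in curves:
        for lag, v, vmsd in zip(c.lags, c.c2, c.c2_from_msd):
            corr_rows.append(
                {"s_kb": c.separation_kb, "lag_s": lag, "c2_nm2": v,
                 "c2_from_msd": vmsd, "r2_nm2": c.r2}
            )
    pd.DataFrame(corr_rows).to_csv(outdir / "autocorrelations.csv", index=False)

    # single-locus dynamic exponent over intermediate lags
    m1 = msd_single(trajs, n_boot=config.n_bootstrap, seed=seed)
    nlag = len(m1.lags)
    sl = slice(0, max(3, nlag // 3))
    beta_fit = powerlaw_fit(m1.lags[sl], m1.values[sl], m1.se[sl])
    pd.DataFrame(
        [{"lag_s": l, "m1_nm2": v, "se": e} for l, v, e in zip(m1.lags, m1.values, m1.se)]
    ).to_csv(outdir / "single_locus_msd.csv", index=False)

    # mean open-state distance per separation -> 1/d
    dist_rows = []
    for s in sorted(by_s):
        vals = []
        for t in by_s[s]:
            path = paths.get(t.traj_id)
            if path is None:
                continue
            d = compute_distance(t)
            sel = (~d.missing) & (path.states == O_OFF)
            vals.extend(d.distance[sel].tolist())
        if vals:
            vals = np.asarray(vals)
            dist_rows.append(
                {
                    "s_kb": s,
                    "mean_distance_nm": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                    "n_frames": len(vals),
                }
            )
    dist_tab = pd.DataFrame(dist_rows)
    dist_tab.to_csv(outdir / "open_state_distances.csv", index=False)
    invd_fit = None
    if len(dist_tab) >= 3:
        invd_fit = powerlaw_fit(
            dist_tab["s_kb"], dist_tab["mean_distance_nm"], dist_tab["se"],
            config.fit_range,
        )

    summary = {
        "alpha": alpha_fit.exponent,
        "alpha_se": alpha_fit.exponent_se,
        "gamma_scaling": gamma_fit.exponent,
        "gamma_scaling_se": gamma_fit.exponent_se,
        "gamma_collapse": collapse.gamma,
        "gamma_collapse_se": collapse.gamma_se,
        "beta_single_locus": beta_fit.exponent,
        "beta_single_locus_se": beta_fit.exponent_se,
    }
    if invd_fit is not None:
        summary["inv_d"] = invd_fit.exponent
        summary["inv_d_se"] = invd_fit.exponent_se
    pd.DataFrame([summary]).to_csv(outdir / "scaling_exponents.csv", index=False)
    log.info("dynamics: gamma_scaling=%.3f gamma_collapse=%.3f",
             gamma_fit.exponent, collapse.gamma)


REPORT_DEPS = {
    "occupancy": ["occupancies.csv"],
    "lifetimes": ["lifetimes.csv"],
    "pairing": ["pairing_probability.csv", "conditional_on_fraction.csv"],
    "msd_fits": ["m2_fits.csv"],
    "scaling": ["scaling_exponents.csv"],
    "velocity": ["velocity_correlations.csv"],
}


def make_report(outdir) -> dict:
    """Collect the figure-analog summary tables of a completed run.

    Returns a dict of DataFrames (occupancy, lifetimes, pairing, msd_fits,
    scaling, velocity) and writes one combined ``report.yaml``.  Raises a
    named-dependency error listing every missing upstream table.
    """
    outdir = Path(outdir)
    missing = [
        f
        for files in REPORT_DEPS.values()
        for f in files
        if not (outdir / f).exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"missing upstream table(s): {sorted(set(missing))}; "
            "run the corresponding pipeline stages first"
        )
    report = {
        name: pd.concat([pd.read_csv(outdir / f) for f in files], axis=1)
        for name, files in REPORT_DEPS.items()
    }
    scal = report["scaling"].iloc[0]
    summary = {
        "version": __version__,
        "gamma_scaling": float(scal["gamma_scaling"]),
        "gamma_collapse": float(scal["gamma_collapse"]),
        "alpha": float(scal["alpha"]),
        "beta_single_locus": float(scal["beta_single_locus"]),
    }
    if "inv_d" in scal:
        summary["inv_d"] = float(scal["inv_d"])
    pooled = report["lifetimes"][report["lifetimes"]["s_kb"] == "pooled"]
    if len(pooled) and np.isfinite(pooled["km_median_s"].iloc[0]):
        summary["km_median_lifetime_min"] = float(pooled["km_median_s"].iloc[0]) / 60.0
    with open(outdir / "report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "infer": stage_infer,
    "kinetics": stage_kinetics,
    "dynamics": stage_dynamics,
}


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in order; returns the run directory.

    Deterministic for a fixed global seed.  A stage failure aborts with
    the failing stage named; tables from completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    save_config(config, outdir / "config_snapshot.yaml")
    (outdir / "VERSION").write_text(__version__ + "\n", encoding="utf-8")
    for stage in config.stages:
        if stage == "report":
            make_report(outdir)
            continue
        func = _STAGE_FUNCS.get(stage)
        if func is None:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            func(config, outdir)
        except Exception as exc:
            log.error("stage %r failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    return outdir
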