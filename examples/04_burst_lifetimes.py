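"""Transcriptional burst lifetimes with censoring-aware survival analysis.

Dwells of the transcribing P_on state are extracted from ground-truth
state paths; runs touching a trajectory boundary or a masked gap are
censored.  The Kaplan-Meier estimator and the censoring-aware exponential
MLE both recover the ~10 min median lifetime encoded in the kinetics.
"""

import numpy as np

from locusdyn import (
    StateKinetics,
    SurrogateConfig,
    exponential_mle,
    extract_dwells,
    kaplan_meier,
    overlay_state_process,
    simulate_surrogate_pair,
)
from locusdyn.hmm import StatePath
from locusdyn.simulate import P_ON

rng = np.random.default_rng(3)
kinetics = StateKinetics(pairing_rate=5e-3)
config = SurrogateConfig(seed=2, n_trajectories=300, separations=(100.0,))
trajectories = [
    overlay_state_process(t, kinetics, rng) for t in simulate_surrogate_pair(config)
]
paths = [
    StatePath(
        traj_id=t.traj_id, separation_kb=t.separation_kb, states=t.states,
        posteriors=np.zeros((t.n_frames, 3)), missing=t.missing,
        frame_interval=t.frame_interval, log_likelihood=0.0,
    )
    for t in trajectories
]

dwells = extract_dwells(paths)
km = kaplan_meier(dwells, state=P_ON)
mle = exponential_mle(dwells, state=P_ON)
print(f"P_on dwells: {km.n_events} events, {km.n_censored} censored")
print(f"Kaplan-Meier median lifetime:   {km.median / 60:.1f} min")
print(f"exponential-MLE median lifetime: {mle['median'] / 60:.1f} min "
      f"(95% CI {mle['median_ci'][0] / 60:.1f}-{mle['median_ci'][1] / 60:.1f})")
print(f"generator median: {np.log(2) / kinetics.off_rate / 60:.1f} min")
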