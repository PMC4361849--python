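"""Extract hidden conformational states from a simulated smFRET photon stream.

Simulates three photon traces from a 3-state Markov system (efficiencies
0.3 / 0.55 / 0.8), bins them at 3 ms, and runs the full state-extraction
pipeline. Prints the selected number of states, their mean efficiencies,
populations and escape times.
"""

import numpy as np

from scism import PhotonSimSpec, RunConfig, SelectionConfig, simulate_photons
from scism.io import bin_photons, compute_fret_trajectory
from scism.pipeline import run_on_trajectories

sim = simulate_photons(PhotonSimSpec(seed=11, n_traces=3, duration=40.0))
trajs = []
for i, stream in enumerate(sim.streams):
    counts = bin_photons(stream, 3e-3)
    trajs.append(compute_fret_trajectory(counts, 3e-3, trajectory_id=f"trace{i}"))

config = RunConfig(
    seed=1,
    observable_range=(0.0, 1.0),
    boot_batch=40,
    boot_cap=400,
    n_boot_dist=20,
    selection=SelectionConfig(n_max=5, restarts_initial=4, restarts_anneal=1),
)
result = run_on_trajectories(trajs, config)

pk = (result.assignment * result.segments.prior[:, None]).sum(axis=0)
means = result.state_mean_observables()
print(f"selected {result.n_states} states (distortion cutoff {result.self_distortion.cutoff:.4f})")
for k in range(result.n_states):
    tau = result.kinetics.escape_time_s.get(k, float("nan"))
    lo, hi = result.kinetics.escape_ci_s.get(k, (float("nan"),) * 2)
    print(
        f"  state {k}: <E> = {means[k]:.2f}  population = {pk[k]*100:.0f}%  "
        f"escape = {tau*1e3:.0f} ms (95% CI {lo*1e3:.0f}-{hi*1e3:.0f})"
    )
# The three states correspond to the apparent efficiencies of the simulated
# levels (true E shifted slightly by background and crosstalk); escape times
# approximate the 500 ms mean dwell of the generating Markov process at the
# 99 ms segment resolution.
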