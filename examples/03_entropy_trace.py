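"""Entropy-based source estimation along one simulated search.

Recomputes the posterior over candidate source cells from the encounter
history up to each evaluation time and prints how the relative entropy
S_t/S_0 and the source-estimate error evolve.
"""

import numpy as np

from entotaxis import (
    EncounterSeries, PlumeParameters, ScenarioConfig, SourceGrid,
    Trajectory, entropy_trace, simulate_moth,
)

p = PlumeParameters()
traj, enc = simulate_moth(ScenarioConfig(seed=7))
grid = SourceGrid.from_arena((-0.1, 0.25), (-0.15, 0.15), 0.01)

idx = np.arange(0, len(traj), 5)   # 20 Hz for the likelihood integral
if idx[-1] != len(traj) - 1:
    idx = np.append(idx, len(traj) - 1)
coarse = Trajectory(traj.t[idx], traj.x[idx], traj.y[idx])
series = EncounterSeries(enc.times, float(traj.t[0]), float(traj.t[-1]),
                         positions_mm=enc.positions_mm)
eval_times = np.linspace(traj.t[0], traj.t[-1], 11)
tr = entropy_trace(coarse, series, p, grid, eval_times,
                   true_source_m=p.r0)

print(" t (s)   S_t/S_0   est. error (mm)")
for t, s, e in zip(tr.eval_times, tr.S_rel, tr.est_error_m * 1000.0):
    print(f"{t:6.1f}   {s:7.3f}   {e:8.1f}")
print("-> entropy falls as detections (and silences) accumulate, and "
      "the posterior mode closes in on the true source.")
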