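"""Encounter-rate field and a closed-form posterior check.

Builds the default advection-diffusion plume (sensor size 10 mm, E=1,
tau=6.3 s, D=0.057 m^2/s, wind 0.6 m/s), prints the decay length and the
rate at a few positions, then verifies the Bayesian machinery against
the zero-encounter closed form for a stationary searcher.
"""

import numpy as np

from entotaxis import (
    EncounterSeries, PlumeParameters, SourceGrid, Trajectory,
    encounter_rate, entropy, log_likelihood_grid, posterior_from_loglik,
)

p = PlumeParameters()
print(f"decay length lambda = {p.lambda_:.5f} m")
for label, pos in [("50 mm downwind", (0.05, 0.0)),
                   ("50 mm upwind", (-0.05, 0.0)),
                   ("150 mm downwind (start)", (0.15, 0.0))]:
    r = float(encounter_rate(np.array(pos), p))
    print(f"encounter rate {label}: {r:.3f} /s")
print("-> the plume decays more slowly downwind; a moth at the start "
      "position meets odor about once every 15 s.")

# stationary searcher, 30 s, no detections: absence of odor is evidence
grid = SourceGrid.from_arena((-0.05, 0.05), (-0.05, 0.05), 0.01)
traj = Trajectory(np.array([0.0, 30.0]), np.array([150.0, 150.0]),
                  np.array([0.0, 0.0]))
enc = EncounterSeries(np.empty(0), 0.0, 30.0)
post = posterior_from_loglik(log_likelihood_grid(enc, traj, p, grid), grid)
R = encounter_rate(np.array([0.15, 0.0]), p, r0=grid.centers)
closed = np.exp(-R * 30.0)
closed /= closed.sum()
print(f"max |pipeline - closed form| = "
      f"{np.max(np.abs(post.probs - closed)):.2e}")
print(f"posterior entropy {entropy(post):.4f} nats "
      f"(uniform prior would be {np.log(grid.n_cells):.4f})")
print("-> 30 s of silence already rules out nearby source cells.")
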