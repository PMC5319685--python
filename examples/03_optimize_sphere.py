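"""Particle swarm optimization on a standard benchmark.

Minimizes the 5-D sphere function sum(x^2) with the default swarm: 40
particles, 200 iterations, linearly decreasing inertia (0.9 -> 0.3) and
time-varying learning factors (cognitive 2.5 -> 0.5, social 0.5 -> 2.5).
The best-fitness history is monotone non-increasing; the final value
should be far below 1e-3.
"""

import numpy as np

from emdcast import pso

best, fitness, history = pso.optimize(
    lambda x: float(np.sum(x * x)), dimension=5, cfg=pso.PSOConfig(seed=1)
)
for it in (0, 9, 49, 99, len(history) - 1):
    print(f"  iteration {it + 1:3d}: best fitness {history[it]:.3e}")
print(f"\nfinal best position (should be near the origin): {np.round(best, 4)}")
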