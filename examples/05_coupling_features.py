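"""Multiscale transfer entropy and transition-network features.

The 30-s HR, DC and activity grids are coarse-grained at scales 1-10;
transfer entropy (adaptive-partition estimator) quantifies directed
coupling per scale, and the 3-D partition of the joint cloud yields a
transition network with 11 graph metrics.
"""

import numpy as np

from physiomot import (
    VAR1Params, analytic_te_var1, build_transition_network, network_metrics,
    simulate_var1, transfer_entropy, TrivariateGrid,
)

# --- transfer entropy against its closed-form oracle -------------------
p = VAR1Params(a=0.5, gamma=0.8, b=0.5)
act, hr = simulate_var1(p, 10000, seed=1)
est = transfer_entropy(act, hr)
print(f"TE act->hr estimate {est:.4f} nats | closed form {analytic_te_var1(p):.4f} nats")
print(f"TE hr->act (no coupling this way): {transfer_entropy(hr, act):.4f} nats")

# --- transition network on a synthetic trivariate grid ------------------
rng = np.random.default_rng(2)
n = 2880
grid = TrivariateGrid(
    t=30.0 * np.arange(n),
    hr=80 + np.cumsum(rng.normal(0, 0.5, n)) * 0.1 + rng.normal(0, 2, n),
    dc=5 + rng.normal(0, 1, n),
    act=np.abs(rng.normal(20, 8, n)),
)
for scale in (1, 5, 10):
    net = build_transition_network(grid, scale)
    m = network_metrics(net)
    print(f"scale {scale:2d}: nodes={m['n_nodes']:.0f} loops={m['n_loops']:.0f} "
          f"loop3={m['loop3']:.0f} radius={m['radius']:.0f} "
          f"spectral_radius={m['spectral_radius']:.2f} energy={m['energy']:.0f}")
# Structured dynamics produce richer partitions (more nodes, more cycles)
# than independent noise; the metrics shrink as coarse-graining removes
# fast structure.
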