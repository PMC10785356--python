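"""The random walk with restart that powers the topology-based methods.

Seeds a directed network with per-gene |t|-scores, iterates
W_{t+1} = (1-r) M^T W_t + r W_0 to convergence, and checks the stationary
vector against the closed-form solve r (I - (1-r) M^T)^{-1} W_0.
"""

import numpy as np
import pandas as pd

import pathact as pa
from pathact.topology import WalkConfig

net = pa.generate_synthetic_network(n_nodes=12, n_edges=30, seed=9)
rng = np.random.default_rng(0)
seed_scores = rng.exponential(size=12)  # stands in for per-gene |t|
w0 = pd.Series(seed_scores / seed_scores.sum(), index=net.nodes)

res = pa.random_walk_restart(net, w0, WalkConfig(restart=0.7, tolerance=1e-10))
exact = pa.closed_form_walk(net, w0, restart=0.7)

print(f"network: {net.n_nodes} nodes, {net.n_edges} edges, "
      f"dangling = {net.dangling or 'none'}")
print(f"converged in {res.iterations} iterations, final L1 residual "
      f"{res.residual:.2e}, total probability {res.w_inf.sum():.12f}")
print(f"max |iterative - closed form| = "
      f"{np.abs(res.w_inf - exact).max():.2e}\n")

table = pd.DataFrame({"seed w0": w0, "stationary w_inf": res.w_inf})
print(table.sort_values("stationary w_inf", ascending=False).round(4).to_string())
print("\nThe stationary weights blend a gene's own seed score (restart mass) "
      "with what flows in from its neighbours; hubs fed by high-|t| genes "
      "gain weight, which is what the DRW-family activities exploit.")
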