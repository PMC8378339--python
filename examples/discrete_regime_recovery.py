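"""Recovering discrete rate regimes the fitter was never told about.

An ordered three-state Markov chain paints low / medium / high diffusion
regimes (sigma^2 = 0.1, 1, 10) on a 50-tip tree, with each transition at an
edge midpoint; traits are simulated under those regimes.  The penalized fit
(lambda = 0.1) knows nothing of the painting, yet the mean estimated rate
within each regime lands near the generating value.
"""

import numpy as np

import ratesmooth as rs

sim = rs.simulate_scenario("mk", n_tips=50, seed=3)
fm = rs.fit_multirate(sim.tree, sim.trait_vector(), lam=0.1)

print(f"{len(sim.painting.shift_edges)} regime shifts on the tree\n")
print("regime    generating   n nodes   mean estimated sigma2")
for st, name, gen in ((0, "low", 0.1), (1, "medium", 1.0), (2, "high", 10.0)):
    ids = [v for v in range(1, sim.tree.n_nodes + 1)
           if sim.painting.node_state[v] == st]
    mean_est = np.mean([fm.sigma2[v] for v in ids]) if ids else float("nan")
    print(f"{name:<9} {gen:>9.1f}   {len(ids):>7d}   {mean_est:>12.3f}")

print("\nIndividual node estimates scatter widely, but averaging within a "
      "regime brings the estimate close to the generating value.  Regimes "
      "painted on only a handful of terminal nodes are an exception: a "
      "single trait realization carries too little signal there, and the "
      "penalty shrinks those rates toward the background.")
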