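"""Coupled finite-difference sensitivity on a model with a known answer.

For the pure birth process 0 -> S at rate c, E[X(t)] = c t, so the exact
parametric sensitivity is dE[X(t)]/dc = t. The example estimates it with all
three couplings and prints the estimate, its Monte Carlo standard error and
the truth at t = 1.
"""

import numpy as np

from stochident import FDConfig, estimate_sensitivity
from stochident.network import ParameterSet, PropensityDescriptor, ReactionNetwork
from stochident.simulate import uniform_grid

net = ReactionNetwork(["S"], np.array([[1]]),
                      [PropensityDescriptor("zeroth", (), rate_param=0)],
                      ["c"])
c = ParameterSet(np.array([25.0]), ("c",))
grid = uniform_grid(1.0, 5)

print("d E[X(1)]/dc for the Poisson birth process (truth: 1.0)")
for est in ("CFD", "CRP", "CRN"):
    cfg = FDConfig(estimator=est, R=4000, theta=0.05, seed=7)
    tensor, _ = estimate_sensitivity(net, c, np.array([0]), grid, cfg)
    v, se = tensor.values[-1, 0, 0], tensor.stderr[-1, 0, 0]
    print(f"  {est}: {v:.4f} +- {se:.4f}")
print()
print("All three are unbiased for the forward difference; the standard")
print("errors shrink with coupling tightness (CFD tightest, CRN loosest),")
print("which is why CFD needs far fewer pairs for table-quality estimates.")
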