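"""Full deterministic identifiability analysis of the Michaelis-Menten model.

Forward sensitivity ODEs give dX/dc along the mass-action solution; the
pipeline assembles the non-dimensional sensitivity matrix, ranks parameters
by their root-mean-square sensitivity delta, and scores every parameter
subset with the collinearity index CI (identifiable when delta > 0.2 for
every member and CI <= 20).
"""

import numpy as np

from stochident import RunConfig, run_pipeline

report, _ = run_pipeline(RunConfig(model="michaelis_menten", backend="RRE"))

names = ["c1", "c2", "c3"]
print("parameter importance (delta, root-mean-square non-dimensional sensitivity):")
for n, d in zip(names, report.delta):
    print(f"  {n}: {d:.4f}")
print(f"ranked (delta > 0.2): {[names[k] for k in report.ranked_params]}")
print()
print("subset collinearity (CI = 1/sqrt(min eigenvalue of the unit-column Gram)):")
for s in report.subsets:
    label = " ".join(names[i] for i in s.indices)
    verdict = "identifiable" if s.identifiable else "not identifiable"
    print(f"  {{{label}}}: CI = {s.ci:.3f}  ({verdict})")
print(f"singular values: {np.round(report.singular_values, 3)} (rank {report.rank})")
print()
print("Reading: the binding (c1) and catalytic (c3) rates are important and")
print("only mildly collinear (CI ~ 2.2), so {c1, c3} can be estimated from")
print("species trajectories; the dissociation rate c2 barely moves the means")
print("(delta ~ 0.002) and cannot be estimated at this operating point.")
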