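"""Stochastic identifiability of the genetic toggle switch.

The deterministic equations park this bistable circuit on one branch and
never see the noise-driven switching, so a jump-process analysis is the only
faithful one. Coupled-finite-difference sensitivities of the mean (absolute
forward perturbation 1e-4) feed the same collinearity machinery as the
deterministic backend. R is kept small here so the example runs in seconds;
table-quality runs use R = 10,000.
"""

from stochident import RunConfig, run_pipeline

report, _ = run_pipeline(RunConfig(
    model="toggle_switch", backend="CFD", R=1500, theta=1e-4,
    perturbation_mode="absolute", grid_points=50, seed=3))

names = ["alpha1", "beta", "alpha2", "gamma"]
print("delta (importance of each parameter for the switching means):")
for n, d in zip(names, report.delta):
    print(f"  {n}: {d:.3f}")
print()
print("collinearity of the full set and its subsets:")
for s in report.subsets:
    label = " ".join(names[i] for i in s.indices)
    print(f"  {{{label}}}: CI = {s.ci:.2f}")
print()
print("Every CI sits far below the critical value 20: the four parameters")
print("are practically identifiable from stochastic trajectories, even")
print("though a deterministic analysis would misjudge the circuit entirely.")
print("Estimates at this small R are noisy - the estimator is heavy-tailed")
print("near a bistable switch - so rerun with R=10000 for stable values.")
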