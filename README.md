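# stochident

Practical parameter identifiability for stochastic discrete models of
well-stirred biochemical reaction networks.

## The problem

A reaction network with state `X(t) ∈ ℕ^N` (molecule counts of N species)
and M reactions evolves as a jump Markov process: reaction `R_j` fires at
propensity `a_j(x, c)` and shifts the state by its stoichiometric column
`ν_j`. The probability law of this process is the chemical master equation
(CME). Fitting such a model to data requires estimating the kinetic
parameters `c = (c_1, …, c_P)` — but not every parameter *can* be estimated:
a parameter may barely move the observable means, or a group of parameters
may compensate for one another. This package decides, before any fitting is
attempted, **which parameter subsets are practically identifiable** from
trajectory data of a stochastic discrete model, where the classical
ODE-based identifiability toolkit does not directly apply.

## The method

1. **Sensitivities of the mean.** `S_ik(t) = ∂E[X_i(t)]/∂c_k` is estimated
   by forward finite differences over *coupled* pairs of exact trajectories,

   `Z^(r)(t) = (X^(r)(t, c + θ e_k) − X^(r)(t, c)) / θ`,   `S ≈ mean_r Z^(r)`,

   with three couplings of increasing tightness: common random numbers
   (CRN: two SSA runs sharing one uniform stream), common reaction paths
   (CRP: two random-time-change runs sharing per-reaction Exp(1) streams),
   and coupled finite differences (CFD: one joint jump process with a shared
   `min(a_j, a_j′)` channel plus two residual channels per reaction). Two
   reference backends — forward sensitivity ODEs for the reaction-rate
   equations (RRE) and pathwise sensitivities of the chemical Langevin
   equation (CLE) — cross-validate the stochastic estimates.

2. **Non-dimensional sensitivity matrix.** On a grid `t_1 < … < t_L` the
   entries `s_ik(t_ℓ) = c_k / E[X_i(t_ℓ)] · S_ik(t_ℓ)` are stacked into an
   `n × P` matrix `s` (one row per time point and species; rows with
   vanishing means are masked).

3. **Identifiability metrics.**
   * importance: `δ_k^msqr = sqrt(1/n Σ_i s_ik²)` (parameters with
     `δ ≤ 0.2` are considered unestimable);
   * collinearity: with unit-normalized columns `s̃_k`,
     `CI_K = 1 / sqrt(λ_min(s̃_Kᵀ s̃_K))` for each subset `K`; `CI_K ≤ 20`
     means the subset is not collinear;
   * the singular spectrum and numerical rank of `s` (the number of
     non-collinear parameters) and the determinant measure
     `ρ_K = det(s_Kᵀ s_K)^{1/2k}`.

   A subset is reported **identifiable** when every member is important and
   its collinearity index is at most the critical value.

Three case-study models ship as fixtures: an infectious-disease network
(5 parameters), the Michaelis–Menten system (3), and a bistable genetic
toggle switch (4: two production strengths and two repression exponents),
whose noise-driven switching makes the deterministic analysis inapplicable.

## Worked example

`python examples/03_identifiability_deterministic.py` prints:

```
parameter importance (delta, root-mean-square non-dimensional sensitivity):
  c1: 1.1029
  c2: 0.0019
  c3: 1.3122
ranked (delta > 0.2): ['c3', 'c1']

subset collinearity (CI = 1/sqrt(min eigenvalue of the unit-column Gram)):
  {c2 c3}: CI = 1.879  (not identifiable)
  {c1 c3}: CI = 2.179  (identifiable)
  {c1 c2}: CI = 5.014  (not identifiable)
  {c1 c2 c3}: CI = 5.520  (not identifiable)
```

Reading: the Michaelis–Menten binding (c1) and catalytic (c3) rates both
move the species means strongly (δ ≈ 1.1 and 1.3) and their sensitivity
directions are only mildly collinear (CI ≈ 2.2), so the pair {c1, c3} can be
estimated from trajectory data; the dissociation rate c2 leaves the means
essentially untouched (δ ≈ 0.002) and is not estimable at this operating
point, which is why every subset containing it is rejected. The other
examples simulate trajectories with all four backends, check the coupled
estimators against a closed-form sensitivity, and run the fully stochastic
analysis of the toggle switch.

A thin CLI wraps the same pipeline:

```
stochident identify michaelis_menten --backend RRE --outdir out/
stochident identify toggle_switch --backend CFD --theta 1e-4 --absolute -R 2000
```

Models can also be given as YAML files (`species`, `reactions` with
propensity kind/rate, `parameters`, `initial_state`, `horizon`); see
`stochident.save_model` for the exact schema.

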