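# Methods

This note records the models, estimators, numerical conventions and design
choices behind `stochident`, and what the shipped tests do and do not
establish.

## Model class

A network is N species, an integer N×M stoichiometric matrix, and one
propensity descriptor per reaction drawn from five forms: constant
(`a = k`), unimolecular (`k x_m`), bimolecular distinct (`k x_m x_n`),
dimerisation (`k x_m (x_m − 1)/2`), and rational repression
(`p / (1 + x_reg^q)`). Rates reference named parameter slots, so a slot may
be shared, a repression reaction owns two slots (strength `p`, exponent
`q`), and a fixed-rate reaction (e.g. unit-rate degradation) may own none —
parameters, not reactions, are the axis of the sensitivity and
identifiability layers. Conventions at the state boundary: `0^0 = 1` and
`x^q = 0` for `x = 0, q > 0`; the exponent derivative uses
`x^q ln x → 0` as `x → 0+`; propensities are clamped at 0 (relevant only to
the continuous backends, where Euler steps may graze negative states).

## Simulators

* **SSA** (direct method): per event two uniforms give the waiting time
  `τ = −ln η₁ / a₀` and the reaction index (smallest j with cumulative
  propensity exceeding `η₂ a₀`).
* **RTC / next reaction**: per-reaction internal clocks advance by
  `∫ a_j dt` and fire against cumulative sums of unit-rate exponentials
  (modified next-reaction scheme). Distributionally equivalent to SSA; its
  per-reaction streams are what the CRP and CFD couplings share.
* **CLE**: Euler–Maruyama with default `dt = 1e-3`; diffusion coefficients
  `sqrt(a_j)` with `a_j` clamped at 0 first; the final sub-step of a grid
  interval is shortened to land exactly on the grid point. The *state* is
  deliberately not clamped: propensity clamping already freezes the noise
  and drift of a channel at an absorbing boundary, whereas clamping the
  state would bias the mean upward for populations near 0 (a pure-birth
  path started at 0 would no longer average to `c t`) and leak conservation
  laws. Small negative excursions are possible and are treated by the
  propensity forms as zero occupancy.
* **RRE**: LSODA with `rtol 1e-8`, `atol 1e-10` by default, so the table
  digits of every deterministic quantity are integrator-independent.

Grid sampling is uniform across backends: the state reported at `t_ℓ`
reflects every event with time ≤ `t_ℓ`. All randomness flows from integer
seeds through counter-keyed PCG64 streams; a (seed, stream, kind) triple
always reproduces the same variate prefix, which is what makes stream
sharing between coupled paths exact and every run bit-reproducible. The
jump kernels carry an event cap (default 1e7) to fail loudly on runaway
models.

## Coupled finite-difference estimators

For parameter slot k, perturbation θ (a fraction of `c_k` in relative mode,
an absolute shift otherwise), pair r yields
`Z(t) = (X′(t) − X(t))/θ`; the sensitivity tensor is the pairwise sample
mean with standard error `sd/√R`. Couplings:

* **CRN**: both paths consume one shared uniform sequence strictly in
  per-event order (η₁ then η₂); after their event counts diverge the paths
  desynchronise — the scheme is deliberately the loosest.
* **CRP**: both paths run the RTC scheme against the same M exponential
  streams, so increment i of stream j is identical across the pair.
* **CFD**: one joint process with three channels per reaction — rate
  `min(a_j, a_j′)` fires both paths, the two residuals fire exactly one —
  each channel driven by its own independent exponential stream, and all 3M
  rates recomputed after every firing. At θ = 0 the residual rates vanish
  identically and the pair is bit-identical.

The mean trajectory used for normalization pools the unperturbed members of
*all* parameter ensembles (they are i.i.d. at `c`), the lowest-variance
estimate available in the run. Perturbations are forward one-sided; the
estimator therefore carries an O(θ) forward-difference bias, which is part
of the quantity being reported (the same convention as the reference
analyses it reproduces).

### Heavy tails near bistability

On the genetic toggle switch with an absolute θ = 1e-4, a coupled pair is
bit-identical unless a residual channel fires (probability of order
`θ · |∂a/∂c| · T` per pair); when it does, the one-molecule discrepancy can
tip one path across the separatrix, producing a persistent branch
divergence and a Z spike of order (branch separation)/θ ≈ 5·10⁵. Sensitivity
estimates, the singular spectrum, and δ values for this model are therefore
*heavy-tailed across seeds* even at R = 10⁴ (the leading singular value
varies by factors of 2–4 between seeds). The collinearity conclusion
(all CI ≤ 20, every subset identifiable) is robust to this noise — the
spike directions are nearly orthogonal across parameters, which if anything
*lowers* CI — but individual spectrum entries are not. The package reports
standard errors precisely so users can see this.

## Identifiability layer

* Non-dimensionalisation `s_ik = c_k / E[X_i] · S_ik`, rows = (time point,
  species). The `t = 0` block is dropped (sensitivities vanish there);
  rows with `E[X_i] ≤ mask_tol` (default `1e-8 · max(mean, 1)`) are masked
  and logged. An `observed` argument restricts rows to measured species —
  what is observed determines what is identifiable.
* `δ^msqr` is the root-mean-square of a column of the **un-normalized**
  matrix. (Normalizing first would force `δ = 1/√n` for every parameter and
  destroy the ranking; the published reference values exceed 1, confirming
  the RMS-of-raw-columns reading.)
* CI uses unit-normalized columns; columns with norm ≤ `zero_tol` (default
  `1e-12 ×` the largest norm) are flagged and any CI touching them is
  reported as *undefined* rather than a number; an exactly singular Gram
  matrix reports CI = ∞. The SVD spectrum and rank in reports are taken
  from the un-normalized matrix (both are exported); the rank tolerance is
  `max(n, P) · eps · σ₁`.
* Subset scoring tabulates CI and ρ for **all** subsets up to
  `max_subset_size` (budget-guarded at 1e5 combinations), while the
  δ-ranking gates only the identifiable verdict: a subset is identifiable
  iff CI is defined, CI ≤ 20 and every member has δ > 0.2. Tabulating
  weak-parameter subsets mirrors the reference tables and keeps the report
  informative about *why* a subset fails.

CI is invariant to positive column rescaling (and thus to the choice of θ
units); δ is not — both facts are asserted by tests. For nested subsets
CI is monotone (Cauchy interlacing), so a collinear core poisons every
superset.

## Grids and problem sizes

The deterministic backends default to L = 500 equally spaced points on
[0, T]: the metrics are time-averages, and by L ≈ 100 they are converged to
well under 1% (a stability test sweeps L ∈ {100, 500, 1000}); the finer
default also resolves the fast transients of the fixtures. The Monte Carlo
backends default to L = 50 (each column already carries sampling error;
finer grids add rows but no information) and R = 10,000 coupled pairs per
parameter for table-quality runs. Unit tests run at R between a few hundred
and a few thousand — enough for their 4-standard-error assertions — and the
acceptance script uses R = 10,000.

## What the fixtures do and do not exercise

The three fixtures are complete study systems, not toys: they cover zeroth-,
first- and second-order mass action, rational repression with exponent
parameters, conservation laws (enzyme system), near-linear dynamics
(infectious disease, where jump-mean ≈ ODE), and bistable switching
(toggle). Passing tests therefore demonstrates correct estimators across
these regimes. They do not exercise: stiff networks (no tau-leaping or
implicit schemes are provided), models with time-varying parameters or
volume dynamics, rate laws outside the five descriptor kinds, or networks
large enough that full subset enumeration is infeasible — the budget guard
exists to refuse, not to solve, that case.

## Known limitations

* CRN/CRP at very small absolute θ on multistable systems can *invert* the
  textbook variance ordering: a CRN pair stays bit-identical until a
  selection threshold flips, while CRP clock drift produces transient ±1
  offsets an order of magnitude more often, each carrying branch-flip risk.
  Measured on the toggle at θ = 1e-4, SD(CFD) < SD(CRN) < SD(CRP); on the
  infectious-disease model at 5% the usual CFD < CRP < CRN holds. CFD is
  the recommended estimator throughout.
* Forward differences are one-sided by design; for strongly curved
  mean-parameter maps choose θ small enough that the O(θ) bias is below the
  Monte Carlo error of the intended R.
* No SBML import; the YAML schema covers exactly the five propensity kinds.
* Direct numerical solution of the master equation is out of scope; all
  jump-process statements are Monte Carlo.
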