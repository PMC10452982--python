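"""Coupled finite-difference sensitivity estimation for the jump process.

For parameter slot k with forward perturbation theta, each coupled pair r
yields the pathwise difference quotient

    Z[r](t) = (X[r](t, c + theta e_k) - X[r](t, c)) / theta,

and the sensitivity of the mean, dE[X(t)]/dc_k, is estimated by the sample
mean of Z over R pairs. Three couplings of the perturbed and unperturbed
paths are provided, in increasing order of coupling tightness (decreasing
estimator variance):

* **CRN** (common random numbers): two SSA runs consuming the *same* uniform
  stream in per-event order (eta1 then eta2); the paths desynchronise once
  their event counts differ.
* **CRP** (common reaction paths): two random-time-change runs sharing one
  unit-rate exponential stream per reaction, so both paths see identical
  internal Poisson clocks.
* **CFD** (coupled finite differences): a single joint jump process with
  three channels per reaction -- a shared channel at rate min(a_j, a_j')
  firing both paths, plus two residual channels firing only one path -- each
  driven by its own independent exponential stream, with all 3M rates
  recomputed after every firing.

At theta = 0 the CRP and CFD couplings reproduce identical paths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import (STATUS_NEED_MORE, cfd_kernel, rtc_kernel, ssa_kernel)
from .network import ModelConfigError, _as_param_vector, validate_state
from .simulate import (DEFAULT_EVENT_CAP, SimulationError, Trajectory,
                       _raise_for_status, check_grid)

__all__ = [
    "FDConfig",
    "CoupledPair",
    "CoupledPairEnsemble",
    "SensitivityTensor",
    "MeanTrajectory",
    "crn_pair",
    "crp_pair",
    "cfd_pair",
    "sample_ensemble",
    "fd_sensitivity",
    "estimate_sensitivity",
]

ESTIMATORS = ("CRN", "CRP", "CFD")
_EST_CODE = {"CRN": 1, "CRP": 2, "CFD": 3}


@dataclass(frozen=True)
class FDConfig:
    """Configuration of a finite-difference sensitivity run.

    ``theta`` is a fraction of each parameter value when
    ``perturbation_mode == "relative"`` (0.05 means a 5% forward bump) and an
    absolute shift when ``"absolute"``.
    """

    estimator: str = "CFD"
    R: int = 10_000
    theta: float = 0.05
    perturbation_mode: str = "relative"
    seed: int = 0
    max_events: int = DEFAULT_EVENT_CAP

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise ModelConfigError(
                f"unknown estimator {self.estimator!r}; expected one of {ESTIMATORS}")
        if self.R < 1:
            raise ModelConfigError("R must be >= 1")
        if self.theta <= 0:
            raise ModelConfigError("theta must be positive")
        if self.perturbation_mode not in ("relative", "absolute"):
            raise ModelConfigError("perturbation_mode must be relative or absolute")

    def theta_abs(self, c, k):
        cv = _as_param_vector(c)
        return float(self.theta * cv[k]) if self.perturbation_mode == "relative" \
            else float(self.theta)


@dataclass
class CoupledPair:
    parameter_index: int
    theta: float
    unperturbed: Trajectory
    perturbed: Trajectory


@dataclass
class CoupledPairEnsemble:
    """R coupled pairs for one parameter, with states kept in memory."""

    parameter_index: int
    theta: float
    grid: np.ndarray
    unperturbed: np.ndarray     # R x L x N
    perturbed: np.ndarray       # R x L x N
    estimator: str
    seed: int

    @property
    def R(self):
        return self.unperturbed.shape[0]

    def pathwise_differences(self):
        """Z[r](t_l, i): the R x L x N array of difference quotients."""
        return (self.perturbed - self.unperturbed) / self.theta


@dataclass
class SensitivityTensor:
    """Estimates of dE[X_i(t_l)]/dc_k on the grid, with Monte Carlo errors."""

    grid: np.ndarray
    values: np.ndarray          # L x N x P
    stderr: np.ndarray          # L x N x P
    R: int
    estimator: str
    theta: np.ndarray           # absolute perturbation per parameter
    seed: int | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise SimulationError("non-finite sensitivity estimate")


@dataclass
class MeanTrajectory:
    """E[X_i(t_l)] estimated from the pooled unperturbed paths."""

    grid: np.ndarray
    means: np.ndarray           # L x N
    stderr: np.ndarray
    n_paths: int = 0


# ---------------------------------------------------------------------------
# variate streams
# ---------------------------------------------------------------------------

def _gen(entropy):
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


def _fill_streams(entropy_base, caps):
    """E[s, :caps[s]] = first caps[s] Exp(1) variates of stream s."""
    E = np.empty((len(caps), int(caps.max())), np.float64)
    for s, cap in enumerate(caps):
        E[s, :cap] = _gen(entropy_base + [s]).standard_exponential(int(cap))
    return E


# ---------------------------------------------------------------------------
# single coupled pairs
# ---------------------------------------------------------------------------

def _run_crn(enc, nu, cv, cvp, x0, grid, entropy, n_start, max_events):
    n = max(int(n_start), 256)
    while True:
        u = _gen(entropy).random(n)
        s1, nev1, used1, st1 = ssa_kernel(*enc, nu, cv, x0, grid, u, max_events)
        s2, nev2, used2, st2 = ssa_kernel(*enc, nu, cvp, x0, grid, u, max_events)
        if st1 != STATUS_NEED_MORE and st2 != STATUS_NEED_MORE:
            break
        n *= 2
    _raise_for_status(st1, "crn_pair (unperturbed)")
    _raise_for_status(st2, "crn_pair (perturbed)")
    return s1, s2, nev1, nev2, max(used1, used2)


def _run_crp(enc, nu, cv, cvp, x0, grid, entropy_base, caps, max_events):
    while True:
        E = _fill_streams(entropy_base, caps)
        s1, nev1, used1, st1, need1 = rtc_kernel(*enc, nu, cv, x0, grid, E,
                                                 caps, max_events)
        s2, nev2, used2, st2, need2 = rtc_kernel(*enc, nu, cvp, x0, grid, E,
                                                 caps, max_events)
        if st1 == STATUS_NEED_MORE:
            caps[need1] *= 2
            continue
        if st2 == STATUS_NEED_MORE:
            caps[need2] *= 2
            continue
        break
    _raise_for_status(st1, "crp_pair (unperturbed)")
    _raise_for_status(st2, "crp_pair (perturbed)")
    return s1, s2, nev1, nev2, caps


def _run_cfd(enc, nu, cv, cvp, x0, grid, entropy_base, caps, max_events):
    while True:
        E = _fill_streams(entropy_base, caps)
        s1, s2, nev, used, st, need = cfd_kernel(*enc, nu, cv, cvp, x0, grid,
                                                 E, caps, max_events)
        if st == STATUS_NEED_MORE:
            caps[need] *= 2
            continue
        break
    _raise_for_status(st, "cfd_pair")
    return s1, s2, nev, nev, caps


def _pair(net, c, x0, k, theta, grid, seed, r, estimator, caps=None,
          max_events=DEFAULT_EVENT_CAP):
    grid = check_grid(grid)
    x0 = validate_state(net, x0).astype(np.int64)
    cv = _as_param_vector(c).copy()
    if not 0 <= k < net.n_params:
        raise ModelConfigError(f"parameter index {k} out of range")
    if theta < 0:
        raise ModelConfigError("theta must be non-negative")
    cvp = cv.copy()
    cvp[k] += theta
    enc = net.encoded()
    nu = net.stoich
    ent = [int(seed), _EST_CODE[estimator], int(k), int(r)]
    if estimator == "CRN":
        n_start = caps[0] if caps is not None else 256
        s1, s2, nev1, nev2, used = _run_crn(enc, nu, cv, cvp, x0, grid,
                                            ent + [0], n_start, max_events)
        if caps is not None:
            caps[0] = max(caps[0], int(2.5 * used))
    elif estimator == "CRP":
        own = caps if caps is not None else np.full(net.n_reactions, 256, np.int64)
        s1, s2, nev1, nev2, _ = _run_crp(enc, nu, cv, cvp, x0, grid, ent, own,
                                         max_events)
    else:
        own = caps if caps is not None else np.full(3 * net.n_reactions, 64, np.int64)
        s1, s2, nev1, nev2, _ = _run_cfd(enc, nu, cv, cvp, x0, grid, ent, own,
                                         max_events)
    return s1, s2, nev1, nev2


def crn_pair(net, c, x0, k, theta, grid, seed, r=0,
             max_events=DEFAULT_EVENT_CAP):
    """One common-random-number coupled pair (theta is absolute)."""
    s1, s2, nev1, nev2 = _pair(net, c, x0, k, theta, grid, seed, r, "CRN",
                               max_events=max_events)
    g = check_grid(grid)
    return CoupledPair(k, theta, Trajectory(g, s1, nev1, seed),
                       Trajectory(g, s2, nev2, seed))


def crp_pair(net, c, x0, k, theta, grid, seed, r=0,
             max_events=DEFAULT_EVENT_CAP):
    """One common-reaction-path coupled pair (theta is absolute)."""
    s1, s2, nev1, nev2 = _pair(net, c, x0, k, theta, grid, seed, r, "CRP",
                               max_events=max_events)
    g = check_grid(grid)
    return CoupledPair(k, theta, Trajectory(g, s1, nev1, seed),
                       Trajectory(g, s2, nev2, seed))


def cfd_pair(net, c, x0, k, theta, grid, seed, r=0,
             max_events=DEFAULT_EVENT_CAP):
    """One coupled-finite-difference pair (theta is absolute)."""
    s1, s2, nev1, nev2 = _pair(net, c, x0, k, theta, grid, seed, r, "CFD",
                               max_events=max_events)
    g = check_grid(grid)
    return CoupledPair(k, theta, Trajectory(g, s1, nev1, seed),
                       Trajectory(g, s2, nev2, seed))


def _fresh_caps(net, estimator):
    if estimator == "CRN":
        return np.array([4096], np.int64)
    if estimator == "CRP":
        return np.full(net.n_reactions, 256, np.int64)
    return np.full(3 * net.n_reactions, 64, np.int64)


def sample_ensemble(net, c, x0, k, grid, config):
    """Generate and keep R coupled pairs for parameter slot k."""
    grid = check_grid(grid)
    theta = config.theta_abs(c, k)
    L, N = grid.size, net.n_species
    unp = np.empty((config.R, L, N), np.int64)
    per = np.empty((config.R, L, N), np.int64)
    caps = _fresh_caps(net, config.estimator)
    for r in range(config.R):
        s1, s2, _, _ = _pair(net, c, x0, k, theta, grid, config.seed, r,
                             config.estimator, caps, config.max_events)
        unp[r] = s1
        per[r] = s2
    return CoupledPairEnsemble(k, theta, grid, unp, per, config.estimator,
                               config.seed)


# ---------------------------------------------------------------------------
# sensitivity estimation
# ---------------------------------------------------------------------------

def fd_sensitivity(ensembles, param_count=None):
    """Combine per-parameter ensembles into a sensitivity tensor.

    ``values[l, i, k]`` is the sample mean of Z[r](t_l, i) over the k-th
    ensemble; ``stderr`` the sample standard deviation over sqrt(R). The
    mean trajectory pools the unperturbed members of all ensembles (i.i.d.
    realizations at the unperturbed parameters).
    """
    if not ensembles:
        raise ModelConfigError("no ensembles given")
    grid = ensembles[0].grid
    L, N = ensembles[0].unperturbed.shape[1:]
    P = param_count if param_count is not None else \
        max(e.parameter_index for e in ensembles) + 1
    R = ensembles[0].R
    if R < 2:
        raise ModelConfigError("R >= 2 pairs are required for a standard error")
    values = np.zeros((L, N, P))
    stderr = np.zeros((L, N, P))
    theta = np.zeros(P)
    msum = np.zeros((L, N))
    msq = np.zeros((L, N))
    n_paths = 0
    for e in ensembles:
        if e.grid.shape != grid.shape or not np.allclose(e.grid, grid):
            raise ModelConfigError("ensembles must share one time grid")
        if e.R != R:
            raise ModelConfigError("ensembles must share R")
        Z = e.pathwise_differences()
        k = e.parameter_index
        values[:, :, k] = Z.mean(axis=0)
        stderr[:, :, k] = Z.std(axis=0, ddof=1) / np.sqrt(e.R)
        theta[k] = e.theta
        msum += e.unperturbed.sum(axis=0)
        msq += (e.unperturbed.astype(np.float64) ** 2).sum(axis=0)
        n_paths += e.R
    means = msum / n_paths
    mvar = np.maximum(msq / n_paths - means ** 2, 0.0)
    mstderr = np.sqrt(mvar / n_paths)
    tensor = SensitivityTensor(grid, values, stderr, R, ensembles[0].estimator,
                               theta, ensembles[0].seed)
    return tensor, MeanTrajectory(grid, means, mstderr, n_paths)


def estimate_sensitivity(net, c, x0, grid, config, param_indices=None,
                         progress=None):
    """Streaming finite-difference estimate over all (or chosen) parameters.

    Memory stays O(L x N x P) regardless of R; the mean trajectory pools the
    unperturbed members of every parameter's ensemble.
    """
    grid = check_grid(grid)
    if config.R < 2:
        raise ModelConfigError("R >= 2 pairs are required for a standard error")
    P = net.n_params
    ks = list(range(P)) if param_indices is None else list(param_indices)
    L, N = grid.size, net.n_species
    values = np.zeros((L, N, P))
    stderr = np.zeros((L, N, P))
    theta = np.zeros(P)
    msum = np.zeros((L, N))
    msq = np.zeros((L, N))
    n_paths = 0
    for k in ks:
        th = config.theta_abs(c, k)
        theta[k] = th
        zsum = np.zeros((L, N))
        zsq = np.zeros((L, N))
        caps = _fresh_caps(net, config.estimator)
        for r in range(config.R):
            s1, s2, _, _ = _pair(net, c, x0, k, th, grid, config.seed, r,
                                 config.estimator, caps, config.max_events)
            z = (s2 - s1) / th
            zsum += z
            zsq += z * z
            msum += s1
            msq += s1.astype(np.float64) ** 2
            n_paths += 1
            if progress is not None and (r + 1) % 1000 == 0:
                progress(k, r + 1)
        mean = zsum / config.R
        var = np.maximum((zsq - config.R * mean ** 2) / (config.R - 1), 0.0)
        values[:, :, k] = mean
        stderr[:, :, k] = np.sqrt(var / config.R)
    means = msum / n_paths
    mvar = np.maximum(msq / n_paths - means ** 2, 0.0)
    tensor = SensitivityTensor(grid, values, stderr, config.R,
                               config.estimator, theta, config.seed)
    return tensor, MeanTrajectory(grid, means, np.sqrt(mvar / n_paths), n_paths)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def ensemble_to_hdf5(ensemble, path):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("grid", data=ensemble.grid)
        fh.create_dataset("unperturbed", data=ensemble.unperturbed,
                          compression="gzip")
        fh.create_dataset("perturbed", data=ensemble.perturbed,
                          compression="gzip")
        fh.attrs.update({"parameter_index": ensemble.parameter_index,
                         "theta": ensemble.theta,
                         "estimator": ensemble.estimator,
                         "seed": ensemble.seed})


def sensitivity_to_csv(tensor, path, species_names, param_names):
    """Long-format CSV: time, species, parameter, estimate, stderr."""
    import pandas as pd

    L, N, P = tensor.values.shape
    rows = []
    for l in range(L):
        for i in range(N):
            for k in range(P):
                rows.append((tensor.grid[l], species_names[i], param_names[k],
                             tensor.values[l, i, k], tensor.stderr[l, i, k]))
    pd.DataFrame(rows, columns=["time", "species", "parameter", "estimate",
                                "stderr"]).to_csv(path, index=False)
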