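"""Reference sensitivity backends for cross-validating the jump-process
estimates: forward sensitivity ODEs for the deterministic mass-action model,
and pathwise sensitivities for the diffusion (Langevin) approximation.

Both start from S(0) = 0: at t = 0 the state does not yet depend on the rate
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from ._kernels import cle_pathwise_kernel
from .network import ModelConfigError, _as_param_vector
from .simulate import SimulationError, check_grid

__all__ = [
    "RRESensitivitySolution",
    "CLESensitivityEnsemble",
    "rre_sensitivity",
    "cle_pathwise_sensitivity",
]


@dataclass
class RRESensitivitySolution:
    grid: np.ndarray
    states: np.ndarray          # L x N
    sens: np.ndarray            # L x N x P, dX_i(t)/dc_k


@dataclass
class CLESensitivityEnsemble:
    grid: np.ndarray
    mean_states: np.ndarray     # L x N
    states_stderr: np.ndarray
    mean_sens: np.ndarray       # L x N x P
    sens_stderr: np.ndarray
    R: int
    dt: float
    seed: int


def rre_sensitivity(net, c, x0_real, grid, rtol=1e-8, atol=1e-10):
    """Solve the coupled state + forward-sensitivity ODE system.

    The sensitivity S = dX/dc obeys dS/dt = nu (da/dX S + da/dc) along the
    deterministic trajectory; the joint system has N (1 + P) components.
    """
    grid = check_grid(grid)
    x0 = np.asarray(x0_real, dtype=np.float64)
    cv = _as_param_vector(c)
    enc = net.encoded()
    nu = net.stoich.astype(np.float64)
    N, M = net.n_species, net.n_reactions
    P = net.n_params
    a = np.empty(M, np.float64)
    ds = np.empty((M, N), np.float64)
    dp = np.empty((M, P), np.float64)

    def rhs(t, y):
        x = np.maximum(y[:N], 0.0)
        S = y[N:].reshape(N, P)
        _kernels.props_kernel(*enc, x, cv, a)
        _kernels.prop_derivs_kernel(*enc, x, cv, ds, dp)
        dx = nu @ a
        dS = nu @ (ds @ S + dp)
        return np.concatenate([dx, dS.ravel()])

    y0 = np.concatenate([x0, np.zeros(N * P)])
    sol = solve_ivp(rhs, (0.0, grid[-1]), y0, t_eval=grid, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(
            f"rre_sensitivity: integrator failed after t = {last:g}: {sol.message}")
    states = sol.y[:N].T
    sens = sol.y[N:].T.reshape(grid.size, N, P)
    return RRESensitivitySolution(grid, states, sens)


def cle_pathwise_sensitivity(net, c, x0_real, grid, dt=1e-3, R=1000, seed=0):
    """Monte Carlo pathwise sensitivities of the diffusion approximation.

    Each path integrates the joint (X, dX/dc) Euler-Maruyama system driven by
    one set of Wiener increments; the ensemble mean estimates
    dE[X_i(t_l)]/dc_k. The sensitivity diffusion term is dropped wherever the
    corresponding propensity is 0 (removable singularity under clamping).
    """
    grid = check_grid(grid)
    if dt <= 0:
        raise ModelConfigError("dt must be positive")
    if R < 2:
        raise ModelConfigError("R >= 2 paths are required for a standard error")
    x0 = np.asarray(x0_real, dtype=np.float64)
    cv = _as_param_vector(c)
    enc = net.encoded()
    nuf = net.stoich.astype(np.float64)
    L, N, P = grid.size, net.n_species, net.n_params
    ssum = np.zeros((L, N))
    ssq = np.zeros((L, N))
    zsum = np.zeros((L, N, P))
    zsq = np.zeros((L, N, P))
    root = np.random.SeedSequence([int(seed), 0xC1E5])
    kseeds = root.generate_state(R)
    for r in range(R):
        states, sens = cle_pathwise_kernel(*enc, nuf, cv, x0, grid, float(dt),
                                           int(kseeds[r]), P)
        ssum += states
        ssq += states ** 2
        zsum += sens
        zsq += sens ** 2
    mean_states = ssum / R
    svar = np.maximum(ssq / R - mean_states ** 2, 0.0)
    mean_sens = zsum / R
    zvar = np.maximum(zsq / R - mean_sens ** 2, 0.0)
    return CLESensitivityEnsemble(grid, mean_states, np.sqrt(svar / R),
                                  mean_sens, np.sqrt(zvar / R), R, float(dt),
                                  int(seed))
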