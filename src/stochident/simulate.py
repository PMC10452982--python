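"""Trajectory generation: exact jump processes, diffusion paths, ODE solutions.

All simulators sample on a common, strictly increasing time grid starting at
0; the state reported at a grid point t_l reflects every event with event
time <= t_l. Randomness is controlled through integer seeds (or explicit
:class:`RNGStream` objects for the random-time-change scheme): the same seed
always reproduces the same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from ._kernels import (STATUS_EVENT_CAP, STATUS_NEED_MORE, STATUS_NOT_FINITE,
                       cfd_kernel, cle_kernel, rtc_kernel, ssa_kernel)
from .network import ModelConfigError, _as_param_vector, validate_state

__all__ = [
    "SimulationError",
    "RNGStream",
    "Trajectory",
    "CLEPath",
    "uniform_grid",
    "check_grid",
    "ssa_simulate",
    "rtc_simulate",
    "cle_simulate",
    "rre_solve",
    "DEFAULT_EVENT_CAP",
]

DEFAULT_EVENT_CAP = 10_000_000
_KIND_CODES = {"uniform": 0, "exponential": 1}


class SimulationError(RuntimeError):
    pass


def uniform_grid(horizon, n_points=500):
    """``n_points`` equally spaced sampling times on [0, horizon]."""
    if n_points < 2:
        raise ModelConfigError("a time grid needs at least 2 points")
    if horizon <= 0:
        raise ModelConfigError("horizon must be positive")
    return np.linspace(0.0, float(horizon), int(n_points))


def check_grid(grid):
    g = np.asarray(grid, dtype=np.float64)
    if g.ndim != 1 or g.size < 2:
        raise ModelConfigError("time grid must be a 1-d array with >= 2 points")
    if g[0] != 0.0:
        raise ModelConfigError("time grid must start at t = 0")
    if np.any(np.diff(g) <= 0):
        raise ModelConfigError("time grid must be strictly increasing")
    return g


@dataclass(frozen=True)
class RNGStream:
    """A reproducible variate sequence identified by (seed, stream_id, kind).

    ``generate(n)`` always returns the first n variates of the sequence, so a
    longer request extends a shorter one without changing its prefix. This is
    what makes stream sharing between coupled paths exact.
    """

    seed: int
    stream_id: int = 0
    kind: str = "exponential"

    def generate(self, n):
        gen = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(self.seed), int(self.stream_id),
                                    _KIND_CODES[self.kind]])))
        if self.kind == "exponential":
            return gen.standard_exponential(int(n))
        return gen.random(int(n))


@dataclass
class Trajectory:
    """A grid-sampled jump-process path (integer molecule counts)."""

    grid: np.ndarray
    states: np.ndarray          # L x N int64
    n_events: int
    seed: int | None = None

    def __post_init__(self):
        if np.any(self.states < 0):
            raise SimulationError("negative molecule count in trajectory")


@dataclass
class CLEPath:
    """A grid-sampled Euler-Maruyama path of the diffusion approximation."""

    grid: np.ndarray
    states: np.ndarray          # L x N float64
    dt: float
    seed: int | None = None


def _raise_for_status(status, what):
    if status == STATUS_EVENT_CAP:
        raise SimulationError(
            f"{what}: event cap reached (runaway model?); raise max_events "
            "if this is expected")
    if status == STATUS_NOT_FINITE:
        raise SimulationError(f"{what}: propensity overflowed to a non-finite value")


def ssa_simulate(net, c, x0, grid, seed, max_events=DEFAULT_EVENT_CAP):
    """Exact SSA (direct method) path sampled on the grid."""
    grid = check_grid(grid)
    x0 = validate_state(net, x0).astype(np.int64)
    cv = _as_param_vector(c)
    stream = RNGStream(seed, 0, "uniform")
    n = 4096
    while True:
        u = stream.generate(n)
        states, nev, used, status = ssa_kernel(*net.encoded(), net.stoich, cv,
                                               x0, grid, u, max_events)
        if status != STATUS_NEED_MORE:
            break
        n *= 4
    _raise_for_status(status, "ssa_simulate")
    return Trajectory(grid, states, int(nev), seed)


def rtc_simulate(net, c, x0, grid, streams=None, seed=None,
                 max_events=DEFAULT_EVENT_CAP):
    """Random-time-change (modified next reaction) path.

    Each reaction consumes its own unit-rate exponential stream; supply
    ``streams`` (one per reaction) for explicit coupling, or just a ``seed``.
    Distributionally equivalent to :func:`ssa_simulate`.
    """
    grid = check_grid(grid)
    x0 = validate_state(net, x0).astype(np.int64)
    cv = _as_param_vector(c)
    M = net.n_reactions
    if streams is None:
        if seed is None:
            raise ModelConfigError("rtc_simulate needs either streams or a seed")
        streams = [RNGStream(seed, j, "exponential") for j in range(M)]
    if len(streams) != M:
        raise ModelConfigError(f"need one stream per reaction ({M}), got {len(streams)}")
    caps = np.full(M, 256, np.int64)
    while True:
        cap = int(caps.max())
        E = np.empty((M, cap), np.float64)
        for j in range(M):
            E[j, :caps[j]] = streams[j].generate(caps[j])
        states, nev, used, status, needj = rtc_kernel(
            *net.encoded(), net.stoich, cv, x0, grid, E, caps, max_events)
        if status != STATUS_NEED_MORE:
            break
        caps[needj] *= 4
    _raise_for_status(status, "rtc_simulate")
    return Trajectory(grid, states, int(nev), seed)


def cle_simulate(net, c, x0_real, grid, dt=1e-3, seed=0):
    """Euler-Maruyama path of the diffusion (Langevin) approximation.

    Propensities are clamped at 0 before entering the drift and the
    square-root diffusion coefficient; the state is left unclamped so the
    scheme is mean-exact for linear systems and conserves the left null
    space of the stoichiometry pathwise.
    """
    grid = check_grid(grid)
    if dt <= 0:
        raise ModelConfigError("dt must be positive")
    if dt > np.min(np.diff(grid)) + 1e-12:
        raise ModelConfigError("dt must not exceed the smallest grid spacing")
    x0 = np.asarray(x0_real, dtype=np.float64)
    cv = _as_param_vector(c)
    kseed = int(np.random.SeedSequence([int(seed), 0xC1E]).generate_state(1)[0])
    states = cle_kernel(*net.encoded(), net.stoich.astype(np.float64), cv,
                        x0, grid, float(dt), kseed)
    return CLEPath(grid, states, float(dt), seed)


def rre_solve(net, c, x0_real, grid, rtol=1e-8, atol=1e-10):
    """Deterministic mass-action (reaction-rate equation) solution.

    Returns the L x N state array on the grid. Conservation laws (left null
    vectors of the stoichiometry) are preserved to integrator tolerance.
    """
    grid = check_grid(grid)
    x0 = np.asarray(x0_real, dtype=np.float64)
    cv = _as_param_vector(c)
    enc = net.encoded()
    nu = net.stoich.astype(np.float64)
    M = net.n_reactions
    a = np.empty(M, np.float64)

    def rhs(t, x):
        _kernels.props_kernel(*enc, np.maximum(x, 0.0), cv, a)
        return nu @ a

    sol = solve_ivp(rhs, (0.0, grid[-1]), x0, t_eval=grid, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(
            f"rre_solve: integrator failed after t = {last:g}: {sol.message}")
    return sol.y.T


def trajectory_to_csv(traj, path, species_names):
    """Dump one trajectory as CSV (time plus one column per species)."""
    import pandas as pd

    df = pd.DataFrame(traj.states, columns=list(species_names))
    df.insert(0, "time", traj.grid)
    df.to_csv(path, index=False)
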