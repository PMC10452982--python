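"""Reaction networks with evaluable propensities and analytic derivatives.

A :class:`ReactionNetwork` couples an integer stoichiometric matrix (one
state-change column per reaction) with a list of propensity descriptors.
Five propensity forms are supported:

``zeroth``               a = k                      (production from a source)
``first``                a = k x_m                  (unimolecular)
``second_hetero``        a = k x_m x_n,  m != n     (bimolecular, distinct)
``second_homo``          a = k x_m (x_m - 1) / 2    (dimerisation)
``rational_repression``  a = p / (1 + x_reg^q)      (repressive regulation)

Rates refer to named parameter slots so that several reactions may share a
parameter and a single reaction (the repression form) may reference two.
Reactions whose rate is a fixed, known constant (e.g. a degradation at unit
rate) may use ``rate_const`` instead of a parameter slot; such constants are
invisible to the sensitivity and identifiability layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._kernels import props_kernel, prop_derivs_kernel

__all__ = [
    "ModelConfigError",
    "PropensityDomainError",
    "PropensityDescriptor",
    "ParameterSet",
    "ReactionNetwork",
    "evaluate_propensities",
    "propensity_derivatives",
    "load_model",
    "save_model",
]

PROPENSITY_KINDS = ("zeroth", "first", "second_hetero", "second_homo",
                    "rational_repression")
_KIND_CODE = {k: i for i, k in enumerate(PROPENSITY_KINDS)}


class ModelConfigError(ValueError):
    """An invalid network, descriptor, or model configuration file."""


class PropensityDomainError(ValueError):
    """Propensity (derivative) evaluation requested outside its domain."""


@dataclass(frozen=True)
class PropensityDescriptor:
    """One reaction's rate law, referencing species and parameter slots."""

    kind: str
    reactant_indices: tuple = ()
    rate_param: int | None = None
    rate_const: float = 1.0
    exponent_param: int | None = None
    regulator: int | None = None

    def __post_init__(self):
        if self.kind not in PROPENSITY_KINDS:
            raise ModelConfigError(
                f"unknown propensity kind {self.kind!r}; expected one of "
                f"{PROPENSITY_KINDS}")
        object.__setattr__(self, "reactant_indices",
                           tuple(int(i) for i in self.reactant_indices))
        n = len(self.reactant_indices)
        if self.kind == "zeroth" and n != 0:
            raise ModelConfigError("zeroth-order propensity takes no reactants")
        if self.kind in ("first", "second_homo") and n != 1:
            raise ModelConfigError(f"{self.kind} requires exactly 1 reactant index")
        if self.kind == "second_hetero":
            if n != 2 or self.reactant_indices[0] == self.reactant_indices[1]:
                raise ModelConfigError(
                    "second_hetero requires exactly 2 distinct reactant indices")
        if self.kind == "rational_repression":
            if self.regulator is None or self.exponent_param is None:
                raise ModelConfigError(
                    "rational_repression requires a regulator species and an "
                    "exponent parameter slot")


@dataclass(frozen=True)
class ParameterSet:
    """Positive kinetic parameter values keyed by the network's slot names."""

    values: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", tuple(self.names))
        if v.ndim != 1:
            raise ModelConfigError("parameter values must form a 1-d vector")
        if self.names and len(self.names) != v.size:
            raise ModelConfigError("parameter names and values differ in length")
        if not np.all(v > 0):
            bad = [self.names[i] if self.names else str(i)
                   for i in np.nonzero(~(v > 0))[0]]
            raise ModelConfigError(f"non-positive parameter value(s): {bad}")

    def __getitem__(self, name):
        return float(self.values[self.names.index(name)])

    def perturbed(self, k, theta):
        """A copy with slot ``k`` shifted to c_k + theta."""
        v = self.values.copy()
        v[k] += theta
        return ParameterSet(v, self.names)


def _as_param_vector(c):
    if isinstance(c, ParameterSet):
        return c.values
    return np.asarray(c, dtype=float)


@dataclass
class ReactionNetwork:
    species_names: list
    stoich: np.ndarray                 # N x M, column j is the jump of R_j
    propensities: list                 # M PropensityDescriptor
    param_names: list

    _encoded: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.stoich = np.asarray(self.stoich, dtype=np.int64)
        if self.stoich.ndim != 2:
            raise ModelConfigError("stoichiometric matrix must be 2-d (N x M)")
        N, M = self.stoich.shape
        if len(self.species_names) != N:
            raise ModelConfigError(
                f"{len(self.species_names)} species names for a stoichiometric "
                f"matrix with {N} rows")
        if len(self.propensities) != M:
            raise ModelConfigError(
                f"{len(self.propensities)} propensity descriptors for "
                f"{M} stoichiometry columns")
        P = len(self.param_names)
        for j, d in enumerate(self.propensities):
            for i in d.reactant_indices + ((d.regulator,) if d.regulator is not None else ()):
                if not 0 <= i < N:
                    raise ModelConfigError(
                        f"reaction {j}: species index {i} out of range 0..{N - 1}")
            for p in (d.rate_param, d.exponent_param):
                if p is not None and not 0 <= p < P:
                    raise ModelConfigError(
                        f"reaction {j}: parameter slot {p} out of range 0..{P - 1}")

    @property
    def n_species(self):
        return self.stoich.shape[0]

    @property
    def n_reactions(self):
        return self.stoich.shape[1]

    @property
    def n_params(self):
        return len(self.param_names)

    def encoded(self):
        """Flat integer/float arrays consumed by the compiled kernels."""
        if self._encoded is None:
            M = self.n_reactions
            kinds = np.empty(M, np.int64)
            sp1 = np.full(M, -1, np.int64)
            sp2 = np.full(M, -1, np.int64)
            ratep = np.full(M, -1, np.int64)
            expp = np.full(M, -1, np.int64)
            ratec = np.ones(M, np.float64)
            for j, d in enumerate(self.propensities):
                kinds[j] = _KIND_CODE[d.kind]
                if d.kind == "rational_repression":
                    sp1[j] = d.regulator
                elif d.reactant_indices:
                    sp1[j] = d.reactant_indices[0]
                    if len(d.reactant_indices) > 1:
                        sp2[j] = d.reactant_indices[1]
                ratep[j] = -1 if d.rate_param is None else d.rate_param
                expp[j] = -1 if d.exponent_param is None else d.exponent_param
                ratec[j] = d.rate_const
            self._encoded = (kinds, sp1, sp2, ratep, expp, ratec)
        return self._encoded

    def conservation_laws(self):
        """Left null space basis of the stoichiometric matrix (rows)."""
        u, sv, _ = np.linalg.svd(self.stoich.astype(float))
        tol = max(self.stoich.shape) * np.finfo(float).eps * (sv[0] if sv.size else 1.0)
        rank = int(np.sum(sv > tol))
        return u[:, rank:].T


def validate_state(net, x):
    x = np.asarray(x)
    if x.shape != (net.n_species,):
        raise ModelConfigError(
            f"state has shape {x.shape}, expected ({net.n_species},)")
    if np.any(x < 0):
        raise PropensityDomainError(f"negative molecule count in state {x}")
    return x


def evaluate_propensities(net, x, c):
    """Propensity vector a(x) at integer state ``x`` and parameters ``c``."""
    x = validate_state(net, x).astype(np.float64)
    cv = _as_param_vector(c)
    out = np.empty(net.n_reactions, np.float64)
    props_kernel(*net.encoded(), x, cv, out)
    return out


def propensity_derivatives(net, x, c):
    """Analytic (d a/d x, d a/d c) at a real-valued non-negative state.

    Returns the M x N state Jacobian and the M x P parameter gradient used by
    the deterministic and diffusion sensitivity backends. At x_reg = 0 the
    repression-form exponent derivative uses the convention
    x^q ln x -> 0 as x -> 0+.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (net.n_species,):
        raise ModelConfigError(
            f"state has shape {x.shape}, expected ({net.n_species},)")
    if np.any(x < 0):
        raise PropensityDomainError(f"negative entries in state {x}")
    cv = _as_param_vector(c)
    dstate = np.empty((net.n_reactions, net.n_species), np.float64)
    dparam = np.empty((net.n_reactions, net.n_params), np.float64)
    prop_derivs_kernel(*net.encoded(), x, cv, dstate, dparam)
    return dstate, dparam


# ---------------------------------------------------------------------------
# model configuration files
# ---------------------------------------------------------------------------

def _err(path, msg):
    raise ModelConfigError(f"{path}: {msg}")


def _build_descriptor(spec, j, species_index, param_index, reactants):
    where = f"reactions[{j}].propensity"
    if not isinstance(spec, dict) or "kind" not in spec:
        _err(where, "expected a mapping with a 'kind' key")
    kind = spec["kind"]
    if kind not in PROPENSITY_KINDS:
        _err(f"{where}.kind", f"unknown propensity kind {kind!r}")
    rate = spec.get("rate")
    rate_param = None
    rate_const = 1.0
    if isinstance(rate, str):
        if rate not in param_index:
            _err(f"{where}.rate", f"unknown parameter {rate!r}")
        rate_param = param_index[rate]
    elif rate is not None:
        rate_const = float(rate)
    kw = {}
    if kind == "rational_repression":
        for key in ("regulator", "exponent"):
            if key not in spec:
                _err(f"{where}.{key}", "required for rational_repression")
        reg = spec["regulator"]
        if reg not in species_index:
            _err(f"{where}.regulator", f"unknown species {reg!r}")
        expo = spec["exponent"]
        if expo not in param_index:
            _err(f"{where}.exponent", f"unknown parameter {expo!r}")
        kw = {"regulator": species_index[reg],
              "exponent_param": param_index[expo]}
        reactant_indices = ()
    else:
        reactant_indices = tuple(species_index[r] for r in reactants)
        if kind == "second_homo":
            # a dimerisation lists its reactant twice
            if len(reactant_indices) == 2 and reactant_indices[0] == reactant_indices[1]:
                reactant_indices = reactant_indices[:1]
        if kind == "zeroth":
            reactant_indices = ()
    try:
        return PropensityDescriptor(kind, reactant_indices, rate_param,
                                    rate_const, **kw)
    except ModelConfigError as e:
        _err(where, str(e))


def load_model(config_path):
    """Read a YAML/JSON model file -> (network, parameters, x0, horizon)."""
    path = Path(config_path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ModelConfigError(f"model file not found: {path}")
    except yaml.YAMLError as e:
        raise ModelConfigError(f"{path}: invalid YAML: {e}")
    if not isinstance(doc, dict):
        raise ModelConfigError(f"{path}: expected a mapping at top level")
    for key in ("species", "reactions", "parameters", "initial_state", "horizon"):
        if key not in doc:
            _err(str(path), f"missing required key {key!r}")
    species = list(doc["species"])
    if not species:
        _err("species", "at least one species is required")
    species_index = {s: i for i, s in enumerate(species)}
    params = doc["parameters"]
    if not isinstance(params, dict) or not params:
        _err("parameters", "expected a non-empty mapping of name: value")
    param_names = list(params)
    param_index = {p: i for i, p in enumerate(param_names)}
    for name, v in params.items():
        if not isinstance(v, (int, float)) or v <= 0:
            _err(f"parameters.{name}", f"parameter must be a positive number, got {v!r}")
    reactions = doc["reactions"]
    if not isinstance(reactions, list) or not reactions:
        _err("reactions", "expected a non-empty list of reactions")
    N, M = len(species), len(reactions)
    stoich = np.zeros((N, M), np.int64)
    descs = []
    for j, rxn in enumerate(reactions):
        if not isinstance(rxn, dict):
            _err(f"reactions[{j}]", "expected a mapping")
        reactants = rxn.get("reactants", []) or []
        products = rxn.get("products", []) or []
        for s in list(reactants) + list(products):
            if s not in species_index:
                _err(f"reactions[{j}]", f"unknown species {s!r}")
        for s in reactants:
            stoich[species_index[s], j] -= 1
        for s in products:
            stoich[species_index[s], j] += 1
        descs.append(_build_descriptor(rxn.get("propensity"), j, species_index,
                                       param_index, reactants))
    x0_doc = doc["initial_state"]
    if isinstance(x0_doc, dict):
        x0 = np.zeros(N, np.int64)
        for s, v in x0_doc.items():
            if s not in species_index:
                _err(f"initial_state.{s}", "unknown species")
            x0[species_index[s]] = int(v)
    else:
        x0 = np.asarray(x0_doc, dtype=np.int64)
        if x0.shape != (N,):
            _err("initial_state", f"expected {N} entries")
    if np.any(x0 < 0):
        _err("initial_state", "molecule counts must be non-negative")
    horizon = float(doc["horizon"])
    if horizon <= 0:
        _err("horizon", "must be positive")
    net = ReactionNetwork(species, stoich, descs, param_names)
    pset = ParameterSet(np.array([params[p] for p in param_names], float),
                        tuple(param_names))
    return net, pset, x0, horizon


def save_model(config_path, net, c, x0, horizon):
    """Write a model file that :func:`load_model` round-trips exactly."""
    cv = _as_param_vector(c)
    reactions = []
    for j, d in enumerate(net.propensities):
        col = net.stoich[:, j]
        consumed = {i: 0 for i in range(net.n_species)}
        for i in d.reactant_indices:
            consumed[i] += 2 if d.kind == "second_homo" else 1
        reactants = []
        for i, n in consumed.items():
            reactants += [net.species_names[i]] * n
        products = []
        for i in range(net.n_species):
            made = int(col[i]) + consumed[i]
            products += [net.species_names[i]] * made
        prop = {"kind": d.kind}
        if d.rate_param is not None:
            prop["rate"] = net.param_names[d.rate_param]
        else:
            prop["rate"] = float(d.rate_const)
        if d.kind == "rational_repression":
            prop["regulator"] = net.species_names[d.regulator]
            prop["exponent"] = net.param_names[d.exponent_param]
        reactions.append({"reactants": reactants, "products": products,
                          "propensity": prop})
    doc = {
        "species": list(net.species_names),
        "reactions": reactions,
        "parameters": {name: float(v) for name, v in zip(net.param_names, cv)},
        "initial_state": [int(v) for v in np.asarray(x0)],
        "horizon": float(horizon),
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
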