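"""Built-in case-study models.

Three small networks commonly used to exercise stochastic sensitivity and
identifiability machinery:

* ``infectious_disease`` -- two interacting populations (infected S1,
  susceptible S2) with births, deaths and an autocatalytic infection step
  S1 + S2 -> 2 S1; five rate parameters.
* ``michaelis_menten`` -- enzyme kinetics (substrate, enzyme, complex,
  product) with three rate parameters; initial counts follow from
  concentrations of 5e-7 M substrate and 2e-7 M enzyme in a 1e-15 L volume
  (rounded to the nearest molecule), and the binding rate constant is the
  concentration-scale 1e6 converted to molecule numbers.
* ``toggle_switch`` -- two mutually repressing genes U and V with
  rational-repression production a_U = alpha1 / (1 + X_V^beta),
  a_V = alpha2 / (1 + X_U^gamma) and unit-rate degradation; four named
  parameters (alpha1, beta, alpha2, gamma), bistable under noise.
"""

import numpy as np

from .network import ParameterSet, PropensityDescriptor, ReactionNetwork

__all__ = ["AVOGADRO", "VOLUME", "FIXTURE_NAMES", "fixture"]

# Avogadro constant as conventionally rounded in the modelling literature
# this package targets (not the CODATA value), and the cell volume in litres.
AVOGADRO = 6.023e23
VOLUME = 1e-15

FIXTURE_NAMES = ("infectious_disease", "michaelis_menten", "toggle_switch")


def _round_half_away(x):
    return int(np.floor(x + 0.5))


def _infectious_disease():
    species = ["S1", "S2"]
    #        R1  R2  R3  R4  R5
    stoich = np.array([[-1, 0, 1, 0, 1],
                       [0, -1, 0, 1, -1]], np.int64)
    descs = [
        PropensityDescriptor("first", (0,), rate_param=0),          # S1 -> 0
        PropensityDescriptor("first", (1,), rate_param=1),          # S2 -> 0
        PropensityDescriptor("zeroth", (), rate_param=2),           # 0 -> S1
        PropensityDescriptor("zeroth", (), rate_param=3),           # 0 -> S2
        PropensityDescriptor("second_hetero", (0, 1), rate_param=4),  # S1+S2 -> 2 S1
    ]
    net = ReactionNetwork(species, stoich, descs, ["c1", "c2", "c3", "c4", "c5"])
    c = ParameterSet(np.array([2.0, 0.1, 25.0, 75.0, 0.05]), tuple(net.param_names))
    x0 = np.array([20, 40], np.int64)
    return net, c, x0, 10.0


def _michaelis_menten():
    species = ["S1", "S2", "S3", "S4"]  # substrate, enzyme, complex, product
    stoich = np.array([[-1, 1, 0],
                       [-1, 1, 1],
                       [1, -1, -1],
                       [0, 0, 1]], np.int64)
    descs = [
        PropensityDescriptor("second_hetero", (0, 1), rate_param=0),  # S1+S2 -> S3
        PropensityDescriptor("first", (2,), rate_param=1),            # S3 -> S1+S2
        PropensityDescriptor("first", (2,), rate_param=2),            # S3 -> S4+S2
    ]
    net = ReactionNetwork(species, stoich, descs, ["c1", "c2", "c3"])
    c = ParameterSet(np.array([1e6 / (AVOGADRO * VOLUME), 1e-4, 1e-1]),
                     tuple(net.param_names))
    x0 = np.array([_round_half_away(5e-7 * AVOGADRO * VOLUME),
                   _round_half_away(2e-7 * AVOGADRO * VOLUME), 0, 0], np.int64)
    return net, c, x0, 50.0


def _toggle_switch():
    species = ["U", "V"]
    stoich = np.array([[1, -1, 0, 0],
                       [0, 0, 1, -1]], np.int64)
    # params: alpha1, beta, alpha2, gamma; degradations run at fixed unit rate
    descs = [
        PropensityDescriptor("rational_repression", (), rate_param=0,
                             exponent_param=1, regulator=1),   # 0 -> U
        PropensityDescriptor("first", (0,), rate_const=1.0),   # U -> 0
        PropensityDescriptor("rational_repression", (), rate_param=2,
                             exponent_param=3, regulator=0),   # 0 -> V
        PropensityDescriptor("first", (1,), rate_const=1.0),   # V -> 0
    ]
    net = ReactionNetwork(species, stoich, descs,
                          ["alpha1", "beta", "alpha2", "gamma"])
    c = ParameterSet(np.array([50.0, 2.5, 16.0, 1.0]), tuple(net.param_names))
    x0 = np.array([0, 0], np.int64)
    return net, c, x0, 50.0


_BUILDERS = {
    "infectious_disease": _infectious_disease,
    "michaelis_menten": _michaelis_menten,
    "toggle_switch": _toggle_switch,
}


def fixture(name):
    """Return ``(network, parameters, x0, horizon)`` for a built-in model."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return builder()
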