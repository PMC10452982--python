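import numpy as np
import pytest

import stochident as si
from stochident.network import (ModelConfigError, ParameterSet,
                                PropensityDescriptor, PropensityDomainError,
                                ReactionNetwork, evaluate_propensities,
                                load_model, propensity_derivatives, save_model)


class TestEvaluatePropensities:
    def test_infectious_disease_at_x0(self, infectious):
        net, c, x0, _ = infectious
        np.testing.assert_allclose(evaluate_propensities(net, x0, c),
                                   [40.0, 4.0, 25.0, 75.0, 40.0])

    def test_dimerisation_combinatorics(self):
        net = ReactionNetwork(
            ["A"], np.array([[-2]]),
            [PropensityDescriptor("second_homo", (0,), rate_param=0)], ["c"])
        # a = c x (x-1) / 2
        assert evaluate_propensities(net, [2], [1.0])[0] == 1.0
        assert evaluate_propensities(net, [1], [1.0])[0] == 0.0
        assert evaluate_propensities(net, [0], [1.0])[0] == 0.0

    def test_repression_at_zero_regulator(self, toggle):
        net, c, x0, _ = toggle
        a = evaluate_propensities(net, x0, c)
        np.testing.assert_allclose(a, [50.0, 0.0, 16.0, 0.0])

    def test_zero_when_reactants_absent(self, infectious):
        net, c, _, _ = infectious
        a = evaluate_propensities(net, np.array([0, 0]), c)
        np.testing.assert_allclose(a, [0.0, 0.0, 25.0, 75.0, 0.0])

    def test_negative_state_rejected(self, infectious):
        net, c, _, _ = infectious
        with pytest.raises(PropensityDomainError):
            evaluate_propensities(net, np.array([-1, 3]), c)

    def test_non_negativity_at_random_states(self, infectious, mm, toggle):
        rng = np.random.default_rng(0)
        for net, c, _, _ in (infectious, mm, toggle):
            states = rng.integers(0, 500, size=(10_000, net.n_species))
            for x in states[:200]:
                assert np.all(evaluate_propensities(net, x, c) >= 0)
            # vectorised spot check of the remaining draws via the kernel
            from stochident._kernels import props_kernel
            out = np.empty(net.n_reactions)
            for x in states[200:]:
                props_kernel(*net.encoded(), x.astype(float), c.values, out)
                assert np.all(out >= 0)


class TestPropensityDerivatives:
    def test_linear_forms(self, pure_death):
        net, _, _ = pure_death
        ds, dp = propensity_derivatives(net, [7.0], [2.0])
        assert ds[0, 0] == 2.0 and dp[0, 0] == 7.0

    def test_dimerisation_derivative(self):
        net = ReactionNetwork(
            ["A"], np.array([[-2]]),
            [PropensityDescriptor("second_homo", (0,), rate_param=0)], ["c"])
        ds, dp = propensity_derivatives(net, [3.0], [2.0])
        assert ds[0, 0] == pytest.approx(5.0)   # c (2x - 1) / 2
        assert dp[0, 0] == pytest.approx(3.0)   # x (x - 1) / 2

    def test_repression_limits_at_zero(self, toggle):
        net, c, _, _ = toggle
        ds, dp = propensity_derivatives(net, np.zeros(2), c)
        # p = 50, q = 2.5 at x = 0: d a/d x = 0 and d a/d q = 0
        assert ds[0, 1] == 0.0
        assert dp[0, 1] == 0.0
        # q = 1 branch: d a/d x -> -p q at x = 0
        assert ds[2, 0] == pytest.approx(-16.0)

    @pytest.mark.parametrize("name", ["infectious_disease", "michaelis_menten",
                                      "toggle_switch"])
    def test_matches_central_differences(self, name):
        net, c, _, _ = si.fixture(name)
        rng = np.random.default_rng(7)
        h = 1e-6
        for _ in range(100):
            x = rng.uniform(0.5, 200.0, net.n_species)
            ds, dp = propensity_derivatives(net, x, c)
            for i in range(net.n_species):
                xp, xm = x.copy(), x.copy()
                xp[i] += h * max(x[i], 1)
                xm[i] -= h * max(x[i], 1)
                fd = (evaluate_fc(net, xp, c.values) -
                      evaluate_fc(net, xm, c.values)) / (2 * h * max(x[i], 1))
                np.testing.assert_allclose(ds[:, i], fd, rtol=1e-6, atol=1e-6)
            for k in range(net.n_params):
                cp, cm = c.values.copy(), c.values.copy()
                cp[k] += h * c.values[k]
                cm[k] -= h * c.values[k]
                fd = (evaluate_fc(net, x, cp) - evaluate_fc(net, x, cm)) / \
                    (2 * h * c.values[k])
                np.testing.assert_allclose(dp[:, k], fd, rtol=1e-6, atol=1e-6)

    def test_negative_state_rejected(self, toggle):
        net, c, _, _ = toggle
        with pytest.raises(PropensityDomainError):
            propensity_derivatives(net, np.array([-0.1, 1.0]), c)


def evaluate_fc(net, x, cv):
    """Unclamped propensity evaluation at a real state (test helper)."""
    from stochident._kernels import props_kernel
    out = np.empty(net.n_reactions)
    props_kernel(*net.encoded(), np.asarray(x, float), np.asarray(cv, float), out)
    return out


class TestGuards:
    @pytest.mark.parametrize("name", ["infectious_disease", "michaelis_menten",
                                      "toggle_switch"])
    def test_active_reaction_walk_stays_non_negative(self, name):
        # firing any reaction with a_j(x) > 0 can never push a count below 0
        net, c, x0, _ = si.fixture(name)
        rng = np.random.default_rng(11)
        x = x0.astype(np.int64).copy()
        for _ in range(10_000):
            a = evaluate_propensities(net, x, c)
            active = np.nonzero(a > 0)[0]
            if active.size == 0:
                break
            j = rng.choice(active)
            x = x + net.stoich[:, j]
            assert np.all(x >= 0)


class TestValidation:
    def test_descriptor_arity(self):
        with pytest.raises(ModelConfigError):
            PropensityDescriptor("first", (0, 1), rate_param=0)
        with pytest.raises(ModelConfigError):
            PropensityDescriptor("second_hetero", (1, 1), rate_param=0)
        with pytest.raises(ModelConfigError):
            PropensityDescriptor("rational_repression", ())

    def test_out_of_range_indices(self):
        with pytest.raises(ModelConfigError):
            ReactionNetwork(["A"], np.array([[1]]),
                            [PropensityDescriptor("first", (3,), rate_param=0)],
                            ["c"])
        with pytest.raises(ModelConfigError):
            ReactionNetwork(["A"], np.array([[1]]),
                            [PropensityDescriptor("first", (0,), rate_param=5)],
                            ["c"])

    def test_parameters_must_be_positive(self):
        with pytest.raises(ModelConfigError):
            ParameterSet(np.array([1.0, 0.0]), ("a", "b"))


class TestModelIO:
    @pytest.mark.parametrize("name", ["infectious_disease", "michaelis_menten",
                                      "toggle_switch"])
    def test_round_trip(self, tmp_path, name):
        net, c, x0, T = si.fixture(name)
        p = tmp_path / f"{name}.yaml"
        save_model(p, net, c, x0, T)
        net2, c2, x02, T2 = load_model(p)
        assert net2.species_names == list(net.species_names)
        assert net2.param_names == list(net.param_names)
        np.testing.assert_array_equal(net2.stoich, net.stoich)
        np.testing.assert_allclose(c2.values, c.values)
        np.testing.assert_array_equal(x02, x0)
        assert T2 == T
        for d, d2 in zip(net.propensities, net2.propensities):
            assert d.kind == d2.kind
            assert d.rate_param == d2.rate_param
        # and the propensities agree at the initial state
        np.testing.assert_allclose(evaluate_propensities(net2, x02, c2),
                                   evaluate_propensities(net, x0, c))

    def test_empty_reaction_list_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("species: [A]\nreactions: []\nparameters: {c: 1.0}\n"
                     "initial_state: [1]\nhorizon: 1.0\n")
        with pytest.raises(ModelConfigError, match="reactions"):
            load_model(p)

    def test_unknown_kind_names_field(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "species: [A]\n"
            "reactions:\n"
            "  - {reactants: [A], products: [], propensity: {kind: cubic, rate: c}}\n"
            "parameters: {c: 1.0}\ninitial_state: [1]\nhorizon: 1.0\n")
        with pytest.raises(ModelConfigError, match="kind"):
            load_model(p)

    def test_non_positive_parameter_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "species: [A]\n"
            "reactions:\n"
            "  - {reactants: [A], products: [], propensity: {kind: first, rate: c}}\n"
            "parameters: {c: -2.0}\ninitial_state: [1]\nhorizon: 1.0\n")
        with pytest.raises(ModelConfigError, match="parameters.c"):
            load_model(p)


class TestFixtures:
    def test_infectious_disease_values(self, infectious):
        net, c, x0, T = infectious
        assert (net.n_species, net.n_reactions) == (2, 5)
        np.testing.assert_allclose(c.values, [2.0, 0.1, 25.0, 75.0, 0.05])
        np.testing.assert_array_equal(x0, [20, 40])
        assert T == 10.0

    def test_michaelis_menten_values(self, mm):
        net, c, x0, T = mm
        assert c["c1"] == pytest.approx(1.6604e-3, rel=1e-4)
        assert c["c2"] == 1e-4 and c["c3"] == 1e-1
        np.testing.assert_array_equal(x0, [301, 120, 0, 0])
        assert T == 50.0

    def test_toggle_values(self, toggle):
        net, c, x0, T = toggle
        np.testing.assert_allclose(c.values, [50.0, 2.5, 16.0, 1.0])
        np.testing.assert_array_equal(x0, [0, 0])
        assert T == 50.0
        assert net.param_names == ["alpha1", "beta", "alpha2", "gamma"]

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            si.fixture("lotka_volterra")
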