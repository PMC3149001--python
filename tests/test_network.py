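"""Reaction-network engine: stoichiometry, fluxes, conservation, switches."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mlcpath.network import (
    MASS_ACTION_IRREVERSIBLE,
    MASS_ACTION_REVERSIBLE,
    MICHAELIS_MENTEN,
    NetworkError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
)

from conftest import random_mass_action_network


def simple_net(reversible=True):
    """A + B <-> C with kf=2, kb=1."""
    return ReactionNetwork(
        [
            Species("A", initial_concentration=1.0),
            Species("B", initial_concentration=0.5),
            Species("C", initial_concentration=0.0),
        ],
        [
            Reaction(
                "bind",
                [("A", 1), ("B", 1)],
                [("C", 1)],
                rate_law=RateLaw(
                    MASS_ACTION_REVERSIBLE if reversible
                    else MASS_ACTION_IRREVERSIBLE,
                    kf=2.0,
                    kb=1.0 if reversible else 0.0,
                ),
            )
        ],
    )


class TestStoichiometry:
    def test_single_conversion(self):
        net = ReactionNetwork(
            [Species("A", initial_concentration=1.0), Species("B")],
            [Reaction("r", [("A", 1)], [("B", 1)],
                      rate_law=RateLaw(kf=1.0))],
        )
        assert net.stoichiometry_matrix().tolist() == [[-1], [1]]

    def test_binding_column(self):
        S = simple_net().stoichiometry_matrix()
        assert S[:, 0].tolist() == [-1, -1, 1]

    def test_random_network_matches_loop_oracle(self):
        rng = np.random.default_rng(42)
        net = random_mass_action_network(rng, n_species=12, n_reactions=20)
        S = net.stoichiometry_matrix()
        # independent per-reaction assembly
        oracle = np.zeros_like(S)
        index = {s.id: i for i, s in enumerate(net.species)}
        for j, r in enumerate(net.reactions):
            for sp, c in r.reactants:
                oracle[index[sp], j] -= c
            for sp, c in r.products:
                oracle[index[sp], j] += c
        np.testing.assert_array_equal(S, oracle)

    def test_unknown_species_rejected(self):
        with pytest.raises(NetworkError, match="unknown species"):
            ReactionNetwork(
                [Species("A")],
                [Reaction("r", [("Z", 1)], [("A", 1)],
                          rate_law=RateLaw(kf=1.0))],
            )


class TestFlux:
    def test_reversible_arithmetic(self):
        net = ReactionNetwork(
            [Species("A", initial_concentration=3.0),
             Species("B", initial_concentration=4.0)],
            [Reaction("r", [("A", 1)], [("B", 1)],
                      rate_law=RateLaw(MASS_ACTION_REVERSIBLE,
                                       kf=2.0, kb=1.0))],
        )
        assert net.flux_vector(np.array([3.0, 4.0]))[0] == pytest.approx(2.0)

    def test_mm_half_saturation(self):
        net = ReactionNetwork(
            [Species("E", initial_concentration=0.1),
             Species("S", initial_concentration=1.0),
             Species("P")],
            [Reaction("mm", [("S", 1)], [("P", 1)], enzyme="E",
                      rate_law=RateLaw(MICHAELIS_MENTEN, kcat=10.0,
                                       Km=1.0))],
        )
        flux = net.flux_vector(np.array([0.1, 1.0, 0.0]))
        assert flux[0] == pytest.approx(0.5)

    def test_zero_state_zero_flux(self):
        rng = np.random.default_rng(7)
        net = random_mass_action_network(rng)
        flux = net.flux_vector(np.zeros(net.n_species))
        np.testing.assert_allclose(flux, 0.0)

    def test_negative_state_rejected(self):
        net = simple_net()
        with pytest.raises(NetworkError, match="negative"):
            net.flux_vector(np.array([-1.0, 0.5, 0.0]))


class TestRhs:
    def test_first_order_decay_analytic(self):
        net = ReactionNetwork(
            [Species("A", initial_concentration=1.0)],
            [Reaction("d", [("A", 1)], [], rate_law=RateLaw(kf=0.01))],
        )
        sol = solve_ivp(net.rhs, (0, 600), [1.0], rtol=1e-8, atol=1e-10)
        assert sol.y[0, -1] == pytest.approx(np.exp(-6.0), rel=1e-4)

    def test_equilibrium_is_stationary(self):
        net = simple_net()
        # [C]/([A][B]) = kf/kb = 2 at equilibrium
        state = np.array([0.5, 0.5, 0.5])
        np.testing.assert_allclose(net.rhs(0.0, state), 0.0, atol=1e-12)

    def test_rhs_consistent_with_trajectory_derivative(self):
        rng = np.random.default_rng(3)
        net = random_mass_action_network(rng, n_species=10, n_reactions=15)
        y0 = net.initial_state()
        sol = solve_ivp(net.rhs, (0, 5.0), y0, rtol=1e-10, atol=1e-12,
                        dense_output=True)
        t = 2.5
        h = 1e-4
        fd = (sol.sol(t + h) - sol.sol(t - h)) / (2 * h)
        np.testing.assert_allclose(net.rhs(t, sol.sol(t)), fd,
                                   rtol=1e-4, atol=1e-8)

    def test_boundary_species_has_zero_derivative(self):
        net = ReactionNetwork(
            [Species("EXT", initial_concentration=1.0, is_boundary=True),
             Species("A")],
            [Reaction("in", [("EXT", 1)], [("EXT", 1), ("A", 1)],
                      rate_law=RateLaw(kf=0.5))],
        )
        d = net.rhs(0.0, np.array([1.0, 0.0]))
        assert d[0] == 0.0
        assert d[1] == pytest.approx(0.5)


class TestConservedMoieties:
    def test_two_state(self):
        net = ReactionNetwork(
            [Species("A", initial_concentration=1.0), Species("B")],
            [Reaction("r", [("A", 1)], [("B", 1)],
                      rate_law=RateLaw(MASS_ACTION_REVERSIBLE,
                                       kf=1.0, kb=1.0))],
        )
        vecs = net.conserved_moieties()
        assert len(vecs) == 1
        np.testing.assert_array_equal(vecs[0], [1, 1])

    def test_binding_two_relations(self):
        vecs = simple_net().conserved_moieties()
        assert len(vecs) == 2
        S = simple_net().stoichiometry_matrix()
        for v in vecs:
            np.testing.assert_array_equal(v @ S, 0)

    def test_left_null_space_property_random(self):
        rng = np.random.default_rng(11)
        net = random_mass_action_network(rng, n_species=8, n_reactions=12)
        S = net.stoichiometry_matrix()
        for v in net.conserved_moieties():
            np.testing.assert_array_equal(v @ S, np.zeros(S.shape[1]))


class TestApplySwitch:
    def tagged_net(self):
        return ReactionNetwork(
            [Species("A", initial_concentration=1.0), Species("B"),
             Species("C")],
            [
                Reaction("r1", [("A", 1)], [("B", 1)],
                         rate_law=RateLaw(kf=1.0), tags={"x"}),
                Reaction("r2", [("B", 1)], [("C", 1)],
                         rate_law=RateLaw(kf=2.0), tags={"y"}),
            ],
        )

    def test_all_on_identity(self):
        net = self.tagged_net()
        out = net.apply_switch({"x": True, "y": True})
        assert out.parameters == net.parameters

    def test_off_zeroes_constants(self):
        out = self.tagged_net().apply_switch({"x": False})
        assert out.reaction("r1").rate_law.kf == 0.0
        assert out.reaction("r2").rate_law.kf == 2.0

    def test_idempotent_and_commutes(self):
        net = self.tagged_net()
        once = net.apply_switch({"x": False})
        twice = once.apply_switch({"x": False})
        assert once.parameters == twice.parameters
        ab = net.apply_switch({"x": False}).apply_switch({"y": False})
        ba = net.apply_switch({"y": False}).apply_switch({"x": False})
        assert ab.parameters == ba.parameters

    def test_unknown_label_rejected(self):
        with pytest.raises(NetworkError, match="unknown cascade"):
            self.tagged_net().apply_switch({"zzz": False})


class TestValidation:
    def test_duplicate_species_ids(self):
        with pytest.raises(NetworkError, match="duplicate species"):
            ReactionNetwork([Species("A"), Species("A")], [])

    def test_mm_requires_enzyme(self):
        with pytest.raises(NetworkError, match="enzyme"):
            Reaction("m", [("S", 1)], [("P", 1)],
                     rate_law=RateLaw(MICHAELIS_MENTEN, kcat=1.0, Km=1.0))

    def test_mm_requires_positive_km(self):
        with pytest.raises(NetworkError, match="Km"):
            RateLaw(MICHAELIS_MENTEN, kcat=1.0, Km=0.0)

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(NetworkError):
            RateLaw(kf=-1.0)

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(NetworkError):
            Species("A", initial_concentration=-0.1)

    def test_set_parameter(self):
        net = simple_net()
        net.set_parameter("bind", "kf", 5.0)
        assert net.parameters[("bind", "kf")] == 5.0
        with pytest.raises(NetworkError):
            net.set_parameter("bind", "kcat", 1.0)

    def test_text_listing(self):
        text = simple_net().to_text()
        assert "A + B <-> C" in text
        assert "kf=2" in text


class TestPropertyBased:
    """Derandomized property tests over random small mass-action networks."""

    def test_moieties_annihilate_stoichiometry(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=15, deadline=None, derandomize=True)
        @given(st.integers(min_value=0, max_value=10_000))
        def check(seed):
            rng = np.random.default_rng(seed)
            net = random_mass_action_network(
                rng, n_species=int(rng.integers(4, 10)),
                n_reactions=int(rng.integers(3, 15)),
            )
            S = net.stoichiometry_matrix()
            for v in net.conserved_moieties():
                np.testing.assert_array_equal(v @ S, np.zeros(S.shape[1]))

        check()

    def test_switches_idempotent_and_flux_consistent(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=15, deadline=None, derandomize=True)
        @given(st.integers(min_value=0, max_value=10_000))
        def check(seed):
            rng = np.random.default_rng(seed)
            net = random_mass_action_network(
                rng, n_species=int(rng.integers(4, 10)),
                n_reactions=int(rng.integers(3, 15)),
            )
            state = rng.uniform(0.0, 2.0, net.n_species)
            flux = net.flux_vector(state)
            # rhs equals S @ flux at arbitrary non-negative states
            np.testing.assert_allclose(
                net.rhs(0.0, state),
                net.stoichiometry_matrix() @ flux,
                rtol=1e-12, atol=1e-12,
            )
            # zero state annihilates all fluxes (mass action only)
            np.testing.assert_allclose(
                net.flux_vector(np.zeros(net.n_species)), 0.0
            )

        check()
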