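"""Structural and kinetic-law tests of the canonical reaction network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jakstat.engine import run_ensemble, ssa_exact
from jakstat.model import (
    GENES,
    ModelState,
    ParameterSet,
    Reaction,
    ReactionNetwork,
    SpeciesDef,
    SpeciesRole,
    StructuralError,
    COMPARTMENT_TABLE,
    build_canonical_model,
    ifn_units_to_molecules,
    ode_rhs,
    promoter_stationary_fraction,
    propensities,
)
from scipy.integrate import solve_ivp


def brute_force_propensities(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Independent mass-action evaluation straight from the reaction table."""
    out = []
    for r in net.reactions:
        k = net.parameters[r.rate_parameter]
        if r.order == 2:
            k = k / net.volume_fraction(r.compartment)
        a = k
        for sp, c in r.reactants:
            a *= x[net.species_index(sp)] ** c
        out.append(max(a, 0.0))
    return np.array(out)


class TestStructure:
    def test_counts(self, canonical):
        assert canonical.n_species == 42
        assert canonical.n_reactions == 62
        assert len(canonical.compartments) == 2

    def test_compartment_fractions(self, canonical):
        fractions = {c.name: c.volume_fraction for c in canonical.compartments}
        assert fractions == {"cytoplasm": 0.865, "nucleus": 0.135}
        assert abs(sum(fractions.values()) - 1.0) < 1e-9

    def test_initial_conditions_loaded(self, canonical):
        x0 = canonical.initial_state()
        idx = canonical.species_index
        assert x0[idx("STAT1_c")] == 850667
        assert x0[idx("STAT2_c")] == 9325
        assert x0[idx("IRF9_c")] == 10
        assert x0[idx("STAT2-IRF9_n")] == 325
        assert x0[idx("mIRF9_c")] == 14
        assert x0[idx("MxA")] == 1582
        assert x0[idx("IFIT1")] == 705
        assert x0[idx("irf9*")] == pytest.approx(0.62)
        assert x0[idx("I_socs")] == pytest.approx(0.98)

    def test_every_parameter_referenced(self, canonical):
        referenced = {r.rate_parameter for r in canonical.reactions}
        assert referenced == set(canonical.parameters)
        assert len(canonical.parameters) == 52

    def test_every_species_in_a_reaction(self, canonical):
        used = set()
        for r in canonical.reactions:
            used.update(sp for sp, _ in r.reactants + r.products)
        assert used == set(canonical.species_names)

    def test_promoter_initial_occupancies_sum_to_one(self, canonical):
        x0 = canonical.initial_state()
        for g, (i, j, k) in canonical.promoter_triples().items():
            assert x0[i] + x0[j] + x0[k] == pytest.approx(1.0, abs=1e-9)

    def test_promoter_conservation_stoichiometric(self, canonical):
        S = canonical.stoichiometry_matrix()
        for g, triple in canonical.promoter_triples().items():
            assert np.all(S[:, list(triple)].sum(axis=1) == 0)

    def test_structural_report_on_bad_network(self):
        species = [SpeciesDef("X", "cytoplasm", SpeciesRole.PROTEIN, 1.0)]
        reactions = [Reaction("r", (("X", 1),), (), "nope")]
        params = ParameterSet({"k": 1.0}, {"k": "1/min"})
        with pytest.raises(StructuralError, match="structural report"):
            ReactionNetwork(species, COMPARTMENT_TABLE, reactions, params)

    def test_bimolecular_units_recorded(self, canonical):
        for name in ("k_1", "k_2", "k_7", "k_44", "k_12"):
            assert canonical.parameters.units[name] == "1/(Molecules*min)"
        for name in ("k_5", "k_20", "k_38"):
            assert canonical.parameters.units[name] == "1/min"


class TestDoseConversion:
    @pytest.mark.parametrize(
        "dose,molecules",
        [(500.0, 10000), (250.0, 5000), (0.0, 0), (1250.0, 25000), (10.0, 200)],
    )
    def test_linear_map(self, dose, molecules):
        assert ifn_units_to_molecules(dose) == molecules

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            ifn_units_to_molecules(-1.0)


class TestPropensities:
    def test_zero_ifn_silences_binding(self, basal_network):
        a = propensities(basal_network.initial_state(), basal_network.parameters,
                         basal_network)
        binding = [
            i for i, r in enumerate(basal_network.reactions)
            if any(sp == "IFN" for sp, _ in r.reactants)
        ]
        assert binding and np.all(a[binding] == 0.0)

    def test_unimolecular_definition(self):
        from tests.conftest import make_birth_death

        bd = make_birth_death(k_b=5.0, k_d=0.5, x0=4.0)
        a = propensities(bd.initial_state(), bd.parameters, bd)
        assert a[0] == pytest.approx(5.0)  # zero-order birth
        assert a[1] == pytest.approx(0.5 * 4)  # k * x

    def test_matches_brute_force_at_initial_state(self, canonical):
        x0 = canonical.initial_state()
        a = propensities(x0, canonical.parameters, canonical)
        b = brute_force_propensities(canonical, x0)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_matches_brute_force_random_states(self, canonical):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.integers(0, 1000, canonical.n_species).astype(float)
            a = propensities(x, canonical.parameters, canonical)
            b = brute_force_propensities(canonical, x)
            np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_model_state_wrapper(self, canonical):
        state = ModelState(0.0, canonical.initial_state())
        a = propensities(state, canonical.parameters, canonical)
        assert a.shape == (62,)
        assert np.all(a >= 0)


class TestOdeRhs:
    def test_promoter_totals_conserved(self, canonical):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(0, 500, canonical.n_species)
            dx = ode_rhs(0.0, x, canonical)
            for g, (i, j, k) in canonical.promoter_triples().items():
                assert dx[i] + dx[j] + dx[k] == pytest.approx(0.0, abs=1e-9)

    def test_birth_death_fixed_point(self):
        from tests.conftest import make_birth_death

        bd = make_birth_death(k_b=6.0, k_d=0.3, x0=0.0)
        sol = solve_ivp(
            lambda t, x: ode_rhs(t, x, bd), (0, 200), [0.0],
            rtol=1e-9, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(6.0 / 0.3, rel=1e-5)

    def test_mean_field_matches_ssa_on_linear_cascade(self):
        """For networks with linear propensities the first moment is exact,
        so the ODE must match the SSA ensemble mean within Monte Carlo error."""
        species = [
            SpeciesDef(n, "cytoplasm", SpeciesRole.PROTEIN, 0.0) for n in "ABC"
        ]
        reactions = [
            Reaction("bA", (), (("A", 1),), "k0"),
            Reaction("dA", (("A", 1),), (), "d0"),
            Reaction("tB", (("A", 1),), (("A", 1), ("B", 1)), "k1"),
            Reaction("dB", (("B", 1),), (), "d1"),
            Reaction("tC", (("B", 1),), (("B", 1), ("C", 1)), "k2"),
            Reaction("dC", (("C", 1),), (), "d2"),
        ]
        params = ParameterSet(
            {"k0": 2.0, "d0": 0.1, "k1": 0.5, "d1": 0.2, "k2": 0.3, "d2": 0.15},
            {k: "1/min" for k in ("k0", "d0", "k1", "d1", "k2", "d2")},
        )
        net = ReactionNetwork(species, COMPARTMENT_TABLE, reactions, params)
        t_grid = np.array([0.0, 10.0, 20.0, 40.0])
        ens = run_ensemble(net, n_reps=2000, t_grid=t_grid, master_seed=5,
                           engine="exact")
        sol = solve_ivp(
            lambda t, x: ode_rhs(t, x, net), (0, 40), [0.0, 0.0, 0.0],
            rtol=1e-9, atol=1e-12, t_eval=t_grid,
        )
        for si, sp in enumerate("ABC"):
            m = ens.species_matrix(sp)
            mean = m.mean(axis=0)
            se = m.std(axis=0, ddof=1) / np.sqrt(m.shape[0])
            for ti in range(1, len(t_grid)):
                assert abs(mean[ti] - sol.y[si, ti]) < 3 * se[ti] + 1e-9


class TestPromoterStationaryFraction:
    def test_no_tf(self):
        assert promoter_stationary_fraction(1e-3, 0.0, 2.0) == 0.0

    def test_symmetry_point(self):
        # k_on * T == k_off -> bound half the time
        assert promoter_stationary_fraction(0.01, 100.0, 1.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # mxa promoter facing 325 STAT2-IRF9 at the raw (cell-referenced)
        # association constant
        assert promoter_stationary_fraction(6.1e-4, 325.0, 22.8) == pytest.approx(
            0.0086202, abs=1e-6
        )

    @given(
        st.floats(1e-6, 1.0), st.floats(0.0, 1e6), st.floats(1e-6, 1e3)
    )
    @settings(max_examples=50, deadline=None)
    def test_is_a_fraction(self, k_on, tf, k_off):
        f = promoter_stationary_fraction(k_on, tf, k_off)
        assert 0.0 <= f < 1.0


class TestSerialization:
    def test_round_trip(self, canonical):
        text = canonical.to_text()
        back = ReactionNetwork.from_text(text)
        assert back.n_species == canonical.n_species
        assert back.n_reactions == canonical.n_reactions
        assert back.species_names == canonical.species_names
        assert dict(back.parameters) == dict(canonical.parameters)
        assert back.parameters.units == canonical.parameters.units
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2000, canonical.n_species).astype(float)
        np.testing.assert_allclose(
            propensities(x, back.parameters, back),
            propensities(x, canonical.parameters, canonical),
            rtol=0, atol=0,
        )
        assert back.to_text() == text
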