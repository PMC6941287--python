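import numpy as np
import pytest

from carbonfba import (
    BoundsPolicy,
    Compartment,
    Metabolite,
    NetworkStructureError,
    Reaction,
    StoichiometricNetwork,
    apply_bounds,
    build_stoichiometric_matrix,
    make_random_network,
    validate_network,
)


class TestReactionInvariants:
    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            Reaction("R", {})

    def test_zero_coefficient_rejected(self):
        with pytest.raises(ValueError, match="zero coefficient"):
            Reaction("R", {"A": 0.0})

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            Reaction("R", {"A": 1.0}, lower_bound=2.0, upper_bound=1.0)

    def test_irreversible_negative_lower_bound_rejected(self):
        with pytest.raises(ValueError, match="negative lower bound"):
            Reaction("R", {"A": 1.0}, reversible=False, lower_bound=-1.0, upper_bound=1.0)


class TestStoichiometricMatrix:
    def test_chain_matrix(self, chain_network):
        S = build_stoichiometric_matrix(chain_network)
        assert S.shape == (2, 3)
        np.testing.assert_array_equal(S, [[1, -1, 0], [0, 1, -1]])

    def test_unknown_metabolite_reference_names_reaction(self):
        mets = [Metabolite("A")]
        with pytest.raises(NetworkStructureError, match="Rbad"):
            StoichiometricNetwork(mets, [Reaction("Rbad", {"A": -1.0, "ghost": 1.0})])

    def test_external_species_excluded_from_rows(self):
        mets = [
            Metabolite("A", compartment=Compartment.CYTOSOL),
            Metabolite("A_ext", compartment=Compartment.EXTERNAL),
        ]
        rxns = [Reaction("Ex", {"A_ext": -1.0, "A": 1.0})]
        net = StoichiometricNetwork(mets, rxns)
        S = build_stoichiometric_matrix(net)
        assert S.shape == (1, 1)
        assert S[0, 0] == 1.0  # only the balanced species contributes a row

    def test_orphan_metabolite_gives_zero_row_and_warning(self, chain_network):
        net = StoichiometricNetwork(
            chain_network.metabolites + [Metabolite("C")],
            chain_network.reactions,
        )
        S = build_stoichiometric_matrix(net)
        assert S.shape == (3, 3)
        np.testing.assert_array_equal(S[2], 0.0)
        report = validate_network(net)
        assert any(i.code == "orphan-metabolite" for i in report.warnings)

    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_preserves_all_coefficients(self, seed):
        """network -> matrix is information-preserving on balanced species."""
        net = make_random_network(seed, n_metabolites=5, n_reactions=7)
        S = build_stoichiometric_matrix(net)
        rows = {m.id: i for i, m in enumerate(net.balanced_metabolites)}
        for j, rxn in enumerate(net.reactions):
            rebuilt = {
                m: S[i, j] for m, i in rows.items() if S[i, j] != 0.0
            }
            expected = {m: c for m, c in rxn.stoichiometry.items() if m in rows}
            assert rebuilt == expected


class TestApplyBounds:
    def test_defaults_by_reversibility(self, chain_network):
        net = StoichiometricNetwork(
            chain_network.metabolites,
            [
                Reaction("R1", {"A": 1.0}),
                Reaction("R2", {"A": -1.0, "B": 1.0}, reversible=True),
                Reaction("R3", {"B": -1.0}),
            ],
        )
        out = apply_bounds(net, BoundsPolicy())
        assert (out.reaction("R1").lower_bound, out.reaction("R1").upper_bound) == (0.0, 100.0)
        assert (out.reaction("R2").lower_bound, out.reaction("R2").upper_bound) == (-100.0, 100.0)

    def test_fixed_flux_override(self, chain_network):
        out = apply_bounds(chain_network, overrides={"R2": (0.92, 0.92)})
        r = out.reaction("R2")
        assert r.lower_bound == r.upper_bound == 0.92

    def test_override_replaces_existing_bound(self, chain_network):
        once = apply_bounds(chain_network)
        again = apply_bounds(once, overrides={"R1": (0.0, 5.0)})
        assert again.reaction("R1").upper_bound == 5.0

    def test_idempotent(self, chain_network):
        once = apply_bounds(chain_network)
        twice = apply_bounds(once)
        for a, b in zip(once.reactions, twice.reactions):
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)

    def test_invalid_override_rejected(self, chain_network):
        with pytest.raises(ValueError, match="exceeds"):
            apply_bounds(chain_network, overrides={"R1": (3.0, 1.0)})
        with pytest.raises(NetworkStructureError):
            apply_bounds(chain_network, overrides={"nope": (0.0, 1.0)})

    def test_does_not_mutate_input(self, chain_network):
        apply_bounds(chain_network)
        assert chain_network.reaction("R1").lower_bound is None


class TestValidateNetwork:
    def test_clean_chain_empty_report(self, chain_network):
        assert validate_network(chain_network).ok()

    def test_duplicate_reaction_id(self, chain_network):
        net = StoichiometricNetwork(
            chain_network.metabolites,
            chain_network.reactions + [Reaction("R1", {"B": -1.0})],
        )
        report = validate_network(net)
        assert any(i.code == "duplicate-reaction-id" and i.subject == "R1"
                   for i in report.errors)

    def test_missing_biomass_role_warns(self, chain_network):
        net = StoichiometricNetwork(
            chain_network.metabolites,
            chain_network.reactions,
            named_roles={"light_exchange": "R1"},
        )
        report = validate_network(net)
        assert any(i.code == "named-role-absent" and i.subject == "biomass"
                   for i in report.warnings)
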