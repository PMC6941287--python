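import numpy as np
import pytest

from carbonfba import (
    Compartment,
    FluxBalanceModel,
    Metabolite,
    ObjectiveSpec,
    Reaction,
    StoichiometricNetwork,
    enumerate_vertices_oracle,
    make_random_network,
    solve_fba,
    solve_lexicographic,
)


def _scaled(network, lam):
    """Copy of the network with every bound multiplied by lam."""
    out = network.copy()
    for rxn in list(out.reactions):
        out.replace_reaction(rxn.with_bounds(rxn.lower_bound * lam, rxn.upper_bound * lam))
    return out


class TestSingleObjective:
    def test_chain_secretion_capped_by_uptake(self, chain_network):
        res = solve_fba(
            chain_network,
            objective=ObjectiveSpec.maximize("R3"),
            bound_overrides={"R1": (0.0, 5.0)},
        )
        assert res.status == "optimal"
        assert res.stage_values[0] == pytest.approx(5.0, abs=1e-9)

    def test_all_zero_bounds_give_zero_everything(self, chain_network):
        res = solve_fba(
            chain_network,
            objective=ObjectiveSpec.maximize("R3"),
            bound_overrides={r.id: (0.0, 0.0) for r in chain_network.reactions},
        )
        assert res.status == "optimal"
        assert res.stage_values[0] == pytest.approx(0.0, abs=1e-12)
        assert all(abs(v) <= 1e-12 for v in res.flux.values())

    def test_unbounded_cycle_reports_support(self):
        mets = [Metabolite("A"), Metabolite("B")]
        inf = float("inf")
        rxns = [
            Reaction("F", {"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=inf),
            Reaction("G", {"B": -1.0, "A": 1.0}, lower_bound=0.0, upper_bound=inf),
        ]
        net = StoichiometricNetwork(mets, rxns)
        res = solve_fba(net, objective=ObjectiveSpec.maximize("F"))
        assert res.status == "unbounded"
        assert set(res.unbounded_support) == {"F", "G"}

    def test_infeasible_status(self, chain_network):
        res = solve_fba(
            chain_network,
            objective=ObjectiveSpec.maximize("R3"),
            bound_overrides={"R1": (0.0, 5.0), "R3": (10.0, 10.0)},
        )
        assert res.status == "infeasible"

    def test_objective_value_matches_flux_inner_product(self, toy_phototroph):
        net, _ = toy_phototroph
        from carbonfba import make_scenario

        res = solve_fba(net, scenario=make_scenario("A"))
        recomputed = sum(w * res.flux[rid] for rid, w in res.objective_stages[0].items())
        assert res.stage_values[0] == pytest.approx(recomputed, abs=1e-9)


class TestLexicographic:
    def _two_branch_net(self, shared_uptake: bool):
        mets = [Metabolite("E"), Metabolite("P"), Metabolite("Q")]
        if shared_uptake:
            rxns = [
                Reaction("U", {"E": 1.0}, lower_bound=0.0, upper_bound=10.0),
                Reaction("Bio", {"E": -2.0, "P": 1.0}, lower_bound=0.0, upper_bound=4.0),
                Reaction("Pig", {"E": -1.0, "Q": 1.0}, lower_bound=0.0, upper_bound=100.0),
                Reaction("SecP", {"P": -1.0}, lower_bound=0.0, upper_bound=100.0),
                Reaction("SecQ", {"Q": -1.0}, lower_bound=0.0, upper_bound=100.0),
            ]
        else:
            mets.append(Metabolite("E2"))
            rxns = [
                Reaction("U", {"E": 1.0}, lower_bound=0.0, upper_bound=10.0),
                Reaction("U2", {"E2": 1.0}, lower_bound=0.0, upper_bound=7.0),
                Reaction("Bio", {"E": -2.0, "P": 1.0}, lower_bound=0.0, upper_bound=100.0),
                Reaction("Pig", {"E2": -1.0, "Q": 1.0}, lower_bound=0.0, upper_bound=100.0),
                Reaction("SecP", {"P": -1.0}, lower_bound=0.0, upper_bound=100.0),
                Reaction("SecQ", {"Q": -1.0}, lower_bound=0.0, upper_bound=100.0),
            ]
        return StoichiometricNetwork(mets, rxns)

    def test_independent_branches_reach_standalone_maxima(self):
        net = self._two_branch_net(shared_uptake=False)
        res = solve_lexicographic(net, objective=ObjectiveSpec.maximize("Bio", "Pig"))
        assert res.stage_values[0] == pytest.approx(5.0, abs=1e-9)  # 10 E / 2
        assert res.stage_values[1] == pytest.approx(7.0, abs=1e-9)  # all of E2

    def test_competing_branch_gets_leftover_capacity(self):
        net = self._two_branch_net(shared_uptake=True)
        res = solve_lexicographic(net, objective=ObjectiveSpec.maximize("Bio", "Pig"))
        # stage 1: Bio capped at 4 (uses 8 E); stage 2: 2 E left for Pig
        assert res.stage_values[0] == pytest.approx(4.0, abs=1e-9)
        assert res.stage_values[1] == pytest.approx(2.0, abs=1e-9)
        # independent confirmation by exhaustive vertex enumeration of the
        # stage-2 LP (stage-1 optimum anchored as a fixed bound)
        anchored = enumerate_vertices_oracle(
            net,
            objective=ObjectiveSpec(({"Pig": 1.0},)),
            bound_overrides={"Bio": (4.0, 4.0)},
        )
        assert anchored.value == pytest.approx(res.stage_values[1], abs=1e-6)

    def test_stage1_equals_single_objective(self, toy_phototroph):
        from carbonfba import make_scenario

        net, _ = toy_phototroph
        for label, staged in (("A", "E"), ("B", "F"), ("C", "G"), ("D", "H")):
            single = solve_fba(net, scenario=make_scenario(label))
            lex = solve_lexicographic(net, scenario=make_scenario(staged))
            assert lex.stage_values[0] == pytest.approx(
                single.stage_values[0], abs=1e-6
            )

    def test_weighted_mode_is_available(self):
        net = self._two_branch_net(shared_uptake=True)
        model = FluxBalanceModel(
            net,
            objective=ObjectiveSpec.maximize("Bio", "Pig"),
            method="weighted",
            stage_weights=[1.0, 1e-3],
        )
        res = model.fit()
        assert res.status == "optimal"

    def test_min_l1_tie_break_is_deterministic_and_optimal(self):
        net = self._two_branch_net(shared_uptake=True)
        runs = [
            FluxBalanceModel(
                net, objective=ObjectiveSpec.maximize("Bio", "Pig"), tie_break="min_l1"
            ).fit()
            for _ in range(2)
        ]
        assert runs[0].flux == runs[1].flux
        assert runs[0].stage_values == pytest.approx([4.0, 2.0], abs=1e-9)


class TestSolutionInvariants:
    @pytest.mark.parametrize("seed", range(20))
    def test_steady_state_and_bounds(self, seed):
        net = make_random_network(seed, n_metabolites=4, n_reactions=7)
        res = solve_fba(net, objective=ObjectiveSpec.maximize(net.reactions[0].id))
        assert res.status == "optimal"
        assert res.residual <= 1e-6
        assert res.max_bound_violation <= 1e-9

    @pytest.mark.parametrize("seed", range(15))
    def test_bound_enlargement_never_decreases_optimum(self, seed):
        rng = np.random.default_rng(seed)
        net = make_random_network(seed, n_metabolites=4, n_reactions=6)
        obj = ObjectiveSpec.maximize(net.reactions[-1].id)
        base = solve_fba(net, objective=obj).stage_values[0]
        j = int(rng.integers(len(net.reactions)))
        rxn = net.reactions[j]
        widened = net.copy()
        widened.replace_reaction(
            rxn.with_bounds(
                rxn.lower_bound - (0.0 if rxn.lower_bound == 0 else rng.uniform(0, 5)),
                rxn.upper_bound + rng.uniform(0, 5),
            )
        )
        enlarged = solve_fba(widened, objective=obj).stage_values[0]
        assert enlarged >= base - 1e-9

    @pytest.mark.parametrize("lam", [0.5, 2.0, 7.3])
    def test_lp_homogeneity_under_bound_scaling(self, toy_phototroph, lam):
        from carbonfba import apply_bounds, make_scenario

        net, _ = toy_phototroph
        sc = make_scenario("E")
        bounded = apply_bounds(net, overrides=sc.bound_overrides(net))
        obj = ObjectiveSpec.maximize("mu", "Car14")
        base = solve_lexicographic(bounded, objective=obj)
        scaled = solve_lexicographic(_scaled(bounded, lam), objective=obj)
        for b, s in zip(base.stage_values, scaled.stage_values):
            assert s == pytest.approx(lam * b, rel=1e-9)


class TestVertexOracle:
    def test_chain_matches_lp(self, chain_network):
        obj = ObjectiveSpec.maximize("R3")
        overrides = {"R1": (0.0, 5.0)}
        lp = solve_fba(chain_network, objective=obj, bound_overrides=overrides)
        oracle = enumerate_vertices_oracle(
            chain_network, objective=obj, bound_overrides=overrides
        )
        assert oracle.status == "optimal"
        assert oracle.value == pytest.approx(lp.stage_values[0], abs=1e-6)
        assert oracle.value == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(30))
    def test_random_networks_agree_with_lp(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_mets = int(rng.integers(2, 6))
        n_rxns = int(rng.integers(3, 9))
        net = make_random_network(seed, n_metabolites=n_mets, n_reactions=n_rxns)
        target = net.reactions[int(rng.integers(n_rxns))].id
        obj = ObjectiveSpec.maximize(target)
        lp = solve_fba(net, objective=obj)
        oracle = enumerate_vertices_oracle(net, objective=obj)
        assert lp.status == oracle.status == "optimal"
        assert oracle.value == pytest.approx(lp.stage_values[0], abs=1e-6)

    def test_infeasible_seen_by_both_paths(self, chain_network):
        overrides = {"R1": (0.0, 5.0), "R3": (10.0, 10.0)}
        obj = ObjectiveSpec.maximize("R3")
        lp = solve_fba(chain_network, objective=obj, bound_overrides=overrides)
        oracle = enumerate_vertices_oracle(
            chain_network, objective=obj, bound_overrides=overrides
        )
        assert lp.status == "infeasible"
        assert oracle.status == "infeasible"

    def test_refuses_large_instances(self):
        net = make_random_network(0, n_metabolites=6, n_reactions=13)
        with pytest.raises(ValueError, match="12 reactions"):
            enumerate_vertices_oracle(
                net, objective=ObjectiveSpec.maximize(net.reactions[0].id)
            )


class TestCrossCheckWithCobra:
    def test_toy_scenario_matches_independent_solver(self, toy_phototroph, tmp_path):
        """The same SBML solved by an unrelated FBA stack (cobrapy + GLPK)
        gives the same growth optimum as our HiGHS-based engine."""
        cobra = pytest.importorskip("cobra")
        from carbonfba import apply_bounds, make_scenario, write_sbml

        net, closed = toy_phototroph
        sc = make_scenario("A")
        bounded = apply_bounds(net, overrides=sc.bound_overrides(net))
        path = tmp_path / "toy.xml"
        write_sbml(bounded, path)
        model = cobra.io.read_sbml_model(str(path))
        # cobra may clip the SBML "R_" prefix depending on its id policy
        biomass_id = "mu" if model.reactions.has_id("mu") else "R_mu"
        model.objective = biomass_id
        external = model.optimize().objective_value
        ours = solve_fba(net, scenario=sc).stage_values[0]
        assert external == pytest.approx(ours, abs=1e-8)
        assert ours == pytest.approx(closed.mu_star(320.0, 0.19), abs=1e-9)
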