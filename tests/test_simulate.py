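import random
from fractions import Fraction

import pytest

from gemforge.fixtures import random_small_network, toy_models
from gemforge.model_core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    remove_reactions,
)
from gemforge.simulate import (
    fba,
    fseof,
    gap_fill,
    gap_report,
    growth_screen,
    single_gene_deletion,
)
from oracles import eval_rule_string, exhaustive_gap_fill_size, vertex_enumeration_optimum


class TestFBA:
    def test_linear_chain_optimum_is_uptake_bound(self, toys):
        sol = fba(toys["toy-chain"])
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        # steady state holds on every metabolite
        for mid in toys["toy-chain"].metabolites:
            balance = sum(float(c) * sol.fluxes[rid]
                          for rid, r in toys["toy-chain"].reactions.items()
                          for m, c in r.stoichiometry.items() if m == mid)
            assert abs(balance) < 1e-6

    def test_closed_uptake_gives_zero(self, toys):
        model = toys["toy-chain"].copy()
        model.reactions["EX_A"].lower_bound = 0.0
        assert fba(model).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_missing_objective_errors(self, toys):
        model = toys["toy-chain"].copy()
        model.objective = None
        with pytest.raises(ModelError):
            fba(model)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_vertex_enumeration_oracle(self, seed):
        """FBA optimum equals brute-force basic-solution enumeration on
        random bounded networks with <= 6 reactions."""
        model = random_small_network(random.Random(seed))
        expected = vertex_enumeration_optimum(model)
        sol = fba(model)
        assert sol.status == "optimal"
        if expected is not None:
            assert sol.objective_value == pytest.approx(expected, abs=1e-6)


class TestGapReport:
    def test_dead_end_and_blocked_detection(self, toys):
        model = remove_reactions(toys["toy-chain"], ["BIOMASS"])
        model.objective = None
        rep = gap_report(model)
        assert "C" in rep.dead_end_metabolites
        assert set(rep.blocked_reactions) == set(model.reactions)  # chain cannot drain

    def test_mass_conserving_toys_have_no_leaks(self, toys):
        for name in ("toy-chain", "toy-branch", "toy-gpr"):
            rep = gap_report(toys[name])
            assert rep.leaky_metabolites == []
            assert rep.consumable_from_nothing == []

    def test_planted_imbalance_is_flagged(self, toys):
        rep = gap_report(toys["toy-leaky"])
        # the B -> 2A cycle nets one A per turn, so both cycle members leak
        assert rep.leaky_metabolites == ["A", "B"]

    def test_disjoint_pathways_give_two_components(self, toys):
        model = toys["toy-chain"].copy()
        model.metabolites["D"] = Metabolite(id="D", compartment="c")
        model.metabolites["E"] = Metabolite(id="E", compartment="c")
        model.reactions["R9"] = Reaction(id="R9",
                                         stoichiometry={"D": Fraction(-1), "E": Fraction(1)})
        rep = gap_report(model)
        assert len(rep.components) == 2
        assert {"D", "E", "R9"} in rep.components

    def test_dead_end_side_reactions_are_blocked(self, toys):
        model = toys["toy-chain"].copy()
        model.metabolites["D"] = Metabolite(id="D", compartment="c")
        model.reactions["RD"] = Reaction(id="RD",
                                         stoichiometry={"C": Fraction(-1), "D": Fraction(1)})
        rep = gap_report(model)
        assert "D" in rep.dead_end_metabolites
        assert "RD" in rep.blocked_reactions


class TestGapFill:
    def test_missing_link_restored(self, toys):
        added = gap_fill(toys["toy-gapped"], toys["toy-gap-universal"], 1.0)
        assert added == ["R1"]

    def test_growing_model_needs_nothing(self, toys):
        assert gap_fill(toys["toy-chain"], toys["toy-gap-universal"], 1.0) == []

    def test_unfillable_raises(self, toys):
        pool = remove_reactions(toys["toy-gap-universal"], ["R1"])
        with pytest.raises(ModelError, match="unfillable"):
            gap_fill(toys["toy-gapped"], pool, 1.0)

    @pytest.mark.parametrize("extra", [0, 3, 6])
    def test_cardinality_matches_exhaustive_search(self, toys, extra, rng):
        """MILP minimal set size equals exhaustive subset search with up to
        ten candidates (decoys included)."""
        pool = toys["toy-gap-universal"].copy()
        for i in range(extra):
            mids = [f"D{i}", f"E{i}"]
            for mid in mids:
                pool.metabolites[mid] = Metabolite(id=mid, compartment="c")
            pool.reactions[f"RX{i}"] = Reaction(
                id=f"RX{i}", stoichiometry={mids[0]: Fraction(-1), mids[1]: Fraction(1)})
        added = gap_fill(toys["toy-gapped"], pool, 1.0)
        assert len(added) == exhaustive_gap_fill_size(toys["toy-gapped"], pool, 1.0)

    def test_two_step_gap(self, toys):
        model = remove_reactions(toys["toy-chain"], ["R1", "R2"])
        model.objective = ("BIOMASS", "maximize")
        pool = toys["toy-chain"]
        added = gap_fill(model, pool, 1.0)
        assert added == ["R1", "R2"]
        assert len(added) == exhaustive_gap_fill_size(model, pool, 1.0)


class TestEssentiality:
    def test_matches_reaction_knockout_oracle(self, toys):
        """Essential set equals exhaustive reaction knockout mapped through
        rule strings evaluated independently."""
        model = toys["toy-gpr"]
        result = single_gene_deletion(model)
        wt = fba(model).objective_value
        expected_essential = set()
        for gene in model.genes:
            active = set(model.genes) - {gene}
            disabled = [rid for rid, r in model.reactions.items()
                        if r.gene_rule is not None
                        and not eval_rule_string(r.gene_rule.to_string(), active)]
            ko_model = remove_reactions(model, disabled) if disabled else model
            sol = fba(ko_model)
            growth = sol.objective_value if sol.status == "optimal" else 0.0
            if growth / wt < 0.25:
                expected_essential.add(gene)
        assert result.essential_genes == expected_essential == {"g3", "g4", "g5"}

    def test_isozyme_knockout_is_neutral(self, toys):
        result = single_gene_deletion(toys["toy-gpr"])
        assert result.per_gene["g1"]["ratio"] == pytest.approx(1.0)
        assert not result.per_gene["g1"]["essential"]

    def test_transporter_knockout_is_lethal(self, toys):
        result = single_gene_deletion(toys["toy-gpr"])
        assert result.per_gene["g3"]["ratio"] == pytest.approx(0.0, abs=1e-9)
        assert result.per_gene["g3"]["essential"]

    def test_ratio_exactly_one_quarter_is_non_essential(self, toys):
        """The cutoff is strict: exactly 75% reduction does not count."""
        model = toys["toy-gpr"].copy()
        # give the knockout a bypass capped at exactly a quarter of wild type
        model.metabolites["A2"] = Metabolite(id="A2", compartment="c")
        model.reactions["T_A2"] = Reaction(
            id="T_A2", stoichiometry={"A_e": Fraction(-1), "A": Fraction(1)},
            lower_bound=0.0, upper_bound=2.5)
        result = single_gene_deletion(model)
        assert result.per_gene["g3"]["ratio"] == pytest.approx(0.25, abs=1e-9)
        assert not result.per_gene["g3"]["essential"]

    def test_non_growing_wild_type_errors(self, toys):
        with pytest.raises(ModelError, match="wild type"):
            single_gene_deletion(toys["toy-gapped"])


class TestGrowthScreen:
    def make_two_source_model(self):
        toys_ = toy_models()
        model = toys_["toy-chain"].copy()
        model.metabolites["N_e"] = Metabolite(id="N_e", compartment="e")
        model.reactions["EX_N"] = Reaction(id="EX_N",
                                           stoichiometry={"N_e": Fraction(-1)},
                                           lower_bound=0.0, upper_bound=1000.0,
                                           exchange=True)
        return model

    def test_predictions_follow_network_paths(self):
        model = self.make_two_source_model()
        result = growth_screen(model, [
            {"exchange": "EX_A", "observed": True},
            {"exchange": "EX_N", "observed": False},  # no path from N
        ])
        assert [r["predicted"] for r in result.per_condition] == [True, False]
        assert result.sensitivity == 1.0
        assert result.specificity == 1.0

    def test_false_negative_lowers_sensitivity(self):
        model = self.make_two_source_model()
        result = growth_screen(model, [
            {"exchange": "EX_A", "observed": True},
            {"exchange": "EX_N", "observed": True},
        ])
        assert result.sensitivity == 0.5

    def test_unknown_exchange_names_condition(self):
        model = self.make_two_source_model()
        with pytest.raises(ModelError, match="EX_Z"):
            growth_screen(model, [{"exchange": "EX_Z"}])

    def test_empty_condition_list_errors(self, toys):
        with pytest.raises(ModelError):
            growth_screen(toys["toy-chain"], [])


class TestFseof:
    def test_product_branch_is_the_target_set(self, toys):
        result = fseof(toys["toy-branch"], "BIOMASS", "EX_P")
        assert result.targets == {"RP", "EX_P"}
        assert result.v_product_max == pytest.approx(10.0, abs=1e-6)
        # enforced levels climb to 90% of the product maximum
        assert result.levels[-1] == pytest.approx(9.0, abs=1e-6)
        for rid in result.targets:
            series = [abs(v) for v in result.fluxes[rid]]
            assert all(b >= a - 1e-6 for a, b in zip(series, series[1:]))
            assert series[-1] > series[0] + 1e-6

    def test_shared_uptake_and_biomass_branch_are_not_targets(self, toys):
        result = fseof(toys["toy-branch"], "BIOMASS", "EX_P")
        assert "EX_A" not in result.targets   # constant |flux| = 10
        assert "RB" not in result.targets     # decreasing
        assert "BIOMASS" not in result.targets

    def test_direction_codes_follow_reversibility(self, toys):
        model = toys["toy-branch"].copy()
        model.reactions["RP"].lower_bound = -1000.0  # make the product step reversible
        result = fseof(model, "BIOMASS", "EX_P")
        assert result.direction["RP"] == 1            # reversible, forward flux
        assert result.direction["EX_A"] == -1         # reversible exchange, negative (import) flux
        assert result.direction["R1"] == 0            # irreversible
        assert "RP" in result.targets

    def test_invariant_to_reaction_reordering(self, toys):
        model = toys["toy-branch"]
        shuffled = model.copy()
        order = list(shuffled.reactions)
        random.Random(11).shuffle(order)
        shuffled.reactions = {rid: shuffled.reactions[rid] for rid in order}
        a = fseof(model, "BIOMASS", "EX_P")
        b = fseof(shuffled, "BIOMASS", "EX_P")
        assert a.targets == b.targets
        for rid in model.reactions:
            assert a.fluxes[rid] == pytest.approx(b.fluxes[rid], abs=1e-6)

    def test_invariant_to_uniform_bound_rescaling(self, toys):
        model = toys["toy-branch"].copy()
        for rxn in model.reactions.values():
            rxn.lower_bound *= 3.0
            rxn.upper_bound *= 3.0
        assert fseof(model, "BIOMASS", "EX_P").targets == {"RP", "EX_P"}

    def test_unreachable_product_errors(self, toys):
        model = toys["toy-branch"].copy()
        model.reactions["RP"].upper_bound = 0.0
        with pytest.raises(ModelError, match="unreachable"):
            fseof(model, "BIOMASS", "EX_P")

    def test_unknown_reaction_errors(self, toys):
        with pytest.raises(ModelError, match="EX_Q"):
            fseof(toys["toy-branch"], "BIOMASS", "EX_Q")


class TestDirectionSignFromFixtures:
    def test_reverse_direction_code(self):
        """A reversible reaction forced to carry negative flux codes as -1."""
        model = MetabolicModel(id="revnet", compartments={"c": "c"})
        for mid in ["A", "B", "C", "P"]:
            model.metabolites[mid] = Metabolite(id=mid, compartment="c")
        def rxn(rid, stoich, lb=0.0, ub=1000.0):
            model.reactions[rid] = Reaction(
                id=rid, stoichiometry={m: Fraction(c) for m, c in stoich.items()},
                lower_bound=lb, upper_bound=ub)
        rxn("EX_A", {"A": -1}, lb=-10.0)
        # B -> A written backwards: carries negative flux when converting A to B
        rxn("RREV", {"B": -1, "A": 1}, lb=-1000.0)
        rxn("RB", {"B": -1, "C": 1})
        rxn("BIOMASS", {"C": -1})
        rxn("RP", {"B": -1, "P": 1})
        rxn("EX_P", {"P": -1})
        model.objective = ("BIOMASS", "maximize")
        result = fseof(model, "BIOMASS", "EX_P")
        assert result.direction["RREV"] == -1
        assert "RREV" not in result.targets or result.slope["RREV"] > 0
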