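from fractions import Fraction

import pytest

from gemforge.combine import ReactionMapping, combine_models, link_cross_db_reactions
from gemforge.db_recon import build_universal_model, reconstruct_from_database
from gemforge.kegg_recon import assign_kos_from_annotation, reconstruct_from_kos
from gemforge.model_core import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    validate_model,
)


def small_model(model_id, rxns, comp="c"):
    model = MetabolicModel(id=model_id, compartments={comp: comp})
    for rid, stoich, lb in rxns:
        for mid in stoich:
            if mid not in model.metabolites:
                model.metabolites[mid] = Metabolite(id=mid, compartment=comp)
        model.reactions[rid] = Reaction(
            id=rid, stoichiometry={m: Fraction(c) for m, c in stoich.items()},
            lower_bound=lb, upper_bound=1000.0)
    return model


@pytest.fixture()
def ab_models():
    a = small_model("A", [
        ("RXN-GLC", {"GLC": -1, "GLC-6-P": 1}, 0.0),
        ("RXN-PROTON", {"GLC-6-P": -1, "PROTON": 1, "FRU-6-P": 1}, 0.0),
        ("RXN-ONLYA", {"FRU-6-P": -1, "PYR": 2}, 0.0),
    ])
    b = small_model("B", [
        ("R00771", {"C00031": -1, "C00668": 1}, 0.0),           # = RXN-GLC
        ("R09999", {"C00668": -1, "C05345": 1}, 0.0),            # = RXN-PROTON sans proton
        ("R00222", {"C05345": -1, "C99999": 1}, 0.0),            # B-unique, C99999 foreign
    ])
    met_xref = [("GLC", "C00031", False), ("GLC-6-P", "C00668", False),
                ("FRU-6-P", "C05345", False), ("PROTON", "C00080", True)]
    return a, b, met_xref


def brute_force_stage2(a, b, met_map, protons, already):
    """Oracle: all-pairs multiset comparison (coefficients, proton-blind,
    direction-agnostic), independent of the linker's signature trick."""
    def bag(model, rid, translate):
        items = {}
        for mid, coef in model.reactions[rid].stoichiometry.items():
            base = translate.get(mid, mid) if translate else mid
            if translate is not None and mid not in translate:
                return None
            if base in protons:
                continue
            items[base] = items.get(base, Fraction(0)) + coef
        return {m: c for m, c in items.items() if c != 0}

    result = {}
    for b_id in b.reactions:
        if b_id in {p[1] for p in already}:
            continue
        tb = bag(b, b_id, met_map)
        if tb is None or not tb:
            continue
        cands = []
        for a_id in a.reactions:
            if a_id in {p[0] for p in already}:
                continue
            ta = bag(a, a_id, None)
            if ta == tb or ta == {m: -c for m, c in tb.items()}:
                cands.append(a_id)
        result[b_id] = sorted(cands)
    return result


class TestLinking:
    def test_explicit_xref_pairs(self, ab_models):
        a, b, met_xref = ab_models
        mapping = link_cross_db_reactions(a, b, [("RXN-GLC", "R00771")], met_xref)
        assert ("RXN-GLC", "R00771", "xref") in mapping.pairs

    def test_reactant_match_oracle_agreement(self, ab_models):
        a, b, met_xref = ab_models
        mapping = link_cross_db_reactions(a, b, [], met_xref)
        met_map = {bb: aa for aa, bb, _ in met_xref}
        oracle = brute_force_stage2(a, b, met_map, {"PROTON"}, [])
        for a_id, b_id, origin in mapping.pairs:
            assert origin == "reactant-match"
            assert oracle[b_id] == [a_id]
        # every unique oracle match was found
        uniquely = {b_id for b_id, cands in oracle.items() if len(cands) == 1}
        assert {p[1] for p in mapping.pairs} == uniquely

    def test_proton_blind_matching(self, ab_models):
        a, b, met_xref = ab_models
        mapping = link_cross_db_reactions(a, b, [], met_xref)
        # R09999 lacks the explicit proton that RXN-PROTON carries
        assert ("RXN-PROTON", "R09999", "reactant-match") in mapping.pairs

    def test_ambiguous_candidates_reported_not_assigned(self, ab_models):
        a, b, met_xref = ab_models
        a.reactions["RXN-GLC-COPY"] = Reaction(
            id="RXN-GLC-COPY",
            stoichiometry={"GLC": Fraction(-1), "GLC-6-P": Fraction(1)},
            lower_bound=0.0, upper_bound=1000.0)
        mapping = link_cross_db_reactions(a, b, [], met_xref)
        assert "R00771" in mapping.ambiguous
        assert set(mapping.ambiguous["R00771"]) == {"RXN-GLC", "RXN-GLC-COPY"}
        assert "R00771" not in {p[1] for p in mapping.pairs}

    def test_unmatched_reactions_stay_unmapped(self, ab_models):
        a, b, met_xref = ab_models
        mapping = link_cross_db_reactions(a, b, [], met_xref)
        assert "R00222" not in {p[1] for p in mapping.pairs}  # C99999 untranslatable

    def test_symmetry_on_bijective_fixture(self, bundle_fixture, proteome_fixture):
        uni_a = build_universal_model(bundle_fixture.bundle)
        uni_b = build_universal_model(bundle_fixture.shadow_bundle)
        a = reconstruct_from_database(uni_a, proteome_fixture.hits)
        b = reconstruct_from_kos(
            assign_kos_from_annotation(proteome_fixture.ko_annotation), uni_b)
        met_xref = bundle_fixture.met_xref
        fwd = link_cross_db_reactions(a, b, [], met_xref)
        mirrored = [(bb, aa, pr) for aa, bb, pr in met_xref]
        rev = link_cross_db_reactions(b, a, [], mirrored)
        assert {(x, y) for x, y, _ in fwd.pairs} == {(y, x) for x, y, _ in rev.pairs}

    def test_one_to_one_invariant(self):
        with pytest.raises(ModelError):
            ReactionMapping(pairs=[("A1", "B1", "xref"), ("A2", "B1", "xref")])


class TestCombine:
    def test_counting_identity(self, ab_models):
        a, b, met_xref = ab_models
        mapping = link_cross_db_reactions(a, b, [("RXN-GLC", "R00771")], met_xref)
        combined = combine_models(a, b, mapping)
        stats = combined.extras["combine_stats"]
        assert len(combined.reactions) == \
            stats["n_a"] + stats["n_b"] - stats["n_mapped"] - stats["n_duplicates"]
        assert set(a.reactions) <= set(combined.reactions)  # A is never lost

    def test_self_combine_is_identity_on_counts(self, ab_models):
        a, _, _ = ab_models
        mapping = ReactionMapping(pairs=[(rid, rid, "xref") for rid in a.reactions])
        combined = combine_models(a, a, mapping)
        assert len(combined.reactions) == len(a.reactions)
        assert len(combined.metabolites) == len(a.metabolites)

    def test_mapped_rules_or_combined(self, ab_models):
        a, b, met_xref = ab_models
        a.reactions["RXN-GLC"].gene_rule = GeneRule.from_string("gA")
        b.reactions["R00771"].gene_rule = GeneRule.from_string("gB")
        a.rebuild_gene_list()
        b.rebuild_gene_list()
        mapping = link_cross_db_reactions(a, b, [("RXN-GLC", "R00771")], met_xref)
        combined = combine_models(a, b, mapping)
        assert combined.reactions["RXN-GLC"].gene_rule.dnf == (("gA",), ("gB",))
        assert "R00771" not in combined.reactions

    def test_unmapped_b_reaction_translated_and_foreign_flagged(self, ab_models):
        a, b, met_xref = ab_models
        mapping = link_cross_db_reactions(a, b, [], met_xref)
        combined = combine_models(a, b, mapping)
        rxn = combined.reactions["R00222"]
        assert "FRU-6-P" in rxn.stoichiometry          # translated to A namespace
        assert "C99999" in rxn.stoichiometry           # untranslatable keeps B id
        assert combined.metabolites["C99999"].extras.get("foreign")
        assert validate_model(combined) == []

    def test_mapping_citing_absent_reaction_errors(self, ab_models):
        a, b, _ = ab_models
        with pytest.raises(ModelError, match="GHOST"):
            combine_models(a, b, ReactionMapping(pairs=[("GHOST", "R00771", "xref")]))

    def test_withheld_xrefs_recovered_on_fixture(self, bundle_fixture, proteome_fixture):
        """Stage 2 recovers every withheld pair present in both drafts."""
        uni_a = build_universal_model(bundle_fixture.bundle)
        uni_b = build_universal_model(bundle_fixture.shadow_bundle)
        a = reconstruct_from_database(uni_a, proteome_fixture.hits)
        b = reconstruct_from_kos(
            assign_kos_from_annotation(proteome_fixture.ko_annotation), uni_b)
        mapping = link_cross_db_reactions(a, b, bundle_fixture.bundle.rxn_xref,
                                          bundle_fixture.met_xref)
        recovered = {(x, y) for x, y, origin in mapping.pairs if origin == "reactant-match"}
        withheld_present = {(x, y) for x, y in bundle_fixture.withheld_rxn_xrefs
                            if x in a.reactions and y in b.reactions}
        ambiguous_b = set(mapping.ambiguous)
        assert withheld_present - {p for p in withheld_present if p[1] in ambiguous_b} \
            <= recovered
        combined = combine_models(a, b, mapping)
        stats = combined.extras["combine_stats"]
        assert len(combined.reactions) == \
            stats["n_a"] + stats["n_b"] - stats["n_mapped"] - stats["n_duplicates"]
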