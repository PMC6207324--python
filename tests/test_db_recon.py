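from fractions import Fraction

import pytest

from gemforge.db_recon import (
    BundleEnzyme,
    BundleMetabolite,
    BundleReaction,
    DatabaseBundle,
    add_spontaneous_reactions,
    build_universal_model,
    load_bundle,
    parse_equation,
    reconstruct_from_database,
    write_bundle,
)
from gemforge.io_formats import AlignmentHit, FormatError
from gemforge.model_core import validate_model


def hit(subject, bit, ppos, query="q1"):
    return AlignmentHit(query_id=query, subject_id=subject, evalue=1e-40,
                        bit_score=bit, percent_positives=ppos,
                        percent_identity=ppos, aln_length=100)


def tiny_bundle(spontaneous_reversible=True):
    mets = {m: BundleMetabolite(id=m, name=m.lower()) for m in
            ["CO2", "WATER", "CARBONIC-ACID", "GLC", "G6P", "X", "Y", "Z"]}
    reactions = {
        "HEXOKINASE-RXN": BundleReaction(id="HEXOKINASE-RXN", name="glc kinase",
                                         stoichiometry={"GLC": Fraction(-1), "G6P": Fraction(1)},
                                         reversible=False),
        "CARBONATE-RXN": BundleReaction(
            id="CARBONATE-RXN", name="co2 hydration",
            stoichiometry={"CO2": Fraction(-1), "WATER": Fraction(-1),
                           "CARBONIC-ACID": Fraction(1)},
            reversible=spontaneous_reversible, spontaneous=True),
        "XYZ-RXN": BundleReaction(id="XYZ-RXN", name="xy to z",
                                  stoichiometry={"X": Fraction(-1), "Y": Fraction(-1),
                                                 "Z": Fraction(1)},
                                  reversible=False, spontaneous=True),
        "GLC-TRANSPORT": BundleReaction(id="GLC-TRANSPORT", name="glc uptake",
                                        stoichiometry={"GLC": Fraction(1)},
                                        reversible=False, transport=True),
    }
    enzymes = {
        "HK": BundleEnzyme(id="HK", reactions=["HEXOKINASE-RXN"]),
        "CPLX": BundleEnzyme(id="CPLX", reactions=["GLC-TRANSPORT"],
                             subunits=["CPLX-SU1", "CPLX-SU2"]),
    }
    sequences = {"HK": "MKVAAAA", "CPLX-SU1": "MLLLLLL", "CPLX-SU2": "MTTTTTT"}
    return DatabaseBundle(reactions=reactions, metabolites=mets, enzymes=enzymes,
                          pathways={}, sequences=sequences)


class TestBundle:
    def test_roundtrip_through_directory(self, tmp_path, bundle_fixture):
        write_bundle(bundle_fixture.bundle, tmp_path / "bundle")
        back = load_bundle(tmp_path / "bundle")
        src = bundle_fixture.bundle
        assert set(back.reactions) == set(src.reactions)
        for rid in src.reactions:
            assert back.reactions[rid].stoichiometry == src.reactions[rid].stoichiometry
            assert back.reactions[rid].reversible == src.reactions[rid].reversible
            assert back.reactions[rid].spontaneous == src.reactions[rid].spontaneous
        assert back.sequences == src.sequences
        assert back.rxn_xref == sorted(src.rxn_xref)

    def test_dangling_enzyme_reference_errors(self):
        bundle = tiny_bundle()
        bundle.enzymes["BAD"] = BundleEnzyme(id="BAD", reactions=["NOPE-RXN"])
        bundle.sequences["BAD"] = "MAAA"
        with pytest.raises(FormatError, match="NOPE-RXN"):
            bundle.validate()

    def test_missing_sequence_errors(self):
        bundle = tiny_bundle()
        del bundle.sequences["CPLX-SU2"]
        with pytest.raises(FormatError, match="CPLX-SU2"):
            bundle.validate()

    def test_spontaneous_with_enzyme_errors(self):
        bundle = tiny_bundle()
        bundle.enzymes["HK"].reactions.append("CARBONATE-RXN")
        with pytest.raises(FormatError, match="spontaneous"):
            bundle.validate()

    def test_equation_parsing(self):
        stoich, rev = parse_equation("2 A + B <=> C")
        assert stoich == {"A": Fraction(-2), "B": Fraction(-1), "C": Fraction(1)}
        assert rev
        stoich, rev = parse_equation("=> GLC")
        assert stoich == {"GLC": Fraction(1)} and not rev


class TestUniversalModel:
    def test_counts_preserved_without_transport(self):
        bundle = tiny_bundle()
        del bundle.reactions["GLC-TRANSPORT"]
        del bundle.enzymes["CPLX"]
        uni = build_universal_model(bundle)
        assert len(uni.model.reactions) == len(bundle.reactions)
        assert len(uni.model.metabolites) == len(bundle.metabolites)
        assert len(uni.enzyme_index) == len(bundle.enzymes)

    def test_reversible_reaction_gets_symmetric_bounds(self):
        uni = build_universal_model(tiny_bundle())
        assert uni.model.reactions["CARBONATE-RXN"].lower_bound == -1000.0
        assert uni.model.reactions["HEXOKINASE-RXN"].lower_bound == 0.0

    def test_spontaneous_and_transport_indexed(self):
        uni = build_universal_model(tiny_bundle())
        assert uni.spontaneous_ids == {"CARBONATE-RXN", "XYZ-RXN"}
        assert uni.transport_ids == {"GLC-TRANSPORT"}


class TestReconstruction:
    def test_threshold_boundaries(self):
        """Cut-off semantics: both bit >= 100 and positives >= 45 on one HSP."""
        uni = build_universal_model(tiny_bundle())
        included = reconstruct_from_database(uni, [hit("HK", 120, 50)])
        assert "HEXOKINASE-RXN" in included.reactions
        exact = reconstruct_from_database(uni, [hit("HK", 100, 45)])
        assert "HEXOKINASE-RXN" in exact.reactions
        below_bit = reconstruct_from_database(uni, [hit("HK", 99.9, 80)])
        assert below_bit.reactions == {}
        below_pos = reconstruct_from_database(uni, [hit("HK", 150, 44.9)])
        assert below_pos.reactions == {}

    def test_transport_reaction_spans_compartments(self):
        uni = build_universal_model(tiny_bundle())
        draft = reconstruct_from_database(uni, [hit("CPLX-SU1", 150, 60, "qS1")])
        rxn = draft.reactions["GLC-TRANSPORT"]
        assert rxn.stoichiometry == {"GLC_e": Fraction(-1), "GLC": Fraction(1)}
        assert draft.metabolites["GLC_e"].compartment == "e"
        assert draft.metabolites["GLC"].compartment == "c"

    def test_complex_rule_contains_matched_subunits_only(self):
        uni = build_universal_model(tiny_bundle())
        one = reconstruct_from_database(uni, [hit("CPLX-SU1", 150, 60, "qS1")])
        assert one.reactions["GLC-TRANSPORT"].gene_rule.dnf == (("qS1",),)
        both = reconstruct_from_database(uni, [hit("CPLX-SU1", 150, 60, "qS1"),
                                               hit("CPLX-SU2", 150, 60, "qS2")])
        assert both.reactions["GLC-TRANSPORT"].gene_rule.dnf == (("qS1", "qS2"),)

    def test_unknown_subject_warns_and_is_ignored(self):
        uni = build_universal_model(tiny_bundle())
        with pytest.warns(UserWarning, match="unknown subject"):
            draft = reconstruct_from_database(uni, [hit("GHOST", 150, 60)])
        assert draft.reactions == {}

    def test_planted_recovery_is_exact(self, bundle_fixture, proteome_fixture):
        """On noiseless planted fixtures precision = recall = 1.0."""
        uni = build_universal_model(bundle_fixture.bundle)
        draft = reconstruct_from_database(uni, proteome_fixture.hits)
        assert set(draft.reactions) == proteome_fixture.planted_reactions
        assert validate_model(draft) == []
        assert all(r.provenance for r in draft.reactions.values())

    def test_raising_thresholds_is_monotone(self, bundle_fixture, proteome_fixture):
        uni = build_universal_model(bundle_fixture.bundle)
        prev = None
        for min_bit, min_pos in [(100, 45), (130, 45), (130, 80), (500, 99)]:
            rxns = set(reconstruct_from_database(uni, proteome_fixture.hits,
                                                 min_bit=min_bit,
                                                 min_positives=min_pos).reactions)
            if prev is not None:
                assert rxns <= prev
            prev = rxns


class TestSpontaneous:
    def test_added_when_substrates_present(self, toys):
        bundle = tiny_bundle()
        uni = build_universal_model(bundle)
        draft = reconstruct_from_database(uni, [hit("HK", 150, 60)])
        draft.metabolites["CO2"] = draft.metabolites["GLC"].copy()
        draft.metabolites["CO2"].id = "CO2"
        draft.metabolites["WATER"] = draft.metabolites["GLC"].copy()
        draft.metabolites["WATER"].id = "WATER"
        out = add_spontaneous_reactions(draft, uni)
        assert "CARBONATE-RXN" in out.reactions
        assert "CARBONIC-ACID" in out.metabolites  # product created
        rxn = out.reactions["CARBONATE-RXN"]
        assert rxn.gene_rule is None and rxn.spontaneous
        assert rxn.provenance[0].source == "spontaneous"

    def test_not_added_when_substrate_missing(self):
        uni = build_universal_model(tiny_bundle())
        draft = reconstruct_from_database(uni, [hit("HK", 150, 60)])
        out = add_spontaneous_reactions(draft, uni)  # X or Y absent, CO2 absent
        assert "XYZ-RXN" not in out.reactions
        assert "CARBONATE-RXN" not in out.reactions

    def test_reverse_direction_satisfies_reversible_rule(self):
        uni = build_universal_model(tiny_bundle())
        draft = reconstruct_from_database(uni, [hit("HK", 150, 60)])
        met = draft.metabolites["GLC"].copy()
        met.id = "CARBONIC-ACID"
        draft.metabolites["CARBONIC-ACID"] = met
        out = add_spontaneous_reactions(draft, uni)
        assert "CARBONATE-RXN" in out.reactions  # product side present, reversible

    def test_irreversible_product_side_does_not_qualify(self):
        uni = build_universal_model(tiny_bundle(spontaneous_reversible=False))
        draft = reconstruct_from_database(uni, [hit("HK", 150, 60)])
        met = draft.metabolites["GLC"].copy()
        met.id = "CARBONIC-ACID"
        draft.metabolites["CARBONIC-ACID"] = met
        out = add_spontaneous_reactions(draft, uni)
        assert "CARBONATE-RXN" not in out.reactions

    def test_idempotent_on_fixture_draft(self, bundle_fixture, proteome_fixture):
        uni = build_universal_model(bundle_fixture.bundle)
        draft = reconstruct_from_database(uni, proteome_fixture.hits)
        once = add_spontaneous_reactions(draft, uni)
        twice = add_spontaneous_reactions(once, uni)
        assert set(twice.reactions) == set(once.reactions)
        added = set(once.reactions) - set(draft.reactions)
        present = set(draft.metabolites)
        for rid in added:  # every added reaction overlaps the prior draft
            subs = set(bundle_fixture.bundle.reactions[rid].stoichiometry)
            assert subs & present
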