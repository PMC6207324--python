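"""Deterministic synthetic fixtures: database bundles with planted enzymes,
query proteomes, alignment-hit tables and named toy models.

The generator emulates the inputs of a curated pathway database at desk
scale: linear pathways of elementally balanced reactions (isomerizations and
carrier-coupled transfers over ATP/ADP, NAD/NADH and protons), enzymes —
single proteins and two-subunit complexes — with random amino-acid sequences,
spontaneous and transport reactions, plus an id-renamed shadow namespace with
cross-reference tables (a fraction of reaction xrefs withheld so reactant
matching has work to do).  Planted query proteomes are mutated copies of
enzyme sequences; alignment hits are computed with the package's internal
global aligner using a bit-score proxy of 2×matches and percent positives
equal to percent identity.  Everything is a pure function of the spec and its
seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .db_recon import (
    BundleEnzyme,
    BundleMetabolite,
    BundleReaction,
    DatabaseBundle,
)
from .homology import global_align
from .io_formats import AlignmentHit, ProteinRecord
from .model_core import (
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "BundleFixture",
    "FixtureSpec",
    "ProteomeFixture",
    "generate_bundle",
    "generate_proteome_and_hits",
    "toy_models",
    "write_fixture_tree",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# fixed carrier chemistry (elemental formulas as dicts)
_CARRIERS = {
    "ATP": {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3},
    "ADP": {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2},
    "NAD": {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2},
    "NADH": {"C": 21, "H": 29, "N": 7, "O": 14, "P": 2},
    "PROTON": {"H": 1},
    "WATER": {"H": 2, "O": 1},
}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_pathways: int = 4
    reactions_per_pathway: int = 3
    n_enzymes: int = 12
    n_decoys: int = 4
    planted_fraction: float = 1.0
    noise: float = 0.0
    withheld_xref_fraction: float = 0.2

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.reactions_per_pathway, self.n_enzymes) < 1:
            raise ModelError("fixture sizes must be >= 1")
        for rate in (self.planted_fraction, self.noise, self.withheld_xref_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ModelError("fixture rates must lie in [0, 1]")


@dataclass
class BundleFixture:
    """A synthetic database bundle plus its planted ground truth."""

    bundle: DatabaseBundle                 # primary (A) namespace, xrefs partially withheld
    shadow_bundle: DatabaseBundle          # renamed (B) namespace, KO-style enzymes
    rxn_xref_full: list[tuple[str, str]]   # every (A, B) reaction pair
    withheld_rxn_xrefs: list[tuple[str, str]]
    met_xref: list[tuple[str, str, bool]]  # complete (A, B, is_proton)
    eligible_enzymes: list[str]            # enzymes a proteome may be planted from
    decoy_enzymes: list[str]
    spontaneous_ids: set[str]
    ko_of_enzyme: dict[str, str]           # A enzyme id -> shadow KO id

    def enzyme_reactions(self, enzyme_ids) -> set[str]:
        out: set[str] = set()
        for eid in enzyme_ids:
            out |= set(self.bundle.enzymes[eid].reactions)
        return out


@dataclass
class ProteomeFixture:
    records: list[ProteinRecord]
    hits: list[AlignmentHit]
    planted_enzymes: list[str]
    planted_reactions: set[str]
    gene_of_sequence: dict[str, str]       # bundle sequence id -> query gene id
    ko_annotation: dict[str, list[str]]    # query gene -> KO ids (curated table)
    hmm_scores: dict[str, dict[str, float]]  # query gene -> KO -> bit score


def _formula_str(counts: dict[str, int]) -> str:
    return "".join(f"{el}{counts[el]}" for el in sorted(counts) if counts[el] > 0)


def _add(a: dict[str, int], b: dict[str, int], sign: int = 1) -> dict[str, int]:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + sign * n
    return {el: n for el, n in out.items() if n != 0}


def _random_sequence(rng: random.Random, lo: int = 60, hi: int = 90) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(lo, hi)))


def generate_bundle(spec: FixtureSpec) -> BundleFixture:
    """Build a synthetic bundle (plus shadow namespace) from a spec.

    All internal reactions are elementally balanced by construction; the
    shadow bundle is an id-renamed copy whose proton-containing reactions may
    drop the explicit proton (the two databases disagree on protons, as real
    ones do), with ``withheld_xref_fraction`` of reaction xrefs removed from
    the primary bundle's table.
    """
    rng = random.Random(spec.seed)
    metabolites: dict[str, BundleMetabolite] = {}
    reactions: dict[str, BundleReaction] = {}
    pathways: dict[str, tuple[str, list[str]]] = {}

    formulas: dict[str, dict[str, int]] = {}

    def declare_met(mid: str, counts: dict[str, int]) -> None:
        if mid not in metabolites:
            metabolites[mid] = BundleMetabolite(id=mid, name=mid.lower(),
                                                formula=_formula_str(counts), charge=0)
            formulas[mid] = counts

    for cid, counts in _CARRIERS.items():
        declare_met(cid, counts)

    n_main = spec.n_pathways
    n_total = n_main + (1 if spec.n_decoys else 0)  # extra pathway feeds decoy enzymes
    decoy_rxns: list[str] = []
    main_rxns: list[str] = []
    spontaneous_ids: set[str] = set()

    for p in range(n_total):
        c = rng.randint(4, 8)
        counts = {"C": c, "H": 2 * c, "O": rng.randint(c - 1, c + 2)}
        prev = f"MET-{p}-0"
        declare_met(prev, counts)
        rxn_ids: list[str] = []
        for i in range(spec.reactions_per_pathway):
            nxt = f"MET-{p}-{i + 1}"
            kind = rng.choice(["iso", "phos", "red"])
            if kind == "iso":
                counts_next = dict(counts)
                stoich = {prev: Fraction(-1), nxt: Fraction(1)}
            elif kind == "phos":
                counts_next = _add(counts, {"H": 1, "P": 1, "O": 3})
                stoich = {prev: Fraction(-1), "ATP": Fraction(-1),
                          nxt: Fraction(1), "ADP": Fraction(1)}
            else:  # reduction: M + NADH + H+ -> M' + NAD  (M' gains 3 H in neutral-formula bookkeeping)
                counts_next = _add(counts, {"H": 3})
                stoich = {prev: Fraction(-1), "NADH": Fraction(-1), "PROTON": Fraction(-1),
                          nxt: Fraction(1), "NAD": Fraction(1)}
            declare_met(nxt, counts_next)
            rid = f"RXN-{p}-{i}"
            reactions[rid] = BundleReaction(
                id=rid, name=f"reaction {p}.{i} ({kind})", stoichiometry=stoich,
                reversible=rng.random() < 0.5,
                ec_numbers=[f"{rng.randint(1, 6)}.{rng.randint(1, 9)}.1.{rng.randint(1, 99)}"],
                pathways=[f"PWY-{p}"],
            )
            rxn_ids.append(rid)
            (decoy_rxns if p >= n_main else main_rxns).append(rid)
            counts, prev = counts_next, nxt
        pathways[f"PWY-{p}"] = (f"pathway {p}", rxn_ids)

    # spontaneous reactions off the main pathways (enzyme-free by construction):
    # even ones are tautomerizations (retrievable once the pathway is drafted),
    # odd ones are hydrations needing explicit water (usually absent from drafts)
    n_spont = max(1, n_main // 2)
    for s in range(n_spont):
        src = f"MET-{s % n_main}-1"
        prod = f"SPONT-MET-{s}"
        rid = f"SPONT-RXN-{s}"
        if s % 2 == 0:
            declare_met(prod, formulas[src])
            stoich = {src: Fraction(-1), prod: Fraction(1)}
            name = f"spontaneous tautomerization {s}"
        else:
            declare_met(prod, _add(formulas[src], _CARRIERS["WATER"]))
            stoich = {src: Fraction(-1), "WATER": Fraction(-1), prod: Fraction(1)}
            name = f"spontaneous hydration {s}"
        reactions[rid] = BundleReaction(
            id=rid, name=name, stoichiometry=stoich,
            reversible=True, spontaneous=True, pathways=[],
        )
        spontaneous_ids.add(rid)

    # transport of each pathway's entry metabolite (enzyme-associated)
    transport_rxns: list[str] = []
    for p in range(0, n_main, 2):
        rid = f"TRANS-RXN-{p}"
        # transported compound carries +1: expanded to MET_e -> MET at placement
        reactions[rid] = BundleReaction(
            id=rid, name=f"uptake of MET-{p}-0",
            stoichiometry={f"MET-{p}-0": Fraction(1)},
            reversible=False, transport=True,
        )
        transport_rxns.append(rid)
        main_rxns.append(rid)

    # enzymes: eligible (plantable) over main+transport reactions, decoys over the decoy pathway
    enzymes: dict[str, BundleEnzyme] = {}
    sequences: dict[str, str] = {}
    eligible: list[str] = []
    catalyzable = list(main_rxns)
    for i in range(spec.n_enzymes):
        eid = f"ENZ-{i}"
        if not catalyzable:
            catalyzable = list(main_rxns)
        k = min(len(catalyzable), rng.randint(1, 2))
        rxns = [catalyzable.pop(0) for _ in range(k)]
        if i % 4 == 3:  # two-subunit complex
            subunits = [f"{eid}-SU1", f"{eid}-SU2"]
            for su in subunits:
                sequences[su] = _random_sequence(rng)
        else:
            subunits = []
            sequences[eid] = _random_sequence(rng)
        enzymes[eid] = BundleEnzyme(id=eid, reactions=rxns, subunits=subunits)
        eligible.append(eid)

    decoys: list[str] = []
    for d in range(spec.n_decoys):
        eid = f"DECOY-{d}"
        rxns = [decoy_rxns[d % len(decoy_rxns)]] if decoy_rxns else [main_rxns[0]]
        sequences[eid] = _random_sequence(rng)
        enzymes[eid] = BundleEnzyme(id=eid, reactions=rxns, subunits=[])
        decoys.append(eid)

    # shadow (B) namespace: systematic renames + KO-style enzymes
    met_rename = {mid: f"C{idx:05d}" for idx, mid in enumerate(sorted(metabolites), start=1)}
    rxn_rename = {rid: f"R{idx:05d}" for idx, rid in enumerate(sorted(reactions), start=1)}
    shadow_reactions: dict[str, BundleReaction] = {}
    for rid in sorted(reactions):
        rxn = reactions[rid]
        stoich = {met_rename[m]: c for m, c in rxn.stoichiometry.items()}
        proton = met_rename["PROTON"]
        if proton in stoich and rng.random() < 0.5:
            del stoich[proton]  # shadow database writes this reaction proton-implicit
        shadow_reactions[rxn_rename[rid]] = BundleReaction(
            id=rxn_rename[rid], name=rxn.name, stoichiometry=stoich,
            reversible=rxn.reversible, ec_numbers=list(rxn.ec_numbers),
            pathways=list(rxn.pathways), spontaneous=rxn.spontaneous,
            transport=rxn.transport, balanced=rxn.balanced,
        )
    shadow_mets = {
        met_rename[mid]: BundleMetabolite(
            id=met_rename[mid], name=metabolites[mid].name,
            formula=metabolites[mid].formula, charge=metabolites[mid].charge)
        for mid in sorted(metabolites)
    }
    ko_of_enzyme: dict[str, str] = {}
    shadow_enzymes: dict[str, BundleEnzyme] = {}
    shadow_sequences: dict[str, str] = {}
    for idx, eid in enumerate(sorted(eligible), start=1):
        ko = f"K{idx:05d}"
        ko_of_enzyme[eid] = ko
        enz = enzymes[eid]
        shadow_enzymes[ko] = BundleEnzyme(
            id=ko, reactions=[rxn_rename[r] for r in enz.reactions], subunits=[])
        seq_ids = enz.subunits if enz.subunits else [eid]
        shadow_sequences[ko] = sequences[seq_ids[0]]
    shadow_bundle = DatabaseBundle(
        reactions=shadow_reactions, metabolites=shadow_mets, enzymes=shadow_enzymes,
        pathways={pid: (name, [rxn_rename[r] for r in rids])
                  for pid, (name, rids) in pathways.items()},
        sequences=shadow_sequences,
    )

    rxn_xref_full = [(rid, rxn_rename[rid]) for rid in sorted(reactions)]
    n_withheld = round(spec.withheld_xref_fraction * len(rxn_xref_full))
    withheld = sorted(rng.sample(rxn_xref_full, n_withheld))
    kept = [pair for pair in rxn_xref_full if pair not in set(withheld)]
    met_xref = [(mid, met_rename[mid], mid == "PROTON") for mid in sorted(metabolites)]

    bundle = DatabaseBundle(reactions=reactions, metabolites=metabolites, enzymes=enzymes,
                            pathways=pathways, sequences=sequences,
                            rxn_xref=kept, met_xref=met_xref)
    bundle.validate()
    shadow_bundle.validate()
    return BundleFixture(
        bundle=bundle, shadow_bundle=shadow_bundle,
        rxn_xref_full=rxn_xref_full, withheld_rxn_xrefs=withheld, met_xref=met_xref,
        eligible_enzymes=eligible, decoy_enzymes=decoys,
        spontaneous_ids=spontaneous_ids, ko_of_enzyme=ko_of_enzyme,
    )


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AMINO_ACIDS if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def generate_proteome_and_hits(fixture: BundleFixture, spec: FixtureSpec) -> ProteomeFixture:
    """Plant a query proteome from enzyme sequences and compute its hit table.

    Planted queries are copies of eligible enzyme (or subunit) sequences with
    per-residue substitution rate ``spec.noise``.  Hits against every bundle
    sequence are computed with the internal global aligner; bit-score proxy =
    2×matches, percent positives = percent identity, so decoy hits sit far
    below the (100 bits, 45 %) cut-offs by construction.
    """
    rng = random.Random((spec.seed * 2654435761 + 17) % (2**31))
    n_planted = round(spec.planted_fraction * len(fixture.eligible_enzymes))
    planted = sorted(rng.sample(sorted(fixture.eligible_enzymes), n_planted))

    bundle = fixture.bundle
    records: list[ProteinRecord] = []
    gene_of_sequence: dict[str, str] = {}
    for eid in planted:
        enz = bundle.enzymes[eid]
        for sid in (enz.subunits if enz.subunits else [eid]):
            gene = f"q_{sid}"
            records.append(ProteinRecord(id=gene, sequence=_mutate(rng, bundle.sequences[sid], spec.noise)))
            gene_of_sequence[sid] = gene

    hits: list[AlignmentHit] = []
    for rec in records:
        for sid in sorted(bundle.sequences):
            matches, columns = global_align(rec.sequence, bundle.sequences[sid])
            identity = 100.0 * matches / columns if columns else 0.0
            bit = 2.0 * matches
            hits.append(AlignmentHit(
                query_id=rec.id, subject_id=sid,
                evalue=10.0 ** (-bit / 10.0), bit_score=bit,
                percent_positives=identity, percent_identity=identity,
                aln_length=max(columns, 1),
            ))

    ko_annotation: dict[str, list[str]] = {}
    hmm_scores: dict[str, dict[str, float]] = {}
    seq_of_gene = {r.id: r.sequence for r in records}
    all_kos = sorted(fixture.ko_of_enzyme.values())
    for eid in planted:
        ko = fixture.ko_of_enzyme[eid]
        enz = bundle.enzymes[eid]
        for sid in (enz.subunits if enz.subunits else [eid]):
            gene = gene_of_sequence[sid]
            ko_annotation.setdefault(gene, []).append(ko)
            # emulated hmmsearch: profile of the gene's own family vs the query
            matches, _ = global_align(seq_of_gene[gene], bundle.sequences[sid])
            row = hmm_scores.setdefault(gene, {})
            row[ko] = 2.0 * matches
            # sub-threshold scores against unrelated profiles, to be rejected
            for other in rng.sample(all_kos, min(2, len(all_kos))):
                if other != ko:
                    row.setdefault(other, round(rng.uniform(5.0, 40.0), 1))
    return ProteomeFixture(
        records=records, hits=hits, planted_enzymes=planted,
        planted_reactions=fixture.enzyme_reactions(planted),
        gene_of_sequence=gene_of_sequence,
        ko_annotation=ko_annotation, hmm_scores=hmm_scores,
    )


# ---------------------------------------------------------------------------
# Named toy models
# ---------------------------------------------------------------------------


def _toy(model_id: str, mets: list[tuple[str, str]], rxns: list[dict],
         objective: Optional[str] = None) -> MetabolicModel:
    model = MetabolicModel(id=model_id, name=model_id,
                           compartments={"c": "cytosol", "e": "extracellular"})
    for mid, comp in mets:
        model.metabolites[mid] = Metabolite(id=mid, name=mid, compartment=comp)
    for spec in rxns:
        rule = GeneRule.from_string(spec.get("rule", ""))
        model.add_reaction(Reaction(
            id=spec["id"],
            stoichiometry={m: Fraction(c) for m, c in spec["stoich"].items()},
            lower_bound=spec.get("lb", 0.0), upper_bound=spec.get("ub", 1000.0),
            gene_rule=rule, exchange=spec.get("exchange", False),
        ))
    if objective:
        model.objective = (objective, "maximize")
    model.rebuild_gene_list()
    return model


def toy_models() -> dict[str, MetabolicModel]:
    """Hand-built models with documented optima and truth sets.

    * ``toy-chain`` — linear uptake chain; FBA optimum equals the uptake bound (10).
    * ``toy-branch`` — growth branch vs product branch; the product-branch
      reactions (RP, EX_P) are the amplification targets.
    * ``toy-gapped`` — toy-chain missing R1 (infeasible until gap-filled).
    * ``toy-gap-universal`` — donor pool holding the missing R1 and a decoy R9.
    * ``toy-leaky`` — contains B → 2 A, so A is producible with exchanges closed.
    * ``toy-gpr`` — toy-chain with gene rules; essential genes are g3, g4, g5.
    """
    models: dict[str, MetabolicModel] = {}

    chain_mets = [("A_e", "e"), ("A", "c"), ("B", "c"), ("C", "c")]
    chain_rxns = [
        {"id": "EX_A", "stoich": {"A_e": -1}, "lb": -10.0, "exchange": True},
        {"id": "T_A", "stoich": {"A_e": -1, "A": 1}},
        {"id": "R1", "stoich": {"A": -1, "B": 1}},
        {"id": "R2", "stoich": {"B": -1, "C": 1}},
        {"id": "BIOMASS", "stoich": {"C": -1}},
    ]
    models["toy-chain"] = _toy("toy-chain", chain_mets, chain_rxns, objective="BIOMASS")

    branch_mets = chain_mets + [("P", "c")]
    branch_rxns = [
        {"id": "EX_A", "stoich": {"A_e": -1}, "lb": -10.0, "exchange": True},
        {"id": "T_A", "stoich": {"A_e": -1, "A": 1}},
        {"id": "R1", "stoich": {"A": -1, "B": 1}},
        {"id": "RB", "stoich": {"B": -1, "C": 1}},
        {"id": "BIOMASS", "stoich": {"C": -1}},
        {"id": "RP", "stoich": {"B": -1, "P": 1}},
        {"id": "EX_P", "stoich": {"P": -1}, "exchange": True},
    ]
    models["toy-branch"] = _toy("toy-branch", branch_mets, branch_rxns, objective="BIOMASS")

    gapped = _toy("toy-gapped", chain_mets,
                  [r for r in chain_rxns if r["id"] != "R1"], objective="BIOMASS")
    models["toy-gapped"] = gapped
    models["toy-gap-universal"] = _toy(
        "toy-gap-universal",
        chain_mets + [("D", "c"), ("E", "c")],
        [{"id": "R1", "stoich": {"A": -1, "B": 1}},
         {"id": "R9", "stoich": {"D": -1, "E": 1}}],
    )

    models["toy-leaky"] = _toy(
        "toy-leaky",
        [("A", "c"), ("B", "c")],
        [{"id": "EX_A", "stoich": {"A": -1}, "lb": -10.0, "exchange": True},
         {"id": "R1", "stoich": {"A": -1, "B": 1}},
         {"id": "RBAD", "stoich": {"B": -1, "A": 2}}],
    )

    gpr_rxns = [
        {"id": "EX_A", "stoich": {"A_e": -1}, "lb": -10.0, "exchange": True},
        {"id": "T_A", "stoich": {"A_e": -1, "A": 1}, "rule": "g3"},
        {"id": "R1", "stoich": {"A": -1, "B": 1}, "rule": "g1 or g2"},
        {"id": "R2", "stoich": {"B": -1, "C": 1}, "rule": "g4 and g5"},
        {"id": "BIOMASS", "stoich": {"C": -1}},
    ]
    models["toy-gpr"] = _toy("toy-gpr", chain_mets, gpr_rxns, objective="BIOMASS")
    return models


# ---------------------------------------------------------------------------
# On-disk fixture tree (pipeline inputs)
# ---------------------------------------------------------------------------


def write_fixture_tree(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Materialize a full pipeline input set under ``outdir``.

    Writes the primary bundle, the shadow (KO-style) bundle, the planted
    proteome with its alignment-hit table, the KO annotation and HMM score
    tables, and the cross-reference tables.  Returns the path map.
    """
    from pathlib import Path

    from .db_recon import write_bundle
    from .io_formats import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = generate_bundle(spec)
    proteome = generate_proteome_and_hits(fixture, spec)

    write_bundle(fixture.bundle, outdir / "bundle")
    write_bundle(fixture.shadow_bundle, outdir / "shadow_bundle")
    write_fasta(proteome.records, outdir / "proteome.faa")
    with open(outdir / "hits.tsv", "w") as fh:
        for h in proteome.hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.evalue:.3e}\t{h.bit_score:.1f}"
                     f"\t{h.percent_positives:.2f}\t{h.percent_identity:.2f}\t{h.aln_length}\n")
    with open(outdir / "annotation.tsv", "w") as fh:
        for gene in sorted(proteome.ko_annotation):
            fh.write(f"{gene}\t{';'.join(sorted(proteome.ko_annotation[gene]))}\n")
    with open(outdir / "hmm_scores.tsv", "w") as fh:
        for gene in sorted(proteome.hmm_scores):
            for ko in sorted(proteome.hmm_scores[gene]):
                fh.write(f"{gene}\t{ko}\t{proteome.hmm_scores[gene][ko]:.1f}\n")
    with open(outdir / "rxn_xref.tsv", "w") as fh:
        for a, b in fixture.bundle.rxn_xref:
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "met_xref.tsv", "w") as fh:
        for a, b, proton in fixture.met_xref:
            fh.write(f"{a}\t{b}\t{'proton' if proton else '-'}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("# planted reactions (primary namespace)\n")
        for rid in sorted(proteome.planted_reactions):
            fh.write(rid + "\n")
    return {
        "bundle": str(outdir / "bundle"),
        "shadow_bundle": str(outdir / "shadow_bundle"),
        "proteome": str(outdir / "proteome.faa"),
        "hits": str(outdir / "hits.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "hmm_scores": str(outdir / "hmm_scores.tsv"),
        "rxn_xref": str(outdir / "rxn_xref.tsv"),
        "met_xref": str(outdir / "met_xref.tsv"),
    }


# ---------------------------------------------------------------------------
# Random generators for property testing
# ---------------------------------------------------------------------------


def random_valid_model(rng: random.Random, model_id: str = "random") -> MetabolicModel:
    """A small random but structurally valid model (for round-trip properties).

    Covers the serialization surface: multiple compartments, fractional and
    integer coefficients, reversible/irreversible/exchange reactions, gene
    rules with isozymes and complexes, xrefs, formulas and charges.
    """
    model = MetabolicModel(id=f"{model_id}_{rng.randint(0, 10**6)}",
                           name="randomly generated model",
                           compartments={"c": "cytosol", "e": "extracellular"})
    n_mets = rng.randint(3, 8)
    for i in range(n_mets):
        comp = "e" if i == 0 else "c"
        met = Metabolite(id=f"m{i}", name=f"metabolite {i}", compartment=comp,
                         formula=rng.choice([None, "C6H12O6", "H2O", "C3H7NO2"]),
                         charge=rng.choice([None, -1, 0, 1, 2]))
        if rng.random() < 0.5:
            met.xrefs = {"kegg": [f"C{rng.randint(1, 99999):05d}"]}
        model.metabolites[met.id] = met
    genes = [f"g{i}" for i in range(rng.randint(1, 6))]
    coefs = [Fraction(1), Fraction(2), Fraction(3), Fraction(1, 2), Fraction(5, 4)]
    n_rxns = rng.randint(2, 6)
    for j in range(n_rxns):
        k = rng.randint(1, min(3, n_mets))
        chosen = rng.sample(sorted(model.metabolites), k)
        stoich = {}
        for idx, mid in enumerate(chosen):
            sign = -1 if idx < max(1, k // 2) else 1
            stoich[mid] = sign * rng.choice(coefs)
        reversible = rng.random() < 0.4
        rule = None
        if rng.random() < 0.7:
            terms = []
            for _ in range(rng.randint(1, 2)):
                terms.append(tuple(sorted(rng.sample(genes, rng.randint(1, min(2, len(genes)))))))
            rule = GeneRule(dnf=tuple(sorted(set(terms))))
        rxn = Reaction(id=f"r{j}", name=f"reaction {j}", stoichiometry=stoich,
                       lower_bound=-1000.0 if reversible else 0.0, upper_bound=1000.0,
                       gene_rule=rule,
                       subsystem=rng.choice([None, "glycolysis", "transport"]),
                       ec_numbers=rng.choice([[], ["1.1.1.1"]]),
                       exchange=len(stoich) == 1)
        if rng.random() < 0.3:
            rxn.xrefs = {"metacyc": [f"RXN-{rng.randint(1, 9999)}"]}
        model.reactions[rxn.id] = rxn
    model.rebuild_gene_list()
    model.objective = (rng.choice(sorted(model.reactions)), "maximize")
    return model


def random_small_network(rng: random.Random) -> MetabolicModel:
    """A random bounded flux network with ≤ 6 reactions (for LP oracles).

    All bounds are finite and contain zero, so the network is feasible and the
    optimum is attained at a vertex of the flux polytope.
    """
    n_mets = rng.randint(2, 4)
    n_rxns = rng.randint(3, 6)
    model = MetabolicModel(id=f"net_{rng.randint(0, 10**6)}", compartments={"c": "c"})
    for i in range(n_mets):
        model.metabolites[f"m{i}"] = Metabolite(id=f"m{i}", compartment="c")
    for j in range(n_rxns):
        k = rng.randint(1, n_mets)
        chosen = rng.sample(sorted(model.metabolites), k)
        stoich = {mid: Fraction(rng.choice([-2, -1, 1, 2])) for mid in chosen}
        lb = float(rng.choice([-10, -5, 0]))
        ub = float(rng.choice([0, 5, 10]))
        model.reactions[f"r{j}"] = Reaction(id=f"r{j}", stoichiometry=stoich,
                                            lower_bound=lb, upper_bound=ub)
    model.objective = (rng.choice(sorted(model.reactions)), "maximize")
    return model
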