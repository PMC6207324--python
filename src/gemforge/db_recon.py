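"""Universal-model construction from a pathway-database bundle and
homology-based de-novo draft reconstruction, including spontaneous and
transport reactions.

A :class:`DatabaseBundle` is a canonical TSV/FASTA directory modelling the
content of a curated pathway database: reactions (with reversibility,
spontaneous/transport flags and balance status), metabolites, enzymes with
protein sequences (single proteins or multi-subunit complexes), pathways and
cross-reference tables to a second identifier namespace.  The whole bundle is
expressed as one :class:`UniversalModel` — the candidate pool for draft
reconstruction and gap filling.

Draft reconstruction keeps the enzymes whose sequences show homology to the
query proteome (best-HSP bit score and percent positives both above their
cut-offs; defaults 100 bits and 45 %) together with the reactions they
catalyze.  Spontaneous reactions — which carry no enzyme association and would
otherwise turn into gaps — are retrieved afterwards whenever their reactants
are already present in the draft.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

from .io_formats import (
    AlignmentHit,
    FormatError,
    ProteinRecord,
    format_coefficient,
    parse_coefficient,
    read_fasta,
    write_fasta,
)
from .model_core import (
    DEFAULT_UPPER,
    Evidence,
    GeneRule,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "BundleEnzyme",
    "BundleMetabolite",
    "BundleReaction",
    "DatabaseBundle",
    "UniversalModel",
    "add_spontaneous_reactions",
    "build_universal_model",
    "load_bundle",
    "write_bundle",
    "DEFAULT_MIN_BIT",
    "DEFAULT_MIN_POSITIVES",
    "reconstruct_from_database",
]

DEFAULT_MIN_BIT = 100.0       # bit-score cut-off for enzyme homology support
DEFAULT_MIN_POSITIVES = 45.0  # percent-positives cut-off (best HSP)

EXTRACELLULAR_SUFFIX = "_e"


# ---------------------------------------------------------------------------
# Bundle content types
# ---------------------------------------------------------------------------


@dataclass
class BundleReaction:
    id: str
    name: str
    stoichiometry: dict[str, Fraction]  # signed; negative = substrate
    reversible: bool
    ec_numbers: list[str] = field(default_factory=list)
    pathways: list[str] = field(default_factory=list)
    spontaneous: bool = False
    transport: bool = False
    balanced: bool = True


@dataclass
class BundleMetabolite:
    id: str
    name: str
    formula: Optional[str] = None
    charge: Optional[int] = None
    xrefs: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class BundleEnzyme:
    id: str
    reactions: list[str]
    subunits: list[str] = field(default_factory=list)  # empty = single-sequence enzyme


@dataclass
class DatabaseBundle:
    reactions: dict[str, BundleReaction]
    metabolites: dict[str, BundleMetabolite]
    enzymes: dict[str, BundleEnzyme]
    pathways: dict[str, tuple[str, list[str]]]  # id -> (name, reaction ids)
    sequences: dict[str, str]  # enzyme/subunit id -> amino-acid sequence
    rxn_xref: list[tuple[str, str]] = field(default_factory=list)  # (local, foreign)
    met_xref: list[tuple[str, str, bool]] = field(default_factory=list)  # (local, foreign, is_proton)

    def validate(self) -> None:
        for rid, rxn in self.reactions.items():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise FormatError(f"reactions.tsv: reaction {rid!r} references undeclared metabolite {mid!r}")
        for eid, enz in self.enzymes.items():
            for rid in enz.reactions:
                if rid not in self.reactions:
                    raise FormatError(f"enzymes.tsv: enzyme {eid!r} cites unknown reaction {rid!r}")
                if self.reactions[rid].spontaneous:
                    raise FormatError(f"enzymes.tsv: enzyme {eid!r} attached to spontaneous reaction {rid!r}")
            seq_ids = enz.subunits if enz.subunits else [eid]
            for sid in seq_ids:
                if sid not in self.sequences:
                    raise FormatError(f"protseq.fsa: missing sequence for {sid!r} (enzyme {eid!r})")
        for pid, (_, rids) in self.pathways.items():
            for rid in rids:
                if rid not in self.reactions:
                    raise FormatError(f"pathways.tsv: pathway {pid!r} cites unknown reaction {rid!r}")


# ---------------------------------------------------------------------------
# Equation grammar (compartment-free): "2 A + B <=> C" / "A => B"
# ---------------------------------------------------------------------------


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse a compartment-free equation into signed stoichiometry + reversibility."""
    if "<=>" in text:
        lhs, rhs = text.split("<=>")
        reversible = True
    elif "=>" in text:
        lhs, rhs = text.split("=>")
        reversible = False
    else:
        raise FormatError(f"equation {text!r} lacks an arrow (=> or <=>)")
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                coef, mid = Fraction(1), parts[0]
            elif len(parts) == 2:
                coef, mid = parse_coefficient(parts[0]), parts[1]
            else:
                raise FormatError(f"cannot parse equation term {term!r}")
            stoich[mid] = stoich.get(mid, Fraction(0)) + sign * coef

    add_side(lhs, -1)
    add_side(rhs, +1)
    return {m: c for m, c in stoich.items() if c != 0}, reversible


def equation_string(stoich: dict[str, Fraction], reversible: bool) -> str:
    def side(items: dict[str, Fraction]) -> str:
        return " + ".join(
            (f"{format_coefficient(c)} {m}" if c != 1 else m)
            for m, c in sorted(items.items())
        )

    subs = {m: -c for m, c in stoich.items() if c < 0}
    prods = {m: c for m, c in stoich.items() if c > 0}
    arrow = "<=>" if reversible else "=>"
    return f"{side(subs)} {arrow} {side(prods)}".strip()


# ---------------------------------------------------------------------------
# Bundle directory I/O
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False, "": False}


def _split_list(cell: str) -> list[str]:
    cell = cell.strip()
    if not cell or cell == "-":
        return []
    return [tok for tok in cell.split(";") if tok]


def load_bundle(path: Union[str, Path]) -> DatabaseBundle:
    """Load and validate a bundle directory."""
    path = Path(path)

    def rows(name: str) -> list[dict[str, str]]:
        fp = path / name
        if not fp.exists():
            raise FormatError(f"bundle is missing {name}")
        with open(fp) as fh:
            return list(csv.DictReader(fh, delimiter="\t"))

    reactions: dict[str, BundleReaction] = {}
    for row in rows("reactions.tsv"):
        stoich, reversible_eq = parse_equation(row["equation"])
        reactions[row["id"]] = BundleReaction(
            id=row["id"], name=row.get("name", ""), stoichiometry=stoich,
            reversible=_BOOL[row.get("reversible", "").lower()] or reversible_eq,
            ec_numbers=_split_list(row.get("ec", "")),
            pathways=_split_list(row.get("pathways", "")),
            spontaneous=_BOOL[row.get("spontaneous", "").lower()],
            transport=_BOOL[row.get("transport", "").lower()],
            balanced=_BOOL[row.get("balanced", "true").lower()],
        )
    metabolites: dict[str, BundleMetabolite] = {}
    for row in rows("metabolites.tsv"):
        xrefs: dict[str, list[str]] = {}
        for tok in _split_list(row.get("xrefs", "")):
            ns, _, fid = tok.partition(":")
            xrefs.setdefault(ns, []).append(fid)
        metabolites[row["id"]] = BundleMetabolite(
            id=row["id"], name=row.get("name", ""),
            formula=row.get("formula") or None,
            charge=int(row["charge"]) if row.get("charge") not in (None, "", "-") else None,
            xrefs=xrefs,
        )
    enzymes = {
        row["id"]: BundleEnzyme(id=row["id"], reactions=_split_list(row["reactions"]),
                                subunits=_split_list(row.get("subunits", "")))
        for row in rows("enzymes.tsv")
    }
    pathways = {
        row["id"]: (row.get("name", ""), _split_list(row["reactions"]))
        for row in rows("pathways.tsv")
    }
    sequences = {rec.id: rec.sequence for rec in read_fasta(path / "protseq.fsa")}

    def xref_rows(name: str) -> list[list[str]]:
        fp = path / name
        if not fp.exists():
            return []
        out = []
        with open(fp) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                out.append(line.split("\t"))
        return out

    rxn_xref = [(c[0], c[1]) for c in xref_rows("rxn_xref.tsv")]
    met_xref = [(c[0], c[1], len(c) > 2 and c[2] == "proton") for c in xref_rows("met_xref.tsv")]

    bundle = DatabaseBundle(reactions=reactions, metabolites=metabolites, enzymes=enzymes,
                            pathways=pathways, sequences=sequences,
                            rxn_xref=rxn_xref, met_xref=met_xref)
    bundle.validate()
    return bundle


def write_bundle(bundle: DatabaseBundle, path: Union[str, Path]) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "reactions.tsv", "w") as fh:
        fh.write("id\tname\tequation\treversible\tec\tpathways\tspontaneous\ttransport\tbalanced\n")
        for rid in sorted(bundle.reactions):
            r = bundle.reactions[rid]
            fh.write("\t".join([
                r.id, r.name, equation_string(r.stoichiometry, r.reversible),
                str(r.reversible).lower(), ";".join(r.ec_numbers) or "-",
                ";".join(r.pathways) or "-", str(r.spontaneous).lower(),
                str(r.transport).lower(), str(r.balanced).lower(),
            ]) + "\n")
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tformula\tcharge\txrefs\n")
        for mid in sorted(bundle.metabolites):
            m = bundle.metabolites[mid]
            xr = ";".join(f"{ns}:{fid}" for ns in sorted(m.xrefs) for fid in sorted(m.xrefs[ns]))
            fh.write("\t".join([m.id, m.name, m.formula or "-",
                                str(m.charge) if m.charge is not None else "-", xr or "-"]) + "\n")
    with open(path / "enzymes.tsv", "w") as fh:
        fh.write("id\treactions\tsubunits\n")
        for eid in sorted(bundle.enzymes):
            e = bundle.enzymes[eid]
            fh.write("\t".join([e.id, ";".join(e.reactions), ";".join(e.subunits) or "-"]) + "\n")
    with open(path / "pathways.tsv", "w") as fh:
        fh.write("id\tname\treactions\n")
        for pid in sorted(bundle.pathways):
            name, rids = bundle.pathways[pid]
            fh.write("\t".join([pid, name, ";".join(rids)]) + "\n")
    write_fasta([ProteinRecord(id=sid, sequence=seq)
                 for sid, seq in sorted(bundle.sequences.items())], path / "protseq.fsa")
    with open(path / "rxn_xref.tsv", "w") as fh:
        for a, b in bundle.rxn_xref:
            fh.write(f"{a}\t{b}\n")
    with open(path / "met_xref.tsv", "w") as fh:
        for a, b, proton in bundle.met_xref:
            fh.write(f"{a}\t{b}\t{'proton' if proton else '-'}\n")


# ---------------------------------------------------------------------------
# Universal model
# ---------------------------------------------------------------------------


@dataclass
class UniversalModel:
    """The whole database bundle expressed as one model.

    Metabolites live in the pseudo-compartment ``u`` (the database is
    compartment-free); transport reactions place their substrate side in
    ``e``.  The enzyme index, spontaneous set and transport set drive draft
    reconstruction.
    """

    model: MetabolicModel
    bundle: DatabaseBundle
    enzyme_index: dict[str, BundleEnzyme]
    spontaneous_ids: set[str]
    transport_ids: set[str]

    def as_candidate_model(self, compartment: str = "c") -> MetabolicModel:
        """The universal network re-homed to ``compartment`` (gap-fill pool)."""
        out = MetabolicModel(id=self.model.id + "_pool",
                             compartments={compartment: compartment, "e": "extracellular"})
        for rid, rxn in self.bundle.reactions.items():
            stoich, comp_of = _place_reaction(rxn, compartment)
            for mid, comp in comp_of.items():
                if mid not in out.metabolites:
                    out.metabolites[mid] = _draft_metabolite(self.bundle, mid, comp)
            out.reactions[rid] = _draft_reaction(rxn, stoich)
        return out


def _bounds(reversible: bool) -> tuple[float, float]:
    return (-DEFAULT_UPPER, DEFAULT_UPPER) if reversible else (0.0, DEFAULT_UPPER)


def _place_reaction(rxn: BundleReaction, compartment: str) -> tuple[dict[str, Fraction], dict[str, str]]:
    """Compartment placement for a draft.

    Ordinary reactions land entirely in ``compartment``.  For transport
    reactions the bundle stores the transported compound with a positive
    coefficient (a stoichiometry mapping cannot carry the same compound on
    both sides); placement expands it to substrate in ``e`` (id suffixed) and
    product in ``compartment``, while negative entries stay internal
    co-substrates.
    """
    stoich: dict[str, Fraction] = {}
    comp_of: dict[str, str] = {}
    for mid, coef in rxn.stoichiometry.items():
        if rxn.transport and coef > 0:
            ext = mid + EXTRACELLULAR_SUFFIX
            stoich[ext] = stoich.get(ext, Fraction(0)) - coef
            comp_of[ext] = "e"
        stoich[mid] = stoich.get(mid, Fraction(0)) + coef
        comp_of[mid] = compartment
    return stoich, comp_of


def _draft_metabolite(bundle: DatabaseBundle, mid: str, comp: str) -> Metabolite:
    base = mid[:-len(EXTRACELLULAR_SUFFIX)] if mid.endswith(EXTRACELLULAR_SUFFIX) else mid
    bm = bundle.metabolites.get(base)
    if bm is None:
        return Metabolite(id=mid, name=mid, compartment=comp)
    return Metabolite(id=mid, name=bm.name, compartment=comp, formula=bm.formula,
                      charge=bm.charge, xrefs={ns: list(v) for ns, v in bm.xrefs.items()})


def _draft_reaction(rxn: BundleReaction, stoich: dict[str, Fraction]) -> Reaction:
    lb, ub = _bounds(rxn.reversible)
    return Reaction(id=rxn.id, name=rxn.name, stoichiometry=stoich,
                    lower_bound=lb, upper_bound=ub,
                    subsystem=rxn.pathways[0] if rxn.pathways else None,
                    ec_numbers=list(rxn.ec_numbers),
                    spontaneous=rxn.spontaneous, transport=rxn.transport)


def build_universal_model(bundle: DatabaseBundle, model_id: str = "universal") -> UniversalModel:
    """Express the whole bundle as one model plus enzyme/spontaneous/transport indexes."""
    bundle.validate()
    model = MetabolicModel(id=model_id, name="universal database model",
                           compartments={"u": "universal", "e": "extracellular"})
    for mid in sorted(bundle.metabolites):
        model.metabolites[mid] = _draft_metabolite(bundle, mid, "u")
    for rid in sorted(bundle.reactions):
        rxn = bundle.reactions[rid]
        stoich, comp_of = _place_reaction(rxn, "u")
        for mid, comp in comp_of.items():
            if mid not in model.metabolites:
                model.metabolites[mid] = _draft_metabolite(bundle, mid, comp)
        model.reactions[rid] = _draft_reaction(rxn, stoich)
    return UniversalModel(
        model=model, bundle=bundle,
        enzyme_index={eid: bundle.enzymes[eid] for eid in sorted(bundle.enzymes)},
        spontaneous_ids={rid for rid, r in bundle.reactions.items() if r.spontaneous},
        transport_ids={rid for rid, r in bundle.reactions.items() if r.transport},
    )


# ---------------------------------------------------------------------------
# De-novo draft reconstruction from homology hits
# ---------------------------------------------------------------------------


def reconstruct_from_database(universal: UniversalModel, hits: list[AlignmentHit],
                              min_bit: float = DEFAULT_MIN_BIT,
                              min_positives: float = DEFAULT_MIN_POSITIVES,
                              model_id: str = "draft_from_db") -> MetabolicModel:
    """Draft model from database enzymes homologous to the query proteome.

    An enzyme is supported iff at least one hit to its sequence (or to any of
    its subunit sequences) has ``bit_score >= min_bit`` **and**
    ``percent_positives >= min_positives`` on the same HSP.  Every reaction a
    supported enzyme catalyzes enters the draft in compartment ``c`` (transport
    substrates in ``e``); the gene rule is an OR over supported enzymes, each
    complex contributing an AND term over the query genes matched to its
    subunits.
    """
    bundle = universal.bundle
    subject_index: dict[str, list[tuple[str, Optional[str]]]] = {}
    for eid, enz in universal.enzyme_index.items():
        if enz.subunits:
            for su in enz.subunits:
                subject_index.setdefault(su, []).append((eid, su))
        else:
            subject_index.setdefault(eid, []).append((eid, None))

    # passing hits per (enzyme, subunit-or-None): query gene -> best bit score
    support: dict[str, dict[Optional[str], dict[str, float]]] = {}
    for h in hits:
        if h.subject_id not in subject_index:
            warnings.warn(f"alignment hit to unknown subject {h.subject_id!r} ignored")
            continue
        if h.bit_score < min_bit or h.percent_positives < min_positives:
            continue
        for eid, su in subject_index[h.subject_id]:
            per_su = support.setdefault(eid, {}).setdefault(su, {})
            per_su[h.query_id] = max(per_su.get(h.query_id, 0.0), h.bit_score)

    draft = MetabolicModel(id=model_id, name="de novo draft",
                           compartments={"c": "cytosol", "e": "extracellular"})
    rxn_terms: dict[str, list[tuple[tuple[str, ...], float]]] = {}
    for eid in sorted(support):
        enz = universal.enzyme_index[eid]
        best_score = 0.0
        if enz.subunits:
            term_genes = []
            for su in enz.subunits:
                matched = support[eid].get(su)
                if not matched:
                    continue  # permissive: AND term over matched subunits only
                gene = min(g for g, s in matched.items() if s == max(matched.values()))
                term_genes.append(gene)
                best_score = max(best_score, max(matched.values()))
            terms = [tuple(sorted(set(term_genes)))] if term_genes else []
        else:
            matched = support[eid].get(None, {})
            terms = [(g,) for g in sorted(matched)]
            best_score = max(matched.values(), default=0.0)
        for rid in enz.reactions:
            bucket = rxn_terms.setdefault(rid, [])
            for t in terms:
                bucket.append((t, best_score))

    for rid in sorted(rxn_terms):
        rxn = bundle.reactions[rid]
        stoich, comp_of = _place_reaction(rxn, "c")
        for mid, comp in comp_of.items():
            if mid not in draft.metabolites:
                draft.metabolites[mid] = _draft_metabolite(bundle, mid, comp)
        new = _draft_reaction(rxn, stoich)
        terms = tuple(sorted({t for t, _ in rxn_terms[rid] if t}))
        if terms:
            new.gene_rule = GeneRule(dnf=terms)
        new.provenance = [Evidence(source="metacyc-db",
                                   genes=sorted({g for t, _ in rxn_terms[rid] for g in t}),
                                   score=max(s for _, s in rxn_terms[rid]))]
        draft.add_reaction(new)
    draft.rebuild_gene_list()
    return draft


def add_spontaneous_reactions(draft: MetabolicModel, universal: UniversalModel) -> MetabolicModel:
    """Retrieve spontaneous reactions whose reactants are already in the draft.

    A spontaneous reaction is added iff all substrates of at least one of its
    directions (both directions tested when reversible) are present in the
    draft's cytosolic metabolite set; missing partners are created.  Added
    reactions carry no gene rule and spontaneous provenance.  Presence is
    judged against the draft as passed in (single pass).
    """
    bundle = universal.bundle
    present = {mid for mid, met in draft.metabolites.items() if met.compartment == "c"}
    out = draft.copy()
    for rid in sorted(universal.spontaneous_ids):
        if rid in out.reactions:
            continue
        rxn = bundle.reactions[rid]
        subs = {m for m, c in rxn.stoichiometry.items() if c < 0}
        prods = {m for m, c in rxn.stoichiometry.items() if c > 0}
        forward_ok = subs and subs <= present
        reverse_ok = rxn.reversible and prods and prods <= present
        if not (forward_ok or reverse_ok):
            continue
        stoich, comp_of = _place_reaction(rxn, "c")
        for mid, comp in comp_of.items():
            if mid not in out.metabolites:
                out.metabolites[mid] = _draft_metabolite(bundle, mid, comp)
        new = _draft_reaction(rxn, stoich)
        new.gene_rule = None
        new.spontaneous = True
        new.provenance = [Evidence(source="spontaneous")]
        out.add_reaction(new)
    return out
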