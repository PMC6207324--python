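"""Model and sequence I/O: SBML L3V1-FBCv2, canonical YAML, flat text, FASTA, alignment tables.

The YAML format is this package's canonical diff-friendly serialization: all
collections are sorted by id and scalar formatting is fixed, so two files are
byte-identical exactly when the models they encode are semantically equal.
SBML goes through libSBML with the FBC v2 package (gene-product associations,
flux bounds as parameters, an active objective, MIRIAM-style annotation URIs
for cross-references).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import libsbml
import yaml
from Bio import SeqIO

from .model_core import (
    DEFAULT_UPPER,
    Evidence,
    GeneRule,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = [
    "AlignmentHit",
    "FormatError",
    "ProteinRecord",
    "format_coefficient",
    "models_semantically_equal",
    "read_alignment_table",
    "read_fasta",
    "read_sbml",
    "read_yaml",
    "write_fasta",
    "write_flat_text",
    "write_sbml",
    "write_yaml",
]


class FormatError(ModelError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# Sequence / alignment records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a BLAST-style tabular alignment result.

    ``bit_score`` and ``percent_positives`` are the two quantities used by the
    homology filters downstream.
    """

    query_id: str
    subject_id: str
    evalue: float
    bit_score: float
    percent_positives: float
    percent_identity: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise FormatError(f"negative bit score for {self.query_id}->{self.subject_id}")
        for pct in (self.percent_positives, self.percent_identity):
            if not 0 <= pct <= 100:
                raise FormatError(f"percentage out of range for {self.query_id}->{self.subject_id}")
        if self.aln_length < 1:
            raise FormatError(f"alignment length < 1 for {self.query_id}->{self.subject_id}")


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a protein FASTA; ids are the header tokens before the first whitespace."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no sequences found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_alignment_table(path: Union[str, Path], dialect: str = "blast6+ppos") -> list[AlignmentHit]:
    """Parse a tabular alignment file.

    Dialect ``blast6+ppos`` is BLAST outfmt-6 reduced to the columns this
    package consumes: qseqid, sseqid, evalue, bitscore, ppos, pident, length.
    """
    if dialect != "blast6+ppos":
        raise FormatError(f"unknown alignment dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 tab-separated columns, got {len(cols)}")
            try:
                hits.append(AlignmentHit(
                    query_id=cols[0], subject_id=cols[1],
                    evalue=float(cols[2]), bit_score=float(cols[3]),
                    percent_positives=float(cols[4]), percent_identity=float(cols[5]),
                    aln_length=int(cols[6]),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Coefficient formatting (exact rationals <-> decimal strings)
# ---------------------------------------------------------------------------


def format_coefficient(coef: Fraction) -> str:
    """Serialize a rational coefficient as a decimal string.

    Finite decimals (denominator 2^a·5^b) are written exactly; other rationals
    are rounded to 12 significant digits.
    """
    den = coef.denominator
    while den % 2 == 0:
        den //= 2
    while den % 5 == 0:
        den //= 5
    if den == 1:
        s = str(Decimal(coef.numerator) / Decimal(coef.denominator))
    else:
        s = format(float(coef), ".12g")
    return s


def parse_coefficient(text: Union[str, int, float]) -> Fraction:
    if isinstance(text, float):
        return Fraction(str(text))
    return Fraction(str(text))


# ---------------------------------------------------------------------------
# YAML (canonical, diff-stable)
# ---------------------------------------------------------------------------


def _rule_to_yaml(rule: Optional[GeneRule]) -> Optional[str]:
    return rule.to_string() if rule is not None else None


def write_yaml(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Write the canonical YAML serialization (sorted, fixed formatting)."""
    doc = {
        "metadata": {
            "id": model.id,
            "name": model.name,
            "objective": (
                {"reaction": model.objective[0], "sense": model.objective[1]}
                if model.objective else None
            ),
        },
        "compartments": {cid: model.compartments[cid] for cid in sorted(model.compartments)},
        "metabolites": [_met_to_dict(model.metabolites[mid]) for mid in sorted(model.metabolites)],
        "reactions": [_rxn_to_dict(model.reactions[rid]) for rid in sorted(model.reactions)],
        "genes": sorted(model.genes),
    }
    text = yaml.safe_dump(doc, default_flow_style=False, sort_keys=False, width=100000)
    Path(path).write_text(text)


def _met_to_dict(met: Metabolite) -> dict:
    d: dict = {"id": met.id, "name": met.name, "compartment": met.compartment}
    if met.formula is not None:
        d["formula"] = met.formula
    if met.charge is not None:
        d["charge"] = met.charge
    if met.xrefs:
        d["xrefs"] = {ns: sorted(ids) for ns, ids in sorted(met.xrefs.items())}
    return d


def _rxn_to_dict(rxn: Reaction) -> dict:
    d: dict = {
        "id": rxn.id,
        "name": rxn.name,
        "stoichiometry": {mid: format_coefficient(c) for mid, c in sorted(rxn.stoichiometry.items())},
        "lower_bound": float(rxn.lower_bound),
        "upper_bound": float(rxn.upper_bound),
    }
    if rxn.gene_rule is not None:
        d["gene_rule"] = rxn.gene_rule.to_string()
    if rxn.subsystem is not None:
        d["subsystem"] = rxn.subsystem
    if rxn.ec_numbers:
        d["ec_numbers"] = sorted(rxn.ec_numbers)
    if rxn.xrefs:
        d["xrefs"] = {ns: sorted(ids) for ns, ids in sorted(rxn.xrefs.items())}
    flags = [f for f in ("spontaneous", "transport", "exchange") if getattr(rxn, f)]
    if flags:
        d["flags"] = flags
    if rxn.provenance:
        d["provenance"] = [
            {"source": ev.source, "genes": list(ev.genes),
             **({"score": float(ev.score)} if ev.score is not None else {})}
            for ev in rxn.provenance
        ]
    return d


def read_yaml(path: Union[str, Path]) -> MetabolicModel:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: not a model document")
    meta = doc.get("metadata", {})
    model = MetabolicModel(id=meta.get("id", "model"), name=meta.get("name", ""))
    model.compartments = dict(doc.get("compartments", {}))
    for md in doc.get("metabolites", []):
        if md["id"] in model.metabolites:
            raise FormatError(f"{path}: duplicate metabolite id {md['id']!r}")
        model.metabolites[md["id"]] = Metabolite(
            id=md["id"], name=md.get("name", ""), compartment=md.get("compartment", "c"),
            formula=md.get("formula"), charge=md.get("charge"),
            xrefs={ns: list(ids) for ns, ids in (md.get("xrefs") or {}).items()},
        )
    for rd in doc.get("reactions", []):
        if rd["id"] in model.reactions:
            raise FormatError(f"{path}: duplicate reaction id {rd['id']!r}")
        flags = set(rd.get("flags", []))
        rxn = Reaction(
            id=rd["id"], name=rd.get("name", ""),
            stoichiometry={m: parse_coefficient(c) for m, c in (rd.get("stoichiometry") or {}).items()},
            lower_bound=float(rd.get("lower_bound", 0.0)),
            upper_bound=float(rd.get("upper_bound", DEFAULT_UPPER)),
            gene_rule=GeneRule.from_string(rd.get("gene_rule", "") or "", context=f"reaction {rd['id']}: "),
            subsystem=rd.get("subsystem"),
            ec_numbers=list(rd.get("ec_numbers", [])),
            xrefs={ns: list(ids) for ns, ids in (rd.get("xrefs") or {}).items()},
            spontaneous="spontaneous" in flags,
            transport="transport" in flags,
            exchange="exchange" in flags,
            provenance=[
                Evidence(source=ed["source"], genes=list(ed.get("genes", [])), score=ed.get("score"))
                for ed in rd.get("provenance", [])
            ],
        )
        model.reactions[rxn.id] = rxn
    model.genes = list(doc.get("genes", []))
    obj = meta.get("objective")
    if obj:
        model.objective = (obj["reaction"], obj["sense"])
    return model


# ---------------------------------------------------------------------------
# Flat text (one tab-separated line per reaction; diff-friendly)
# ---------------------------------------------------------------------------


def _equation_string(model: MetabolicModel, rxn: Reaction) -> str:
    def side(items: dict[str, Fraction]) -> str:
        parts = []
        for mid in sorted(items):
            coef = items[mid]
            comp = model.metabolites[mid].compartment if mid in model.metabolites else "?"
            tok = f"{mid}[{comp}]"
            if coef != 1:
                tok = f"{format_coefficient(coef)} {tok}"
            parts.append(tok)
        return " + ".join(parts)

    arrow = "<=>" if rxn.reversible else "=>"
    return f"{side(rxn.substrates())} {arrow} {side(rxn.products())}".strip()


def write_flat_text(model: MetabolicModel, path: Union[str, Path]) -> None:
    """One line per reaction: id, equation, gene rule, subsystem, lb, ub."""
    with open(path, "w") as fh:
        fh.write("# id\tequation\tgene_rule\tsubsystem\tlb\tub\n")
        for rid in sorted(model.reactions):
            rxn = model.reactions[rid]
            fh.write("\t".join([
                rid,
                _equation_string(model, rxn),
                rxn.gene_rule.to_string() if rxn.gene_rule else "",
                rxn.subsystem or "",
                repr(float(rxn.lower_bound)),
                repr(float(rxn.upper_bound)),
            ]) + "\n")


# ---------------------------------------------------------------------------
# SBML L3V1 + FBC v2
# ---------------------------------------------------------------------------

_FBC_URI = "http://www.sbml.org/sbml/level3/version1/fbc/version2"
_ESCAPE_RE = re.compile(r"__(\d+)__")


def _encode_sid(raw: str) -> str:
    return "".join(c if (c.isalnum() and c.isascii()) or c == "_" else f"__{ord(c)}__" for c in raw)


def _decode_sid(sid: str) -> str:
    return _ESCAPE_RE.sub(lambda m: chr(int(m.group(1))), sid)


def _strip_prefix(sid: str, prefix: str) -> str:
    return _decode_sid(sid[len(prefix):] if sid.startswith(prefix) else sid)


def _check(value, what: str):
    if value is None or (isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS):
        raise FormatError(f"libSBML failure while writing {what}")
    return value


def write_sbml(model: MetabolicModel, path: Union[str, Path]) -> None:
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_encode_sid(model.id))
    if model.name:
        sb.setName(model.name)
    mplug = sb.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in sorted(model.compartments):
        comp = sb.createCompartment()
        comp.setId("C_" + _encode_sid(cid))
        comp.setName(model.compartments[cid])
        comp.setConstant(True)

    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        sp = sb.createSpecies()
        sp.setId("M_" + _encode_sid(mid))
        sp.setName(met.name)
        sp.setCompartment("C_" + _encode_sid(met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        _write_cvterms(sp, met.xrefs)

    gene_ids = sorted({g for rxn in model.reactions.values()
                       if rxn.gene_rule for g in rxn.gene_rule.genes()} | set(model.genes))
    for gid in gene_ids:
        gp = mplug.createGeneProduct()
        gp.setId("G_" + _encode_sid(gid))
        gp.setLabel(gid)

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        for suffix, value in (("_lb", rxn.lower_bound), ("_ub", rxn.upper_bound)):
            par = sb.createParameter()
            par.setId("R_" + _encode_sid(rid) + suffix)
            par.setValue(float(value))
            par.setConstant(True)

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        sr = sb.createReaction()
        sr.setId("R_" + _encode_sid(rid))
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound("R_" + _encode_sid(rid) + "_lb")
        rplug.setUpperFluxBound("R_" + _encode_sid(rid) + "_ub")
        for mid, coef in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coef < 0 else sr.createProduct()
            ref.setSpecies("M_" + _encode_sid(mid))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        if rxn.gene_rule is not None and rxn.gene_rule.dnf:
            gpa = rplug.createGeneProductAssociation()
            _write_association(gpa, rxn.gene_rule)
        _write_cvterms(sr, rxn.xrefs)
        notes = []
        if rxn.subsystem:
            notes.append(("SUBSYSTEM", rxn.subsystem))
        if rxn.ec_numbers:
            notes.append(("EC", ";".join(sorted(rxn.ec_numbers))))
        flags = [f for f in ("spontaneous", "transport", "exchange") if getattr(rxn, f)]
        if flags:
            notes.append(("FLAGS", ";".join(flags)))
        if notes:
            body = "".join(f"<p>{k}: {v}</p>" for k, v in notes)
            sr.setNotes(f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>')

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType(model.objective[1])
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _encode_sid(model.objective[0]))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise FormatError(f"could not write SBML to {path}")


def _write_association(parent, rule: GeneRule) -> None:
    def make_term(container, term: tuple[str, ...]):
        if len(term) == 1:
            ref = container.createGeneProductRef()
            ref.setGeneProduct("G_" + _encode_sid(term[0]))
        else:
            and_ = container.createAnd()
            for g in term:
                ref = and_.createGeneProductRef()
                ref.setGeneProduct("G_" + _encode_sid(g))

    if len(rule.dnf) == 1:
        make_term(parent, rule.dnf[0])
    else:
        or_ = parent.createOr()
        for term in rule.dnf:
            make_term(or_, term)


def _write_cvterms(element, xrefs: dict[str, list[str]]) -> None:
    if not xrefs:
        return
    element.setMetaId("meta_" + element.getId())
    cv = libsbml.CVTerm()
    cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
    cv.setBiologicalQualifierType(libsbml.BQB_IS)
    for ns_name in sorted(xrefs):
        for fid in sorted(xrefs[ns_name]):
            cv.addResource(f"http://identifiers.org/{ns_name}/{fid}")
    element.addCVTerm(cv)


_IDENTIFIERS_RE = re.compile(r"identifiers\.org/([^/]+)/(.+)$")


def _read_cvterms(element) -> dict[str, list[str]]:
    xrefs: dict[str, list[str]] = {}
    for i in range(element.getNumCVTerms()):
        cv = element.getCVTerm(i)
        for j in range(cv.getNumResources()):
            m = _IDENTIFIERS_RE.search(cv.getResourceURI(j))
            if m:
                xrefs.setdefault(m.group(1), []).append(m.group(2))
    return {ns: sorted(set(ids)) for ns, ids in xrefs.items()}


_NOTE_RE = re.compile(r"<p>\s*([A-Z]+):\s*(.*?)\s*</p>", re.S)


def read_sbml(path: Union[str, Path]) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path}: malformed SBML: {err.getMessage().strip()}")
    sb = doc.getModel()
    if sb is None:
        raise FormatError(f"{path}: no model element")
    mplug = sb.getPlugin("fbc")
    if mplug is None:
        raise FormatError(f"{path}: FBC v2 required (fbc package missing on element 'model')")

    model = MetabolicModel(id=_decode_sid(sb.getId() or "model"), name=sb.getName() or "")
    for i in range(sb.getNumCompartments()):
        comp = sb.getCompartment(i)
        model.compartments[_strip_prefix(comp.getId(), "C_")] = comp.getName() or _strip_prefix(comp.getId(), "C_")

    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        splug = sp.getPlugin("fbc")
        met = Metabolite(
            id=_strip_prefix(sp.getId(), "M_"),
            name=sp.getName() or "",
            compartment=_strip_prefix(sp.getCompartment(), "C_"),
            formula=(splug.getChemicalFormula() or None) if splug and splug.isSetChemicalFormula() else None,
            charge=splug.getCharge() if splug and splug.isSetCharge() else None,
            xrefs=_read_cvterms(sp),
        )
        model.metabolites[met.id] = met

    gene_labels: dict[str, str] = {}
    for i in range(mplug.getNumGeneProducts()):
        gp = mplug.getGeneProduct(i)
        gene_labels[gp.getId()] = gp.getLabel() or _strip_prefix(gp.getId(), "G_")

    params = {sb.getParameter(i).getId(): sb.getParameter(i).getValue()
              for i in range(sb.getNumParameters())}

    for i in range(sb.getNumReactions()):
        sr = sb.getReaction(i)
        rplug = sr.getPlugin("fbc")
        if rplug is None:
            raise FormatError(f"{path}: FBC v2 required (reaction {sr.getId()!r} lacks fbc bounds)")
        rid = _strip_prefix(sr.getId(), "R_")
        stoich: dict[str, Fraction] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, Fraction(0)) - Fraction(str(ref.getStoichiometry()))
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, Fraction(0)) + Fraction(str(ref.getStoichiometry()))
        lb = params.get(rplug.getLowerFluxBound(), -DEFAULT_UPPER if sr.getReversible() else 0.0)
        ub = params.get(rplug.getUpperFluxBound(), DEFAULT_UPPER)
        rule = None
        gpa = rplug.getGeneProductAssociation()
        if gpa is not None:
            dnf = _association_to_dnf(gpa.getAssociation(), gene_labels)
            if dnf:
                rule = GeneRule(dnf=dnf)
        subsystem = None
        ec: list[str] = []
        flags: set[str] = set()
        if sr.isSetNotes():
            for key, value in _NOTE_RE.findall(sr.getNotesString()):
                if key == "SUBSYSTEM":
                    subsystem = value
                elif key == "EC":
                    ec = value.split(";")
                elif key == "FLAGS":
                    flags = set(value.split(";"))
        rxn = Reaction(
            id=rid, name=sr.getName() or "", stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gene_rule=rule,
            subsystem=subsystem, ec_numbers=ec, xrefs=_read_cvterms(sr),
            spontaneous="spontaneous" in flags, transport="transport" in flags,
            exchange="exchange" in flags,
        )
        model.reactions[rid] = rxn
    model.rebuild_gene_list()

    obj = mplug.getActiveObjective()
    if obj is not None and obj.getNumFluxObjectives() > 0:
        fo = obj.getFluxObjective(0)
        model.objective = (_strip_prefix(fo.getReaction(), "R_"), obj.getType())
    return model


def _association_to_dnf(assoc, gene_labels: dict[str, str]) -> tuple[tuple[str, ...], ...]:
    if assoc is None:
        return ()
    if isinstance(assoc, libsbml.GeneProductRef):
        return ((gene_labels.get(assoc.getGeneProduct(), _strip_prefix(assoc.getGeneProduct(), "G_")),),)
    children = [_association_to_dnf(assoc.getAssociation(i), gene_labels)
                for i in range(assoc.getNumAssociations())]
    if isinstance(assoc, libsbml.FbcOr):
        return tuple(term for child in children for term in child)
    if isinstance(assoc, libsbml.FbcAnd):
        result: tuple[tuple[str, ...], ...] = ((),)
        for child in children:
            result = tuple(tuple(sorted(set(a) | set(b))) for a in result for b in child)
        return result
    raise FormatError(f"unsupported FBC association element {type(assoc).__name__}")


# ---------------------------------------------------------------------------
# Semantic model equality (the round-trip contract)
# ---------------------------------------------------------------------------


def models_semantically_equal(a: MetabolicModel, b: MetabolicModel,
                              include_provenance: bool = False,
                              tol: float = 0.0) -> bool:
    """Compare two models on ids, names, compartments, stoichiometry, bounds,
    gene rules, objective, xrefs, formulas/charges, subsystems, EC numbers and
    flags.  Provenance comparison is optional (SBML does not carry it)."""
    if (a.id, a.name) != (b.id, b.name):
        return False
    if dict(a.compartments) != dict(b.compartments):
        return False
    if set(a.metabolites) != set(b.metabolites) or set(a.reactions) != set(b.reactions):
        return False
    for mid, am in a.metabolites.items():
        bm = b.metabolites[mid]
        if (am.name, am.compartment, am.formula, am.charge) != (bm.name, bm.compartment, bm.formula, bm.charge):
            return False
        if {ns: sorted(v) for ns, v in am.xrefs.items() if v} != {ns: sorted(v) for ns, v in bm.xrefs.items() if v}:
            return False
    for rid, ar in a.reactions.items():
        br = b.reactions[rid]
        if set(ar.stoichiometry) != set(br.stoichiometry):
            return False
        for mid in ar.stoichiometry:
            if abs(float(ar.stoichiometry[mid] - br.stoichiometry[mid])) > tol:
                return False
        if abs(ar.lower_bound - br.lower_bound) > tol or abs(ar.upper_bound - br.upper_bound) > tol:
            return False
        a_dnf = ar.gene_rule.dnf if ar.gene_rule else ()
        b_dnf = br.gene_rule.dnf if br.gene_rule else ()
        if a_dnf != b_dnf:
            return False
        if (ar.name, ar.subsystem or None, sorted(ar.ec_numbers)) != (br.name, br.subsystem or None, sorted(br.ec_numbers)):
            return False
        if (ar.spontaneous, ar.transport, ar.exchange) != (br.spontaneous, br.transport, br.exchange):
            return False
        if {ns: sorted(v) for ns, v in ar.xrefs.items() if v} != {ns: sorted(v) for ns, v in br.xrefs.items() if v}:
            return False
        if include_provenance:
            key = lambda evs: sorted((e.source, tuple(e.genes), e.score) for e in evs)
            if key(ar.provenance) != key(br.provenance):
                return False
    if a.objective != b.objective:
        return False
    return True
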