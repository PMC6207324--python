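"""Constraint-based metabolic model data structures and curation operations.

A :class:`MetabolicModel` holds compartments, metabolites, reactions (with
signed rational stoichiometry, flux bounds in mmol·gDW⁻¹·h⁻¹ and boolean
gene–protein–reaction rules) and an optional linear objective.  All other
modules of the package produce or consume this structure.

Gene rules are stored canonically in disjunctive normal form (DNF): an OR of
AND terms, where OR terms represent isozymes and AND terms enzyme-complex
subunits.  Reversibility is derived from the bounds (lb < 0 < ub), never
stored separately.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "DEFAULT_UPPER",
    "EVIDENCE_SOURCES",
    "Evidence",
    "GeneRule",
    "GeneRuleParseError",
    "Metabolite",
    "MetabolicModel",
    "ModelError",
    "Reaction",
    "ValidationReport",
    "Violation",
    "add_reactions",
    "change_gene_association",
    "merge_models",
    "remove_reactions",
    "standardize_gene_rules",
    "validate_model",
]

#: Conventional big-M flux cap used for database reactions without measured bounds.
DEFAULT_UPPER = 1000.0

EVIDENCE_SOURCES = frozenset(
    {"template-homology", "metacyc-db", "kegg-annotation", "kegg-hmm", "spontaneous", "manual"}
)

Number = Union[int, float, Fraction, str]


class ModelError(ValueError):
    """Raised for contract violations in model-manipulating operations."""


class GeneRuleParseError(ModelError):
    """Raised when a gene-rule string does not parse."""


def _coef(value: Number) -> Fraction:
    """Coerce a stoichiometric coefficient to an exact rational."""
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


# ---------------------------------------------------------------------------
# Gene rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


@dataclass(frozen=True)
class GeneRule:
    """Boolean gene association in canonical DNF.

    ``dnf`` is a sorted tuple of sorted gene-id tuples; each inner tuple is a
    conjunction (complex), the outer level a disjunction (isozymes).  ``raw``
    optionally keeps the original string for provenance.
    """

    dnf: tuple[tuple[str, ...], ...]
    raw: Optional[str] = None

    def __post_init__(self) -> None:
        canon = tuple(sorted({tuple(sorted(set(term))) for term in self.dnf}))
        for term in canon:
            if not term:
                raise ModelError("gene rule contains an empty conjunction")
        object.__setattr__(self, "dnf", canon)

    @classmethod
    def from_string(cls, text: str, context: str = "") -> Optional["GeneRule"]:
        """Parse ``text`` ("g1 and (g2 or g3)") into canonical DNF.

        Keywords ``and``/``or`` are case-insensitive; identifiers are any
        non-keyword, non-parenthesis tokens.  Returns None for blank input.
        """
        if text is None or not text.strip():
            return None
        tokens = _tokenize(text, context)
        dnf, pos = _parse_or(tokens, 0, context)
        if pos != len(tokens):
            raise GeneRuleParseError(
                f"{context}unexpected token {tokens[pos][0]!r} at position {tokens[pos][1]}"
            )
        return cls(dnf=dnf, raw=text)

    def to_string(self) -> str:
        parts = []
        for term in self.dnf:
            inner = " and ".join(term)
            parts.append(f"({inner})" if len(term) > 1 and len(self.dnf) > 1 else inner)
        return " or ".join(parts)

    def genes(self) -> frozenset[str]:
        return frozenset(g for term in self.dnf for g in term)

    def evaluate(self, active: Iterable[str]) -> bool:
        """True iff at least one AND term has all its genes in ``active``."""
        present = set(active)
        return any(all(g in present for g in term) for term in self.dnf)

    def or_with(self, other: Optional["GeneRule"]) -> "GeneRule":
        if other is None:
            return self
        return GeneRule(dnf=self.dnf + other.dnf)


def _tokenize(text: str, context: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    if not tokens:
        raise GeneRuleParseError(f"{context}empty rule")
    return tokens


def _parse_or(tokens, pos, ctx) -> tuple[tuple[tuple[str, ...], ...], int]:
    terms, pos = _parse_and(tokens, pos, ctx)
    result = list(terms)
    while pos < len(tokens) and tokens[pos][0].lower() == "or":
        terms, pos = _parse_and(tokens, pos + 1, ctx)
        result.extend(terms)
    return tuple(result), pos


def _parse_and(tokens, pos, ctx) -> tuple[tuple[tuple[str, ...], ...], int]:
    dnf, pos = _parse_atom(tokens, pos, ctx)
    while pos < len(tokens) and tokens[pos][0].lower() == "and":
        rhs, pos = _parse_atom(tokens, pos + 1, ctx)
        # distribute: (A or B) and (C or D) -> AC or AD or BC or BD
        dnf = tuple(tuple(sorted(set(a) | set(b))) for a in dnf for b in rhs)
    return dnf, pos


def _parse_atom(tokens, pos, ctx) -> tuple[tuple[tuple[str, ...], ...], int]:
    if pos >= len(tokens):
        raise GeneRuleParseError(f"{ctx}unexpected end of rule")
    tok, at = tokens[pos]
    if tok == "(":
        dnf, pos = _parse_or(tokens, pos + 1, ctx)
        if pos >= len(tokens) or tokens[pos][0] != ")":
            raise GeneRuleParseError(f"{ctx}unbalanced parenthesis opened at position {at}")
        return dnf, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GeneRuleParseError(f"{ctx}unexpected token {tok!r} at position {at}")
    return ((tok,),), pos + 1


# ---------------------------------------------------------------------------
# Model element types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None
    xrefs: dict[str, list[str]] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def copy(self) -> "Metabolite":
        return _copy.deepcopy(self)


@dataclass
class Evidence:
    """Provenance record attached to a reaction."""

    source: str
    genes: list[str] = field(default_factory=list)
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in EVIDENCE_SOURCES:
            raise ModelError(f"unknown evidence source {self.source!r}")


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER
    gene_rule: Optional[GeneRule] = None
    subsystem: Optional[str] = None
    ec_numbers: list[str] = field(default_factory=list)
    xrefs: dict[str, list[str]] = field(default_factory=dict)
    spontaneous: bool = False
    transport: bool = False
    exchange: bool = False
    provenance: list[Evidence] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stoichiometry = {
            m: _coef(c) for m, c in self.stoichiometry.items() if _coef(c) != 0
        }

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def copy(self) -> "Reaction":
        return _copy.deepcopy(self)


@dataclass
class MetabolicModel:
    id: str = "model"
    name: str = ""
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    objective: Optional[tuple[str, str]] = None  # (reaction id, "maximize"|"minimize")
    extras: dict = field(default_factory=dict)

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- element management --------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        if rxn.gene_rule is not None:
            self._register_genes(rxn.gene_rule.genes())

    def _register_genes(self, gene_ids: Iterable[str]) -> None:
        known = set(self.genes)
        for g in sorted(set(gene_ids) - known):
            self.genes.append(g)

    def rebuild_gene_list(self) -> None:
        """Reset the gene list to the union of genes in all rules (sorted)."""
        used: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gene_rule is not None:
                used |= rxn.gene_rule.genes()
        self.genes = sorted(used)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class Violation:
    severity: str  # "error" | "warning"
    code: str
    element: str
    message: str


ValidationReport = list


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check every structural invariant; never raises.

    An empty report means the model is well formed.  Each entry names the
    offending element so reports can drive curation.
    """
    report: list[Violation] = []
    seen_mets: set[str] = set()
    for mid, met in model.metabolites.items():
        if mid != met.id:
            report.append(Violation("error", "id-mismatch", mid, f"metabolite keyed {mid!r} has id {met.id!r}"))
        if mid in seen_mets:
            report.append(Violation("error", "duplicate-id", mid, f"duplicate metabolite id {mid!r}"))
        seen_mets.add(mid)
        if met.compartment not in model.compartments:
            report.append(
                Violation("error", "unknown-compartment", mid,
                          f"metabolite {mid!r} references unknown compartment {met.compartment!r}")
            )
        for ns, ids in met.xrefs.items():
            if len(ids) != len(set(ids)):
                report.append(Violation("warning", "duplicate-xref", mid, f"duplicate {ns} xrefs on {mid!r}"))

    gene_set = set(model.genes)
    if len(model.genes) != len(gene_set):
        report.append(Violation("error", "duplicate-id", "genes", "duplicate gene ids in gene list"))

    used_genes: set[str] = set()
    for rid, rxn in model.reactions.items():
        if rid != rxn.id:
            report.append(Violation("error", "id-mismatch", rid, f"reaction keyed {rid!r} has id {rxn.id!r}"))
        if rxn.lower_bound > rxn.upper_bound:
            report.append(Violation("error", "bounds", rid,
                                    f"reaction {rid!r} has lower bound {rxn.lower_bound} > upper bound {rxn.upper_bound}"))
        for mid, coef in rxn.stoichiometry.items():
            if mid not in model.metabolites:
                report.append(Violation("error", "unknown-metabolite", rid,
                                        f"reaction {rid!r} references unknown metabolite {mid!r}"))
            if coef == 0:
                report.append(Violation("error", "zero-coefficient", rid,
                                        f"reaction {rid!r} stores a zero coefficient for {mid!r}"))
        if rxn.gene_rule is not None:
            rule_genes = rxn.gene_rule.genes()
            used_genes |= rule_genes
            for g in sorted(rule_genes - gene_set):
                report.append(Violation("error", "unknown-gene", rid,
                                        f"reaction {rid!r} gene rule references unknown gene {g}"))
        for ev in rxn.provenance:
            if ev.source not in EVIDENCE_SOURCES:
                report.append(Violation("error", "bad-evidence", rid,
                                        f"reaction {rid!r} has evidence with unknown source {ev.source!r}"))

    for g in sorted(gene_set - used_genes):
        report.append(Violation("warning", "orphan-gene", g, f"gene {g} appears in no gene rule"))

    if model.objective is not None:
        obj_rxn, sense = model.objective
        if obj_rxn not in model.reactions:
            report.append(Violation("error", "missing-objective", obj_rxn,
                                    f"objective reaction {obj_rxn!r} not in model"))
        if sense not in ("maximize", "minimize"):
            report.append(Violation("error", "bad-objective-sense", str(sense),
                                    f"objective sense {sense!r} invalid"))
    return report


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------


def add_reactions(model: MetabolicModel, donor: MetabolicModel,
                  rxn_ids: Sequence[str]) -> MetabolicModel:
    """Move reactions (plus required metabolites/genes) from ``donor`` into a copy of ``model``.

    Pre-existing ids are never duplicated; an id collision with differing
    stoichiometry is an error rather than a silent overwrite.  Added reactions
    get manual provenance.
    """
    out = model.copy()
    for rid in rxn_ids:
        if rid not in donor.reactions:
            raise ModelError(f"unknown reaction id {rid!r} in donor model")
        src = donor.reactions[rid]
        if rid in out.reactions:
            if out.reactions[rid].stoichiometry != src.stoichiometry:
                raise ModelError(f"reaction id {rid!r} already present with different stoichiometry")
            continue
        rxn = src.copy()
        rxn.provenance = list(rxn.provenance) + [
            Evidence(source="manual", genes=sorted(rxn.gene_rule.genes()) if rxn.gene_rule else [])
        ]
        for mid in rxn.stoichiometry:
            if mid not in out.metabolites:
                met = donor.metabolites[mid].copy()
                if met.compartment not in out.compartments:
                    out.compartments[met.compartment] = donor.compartments.get(
                        met.compartment, met.compartment)
                out.metabolites[mid] = met
        out.add_reaction(rxn)
    return out


def remove_reactions(model: MetabolicModel, rxn_ids: Sequence[str],
                     prune_orphans: bool = False) -> MetabolicModel:
    """Remove reactions; optionally prune metabolites/genes left unreferenced."""
    out = model.copy()
    for rid in rxn_ids:
        if rid not in out.reactions:
            raise ModelError(f"unknown reaction id {rid!r}")
        del out.reactions[rid]
    if prune_orphans:
        used_mets = {m for rxn in out.reactions.values() for m in rxn.stoichiometry}
        out.metabolites = {m: met for m, met in out.metabolites.items() if m in used_mets}
        used_genes: set[str] = set()
        for rxn in out.reactions.values():
            if rxn.gene_rule is not None:
                used_genes |= rxn.gene_rule.genes()
        out.genes = [g for g in out.genes if g in used_genes]
    return out


def standardize_gene_rules(model: MetabolicModel) -> MetabolicModel:
    """Re-canonicalize every gene rule and rebuild the gene list.

    Raw rule strings (if present) are re-parsed under the grammar
    ``identifiers, 'and', 'or', parentheses``; the model gene list becomes
    exactly the union of genes appearing in rules.  Idempotent.
    """
    out = model.copy()
    for rid, rxn in out.reactions.items():
        if rxn.gene_rule is None:
            continue
        if rxn.gene_rule.raw is not None:
            try:
                rxn.gene_rule = GeneRule.from_string(rxn.gene_rule.raw, context=f"reaction {rid}: ")
            except GeneRuleParseError:
                raise
        else:
            rxn.gene_rule = GeneRule(dnf=rxn.gene_rule.dnf)
    out.rebuild_gene_list()
    return out


def change_gene_association(model: MetabolicModel, rxn_id: str,
                            rule_string: str) -> MetabolicModel:
    """Replace one reaction's gene rule with a parsed, canonicalized rule.

    An empty string clears the association.  New genes are appended to the
    model gene list.
    """
    if rxn_id not in model.reactions:
        raise ModelError(f"unknown reaction id {rxn_id!r}")
    out = model.copy()
    rule = GeneRule.from_string(rule_string, context=f"reaction {rxn_id}: ")
    out.reactions[rxn_id].gene_rule = rule
    if rule is not None:
        out._register_genes(rule.genes())
    return out


def merge_models(a: MetabolicModel, b: MetabolicModel) -> MetabolicModel:
    """Union of two models sharing an identifier namespace.

    Reactions present in both with identical stoichiometry have their gene
    rules OR-combined, provenance concatenated and bounds widened to the
    containing interval.  Identical ids with different stoichiometry are a
    hard error (listed all at once).
    """
    conflicts = [
        rid for rid in a.reactions
        if rid in b.reactions and a.reactions[rid].stoichiometry != b.reactions[rid].stoichiometry
    ]
    if conflicts:
        raise ModelError("same reaction id with different stoichiometry: " + ", ".join(sorted(conflicts)))

    out = a.copy()
    out.id = a.id
    out.name = a.name or b.name
    for cid, cname in b.compartments.items():
        out.compartments.setdefault(cid, cname)
    for mid, met in b.metabolites.items():
        if mid not in out.metabolites:
            out.metabolites[mid] = met.copy()
        else:
            tgt = out.metabolites[mid]
            for ns, ids in met.xrefs.items():
                merged = list(dict.fromkeys(tgt.xrefs.get(ns, []) + ids))
                tgt.xrefs[ns] = merged
    for rid, rxn in b.reactions.items():
        if rid not in out.reactions:
            out.add_reaction(rxn.copy())
            continue
        tgt = out.reactions[rid]
        tgt.lower_bound = min(tgt.lower_bound, rxn.lower_bound)
        tgt.upper_bound = max(tgt.upper_bound, rxn.upper_bound)
        if rxn.gene_rule is not None:
            tgt.gene_rule = rxn.gene_rule.or_with(tgt.gene_rule)
            out._register_genes(tgt.gene_rule.genes())
        existing = [(e.source, tuple(e.genes), e.score) for e in tgt.provenance]
        for ev in rxn.provenance:
            if (ev.source, tuple(ev.genes), ev.score) not in existing:
                tgt.provenance.append(_copy.deepcopy(ev))
        tgt.spontaneous = tgt.spontaneous or rxn.spontaneous
        tgt.transport = tgt.transport or rxn.transport
        tgt.exchange = tgt.exchange or rxn.exchange
    out._register_genes(b.genes)
    if out.objective is None:
        out.objective = b.objective
    return out
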