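"""Cross-database reaction linking and model combination.

Drafts reconstructed from two databases (an A/MetaCyc-style namespace and a
B/KEGG-style namespace) describe overlapping chemistry under different
identifiers.  Linking proceeds in two stages: explicit cross-reference pairs
first, then reactant matching — a B reaction whose metabolites all translate
uniquely into the A namespace and whose substrate/product multisets (with
coefficients, protons ignored) equal those of exactly one unmapped A reaction
is linked with origin ``reactant-match``; ambiguous candidates are reported,
never auto-assigned.  Combination keeps all of A, discards mapped B copies
while OR-merging their gene rules into the A counterparts, and rewrites
unmapped B reactions into the A namespace wherever a translation exists.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .model_core import MetabolicModel, ModelError, Reaction

__all__ = ["ReactionMapping", "combine_models", "link_cross_db_reactions"]


@dataclass
class ReactionMapping:
    """Outcome of cross-database reaction linking.

    ``pairs`` holds (A id, B id, origin); ``met_map`` translates B-namespace
    metabolite ids to A-namespace ids; ``ambiguous`` records B reactions with
    two or more stage-2 candidates (reported for curation, never assigned).
    """

    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    met_map: dict[str, str] = field(default_factory=dict)
    proton_ids: set[str] = field(default_factory=set)
    ambiguous: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        b_side = [b for _, b, _ in self.pairs]
        if len(b_side) != len(set(b_side)):
            raise ModelError("a B reaction maps to more than one A reaction")
        for _, _, origin in self.pairs:
            if origin not in ("xref", "reactant-match"):
                raise ModelError(f"unknown mapping origin {origin!r}")

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b, _ in self.pairs}


def _strip_compartment(mid: str) -> str:
    return mid[:-2] if mid.endswith("_e") else mid


def _signature(rxn: Reaction, translate: Optional[dict[str, str]],
               protons: set[str]) -> Optional[frozenset[tuple[str, Fraction]]]:
    """Direction-agnostic, compartment-aware reactant signature, proton-blind.

    Metabolite ids are translated on their base id (the ``_e`` extracellular
    suffix is preserved, so transporters keep a nonempty signature).  Returns
    None when any metabolite lacks a unique translation.  The signature of a
    reaction and of its mirror image compare equal through the canonical
    orientation below.
    """
    items: dict[str, Fraction] = {}
    for mid, coef in rxn.stoichiometry.items():
        ext = mid.endswith("_e")
        base = _strip_compartment(mid)
        if translate is not None:
            if base not in translate:
                return None
            base = translate[base]
        if base in protons:
            continue
        key = base + "_e" if ext else base
        items[key] = items.get(key, Fraction(0)) + coef
    fwd = frozenset((m, c) for m, c in items.items() if c != 0)
    rev = frozenset((m, -c) for m, c in items.items() if c != 0)
    # canonical orientation: the lexicographically smaller of the two
    return min(fwd, rev, key=lambda s: sorted(s))


def link_cross_db_reactions(model_a: MetabolicModel, model_b: MetabolicModel,
                            rxn_xref: list[tuple[str, str]],
                            met_xref: list[tuple[str, str, bool]]) -> ReactionMapping:
    """Map B reactions onto A reactions via explicit xrefs, then reactant matching.

    ``rxn_xref``/``met_xref`` rows are (A id, B id[, proton flag]) pairs.
    Stage 2 requires every B metabolite to translate uniquely and the
    translated substrate/product multisets (coefficients included, protons
    excluded) to equal those of exactly one still-unmapped A reaction, in
    either direction.  Ambiguity (two or more candidates) is reported and
    skipped.
    """
    protons_a: set[str] = set()
    translate: dict[str, str] = {}
    seen_b: dict[str, set[str]] = {}
    for a_id, b_id, is_proton in met_xref:
        seen_b.setdefault(b_id, set()).add(a_id)
        if is_proton:
            protons_a.add(a_id)
    for b_id, a_ids in seen_b.items():
        if len(a_ids) == 1:
            translate[b_id] = next(iter(a_ids))
    # A-namespace metabolites translate to themselves
    identity = {_strip_compartment(m): _strip_compartment(m) for m in model_a.metabolites}

    pairs: list[tuple[str, str, str]] = []
    mapped_b: set[str] = set()
    mapped_a: set[str] = set()
    for a_id, b_id in rxn_xref:
        if a_id in model_a.reactions and b_id in model_b.reactions \
                and b_id not in mapped_b and a_id not in mapped_a:
            pairs.append((a_id, b_id, "xref"))
            mapped_b.add(b_id)
            mapped_a.add(a_id)

    signatures_a: dict[str, list[str]] = {}
    for rid in sorted(model_a.reactions):
        if rid in mapped_a:
            continue
        sig = _signature(model_a.reactions[rid], identity, protons_a)
        if sig is not None and sig:
            signatures_a.setdefault(sig, []).append(rid)  # type: ignore[arg-type]

    ambiguous: dict[str, list[str]] = {}
    for b_id in sorted(model_b.reactions):
        if b_id in mapped_b:
            continue
        sig = _signature(model_b.reactions[b_id], translate, protons_a)
        if sig is None or not sig:
            continue
        candidates = [a for a in signatures_a.get(sig, []) if a not in mapped_a]  # type: ignore[call-overload]
        if len(candidates) == 1:
            pairs.append((candidates[0], b_id, "reactant-match"))
            mapped_a.add(candidates[0])
            mapped_b.add(b_id)
        elif len(candidates) >= 2:
            ambiguous[b_id] = sorted(candidates)

    return ReactionMapping(pairs=pairs, met_map=dict(translate),
                           proton_ids=protons_a, ambiguous=ambiguous)


def combine_models(model_a: MetabolicModel, model_b: MetabolicModel,
                   mapping: ReactionMapping,
                   model_id: str = "combined") -> MetabolicModel:
    """Combine two drafts, preferring the A namespace throughout.

    All of A is kept.  Mapped B reactions are discarded with their gene rules
    OR-merged into the A counterparts (provenance concatenated).  Unmapped B
    reactions are retained with every translatable metabolite rewritten to the
    A namespace; untranslatable metabolites keep their B ids and are flagged
    foreign.  B reactions that become stoichiometric duplicates of an A
    reaction after translation are coalesced the same way as mapped pairs.
    """
    b_to_a = mapping.b_to_a()
    for a_id, b_id, _ in mapping.pairs:
        if a_id not in model_a.reactions:
            raise ModelError(f"mapping cites absent A reaction {a_id!r}")
        if b_id not in model_b.reactions:
            raise ModelError(f"mapping cites absent B reaction {b_id!r}")

    out = model_a.copy()
    out.id = model_id
    out.name = f"combined({model_a.id}, {model_b.id})"

    def absorb(a_rxn: Reaction, b_rxn: Reaction) -> None:
        if b_rxn.gene_rule is not None:
            a_rxn.gene_rule = b_rxn.gene_rule.or_with(a_rxn.gene_rule)
            out._register_genes(a_rxn.gene_rule.genes())
        a_rxn.provenance = a_rxn.provenance + _copy.deepcopy(b_rxn.provenance)
        for ns, ids in b_rxn.xrefs.items():
            a_rxn.xrefs[ns] = list(dict.fromkeys(a_rxn.xrefs.get(ns, []) + ids))
        a_rxn.xrefs.setdefault("combined_from", []).append(b_rxn.id)

    for a_id, b_id, _ in mapping.pairs:
        absorb(out.reactions[a_id], model_b.reactions[b_id])

    def translate_mid(mid: str) -> tuple[str, bool]:
        """B metabolite id -> A namespace id (compartment-suffix aware)."""
        ext = mid.endswith("_e")
        base = _strip_compartment(mid)
        if base in mapping.met_map:
            new = mapping.met_map[base]
            return (new + "_e" if ext else new), False
        return mid, True

    # signatures of A reactions for post-translation duplicate detection
    sig_index: dict = {}
    for rid, rxn in out.reactions.items():
        sig = _signature(rxn, None, mapping.proton_ids)
        if sig:
            sig_index.setdefault(sig, rid)

    duplicates = 0
    for b_id in sorted(model_b.reactions):
        if b_id in b_to_a:
            continue
        src = model_b.reactions[b_id]
        new = src.copy()
        stoich: dict[str, Fraction] = {}
        foreign_mets: list[str] = []
        for mid, coef in src.stoichiometry.items():
            new_mid, foreign = translate_mid(mid)
            stoich[new_mid] = stoich.get(new_mid, Fraction(0)) + coef
            if foreign:
                foreign_mets.append(new_mid)
            if new_mid not in out.metabolites:
                met = model_b.metabolites[mid].copy()
                met.id = new_mid
                if foreign:
                    met.extras["foreign"] = True
                out.metabolites[new_mid] = met
                out.compartments.setdefault(met.compartment,
                                            model_b.compartments.get(met.compartment, met.compartment))
        new.stoichiometry = {m: c for m, c in stoich.items() if c != 0}
        sig = _signature(new, None, mapping.proton_ids)
        dup_of = sig_index.get(sig) if sig else None
        if dup_of is not None:
            absorb(out.reactions[dup_of], new)
            duplicates += 1
            continue
        if new.id in out.reactions:
            raise ModelError(f"unmapped B reaction id {new.id!r} collides with an A reaction id")
        out.add_reaction(new)
        if sig:
            sig_index.setdefault(sig, new.id)

    out.extras["combine_stats"] = {
        "n_a": len(model_a.reactions),
        "n_b": len(model_b.reactions),
        "n_mapped": len(mapping.pairs),
        "n_duplicates": duplicates,
        "n_ambiguous": len(mapping.ambiguous),
    }
    out.rebuild_gene_list()
    return out
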