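"""Bidirectional-best-hit orthology and template-model draft reconstruction.

Orthology between a query proteome and a template proteome is approximated by
reciprocal best alignment hits (BBH): gene q pairs with template gene t iff t
is q's best forward hit and q is t's best reverse hit, with both hits passing
bit-score and e-value thresholds.  A draft model for the query organism is
then obtained by rewriting the template's gene rules through the ortholog
mapping and keeping the reactions whose rewritten rules are non-empty.

Also hosts the package's internal global (Needleman–Wunsch) aligner, used by
the sequence-clustering step and by the synthetic-data generator.  Scoring is
match=1, mismatch=0, linear gap −1; identity = matches / alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AlignmentHit
from .model_core import Evidence, GeneRule, MetabolicModel

__all__ = [
    "OrthologPair",
    "bidirectional_best_hits",
    "global_align",
    "reconstruct_from_template",
]

DEFAULT_MIN_BIT = 100.0
DEFAULT_MAX_EVALUE = 1e-30


# ---------------------------------------------------------------------------
# Global alignment (internal utility)
# ---------------------------------------------------------------------------


def global_align(a: str, b: str) -> tuple[int, int]:
    """Needleman–Wunsch with match=1, mismatch=0, linear gap −1.

    Returns ``(matches, columns)`` for one optimal alignment (deterministic
    tie-break: diagonal > up > left during traceback).
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0, max(n, m)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = -np.arange(m + 1)
    score[:, 0] = -np.arange(n + 1)
    eq = (av[:, None] == bv[None, :]).astype(np.int32)
    for i in range(1, n + 1):
        row_prev = score[i - 1]
        row = score[i]
        diag = row_prev[:-1] + eq[i - 1]
        up = row_prev[1:] - 1
        best = np.maximum(diag, up)
        # left-dependency forces a scan within the row
        acc = row[0]
        for j in range(1, m + 1):
            acc = max(best[j - 1], acc - 1)
            row[j] = acc
    # traceback
    i, j = n, m
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        columns += 1
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + eq[i - 1, j - 1]:
            matches += int(eq[i - 1, j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
    return matches, columns


# ---------------------------------------------------------------------------
# Bidirectional best hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrthologPair:
    query_gene: str
    template_gene: str
    forward_hit: AlignmentHit
    reverse_hit: AlignmentHit

    def __post_init__(self) -> None:
        assert self.forward_hit.query_id == self.query_gene
        assert self.forward_hit.subject_id == self.template_gene
        assert self.reverse_hit.query_id == self.template_gene
        assert self.reverse_hit.subject_id == self.query_gene


def _best_hits(hits: list[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Best subject per query: highest bit score, then lower e-value, then
    lexicographically smaller subject id.  Multiple HSPs for one (query,
    subject) pair collapse to the best-scoring one first."""
    per_pair: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = per_pair.get(key)
        if prev is None or (h.bit_score, -h.evalue) > (prev.bit_score, -prev.evalue):
            per_pair[key] = h
    best: dict[str, AlignmentHit] = {}
    for h in per_pair.values():
        prev = best.get(h.query_id)
        if prev is None:
            best[h.query_id] = h
            continue
        cand = (-h.bit_score, h.evalue, h.subject_id)
        incumbent = (-prev.bit_score, prev.evalue, prev.subject_id)
        if cand < incumbent:
            best[h.query_id] = h
    return best


def bidirectional_best_hits(fwd: list[AlignmentHit], rev: list[AlignmentHit],
                            min_bit: float = DEFAULT_MIN_BIT,
                            max_eval: float = DEFAULT_MAX_EVALUE) -> list[OrthologPair]:
    """Reciprocal best-hit ortholog pairs between two proteomes.

    ``fwd`` maps query → template, ``rev`` the converse.  A pair is returned
    iff each member is the other's best hit and both hits pass ``min_bit`` and
    ``max_eval``.
    """
    best_fwd = _best_hits(fwd)
    best_rev = _best_hits(rev)
    pairs: list[OrthologPair] = []
    for q in sorted(best_fwd):
        f = best_fwd[q]
        r = best_rev.get(f.subject_id)
        if r is None or r.subject_id != q:
            continue
        if f.bit_score < min_bit or f.evalue > max_eval:
            continue
        if r.bit_score < min_bit or r.evalue > max_eval:
            continue
        pairs.append(OrthologPair(query_gene=q, template_gene=f.subject_id,
                                  forward_hit=f, reverse_hit=r))
    return pairs


# ---------------------------------------------------------------------------
# Template-based draft reconstruction
# ---------------------------------------------------------------------------


def reconstruct_from_template(template: MetabolicModel, pairs: list[OrthologPair],
                              include_no_gene_reactions: bool = False,
                              model_id: str = "draft_from_template") -> MetabolicModel:
    """Build a draft model by mapping template gene rules onto query genes.

    Each DNF term survives only if *every* template gene in it has an ortholog
    (partial enzyme complexes are dropped); reactions whose rewritten rule is
    empty are excluded.  Reactions without gene rules are excluded unless
    ``include_no_gene_reactions``.
    """
    mapping: dict[str, set[str]] = {}
    for p in pairs:
        mapping.setdefault(p.template_gene, set()).add(p.query_gene)
    score_by_query = {p.query_gene: p.forward_hit.bit_score for p in pairs}

    draft = MetabolicModel(id=model_id, name=f"homology draft from {template.id}")
    for rid in sorted(template.reactions):
        rxn = template.reactions[rid]
        if rxn.gene_rule is None:
            if not include_no_gene_reactions:
                continue
            new_rule = None
        else:
            terms: set[tuple[str, ...]] = set()
            for term in rxn.gene_rule.dnf:
                if not all(t in mapping for t in term):
                    continue
                # expand over alternative orthologs of each subunit
                expansions: list[tuple[str, ...]] = [()]
                for t in term:
                    expansions = [e + (q,) for e in expansions for q in sorted(mapping[t])]
                terms.update(tuple(sorted(set(e))) for e in expansions)
            if not terms:
                continue
            new_rule = GeneRule(dnf=tuple(sorted(terms)))
        new = rxn.copy()
        new.gene_rule = new_rule
        genes = sorted(new_rule.genes()) if new_rule else []
        scores = [score_by_query[g] for g in genes if g in score_by_query]
        new.provenance = [Evidence(source="template-homology", genes=genes,
                                   score=max(scores) if scores else None)]
        for mid in new.stoichiometry:
            if mid not in draft.metabolites:
                met = template.metabolites[mid].copy()
                draft.metabolites[mid] = met
                draft.compartments.setdefault(
                    met.compartment, template.compartments.get(met.compartment, met.compartment))
        draft.add_reaction(new)
    draft.rebuild_gene_list()
    return draft
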