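"""KO-based draft reconstruction and the HMM training-set pipeline contract.

Query genes are assigned to orthology groups (KOs) either from a supplied
annotation table or from an HMM bit-score table with a score threshold; KOs
then map to reactions through a KEGG-style database bundle whose enzyme rows
are KOs.  The cluster → align → build pipeline used to produce KO-specific
profile HMMs is exposed behind a runner contract: greedy sequence clustering
is implemented here, while multiple alignment and HMM construction are
pluggable (external tools or test stubs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

from .db_recon import UniversalModel, _draft_metabolite, _draft_reaction, _place_reaction
from .homology import global_align
from .io_formats import ProteinRecord, write_fasta
from .model_core import Evidence, GeneRule, MetabolicModel, ModelError

__all__ = [
    "KOAssignment",
    "PipelineError",
    "SequenceCluster",
    "StubRunner",
    "assign_kos_from_annotation",
    "assign_kos_from_hmm_scores",
    "build_ko_training_sets",
    "cluster_sequences",
    "reconstruct_from_kos",
    "DEFAULT_MIN_HMM_SCORE",
]

#: Default HMM bit-score acceptance threshold for KO assignment (user-overridable).
DEFAULT_MIN_HMM_SCORE = 100.0

STANDARD_CUTOFFS = (100.0, 90.0, 50.0)


@dataclass(frozen=True)
class KOAssignment:
    gene_id: str
    ko_id: str
    score: float  # HMM bit score, or +inf for curated annotation
    source: str  # "annotation" | "hmm"

    def __post_init__(self) -> None:
        if self.source not in ("annotation", "hmm"):
            raise ModelError(f"unknown KO assignment source {self.source!r}")
        if self.source == "hmm" and not math.isfinite(self.score):
            raise ModelError(f"HMM assignment {self.gene_id}->{self.ko_id} needs a finite score")


def assign_kos_from_annotation(table: Mapping[str, list[str]]) -> list[KOAssignment]:
    """One assignment per (gene, KO) pair from a curated annotation table."""
    return [
        KOAssignment(gene_id=g, ko_id=ko, score=math.inf, source="annotation")
        for g in sorted(table)
        for ko in table[g]
    ]


def assign_kos_from_hmm_scores(scores: Mapping[str, Mapping[str, float]],
                               min_score: float = DEFAULT_MIN_HMM_SCORE) -> list[KOAssignment]:
    """Assign every KO scoring at least ``min_score`` bits to each gene.

    Multi-assignment is allowed: a gene similar to several KO profiles keeps
    all of them.
    """
    out: list[KOAssignment] = []
    for g in sorted(scores):
        for ko in sorted(scores[g]):
            s = float(scores[g][ko])
            if s >= min_score:
                out.append(KOAssignment(gene_id=g, ko_id=ko, score=s, source="hmm"))
    return out


def reconstruct_from_kos(assignments: list[KOAssignment], universal: UniversalModel,
                         model_id: str = "draft_from_ko") -> MetabolicModel:
    """Draft model from KO assignments against a KEGG-style bundle.

    A reaction enters the draft iff at least one of its KOs is assigned; the
    gene rule is an OR over all genes assigned to any of its KOs (each gene a
    single-gene isozyme term).  Metabolites are placed in compartment ``c``.
    """
    bundle = universal.bundle
    by_rxn: dict[str, list[KOAssignment]] = {}
    for a in assignments:
        enz = universal.enzyme_index.get(a.ko_id)
        if enz is None:
            warnings.warn(f"KO {a.ko_id!r} not present in bundle; assignment skipped")
            continue
        for rid in enz.reactions:
            by_rxn.setdefault(rid, []).append(a)

    draft = MetabolicModel(id=model_id, name="KO-based draft",
                           compartments={"c": "cytosol", "e": "extracellular"})
    for rid in sorted(by_rxn):
        rxn = bundle.reactions[rid]
        stoich, comp_of = _place_reaction(rxn, "c")
        for mid, comp in comp_of.items():
            if mid not in draft.metabolites:
                draft.metabolites[mid] = _draft_metabolite(bundle, mid, comp)
        new = _draft_reaction(rxn, stoich)
        genes = sorted({a.gene_id for a in by_rxn[rid]})
        new.gene_rule = GeneRule(dnf=tuple((g,) for g in genes))
        for source_name, ev_source in (("annotation", "kegg-annotation"), ("hmm", "kegg-hmm")):
            sub = [a for a in by_rxn[rid] if a.source == source_name]
            if sub:
                finite = [a.score for a in sub if math.isfinite(a.score)]
                new.provenance.append(Evidence(
                    source=ev_source, genes=sorted({a.gene_id for a in sub}),
                    score=max(finite) if finite else None))
        draft.add_reaction(new)
    draft.rebuild_gene_list()
    return draft


# ---------------------------------------------------------------------------
# Sequence clustering (greedy, longest-first)
# ---------------------------------------------------------------------------


@dataclass
class SequenceCluster:
    representative: str
    members: list[str]
    cutoff: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ModelError("cluster representative must be a member")


def cluster_sequences(records: list[ProteinRecord], cutoff: float) -> list[SequenceCluster]:
    """Greedy incremental redundancy clustering at a percent-identity cutoff.

    Sequences are processed longest-first (ties by id); each joins the first
    existing cluster whose representative aligns with global identity
    (matches / alignment columns) at least ``cutoff`` %, otherwise it founds a
    new cluster.  Deterministic given the input set.
    """
    if cutoff not in STANDARD_CUTOFFS:
        warnings.warn(f"non-standard redundancy cutoff {cutoff} (typical: 100, 90, 50)")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    by_id = {r.id: r for r in records}
    clusters: list[SequenceCluster] = []
    for rec in order:
        placed = False
        for cl in clusters:
            rep = by_id[cl.representative]
            if rec.sequence == rep.sequence:
                identity = 100.0
            else:
                matches, columns = global_align(rec.sequence, rep.sequence)
                identity = 100.0 * matches / columns if columns else 0.0
            if identity >= cutoff:
                cl.members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(SequenceCluster(representative=rec.id, members=[rec.id], cutoff=cutoff))
    return clusters


# ---------------------------------------------------------------------------
# KO training-set pipeline (cluster -> align -> build), runner contract
# ---------------------------------------------------------------------------


class PipelineError(ModelError):
    """Raised when a pipeline stage fails; names KO and stage."""


@dataclass
class StubRunner:
    """Dependency-free runner for the align/build stages.

    Writes placeholder MSA/HMM text files so the pipeline's file manifest is
    fully determined without external binaries.  Real deployments substitute
    an object with the same two callables wrapping e.g. MAFFT and hmmbuild.
    """

    def align(self, fasta: Path) -> Path:
        out = fasta.with_suffix(".msa")
        out.write_text(f"# stub alignment of {fasta.name}\n")
        return out

    def hmmbuild(self, msa: Path) -> Path:
        out = msa.with_suffix(".hmm")
        out.write_text(f"# stub profile of {msa.name}\n")
        return out


@dataclass
class KOTrainingSet:
    ko_id: str
    clusters: list[SequenceCluster]
    files: list[Path]
    single_sequence: bool = False


def build_ko_training_sets(sequences_by_ko: Mapping[str, list[ProteinRecord]],
                           cutoff: float, outdir: Union[str, Path],
                           runner=None) -> dict[str, KOTrainingSet]:
    """Per-KO training sets: cluster members, write representatives, run align/build.

    Stage order per KO: cluster → align → build.  KOs with fewer than two
    unique representative sequences skip the alignment stage and are flagged
    single-sequence (the profile is built from the lone sequence).  Runner
    failures raise :class:`PipelineError` naming the KO and the stage.
    """
    runner = runner or StubRunner()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, KOTrainingSet] = {}
    for ko in sorted(sequences_by_ko):
        records = sequences_by_ko[ko]
        try:
            clusters = cluster_sequences(records, cutoff)
        except Exception as exc:
            raise PipelineError(f"KO {ko}: stage 'cluster' failed: {exc}") from exc
        by_id = {r.id: r for r in records}
        reps = [by_id[cl.representative] for cl in clusters]
        faa = outdir / f"{ko}.faa"
        write_fasta(reps, faa)
        files = [faa]
        single = len(reps) < 2
        msa: Optional[Path] = None
        if not single:
            try:
                msa = Path(runner.align(faa))
            except Exception as exc:
                raise PipelineError(f"KO {ko}: stage 'align' failed: {exc}") from exc
            files.append(msa)
        try:
            hmm = Path(runner.hmmbuild(msa if msa is not None else faa))
        except Exception as exc:
            raise PipelineError(f"KO {ko}: stage 'build' failed: {exc}") from exc
        files.append(hmm)
        results[ko] = KOTrainingSet(ko_id=ko, clusters=clusters, files=files,
                                    single_sequence=single)
    return results
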