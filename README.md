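# gemforge

Genome-scale metabolic model (GEM) reconstruction, curation and
constraint-based simulation, as a Python library with a thin CLI.

A GEM represents an organism's metabolism as a stoichiometric matrix **S**
over reactions with flux bounds *lb ≤ v ≤ ub*, boolean gene–protein–reaction
(GPR) rules (OR = isozymes, AND = enzyme-complex subunits) and a linear
objective.  gemforge covers the whole reconstruction workflow for systems
biologists building such models:

* **De-novo drafts from a pathway-database bundle** — a canonical TSV/FASTA
  directory of reactions, metabolites, enzymes with protein sequences,
  pathways and spontaneous/transport flags.  An enzyme enters the draft when
  a query protein aligns to it (or one of its subunits) with bit score ≥ 100
  **and** percent positives ≥ 45 on the same HSP; its reactions follow, with
  GPR rules assembled from the matched query genes.  Spontaneous reactions —
  which carry no enzyme association and would otherwise become gaps — are
  retrieved afterwards whenever their reactants are already in the draft.
* **KO-based drafts** — genes are assigned to orthology groups (KOs) from a
  curated annotation table or from profile-HMM bit scores (threshold 100 bits
  by default), and KOs map to reactions through a KO-style bundle.  The
  cluster → align → build HMM training pipeline is included with greedy
  longest-first sequence clustering and pluggable alignment/build runners.
* **Template drafts by orthology** — reciprocal best alignment hits (BBH)
  between the query and template proteomes rewrite the template's GPR rules;
  an AND term survives only if every subunit has an ortholog.
* **Cross-database combination** — reactions are linked by explicit
  cross-references first, then by compartment-aware reactant matching
  (coefficients compared, protons ignored, direction-agnostic); ambiguous
  matches are reported, never auto-assigned.  The combined model keeps the
  primary namespace and OR-merges gene rules of matched pairs.
* **Simulation** — flux balance analysis (max c·v s.t. S·v = 0, lb ≤ v ≤ ub),
  gap analysis (dead ends, blocked reactions, leak tests, connectivity),
  minimal-cardinality MILP gap filling, single-gene essentiality (essential ⇔
  knockout/wild-type growth ratio < 0.25, i.e. strictly more than 75 %
  reduction), growth screening over nutrient conditions, and FSEOF (flux
  scanning with enforced objective function) for overproduction targets.
* **I/O** — SBML L3V1 with FBC v2, a canonical diff-stable YAML format, flat
  text, FASTA and BLAST-style tabular alignments.

Everything is testable offline: `gemforge.fixtures` generates deterministic
synthetic bundles with planted enzymes, proteomes and hit tables, so no
licensed database content is required.

## Worked example

Generate a synthetic input tree and run the full reconstruction pipeline
(database draft → KO drafts → merge → combine → spontaneous retrieval → gap
report):

```sh
gemforge fixtures --seed 1 --out tree/
gemforge pipeline --inputs tree/ -o combined.yml
```

which logs per-stage counts and prints the final tally:

```
INFO [combine] 14 reactions, 23 metabolites, 15 genes (mapped 14, duplicates 0, ambiguous 0)
INFO [spontaneous] 15 reactions, 24 metabolites, 15 genes
INFO [gapreport] 6 dead ends, 15 blocked, 0 leaky, 1 components
15 reactions, 24 metabolites, 15 genes
```

All 14 reactions of the KO-based draft were matched to their database-draft
counterparts (12 via cross-references, the 2 withheld ones via reactant
matching), one spontaneous tautomerization was retrieved on top, and the gap
report shows the raw draft still lacks exchanges — exactly what a curator
would fix next.

FSEOF on the bundled branched toy model (biomass branch vs product branch,
uptake bound 10):

```sh
gemforge fseof --model branch.yml --biomass BIOMASS --product EX_P
```

```
rxn     level_0 ... level_10  slope      direction  target
EX_P    0.000000 ... 9.000000  9.000000   0          True
RP      0.000000 ... 9.000000  9.000000   0          True
RB      10.000000 ... 1.000000 -9.000000  0          False
EX_A    -10.000000 ... -10.000000 0.000000 -1        False
```

As the enforced product flux steps from 0 to 90 % of its theoretical maximum,
only the product-branch reactions (RP, EX_P) increase monotonically — they
are the amplification targets; the shared uptake stays saturated and the
biomass branch shrinks.  Direction codes: 1 forward, −1 reverse, 0
irreversible.

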