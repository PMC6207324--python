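# Methods

This note documents the models, procedures, parameter choices and numerical
conventions behind gemforge, and what the synthetic fixtures do and do not
demonstrate.

## Model structure

A model is a set of compartments, metabolites, reactions and genes with a
single linear objective.  Stoichiometric coefficients are exact rationals
(`fractions.Fraction`) internally and are serialized as decimals — finite
decimals exactly, other rationals at 12 significant digits — so repeated
round trips are bit-stable.  Reversibility is *derived* from the bounds
(reversible ⇔ lb < 0 < ub) and never stored separately; a stored flag can
drift out of sync with the bounds, which is a known source of inconsistency
in model files.  Default bounds for database reactions are [−1000, 1000]
(reversible) and [0, 1000] (irreversible), the conventional big-M flux caps
in mmol·gDW⁻¹·h⁻¹.

Gene rules are canonicalized to disjunctive normal form: a sorted tuple of
sorted AND-terms, duplicates removed.  OR terms are isozymes, AND terms
complex subunits.  DNF makes essentiality evaluation and rule merging plain
set operations; the original string is retained in `raw` for provenance.
Arbitrary nesting is accepted on input (`identifiers, and, or, parentheses`,
case-insensitive keywords) and expanded by distribution.  Expansion is
worst-case exponential in rule depth; GEM rules in practice are shallow.

Every reaction carries provenance (`Evidence`) naming the reconstruction
source (template-homology, metacyc-db, kegg-annotation, kegg-hmm,
spontaneous, manual), the supporting genes and a score where meaningful.
This makes source-overlap accounting of a combined model a pure bookkeeping
query.

## Serialization

The YAML format is the canonical diff-friendly representation: top-level
keys `metadata, compartments, metabolites, reactions, genes`, every
collection sorted by id, fixed scalar formatting.  Two YAML files are
byte-identical exactly when the models are semantically equal, which is what
makes version-controlled model repositories reviewable.  No community YAML
schema exists for this; the schema here is the package's own.

SBML uses Level 3 Version 1 with the FBC v2 package: flux bounds as
parameters, gene associations as FBC Or/And/GeneProductRef trees built from
the DNF, the objective as an FBC objective, cross-references as MIRIAM-style
`identifiers.org` CV terms.  Identifiers are escaped into valid SIds
(`__<codepoint>__` for characters outside `[A-Za-z0-9_]`, with `M_/R_/G_/C_`
prefixes) and restored on read.  Subsystem, EC numbers and the
spontaneous/transport/exchange flags travel in reaction notes.  Provenance
records are *not* carried in SBML (there is no natural FBC slot); they
round-trip through YAML.  The semantic-equality contract for round trips
covers ids, names, compartments, stoichiometry, bounds, rules, objective,
xrefs, formulas/charges, subsystems, EC numbers and flags.

Flat text writes one tab-separated line per reaction (id, equation, gene
rule, subsystem, lb, ub) with the `met[compartment]` convention and `=>` /
`<=>` arrows; unit coefficients are omitted.  An exchange reaction prints
with an empty side (`A[e] <=>`).

## Homology-based reconstruction

Alignment input is a file contract (BLAST outfmt-6 columns qseqid, sseqid,
evalue, bitscore, ppos, pident, length), not a BLAST invocation — the
selection logic is the computation of interest and tests need no external
binary.

*Bidirectional best hits.*  Per query, multiple HSPs per subject collapse to
the best one; the best subject is chosen by highest bit score, then lower
e-value, then lexicographically smaller subject id (a deterministic total
order).  A pair is accepted iff each member is the other's best hit and both
hits pass `min_bit` (default 100) and `max_eval` (default 1e-30); both
defaults are user-overridable, as no universal convention exists.

*Template rewriting.*  Template gene rules are rewritten through the
ortholog map.  An AND term survives only if **every** subunit is mapped —
partial complexes are dropped rather than invented; when a template gene has
several orthologs the term expands over the alternatives.  Reactions whose
rewritten rule is empty are excluded, as are rule-free reactions unless
explicitly requested.

*Database drafts.*  An enzyme is supported iff at least one hit to its
sequence (or any subunit's) satisfies bit ≥ 100 **and** positives ≥ 45 on
the same HSP — the conjunction is evaluated per HSP, not across HSPs.
"Positives" is taken as the alignment's percent-positive-substitutions
column.  Complexes are included permissively on any supported subunit; the
AND term contains only the matched subunits, each represented by its
best-scoring query gene (ties lexicographic).  Raising either cut-off can
only shrink the draft (monotonicity), which the tests assert.

Drafts are single-compartment (`c`), with transport reactions spanning `e`
→ `c`; sub-cellular localization is out of scope.  A transported compound is
stored in the bundle with a positive coefficient and expanded at placement
time to substrate-in-`e` / product-in-`c` (a stoichiometry mapping cannot
hold one compound on both sides).

*Spontaneous retrieval* adds a reaction iff all substrates of at least one
direction (both checked when reversible) are already present in the draft's
cytosolic metabolite set, judged against the draft as passed in (single
pass); missing partners are created.  Chained cascades (a spontaneous
product enabling another spontaneous reaction) therefore require re-running,
which keeps the operation idempotent on a drafted network.

## KO-based reconstruction

KO assignment takes either a curated annotation table (score +∞) or an HMM
bit-score table with threshold 100 bits (the package's own default — no
published convention exists; always overridable).  Multi-assignment is
deliberate: a gene scoring above threshold against several KO profiles keeps
all of them.  A reaction enters the draft iff any of its KOs is assigned;
its rule is an OR over all assigned genes, since KO membership carries no
subunit structure.

Sequence clustering is greedy and longest-first (ties by id): a sequence
joins the first cluster whose representative aligns at identity ≥ cutoff,
else founds one.  Identity = matches / alignment columns under global
alignment with match 1, mismatch 0, linear gap −1 (the package's internal
Needleman–Wunsch; its score is cross-checked against Biopython's aligner in
the tests).  This mirrors the documented strategy of standard redundancy
clusterers without claiming exact equivalence.  The align/build stages of
the HMM training pipeline sit behind a two-callable runner contract
(`align`, `hmmbuild`); the bundled stub runner fixes the file manifest
(`ko.faa[, ko.msa], ko.hmm`) without external tools, and KOs with fewer than
two unique representatives skip alignment and are flagged single-sequence.
Profile-HMM scoring itself is outside the package.

## Cross-database linking and combination

Stage 1 links explicit cross-reference pairs present in both models.  Stage
2 translates each remaining B reaction's metabolites through the metabolite
cross-references (base ids; the `_e` compartment suffix is preserved so pure
transporters keep a nonempty signature) and compares substrate/product
multisets *with coefficients*, ignoring proton-class metabolites (flagged in
the cross-reference table), in either orientation.  Coefficient-strict
matching was chosen over metabolite-set matching: it under-maps rather than
mis-maps.  Protons are ignored because databases disagree systematically on
writing them explicitly; every proton-blind match is reported per pair so a
curator can audit.  A B reaction with two or more candidate partners is
never auto-assigned — it is reported as ambiguous and left unmapped.

Combination keeps all of the A (primary-namespace) model.  Mapped B
reactions are discarded with their gene rules OR-merged into the A
counterpart and provenance concatenated.  Unmapped B reactions are retained
with every translatable metabolite rewritten to the A namespace;
untranslatable metabolites keep their B ids and are flagged foreign.  A B
reaction that becomes stoichiometrically identical to an A reaction after
translation is coalesced the same way as a mapped pair and counted as a
duplicate, so the accounting identity |combined| = |A| + |B| − |mapped| −
|duplicates| holds exactly.

## Simulation

All linear programs share one formulation (optimize c·v subject to S·v = 0
and bounds) solved with HiGHS via scipy; MILP for gap filling uses the same
backend.  The numerical tolerance is 1e-6 throughout and appears in result
metadata.

*Gap analysis.*  Dead ends come from a reversibility-aware sign scan
(produced ⇔ some reaction can run in a producing direction).  Blocked
reactions are found by flux variability (max and min of each flux both zero
within tolerance).  The leak test zeroes all exchange *lower* bounds, gives
each metabolite a temporary sink and maximizes it — a positive optimum means
the metabolite is producible without input, the signature of an unbalanced
reaction.  The consumption test mirrors it with a temporary source and
exchange *upper* bounds at zero.  Connectivity is reported on the
metabolite–reaction bipartite graph.

*Gap filling* solves min Σy subject to steady state over model + candidate
pool, the objective floor, and indicator constraints −M·y ≤ v ≤ M·y with
M = 1000 per candidate.  It returns one minimal-cardinality set (ties are
solver-dependent; the tests therefore compare cardinality against an
exhaustive-subset oracle, not identity).

*Essentiality* evaluates each DNF rule without the knocked-out gene;
false ⇒ bounds [0, 0]; rule-free reactions are untouched.  The cutoff is
strict — essential ⇔ ratio < 0.25 — so a knockout at exactly 75 % reduction
is non-essential, and the boundary is tested explicitly.

*Growth screening* closes all exchange imports, opens a fixed minimal-media
set plus the condition's own exchange (default uptake bound 10), and calls
growth at objective > 1e-6.  Sensitivity and specificity are computed
against observed labels; the minimal-media set is an explicit input, never
hard-coded.

*FSEOF* first maximizes the product flux (v_max), then steps the product
lower bound from its value at maximal growth up to `max_fraction`·v_max
(defaults: 10 levels, fraction 0.9) and maximizes growth at each level.
Because the growth optimum is usually degenerate, each level adds a
secondary minimization of Σ|v| (split-variable LP with growth fixed at its
optimum) so trajectories are solver-stable.  A reaction is a target iff its
|flux| is non-decreasing across levels (tolerance 1e-6), strictly larger at
the last level than the first, and of constant sign.  Direction codes:
0 for irreversible reactions, otherwise the sign of the carried flux
(1 forward, −1 reverse).

## Synthetic fixtures

The generator emulates curated pathway-database content at desk scale:
linear pathways of elementally balanced reactions (isomerizations,
ATP/ADP-coupled phosphorylations, NADH/proton-coupled reductions over
neutral-formula bookkeeping), enzymes of one or two subunits with random
sequences of 60–90 residues, spontaneous tautomerizations/hydrations,
transport of pathway entry metabolites, and an id-renamed shadow namespace
with KO-style enzymes.  A fraction of reaction cross-references (default
20 %) is withheld so reactant matching has genuine work; the shadow copy
drops explicit protons from about half of the proton-containing reactions to
exercise proton-blind matching.  Planted proteomes are substitution-mutated
copies of enzyme sequences; hits are computed by the internal global aligner
with bit-score proxy 2×matches and positives = percent identity.  The proxy
is monotone in alignment quality — sufficient for threshold logic — but it
is not an alignment statistic: at the default lengths an exact copy scores
well above the (100, 45) cut-offs and a random decoy far below, with nothing
guaranteed about intermediate real-world divergence.  Default sizes (4
pathways × 3 reactions, 12 eligible + 4 decoy enzymes, full planting, no
noise) keep every oracle exhaustive and the whole suite and acceptance run
in seconds; they are deliberately small, closed-world conditions.

Consequently, passing tests demonstrate the correctness of the selection,
mapping, accounting and optimization logic — not performance on real
databases: real content has fuzzy homology, inconsistent annotations,
unbalanced legacy reactions and many-to-many cross-references at a scale the
fixtures do not emulate.  Headline statistics from real reconstructions
depend on licensed, versioned database content and are out of scope here.

Everything is a pure function of the fixture spec and its seed; the pipeline
output is byte-deterministic given config and seed.

## Known limitations

* No sub-cellular localization prediction, solution-space sampling, tINIT
  extraction, or map visualization.
* SBML support is limited to L3V1-FBCv2; spreadsheet formats are replaced by
  TSV/flat text.
* Gap filling returns one optimum among possibly many minimal sets.
* The DNF expansion of pathologically deep gene rules can blow up.
* The internal aligner is O(nm) per pair; clustering large sequence sets is
  quadratic and intended for fixture-scale input, with real deployments
  expected to plug external tools into the runner contract.
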