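# Methods

`dupscape` re-implements, as one tested pipeline, a comparative-genomic
procedure for detecting, classifying, dating and rate-quantifying
lineage-specific gene duplications across a small set of genomes on a dated
species tree, together with the branch-asymmetry screen used to recognize
intralocus sexual conflict resolution (ISCR) by germline
subfunctionalization.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Species tree and branch addressing

A `SpeciesPhylogeny` is a dendropy tree whose edge lengths are branch
durations in million years (My).  Branches are addressed by the species
content of the clade below them (`"Dmel"`, `"Agam+Dmel"`, `"root"`), which
makes duplication placements stable across serializations.  The default
comparison set is the four holometabolan genome models — fruit fly (Dmel),
malaria mosquito (Agam), red flour beetle (Tcas), honeybee (Amel) — on the
topology `(Amel,(Tcas,(Agam,Dmel)))`.  Published timetables give no single
canonical set of node ages for this quartet; we use root 345 My, Coleoptera
split 300 My, Diptera split 250 My, which are standard holometabolan
values.  Any dated Newick tree can be substituted.

## Similarity search

Homology is established by an exact affine-gap Smith–Waterman local
aligner (Biopython's `PairwiseAligner` engine) with BLOSUM62, gap open 11,
gap extend 1 (a length-k gap costs 11 + k).  The unknown residue X scores
0 against everything.  Raw scores convert to bit scores with fixed
Karlin–Altschul parameters (λ = 0.267, K = 0.041, the standard calibration
for gapped BLOSUM62); E = m·n·2^(−bit) with m the query length and n the
subject proteome length.  Hits with E > 1.0e−4 are discarded.  Because the
aligner is exhaustive rather than seeded, it is exact but not intended for
genome-scale searches; 12-column blast-tab files from an external search
tool can be ingested instead.

## Family construction and the count rule

Families are seeded from a reference species (Dmel by default).  A
query's *within-species group* is itself plus its reciprocating
within-species hits; its candidate set in species T holds every gene of T
that hits the query and whose best hit back into the query's species lands
inside that group.  Reference genes whose groups overlap are merged into
one family (union–find).  Per-species member counts, sorted descending as
(a, b, c, d), drive the classification:

* a = b = c = 1 → 1:1 orthology (a three-species family, d = 0, still
  qualifies);
* a = b = c > 1 → ancient duplication shared by the lineages;
* a > b = c = 1 → lineage-specific duplication in the species attaining a;
* anything else → unresolved, settled on the family's gene tree by species
  overlap: a duplication node confined to one species flags that lineage,
  one spanning several species flags the shared position.  The
  `a > b = c` pattern with b = c > 1 mixes ancient and lineage-specific
  signal and is also routed to the tree.

The sampling frame ("core families") keeps families conserved in at least
3 of the 4 species with at most 6 members per species, which suppresses
adaptive mega-expansions and orphans.  Each family carries a six-digit
binary code — 1:1 orthology; shared duplication; lineage-specific
duplication in species 1–4 — and every member gene inherits its family's
code.  Predictions are scored against truth codes position by position
(TP/FP/FN/TN per digit over the shared gene universe), with accuracy =
TP/(TP+FN) and specificity = TN/(TN+FP).

Gene trees for unresolved families use Jukes–Cantor **nucleotide**
distances on the back-translated codon alignment when coding sequences are
available: this triples the number of sites and keeps the synonymous
signal, which measurably sharpens the separation of within-species paralog
clades compared to protein distances on the same families.  Protein
distances are the fallback.

## dS dating (NG86)

Paralog pairs are dated by synonymous divergence.  Protein alignments are
mapped back onto codons (gap residue → gap triplet); codon columns
containing any gap are removed, as are gap-free islands shorter than 3
codons (ambiguously aligned stretches).  The estimator is Nei–Gojobori
site counting: per-codon synonymous site fractions, equal weighting of the
minimal substitution pathways between differing codons, and the
Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)·p).  Two conventions are
fixed and shared with the test oracle: mutations creating stop codons
count as nonsynonymous in site counting, and pathways passing through a
stop are excluded from difference counting (falling back to all pathways
when every one is excluded).  Pairs with pS ≥ 3/4 are flagged *saturated*
and treated as older than any finite threshold; the age screen bins pairs
at dS > 2.0 ("old"), and the exported histogram uses 0.5-wide bins with an
open top bin.  For families with several paralogs, all same-species pairs
are computed and the minimum and maximum retained.

## Gene trees, duplication mapping, asymmetry

Genome-wide gene trees are neighbor joining (Saitou–Nei, deterministic
tie-breaking on the Q criterion, negative branch lengths clamped to zero
with the deficit shifted to the sister branch) on Kimura-corrected protein
distances d = −ln(1 − p − 0.2p²) over pairwise-complete columns, capped
and flagged at p ≥ 0.85.  Bootstrap support comes from majority-rule
(>50%) consensus over column-resampled replicates (default 100).
Multiple alignments use a center-star progressive strategy (highest summed
pairwise score picks the center; pairwise alignments to the center are
merged column-wise).  This is adequate for small within-family alignments
and is not a general-purpose MSA tool.

A duplication node is an internal node whose child clades share a species.
It maps onto the species tree at the branch immediately above the LCA of
all species carrying either paralog lineage — the most recent placement
consistent with presence; losses can only make the true origin older, so
ages are lower bounds.  An outgroup genome can date duplications relative
to its split: two or more outgroup orthologs of a duplicated family imply
the duplication preceded the split, a singleton implies it followed, and
absence is uninformative.

Branch asymmetry — the ISCR signature — is the ratio of the two path
lengths from a duplication node to its paralog descendants (mean
root-to-tip path for clades), flagged at a strict ratio > 2.  Rooting is
midpoint by default; if the midpoint falls exactly on a leaf (possible for
extremely asymmetric trees) the leaf is preserved as a zero-length child
of the new root.  For explicitly supplied paralog pairs the tree is rooted
with a cross-species outgroup leaf when one exists, because a midpoint
root tends to fall *inside* the long branch of exactly the asymmetric
pairs being measured.  A zero-length shorter branch yields an infinite,
flagged ratio with a degenerate-length warning.

## Rates, spectra, tallies, enrichment

The branch-level duplicate accumulation rate is D/(F·T): duplications
mapped to the branch over sampled families times branch duration (My),
rounded half-up to 4 decimals; a rate table's average row is the
arithmetic mean of the rounded per-branch rates.  Expansion spectra report
per-species percentages of lineage-specifically expanded families by
post-duplication size class (2–6), each over that species' sampled family
total, rounded half-up to 1 decimal; the reference/others ratio divides
the reference percentage by the mean of the other species' percentages.
Half-up rounding is used throughout because it reproduces the published
reference values (e.g. 698/5,983 → 11.7%, 21/(111·35) → 0.0054).  One
packaged reference value is internally inconsistent (a lineage total
printed 6.7% where its own counts give 7.0%); `reproduce-tables` computes
from counts and flags the mismatch rather than matching the printed
number, and similarly reports the published 55.1% whose exact quotient
rounds to 55.2%.

Parallel duplications (independent duplications of a family in non-
reference terminal lineages) are tallied per lineage with their asymmetric
subset; group means are arithmetic means over lineages.

Term enrichment is the exact hypergeometric tail (SciPy) in both
directions, with Benjamini–Hochberg step-up FDR applied separately per
direction (mirroring direction-specific testing in the standard GO tools)
at α = 0.05.  Ancestor closure of the ontology is the caller's
responsibility; a helper closes annotations over a parent–child edge list.
The packaged expression fixture is a curated TSV of the 18 expanded
energy-metabolism gene families of the fly, with per-paralog testis/ovary
bias and long-branch flags; free-text cells (e.g. "muscle specific") are
preserved but are not flags.

## The synthetic-data generator

The generator exists because the original genome datasets cannot be
redistributed or downloaded at test time; it emulates the inferred
evolutionary regime, not any particular genome.  Each family starts from
one random stop-free CDS at the root.  Along each branch, duplications
arrive at a constant per-family rate (per-branch counts are Poisson with
mean dup_rate·T; times uniform within the branch) and losses at a constant
per-gene rate; duplication copies the whole CDS, loss deletes a whole
gene.  Sequences evolve by per-site nucleotide proposals (Jukes–Cantor
style uniform process): proposals creating stops are rejected,
nonsynonymous proposals are accepted with probability ω, synonymous ones
always.  A new duplicate is "germline" with probability `germline_prob`,
and germline genes evolve with their proposal rate multiplied by `accel`,
emulating the accelerated divergence of germline-specialized paralogs.
All randomness flows from a single seed; outputs are byte-identical across
runs.

Truth codes are emitted from the event log with visibility semantics
matched to what presence-based detection can see: an event is *shown* in a
species iff both daughter lineages have an extant descendant there; shown
in one species → that lineage's position, in two or more → the shared
position, in none → invisible.  This means losses never create spurious
validation mismatches by construction.

Not modeled: indels, codon-usage bias, among-site rate variation, partial
duplications, genome coordinates/synteny.  Consequently the validation
experiments say nothing about alignment-quality failure modes of real
data; they test the logic of the pipeline, not its robustness to messy
annotation.

### Default and experiment parameter regimes

`SimConfig` defaults: 100 families, dup_rate 5e−4 /family/My (which puts
roughly 12% of families with a duplication on a 250-My terminal branch, in
the range reported for real insect core-gene comparisons), loss 1e−4
/gene/My, 100 codons, subst 1.2e−3 proposals/site/My, ω 0.3,
germline_prob 0.1, accel 2.

`EASY_RECOVERY_SETTINGS` (end-to-end code validation): 200 families, 60
codons, dup_rate 2.5e−4, on the default deep tree.  The rate is kept low
so that families with independent duplications in several lineages — which
the count rule cannot fully separate from shared ancient duplication —
stay rare; divergence is kept low enough that cross-species best hits are
essentially unambiguous.  Pooled over 20 seeds this regime recovers
per-digit accuracy ≥ 0.90 and specificity ≥ 0.85 (the validation
thresholds reported for the original pipeline).

`ASYMMETRY_SETTINGS` (branch-asymmetry recovery): 60 families of 300
codons, subst 4e−3, ω 0.6, dup_rate 1e−3, no loss, on a shallower dated
tree (terminals 60–100 My) mirroring the younger radiations in which the
germline-specialized duplicates of interest arise.  Ratios are evaluated
only for pairs whose two branches sum to ≥ 0.1 substitutions/site
(`ASYMMETRY_DIVERGENCE_FLOOR`): a duplication at the very end of a branch
has accumulated essentially no substitutions and its ratio is noise — the
same degenerate class the asymmetry call marks with a warning.

## Numerical conventions

* Rounding of displayed values: half-up at displayed precision.
* Local alignment: deterministic; ties in traceback resolved by the
  engine's fixed enumeration order (scores are what downstream uses).
* NJ ties: smallest (row, column) index pair in current matrix order.
* Best-hit ties: higher bit score, then lexicographically smaller subject.
* Kimura distance cap: d(0.85) ≈ 5.20, flagged; JC nucleotide cap at
  p = 0.70.
* Saturation: pS ≥ 0.75 → dS treated as > any finite threshold.
* Degenerate inputs: empty filtered alignments and all-saturated families
  are flagged, not raised; zero-length asymmetry branches warn and flag.

## Known limitations

* The count rule is intrinsically blind to independent duplications in
  three or more lineages when the resulting counts mimic a shared ancient
  duplication; the original study resolved such families manually, this
  package resolves them by species overlap on a gene tree.
* The center-star aligner and the exhaustive aligner do not scale to real
  proteome sizes; external tools feed in through blast-tab and Newick.
* E-values use fixed Karlin–Altschul constants; they rank and filter
  correctly but are not calibrated significance estimates per database.
* dS beyond ~2 is effectively qualitative ("old"), as in the source
  analysis.
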