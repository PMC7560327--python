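"""All-vs-all protein similarity search with E-value filtering.

The search engine is an exact affine-gap Smith-Waterman local aligner
(BLOSUM62 by default) with Karlin-Altschul bit-score/E-value conversion:
``bit = (lambda * raw - ln K) / ln 2`` and ``E = m * n * 2**(-bit)`` for a
query of length m against a database of n residues.  Hits with E above the
cutoff (1.0e-4 by default) are discarded.  Precomputed tabular hit files in
the 12-column blast-tab dialect can be ingested instead of running the
built-in aligner, for users with real data and an external search tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_E_CUTOFF = 1.0e-4


class HomologyInputError(ValueError):
    """Raised for invalid sequences, lengths, or inconsistent gene ids."""


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring parameters for the local aligner.

    A gap of length k costs ``gap_open + k * gap_extend``.  ``kappa`` and
    ``lam`` are the Karlin-Altschul parameters used for the bit-score
    conversion; the defaults are the standard calibration for gapped
    BLOSUM62 scoring and any calibrated pair preserves the score ranking
    the pipeline depends on.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    kappa: float = 0.041
    lam: float = 0.267

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise HomologyInputError("gap penalties must be > 0")
        if self.kappa <= 0 or self.lam <= 0:
            raise HomologyInputError("Karlin-Altschul parameters must be > 0")

    def substitution_matrix(self):
        matrix = substitution_matrices.load(self.matrix_name)
        # unknown residue X is tolerated and scored 0 against everything
        if "X" in matrix.alphabet:
            matrix = matrix.copy()
            x = matrix.alphabet.index("X")
            matrix[x, :] = 0.0
            matrix[:, x] = 0.0
        return matrix

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.substitution_matrix()
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.kappa)) / math.log(2.0)


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    query_species: str
    subject_species: str
    raw_score: float
    bit_score: float
    evalue: float
    query_interval: tuple = (0, 0)  # 1-based closed; (0, 0) if not traced
    subject_interval: tuple = (0, 0)


class HitTable:
    """Stored similarity hits keyed by ordered (query, subject) pair."""

    def __init__(self, species_of: dict):
        self.species_of = dict(species_of)
        self.hits: dict = {}

    def add(self, hit: SimilarityHit) -> None:
        key = (hit.query, hit.subject)
        old = self.hits.get(key)
        if old is None or hit.raw_score > old.raw_score:
            self.hits[key] = hit

    def get(self, query: str, subject: str):
        return self.hits.get((query, subject))

    def subjects_of(self, query: str):
        """All stored hits with this query, sorted by subject id."""
        return sorted(
            (h for (q, _), h in self.hits.items() if q == query),
            key=lambda h: h.subject,
        )

    def __len__(self):
        return len(self.hits)

    def build_index(self) -> None:
        """Index hits per query and per (query, subject species)."""
        self._by_query: dict = {}
        for (q, s), hit in self.hits.items():
            self._by_query.setdefault(q, {}).setdefault(hit.subject_species, []).append(hit)

    def hits_into_species(self, query: str, species: str):
        if not hasattr(self, "_by_query"):
            self.build_index()
        return self._by_query.get(query, {}).get(species, [])

    def best_hit(self, query: str, species: str):
        """Best stored hit of ``query`` into ``species``.

        Ties on bit score break to the lexicographically smaller subject.
        """
        if query not in self.species_of:
            raise HomologyInputError(f"unknown query {query!r}")
        candidates = self.hits_into_species(query, species)
        if not candidates:
            return None
        return min(candidates, key=lambda h: (-h.bit_score, h.subject))


def local_align(a: str, b: str, scheme: ScoringScheme | None = None):
    """Optimal affine-gap local alignment score and aligned intervals.

    Returns ``(raw_score, (a_start, a_end), (b_start, b_end))`` with
    1-based closed intervals.  Sequences must be non-empty protein strings;
    the unknown residue X scores 0 against everything.
    """
    if not a or not b:
        raise HomologyInputError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.make_aligner()
    if float(aligner.score(a, b)) <= 0:
        return 0.0, (0, 0), (0, 0)
    alignment = next(iter(aligner.align(a, b)))
    score = float(alignment.score)
    a_blocks, b_blocks = alignment.aligned
    a_iv = (int(a_blocks[0][0]) + 1, int(a_blocks[-1][1]))
    b_iv = (int(b_blocks[0][0]) + 1, int(b_blocks[-1][1]))
    return score, a_iv, b_iv


def estimate_evalue(bit_score: float, query_len: int, db_len: int) -> float:
    """Expected chance-hit count: E = m * n * 2**(-bit)."""
    if query_len < 1 or db_len < 1:
        raise HomologyInputError("sequence/database lengths must be >= 1")
    if not math.isfinite(bit_score):
        raise HomologyInputError("bit score must be finite")
    return query_len * db_len * 2.0 ** (-bit_score)


def all_vs_all(
    proteomes: dict,
    scheme: ScoringScheme | None = None,
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> HitTable:
    """Exhaustive all-vs-all search within and between species.

    ``proteomes`` maps species -> {gene id -> protein sequence}.  Gene ids
    must be globally unique.  Every ordered (query, subject) pair whose
    E-value passes the cutoff is stored (self-hits included).  The local
    alignment score is computed once per unordered pair; the E-value is
    direction-specific because the subject database size differs.
    """
    if len(proteomes) < 1:
        raise HomologyInputError("need at least one proteome")
    scheme = scheme or ScoringScheme()
    species_of = {}
    for species, genes in proteomes.items():
        for gene in genes:
            if gene in species_of:
                raise HomologyInputError(f"duplicate gene id {gene!r}")
            species_of[gene] = species
    db_len = {sp: sum(len(s) for s in genes.values()) for sp, genes in proteomes.items()}
    table = HitTable(species_of)
    aligner = scheme.make_aligner()
    entries = [
        (gene, sp, seq) for sp, genes in sorted(proteomes.items()) for gene, seq in sorted(genes.items())
    ]
    for i, (qid, qsp, qseq) in enumerate(entries):
        for sid, ssp, sseq in entries[i:]:
            raw = float(aligner.score(qseq, sseq))
            bit = scheme.bit_score(raw)
            e_fwd = estimate_evalue(bit, len(qseq), db_len[ssp])
            if e_fwd <= e_cutoff:
                table.add(
                    SimilarityHit(qid, sid, qsp, ssp, raw, bit, e_fwd)
                )
            if qid != sid:
                e_rev = estimate_evalue(bit, len(sseq), db_len[qsp])
                if e_rev <= e_cutoff:
                    table.add(
                        SimilarityHit(sid, qid, ssp, qsp, raw, bit, e_rev)
                    )
    table.build_index()
    return table


def within_species_group(query: str, table: HitTable) -> set:
    """The query plus its reciprocating within-species hits.

    A within-species gene g joins the group when both the (query, g) and
    (g, query) hits survived the E-value filter.
    """
    species = table.species_of.get(query)
    if species is None:
        raise HomologyInputError(f"unknown query {query!r}")
    group = {query}
    for hit in table.hits_into_species(query, species):
        g = hit.subject
        if g != query and table.get(g, query) is not None:
            group.add(g)
    return group


def count_orthologs(query: str, table: HitTable, species_order) -> dict:
    """Per-species homolog counts for the family seeded by ``query``.

    For the query's own species the count is the size of its reciprocal
    within-species group (query included).  For another species T it is the
    number of genes in T that hit the query and whose best hit back into
    the query's species lands inside the query's within-species group.
    """
    group = within_species_group(query, table)
    qsp = table.species_of[query]
    counts = {}
    for species in species_order:
        if species == qsp:
            counts[species] = len(group)
            continue
        n = 0
        for hit in table.hits_into_species(query, species):
            t = hit.subject
            best_back = table.best_hit(t, qsp)
            if best_back is not None and best_back.subject in group:
                n += 1
        counts[species] = n
    return counts


def family_members(query: str, table: HitTable, species_order) -> dict:
    """Member gene ids per species for the family seeded by ``query``."""
    group = within_species_group(query, table)
    qsp = table.species_of[query]
    members = {}
    for species in species_order:
        if species == qsp:
            members[species] = sorted(group)
            continue
        found = []
        for hit in table.hits_into_species(query, species):
            t = hit.subject
            best_back = table.best_hit(t, qsp)
            if best_back is not None and best_back.subject in group:
                found.append(t)
        members[species] = sorted(set(found))
    return members


# ---------------------------------------------------------------------------
# blast-tab interchange
# ---------------------------------------------------------------------------

_BLAST_TAB_COLUMNS = (
    "query subject pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def write_hit_table(table: HitTable, path) -> None:
    """Write hits as 12-column blast-tab text (identity fields zeroed when untraced)."""
    with open(path, "w") as handle:
        for (q, s) in sorted(table.hits):
            h = table.hits[(q, s)]
            handle.write(
                f"{q}\t{s}\t0.0\t0\t0\t0\t{h.query_interval[0]}\t{h.query_interval[1]}\t"
                f"{h.subject_interval[0]}\t{h.subject_interval[1]}\t{h.evalue:.3g}\t{h.bit_score:.1f}\n"
            )


def read_hit_table(path, species_of: dict, e_cutoff: float = DEFAULT_E_CUTOFF) -> HitTable:
    """Ingest a 12-column blast-tab file produced by an external tool."""
    table = HitTable(species_of)
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise HomologyInputError("expected 12 blast-tab columns")
            q, s = f[0], f[1]
            if q not in species_of or s not in species_of:
                raise HomologyInputError(f"hit references unknown gene: {q} / {s}")
            evalue, bit = float(f[10]), float(f[11])
            if evalue > e_cutoff:
                continue
            table.add(
                SimilarityHit(
                    q,
                    s,
                    species_of[q],
                    species_of[s],
                    raw_score=bit,
                    bit_score=bit,
                    evalue=evalue,
                    query_interval=(int(f[6]), int(f[7])),
                    subject_interval=(int(f[8]), int(f[9])),
                )
            )
    table.build_index()
    return table
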