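"""Codon alignments and synonymous/nonsynonymous divergence (dS/dN).

The estimator is the Nei-Gojobori site-counting method: per-codon
synonymous site fractions with equal weighting of the minimal substitution
pathways between codon pairs, followed by a Jukes-Cantor multiple-hit
correction ``d = -(3/4) ln(1 - (4/3) p)``.  Pairs with a synonymous
proportion at or beyond the correction's domain (pS >= 3/4) are flagged
saturated; downstream age binning treats saturated pairs as older than the
dS threshold.  Mutations to stop codons count as nonsynonymous in site
counting, and substitution pathways passing through a stop codon are
excluded from difference counting (with a fall-back to all pathways when
every pathway is excluded).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .simulate import AA_BY_CODON_INDEX, BASES, translate


class DivergenceInputError(ValueError):
    """Raised for frame, translation, or length inconsistencies."""


# ---------------------------------------------------------------------------
# codon alignment construction and filtering
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences (gaps as ``---`` triplets)."""

    sequences: dict  # gene -> aligned CDS
    empty: bool = False

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise DivergenceInputError("aligned sequences differ in length")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise DivergenceInputError("alignment length must be a multiple of 3")

    @property
    def n_codons(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values()))) // 3

    def codon_column(self, k: int) -> dict:
        return {g: s[3 * k : 3 * k + 3] for g, s in self.sequences.items()}


def backtranslate(protein_alignment: dict, cds_by_gene: dict) -> CodonAlignment:
    """Map a protein alignment onto CDS codons (gap residue -> gap triplet).

    Every CDS must translate exactly to its ungapped aligned protein; a
    mismatch raises naming the gene and the offending residue position.
    """
    aligned = {}
    for gene, prot_aln in protein_alignment.items():
        if gene not in cds_by_gene:
            raise DivergenceInputError(f"no CDS for gene {gene!r}")
        cds = cds_by_gene[gene]
        if len(cds) % 3 != 0:
            raise DivergenceInputError(f"CDS of {gene!r} is not in frame")
        protein = translate(cds)
        ungapped = prot_aln.replace("-", "")
        if protein != ungapped:
            for i, (x, y) in enumerate(zip(protein, ungapped)):
                if x != y:
                    raise DivergenceInputError(
                        f"CDS of {gene!r} translates to {x!r} at residue {i + 1}, "
                        f"protein alignment has {y!r}"
                    )
            raise DivergenceInputError(
                f"CDS of {gene!r} and its aligned protein differ in length"
            )
        out = []
        pos = 0
        for residue in prot_aln:
            if residue == "-":
                out.append("---")
            else:
                out.append(cds[3 * pos : 3 * pos + 3])
                pos += 1
        aligned[gene] = "".join(out)
    return CodonAlignment(aligned)


def filter_columns(alignment: CodonAlignment, min_block: int = 3) -> CodonAlignment:
    """Drop gapped codon columns and short conserved islands.

    Keeps only gap-free codon columns, and only those lying in contiguous
    gap-free runs of at least ``min_block`` codons (short islands between
    gapped regions are ambiguously aligned and removed).  An empty result
    is returned flagged, not raised.
    """
    n = alignment.n_codons
    gap_free = []
    for k in range(n):
        col = alignment.codon_column(k)
        gap_free.append(all("-" not in codon for codon in col.values()))
    keep = [False] * n
    k = 0
    while k < n:
        if gap_free[k]:
            j = k
            while j < n and gap_free[j]:
                j += 1
            if j - k >= min_block:
                for i in range(k, j):
                    keep[i] = True
            k = j
        else:
            k += 1
    sequences = {
        g: "".join(s[3 * k : 3 * k + 3] for k in range(n) if keep[k])
        for g, s in alignment.sequences.items()
    }
    return CodonAlignment(sequences, empty=not any(keep))


# ---------------------------------------------------------------------------
# NG86 dS / dN
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DsEstimate:
    ds: float
    dn: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    saturated: bool  # pS at or beyond the Jukes-Cantor domain
    dn_saturated: bool = False


def _codon_aa(codon: str) -> str:
    idx = BASES.index(codon[0]) * 16 + BASES.index(codon[1]) * 4 + BASES.index(codon[2])
    return AA_BY_CODON_INDEX[idx]


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of a codon (0..3); stops count nonsynonymous."""
    aa = _codon_aa(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _codon_aa(mutant) == aa:
                syn += 1
        total += syn / 3.0
    return total


def _pair_differences(c1: str, c2: str):
    """Average (syn, nonsyn) difference counts over minimal pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = c1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if _codon_aa(nxt) == "*":
                through_stop = True
            if _codon_aa(nxt) == _codon_aa(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        pathways.append((through_stop, syn, nonsyn))
    usable = [p for p in pathways if not p[0]] or pathways
    syn = sum(p[1] for p in usable) / len(usable)
    nonsyn = sum(p[2] for p in usable) / len(usable)
    return syn, nonsyn


def _jc_correct(p: float):
    """Jukes-Cantor distance and saturation flag for proportion ``p``."""
    if p >= 0.75:
        return math.inf, True
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False


def ds_ng86(a: str, b: str) -> DsEstimate:
    """NG86 synonymous/nonsynonymous divergence between two gap-free CDS.

    Sequences must be equal-length, in frame, and stop-free; at least ~10
    codons are recommended for a stable estimate.
    """
    if len(a) != len(b):
        raise DivergenceInputError("sequences must be equal length")
    if len(a) == 0 or len(a) % 3 != 0:
        raise DivergenceInputError("sequence length must be a positive multiple of 3")
    syn_sites_a = syn_sites_b = 0.0
    syn_d = nonsyn_d = 0.0
    for k in range(0, len(a), 3):
        c1, c2 = a[k : k + 3], b[k : k + 3]
        for codon in (c1, c2):
            if set(codon) - set(BASES):
                raise DivergenceInputError(f"non-ACGT codon {codon!r}")
            if _codon_aa(codon) == "*":
                raise DivergenceInputError(f"stop codon {codon!r} in sequence")
        syn_sites_a += _syn_fraction(c1)
        syn_sites_b += _syn_fraction(c2)
        s, n = _pair_differences(c1, c2)
        syn_d += s
        nonsyn_d += n
    n_codons = len(a) // 3
    S = (syn_sites_a + syn_sites_b) / 2.0
    N = 3.0 * n_codons - S
    ps = syn_d / S if S > 0 else 0.0
    pn = nonsyn_d / N if N > 0 else 0.0
    ds, saturated = _jc_correct(ps)
    dn, dn_saturated = _jc_correct(pn)
    return DsEstimate(
        ds=ds,
        dn=dn,
        syn_sites=S,
        nonsyn_sites=N,
        syn_diffs=syn_d,
        nonsyn_diffs=nonsyn_d,
        saturated=saturated,
        dn_saturated=dn_saturated,
    )


# ---------------------------------------------------------------------------
# family-level summaries and age binning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilyDsSummary:
    family_id: str
    min_ds: float  # nan when all pairs saturated
    max_ds: float
    pair_count: int
    saturated_pairs: int
    all_saturated: bool


def family_ds_summary(family_id: str, members_by_species: dict, cds_by_gene: dict):
    """Min/max dS over all same-species paralog pairs of one family.

    Returns ``None`` (with no computation) when no species holds two or
    more paralogs.  Saturated pairs are tallied separately and excluded
    from the min/max; a family whose pairs are all saturated is flagged.
    """
    pairs = []
    for species, genes in members_by_species.items():
        for g1, g2 in itertools.combinations(sorted(genes), 2):
            pairs.append((g1, g2))
    if not pairs:
        return None
    values = []
    saturated = 0
    estimates = {}
    for g1, g2 in pairs:
        est = ds_ng86(cds_by_gene[g1], cds_by_gene[g2])
        estimates[(g1, g2)] = est
        if est.saturated:
            saturated += 1
        else:
            values.append(est.ds)
    summary = FamilyDsSummary(
        family_id=family_id,
        min_ds=min(values) if values else math.nan,
        max_ds=max(values) if values else math.nan,
        pair_count=len(pairs),
        saturated_pairs=saturated,
        all_saturated=not values,
    )
    return summary, estimates


def old_fraction(ds_values, threshold: float = 2.0) -> float:
    """Fraction of pairs older than ``threshold`` (saturated counts as old).

    ``ds_values`` may mix floats and :class:`DsEstimate` records; an
    infinite or saturated value exceeds any finite threshold.
    """
    values = list(ds_values)
    if not values:
        raise DivergenceInputError("need at least one dS value")
    old = 0
    for v in values:
        if isinstance(v, DsEstimate):
            if v.saturated or v.ds > threshold:
                old += 1
        elif v > threshold:
            old += 1
    return old / len(values)


def ds_histogram(ds_values, bin_width: float = 0.5, top: float = 2.0):
    """Counts per dS bin of ``bin_width``, with an open top bin (> ``top``).

    Returns a list of ``(low, high, count)`` with ``high = inf`` for the
    top bin; saturated estimates fall in the top bin.
    """
    import numpy as np

    edges = list(np.arange(0.0, top + bin_width / 2, bin_width))
    counts = [0] * len(edges)
    for v in ds_values:
        x = v.ds if isinstance(v, DsEstimate) else float(v)
        sat = isinstance(v, DsEstimate) and v.saturated
        if sat or x > top:
            counts[-1] += 1
        else:
            counts[min(int(x // bin_width), len(edges) - 2)] += 1
    out = []
    for i, low in enumerate(edges[:-1]):
        out.append((low, low + bin_width, counts[i]))
    out.append((top, math.inf, counts[-1]))
    return out
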