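"""Distance-based gene trees and duplication-node analysis.

Gene trees are built by neighbor joining on Kimura-corrected protein
distances, optionally with bootstrap support from majority-rule consensus
over column-resampled replicates.  Duplication nodes are internal nodes
whose two child clades share at least one species; each is mapped onto the
dated species tree at the branch immediately above the LCA of the involved
species (the most recent origin consistent with presence).  Branch-length
asymmetry between sister paralogs — the hallmark of germline
subfunctionalization after intralocus sexual conflict resolution — is
called at a strict >2-fold path-length ratio from the duplication node.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align

from .homology import ScoringScheme
from .species_tree import SpeciesPhylogeny

#: Kimura protein distance at the cap proportion p = 0.85.
_P_CAP = 0.85
_D_CAP = -math.log(1.0 - _P_CAP - 0.2 * _P_CAP**2)


class GeneTreeError(ValueError):
    """Raised for malformed alignments, matrices, or trees."""


def species_of(leaf_label: str) -> str:
    """Species prefix of a ``<species>|<gene>`` leaf label."""
    if "|" not in leaf_label:
        raise GeneTreeError(f"leaf {leaf_label!r} has no species prefix")
    return leaf_label.split("|", 1)[0]


def leaf_labels(tree: dendropy.Tree):
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# multiple protein alignment (center-star progressive)
# ---------------------------------------------------------------------------


def _global_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.substitution_matrix()
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def align_proteins(sequences: dict, scheme: ScoringScheme | None = None) -> dict:
    """Center-star progressive multiple alignment.

    The center sequence is the one with the highest summed pairwise global
    alignment score; every other sequence is aligned to the center and the
    pairwise alignments are merged column-wise ("once a gap, always a
    gap").  Adequate for the within-family alignments this pipeline needs;
    not a general replacement for a full progressive aligner.
    """
    names = list(sequences)
    if not names:
        raise GeneTreeError("no sequences to align")
    if len(names) == 1:
        return dict(sequences)
    scheme = scheme or ScoringScheme()
    aligner = _global_aligner(scheme)
    total = {n: 0.0 for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            s = float(aligner.score(sequences[a], sequences[b]))
            total[a] += s
            total[b] += s
    center = max(names, key=lambda n: (total[n], n))
    others = [n for n in names if n != center]

    # master columns: (center char or None, {gene -> char}) built greedily
    master = [(ch, {}) for ch in sequences[center]]
    for name in others:
        alignment = next(iter(aligner.align(sequences[center], sequences[name])))
        c_row, s_row = str(alignment[0]), str(alignment[1])
        merged = []
        mi = pi = 0
        while mi < len(master) or pi < len(c_row):
            m_has_center = mi < len(master) and master[mi][0] is not None
            p_has_center = pi < len(c_row) and c_row[pi] != "-"
            if mi < len(master) and not m_has_center:
                ch, assigned = master[mi]
                merged.append((ch, {**assigned, name: "-"}))
                mi += 1
            elif pi < len(c_row) and not p_has_center:
                merged.append((None, {n: "-" for n in master[0][1]} | {name: s_row[pi]}))
                pi += 1
            else:
                ch, assigned = master[mi]
                merged.append((ch, {**assigned, name: s_row[pi]}))
                mi += 1
                pi += 1
        master = merged
    out = {center: "".join(ch if ch is not None else "-" for ch, _ in master)}
    for name in others:
        out[name] = "".join(assigned.get(name, "-") for _, assigned in master)
    return {n: out[n] for n in names}


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: tuple
    values: np.ndarray  # symmetric, zero diagonal
    capped: bool = False  # any pairwise proportion at/over the cap

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise GeneTreeError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise GeneTreeError("distances must be symmetric, nonnegative, zero-diagonal")
        self.values = v


def kimura_distance(p: float):
    """Kimura-corrected protein distance; capped and flagged at p >= 0.85."""
    if p >= _P_CAP:
        return _D_CAP, True
    return -math.log(1.0 - p - 0.2 * p * p), False


def protein_distance(alignment: dict) -> DistanceMatrix:
    """Pairwise Kimura protein distances on pairwise-complete columns."""
    labels = tuple(alignment)
    if len(labels) < 3:
        raise GeneTreeError("need at least three sequences")
    seqs = [alignment[lab] for lab in labels]
    if len({len(s) for s in seqs}) != 1:
        raise GeneTreeError("aligned sequences differ in length")
    arr = np.array([list(s) for s in seqs])
    n = len(labels)
    d = np.zeros((n, n))
    capped = False
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            if not ok.any():
                raise GeneTreeError(
                    f"no shared ungapped columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float(np.mean(arr[i][ok] != arr[j][ok]))
            dij, cap = kimura_distance(p)
            capped = capped or cap
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d, capped)


def nucleotide_distance(alignment: dict) -> DistanceMatrix:
    """Jukes-Cantor nucleotide distances on pairwise-complete columns.

    For coding alignments this uses roughly three times as many sites as
    the protein distance and keeps the synonymous signal, which sharpens
    the resolution of within-species paralog clades; capped and flagged at
    p >= 0.70 where the correction diverges.
    """
    labels = tuple(alignment)
    if len(labels) < 3:
        raise GeneTreeError("need at least three sequences")
    seqs = [alignment[lab] for lab in labels]
    if len({len(s) for s in seqs}) != 1:
        raise GeneTreeError("aligned sequences differ in length")
    arr = np.array([list(s) for s in seqs])
    n = len(labels)
    d = np.zeros((n, n))
    capped = False
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            if not ok.any():
                raise GeneTreeError(
                    f"no shared ungapped columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float(np.mean(arr[i][ok] != arr[j][ok]))
            if p >= 0.70:
                d[i, j] = d[j, i] = -0.75 * math.log(1.0 - (4.0 / 3.0) * 0.70)
                capped = True
            else:
                d[i, j] = d[j, i] = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    return DistanceMatrix(labels, d, capped)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_build(matrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion break to the smallest (row, column) index pair
    in the current matrix order.  A negative branch length is clamped to
    zero and its deficit shifted onto the sister branch of the join, so
    total path lengths are preserved.  Returns an unrooted tree (trifurcating
    seed node).
    """
    n = len(matrix.labels)
    if n < 3:
        raise GeneTreeError("neighbor joining needs at least three taxa")
    taxa = dendropy.TaxonNamespace([str(lab) for lab in matrix.labels])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in matrix.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(str(lab)))
        nodes.append(node)
    D = matrix.values.copy()
    active = list(range(n))

    def clamp_pair(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        gi, gj = active[i], active[j]
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = sub[i, j] - li
        li, lj = clamp_pair(li, lj)
        new = dendropy.Node()
        nodes[gi].edge.length = li
        nodes[gj].edge.length = lj
        new.add_child(nodes[gi])
        new.add_child(nodes[gj])
        nodes.append(new)
        gnew = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (gi, gj):
                continue
            dk = 0.5 * (D[gi, k] + D[gj, k] - D[gi, gj])
            D[gnew, k] = D[k, gnew] = max(dk, 0.0)
        active = [k for k in active if k not in (gi, gj)] + [gnew]

    (x, y, z) = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    root = dendropy.Node()
    for g, length in ((x, lx), (y, ly), (z, lz)):
        nodes[g].edge.length = max(length, 0.0)
        root.add_child(nodes[g])
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap and consensus
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree, ref: str):
    """Nontrivial splits as frozensets of the side not containing ``ref``."""
    leaves = set(leaf_labels(tree))
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = clade if ref not in clade else frozenset(leaves - clade)
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_consensus(
    alignment: dict, replicates: int = 100, seed: int = 0
) -> dendropy.Tree:
    """Majority-rule (>50%) consensus over column-bootstrap NJ replicates.

    Alignment columns are resampled with replacement for each replicate;
    each internal node of the returned tree carries its bipartition's
    support as a percentage in ``node.label`` (and ``node.support``).
    """
    if replicates < 1:
        raise GeneTreeError("need at least one bootstrap replicate")
    labels = list(alignment)
    if len(labels) < 3:
        raise GeneTreeError("need at least three sequences")
    length = len(next(iter(alignment.values())))
    rng = np.random.default_rng(seed)
    ref = labels[0]
    freq: dict = {}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {lab: "".join(alignment[lab][c] for c in cols) for lab in labels}
        tree = nj_build(protein_distance(resampled))
        for bip in _bipartitions(tree, ref):
            freq[bip] = freq.get(bip, 0) + 1
    kept = sorted(
        (bip for bip, f in freq.items() if f / replicates > 0.5),
        key=lambda b: (len(b), sorted(b)),
    )
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    node_for: dict = {}
    for bip in kept:  # smallest first: parent is the smallest strict superset
        node = dendropy.Node()
        node.support = 100.0 * freq[bip] / replicates
        node.label = f"{node.support:g}"
        node_for[bip] = node
    for bip in kept:
        supersets = [b for b in kept if b != bip and bip < b]
        parent = node_for[min(supersets, key=len)] if supersets else root
        parent.add_child(node_for[bip])
    for lab in labels:
        containing = [b for b in kept if lab in b]
        parent = node_for[min(containing, key=len)] if containing else root
        leaf = dendropy.Node(taxon=taxa.get_taxon(lab))
        parent.add_child(leaf)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# duplication detection, mapping, timing, asymmetry
# ---------------------------------------------------------------------------


@dataclass
class DuplicationCall:
    node_id: int
    species_a: frozenset
    species_b: frozenset
    leaves_a: tuple
    leaves_b: tuple
    branch: str | None = None  # species-tree branch, once mapped
    note: str = ""


@dataclass
class AsymmetryCall:
    node_id: int
    side_a: tuple
    side_b: tuple
    length_a: float
    length_b: float
    ratio: float
    asymmetric: bool
    note: str = ""


def root_tree(tree: dendropy.Tree, outgroup_species: str | None = None) -> dendropy.Tree:
    """Midpoint-root a gene tree, or outgroup-root when a species is given."""
    tree = tree.clone(depth=1)
    if outgroup_species is not None:
        out_leaves = [
            lf for lf in tree.leaf_node_iter() if species_of(lf.taxon.label) == outgroup_species
        ]
        if not out_leaves:
            raise GeneTreeError(f"no leaf from outgroup species {outgroup_species!r}")
        if len(out_leaves) == 1:
            node = out_leaves[0]
            tree.reroot_at_edge(node.edge, length1=node.edge.length / 2 if node.edge.length else 0.0)
        else:
            mrca = tree.mrca(taxa=[lf.taxon for lf in out_leaves])
            if mrca is not tree.seed_node:
                tree.reroot_at_edge(mrca.edge)
    else:
        total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
        if total > 0:
            try:
                tree.reroot_at_midpoint()
            except AssertionError:
                pass  # degenerate lengths: keep the arbitrary seed-node rooting
        if tree.seed_node.taxon is not None:
            # midpoint fell exactly on a leaf node; keep that leaf as a
            # zero-length child so the leaf set is preserved
            taxon = tree.seed_node.taxon
            tree.seed_node.taxon = None
            leaf = dendropy.Node(taxon=taxon)
            tree.seed_node.add_child(leaf)
            leaf.edge.length = 0.0
    tree.is_rooted = True
    return tree


def detect_duplications(tree: dendropy.Tree, rooted: bool = False) -> list:
    """Species-overlap duplication calls on a (midpoint-rooted) gene tree.

    A node is a duplication node iff the species sets of two of its child
    clades intersect.  Leaves must be ``<species>|<gene>``-labeled.
    """
    work = tree if rooted else root_tree(tree)
    for leaf in work.leaf_node_iter():
        if leaf.taxon is None:
            raise GeneTreeError("unlabeled leaf in gene tree")
        species_of(leaf.taxon.label)
    calls = []
    node_ids = {}
    for idx, node in enumerate(work.preorder_node_iter()):
        node_ids[id(node)] = idx
    for node in work.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) < 2:
            continue
        clades = []
        for child in children:
            leaves = tuple(sorted(lf.taxon.label for lf in child.leaf_iter()))
            clades.append((frozenset(species_of(l) for l in leaves), leaves))
        for i in range(len(clades)):
            for j in range(i + 1, len(clades)):
                if clades[i][0] & clades[j][0]:
                    calls.append(
                        DuplicationCall(
                            node_id=node_ids[id(node)],
                            species_a=clades[i][0],
                            species_b=clades[j][0],
                            leaves_a=clades[i][1],
                            leaves_b=clades[j][1],
                        )
                    )
    return calls


def map_to_species_branch(call: DuplicationCall, sp_tree: SpeciesPhylogeny) -> str:
    """Species-tree branch of a duplication call (presence parsimony).

    The duplication is placed on the branch immediately above the LCA of
    all species carrying either paralog lineage — the most recent branch
    consistent with the observed distribution; losses can only make the
    true origin older, so this is a lower bound on age.
    """
    call.branch = sp_tree.branch_above(call.species_a | call.species_b)
    return call.branch


def timing_by_outgroup(outgroup_count: int) -> str:
    """Date a duplication relative to an outgroup split from homolog counts.

    Two or more outgroup orthologs of the duplicated family mean the
    duplication preceded the split (``pre_split``); exactly one means it
    followed (``post_split``); zero is uninformative (``indeterminate``).
    """
    if outgroup_count < 0:
        raise GeneTreeError("outgroup homolog count must be >= 0")
    if outgroup_count >= 2:
        return "pre_split"
    if outgroup_count == 1:
        return "post_split"
    return "indeterminate"


def _path_length(ancestor, leaf) -> float:
    total = 0.0
    node = leaf
    while node is not ancestor:
        total += node.edge.length or 0.0
        node = node.parent_node
        if node is None:
            raise GeneTreeError("leaf is not a descendant of the duplication node")
    return total


def asymmetry(tree: dendropy.Tree, pairs=None, rooted: bool = False) -> list:
    """Branch-length asymmetry between sister paralogs.

    With ``pairs`` (iterables of two leaf labels), each pair's duplication
    node is its LCA on a tree rooted by a cross-species outgroup leaf when
    one exists (midpoint otherwise) — outgroup rooting keeps a strongly
    asymmetric pair's clade intact, where a midpoint root would fall inside
    the pair's own long branch.  Without ``pairs``, every detected
    duplication node is scored using the mean root-to-tip path of each
    child clade.  The asymmetry flag is a strict ratio > 2; a zero shorter
    length yields an infinite, flagged ratio with a degenerate-length
    warning.
    """
    if pairs is not None and not rooted:
        pair_species = {species_of(g) for pr in pairs for g in pr}
        out_leaves = sorted(
            lf.taxon.label
            for lf in tree.leaf_node_iter()
            if species_of(lf.taxon.label) not in pair_species
        )
        work = root_tree(tree, species_of(out_leaves[0]) if out_leaves else None)
    else:
        work = tree if rooted else root_tree(tree)
    name_to_leaf = {lf.taxon.label: lf for lf in work.leaf_node_iter()}
    node_ids = {id(n): i for i, n in enumerate(work.preorder_node_iter())}
    calls = []

    def make_call(node_id, side_a, side_b, la, lb):
        note = ""
        shorter, longer = sorted((la, lb))
        if shorter == 0:
            ratio = math.inf
            note = "degenerate zero-length branch"
            warnings.warn(f"zero-length paralog branch at node {node_id}", stacklevel=3)
        else:
            ratio = longer / shorter
        return AsymmetryCall(
            node_id=node_id,
            side_a=tuple(side_a),
            side_b=tuple(side_b),
            length_a=la,
            length_b=lb,
            ratio=ratio,
            asymmetric=ratio > 2.0,
            note=note,
        )

    if pairs is not None:
        for g1, g2 in pairs:
            if g1 not in name_to_leaf or g2 not in name_to_leaf:
                raise GeneTreeError(f"paralog pair ({g1!r}, {g2!r}) not in tree")
            mrca = work.mrca(taxa=[name_to_leaf[g1].taxon, name_to_leaf[g2].taxon])
            la = _path_length(mrca, name_to_leaf[g1])
            lb = _path_length(mrca, name_to_leaf[g2])
            calls.append(make_call(node_ids[id(mrca)], (g1,), (g2,), la, lb))
        return calls

    for dup in detect_duplications(work, rooted=True):
        node = next(n for n in work.preorder_node_iter() if node_ids[id(n)] == dup.node_id)
        la = float(np.mean([_path_length(node, name_to_leaf[l]) for l in dup.leaves_a]))
        lb = float(np.mean([_path_length(node, name_to_leaf[l]) for l in dup.leaves_b]))
        calls.append(make_call(dup.node_id, dup.leaves_a, dup.leaves_b, la, lb))
    return calls


# ---------------------------------------------------------------------------
# Newick / matrix I/O
# ---------------------------------------------------------------------------


def read_newick(path_or_string) -> dendropy.Tree:
    import os

    if os.path.exists(str(path_or_string)):
        return dendropy.Tree.get(path=str(path_or_string), schema="newick")
    return dendropy.Tree.get(data=str(path_or_string), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_distance_matrix(matrix: DistanceMatrix, path) -> None:
    with open(path, "w") as handle:
        handle.write("\t" + "\t".join(map(str, matrix.labels)) + "\n")
        for lab, row in zip(matrix.labels, matrix.values):
            handle.write(str(lab) + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
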