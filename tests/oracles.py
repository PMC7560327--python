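"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (plain
dynamic programming, exhaustive enumeration, closed formulas) and shares
no code with the package internals it checks.
"""

import itertools
import math

from Bio.Seq import Seq


def sw_affine_local(a, b, matrix, gap_open, gap_extend):
    """Exhaustive affine-gap Smith-Waterman score.

    A gap of length k costs ``gap_open + k * gap_extend``.  Plain
    three-state DP with a floor at zero; no traceback.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + s,
                X[i - 1][j - 1] + s,
                Y[i - 1][j - 1] + s,
            )
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
                X[i][j - 1] - gap_open - gap_extend,
            )
            best = max(best, M[i][j])
    return best


def _aa(codon):
    return str(Seq(codon).translate())


def ng86_sites(codon):
    """Synonymous site count of one codon; stop mutations count nonsynonymous."""
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _aa(mutant) == _aa(codon):
                syn += 1 / 3
    return syn


def ng86_pair(a, b):
    """(S, N, Sd, Nd) for two in-frame CDS by full pathway enumeration."""
    assert len(a) == len(b) and len(a) % 3 == 0
    S_a = S_b = Sd = Nd = 0.0
    for k in range(0, len(a), 3):
        c1, c2 = a[k : k + 3], b[k : k + 3]
        S_a += ng86_sites(c1)
        S_b += ng86_sites(c2)
        diff = [i for i in range(3) if c1[i] != c2[i]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur, syn, non, stop = c1, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _aa(nxt) == "*":
                    stop = True
                if _aa(nxt) == _aa(cur):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            paths.append((stop, syn, non))
        ok = [p for p in paths if not p[0]] or paths
        Sd += sum(p[1] for p in ok) / len(ok)
        Nd += sum(p[2] for p in ok) / len(ok)
    S = (S_a + S_b) / 2
    N = len(a) - S
    return S, N, Sd, Nd


def hypergeom_tail_enum(k, n, K, N, tail):
    """Exact tail by direct enumeration of the hypergeometric pmf."""
    def pmf(x):
        if x > K or n - x > N - K:
            return 0.0
        return math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)

    if tail == "over":
        return sum(pmf(x) for x in range(k, n + 1))
    return sum(pmf(x) for x in range(0, k + 1))


def bh_stepup(pvalues):
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        prev = min(prev, pvalues[i] * m / rank)
        q[i] = prev
    return q


def random_binary_tree(labels, rng, min_len=0.05, max_len=1.0):
    """Random rooted binary dendropy tree by repeated random joins."""
    import dendropy

    taxa = dendropy.TaxonNamespace(list(labels))
    nodes = []
    for label in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        node.edge.length = float(rng.uniform(min_len, max_len))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_len, max_len))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def duplication_nodes_brute(tree):
    """Species-overlap duplication nodes of a rooted dendropy tree.

    Returns the set of frozensets of descendant leaf labels of each node
    whose two (or more) child clades share a species (prefix before '|').
    """
    out = set()
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) < 2:
            continue
        species_sets = []
        for child in children:
            species_sets.append(
                {leaf.taxon.label.split("|", 1)[0] for leaf in child.leaf_iter()}
            )
        overlap = False
        for i in range(len(species_sets)):
            for j in range(i + 1, len(species_sets)):
                if species_sets[i] & species_sets[j]:
                    overlap = True
        if overlap:
            out.add(frozenset(leaf.taxon.label for leaf in node.leaf_iter()))
    return out
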