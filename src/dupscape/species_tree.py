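"""Dated species phylogenies and branch bookkeeping.

A :class:`SpeciesPhylogeny` wraps a dendropy tree whose edge lengths are
branch durations in million years (My).  Every edge is addressed by a stable
string label derived from the species content of the clade below it
(``"Dmel"`` for a terminal branch, ``"Agam+Dmel"`` for the branch above the
Agam/Dmel ancestor, ``"root"`` for the root edge).  Downstream stages use
these labels to place duplication events and to accumulate per-branch
duplication counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable

import dendropy

#: Default comparison set: fruit fly, malaria mosquito, red flour beetle,
#: honeybee -- ordered as they appear in the six-digit duplication code.
DEFAULT_SPECIES_ORDER = ("Dmel", "Agam", "Tcas", "Amel")

#: Default dated topology.  Node ages (My): Holometabola root 345,
#: Coleoptera split 300, Diptera (Dmel-Agam) split 250.  Edge lengths are
#: branch durations derived from those ages.
DEFAULT_NEWICK = "(Amel:345,(Tcas:300,(Agam:250,Dmel:250):50):45);"


class SpeciesTreeError(ValueError):
    """Raised for malformed species trees or unknown species lookups."""


@dataclass(frozen=True)
class Branch:
    """One edge of the dated species tree."""

    label: str
    clade: frozenset
    duration: float
    is_terminal: bool


def _clade_label(species: Iterable[str]) -> str:
    species = sorted(set(species))
    if not species:
        raise SpeciesTreeError("empty clade")
    return "+".join(species)


class SpeciesPhylogeny:
    """A dated, binary species tree with labeled branches.

    Parameters
    ----------
    tree
        dendropy tree; edge lengths are durations in My and must be > 0
        for all non-root edges.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise SpeciesTreeError("leaf labels must be unique")
        if len(leaves) < 2:
            raise SpeciesTreeError("need at least two species")
        self.taxa = tuple(leaves)
        self._clades = {}
        self.branches = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                clade = frozenset([node.taxon.label])
            else:
                clade = frozenset().union(*(self._clades[id(ch)] for ch in node.child_nodes()))
            self._clades[id(node)] = clade
            if node.parent_node is None:
                label = "root"
                duration = node.edge.length or 0.0
            else:
                label = _clade_label(clade)
                duration = node.edge.length
                if duration is None or duration <= 0:
                    raise SpeciesTreeError(f"branch {label!r} needs a positive duration in My")
            node.branch_label = label
            self.branches[label] = Branch(
                label=label,
                clade=clade,
                duration=float(duration),
                is_terminal=node.is_leaf(),
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesPhylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def default_insect(cls) -> "SpeciesPhylogeny":
        """The 4-taxon holometabolan tree (Amel,(Tcas,(Agam,Dmel)))."""
        return cls.from_newick(DEFAULT_NEWICK)

    # -- queries ------------------------------------------------------------

    @property
    def root_age(self) -> float:
        """Age of the root in My (max root-to-leaf duration sum)."""

        def depth(node):
            if node.is_leaf():
                return 0.0
            return max(ch.edge.length + depth(ch) for ch in node.child_nodes())

        return depth(self._tree.seed_node)

    def branch_above(self, species: Iterable[str]) -> str:
        """Label of the branch immediately above the LCA of ``species``.

        This is the most recent branch on which a duplication observed in
        exactly this species set can have occurred (presence parsimony).
        """
        target = frozenset(species)
        unknown = target - frozenset(self.taxa)
        if unknown:
            raise SpeciesTreeError(f"unknown species: {sorted(unknown)}")
        if not target:
            raise SpeciesTreeError("empty species set")
        best = None
        for node in self._tree.postorder_node_iter():
            clade = self._clades[id(node)]
            if target <= clade and (best is None or len(clade) < len(best[1])):
                best = (node, clade)
        node = best[0]
        return node.branch_label

    def preorder_branches(self):
        """Yield (branch_label, parent_label or None, duration) in preorder."""
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            yield (
                node.branch_label,
                parent.branch_label if parent is not None else None,
                self.branches[node.branch_label].duration,
            )

    def child_branches(self, label: str):
        """Labels of the child branches of ``label`` (empty for terminals)."""
        for node in self._tree.preorder_node_iter():
            if node.branch_label == label:
                return [ch.branch_label for ch in node.child_nodes()]
        raise SpeciesTreeError(f"no branch {label!r}")

    def as_newick(self) -> str:
        out = StringIO()
        self._tree.write(file=out, schema="newick", suppress_rooting=True)
        return out.getvalue().strip()
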