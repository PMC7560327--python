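"""Gene-family construction, duplication classification, and validation.

Families are seeded from a reference species (fruit fly by default): each
reference gene's reciprocal within-species group plus its cross-species
candidate sets form one family; seeds sharing within-species group members
are merged.  Sorted per-species ortholog counts (a >= b >= c >= d) drive
the count-based classification rule:

* a = b = c = 1 (d <= 1) -> one-to-one orthology across lineages,
* a = b = c > 1          -> ancient (pre-radiation) duplication,
* a > b = c = 1 (d <= 1) -> lineage-specific duplication in the species
  attaining a,
* anything else          -> unresolved, settled by species-overlap analysis
  of the family's gene tree.

Each family carries a six-digit binary duplication code: position 1 flags
clean 1:1 orthology, position 2 a duplication shared by two or more
lineages, positions 3-6 lineage-specific duplications in species 1-4 of
the configured species order.  Predicted codes are scored against truth
codes position by position (every gene contributes at every position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .species_tree import DEFAULT_SPECIES_ORDER

LABEL_ORTHO = "ORTHO_1TO1"
LABEL_ANCIENT = "ANCIENT_DUP"
LABEL_LINEAGE = "LINEAGE_SPECIFIC"
LABEL_UNRESOLVED = "UNRESOLVED"


class ClassificationError(ValueError):
    """Raised for inconsistent family, code, or validation inputs."""


@dataclass(frozen=True)
class OrthologCountVector:
    """Per-species homolog counts with a sorted-descending (a,b,c,d) view."""

    counts: dict

    def __post_init__(self):
        for sp, n in self.counts.items():
            if not isinstance(n, int) or n < 0:
                raise ClassificationError(f"count for {sp!r} must be a nonnegative integer")

    @property
    def sorted_counts(self) -> tuple:
        return tuple(sorted(self.counts.values(), reverse=True))


@dataclass
class FamilyRecord:
    """A gene family with members, counts, class label and duplication code."""

    family_id: str
    seed_gene: str
    members: dict  # species -> sorted list of gene ids
    counts: dict = field(init=False)
    label: str = LABEL_UNRESOLVED
    expanded_species: tuple = ()
    code: str = "000000"

    def __post_init__(self):
        self.counts = {sp: len(genes) for sp, genes in self.members.items()}

    def all_members(self):
        for genes in self.members.values():
            yield from genes

    def size_in(self, species: str) -> int:
        return self.counts.get(species, 0)


# ---------------------------------------------------------------------------
# family construction
# ---------------------------------------------------------------------------


def build_families(table, species_order=DEFAULT_SPECIES_ORDER, reference=None) -> list:
    """Reference-species-centric family construction from a hit table.

    Every reference-species gene seeds a family; overlapping seeds (shared
    within-species group members) are merged into one family whose members
    are the union of the seeds' groups and candidate sets.
    """
    from . import homology

    species_order = tuple(species_order)
    reference = reference or species_order[0]
    ref_genes = sorted(g for g, sp in table.species_of.items() if sp == reference)
    parent = {g: g for g in ref_genes}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            ra, rb = sorted((ra, rb))
            parent[rb] = ra

    groups = {g: homology.within_species_group(g, table) for g in ref_genes}
    owner = {}
    for g in ref_genes:
        for member in groups[g]:
            if member in owner:
                union(g, owner[member])
            else:
                owner[member] = g
    clusters: dict = {}
    for g in ref_genes:
        clusters.setdefault(find(g), []).append(g)

    families = []
    for i, root in enumerate(sorted(clusters)):
        members = {sp: set() for sp in species_order}
        for seed in clusters[root]:
            for sp, genes in homology.family_members(seed, table, species_order).items():
                members[sp].update(genes)
        families.append(
            FamilyRecord(
                family_id=f"FAM{i:05d}",
                seed_gene=root,
                members={sp: sorted(genes) for sp, genes in members.items()},
            )
        )
    return families


# ---------------------------------------------------------------------------
# the count rule
# ---------------------------------------------------------------------------


def core_filter(family: FamilyRecord, min_species: int = 3, max_members: int = 6) -> bool:
    """Core-family sampling frame: conserved in >= ``min_species`` of the
    compared species and <= ``max_members`` paralogs in every species."""
    counts = list(family.counts.values())
    return sum(n >= 1 for n in counts) >= min_species and all(n <= max_members for n in counts)


def classify_counts(vector: OrthologCountVector):
    """Apply the sorted-count rule; returns ``(label, expanded_species)``.

    ``expanded_species`` is non-empty only for lineage-specific calls (the
    unique species attaining the top count a).
    """
    sorted_desc = vector.sorted_counts
    padded = sorted_desc + (0,) * max(0, 4 - len(sorted_desc))
    a, b, c, d = padded[:4]
    if a == b == c:
        if a == 1 and d <= 1:
            return LABEL_ORTHO, ()
        if a > 1:
            return LABEL_ANCIENT, ()
        return LABEL_UNRESOLVED, ()
    if a > b and b == c:
        if b == 1 and d <= 1:
            winners = [sp for sp, n in vector.counts.items() if n == a]
            return LABEL_LINEAGE, tuple(winners)
        # a > b = c with b > 1 mixes ancient and lineage-specific signal
        return LABEL_UNRESOLVED, ()
    return LABEL_UNRESOLVED, ()


def assign_code(
    label: str,
    lineage_flags=(),
    shared: bool = False,
    species_order=DEFAULT_SPECIES_ORDER,
) -> str:
    """Serialize a label plus per-species duplication flags to six digits."""
    species_order = tuple(species_order)
    flags = [0] * 6
    if label == LABEL_ORTHO:
        if lineage_flags or shared:
            raise ClassificationError("1:1 orthology excludes duplication flags")
        flags[0] = 1
    else:
        if shared or label == LABEL_ANCIENT:
            flags[1] = 1
        for sp in lineage_flags:
            if sp not in species_order:
                raise ClassificationError(f"unknown species {sp!r}")
            flags[2 + species_order.index(sp)] = 1
    return "".join(map(str, flags))


def parse_code(code: str, species_order=DEFAULT_SPECIES_ORDER):
    """Inverse of :func:`assign_code`: ``(label, lineage_flags, shared)``."""
    if len(code) != 6 or set(code) - {"0", "1"}:
        raise ClassificationError(f"malformed code {code!r}")
    if code[0] == "1":
        if "1" in code[1:]:
            raise ClassificationError("position 1 excludes all other positions")
        return LABEL_ORTHO, (), False
    shared = code[1] == "1"
    lineages = tuple(sp for i, sp in enumerate(species_order) if code[2 + i] == "1")
    if lineages:
        label = LABEL_LINEAGE
    elif shared:
        label = LABEL_ANCIENT
    else:
        label = LABEL_UNRESOLVED
    return label, lineages, shared


def classify_family(family: FamilyRecord, species_order=DEFAULT_SPECIES_ORDER) -> FamilyRecord:
    """Apply the count rule to a family and fill label/code in place."""
    label, expanded = classify_counts(OrthologCountVector(family.counts))
    family.label = label
    family.expanded_species = expanded
    if label == LABEL_ORTHO:
        family.code = assign_code(LABEL_ORTHO)
    elif label == LABEL_ANCIENT:
        family.code = assign_code(LABEL_ANCIENT, shared=True, species_order=species_order)
    elif label == LABEL_LINEAGE:
        family.code = assign_code(LABEL_LINEAGE, expanded, species_order=species_order)
    else:
        family.code = "000000"
    return family


def resolve_unresolved(
    family: FamilyRecord, gene_tree, species_order=DEFAULT_SPECIES_ORDER
) -> FamilyRecord:
    """Settle an unresolved family by species overlap on its gene tree.

    Duplication nodes are internal nodes whose child clades share at least
    one species; a duplication confined to a single species flags that
    species' code position, one spanning two or more species flags the
    shared position.  A tree with no duplication node resolves to 1:1
    orthology.
    """
    from . import genetree

    tree_leaves = set(genetree.leaf_labels(gene_tree))
    members = set(family.all_members())
    if tree_leaves != members:
        raise ClassificationError(
            f"gene tree leaves do not match family members for {family.family_id}"
        )
    calls = genetree.detect_duplications(gene_tree)
    shared = False
    lineages = set()
    for call in calls:
        species = call.species_a | call.species_b
        if len(species) == 1:
            lineages.add(next(iter(species)))
        else:
            shared = True
    if lineages:
        family.label = LABEL_LINEAGE
        family.expanded_species = tuple(sorted(lineages))
    elif shared:
        family.label = LABEL_ANCIENT
        family.expanded_species = ()
    else:
        family.label = LABEL_ORTHO
        family.expanded_species = ()
    family.code = (
        assign_code(LABEL_ORTHO)
        if family.label == LABEL_ORTHO
        else assign_code(
            family.label, tuple(sorted(lineages)), shared=shared, species_order=species_order
        )
    )
    return family


# ---------------------------------------------------------------------------
# validation against truth codes
# ---------------------------------------------------------------------------


@dataclass
class ValidationConfusion:
    """Per-code-position confusion counts over the shared gene universe."""

    tp: list
    fp: list
    fn: list
    tn: list
    n_genes: int
    n_excluded: int

    def accuracy(self, position: int):
        """True-positive fraction TP/(TP+FN) at a code position (0-based)."""
        denom = self.tp[position] + self.fn[position]
        return self.tp[position] / denom if denom else None

    def specificity(self, position: int):
        """True-negative fraction TN/(TN+FP) at a code position (0-based)."""
        denom = self.tn[position] + self.fp[position]
        return self.tn[position] / denom if denom else None


def validate_codes(predicted: dict, truth: dict) -> ValidationConfusion:
    """Score predicted six-digit codes against truth, per position.

    Both arguments map gene id -> code.  Genes absent from either map are
    excluded (and counted); every shared gene contributes at all six
    positions.
    """
    shared = sorted(set(predicted) & set(truth))
    if not shared:
        raise ClassificationError("no genes shared between predicted and truth code sets")
    excluded = len(set(predicted) ^ set(truth))
    tp, fp, fn, tn = [0] * 6, [0] * 6, [0] * 6, [0] * 6
    for gene in shared:
        p, t = predicted[gene], truth[gene]
        if len(p) != 6 or len(t) != 6:
            raise ClassificationError(f"malformed code for {gene!r}")
        for i in range(6):
            if t[i] == "1" and p[i] == "1":
                tp[i] += 1
            elif t[i] == "1":
                fn[i] += 1
            elif p[i] == "1":
                fp[i] += 1
            else:
                tn[i] += 1
    return ValidationConfusion(tp, fp, fn, tn, n_genes=len(shared), n_excluded=excluded)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def write_family_table(families, path, species_order=DEFAULT_SPECIES_ORDER) -> None:
    with open(path, "w") as handle:
        cols = ["family", "seed"]
        cols += [f"{sp}_members" for sp in species_order]
        cols += [f"{sp}_n" for sp in species_order]
        cols += ["label", "expanded", "code"]
        handle.write("\t".join(cols) + "\n")
        for fam in families:
            row = [fam.family_id, fam.seed_gene]
            row += [";".join(fam.members.get(sp, [])) for sp in species_order]
            row += [str(fam.size_in(sp)) for sp in species_order]
            row += [fam.label, ";".join(fam.expanded_species), fam.code]
            handle.write("\t".join(row) + "\n")


def write_gene_codes(families, path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\tcode\n")
        rows = []
        for fam in families:
            for gene in fam.all_members():
                rows.append((gene, fam.code))
        for gene, code in sorted(rows):
            handle.write(f"{gene}\t{code}\n")


def gene_codes(families) -> dict:
    """Per-gene codes (each gene inherits its family's code)."""
    out = {}
    for fam in families:
        for gene in fam.all_members():
            out[gene] = fam.code
    return out
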