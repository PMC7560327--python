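"""Synthetic gene-family evolution on a dated species tree.

Generates per-species protein and CDS FASTA files with a fully known
duplication/loss history, so that every downstream stage (similarity
search, classification, dS dating, gene trees) can be validated against
ground truth without any external genome downloads.

Model
-----
Each family starts from one random stop-free CDS at the root of the species
tree.  Along every branch, duplication events arrive at a constant rate per
family (so per-branch event counts are Poisson with mean ``dup_rate * T``)
and loss events at a constant rate per extant gene; event times within a
branch are uniform by construction of the constant-rate process.
Duplications copy the full CDS; losses delete whole genes.

Sequences evolve by a per-site nucleotide proposal process (uniform across
sites and target bases, Jukes-Cantor style): proposals arrive at
``subst_rate`` per site per My, proposals creating a stop codon are
rejected, nonsynonymous proposals are accepted with probability ``omega``,
synonymous proposals always.  A newly born duplicate is marked "germline"
with probability ``germline_prob``; germline genes evolve with their
proposal rate multiplied by ``accel``, emulating the accelerated divergence
of germline-specialized paralogs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .species_tree import DEFAULT_SPECIES_ORDER, SpeciesPhylogeny

# ---------------------------------------------------------------------------
# genetic code tables (standard code, indexed 0..63 with A,C,G,T = 0..3)
# ---------------------------------------------------------------------------

from Bio.Seq import Seq as _BioSeq

BASES = "ACGT"
AA_BY_CODON_INDEX = np.array(
    [str(_BioSeq("".join(c)).translate()) for c in itertools.product(BASES, repeat=3)]
)
SENSE_CODON_INDICES = np.array(
    [i for i, aa in enumerate(AA_BY_CODON_INDEX) if aa != "*"]
)


class SimulationConfigError(ValueError):
    """Raised for invalid simulator configurations or inputs."""


#: Conservative regime for end-to-end classification recovery experiments:
#: sparse duplications (about 0.3 expected events per family over the whole
#: default tree), mild loss, and divergence low enough that homology stays
#: unambiguous across the deepest splits.
EASY_RECOVERY_SETTINGS = dict(
    n_families=200,
    root_len=60,
    dup_rate=0.00025,
    loss_rate=0.0001,
    subst_rate=0.0012,
    omega=0.3,
)

#: Regime for branch-asymmetry recovery experiments, run on a shallower
#: dated tree (terminal branches 60-100 My, mirroring the younger dipteran
#: radiations where germline-specialized duplicates arise).  Longer, faster
#: evolving sequences give measurable per-branch substitution counts; no
#: losses, and every duplicate is germline class when testing acceleration.
ASYMMETRY_SETTINGS = dict(
    n_families=60,
    root_len=300,
    dup_rate=0.001,
    loss_rate=0.0,
    subst_rate=0.004,
    omega=0.6,
)

#: Newick for the shallow tree used with :data:`ASYMMETRY_SETTINGS`.
SHALLOW_TREE_NEWICK = "(Amel:100,(Tcas:80,(Agam:60,Dmel:60):20):20);"

#: Minimum combined paralog divergence (substitutions per site, both
#: branches from the duplication node) for an asymmetry ratio to be
#: considered measurable in recovery experiments; younger pairs carry too
#: few substitutions for a stable ratio.
ASYMMETRY_DIVERGENCE_FLOOR = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults describe a conservative ("easy") evolutionary regime on the
    default holometabolan tree: roughly one duplication per family over the
    whole tree, mild loss, and divergence low enough that homology remains
    detectable across the deepest (root-age ~345 My) splits.
    """

    n_families: int = 100
    dup_rate: float = 0.0005  # duplications per family per My
    loss_rate: float = 0.0001  # losses per gene per My
    root_len: int = 100  # codons
    subst_rate: float = 0.0012  # nucleotide proposals per site per My
    omega: float = 0.3  # nonsynonymous acceptance probability
    germline_prob: float = 0.1
    accel: float = 2.0  # proposal-rate multiplier for germline genes
    seed: int = 0
    branch_dup_rates: dict = field(default_factory=dict)  # optional per-branch override

    def __post_init__(self):
        if self.n_families < 1:
            raise SimulationConfigError("n_families must be >= 1")
        for name in ("dup_rate", "loss_rate", "subst_rate"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.omega <= 1.0:
            raise SimulationConfigError("omega must lie in [0, 1]")
        if self.accel < 1.0:
            raise SimulationConfigError("accel must be >= 1")
        if self.root_len < 30:
            raise SimulationConfigError("root_len must be >= 30 codons")
        if not 0.0 <= self.germline_prob <= 1.0:
            raise SimulationConfigError("germline_prob must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)


@dataclass(frozen=True)
class TruthEvent:
    """One recorded duplication or loss event."""

    family: str
    kind: str  # "duplication" | "loss"
    branch: str
    time: float  # My from the start of the branch
    parent_gene: str
    child_genes: tuple  # (kept lineage, new lineage) for duplications
    germline: bool = False


class _Gene:
    """Mutable in-flight gene lineage (internal to the simulator)."""

    __slots__ = ("uid", "seq", "germline", "tags", "syn", "nonsyn")

    def __init__(self, uid, seq, germline=False, tags=(), syn=0, nonsyn=0):
        self.uid = uid
        self.seq = seq
        self.germline = germline
        self.tags = tags  # tuple of (event_id, side) markers
        self.syn = syn
        self.nonsyn = nonsyn

    def copy(self):
        return _Gene(self.uid, self.seq.copy(), self.germline, self.tags, self.syn, self.nonsyn)


@dataclass
class SyntheticDataset:
    """Simulated proteomes with complete ground truth."""

    proteins: dict  # species -> {gene name -> protein}
    cds: dict  # species -> {gene name -> CDS}
    events: list  # TruthEvent records
    truth_codes: dict  # family -> six-digit code
    gene_codes: dict  # gene name -> six-digit code (family code)
    event_branches: dict  # event id -> species-tree branch label
    families: dict  # family -> species -> [gene names]
    germline_genes: set  # extant gene names of germline class
    subst_counts: dict  # gene name -> (synonymous, nonsynonymous) realized
    gene_tags: dict  # gene name -> tuple of (event id, side) markers
    config: SimConfig
    species_order: tuple

    def all_genes(self):
        for species in self.proteins:
            yield from self.proteins[species]


# ---------------------------------------------------------------------------
# sequence-level operations
# ---------------------------------------------------------------------------


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free CDS of ``n_codons`` codons (uniform sense codons)."""
    idx = rng.choice(SENSE_CODON_INDICES, size=n_codons)
    out = []
    for i in idx:
        out.append(BASES[i // 16] + BASES[(i // 4) % 4] + BASES[i % 4])
    return "".join(out)


def _seq_to_array(cds: str) -> np.ndarray:
    arr = np.frombuffer(cds.encode(), dtype=np.uint8).copy()
    coded = np.full(arr.shape, 255, dtype=np.uint8)
    for i, base in enumerate(BASES):
        coded[arr == ord(base)] = i
    if np.any(coded == 255):
        raise SimulationConfigError("CDS contains non-ACGT characters")
    return coded


def _array_to_seq(arr: np.ndarray) -> str:
    return "".join(BASES[b] for b in arr)


def _codon_index(arr, start) -> int:
    return int(arr[start]) * 16 + int(arr[start + 1]) * 4 + int(arr[start + 2])


def validate_cds(cds: str) -> None:
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise SimulationConfigError("CDS length must be a positive multiple of 3")
    arr = _seq_to_array(cds)
    for start in range(0, len(cds), 3):
        if AA_BY_CODON_INDEX[_codon_index(arr, start)] == "*":
            raise SimulationConfigError(f"internal stop codon at nucleotide {start}")


def translate(cds: str) -> str:
    arr = _seq_to_array(cds)
    return "".join(
        AA_BY_CODON_INDEX[_codon_index(arr, s)] for s in range(0, len(arr), 3)
    )


def _evolve_array(arr, duration, config, accel, rng):
    """Evolve a coded sequence in place; return (syn, nonsyn) realized counts."""
    if duration < 0:
        raise SimulationConfigError("duration must be >= 0")
    n_prop = rng.poisson(config.subst_rate * arr.size * duration * accel)
    syn = nonsyn = 0
    for _ in range(n_prop):
        site = int(rng.integers(arr.size))
        old = int(arr[site])
        new = int(rng.integers(3))
        if new >= old:
            new += 1
        start = site - site % 3
        arr[site] = new
        new_aa = AA_BY_CODON_INDEX[_codon_index(arr, start)]
        arr[site] = old
        if new_aa == "*":
            continue  # stop-creating proposals are rejected
        old_aa = AA_BY_CODON_INDEX[_codon_index(arr, start)]
        if new_aa == old_aa:
            arr[site] = new
            syn += 1
        elif rng.random() < config.omega:
            arr[site] = new
            nonsyn += 1
    return syn, nonsyn


def evolve_sequences(cds: str, duration: float, config: SimConfig, accel: float = 1.0, rng=None):
    """Evolve one CDS for ``duration`` My.

    Returns ``(evolved_cds, synonymous_count, nonsynonymous_count)`` with
    realized (accepted) substitution counts.  ``accel`` multiplies the
    proposal rate, emulating accelerated germline-paralog divergence.
    """
    validate_cds(cds)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    arr = _seq_to_array(cds)
    syn, nonsyn = _evolve_array(arr, duration, config, accel, rng)
    return _array_to_seq(arr), syn, nonsyn


# ---------------------------------------------------------------------------
# the generator proper
# ---------------------------------------------------------------------------


def _simulate_family(fam_id, config, phylogeny, rng, events_out):
    """Evolve one family down the tree; return leaf gene lists per species."""
    uid_counter = itertools.count(1)
    event_counter = itertools.count(1)
    root = _Gene(uid=0, seq=_seq_to_array(random_cds(config.root_len, rng)))
    leaf_genes = {}
    event_branch = {}

    branch_iter = list(phylogeny.preorder_branches())
    children = {lbl: phylogeny.child_branches(lbl) for lbl, _, _ in branch_iter}
    terminal = {lbl: phylogeny.branches[lbl].is_terminal for lbl, _, _ in branch_iter}

    def recurse(label, duration, genes):
        dup_rate = config.branch_dup_rates.get(label, config.dup_rate)
        t = 0.0
        while genes:
            loss_total = config.loss_rate * len(genes)
            total = dup_rate + loss_total
            if total <= 0:
                break
            dt = rng.exponential(1.0 / total)
            if t + dt > duration:
                break
            for g in genes:
                s, n = _evolve_array(g.seq, dt, config, config.accel if g.germline else 1.0, rng)
                g.syn += s
                g.nonsyn += n
            t += dt
            if rng.random() < dup_rate / total:
                parent = genes[int(rng.integers(len(genes)))]
                eid = f"{fam_id}.e{next(event_counter)}"
                new = parent.copy()
                new.uid = next(uid_counter)
                new.germline = parent.germline or (rng.random() < config.germline_prob)
                new.tags = parent.tags + ((eid, 1),)
                parent.tags = parent.tags + ((eid, 0),)
                genes.append(new)
                events_out.append(
                    TruthEvent(
                        family=fam_id,
                        kind="duplication",
                        branch=label,
                        time=t,
                        parent_gene=f"{fam_id}.g{parent.uid}",
                        child_genes=(f"{fam_id}.g{parent.uid}", f"{fam_id}.g{new.uid}"),
                        germline=new.germline and not parent.germline,
                    )
                )
                event_branch[eid] = label
            else:
                victim = genes.pop(int(rng.integers(len(genes))))
                events_out.append(
                    TruthEvent(
                        family=fam_id,
                        kind="loss",
                        branch=label,
                        time=t,
                        parent_gene=f"{fam_id}.g{victim.uid}",
                        child_genes=(),
                    )
                )
        remaining = duration - t
        if remaining > 0:
            for g in genes:
                s, n = _evolve_array(
                    g.seq, remaining, config, config.accel if g.germline else 1.0, rng
                )
                g.syn += s
                g.nonsyn += n
        if terminal[label]:
            (species,) = phylogeny.branches[label].clade
            leaf_genes[species] = genes
        else:
            for child in children[label]:
                recurse(
                    child,
                    phylogeny.branches[child].duration,
                    [g.copy() for g in genes],
                )

    root_label = branch_iter[0][0]
    root_children = children[root_label]
    if not root_children:  # single-species tree: root edge is the terminal
        recurse(root_label, phylogeny.branches[root_label].duration, [root])
    else:
        for child in root_children:
            recurse(child, phylogeny.branches[child].duration, [root.copy()])
    return leaf_genes, event_branch


def emit_truth_codes(events, gene_tags, families, phylogeny, species_order=DEFAULT_SPECIES_ORDER):
    """Per-family six-digit codes from the recorded event history.

    A duplication event is *shown* in a species when both daughter lineages
    left at least one extant descendant there: shown in exactly one species
    sets that species' lineage-specific position (3-6), shown in two or
    more sets the shared position (2).  A family with no shown duplication
    carries the 1:1 orthology code 100000.
    """
    known = set(phylogeny.branches)
    species_order = tuple(species_order)
    tags_by_species = {}
    for fam, per_species in families.items():
        for species, genes in per_species.items():
            for gene in genes:
                for tag in gene_tags[gene]:
                    tags_by_species.setdefault((fam, tag), set()).add(species)
    for event in events:
        if event.branch not in known:
            raise SimulationConfigError(f"event on unknown branch {event.branch!r}")
    codes = {}
    for fam, per_species in families.items():
        flags = [0] * 6
        seen = set()
        for species, genes in per_species.items():
            for gene in genes:
                for eid, _side in gene_tags[gene]:
                    seen.add(eid)
        for eid in sorted(seen):
            shown = {
                sp
                for sp in species_order
                if (fam, (eid, 0)) in tags_by_species
                and (fam, (eid, 1)) in tags_by_species
                and sp in tags_by_species[(fam, (eid, 0))]
                and sp in tags_by_species[(fam, (eid, 1))]
            }
            if len(shown) >= 2:
                flags[1] = 1
            elif len(shown) == 1:
                flags[2 + species_order.index(next(iter(shown)))] = 1
        if not any(flags):
            flags[0] = 1
        codes[fam] = "".join(map(str, flags))
    return codes


def simulate_dataset(
    config: SimConfig,
    phylogeny: SpeciesPhylogeny | None = None,
    species_order=None,
) -> SyntheticDataset:
    """Simulate ``config.n_families`` families on ``phylogeny``.

    Deterministic for a fixed ``(config, phylogeny)``: all randomness flows
    from ``config.seed`` through a single generator.
    """
    if phylogeny is None:
        phylogeny = SpeciesPhylogeny.default_insect()
    if species_order is None:
        species_order = (
            DEFAULT_SPECIES_ORDER
            if set(phylogeny.taxa) == set(DEFAULT_SPECIES_ORDER)
            else tuple(phylogeny.taxa)
        )
    if not phylogeny.taxa:
        raise SimulationConfigError("phylogeny has no taxa")
    rng = np.random.default_rng(config.seed)
    proteins = {sp: {} for sp in phylogeny.taxa}
    cds = {sp: {} for sp in phylogeny.taxa}
    events = []
    families = {}
    germline_genes = set()
    subst_counts = {}
    gene_tags = {}
    event_branches = {}
    for i in range(config.n_families):
        fam_id = f"F{i:04d}"
        leaf_genes, ev_branch = _simulate_family(fam_id, config, phylogeny, rng, events)
        event_branches.update(ev_branch)
        families[fam_id] = {}
        for species in phylogeny.taxa:
            names = []
            for gene in leaf_genes.get(species, []):
                name = f"{species}|{fam_id}.g{gene.uid}"
                seq = _array_to_seq(gene.seq)
                cds[species][name] = seq
                proteins[species][name] = translate(seq)
                subst_counts[name] = (gene.syn, gene.nonsyn)
                gene_tags[name] = gene.tags
                if gene.germline:
                    germline_genes.add(name)
                names.append(name)
            families[fam_id][species] = names
    truth_codes = emit_truth_codes(events, gene_tags, families, phylogeny, species_order)
    gene_codes = {}
    for fam, per_species in families.items():
        for names in per_species.values():
            for name in names:
                gene_codes[name] = truth_codes[fam]
    return SyntheticDataset(
        proteins=proteins,
        cds=cds,
        events=events,
        truth_codes=truth_codes,
        gene_codes=gene_codes,
        event_branches=event_branches,
        families=families,
        germline_genes=germline_genes,
        subst_counts=subst_counts,
        gene_tags=gene_tags,
        config=config,
        species_order=tuple(species_order),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_fasta(records: dict, path) -> None:
    with open(path, "w") as handle:
        for name in sorted(records):
            handle.write(f">{name}\n{records[name]}\n")


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write per-species FASTA files and tab-separated truth tables."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for species in dataset.proteins:
        write_fasta(dataset.proteins[species], os.path.join(outdir, f"{species}.protein.fa"))
        write_fasta(dataset.cds[species], os.path.join(outdir, f"{species}.cds.fa"))
    with open(os.path.join(outdir, "truth_events.tsv"), "w") as handle:
        handle.write("family\tkind\tbranch\ttime_my\tparent_gene\tchild_genes\tgermline\n")
        for ev in dataset.events:
            handle.write(
                f"{ev.family}\t{ev.kind}\t{ev.branch}\t{ev.time:.4f}\t"
                f"{ev.parent_gene}\t{';'.join(ev.child_genes)}\t{int(ev.germline)}\n"
            )
    with open(os.path.join(outdir, "truth_codes.tsv"), "w") as handle:
        handle.write("family\tcode\n")
        for fam in sorted(dataset.truth_codes):
            handle.write(f"{fam}\t{dataset.truth_codes[fam]}\n")
    with open(os.path.join(outdir, "gene_codes.tsv"), "w") as handle:
        handle.write("gene\tcode\n")
        for gene in sorted(dataset.gene_codes):
            handle.write(f"{gene}\t{dataset.gene_codes[gene]}\n")
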