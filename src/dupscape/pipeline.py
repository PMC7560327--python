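"""End-to-end orchestration of the duplication analysis pipeline.

Stages: (optional) simulation -> all-vs-all similarity search -> family
construction and classification -> code validation against truth ->
within-family dS dating -> gene trees with duplication mapping and
asymmetry calls -> expansion spectra, branch rates, parallel-duplication
tallies -> (optional) term enrichment.  Every output is a tab-separated
text file under the configured output directory, and a run manifest
records the seed, thresholds, and a parameter hash so a run can be
regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import classify, divergence, enrich, genetree, homology, summarize
from .simulate import SimConfig, simulate_dataset, write_dataset
from .species_tree import DEFAULT_SPECIES_ORDER, SpeciesPhylogeny

logger = logging.getLogger("dupscape")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    outdir: str = "dupscape_out"
    proteome_dir: str | None = None
    cds_dir: str | None = None
    species_tree: str | None = None  # newick path; default insect tree if None
    annotations: str | None = None
    study_set: str | None = None
    reference_set: str | None = None
    e_cutoff: float = 1.0e-4
    min_species: int = 3
    max_family_size: int = 6
    ds_old_threshold: float = 2.0
    asymmetry_ratio: float = 2.0
    bootstrap: int = 100
    alpha: float = 0.05
    seed: int = 0
    reference: str = "Dmel"
    species_order: tuple = DEFAULT_SPECIES_ORDER
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self):
        for name in ("e_cutoff", "ds_old_threshold", "asymmetry_ratio", "alpha"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"threshold {name} must be positive")
        self.species_order = tuple(self.species_order)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def parameter_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_fasta_dir(directory, suffix) -> dict:
    from Bio import SeqIO

    out = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(suffix):
            continue
        species = name[: -len(suffix)]
        records = {}
        for rec in SeqIO.parse(os.path.join(directory, name), "fasta"):
            records[rec.id] = str(rec.seq)
        out[species] = records
    if not out:
        raise PipelineError(f"no '*{suffix}' files in {directory}")
    return out


def build_family_tree(fam, proteomes, cds_by_gene=None):
    """NJ gene tree for one family's members.

    When every member has a CDS, distances are Jukes-Cantor nucleotide
    distances on the back-translated codon alignment (roughly three times
    as many sites as the protein distance, including the synonymous
    signal); otherwise Kimura protein distances.  Returns ``None`` for
    families with fewer than three members.
    """
    members = {g: proteomes[sp][g] for sp, genes in fam.members.items() for g in genes}
    if len(members) < 3:
        return None
    aligned = genetree.align_proteins(members)
    if cds_by_gene and all(g in cds_by_gene for g in members):
        codon_aln = divergence.backtranslate(aligned, cds_by_gene)
        dm = genetree.nucleotide_distance(codon_aln.sequences)
    else:
        dm = genetree.protein_distance(aligned)
    return genetree.root_tree(genetree.nj_build(dm))


def resolve_family_by_tree(fam, proteomes, cds_by_gene=None, species_order=None):
    """Settle an unresolved family via species overlap on its gene tree."""
    tree = build_family_tree(fam, proteomes, cds_by_gene)
    if tree is None:
        return fam  # too small for a tree; stays unresolved
    return classify.resolve_unresolved(
        fam, tree, species_order or DEFAULT_SPECIES_ORDER
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of result objects and table paths."""
    os.makedirs(config.outdir, exist_ok=True)
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    phylogeny = (
        SpeciesPhylogeny.from_newick(open(config.species_tree).read())
        if config.species_tree
        else SpeciesPhylogeny.default_insect()
    )
    species_order = config.species_order
    if set(species_order) != set(phylogeny.taxa):
        species_order = tuple(phylogeny.taxa)

    # -- input or simulation ------------------------------------------------
    dataset = None
    if config.simulate:
        stage("simulate")
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        dataset = simulate_dataset(sim_cfg, phylogeny, species_order)
        write_dataset(dataset, os.path.join(config.outdir, "simulated"))
        proteomes, cds = dataset.proteins, dataset.cds
    else:
        stage("load")
        if not config.proteome_dir:
            raise PipelineError("stage load: need --proteomes or --simulate")
        proteomes = _load_fasta_dir(config.proteome_dir, ".protein.fa")
        cds = _load_fasta_dir(config.cds_dir, ".cds.fa") if config.cds_dir else {}
    cds_by_gene = {g: s for per in cds.values() for g, s in per.items()}

    # -- similarity search --------------------------------------------------
    stage("homology")
    hits = homology.all_vs_all(proteomes, e_cutoff=config.e_cutoff)
    homology.write_hit_table(hits, os.path.join(config.outdir, "hits.tsv"))
    results["hits"] = hits

    # -- families and classification ---------------------------------------
    stage("classify")
    families = classify.build_families(hits, species_order, config.reference)
    kept = []
    for fam in families:
        if classify.core_filter(fam, config.min_species, config.max_family_size):
            classify.classify_family(fam, species_order)
            kept.append(fam)
    for fam in kept:
        if fam.label == classify.LABEL_UNRESOLVED:
            resolve_family_by_tree(fam, proteomes, cds_by_gene, species_order)
    classify.write_family_table(kept, os.path.join(config.outdir, "families.tsv"), species_order)
    classify.write_gene_codes(kept, os.path.join(config.outdir, "codes.tsv"))
    results["families"] = kept

    # -- validation against simulation truth --------------------------------
    if dataset is not None:
        stage("validate")
        confusion = classify.validate_codes(classify.gene_codes(kept), dataset.gene_codes)
        rows = []
        for pos in range(6):
            rows.append(
                {
                    "position": pos + 1,
                    "TP": confusion.tp[pos],
                    "FP": confusion.fp[pos],
                    "FN": confusion.fn[pos],
                    "TN": confusion.tn[pos],
                    "accuracy": confusion.accuracy(pos),
                    "specificity": confusion.specificity(pos),
                }
            )
        pd.DataFrame(rows).to_csv(
            os.path.join(config.outdir, "validation.tsv"), sep="\t", index=False
        )
        results["validation"] = confusion

    # -- dS dating ----------------------------------------------------------
    stage("ds")
    ds_rows = []
    ds_values = []
    if cds_by_gene:
        for fam in kept:
            expanded = {sp: genes for sp, genes in fam.members.items() if len(genes) >= 2}
            if not expanded:
                continue
            out = divergence.family_ds_summary(fam.family_id, expanded, cds_by_gene)
            if out is None:
                continue
            summary, estimates = out
            for (g1, g2), est in estimates.items():
                ds_values.append(est)
                ds_rows.append(
                    {
                        "family": fam.family_id,
                        "gene1": g1,
                        "gene2": g2,
                        "dS": est.ds,
                        "dN": est.dn,
                        "S": est.syn_sites,
                        "N": est.nonsyn_sites,
                        "saturated": est.saturated,
                    }
                )
        pd.DataFrame(ds_rows).to_csv(os.path.join(config.outdir, "ds.tsv"), sep="\t", index=False)
        if ds_values:
            hist = divergence.ds_histogram(ds_values)
            with open(os.path.join(config.outdir, "ds_histogram.tsv"), "w") as handle:
                handle.write("low\thigh\tcount\n")
                for low, high, count in hist:
                    handle.write(f"{low}\t{high}\t{count}\n")
            results["old_fraction"] = divergence.old_fraction(
                ds_values, config.ds_old_threshold
            )
    results["ds"] = ds_rows

    # -- gene trees, duplication mapping, asymmetry -------------------------
    stage("trees")
    call_rows = []
    branch_counts = {label: 0 for label in phylogeny.branches}
    for fam in kept:
        if "1" not in fam.code[1:]:
            continue
        members = {g: proteomes[sp][g] for sp, genes in fam.members.items() for g in genes}
        if len(members) < 3:
            # two-member family: the duplication branch follows from counts
            for sp, genes in fam.members.items():
                if len(genes) == 2:
                    branch_counts[phylogeny.branch_above({sp})] += 1
                    call_rows.append(
                        {
                            "family": fam.family_id,
                            "node": 0,
                            "branch": phylogeny.branch_above({sp}),
                            "species": sp,
                            "ratio": None,
                            "asymmetric": None,
                        }
                    )
            continue
        tree = build_family_tree(fam, proteomes, cds_by_gene)
        calls = genetree.detect_duplications(tree, rooted=True)
        asym = {c.node_id: c for c in genetree.asymmetry(tree, rooted=True)}
        for call in calls:
            branch = genetree.map_to_species_branch(call, phylogeny)
            branch_counts[branch] += 1
            a = asym.get(call.node_id)
            call_rows.append(
                {
                    "family": fam.family_id,
                    "node": call.node_id,
                    "branch": branch,
                    "species": "+".join(sorted(call.species_a | call.species_b)),
                    "ratio": a.ratio if a else None,
                    "asymmetric": a.asymmetric if a else None,
                }
            )
    calls_df = pd.DataFrame(
        call_rows, columns=["family", "node", "branch", "species", "ratio", "asymmetric"]
    )
    calls_df.to_csv(os.path.join(config.outdir, "duplication_calls.tsv"), sep="\t", index=False)
    results["calls"] = calls_df

    # -- rates, spectra, tallies -------------------------------------------
    stage("summarize")
    # the root edge has no defined duration; its mapped events are reported
    # in the calls table but excluded from branch rates
    branch_labels = sorted(
        b for b in branch_counts if phylogeny.branches[b].duration > 0
    )
    rates = summarize.rate_table(
        [branch_counts[b] for b in branch_labels],
        max(len(kept), 1),
        [phylogeny.branches[b].duration for b in branch_labels],
        branch_labels,
    )
    rates.to_csv(os.path.join(config.outdir, "rates.tsv"), sep="\t", index=False)
    results["rates"] = rates
    spectrum = summarize.expansion_spectrum(kept, species_order, config.reference)
    spectrum.to_csv(os.path.join(config.outdir, "spectrum.tsv"), sep="\t", index=False)
    results["spectrum"] = spectrum
    parallel = calls_df[
        calls_df["species"].isin([sp for sp in species_order if sp != config.reference])
    ]
    if len(parallel):
        tally_input = parallel.rename(columns={"species": "lineage"})[["lineage", "asymmetric"]]
        tally_input = tally_input.assign(asymmetric=tally_input["asymmetric"].fillna(False))
        tally, _ = summarize.parallel_dup_tally(tally_input)
    else:
        tally = pd.DataFrame(columns=["lineage", "families_sampled", "parallel", "asymmetric"])
    tally.to_csv(os.path.join(config.outdir, "parallel_tally.tsv"), sep="\t", index=False)
    results["parallel_tally"] = tally

    # -- enrichment ---------------------------------------------------------
    if config.annotations and config.study_set and config.reference_set:
        stage("enrich")
        annotations = enrich.read_annotations(config.annotations)
        study = [l.strip() for l in open(config.study_set) if l.strip()]
        reference = [l.strip() for l in open(config.reference_set) if l.strip()]
        table = enrich.enrichment_table(study, reference, annotations, config.alpha)
        table.to_csv(os.path.join(config.outdir, "enrichment.tsv"), sep="\t", index=False)
        results["enrichment"] = table

    # -- manifest -----------------------------------------------------------
    stage("manifest")
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "parameters": asdict(config),
        "n_families_total": len(families),
        "n_families_kept": len(kept),
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
    results["manifest"] = manifest
    return results


# ---------------------------------------------------------------------------
# published reference tables
# ---------------------------------------------------------------------------


def reproduce_reference_tables(outdir=None) -> dict:
    """Recompute the published summary arithmetic from packaged counts.

    Emits the lineage expansion totals (percentages and reference/others
    ratio), the energy/development branch-rate table with averages, the
    outgroup-conservation and branch-share percentages, and the germline
    expression summary — each value paired with the printed value and a
    match flag.  Known discrepancy: one lineage's total percentage computes
    to 7.0 from its own counts but was printed as 6.7; the check file flags
    it as a mismatch rather than matching it.
    """
    data = summarize.load_published_counts()
    checks = []

    def check(name, computed, printed):
        checks.append(
            {
                "quantity": name,
                "computed": computed,
                "printed": printed,
                "match": computed == printed,
            }
        )

    totals = data["expansion_totals"]
    species = [sp for sp in totals if sp not in ("printed_percent", "printed_ratio")]
    pct = {sp: summarize.percent(*totals[sp]) for sp in species}
    for sp in species:
        check(f"expansion_total_pct_{sp}", pct[sp], totals["printed_percent"][sp])
    reference = species[0]
    ratio = summarize.ratio_vs_others(pct[reference], [pct[s] for s in species[1:]])
    check("expansion_ratio", ratio, totals["printed_ratio"])

    rates_out = {}
    br = data["branch_rates"]
    for population in ("energy", "development"):
        block = br[population]
        rows = []
        for label, d, t, printed in zip(
            br["branches"], block["duplications"], br["durations_my"], block["printed_rates"]
        ):
            if d is None:
                rows.append({"branch": label, "D": None, "rate": printed, "recomputed": False})
            else:
                rate = summarize.branch_rate(d, block["families"], t)
                rows.append({"branch": label, "D": d, "rate": rate, "recomputed": True})
                check(f"rate_{population}_{label}", rate, printed)
        avg = summarize.round_half_up(sum(r["rate"] for r in rows) / len(rows), 4)
        check(f"rate_{population}_average", avg, float(block["printed_average"]))
        rows.append({"branch": "Average", "D": None, "rate": avg, "recomputed": True})
        rates_out[population] = pd.DataFrame(rows)

    rec = data["outgroup_conservation"]
    check("outgroup_recovered_pct", summarize.percent(*rec["recovered"]), rec["printed_percent"])
    share = data["drosophilid_branch_share"]
    check(
        "drosophilid_branch_pct",
        summarize.percent(*share["on_branch"], ndigits=0),
        float(share["printed_percent"]),
    )

    germ = summarize.germline_family_summary(summarize.load_expression_fixture())
    check("expression_families", germ.families, 18)
    check("expression_families_with_germline", germ.families_with_germline, 18)

    checks_df = pd.DataFrame(checks)
    out = {
        "totals": pd.DataFrame(
            [{"species": sp, "expanded": totals[sp][0], "sampled": totals[sp][1], "pct": pct[sp]}
             for sp in species]
        ),
        "rates_energy": rates_out["energy"],
        "rates_development": rates_out["development"],
        "germline": germ.per_family,
        "checks": checks_df,
    }
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        for name, df in out.items():
            df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    return out
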