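"""Quantitative summaries of a duplication analysis.

Covers the four reporting surfaces of the pipeline: lineage-specific
expansion spectra by post-duplication family size (2-6 members),
branch-level duplicate accumulation rates D/(F*T), germline-bias summaries
of an expression table, and per-lineage parallel-duplication tallies.

All displayed numbers are rounded half-up at the displayed precision
(1 decimal for percentages, 4 decimals for rates); this convention
reproduces published reference values such as 698/5,983 -> 11.7% and
21/(111*35) -> 0.0054.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd
import yaml


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """``count/total`` as a percentage, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# branch rates (duplications per gene family per My)
# ---------------------------------------------------------------------------


def branch_rate(duplications: int, families: int, duration_my: float) -> float:
    """Duplicate accumulation rate D/(F*T), rounded half-up to 4 decimals.

    Parameters
    ----------
    duplications
        Number of duplication events D mapped to the branch.
    families
        Number of gene families F sampled (the normalizing family count).
    duration_my
        Branch duration T in million years.
    """
    if families < 1:
        raise ValueError("family count must be >= 1")
    if duration_my <= 0:
        raise ValueError("branch duration must be > 0 My")
    if duplications < 0:
        raise ValueError("duplication count must be >= 0")
    return round_half_up(duplications / (families * duration_my), 4)


def rate_table(duplications, families: int, durations_my, branch_labels=None) -> pd.DataFrame:
    """Per-branch rate rows plus an ``Average`` row (mean of rounded rates).

    Returns a DataFrame with columns ``branch, D, F, T_my, rate``.  The
    average row carries the arithmetic mean of the per-branch rounded
    rates, itself rounded half-up to 4 decimals.
    """
    duplications = list(duplications)
    durations_my = list(durations_my)
    if len(duplications) != len(durations_my):
        raise ValueError("duplication and duration lists must align")
    if branch_labels is None:
        branch_labels = [f"branch_{i + 1}" for i in range(len(duplications))]
    elif len(branch_labels) != len(duplications):
        raise ValueError("branch label list must align with counts")
    rows = []
    for label, d, t in zip(branch_labels, duplications, durations_my):
        rows.append(
            {"branch": label, "D": d, "F": families, "T_my": t, "rate": branch_rate(d, families, t)}
        )
    mean_rate = round_half_up(sum(r["rate"] for r in rows) / len(rows), 4)
    rows.append({"branch": "Average", "D": None, "F": families, "T_my": None, "rate": mean_rate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expansion spectra
# ---------------------------------------------------------------------------


def ratio_vs_others(reference_pct: float, other_pcts) -> float:
    """Reference-species percentage over the mean of the other species'.

    Computed on percentages (not raw counts); rounded half-up to 1 decimal.
    Returns ``float('nan')`` when the others average to zero.
    """
    other_pcts = list(other_pcts)
    mean_others = sum(other_pcts) / len(other_pcts)
    if mean_others == 0:
        return float("nan")
    return round_half_up(reference_pct / mean_others, 1)


def expansion_spectrum(families, species_order, reference: str) -> pd.DataFrame:
    """Table of lineage-specific expansion percentages by family size class.

    Parameters
    ----------
    families
        Iterable of classified family records (``classify.FamilyRecord``).
        A family counts as expanded in species ``s`` when its duplication
        code flags a lineage-specific duplication in ``s``; its size class
        is the post-duplication member count in ``s`` (classes 2-6).
    species_order
        Species in code-position order.
    reference
        Species for the reference/others ratio column.

    Returns a DataFrame with one row per size class 2-6 plus a ``Total``
    row; per species a percentage column (``<sp>_pct``) and an absolute
    count column (``<sp>_n``), plus the ratio column.
    """
    species_order = list(species_order)
    if reference not in species_order:
        raise ValueError(f"reference {reference!r} not in species order")
    sampled = {s: 0 for s in species_order}
    by_class = {s: {k: 0 for k in range(2, 7)} for s in species_order}
    totals = {s: 0 for s in species_order}
    for fam in families:
        for idx, sp in enumerate(species_order):
            n = fam.counts.get(sp, 0)
            if n >= 1:
                sampled[sp] += 1
            if fam.code[2 + idx] == "1" and n >= 2:
                totals[sp] += 1
                by_class[sp][min(n, 6)] += 1
    for sp in species_order:
        if sampled[sp] == 0:
            raise ValueError(f"no sampled families for species {sp!r}")
    others = [s for s in species_order if s != reference]
    rows = []
    for k in list(range(2, 7)) + ["Total"]:
        row = {"size_class": str(k)}
        for sp in species_order:
            n = totals[sp] if k == "Total" else by_class[sp][k]
            row[f"{sp}_n"] = n
            row[f"{sp}_pct"] = percent(n, sampled[sp])
        row["ratio"] = ratio_vs_others(
            row[f"{reference}_pct"], [row[f"{sp}_pct"] for sp in others]
        )
        row["sampled_" + reference] = sampled[reference]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# germline / long-branch expression summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GermlineSummary:
    families: int
    families_with_germline: int
    per_family: pd.DataFrame


def _flag(value) -> bool:
    """Interpret a table cell as a binary flag; free text is not a flag."""
    return str(value).strip() == "1"


def load_expression_fixture() -> pd.DataFrame:
    """Packaged summary of fly energy-metabolism paralog expression.

    Curated compilation (modENCODE-era expression data) of the 18 expanded
    energy metabolism gene families: paralog identity, cellular
    localization, testis/ovary expression bias, and whether the paralog
    sits on a conspicuously long gene-tree branch.
    """
    ref = resources.files("dupscape.data").joinpath("energy_paralog_expression.tsv")
    with ref.open("r") as handle:
        return pd.read_csv(handle, sep="\t", dtype=str).fillna("")


def germline_family_summary(records: pd.DataFrame) -> GermlineSummary:
    """Per-family paralog, germline-biased, and long-branch counts.

    A paralog is germline-biased when its testis or ovary flag is set.
    Records without a family label are skipped.
    """
    records = records[records["family"].astype(str).str.strip() != ""]
    rows = []
    for family, grp in records.groupby("family", sort=True):
        germ = sum(
            _flag(t) or _flag(o) for t, o in zip(grp["testis_biased"], grp["ovary_biased"])
        )
        rows.append(
            {
                "family": family,
                "paralogs": len(grp),
                "germline_biased": germ,
                "long_branch": sum(_flag(x) for x in grp["long_branch"]),
            }
        )
    per_family = pd.DataFrame(
        rows, columns=["family", "paralogs", "germline_biased", "long_branch"]
    )
    return GermlineSummary(
        families=len(per_family),
        families_with_germline=int((per_family["germline_biased"] >= 1).sum())
        if len(per_family)
        else 0,
        per_family=per_family,
    )


# ---------------------------------------------------------------------------
# parallel duplication tallies
# ---------------------------------------------------------------------------


def parallel_dup_tally(calls: pd.DataFrame, groups: dict | None = None):
    """Per-lineage parallel-duplication tallies and group means.

    Parameters
    ----------
    calls
        DataFrame with columns ``lineage`` (terminal lineage of the
        parallel duplication), ``families_sampled`` (optional, constant per
        lineage) and ``asymmetric`` (bool flag per duplication call).
    groups
        Optional mapping of group name -> list of lineages; group means are
        arithmetic means of the per-lineage asymmetric counts.

    Returns ``(tally, group_means)`` where ``tally`` has one row per
    lineage (parallel and asymmetric counts) and ``group_means`` maps group
    name -> mean asymmetric count (lineages missing from ``calls`` count 0).
    """
    rows = []
    for lineage, grp in calls.groupby("lineage", sort=True):
        rows.append(
            {
                "lineage": lineage,
                "families_sampled": int(grp["families_sampled"].iloc[0])
                if "families_sampled" in grp
                else None,
                "parallel": len(grp),
                "asymmetric": int(grp["asymmetric"].astype(bool).sum()),
            }
        )
    tally = pd.DataFrame(rows, columns=["lineage", "families_sampled", "parallel", "asymmetric"])
    group_means = {}
    if groups:
        by_lineage = dict(zip(tally["lineage"], tally["asymmetric"])) if len(tally) else {}
        for name, members in groups.items():
            vals = [by_lineage.get(m, 0) for m in members]
            group_means[name] = sum(vals) / len(vals)
    return tally, group_means


# ---------------------------------------------------------------------------
# published reference counts
# ---------------------------------------------------------------------------


def load_published_counts() -> dict:
    """Published counts and printed values for the reference comparison."""
    ref = resources.files("dupscape.data").joinpath("published_counts.yaml")
    with ref.open("r") as handle:
        return yaml.safe_load(handle)
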