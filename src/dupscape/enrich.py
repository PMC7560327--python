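"""Hypergeometric over/under-representation of annotation terms.

Tests whether terms (e.g. Gene Ontology biological-process terms) are over-
or under-represented in a study set of duplicated genes relative to a
reference set, with Benjamini-Hochberg FDR control applied separately per
direction (alpha 0.05 by default).  True-path ancestor closure of the
ontology is the caller's responsibility; :func:`close_annotations` ingests
a parent-child edge list for that purpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def hypergeom_tail(k: int, n: int, K: int, N: int, tail: str = "over") -> float:
    """Exact hypergeometric tail probability.

    ``k`` study hits among ``n`` study genes, ``K`` reference hits among
    ``N`` reference genes.  ``tail='over'`` gives P(X >= k),
    ``tail='under'`` gives P(X <= k).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    dist = hypergeom(N, K, n)
    if tail == "over":
        return float(dist.sf(k - 1))
    if tail == "under":
        return float(dist.cdf(k))
    raise ValueError("tail must be 'over' or 'under'")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    study_hits: int
    study_size: int
    ref_hits: int
    ref_size: int
    p_over: float
    p_under: float
    q_over: float
    q_under: float
    relative_abundance: float
    direction: str
    significant: bool


def read_annotations(path) -> dict:
    """Gene -> term-set map from 2-column TSV or GAF 2.x (cols 2 and 5)."""
    annotations: dict = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 5 and fields[4].startswith(("GO:", "DO:")):
                gene, term = fields[1], fields[4]
            else:
                gene, term = fields[0], fields[1]
            annotations.setdefault(gene, set()).add(term)
    return annotations


def close_annotations(annotations: dict, parent_edges) -> dict:
    """Propagate annotations up a term DAG (true-path rule).

    ``parent_edges`` is an iterable of (child_term, parent_term) pairs.
    """
    parents: dict = {}
    for child, parent in parent_edges:
        parents.setdefault(child, set()).add(parent)
    closed = {}
    for gene, terms in annotations.items():
        result = set(terms)
        frontier = list(terms)
        while frontier:
            term = frontier.pop()
            for parent in parents.get(term, ()):
                if parent not in result:
                    result.add(parent)
                    frontier.append(parent)
        closed[gene] = result
    return closed


def enrichment_table(study_genes, reference_genes, annotations: dict, alpha: float = 0.05):
    """Both-tailed hypergeometric term enrichment with per-direction BH FDR.

    The study set must be a subset of the reference set.  The relative
    abundance column is (study term fraction) / (reference term fraction),
    for ratio-style displays where 1 means no shift, >1 over-, <1
    under-representation.
    """
    study = set(study_genes)
    reference = set(reference_genes)
    missing = sorted(study - reference)
    if missing:
        raise ValueError(f"study genes absent from reference: {missing}")
    if not study or not reference:
        raise ValueError("study and reference sets must be non-empty")
    n, N = len(study), len(reference)
    terms: dict = {}
    for gene in reference:
        for term in annotations.get(gene, ()):
            ref_hits, study_hits = terms.get(term, (0, 0))
            terms[term] = (ref_hits + 1, study_hits + (gene in study))
    rows = []
    for term in sorted(terms):
        K, k = terms[term]
        rows.append(
            {
                "term": term,
                "study_hits": k,
                "study_size": n,
                "ref_hits": K,
                "ref_size": N,
                "p_over": hypergeom_tail(k, n, K, N, "over"),
                "p_under": hypergeom_tail(k, n, K, N, "under"),
                "relative_abundance": (k / n) / (K / N),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term",
            "study_hits",
            "study_size",
            "ref_hits",
            "ref_size",
            "p_over",
            "p_under",
            "relative_abundance",
        ],
    )
    if len(table):
        table["q_over"] = bh_adjust(table["p_over"].to_numpy())
        table["q_under"] = bh_adjust(table["p_under"].to_numpy())
    else:
        table["q_over"] = []
        table["q_under"] = []
    table["direction"] = np.where(table["relative_abundance"] >= 1, "over", "under")
    q_directed = np.where(table["direction"] == "over", table["q_over"], table["q_under"])
    table["significant"] = q_directed < alpha
    return table
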