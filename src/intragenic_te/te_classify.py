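"""Classify TEs relative to gene models and summarize host genes.

Categories follow the genome-wide census convention: a TE fully contained
in a (filtered) gene is *intragenic*; a TE with no gene overlap at all is
*intergenic*; a TE partially overlapping, or entirely covering, a gene is
*other*.  Intragenic TEs are subdivided by where they sit in the host gene
body: *intronic* if more than 95% of the TE length lies within introns of
the host's representative (longest) transcript, otherwise *exonic*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from intragenic_te.intervals import GeneModel, GenomicInterval, TERecord
from intragenic_te.stats_core import (
    TestResult,
    bonferroni,
    chisq_contingency_2x2,
    mean_se,
    mwu_test,
)

logger = logging.getLogger(__name__)

INTRONIC_FRACTION_THRESHOLD = 0.95


@dataclass(frozen=True)
class TEClassification:
    te_id: str
    category: str  # intergenic | intragenic | other
    subcategory: str  # intronic | exonic | none
    host_gene_id: str | None
    intronic_fraction: float | None
    te_length: int

    def __post_init__(self) -> None:
        if (self.subcategory != "none") != (self.category == "intragenic"):
            raise ValueError("subcategory defined iff category is intragenic")
        if (self.host_gene_id is not None) != (self.category in {"intragenic", "other"}):
            raise ValueError("host gene present iff intragenic or other")


@dataclass(frozen=True)
class HostGeneSummary:
    gene_id: str
    n_intronic: int
    n_exonic: int
    host_class: str  # only-intronic | only-exonic | both


def _gene_tree(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end + 1, g
        )
    return trees


def _intronic_overlap_bp(te: GenomicInterval, host: GeneModel) -> int:
    """TE bases inside the intron union of the host's representative transcript."""
    return sum(te.overlap_bp(intron) for intron in host.introns())


def classify_intronic(
    te: TERecord, host: GeneModel, threshold: float = INTRONIC_FRACTION_THRESHOLD
) -> tuple[str, float]:
    """Subdivide an intragenic TE into intronic/exonic.

    Intronic iff strictly more than ``threshold`` of the TE length lies
    within the intron set of the host's representative transcript; the
    boundary (exactly the threshold) is exonic.  Returns (subcategory,
    intronic_fraction).
    """
    overlap = _intronic_overlap_bp(te.interval, host)
    fraction = overlap / te.length
    return ("intronic" if fraction > threshold else "exonic"), fraction


def classify_te(
    te: TERecord,
    genes: list[GeneModel],
    trees: dict[str, IntervalTree] | None = None,
    threshold: float = INTRONIC_FRACTION_THRESHOLD,
) -> TEClassification:
    """Assign a TE to intergenic / intragenic / other, with host gene.

    If a TE is contained in several overlapping genes, the gene with the
    smallest span (most specific) hosts it; the ambiguity is logged.  For
    "other" TEs the host is the gene with the largest overlap.
    """
    if trees is None:
        trees = _gene_tree(genes)
    tree = trees.get(te.interval.chrom, IntervalTree())
    overlapping = [
        iv.data for iv in tree.overlap(te.interval.start, te.interval.end + 1)
    ]
    if not overlapping:
        return TEClassification(te.te_id, "intergenic", "none", None, None, te.length)
    containing = [g for g in overlapping if g.interval.contains(te.interval)]
    if containing:
        containing.sort(key=lambda g: (g.interval.length, g.gene_id))
        host = containing[0]
        if len(containing) > 1:
            logger.info(
                "TE %s contained in %d genes; host = smallest span %s",
                te.te_id, len(containing), host.gene_id,
            )
        sub, frac = classify_intronic(te, host, threshold=threshold)
        return TEClassification(te.te_id, "intragenic", sub, host.gene_id, frac, te.length)
    # partial overlap or TE covers a gene
    host = max(
        overlapping,
        key=lambda g: (te.interval.overlap_bp(g.interval), -g.interval.length, g.gene_id),
    )
    return TEClassification(te.te_id, "other", "none", host.gene_id, None, te.length)


def classify_all(
    tes: list[TERecord],
    genes: list[GeneModel],
    threshold: float = INTRONIC_FRACTION_THRESHOLD,
) -> list[TEClassification]:
    trees = _gene_tree(genes)
    return [classify_te(te, genes, trees=trees, threshold=threshold) for te in tes]


def summarize_hosts(classifications: list[TEClassification]) -> list[HostGeneSummary]:
    """Per-host breakdown of intragenic TE content (only-intronic / only-exonic / both)."""
    counts: dict[str, list[int]] = {}
    for c in classifications:
        if c.category != "intragenic":
            continue
        n = counts.setdefault(c.host_gene_id, [0, 0])
        n[0 if c.subcategory == "intronic" else 1] += 1
    out = []
    for gene_id in sorted(counts):
        n_in, n_ex = counts[gene_id]
        if n_in and n_ex:
            cls = "both"
        elif n_in:
            cls = "only-intronic"
        else:
            cls = "only-exonic"
        out.append(HostGeneSummary(gene_id, n_in, n_ex, cls))
    return out


def family_enrichment(
    classifications: list[TEClassification], tes: list[TERecord]
) -> pd.DataFrame:
    """Per-superfamily 2x2 chi-square test of intragenic vs intergenic bias.

    Each superfamily is tested against all others in a 2x2 table
    {this superfamily, rest} x {intragenic, intergenic}; p-values are
    Bonferroni-adjusted by the number of superfamilies tested.  "other"
    category TEs are not part of the contrast.
    """
    cat = {c.te_id: c.category for c in classifications}
    rows = []
    for te in tes:
        if cat.get(te.te_id) in {"intragenic", "intergenic"}:
            rows.append((te.superfamily, cat[te.te_id]))
    df = pd.DataFrame(rows, columns=["superfamily", "category"])
    superfamilies = sorted(df["superfamily"].unique())
    if len(superfamilies) < 2:
        logger.warning("family_enrichment needs >= 2 superfamilies; got %d", len(superfamilies))
        return pd.DataFrame(
            columns=[
                "superfamily", "n_intragenic", "n_intergenic", "chi2",
                "p_value", "p_adjusted", "direction",
            ]
        )
    results = []
    for sf in superfamilies:
        in_sf = df["superfamily"] == sf
        a = int(((df["category"] == "intragenic") & in_sf).sum())
        b = int(((df["category"] == "intergenic") & in_sf).sum())
        c = int(((df["category"] == "intragenic") & ~in_sf).sum())
        d = int(((df["category"] == "intergenic") & ~in_sf).sum())
        if a + b == 0:
            logger.info("superfamily %s has no TEs in the contrast; skipped", sf)
            continue
        if min(a + c, b + d) == 0:
            res = TestResult(0.0, 1.0, "chisq-2x2", a + b + c + d)
        else:
            res = chisq_contingency_2x2([[a, c], [b, d]])
        frac_sf = a / (a + b)
        frac_rest = c / (c + d) if (c + d) else np.nan
        results.append(
            {
                "superfamily": sf,
                "n_intragenic": a,
                "n_intergenic": b,
                "chi2": res.statistic,
                "p_value": res.p_value,
                "direction": "enriched" if frac_sf > frac_rest else "depleted",
            }
        )
    out = pd.DataFrame(results)
    out["p_adjusted"] = bonferroni(out["p_value"].to_numpy(), m=len(out))
    return out[
        ["superfamily", "n_intragenic", "n_intergenic", "chi2", "p_value", "p_adjusted", "direction"]
    ]


def length_comparison(group_a, group_b, long_threshold: int = 1000) -> dict:
    """Compare two groups of TE lengths.

    Returns the two-sided Mann-Whitney U result, mean +/- SE per group,
    and the fraction of TEs equal to or longer than ``long_threshold``
    (default 1 kb) per group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("length_comparison requires non-empty groups")
    test = mwu_test(a, b)
    mean_a, se_a = mean_se(a)
    mean_b, se_b = mean_se(b)
    return {
        "U": test.statistic,
        "p_value": test.p_value,
        "method": test.method,
        "mean_a": mean_a,
        "se_a": se_a,
        "mean_b": mean_b,
        "se_b": se_b,
        "frac_long_a": float((a >= long_threshold).mean()),
        "frac_long_b": float((b >= long_threshold).mean()),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def classifications_to_frame(classifications: list[TEClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "te_id": [c.te_id for c in classifications],
            "category": [c.category for c in classifications],
            "subcategory": [c.subcategory for c in classifications],
            "host_gene_id": [c.host_gene_id for c in classifications],
            "intronic_fraction": [c.intronic_fraction for c in classifications],
            "te_length": [c.te_length for c in classifications],
        }
    )
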