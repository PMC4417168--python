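"""Expression quantification and the downstream-transcription-defect test.

For a gene carrying an intronic TE, exonic reads are split into *pre*
(exons transcriptionally upstream of the TE-containing intron) and *post*
(exons downstream of it), strand-aware.  A mutant genotype is compared to
wild type with a two-sided Fisher's exact test on the 2x2 table
[[pre_wt, post_wt], [pre_mut, post_mut]]; after Benjamini-Hochberg
correction across all tested genes of that genotype, a gene is labeled
'D' (Defect) iff q <= 0.01 and the post/pre ratio dropped relative to
wild type, and 'ND' otherwise.  Genes failing the >=10-read filters
(pre and post in wild type, pre in the mutant) are not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from intragenic_te.intervals import GeneModel
from intragenic_te.stats_core import bh_correct, fisher_exact_2x2, mean_se, mwu_test
from intragenic_te.te_classify import TEClassification

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 10
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class RegionCounts:
    """Pre/post-TE exonic read counts for one (gene, TE, genotype)."""

    gene_id: str
    te_id: str
    genotype: str
    pre_count: int
    post_count: int
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.pre_count < 0 or self.post_count < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class DefectResult:
    gene_id: str
    te_id: str
    genotype: str
    pre_wt: int
    post_wt: int
    pre_mut: int
    post_mut: int
    ratio_change: float
    p_value: float
    q_value: float
    label: str  # D | ND | filtered


def compute_rpkm(counts: float, exon_length: int, total_mapped: int) -> tuple[float, float]:
    """RPKM = counts / (exon_length/1e3 * total_mapped/1e6), plus log2(RPKM+1)."""
    if exon_length <= 0:
        raise ValueError("exon model length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    rpkm = counts / (exon_length / 1e3 * total_mapped / 1e6)
    return rpkm, float(np.log2(rpkm + 1.0))


def expression_group_comparison(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided MWU on log2(RPKM+1) between named gene sets."""
    names = list(groups)
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"gene set {name!r} is empty")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            test = mwu_test(groups[a], groups[b])
            ma, sa = mean_se(groups[a])
            mb, sb = mean_se(groups[b])
            rows.append(
                {
                    "group_a": a, "group_b": b, "U": test.statistic,
                    "p_value": test.p_value, "mean_a": ma, "se_a": sa,
                    "mean_b": mb, "se_b": sb, "n_a": test.n_a, "n_b": test.n_b,
                }
            )
    return pd.DataFrame(rows)


def te_containing_intron_index(gene: GeneModel, te_interval) -> int:
    """Index (genomic order) of the representative-transcript intron holding the TE.

    The intron with the largest overlap wins; raises if the TE overlaps no
    intron at all.  Accepts a bare interval or any record with an
    ``interval`` attribute.
    """
    te_interval = getattr(te_interval, "interval", te_interval)
    introns = gene.introns()
    overlaps = [te_interval.overlap_bp(intron) for intron in introns]
    if not overlaps or max(overlaps) == 0:
        raise ValueError(
            f"TE at {te_interval.chrom}:{te_interval.start}-{te_interval.end} lies in "
            f"no intron of {gene.gene_id} ({gene.longest_transcript_id})"
        )
    return int(np.argmax(overlaps))


def split_pre_post(
    gene: GeneModel,
    te: TEClassification,
    exon_counts: list[int],
    te_interval=None,
    genotype: str = "wild-type",
    total_mapped: int = 0,
    intron_index: int | None = None,
) -> RegionCounts:
    """Split per-exon counts into pre/post relative to the TE-containing intron.

    ``exon_counts`` are in genomic exon order of the representative
    transcript.  Pre/post follow transcription: on the minus strand the
    genomically downstream exons are *pre*.
    """
    exons = gene.exons()
    if len(exon_counts) != len(exons):
        raise ValueError(
            f"{gene.gene_id}: {len(exon_counts)} counts for {len(exons)} exons"
        )
    if intron_index is None:
        if te_interval is None:
            raise ValueError("need te_interval or intron_index")
        intron_index = te_containing_intron_index(
            gene, getattr(te_interval, "interval", te_interval)
        )
    # intron i (genomic order) separates exons 0..i from exons i+1..
    upstream_genomic = sum(exon_counts[: intron_index + 1])
    downstream_genomic = sum(exon_counts[intron_index + 1:])
    if gene.strand == "-":
        pre, post = downstream_genomic, upstream_genomic
    else:
        pre, post = upstream_genomic, downstream_genomic
    return RegionCounts(
        gene_id=gene.gene_id,
        te_id=te.te_id,
        genotype=genotype,
        pre_count=int(pre),
        post_count=int(post),
        total_mapped=total_mapped,
    )


def defect_test(
    wt: RegionCounts, mut: RegionCounts, min_reads: int = DEFAULT_MIN_READS
) -> DefectResult:
    """Fisher's exact test of one (gene, TE) pair; q-value filled in later.

    Filtered unless pre and post wild-type counts and the mutant pre count
    are all >= ``min_reads``.  ratio_change = (post/pre)_mut / (post/pre)_wt.
    """
    if (wt.gene_id, wt.te_id) != (mut.gene_id, mut.te_id):
        raise ValueError("wild-type and mutant counts refer to different (gene, TE)")
    passed = (
        wt.pre_count >= min_reads
        and wt.post_count >= min_reads
        and mut.pre_count >= min_reads
    )
    if not passed:
        return DefectResult(
            wt.gene_id, wt.te_id, mut.genotype,
            wt.pre_count, wt.post_count, mut.pre_count, mut.post_count,
            np.nan, np.nan, np.nan, "filtered",
        )
    ratio_wt = wt.post_count / wt.pre_count
    ratio_mut = mut.post_count / mut.pre_count
    ratio_change = ratio_mut / ratio_wt if ratio_wt > 0 else np.inf
    p = fisher_exact_2x2(
        [[wt.pre_count, wt.post_count], [mut.pre_count, mut.post_count]]
    ).p_value
    return DefectResult(
        wt.gene_id, wt.te_id, mut.genotype,
        wt.pre_count, wt.post_count, mut.pre_count, mut.post_count,
        float(ratio_change), float(p), np.nan, "ND",
    )


def call_defects(
    pairs: list[tuple[RegionCounts, RegionCounts]],
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
) -> list[DefectResult]:
    """Run the defect test for one genotype and apply BH across tested genes.

    Label 'D' iff the BH-adjusted p <= ``alpha`` and the post/pre ratio
    decreased relative to wild type (ratio_change < 1); 'ND' otherwise;
    'filtered' records keep NaN p/q.
    """
    results = [defect_test(wt, mut, min_reads=min_reads) for wt, mut in pairs]
    tested = [r for r in results if r.label != "filtered"]
    if tested:
        qs = bh_correct([r.p_value for r in tested])
        for r, q in zip(tested, qs):
            r.q_value = float(q)
            r.label = "D" if (q <= alpha and r.ratio_change < 1.0) else "ND"
    return results


def defects_to_frame(results: list[DefectResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "te_id": [r.te_id for r in results],
            "genotype": [r.genotype for r in results],
            "pre_wt": [r.pre_wt for r in results],
            "post_wt": [r.post_wt for r in results],
            "pre_mut": [r.pre_mut for r in results],
            "post_mut": [r.post_mut for r in results],
            "ratio_change": [r.ratio_change for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "label": [r.label for r in results],
        }
    )


def dedup_representative_te(
    defects: pd.DataFrame, te_lengths: dict[str, int], wt_chg: dict[str, float]
) -> pd.DataFrame:
    """Keep one representative TE per gene: the longest, ties broken by the
    most CHG-methylated in wild type."""
    def rank(row):
        return (
            te_lengths.get(row.te_id, 0),
            wt_chg.get(row.te_id, float("-inf")),
        )

    keep_idx = []
    for _, sub in defects.groupby(["gene_id", "genotype"], sort=False):
        best = max(sub.itertuples(), key=rank)
        keep_idx.append(best.Index)
    return defects.loc[sorted(keep_idx)].reset_index(drop=True)


def defect_methylation_association(
    defects: pd.DataFrame,
    chg_deltas: pd.DataFrame,
    dedup: bool = False,
    te_lengths: dict[str, int] | None = None,
    wt_chg: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-genotype MWU comparing CHG methylation change between D and ND genes.

    ``chg_deltas`` must have columns te_id, genotype, abs_delta_CHG.  With
    ``dedup`` only one representative TE per gene is kept (longest; ties ->
    most wild-type CHG methylation).  Genotypes with fewer than 2 TEs in
    either group are skipped with a log entry.
    """
    df = defects[defects["label"].isin(["D", "ND"])].merge(
        chg_deltas[["te_id", "genotype", "abs_delta_CHG"]],
        on=["te_id", "genotype"],
        how="inner",
    )
    if dedup:
        df = dedup_representative_te(df, te_lengths or {}, wt_chg or {})
    rows = []
    for genotype, sub in df.groupby("genotype", sort=True):
        d = sub.loc[sub["label"] == "D", "abs_delta_CHG"].dropna().to_numpy()
        nd = sub.loc[sub["label"] == "ND", "abs_delta_CHG"].dropna().to_numpy()
        if len(d) < 2 or len(nd) < 2:
            logger.info(
                "genotype %s skipped in association test (D=%d, ND=%d)",
                genotype, len(d), len(nd),
            )
            continue
        test = mwu_test(d, nd)
        md, sd = mean_se(d)
        mnd, snd = mean_se(nd)
        rows.append(
            {
                "genotype": genotype, "n_D": len(d), "n_ND": len(nd),
                "mean_delta_D": md, "se_D": sd,
                "mean_delta_ND": mnd, "se_ND": snd,
                "U": test.statistic, "p_value": test.p_value,
            }
        )
    return pd.DataFrame(rows)


def te_expression(
    te_counts: dict[str, dict[str, int]],
    te_lengths: dict[str, int],
    library_sizes: dict[str, int],
    wild_type: str = "wild-type",
) -> pd.DataFrame:
    """Per-TE RPKM across genotypes with mutant/wild-type fold change.

    Fold change uses a pseudocount of 1 on RPKM so unexpressed TEs give a
    fold change of 1.
    """
    rows = []
    genotypes = sorted(library_sizes)
    for te_id, length in te_lengths.items():
        if length <= 0:
            raise ValueError(f"TE {te_id} has non-positive length")
        row: dict = {"te_id": te_id, "length": length}
        for g in genotypes:
            counts = te_counts.get(g, {}).get(te_id, 0)
            rpkm, _ = compute_rpkm(counts, length, library_sizes[g])
            row[f"rpkm_{g}"] = rpkm
        for g in genotypes:
            if g == wild_type:
                continue
            row[f"fold_{g}"] = (row[f"rpkm_{g}"] + 1.0) / (row[f"rpkm_{wild_type}"] + 1.0)
        rows.append(row)
    return pd.DataFrame(rows)
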