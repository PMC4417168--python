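"""End-to-end orchestration and the summary report.

``run_pipeline`` wires the stages together on a directory of inputs (as
written by the synthetic-data generator or assembled from real files):
TE-set reconciliation, classification, per-genotype methylation,
downstream-transcription-defect calling, and Nei-Gojobori group
comparison.  The report stores counts; percentages are always recomputed
from the stored counts, never carried independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from intragenic_te import annotations, expression, methylation, popgen, te_classify

logger = logging.getLogger(__name__)


def percentage(count: float, total: float, decimals: int = 0) -> float:
    """100 * count / total, rounded half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("percentage undefined for non-positive total")
    value = Decimal(100 * count) / Decimal(total)
    quant = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quant, rounding=ROUND_HALF_UP))


@dataclass
class PipelineReport:
    """Aggregated pipeline outcome; percentages derive from counts on demand."""

    te_counts: dict = field(default_factory=dict)        # category -> n
    sub_counts: dict = field(default_factory=dict)       # subcategory -> n
    host_classes: dict = field(default_factory=dict)     # host class -> n
    meth_group_means: dict = field(default_factory=dict) # (class, context) -> mean
    defect_counts: dict = field(default_factory=dict)    # genotype -> {D, ND, filtered}
    popgen_summary: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    seed: int | None = None

    def te_percentages(self, decimals: int = 0) -> dict:
        total = sum(self.te_counts.values())
        return {k: percentage(v, total, decimals) for k, v in self.te_counts.items()}

    def sub_percentages(self, decimals: int = 0) -> dict:
        total = sum(self.sub_counts.values())
        return {k: percentage(v, total, decimals) for k, v in self.sub_counts.items()}

    def to_text(self) -> str:
        lines = ["intragenic-TE pipeline report", "=" * 30]
        if self.seed is not None:
            lines.append(f"seed: {self.seed}")
        total = sum(self.te_counts.values())
        if total:
            lines.append(f"TE set: {total} TEs")
            for cat in ("intergenic", "intragenic", "other"):
                n = self.te_counts.get(cat, 0)
                lines.append(f"  {cat}: {n} ({percentage(n, total):g}%)")
        sub_total = sum(self.sub_counts.values())
        if sub_total:
            for sub in ("intronic", "exonic"):
                n = self.sub_counts.get(sub, 0)
                lines.append(f"  {sub}: {n} ({percentage(n, sub_total):g}%)")
        if self.host_classes:
            host_total = sum(self.host_classes.values())
            lines.append(f"host genes: {host_total}")
            for cls, n in sorted(self.host_classes.items()):
                lines.append(f"  {cls}: {n} ({percentage(n, host_total, 1):g}%)")
        for genotype, counts in sorted(self.defect_counts.items()):
            lines.append(
                f"defects[{genotype}]: D={counts.get('D', 0)} ND={counts.get('ND', 0)} "
                f"filtered={counts.get('filtered', 0)}"
            )
        if self.popgen_summary:
            ps = self.popgen_summary
            lines.append(
                "piN/piS: "
                f"{ps.get('group_a', '?')}={ps.get('mean_a', float('nan')):.3f} vs "
                f"{ps.get('group_b', '?')}={ps.get('mean_b', float('nan')):.3f} "
                f"(permutation p={ps.get('p_value', float('nan')):.4f})"
            )
        if self.thresholds:
            lines.append("thresholds: " + json.dumps(self.thresholds, sort_keys=True))
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.txt").write_text(self.to_text())
        rows = []
        for cat, n in self.te_counts.items():
            rows.append({"section": "te_category", "key": cat, "value": n})
        for sub, n in self.sub_counts.items():
            rows.append({"section": "te_subcategory", "key": sub, "value": n})
        for cls, n in self.host_classes.items():
            rows.append({"section": "host_class", "key": cls, "value": n})
        for genotype, counts in self.defect_counts.items():
            for label, n in counts.items():
                rows.append({"section": f"defect_{genotype}", "key": label, "value": n})
        for key, value in self.popgen_summary.items():
            rows.append({"section": "popgen", "key": key, "value": value})
        pd.DataFrame(rows).to_csv(outdir / "report.tsv", sep="\t", index=False)


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    seed: int = 1,
    min_cov: int = 3,
    alpha: float = 0.01,
    min_reads: int = 10,
    n_perm: int = 10_000,
    stages: tuple[str, ...] = ("te-set", "classify", "methylation", "defect", "popgen"),
) -> PipelineReport:
    """Run the requested stages on a directory of pipeline inputs.

    Expects the file layout written by :func:`intragenic_te.synthetic_data.simulate_all`:
    ``genes.gff3``, ``tes.gff3``, ``rm.out``, ``meth_<genotype>.tsv``,
    ``counts_<genotype>.tsv``, ``library_sizes.tsv``, ``alignments/*.fa``
    and ``popgen_groups.tsv``.  Stage artifacts are written to
    ``output_dir``; the returned report aggregates counts and summaries.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(seed=seed)
    report.thresholds = {
        "max_gap": 50, "min_te_len": 50, "min_hit_len": 100, "min_coverage": 0.70,
        "min_overlap": 1, "intronic_threshold": 0.95, "min_site_coverage": min_cov,
        "high_chg_threshold": 0.20, "min_reads": min_reads, "alpha": alpha,
        "min_syn_sites": 100, "n_perm": n_perm,
    }

    required = {
        "te-set": ["tes.gff3", "rm.out"],
        "classify": ["genes.gff3"],
        "methylation": ["meth_wild-type.tsv"],
        "defect": ["counts_wild-type.tsv"],
        "popgen": ["alignments", "popgen_groups.tsv"],
    }
    for stage in stages:
        for fname in required.get(stage, []):
            if not (input_dir / fname).exists():
                raise FileNotFoundError(
                    f"stage {stage!r} requires missing input {input_dir / fname}"
                )

    te_set = None
    if "te-set" in stages:
        raw = annotations.read_te_gff3(input_dir / "tes.gff3")
        hits = annotations.parse_repeatmasker_out(input_dir / "rm.out")
        te_set = annotations.build_te_set(raw, hits)
        annotations.write_te_set(
            te_set, output_dir / "te_set.tsv", output_dir / "te_set.gff3"
        )

    genes = classifications = None
    if "classify" in stages:
        if te_set is None:
            te_set = annotations.read_te_tsv(input_dir / "te_set.tsv")
        genes = annotations.filter_genes(annotations.read_gff3_genes(input_dir / "genes.gff3"))
        classifications = te_classify.classify_all(te_set, genes)
        cdf = te_classify.classifications_to_frame(classifications)
        cdf.to_csv(output_dir / "classifications.tsv", sep="\t", index=False)
        report.te_counts = cdf["category"].value_counts().to_dict()
        report.sub_counts = (
            cdf.loc[cdf["category"] == "intragenic", "subcategory"].value_counts().to_dict()
        )
        hosts = te_classify.summarize_hosts(classifications)
        report.host_classes = (
            pd.Series([h.host_class for h in hosts]).value_counts().to_dict()
        )
        pd.DataFrame(
            {
                "gene_id": [h.gene_id for h in hosts],
                "n_intronic": [h.n_intronic for h in hosts],
                "n_exonic": [h.n_exonic for h in hosts],
                "host_class": [h.host_class for h in hosts],
            }
        ).to_csv(output_dir / "host_summary.tsv", sep="\t", index=False)
        enr = te_classify.family_enrichment(classifications, te_set)
        enr.to_csv(output_dir / "family_enrichment.tsv", sep="\t", index=False)

    meth_tables: dict[str, pd.DataFrame] = {}
    if "methylation" in stages:
        if te_set is None:
            te_set = annotations.read_te_tsv(input_dir / "te_set.tsv")
        for report_path in sorted(input_dir.glob("meth_*.tsv")):
            genotype = report_path.stem[len("meth_"):]
            calls = methylation.read_cytosine_report(report_path)
            meth_tables[genotype] = methylation.te_methylation_table(
                calls, te_set, genotype=genotype, min_coverage=min_cov
            )
        wt = methylation.add_methylation_classes(meth_tables["wild-type"])
        meth_tables["wild-type"] = wt
        combined = pd.concat(meth_tables.values(), ignore_index=True)
        combined.to_csv(output_dir / "te_methylation.tsv", sep="\t", index=False)
        for cls in ("high", "low"):
            sub = wt[wt["meth_class"] == cls]
            for context in methylation.CONTEXTS:
                vals = sub[f"level_{context}"].dropna()
                if len(vals):
                    report.meth_group_means[f"{cls}_{context}"] = float(vals.mean())

    defects_df = None
    if "defect" in stages and classifications is not None:
        exon_counts = {
            p.stem[len("counts_"):]: pd.read_csv(p, sep="\t")
            for p in sorted(input_dir.glob("counts_*.tsv"))
        }
        te_by_id = {t.te_id: t for t in te_set}
        gene_by_id = {g.gene_id: g for g in genes}
        all_results = []
        for genotype in sorted(exon_counts):
            if genotype == "wild-type":
                continue
            pairs = []
            for c in classifications:
                if c.subcategory != "intronic":
                    continue
                gene = gene_by_id[c.host_gene_id]
                try:
                    intron_index = expression.te_containing_intron_index(
                        gene, te_by_id[c.te_id].interval
                    )
                except ValueError:
                    continue
                def counts_of(gt):
                    df = exon_counts[gt]
                    sub = df[df["gene_id"] == gene.gene_id].sort_values("exon_index")
                    return sub["count"].tolist()
                wt_counts, mut_counts = counts_of("wild-type"), counts_of(genotype)
                if len(wt_counts) != len(gene.exons()):
                    continue
                wt = expression.split_pre_post(
                    gene, c, wt_counts, genotype="wild-type", intron_index=intron_index
                )
                mut = expression.split_pre_post(
                    gene, c, mut_counts, genotype=genotype, intron_index=intron_index
                )
                pairs.append((wt, mut))
            results = expression.call_defects(pairs, min_reads=min_reads, alpha=alpha)
            all_results.extend(results)
            report.defect_counts[genotype] = (
                pd.Series([r.label for r in results]).value_counts().to_dict()
            )
        defects_df = expression.defects_to_frame(all_results)
        defects_df.to_csv(output_dir / "defects.tsv", sep="\t", index=False)

    if "popgen" in stages:
        groups = pd.read_csv(input_dir / "popgen_groups.tsv", sep="\t")
        results = []
        for fasta in sorted((input_dir / "alignments").glob("*.fa")):
            aln = popgen.read_codon_alignment(fasta)
            res = popgen.gene_diversity(aln)
            if res is not None:
                results.append(res)
        div = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in results],
                "syn_sites": [r.syn_sites for r in results],
                "nonsyn_sites": [r.nonsyn_sites for r in results],
                "pi_S": [r.pi_S for r in results],
                "pi_N": [r.pi_N for r in results],
                "ratio": [r.ratio for r in results],
                "n_codons_used": [r.n_codons_used for r in results],
            }
        )
        div = div.merge(groups[["gene_id", "group"]], on="gene_id", how="left")
        div.to_csv(output_dir / "diversity.tsv", sep="\t", index=False)
        usable = div.dropna(subset=["ratio"])
        group_names = sorted(usable["group"].dropna().unique())
        if len(group_names) == 2:
            a = usable.loc[usable["group"] == group_names[0], "ratio"].to_numpy()
            b = usable.loc[usable["group"] == group_names[1], "ratio"].to_numpy()
            if len(a) and len(b):
                mean_a, mean_b, p = popgen.group_permutation_test(
                    a, b, n_perm=n_perm, seed=seed
                )
                report.popgen_summary = {
                    "group_a": group_names[0], "group_b": group_names[1],
                    "mean_a": mean_a, "mean_b": mean_b, "p_value": p,
                    "n_a": int(len(a)), "n_b": int(len(b)),
                    "n_excluded_pi_s_zero": int(len(div) - len(usable)),
                }

    report.write(output_dir)
    return report
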