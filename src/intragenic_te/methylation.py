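"""Per-TE DNA methylation from per-cytosine bisulfite calls.

Methylation is the coverage-weighted ratio #C / (#C + #T) pooled over all
qualifying cytosines of a TE in one sequence context (CG, CHG or CHH),
both strands pooled.  Sites covered by fewer than ``min_coverage`` reads
(default 3) are excluded.  TEs are classed high/low methylated from the
wild-type CHG level at a 20% threshold; mutant genotypes are always
compared against the wild-type class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from intragenic_te.intervals import TERecord
from intragenic_te.stats_core import mean_se, mwu_test

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
HIGH_CHG_THRESHOLD = 0.20
DEFAULT_MIN_COVERAGE = 3

REPORT_COLUMNS = [
    "chrom", "position", "strand", "count_methylated", "count_unmethylated",
    "context", "trinucleotide",
]


@dataclass
class TEMethylation:
    te_id: str
    genotype: str
    levels: dict[str, float | None] = field(default_factory=dict)
    covered_sites: dict[str, int] = field(default_factory=dict)
    meth_class: str = "undefined"  # high | low | undefined

    def level(self, context: str) -> float | None:
        return self.levels.get(context)


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a per-cytosine call table (Bismark CX-report dialect).

    Tab-separated columns: chrom, position (1-based), strand, methylated
    count, unmethylated count, context (CG/CHG/CHH), trinucleotide.
    Out-of-order positions are re-sorted with a warning.
    """
    df = pd.read_csv(
        path, sep="\t", names=REPORT_COLUMNS, header=None, comment="#",
        dtype={"chrom": str, "context": str, "trinucleotide": str},
    )
    if df.empty:
        return df
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(
            f"{path}: unknown methylation context(s): {sorted(df.loc[bad, 'context'].unique())}"
        )
    for col in ("position", "count_methylated", "count_unmethylated"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise ValueError(f"{path}: non-integer values in column {col}")
    if (df.groupby("chrom", sort=False)["position"].diff().dropna() < 0).any():
        logger.warning("%s: positions out of order; re-sorting", path)
        df = df.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)
    return df


def te_methylation(
    calls: pd.DataFrame,
    te: TERecord,
    genotype: str = "wild-type",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> TEMethylation:
    """Per-context methylation of one TE (see :func:`te_methylation_table`)."""
    table = te_methylation_table(calls, [te], genotype=genotype, min_coverage=min_coverage)
    row = table.iloc[0]
    levels = {c: (None if pd.isna(row[f"level_{c}"]) else float(row[f"level_{c}"])) for c in CONTEXTS}
    sites = {c: int(row[f"sites_{c}"]) for c in CONTEXTS}
    return TEMethylation(te.te_id, genotype, levels, sites)


def te_methylation_table(
    calls: pd.DataFrame,
    tes: list[TERecord],
    genotype: str = "wild-type",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Coverage-weighted per-context methylation level for every TE.

    Per context: level = sum(methylated) / sum(coverage) over cytosines
    inside the TE with coverage >= ``min_coverage``, both strands pooled;
    NaN when no site qualifies.
    """
    records = []
    if calls.empty:
        grouped = {}
    else:
        cov = calls["count_methylated"] + calls["count_unmethylated"]
        usable = calls[cov >= min_coverage].copy()
        usable["coverage"] = (
            usable["count_methylated"] + usable["count_unmethylated"]
        )
        grouped = {chrom: sub for chrom, sub in usable.groupby("chrom", sort=False)}
    for te in tes:
        row: dict = {"te_id": te.te_id, "genotype": genotype}
        sub = grouped.get(te.interval.chrom)
        if sub is not None:
            inside = sub[
                (sub["position"] >= te.interval.start)
                & (sub["position"] <= te.interval.end)
            ]
        else:
            inside = None
        for context in CONTEXTS:
            if inside is None or inside.empty:
                row[f"level_{context}"] = np.nan
                row[f"sites_{context}"] = 0
                continue
            ctx = inside[inside["context"] == context]
            total_cov = int(ctx["coverage"].sum())
            row[f"sites_{context}"] = int(len(ctx))
            row[f"level_{context}"] = (
                float(ctx["count_methylated"].sum()) / total_cov if total_cov else np.nan
            )
        records.append(row)
    return pd.DataFrame.from_records(records)


def classify_methylation(
    wt_level_chg: float | None, threshold: float = HIGH_CHG_THRESHOLD
) -> str:
    """high iff wild-type CHG level >= threshold (default 20%), low otherwise."""
    if wt_level_chg is None or (isinstance(wt_level_chg, float) and np.isnan(wt_level_chg)):
        return "undefined"
    return "high" if wt_level_chg >= threshold else "low"


def add_methylation_classes(wt_table: pd.DataFrame) -> pd.DataFrame:
    out = wt_table.copy()
    out["meth_class"] = [classify_methylation(v) for v in out["level_CHG"]]
    return out


def methylation_delta(wt_table: pd.DataFrame, mut_table: pd.DataFrame) -> pd.DataFrame:
    """Per-TE per-context methylation change of a mutant against wild-type.

    absolute = mut - wt; relative = (mut - wt)/wt when wt > 0, else NaN.
    """
    if set(wt_table["te_id"]) != set(mut_table["te_id"]):
        raise ValueError("wild-type and mutant tables cover different TEs")
    wt = wt_table.set_index("te_id")
    mut = mut_table.set_index("te_id").loc[wt.index]
    out = pd.DataFrame(index=wt.index)
    out["genotype"] = mut["genotype"].iloc[0] if len(mut) else None
    for context in CONTEXTS:
        w = wt[f"level_{context}"].astype(float)
        m = mut[f"level_{context}"].astype(float)
        out[f"abs_delta_{context}"] = m - w
        out[f"rel_delta_{context}"] = np.where(w > 0, (m - w) / w, np.nan)
    return out.reset_index()


def methylation_matrix(
    tables: dict[str, pd.DataFrame], context: str
) -> pd.DataFrame:
    """TE x genotype matrix of levels in one context (heatmap-style export)."""
    cols = {}
    for genotype, table in tables.items():
        cols[genotype] = table.set_index("te_id")[f"level_{context}"]
    return pd.DataFrame(cols)


def group_methylation_comparison(group_a, group_b, context: str = "CHG") -> dict:
    """Two-sided MWU on per-TE levels of two groups, with mean +/- SE.

    TEs lacking methylation (undefined level or exactly 0) are excluded
    before the comparison, mirroring how group displays are constructed;
    raw tables keep zeros.
    """
    def clean(x):
        arr = np.asarray(x, dtype=float)
        return arr[~np.isnan(arr) & (arr > 0)]

    a, b = clean(group_a), clean(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"group comparison in context {context}: a group is empty after "
            "excluding TEs lacking methylation"
        )
    test = mwu_test(a, b)
    mean_a, se_a = mean_se(a)
    mean_b, se_b = mean_se(b)
    return {
        "context": context,
        "U": test.statistic,
        "p_value": test.p_value,
        "mean_a": mean_a,
        "se_a": se_a,
        "mean_b": mean_b,
        "se_b": se_b,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
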