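"""Synthetic pipeline inputs with recorded ground truth.

Generates, from a single seeded configuration, every input the pipeline
consumes: a gene annotation (GFF3) with multi-exon genes and alternative
isoforms, a TE annotation with planted intergenic / intronic / exonic /
boundary-spanning placements (some emitted as split fragments to exercise
merging, plus sub-50-bp decoys to exercise the length filter), a
RepeatMasker-style ``.out`` file supporting a configurable subset of TEs
(plus junk hits the screen must remove), per-genotype cytosine reports
with class- and genotype-specific methylation means, per-exon RNA-seq
count tables with planted downstream-transcription defects, and per-gene
multi-accession codon alignments with target synonymous / nonsynonymous
diversity plus injected missing data, premature stops and multi-allelic
columns.

Default sizes mirror the genome-wide study conditions at reduced scale:
TE category fractions 88% intergenic / 3% intragenic / 9% other with 85%
of intragenic TEs intronic, a high/low CHG methylation split at 20%,
coverage ~30x bisulfite depth, and an 80-accession polymorphism panel.
All randomness flows through one integer-seeded generator; the same seed
reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from intragenic_te.intervals import GeneModel, GenomicInterval, TERecord
from intragenic_te.popgen import (
    BASES,
    CODONS,
    GENETIC_CODE,
    STOP_CODONS,
    CodonAlignment,
    ng86_sites,
)

SUPERFAMILY_WEIGHTS = {
    "Gypsy": 0.22,
    "Copia": 0.15,
    "LINE": 0.10,
    "SINE": 0.05,
    "MuDR": 0.15,
    "CACTA": 0.08,
    "Helitron": 0.12,
    "Mariner": 0.05,
    "HAT": 0.08,
}

RM_CLASS = {
    "Gypsy": "LTR/Gypsy",
    "Copia": "LTR/Copia",
    "LINE": "LINE/L1",
    "SINE": "SINE/tRNA",
    "MuDR": "DNA/MuDR",
    "CACTA": "DNA/CACTA",
    "Helitron": "RC/Helitron",
    "Mariner": "DNA/Mariner",
    "HAT": "DNA/hAT",
}

#: wild-type methylation means per (meth class, context)
WT_METH_MEANS = {
    ("high", "CG"): 0.85,
    ("high", "CHG"): 0.40,
    ("high", "CHH"): 0.10,
    ("low", "CG"): 0.30,
    ("low", "CHG"): 0.05,
    ("low", "CHH"): 0.02,
}

#: per-genotype multiplicative methylation loss factors by context,
#: mimicking the known pathway dependencies (CG maintenance by MET1/DDM1,
#: CHG by CMT3/KYP/SUVH5-6, CHH by RdDM/CMT2)
GENOTYPE_LOSS = {
    "wild-type": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
    "met1": {"CG": 0.05, "CHG": 0.7, "CHH": 0.8},
    "cmt3": {"CG": 1.0, "CHG": 0.10, "CHH": 0.9},
    "ddm1": {"CG": 0.30, "CHG": 0.40, "CHH": 0.5},
    "kyp": {"CG": 1.0, "CHG": 0.25, "CHH": 0.9},
    "kypsuvh56": {"CG": 1.0, "CHG": 0.10, "CHH": 0.7},
    "cmt2": {"CG": 1.0, "CHG": 0.9, "CHH": 0.8},
    "nrpd1": {"CG": 1.0, "CHG": 0.60, "CHH": 0.25},
    "nrpe1": {"CG": 1.0, "CHG": 0.60, "CHH": 0.25},
    "ibm1": {"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
}

CONTEXT_TRINUC = {"CG": "CGA", "CHG": "CAG", "CHH": "CAT"}


@dataclass
class SimConfig:
    """All tunable parameters of the generator (seed recorded in outputs)."""

    seed: int = 1
    chrom: str = "Chr1"
    # annotation
    n_genes: int = 60
    n_tes: int = 300
    fraction_intragenic: float = 0.03
    fraction_other: float = 0.09
    fraction_intronic_within_intragenic: float = 0.85
    te_len_log_mean: float = 5.6   # lognormal of TE length, bp
    te_len_log_sd: float = 0.7
    min_te_len: int = 60
    fragment_prob: float = 0.15    # emit a TE as two <=50-bp-gapped fragments
    n_short_decoys: int = 10       # sub-50-bp records the length filter must drop
    rm_hit_prob: float = 0.9       # fraction of TEs supported by the RM screen
    n_junk_rm_hits: int = 15
    # methylation
    fraction_high_class: float = 0.5
    meth_mean_jitter_sd: float = 0.03
    bisulfite_depth: float = 30.0
    cytosine_density: float = 0.15   # per-bp chance of a C site within TEs
    background_site_density: float = 0.005
    genotypes: tuple[str, ...] = tuple(GENOTYPE_LOSS)
    # expression
    expression_log_mean: float = 5.0   # lognormal of per-gene expression
    expression_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    defect_genotypes: tuple[str, ...] = ("cmt3", "ddm1", "met1", "kypsuvh56")
    defect_affected_fraction: float = 0.5
    defect_ratio: float = 0.2      # post/pre multiplier in defective mutants
    expression_penalty_high: float = 0.5   # host-gene expression multiplier
    expression_penalty_low: float = 0.8
    te_activation: float = 1.5     # intronic-TE transcript fold in mutants
    # population genomics
    n_accessions: int = 80
    n_codons: int = 300
    n_popgen_genes: int = 12
    theta_S: float = 0.01
    theta_N: float = 0.004
    missing_rate: float = 0.02
    stop_injection_rate: float = 0.01
    multiallelic_injection_rate: float = 0.01
    perm_n: int = 10_000

    def validate(self) -> None:
        fracs = [
            self.fraction_intragenic, self.fraction_other,
            self.fraction_intronic_within_intragenic, self.fraction_high_class,
            self.rm_hit_prob, self.fragment_prob, self.missing_rate,
            self.defect_affected_fraction,
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0,1]")
        if self.fraction_intragenic + self.fraction_other > 1.0:
            raise ValueError("category fractions exceed 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("genotypes", "defect_genotypes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["genotypes"] = list(data["genotypes"])
        data["defect_genotypes"] = list(data["defect_genotypes"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    te: pd.DataFrame          # per-TE class/subcategory/host/meth class
    genes: pd.DataFrame       # per-gene biotype / expression mean
    methylation: pd.DataFrame # per (te, genotype, context) true mean
    defects: pd.DataFrame     # per (gene, te, genotype) defect status
    popgen: pd.DataFrame      # per popgen gene: group, theta targets
    config_hash: str = ""


@dataclass
class AnnotationSim:
    genes: list[GeneModel]
    raw_tes: list[TERecord]   # as emitted (fragments, decoys included)
    rm_lines: list[str]
    truth: GroundTruth
    chrom_length: int = 0


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

def _sample_te_length(cfg: SimConfig, rng: np.random.Generator, max_len: int | None = None) -> int:
    for _ in range(100):
        length = int(rng.lognormal(cfg.te_len_log_mean, cfg.te_len_log_sd))
        length = max(length, cfg.min_te_len)
        if max_len is None or length <= max_len:
            return length
    return max_len if max_len is not None else cfg.min_te_len


def _sample_family(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, str]:
    sfs = list(SUPERFAMILY_WEIGHTS)
    w = np.array([SUPERFAMILY_WEIGHTS[s] for s in sfs])
    sf = sfs[rng.choice(len(sfs), p=w / w.sum())]
    return sf, f"{sf}F{int(rng.integers(1, 4))}"


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator | None = None) -> AnnotationSim:
    """Plant genes and TEs of known category along one chromosome.

    Genes get 1-10 exons and occasionally a second, shorter isoform.
    TE categories are drawn from the configured fractions; intronic TEs
    are placed wholly inside an intron of the host's longest transcript,
    exonic TEs inside an exon, 'other' TEs straddle a gene boundary and
    intergenic TEs go into gene-free gaps.  Same-family placements keep
    >50 bp apart so merging never changes the planted records, except for
    deliberately split fragments whose merge restores the planted span.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    genes: list[GeneModel] = []
    gene_rows = []
    cursor = int(rng.integers(2000, 4000))
    for gi in range(cfg.n_genes):
        gene_id = f"SYNG{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        u = rng.random()
        biotype = "protein-coding" if u < 0.8 else ("ncRNA" if u < 0.95 else "transposable_element_gene")
        n_exons = int(rng.integers(1, 11))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            elen = int(rng.integers(150, 401))
            exons.append(GenomicInterval(cfg.chrom, pos, pos + elen - 1, strand))
            ilen = int(rng.integers(400, 1501))
            pos = pos + elen + ilen
        gene_end = exons[-1].end
        transcripts = {f"{gene_id}.1": exons}
        if n_exons >= 3 and rng.random() < 0.3:
            transcripts[f"{gene_id}.2"] = exons[:-1]
        gene = GeneModel(
            gene_id=gene_id,
            biotype=biotype,
            interval=GenomicInterval(cfg.chrom, cursor, gene_end, strand),
            transcripts={k: list(v) for k, v in transcripts.items()},
        )
        genes.append(gene)
        gene_rows.append(
            {
                "gene_id": gene_id, "biotype": biotype, "strand": strand,
                "start": cursor, "end": gene_end, "n_exons": n_exons,
                "kept": biotype in ("protein-coding", "ncRNA"),
            }
        )
        cursor = gene_end + int(rng.integers(3000, 6001))
    chrom_length = cursor + 5000
    kept_genes = [g for g in genes if g.biotype in ("protein-coding", "ncRNA")]
    genic = [(g.interval.start, g.interval.end) for g in genes]

    # --- TE planting ------------------------------------------------------
    n_intragenic = int(round(cfg.n_tes * cfg.fraction_intragenic))
    n_other = int(round(cfg.n_tes * cfg.fraction_other))
    n_intronic = int(round(n_intragenic * cfg.fraction_intronic_within_intragenic))
    categories = (
        ["intronic"] * n_intronic
        + ["exonic"] * (n_intragenic - n_intronic)
        + ["other"] * n_other
    )
    categories += ["intergenic"] * (cfg.n_tes - len(categories))

    placed: list[tuple[str, int, int]] = []  # (family, start, end)

    def conflicts(family: str, start: int, end: int) -> bool:
        for fam, s, e in placed:
            if fam == family and not (start > e + 51 or end < s - 51):
                return True
            if max(start, s) <= min(end, e):  # any overlap with another TE
                return True
        return False

    te_rows = []
    raw_tes: list[TERecord] = []
    te_counter = itertools.count(1)

    host_intronic = [g for g in kept_genes if g.introns()]
    host_exonic = [g for g in kept_genes if any(e.length >= 160 for e in g.exons())]

    for category in categories:
        for _attempt in range(200):
            sf, family = _sample_family(cfg, rng)
            if category == "intronic":
                g = host_intronic[int(rng.integers(len(host_intronic)))]
                introns = g.introns()
                intron = introns[int(rng.integers(len(introns)))]
                if intron.length < cfg.min_te_len + 20:
                    continue
                length = _sample_te_length(cfg, rng, max_len=intron.length - 10)
                start = intron.start + int(rng.integers(0, intron.length - length + 1))
                host = g.gene_id
            elif category == "exonic":
                g = host_exonic[int(rng.integers(len(host_exonic)))]
                big = [e for e in g.exons() if e.length >= 160]
                exon = big[int(rng.integers(len(big)))]
                length = int(rng.integers(100, min(exon.length - 4, 200) + 1))
                start = exon.start + int(rng.integers(1, exon.length - length))
                host = g.gene_id
            elif category == "other":
                g = kept_genes[int(rng.integers(len(kept_genes)))]
                length = _sample_te_length(cfg, rng, max_len=2000)
                # straddle the gene start
                start = g.interval.start - length // 2
                if start < 1:
                    continue
                host = g.gene_id
            else:  # intergenic
                length = _sample_te_length(cfg, rng, max_len=4000)
                start = int(rng.integers(1, chrom_length - length))
                host = None
            end = start + length - 1
            # intergenic TEs must not touch any gene; others checked above
            if category == "intergenic" and any(
                max(start, s) <= min(end, e) for s, e in genic
            ):
                continue
            if conflicts(family, start, end):
                continue
            placed.append((family, start, end))
            te_id = f"SYNTE{next(te_counter):05d}"
            # records shorter than the 100-bp RepeatMasker hit screen can
            # never carry a qualifying hit
            rm_supported = bool(length >= 100 and rng.random() < cfg.rm_hit_prob)
            te_rows.append(
                {
                    "te_id": te_id, "family": family, "superfamily": sf,
                    "chrom": cfg.chrom, "start": start, "end": end,
                    "length": length,
                    "category": "intragenic" if category in ("intronic", "exonic") else category,
                    "subcategory": category if category in ("intronic", "exonic") else "none",
                    "host_gene_id": host,
                    "rm_supported": rm_supported,
                    "in_final_set": rm_supported,
                    "role": "planted",
                }
            )
            interval = GenomicInterval(cfg.chrom, start, end, ".")
            if length >= 170 and rng.random() < cfg.fragment_prob:
                gap = int(rng.integers(1, 51))
                l1 = int(rng.integers(50, length - gap - 50 + 1))
                raw_tes.append(
                    TERecord(te_id, family, sf, GenomicInterval(cfg.chrom, start, start + l1 - 1, "."))
                )
                raw_tes.append(
                    TERecord(
                        f"{te_id}b", family, sf,
                        GenomicInterval(cfg.chrom, start + l1 + gap, end, "."),
                    )
                )
            else:
                raw_tes.append(TERecord(te_id, family, sf, interval))
            break

    # sub-50-bp decoys the length filter must remove
    for di in range(cfg.n_short_decoys):
        for _attempt in range(100):
            length = int(rng.integers(20, 50))
            start = int(rng.integers(1, chrom_length - length))
            end = start + length - 1
            if conflicts("DecoyF1", start, end):
                continue
            placed.append(("DecoyF1", start, end))
            te_id = f"SYNDECOY{di + 1:03d}"
            raw_tes.append(
                TERecord(te_id, "DecoyF1", "other", GenomicInterval(cfg.chrom, start, end, "."))
            )
            te_rows.append(
                {
                    "te_id": te_id, "family": "DecoyF1", "superfamily": "other",
                    "chrom": cfg.chrom, "start": start, "end": end, "length": length,
                    "category": "none", "subcategory": "none", "host_gene_id": None,
                    "rm_supported": False, "in_final_set": False, "role": "short_decoy",
                }
            )
            break

    te_truth = pd.DataFrame(te_rows)

    # --- methylation classes & true means ---------------------------------
    final = te_truth[te_truth["in_final_set"]]
    classes = {
        row.te_id: ("high" if rng.random() < cfg.fraction_high_class else "low")
        for row in final.itertuples()
    }
    te_truth["meth_class"] = te_truth["te_id"].map(classes).fillna("undefined")
    meth_rows = []
    for row in te_truth[te_truth["role"] == "planted"].itertuples():
        cls = classes.get(row.te_id)
        if cls is None:
            continue
        for context in ("CG", "CHG", "CHH"):
            base = WT_METH_MEANS[(cls, context)]
            jitter = float(rng.normal(0.0, cfg.meth_mean_jitter_sd))
            wt_mean = float(np.clip(base + jitter, 0.005, 0.995))
            # keep the high/low classes separated at the 20% CHG boundary
            if context == "CHG":
                wt_mean = float(np.clip(wt_mean, 0.005, 0.995))
                wt_mean = max(wt_mean, 0.25) if cls == "high" else min(wt_mean, 0.15)
            for genotype in cfg.genotypes:
                loss = GENOTYPE_LOSS.get(genotype, GENOTYPE_LOSS["wild-type"])[context]
                meth_rows.append(
                    {
                        "te_id": row.te_id, "genotype": genotype, "context": context,
                        "true_level": wt_mean * loss,
                    }
                )
    meth_truth = pd.DataFrame(meth_rows)

    # --- expression means & defect assignment -----------------------------
    gene_truth = pd.DataFrame(gene_rows)
    expr = np.exp(rng.normal(cfg.expression_log_mean, cfg.expression_log_sd, len(gene_truth)))
    gene_truth["expr_mean"] = expr
    host_class = {}
    for row in te_truth[(te_truth["in_final_set"]) & (te_truth["category"] == "intragenic")].itertuples():
        cls = classes.get(row.te_id, "low")
        prev = host_class.get(row.host_gene_id)
        host_class[row.host_gene_id] = "high" if cls == "high" or prev == "high" else "low"
    penalty = gene_truth["gene_id"].map(
        lambda g: cfg.expression_penalty_high
        if host_class.get(g) == "high"
        else (cfg.expression_penalty_low if host_class.get(g) == "low" else 1.0)
    )
    gene_truth["expr_mean"] = gene_truth["expr_mean"] * penalty

    gene_by_id = {g.gene_id: g for g in genes}
    defect_rows = []
    intronic_final = te_truth[
        (te_truth["in_final_set"]) & (te_truth["subcategory"] == "intronic")
    ]
    for row in intronic_final.itertuples():
        host = gene_by_id[row.host_gene_id]
        introns = host.introns()
        overlaps = [
            max(0, min(row.end, intr.end) - max(row.start, intr.start) + 1)
            for intr in introns
        ]
        intron_index = int(np.argmax(overlaps))
        for genotype in cfg.defect_genotypes:
            is_defect = bool(rng.random() < cfg.defect_affected_fraction)
            defect_rows.append(
                {
                    "gene_id": row.host_gene_id, "te_id": row.te_id,
                    "genotype": genotype, "intron_index": intron_index,
                    "is_defect": is_defect,
                }
            )
    defect_truth = pd.DataFrame(
        defect_rows,
        columns=["gene_id", "te_id", "genotype", "intron_index", "is_defect"],
    )

    # --- popgen gene selection --------------------------------------------
    te_hosts = sorted(
        set(
            te_truth.loc[
                (te_truth["in_final_set"]) & (te_truth["category"] == "intragenic"),
                "host_gene_id",
            ]
        )
    )
    no_te = [
        g.gene_id for g in kept_genes
        if g.gene_id not in set(te_hosts) and g.biotype == "protein-coding"
    ]
    half = cfg.n_popgen_genes // 2
    with_te = te_hosts[:half]
    without_te = no_te[: cfg.n_popgen_genes - len(with_te)]
    popgen_truth = pd.DataFrame(
        {
            "gene_id": with_te + without_te,
            "group": ["with_te"] * len(with_te) + ["without_te"] * len(without_te),
            "theta_S": cfg.theta_S,
            "theta_N": cfg.theta_N,
        }
    )

    truth = GroundTruth(
        te=te_truth, genes=gene_truth, methylation=meth_truth,
        defects=defect_truth, popgen=popgen_truth, config_hash=cfg.config_hash(),
    )

    rm_lines = _render_repeatmasker(cfg, te_truth, rng, chrom_length)
    return AnnotationSim(genes, raw_tes, rm_lines, truth, chrom_length)


def _render_repeatmasker(
    cfg: SimConfig, te_truth: pd.DataFrame, rng: np.random.Generator, chrom_length: int
) -> list[str]:
    """RepeatMasker-style records: one good hit per supported TE plus junk."""
    lines = [
        "   SW   perc perc perc  query      position in query    matching repeat        position in repeat",
        "score   div. del. ins.  sequence   begin end   (left)   repeat    class/family  begin end (left)  ID",
        "",
    ]

    def row(chrom, qs, qe, strand, name, cls, rbegin, rend, left, hit_id):
        if strand == "C":
            rep = f"({left})  {rend}  {rbegin}"
        else:
            rep = f"{rbegin}  {rend}  ({left})"
        return (
            f"  {int(rng.integers(200, 5000))}  {rng.uniform(1, 25):.1f}  0.0  0.0  "
            f"{chrom}  {qs}  {qe}  ({max(0, chrom_length - qe)})  {strand}  "
            f"{name}  {cls}  {rep}  {hit_id}"
        )

    hit_id = itertools.count(1)
    for te in te_truth[te_truth["rm_supported"]].itertuples():
        # jitter only inward, and never below the 100-bp hit-length screen,
        # so a hit never reaches beyond its own TE yet always survives
        shrink = max(0, min(10, (te.length - 100) // 2))
        qs = te.start + int(rng.integers(0, shrink + 1))
        qe = te.end - int(rng.integers(0, shrink + 1))
        hit_len = qe - qs + 1
        lib_len = int(round(hit_len / rng.uniform(0.75, 0.98)))
        left = lib_len - hit_len
        strand = "C" if rng.random() < 0.4 else "+"
        lines.append(
            row(te.chrom, qs, qe, strand, f"{te.family}_cons", RM_CLASS.get(te.superfamily, "Unknown"),
                1, hit_len, left, next(hit_id))
        )
    # junk: excluded classes, short hits, low-coverage hits
    junk_classes = ["Simple_repeat", "Low_complexity", "rRNA", "Satellite/centr"]
    for _ in range(cfg.n_junk_rm_hits):
        qs = int(rng.integers(1, chrom_length - 600))
        kind = rng.random()
        if kind < 0.4:
            cls = junk_classes[int(rng.integers(len(junk_classes)))]
            qe = qs + int(rng.integers(100, 500))
            lib = qe - qs + 1
            lines.append(row(cfg.chrom, qs, qe, "+", "JUNK", cls, 1, lib, 0, next(hit_id)))
        elif kind < 0.7:
            qe = qs + int(rng.integers(30, 99))  # < 100 bp
            lib = qe - qs + 1
            lines.append(row(cfg.chrom, qs, qe, "+", "SHORTHIT", "DNA/MuDR", 1, lib, 0, next(hit_id)))
        else:
            qe = qs + int(rng.integers(100, 300))
            hit_len = qe - qs + 1
            lib_len = int(hit_len / rng.uniform(0.2, 0.6))  # coverage < 70%
            lines.append(
                row(cfg.chrom, qs, qe, "+", "LOWCOV", "LTR/Gypsy", 1, hit_len, lib_len - hit_len, next(hit_id))
            )
    return lines


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylome(
    cfg: SimConfig,
    truth: GroundTruth,
    genotype: str,
    rng: np.random.Generator,
    chrom_length: int,
) -> pd.DataFrame:
    """Per-cytosine calls for one genotype.

    Sites are scattered within planted TE intervals at the configured
    density (plus a sparse, weakly CG-methylated genic background);
    coverage is Poisson(depth) and methylated counts Binomial(coverage,
    true level), where the true level is the per-TE wild-type mean times
    the genotype's per-context loss factor.
    """
    level = {
        (r.te_id, r.context): r.true_level
        for r in truth.methylation[truth.methylation["genotype"] == genotype].itertuples()
    }
    contexts = np.array(["CG", "CHG", "CHH"])
    ctx_p = np.array([0.3, 0.3, 0.4])
    rows = []
    for te in truth.te[truth.te["role"] == "planted"].itertuples():
        if (te.te_id, "CG") not in level:
            continue
        n_sites = rng.binomial(te.length, cfg.cytosine_density)
        if n_sites == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(te.start, te.end + 1), size=n_sites, replace=False)
        )
        ctx = contexts[rng.choice(3, size=n_sites, p=ctx_p)]
        strands = np.where(rng.random(n_sites) < 0.5, "+", "-")
        coverage = rng.poisson(cfg.bisulfite_depth, n_sites)
        for pos, c, s, cov in zip(positions, ctx, strands, coverage):
            p = level[(te.te_id, c)]
            meth = int(rng.binomial(cov, p)) if cov > 0 else 0
            rows.append(
                (te.chrom, int(pos), s, meth, int(cov) - meth, c, CONTEXT_TRINUC[c])
            )
    # sparse background outside TEs
    n_bg = rng.poisson(cfg.background_site_density * chrom_length)
    te_iv = [(t.start, t.end) for t in truth.te.itertuples()]
    bg_positions = np.sort(rng.integers(1, chrom_length, size=n_bg))
    for pos in bg_positions:
        if any(s <= pos <= e for s, e in te_iv):
            continue
        c = str(contexts[rng.choice(3, p=ctx_p)])
        cov = int(rng.poisson(cfg.bisulfite_depth))
        p = 0.05 if c == "CG" else 0.01
        meth = int(rng.binomial(cov, p)) if cov > 0 else 0
        rows.append((cfg.chrom, int(pos), "+" if rng.random() < 0.5 else "-", meth, cov - meth, c, CONTEXT_TRINUC[c]))
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "position", "strand", "count_methylated",
            "count_unmethylated", "context", "trinucleotide",
        ],
    )
    return df.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# RNA-seq count simulation
# ---------------------------------------------------------------------------

def _gene_multiplier(rng: np.random.Generator, dispersion: float) -> float:
    """Gamma abundance multiplier (mean 1, variance = dispersion).

    Counts of regions sharing a transcript are Poisson around a common
    gamma-distributed abundance, so each count is marginally negative
    binomial with variance m + dispersion * m^2 while within-transcript
    read ratios stay at their expectation -- the standard gamma-Poisson
    RNA-seq noise model.
    """
    if dispersion <= 0:
        return 1.0
    return float(rng.gamma(1.0 / dispersion, dispersion))


def simulate_counts(
    cfg: SimConfig,
    truth: GroundTruth,
    genes: list[GeneModel],
    genotype: str,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-exon and per-TE read counts for one genotype.

    Exon means are proportional to exon length times the gene's expression
    mean; genes planted as defective in this genotype have the means of
    exons transcriptionally downstream of the TE-containing intron
    multiplied by ``defect_ratio``.  Returns (exon counts, TE counts,
    library size).
    """
    expr = dict(zip(truth.genes["gene_id"], truth.genes["expr_mean"]))
    defect_introns: dict[str, int] = {}
    if len(truth.defects):
        sub = truth.defects[
            (truth.defects["genotype"] == genotype) & (truth.defects["is_defect"])
        ]
        for r in sub.itertuples():
            defect_introns[r.gene_id] = int(r.intron_index)

    rows = []
    for gene in genes:
        if not gene.transcripts:
            continue
        exons = gene.exons()
        mu_g = expr.get(gene.gene_id, 0.0) * _gene_multiplier(rng, cfg.nb_dispersion)
        cut = defect_introns.get(gene.gene_id)
        for i, exon in enumerate(exons):
            mean = mu_g * exon.length / 1000.0
            if cut is not None:
                downstream = i > cut if gene.strand != "-" else i <= cut
                if downstream:
                    mean *= cfg.defect_ratio
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "transcript_id": gene.longest_transcript_id,
                    "exon_index": i,
                    "count": int(rng.poisson(mean)),
                }
            )
    exon_df = pd.DataFrame(rows)

    te_rows = []
    for te in truth.te[truth.te["role"] == "planted"].itertuples():
        base = 0.5 * te.length / 1000.0 * _gene_multiplier(rng, cfg.nb_dispersion)
        if genotype != "wild-type" and te.category == "intragenic":
            base *= cfg.te_activation
        te_rows.append({"te_id": te.te_id, "count": int(rng.poisson(base))})
    te_df = pd.DataFrame(te_rows)

    library_size = int(exon_df["count"].sum() + te_df["count"].sum())
    return exon_df, te_df, max(library_size, 1)


def simulate_null_region_counts(
    n_genes: int,
    mean: float = 200.0,
    dispersion: float = 0.1,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Pre/post region counts drawn identically in wild type and mutant.

    The null for the downstream-transcription-defect caller: every region
    count is marginally negative binomial (mean ``mean``, variance
    m + dispersion * m^2) and within each genotype the pre and post
    regions share their transcript's gamma-distributed abundance, so the
    expected post/pre ratio is the wild-type ratio (1) in both genotypes
    and any D label is a false positive.  Columns: gene_id, pre_wt,
    post_wt, pre_mut, post_mut.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if dispersion > 0:
        mult = rng.gamma(1.0 / dispersion, dispersion, size=(n_genes, 2))
    else:
        mult = np.ones((n_genes, 2))
    lam = mean * np.repeat(mult, 2, axis=1)  # pre/post share the genotype draw
    draws = rng.poisson(lam)
    return pd.DataFrame(
        draws, columns=["pre_wt", "post_wt", "pre_mut", "post_mut"]
    ).assign(gene_id=[f"SYNG{i + 1:05d}" for i in range(n_genes)])


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------

_SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def _synonymous_options(codon: str) -> list[tuple[int, str]]:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in STOP_CODONS and GENETIC_CODE[mut] == aa:
                out.append((pos, base))
    return out


def _nonsynonymous_options(codon: str) -> list[tuple[int, str]]:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in STOP_CODONS and GENETIC_CODE[mut] != aa:
                out.append((pos, base))
    return out


def simulate_alignment(
    cfg: SimConfig, gene_id: str, rng: np.random.Generator
) -> tuple[CodonAlignment, dict]:
    """One gene's codon alignment with planted diversity targets.

    Synonymous and nonsynonymous SNPs are sprinkled on distinct codon
    columns so that the expected pairwise diversity per site matches
    ``theta_S`` / ``theta_N``; a biallelic SNP with derived-allele count d
    among n accessions contributes d(n-d)/C(n,2) expected pairwise
    differences.  Missing data (NNN codons), premature stop columns and
    tri-allelic columns are injected at the configured rates on columns
    free of planted SNPs, to exercise the codon screens.
    """
    n, L = cfg.n_accessions, cfg.n_codons
    internal = list(range(1, L - 1))
    ancestral = ["ATG"] + [
        _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))] for _ in internal
    ] + ["TAA"]

    syn_sites_total = sum(ng86_sites(ancestral[j])[0] for j in internal)
    nonsyn_sites_total = 3.0 * len(internal) - syn_sites_total
    d_vals = np.arange(1, n)
    e_pair = float((d_vals * (n - d_vals)).mean()) / (n * (n - 1) / 2)

    n_syn = int(round(cfg.theta_S * syn_sites_total / e_pair))
    n_non = int(round(cfg.theta_N * nonsyn_sites_total / e_pair))
    n_stop = int(round(cfg.stop_injection_rate * len(internal)))
    n_multi = int(round(cfg.multiallelic_injection_rate * len(internal)))

    shuffled = list(rng.permutation(internal))
    syn_cols, non_cols, stop_cols, multi_cols = [], [], [], []
    for col in shuffled:
        if len(syn_cols) < n_syn and _synonymous_options(ancestral[col]):
            syn_cols.append(col)
        elif len(non_cols) < n_non and _nonsynonymous_options(ancestral[col]):
            non_cols.append(col)
        elif len(stop_cols) < n_stop:
            stop_cols.append(col)
        elif len(multi_cols) < n_multi:
            multi_cols.append(col)

    matrix = [list(ancestral) for _ in range(n)]

    def apply_snp(col: int, options: list[tuple[int, str]]) -> None:
        pos, base = options[int(rng.integers(len(options)))]
        derived = ancestral[col][:pos] + base + ancestral[col][pos + 1:]
        d = int(rng.integers(1, n))
        carriers = rng.choice(n, size=d, replace=False)
        for acc in carriers:
            matrix[acc][col] = derived

    for col in syn_cols:
        apply_snp(col, _synonymous_options(ancestral[col]))
    for col in non_cols:
        apply_snp(col, _nonsynonymous_options(ancestral[col]))
    for col in stop_cols:
        acc = int(rng.integers(n))
        matrix[acc][col] = "TAA"
    for col in multi_cols:
        pos = int(rng.integers(3))
        ref = ancestral[col][pos]
        alts = [b for b in BASES if b != ref]
        a1, a2 = rng.choice(n, size=2, replace=False)
        for acc, base in ((a1, alts[0]), (a2, alts[1])):
            codon = matrix[acc][col]
            matrix[acc][col] = codon[:pos] + base + codon[pos + 1:]

    # missing data on columns everywhere (NNN codons)
    miss = rng.random((n, L)) < cfg.missing_rate
    for acc in range(n):
        for col in np.flatnonzero(miss[acc]):
            matrix[acc][col] = "NNN"

    accessions = [f"acc{i + 1:03d}" for i in range(n)]
    aln = CodonAlignment(
        gene_id=gene_id,
        accessions=accessions,
        sequences=["".join(codons) for codons in matrix],
    )
    info = {
        "n_syn_snps": len(syn_cols), "n_nonsyn_snps": len(non_cols),
        "stop_columns": sorted(stop_cols), "multiallelic_columns": sorted(multi_cols),
        "syn_sites_total": syn_sites_total, "nonsyn_sites_total": nonsyn_sites_total,
    }
    return aln, info


def simulate_alignments(
    cfg: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, tuple[CodonAlignment, dict]]:
    return {
        gene_id: simulate_alignment(cfg, gene_id, rng)
        for gene_id in truth.popgen["gene_id"]
    }


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tsynthetic\tgene\t{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )
            for tid in sorted(g.transcripts):
                exons = g.transcripts[tid]
                fh.write(
                    f"{iv.chrom}\tsynthetic\tmRNA\t{exons[0].start}\t{exons[-1].end}\t.\t"
                    f"{iv.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for k, e in enumerate(exons, 1):
                    fh.write(
                        f"{iv.chrom}\tsynthetic\texon\t{e.start}\t{e.end}\t.\t{iv.strand}\t.\t"
                        f"ID={tid}.exon{k};Parent={tid}\n"
                    )


def write_te_gff3(tes: list[TERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in tes:
            iv = t.interval
            fh.write(
                f"{iv.chrom}\tsynthetic\ttransposable_element\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={t.te_id};family={t.family};superfamily={t.superfamily}\n"
            )


def write_alignment_fasta(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, seq in zip(aln.accessions, aln.sequences):
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def simulate_all(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Run every generator and write the full input bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sim = simulate_annotation(cfg, rng)

    write_genes_gff3(sim.genes, outdir / "genes.gff3")
    write_te_gff3(sim.raw_tes, outdir / "tes.gff3")
    (outdir / "rm.out").write_text("\n".join(sim.rm_lines) + "\n")

    lib_rows = []
    for genotype in cfg.genotypes:
        meth = simulate_methylome(cfg, sim.truth, genotype, rng, sim.chrom_length)
        meth.to_csv(outdir / f"meth_{genotype}.tsv", sep="\t", header=False, index=False)
    count_genotypes = ["wild-type"] + [
        g for g in cfg.defect_genotypes if g != "wild-type"
    ]
    for genotype in count_genotypes:
        exon_df, te_df, lib = simulate_counts(cfg, sim.truth, sim.genes, genotype, rng)
        exon_df.to_csv(outdir / f"counts_{genotype}.tsv", sep="\t", index=False)
        te_df.to_csv(outdir / f"te_counts_{genotype}.tsv", sep="\t", index=False)
        lib_rows.append({"genotype": genotype, "total_mapped": lib})
    pd.DataFrame(lib_rows).to_csv(outdir / "library_sizes.tsv", sep="\t", index=False)

    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for gene_id, (aln, _info) in simulate_alignments(cfg, sim.truth, rng).items():
        write_alignment_fasta(aln, aln_dir / f"{gene_id}.fa")
    sim.truth.popgen.to_csv(outdir / "popgen_groups.tsv", sep="\t", index=False)

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    header = f"# seed={cfg.seed} config_hash={sim.truth.config_hash}\n"
    for name, df in (
        ("te_truth", sim.truth.te), ("gene_truth", sim.truth.genes),
        ("methylation_truth", sim.truth.methylation),
        ("defect_truth", sim.truth.defects), ("popgen_truth", sim.truth.popgen),
    ):
        with open(truth_dir / f"{name}.tsv", "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    cfg.to_yaml(outdir / "config-echo.yaml")
    return sim.truth
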