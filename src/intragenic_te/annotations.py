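"""Read, filter, merge, and reconcile gene and TE annotations.

The analysis TE set is built in the following order: same-family records
within a short gap of each other are concatenated, short records are
dropped, and the result is intersected with an independently derived,
filtered RepeatMasker screen.  Gene models come from a GFF3 annotation and
are restricted to protein-coding and ncRNA biotypes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from intragenic_te.intervals import (
    GeneModel,
    GenomicInterval,
    RepeatMaskerHit,
    TERecord,
    pick_longest_transcript,
)

logger = logging.getLogger(__name__)

#: RepeatMasker classes excluded from the screen.  The categories are
#: matched case-insensitively as substrings of the class/family column,
#: because RepeatMasker libraries vary in their exact class strings
#: (e.g. "Satellite/centr", "Low_complexity").
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"Simple_repeat", "Low_complexity", "rRNA", "Satellite", "centr", "composite"}
)


class GFF3ParseError(ValueError):
    """Raised for a structurally malformed GFF3 line (reports line number)."""


def _validate_gff3(path: str | Path) -> str:
    """Return file text after checking each record line has 9 columns."""
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise GFF3ParseError(
                f"{path}: malformed GFF3 line {lineno}: expected 9 tab-separated "
                f"columns, got {len(line.split(chr(9)))}"
            )
    return text


def _attr(feature: gffutils.Feature, *keys: str, default: str | None = None) -> str | None:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return default


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 gene annotation into :class:`GeneModel` records.

    Expects the conventional three-level gene / mRNA(or transcript) / exon
    hierarchy.  The gene biotype is taken from a ``biotype``,
    ``locus_type`` or ``gene_biotype`` attribute.  The longest isoform
    (maximal summed exon length; ties broken by smallest transcript id)
    is selected as the representative transcript.
    """
    text = _validate_gff3(path)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    # every exon must name a parent transcript
    for exon in db.features_of_type("exon"):
        if "Parent" not in exon.attributes:
            raise GFF3ParseError(f"{path}: exon {exon.id} has no Parent attribute")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts: dict[str, list[GenomicInterval]] = {}
        for tx in db.children(gene, level=1):
            exons = [
                GenomicInterval(e.seqid, e.start, e.end, e.strand or ".")
                for e in db.children(tx, featuretype="exon")
            ]
            if exons:
                transcripts[tx.id] = sorted(exons, key=lambda e: e.start)
        biotype = _attr(gene, "biotype", "locus_type", "gene_biotype", default="other")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                biotype=biotype,
                interval=GenomicInterval(gene.seqid, gene.start, gene.end, gene.strand or "."),
                transcripts=transcripts,
                longest_transcript_id=pick_longest_transcript(transcripts)
                if transcripts
                else None,
            )
        )
    return genes


def filter_genes(
    genes: list[GeneModel],
    keep_biotypes: tuple[str, ...] = ("protein-coding", "ncRNA"),
) -> list[GeneModel]:
    """Retain only protein-coding and ncRNA genes, preserving order."""
    keep = set(keep_biotypes)
    return [g for g in genes if g.biotype in keep]


def read_te_gff3(path: str | Path) -> list[TERecord]:
    """Read a TE annotation GFF3; family/superfamily from attributes."""
    text = _validate_gff3(path)
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )
    tes = []
    for feat in db.all_features():
        family = _attr(feat, "family", "Family", "Alias", default=None)
        if family is None:
            continue
        tes.append(
            TERecord(
                te_id=feat.id,
                family=family,
                superfamily=_attr(feat, "superfamily", "Superfamily", default="other"),
                interval=GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand or "."),
                source="tair10",
            )
        )
    return tes


def read_te_tsv(path: str | Path) -> list[TERecord]:
    """Read a TE set from a TSV with columns te_id, family, superfamily, chrom, start, end[, strand, source]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    tes = []
    for row in df.itertuples(index=False):
        tes.append(
            TERecord(
                te_id=str(row.te_id),
                family=str(row.family),
                superfamily=str(row.superfamily),
                interval=GenomicInterval(
                    str(row.chrom),
                    int(row.start),
                    int(row.end),
                    str(getattr(row, "strand", ".")),
                ),
                source=str(getattr(row, "source", "tair10")),
            )
        )
    return tes


def merge_te_annotations(tes: list[TERecord], max_gap: int = 50) -> list[TERecord]:
    """Concatenate same-family TEs lying within ``max_gap`` bp of each other.

    The gap between consecutive records is ``next.start - prev.end - 1``;
    overlapping or abutting records (gap <= 0) always merge.  Merging is
    transitive.  A merged record spans min(start)..max(end) and keeps the
    family and the id of the leftmost constituent.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    out: list[TERecord] = []
    key = lambda t: (t.interval.chrom, t.family, t.interval.start, t.interval.end)
    for te in sorted(tes, key=key):
        prev = out[-1] if out else None
        if (
            prev is not None
            and prev.interval.chrom == te.interval.chrom
            and prev.family == te.family
            and te.interval.start - prev.interval.end - 1 <= max_gap
        ):
            merged = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, te.interval.end),
                prev.interval.strand
                if prev.interval.strand == te.interval.strand
                else ".",
            )
            out[-1] = TERecord(
                te_id=prev.te_id,
                family=prev.family,
                superfamily=prev.superfamily,
                interval=merged,
                source=prev.source,
            )
        else:
            out.append(te)
    return out


def filter_short_tes(tes: list[TERecord], min_len: int = 50) -> list[TERecord]:
    """Drop TEs shorter than ``min_len`` bp (records of exactly ``min_len`` are kept)."""
    return [t for t in tes if t.length >= min_len]


def parse_repeatmasker_out(path: str | Path) -> list[RepeatMaskerHit]:
    """Parse a RepeatMasker ``.out`` file.

    Handles both orientations of the repeat-coordinate columns: for plus
    strand hits they are ``begin end (left)``, for complement ('C') hits
    ``(left) end begin``.  The library consensus length is ``end + left``
    and the coverage fraction ``(end - begin + 1) / (end + left)``.
    """
    hits: list[RepeatMaskerHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # tolerate the standard 3-line header
            if fields[0] in {"SW", "score"} or not fields[0][0].isdigit():
                continue
            try:
                chrom = fields[4]
                qstart, qend = int(fields[5]), int(fields[6])
                strand = fields[8]
                repeat_name = fields[9]
                repeat_class = fields[10]
                if strand == "C":
                    left = int(fields[11].strip("()"))
                    rend = int(fields[12])
                    rbegin = int(fields[13])
                else:
                    rbegin = int(fields[11])
                    rend = int(fields[12])
                    left = int(fields[13].strip("()"))
                lib_len = rend + left
                coverage = (rend - rbegin + 1) / lib_len
            except (IndexError, ValueError) as exc:
                raise ValueError(
                    f"{path}: unparsable RepeatMasker record at line {lineno}: {exc}"
                ) from exc
            hits.append(
                RepeatMaskerHit(
                    interval=GenomicInterval(
                        chrom, qstart, qend, "-" if strand == "C" else "+"
                    ),
                    repeat_name=repeat_name,
                    repeat_class=repeat_class,
                    library_repeat_length=lib_len,
                    hit_coverage_fraction=coverage,
                )
            )
    return hits


def filter_repeatmasker_hits(
    hits: list[RepeatMaskerHit],
    min_hit_len: int = 100,
    min_coverage: float = 0.70,
    excluded_classes: frozenset[str] = DEFAULT_EXCLUDED_CLASSES,
) -> list[RepeatMaskerHit]:
    """Apply the RepeatMasker screen.

    Removes hits whose class matches the exclusion set (simple repeats,
    rRNA, satellite/centromeric, low complexity, composites), hits shorter
    than ``min_hit_len`` bp, and hits covering less than ``min_coverage``
    of the library consensus.  Boundary values (exactly 100 bp, exactly
    70%) are kept.
    """
    tokens = [c.lower() for c in excluded_classes]
    out = []
    for hit in hits:
        cls = hit.repeat_class.lower()
        if any(tok in cls for tok in tokens):
            continue
        if hit.interval.length < min_hit_len:
            continue
        if hit.hit_coverage_fraction < min_coverage - 1e-12:
            continue
        out.append(hit)
    return out


def intersect_te_sets(
    tair_tes: list[TERecord],
    rm_hits: list[RepeatMaskerHit],
    min_overlap: int = 1,
) -> list[TERecord]:
    """Retain primary-annotation TEs supported by the RepeatMasker screen.

    A TE is kept, with its original coordinates and ``source`` set to
    ``reconciled``, iff it shares at least ``min_overlap`` bp with some
    filtered RepeatMasker hit.  Chromosomes present in only one of the two
    sets are reported with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for hit in rm_hits:
        # IntervalTree is half-open; +1 converts the closed end
        trees.setdefault(hit.interval.chrom, IntervalTree()).addi(
            hit.interval.start, hit.interval.end + 1
        )
    te_chroms = {t.interval.chrom for t in tair_tes}
    unmatched = sorted(te_chroms.symmetric_difference(trees))
    if unmatched:
        logger.warning(
            "chromosomes present in only one annotation set: %s", ", ".join(unmatched)
        )
    out = []
    for te in tair_tes:
        tree = trees.get(te.interval.chrom)
        if tree is None:
            continue
        best = 0
        for iv in tree.overlap(te.interval.start, te.interval.end + 1):
            ov = min(iv.end - 1, te.interval.end) - max(iv.begin, te.interval.start) + 1
            best = max(best, ov)
            if best >= min_overlap:
                break
        if best >= min_overlap:
            out.append(
                TERecord(te.te_id, te.family, te.superfamily, te.interval, "reconciled")
            )
    return out


def build_te_set(
    tair_tes: list[TERecord],
    rm_hits: list[RepeatMaskerHit],
    max_gap: int = 50,
    min_te_len: int = 50,
    min_hit_len: int = 100,
    min_coverage: float = 0.70,
    min_overlap: int = 1,
    excluded_classes: frozenset[str] = DEFAULT_EXCLUDED_CLASSES,
) -> list[TERecord]:
    """Full reconciliation: merge -> length filter -> RepeatMasker intersect."""
    merged = merge_te_annotations(tair_tes, max_gap=max_gap)
    kept = filter_short_tes(merged, min_len=min_te_len)
    good_hits = filter_repeatmasker_hits(
        rm_hits, min_hit_len=min_hit_len, min_coverage=min_coverage,
        excluded_classes=excluded_classes,
    )
    return intersect_te_sets(kept, good_hits, min_overlap=min_overlap)


def te_set_to_frame(tes: list[TERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "te_id": [t.te_id for t in tes],
            "family": [t.family for t in tes],
            "superfamily": [t.superfamily for t in tes],
            "chrom": [t.interval.chrom for t in tes],
            "start": [t.interval.start for t in tes],
            "end": [t.interval.end for t in tes],
            "strand": [t.interval.strand for t in tes],
            "length": [t.length for t in tes],
            "source": [t.source for t in tes],
        }
    )


def write_te_set(tes: list[TERecord], tsv_path: str | Path, gff3_path: str | Path | None = None) -> None:
    te_set_to_frame(tes).to_csv(tsv_path, sep="\t", index=False)
    if gff3_path is not None:
        with open(gff3_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for t in tes:
                attrs = f"ID={t.te_id};family={t.family};superfamily={t.superfamily}"
                fh.write(
                    "\t".join(
                        [
                            t.interval.chrom,
                            t.source,
                            "transposable_element",
                            str(t.interval.start),
                            str(t.interval.end),
                            ".",
                            t.interval.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
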