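"""Core located-record types shared by every pipeline stage.

Coordinates are 1-based, closed intervals throughout (the GFF3 convention);
any half-open export (e.g. BED) must convert explicitly at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded 1-based closed genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


SUPERFAMILIES = (
    "Gypsy",
    "Copia",
    "LINE",
    "SINE",
    "MuDR",
    "CACTA",
    "Helitron",
    "Mariner",
    "HAT",
    "other",
)


@dataclass(frozen=True)
class TERecord:
    """A transposable-element annotation with family metadata.

    ``source`` records provenance: the primary genome annotation
    (``tair10``), a RepeatMasker screen (``repeatmasker``), or the
    intersection of the two (``reconciled``).
    """

    te_id: str
    family: str
    superfamily: str
    interval: GenomicInterval
    source: str = "tair10"

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("TE family must be non-empty")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class RepeatMaskerHit:
    """One RepeatMasker alignment of a library repeat to the genome.

    ``hit_coverage_fraction`` is the fraction of the library consensus
    covered by the alignment, computed from the repeat begin/end/(left)
    columns of the ``.out`` file.
    """

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    library_repeat_length: int
    hit_coverage_fraction: float

    def __post_init__(self) -> None:
        if self.library_repeat_length <= 0:
            raise ValueError("library_repeat_length must be positive")
        if not 0.0 <= self.hit_coverage_fraction <= 1.0 + 1e-12:
            raise ValueError(
                f"hit_coverage_fraction out of [0,1]: {self.hit_coverage_fraction}"
            )


@dataclass
class GeneModel:
    """A gene with its transcripts and derived introns.

    ``transcripts`` maps transcript id -> sorted, non-overlapping exon
    intervals.  Introns are the gaps between consecutive exons of one
    transcript.  The representative transcript used throughout the
    pipeline is the longest isoform (maximal summed exon length, ties
    broken by lexicographically smallest transcript id).
    """

    gene_id: str
    biotype: str
    interval: GenomicInterval
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    longest_transcript_id: str | None = None

    def __post_init__(self) -> None:
        for tid, exons in self.transcripts.items():
            exons.sort(key=lambda e: e.start)
            for a, b in zip(exons, exons[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping exons in transcript {tid}")
        if self.longest_transcript_id is None and self.transcripts:
            self.longest_transcript_id = pick_longest_transcript(self.transcripts)

    @property
    def strand(self) -> str:
        return self.interval.strand

    def exons(self, transcript_id: str | None = None) -> list[GenomicInterval]:
        tid = transcript_id or self.longest_transcript_id
        if tid is None:
            return []
        return self.transcripts[tid]

    def introns(self, transcript_id: str | None = None) -> list[GenomicInterval]:
        """Gaps between consecutive exons of one transcript, genomic order."""
        exons = self.exons(transcript_id)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end + 1:
                out.append(
                    GenomicInterval(a.chrom, a.end + 1, b.start - 1, a.strand)
                )
        return out

    def exon_length(self, transcript_id: str | None = None) -> int:
        return sum(e.length for e in self.exons(transcript_id))


def pick_longest_transcript(transcripts: dict[str, list[GenomicInterval]]) -> str:
    """Transcript with maximal summed exon length; ties -> smallest id."""
    return min(
        transcripts,
        key=lambda tid: (-sum(e.length for e in transcripts[tid]), tid),
    )
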