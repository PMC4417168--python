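"""Nei-Gojobori synonymous / nonsynonymous nucleotide diversity.

Per-gene piS and piN are estimated over a multi-accession codon alignment
using NG86 site counting (per codon position, the fraction of the three
possible single-base changes that are synonymous; changes to stop codons
count as nonsynonymous) and NG86 pathway averaging for multi-position
codon differences (all orderings of the mutational steps, excluding
pathways that pass through a stop codon, renormalizing).

Before estimation, codons are screened: start and stop codons are always
removed; a codon is excluded when any of its positions is missing in at
least ``missing_threshold`` accessions, when any accession carries a
premature stop at that codon, or when any position shows more than two
alleles.  Diversity is the average over unordered accession pairs of the
per-pair proportion of differences per site, restricted per pair to
codons where both accessions have complete data.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, stops mapped to '*'
GENETIC_CODE = dict(_table.forward_table)
GENETIC_CODE.update({c: "*" for c in _table.stop_codons})
STOP_CODONS = frozenset(_table.stop_codons)

DEFAULT_MIN_SYN_SITES = 100.0
DEFAULT_N_PERM = 10_000


def ng86_sites(codon: str) -> tuple[float, float]:
    """NG86 expected synonymous and nonsynonymous sites of one codon.

    Per position, the fraction of the three possible single-base changes
    that preserve the amino acid; changes producing a stop codon count as
    nonsynonymous.  The two outputs always sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no NG86 site decomposition")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[mutant] == aa:  # stop ('*') never equals a sense aa
                syn += 1 / 3
    return syn, 3.0 - syn


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 pathway-averaged synonymous / nonsynonymous differences.

    For k differing positions, every ordering of the k single-base steps
    is enumerated; orderings passing through a stop codon are excluded and
    the remainder renormalized.  If every pathway hits a stop (possible
    only for some 3-step pairs), all pathways are used and the case is
    logged.  The two outputs sum to k.
    """
    a, b = codon_a.upper(), codon_b.upper()
    if a in STOP_CODONS or b in STOP_CODONS:
        raise ValueError("NG86 differences undefined for stop codons")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    return _pathway_average(a, b, tuple(diff_pos))


@lru_cache(maxsize=None)
def _pathway_average(a: str, b: str, diff_pos: tuple[int, ...]) -> tuple[float, float]:
    paths = []
    for order in itertools.permutations(diff_pos):
        current = a
        steps = []
        through_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS and nxt != b:
                through_stop = True
            steps.append((current, nxt))
            current = nxt
        syn = sum(
            1.0 for c1, c2 in steps
            if GENETIC_CODE.get(c1) == GENETIC_CODE.get(c2)
        )
        paths.append((through_stop, syn))
    valid = [syn for stop, syn in paths if not stop]
    if not valid:
        logger.info("all NG86 pathways %s->%s pass through a stop; using all", a, b)
        valid = [syn for _, syn in paths]
    syn_mean = sum(valid) / len(valid)
    k = float(len(diff_pos))
    return syn_mean, k - syn_mean


@lru_cache(maxsize=1)
def _ng86_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized lookup tables over codon indices (NaN rows for stops)."""
    syn_sites = np.full(64, np.nan)
    for i, codon in enumerate(CODONS):
        if codon not in STOP_CODONS:
            syn_sites[i] = ng86_sites(codon)[0]
    d_syn = np.full((64, 64), np.nan)
    d_non = np.full((64, 64), np.nan)
    for i, a in enumerate(CODONS):
        if a in STOP_CODONS:
            continue
        for j, b in enumerate(CODONS):
            if b in STOP_CODONS:
                continue
            s, n = ng86_differences(a, b)
            d_syn[i, j] = s
            d_non[i, j] = n
    return syn_sites, d_syn, d_non


@dataclass
class CodonAlignment:
    """An in-frame multi-accession coding alignment for one gene."""

    gene_id: str
    accessions: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.accessions) != len(self.sequences):
            raise ValueError("accessions and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths {lengths}")
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length not a multiple of 3")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def char_matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])

    def codon(self, accession_index: int, codon_index: int) -> str:
        return self.sequences[accession_index][3 * codon_index: 3 * codon_index + 3]


def read_codon_alignment(path: str | Path, gene_id: str | None = None) -> CodonAlignment:
    """Read a per-gene multi-FASTA codon alignment (one record per accession)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return CodonAlignment(
        gene_id=gene_id or path.stem,
        accessions=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


def screen_codons(
    aln: CodonAlignment, missing_threshold: int | None = None
) -> list[int]:
    """Indices of codons usable for diversity estimation.

    Start and final (stop) codons are always removed.  An internal codon
    is excluded when (i) any of its three positions is missing (non-ACGT)
    in >= ``missing_threshold`` accessions (default ceil(0.75 * n), i.e.
    60 of 80), (ii) any accession carries a complete premature stop codon
    there, or (iii) any position shows more than two alleles.
    """
    if aln.n_codons < 3:
        return []
    n = aln.n_accessions
    if missing_threshold is None:
        missing_threshold = math.ceil(0.75 * n)
    chars = aln.char_matrix()
    valid = np.isin(chars, list(BASES))
    usable = []
    for j in range(1, aln.n_codons - 1):
        cols = slice(3 * j, 3 * j + 3)
        ok = valid[:, cols]
        # (i) missing-data load per position
        if ((~ok).sum(axis=0) >= missing_threshold).any():
            continue
        # (ii) premature stops in any accession with a complete codon
        complete = ok.all(axis=1)
        codons_here = ["".join(row) for row in chars[complete, cols]]
        if any(c in STOP_CODONS for c in codons_here):
            continue
        # (iii) no tri-/tetra-allelic positions
        multi = False
        for p in range(3):
            col = chars[:, 3 * j + p]
            alleles = set(col[valid[:, 3 * j + p]])
            if len(alleles) > 2:
                multi = True
                break
        if multi:
            continue
        usable.append(j)
    return usable


@dataclass
class DiversityResult:
    gene_id: str
    syn_sites: float
    nonsyn_sites: float
    pi_S: float
    pi_N: float
    ratio: float | None
    n_codons_used: int
    n_pairs: int


def gene_diversity(
    aln: CodonAlignment,
    usable: list[int] | None = None,
    min_syn_sites: float = DEFAULT_MIN_SYN_SITES,
    missing_threshold: int | None = None,
) -> DiversityResult | None:
    """NG86 diversity of one gene over all accession pairs.

    Per unordered pair, site and difference counts are accumulated over
    the usable codons where both accessions have complete data (per-codon
    pairwise deletion); sites are the average of the two sequences' NG86
    site counts.  piS is the mean over pairs of syn_diffs / syn_sites,
    piN analogously.  Returns None when the gene is discarded: fewer than
    ``min_syn_sites`` expected synonymous sites (average over pairs) or
    fewer than two accessions with data.
    """
    if usable is None:
        usable = screen_codons(aln, missing_threshold=missing_threshold)
    if not usable:
        logger.info("%s discarded: no usable codons", aln.gene_id)
        return None
    syn_sites_tab, d_syn, d_non = _ng86_tables()

    # codon-index matrix, -1 for incomplete/ambiguous codons
    n = aln.n_accessions
    idx = np.full((n, len(usable)), -1, dtype=np.int32)
    for i, seq in enumerate(aln.sequences):
        for k, j in enumerate(usable):
            codon = seq[3 * j: 3 * j + 3]
            code = CODON_INDEX.get(codon, -1)
            if code >= 0 and CODONS[code] not in STOP_CODONS:
                idx[i, k] = code

    has_data = (idx >= 0).any(axis=1)
    acc = np.flatnonzero(has_data)
    if acc.size < 2:
        logger.info("%s discarded: <2 accessions with data", aln.gene_id)
        return None

    pair_syn_sites, pair_non_sites = [], []
    pair_pi_s, pair_pi_n = [], []
    for ai, aj in itertools.combinations(acc, 2):
        ci, cj = idx[ai], idx[aj]
        mask = (ci >= 0) & (cj >= 0)
        if not mask.any():
            continue
        s_i = syn_sites_tab[ci[mask]]
        s_j = syn_sites_tab[cj[mask]]
        syn_sites = float((s_i + s_j).sum()) / 2.0
        total_sites = 3.0 * int(mask.sum())
        syn_diffs = float(d_syn[ci[mask], cj[mask]].sum())
        non_diffs = float(d_non[ci[mask], cj[mask]].sum())
        pair_syn_sites.append(syn_sites)
        pair_non_sites.append(total_sites - syn_sites)
        pair_pi_s.append(syn_diffs / syn_sites if syn_sites > 0 else 0.0)
        pair_pi_n.append(
            non_diffs / (total_sites - syn_sites) if total_sites > syn_sites else 0.0
        )
    if not pair_pi_s:
        logger.info("%s discarded: no accession pair with shared data", aln.gene_id)
        return None

    syn_sites = float(np.mean(pair_syn_sites))
    nonsyn_sites = float(np.mean(pair_non_sites))
    if syn_sites < min_syn_sites:
        logger.info(
            "%s discarded: %.1f synonymous sites < %.0f", aln.gene_id, syn_sites, min_syn_sites
        )
        return None
    pi_s = float(np.mean(pair_pi_s))
    pi_n = float(np.mean(pair_pi_n))
    return DiversityResult(
        gene_id=aln.gene_id,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        pi_S=pi_s,
        pi_N=pi_n,
        ratio=(pi_n / pi_s) if pi_s > 0 else None,
        n_codons_used=len(usable),
        n_pairs=len(pair_pi_s),
    )


def group_permutation_test(
    ratios_a,
    ratios_b,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Two-sided permutation test on the difference of group mean ratios.

    p = (#permutations with |mean difference| >= observed + 1) / (n_perm + 1).
    Returns (mean_a, mean_b, p).
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("permutation test requires non-empty groups")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(perm[: a.size].mean() - perm[a.size:].mean())
        if diff >= observed - 1e-15:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return float(a.mean()), float(b.mean()), float(p)
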