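# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `intragenic_te`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and annotation reconciliation

All intervals are 1-based and closed (the GFF3 convention); any half-open
export converts explicitly at the boundary. "Within 50 bp of each other"
is interpreted as an inter-record gap `next.start − prev.end − 1 ≤ 50`, so
abutting or overlapping same-family records always merge, and merging is
applied transitively (verified against a union–find oracle). "Shorter than
50 bp excluded" keeps records of exactly 50 bp; the RepeatMasker screens
are read with the same strictness (hits of exactly 100 bp and exactly 70%
consensus coverage are kept). The RepeatMasker class exclusion list is a
configurable set matched case-insensitively as substrings
(`Simple_repeat`, `Low_complexity`, `rRNA`, `Satellite`, `centr`,
`composite`), because repeat libraries vary in their exact class strings.
TAIR10-style records are retained with their own coordinates when they
share at least `--min-overlap` (default 1) bp with a screened hit; no
reciprocal-overlap requirement is imposed, but the threshold is
configurable. Strand is carried but ignored for merging and overlap.

## Gene models and classification

Gene biotypes are restricted to protein-coding and ncRNA. One
representative transcript per gene — the longest isoform by summed exon
length, ties broken by smallest transcript id — defines introns for every
downstream stage, so classification, pre/post splitting and expression all
share a single gene model. A TE is intragenic iff its interval is
contained in a gene's full extent (UTRs and introns included); when nested
genes both contain a TE, the smallest-span gene hosts it (logged).
Intronic means strictly more than 95% of the TE length inside the union of
the representative transcript's introns; a TE at exactly the threshold is
exonic. Counting against the intron union of a single transcript (rather
than any single intron, or a union across isoforms) keeps one consistent
gene model; the threshold and the transcript choice are configurable.

## Methylation

Per-TE levels are the coverage-weighted pooled ratio
`Σ methylated / Σ (methylated + unmethylated)` over cytosines of one
context inside the TE, both strands pooled, after excluding sites covered
by fewer than 3 reads. The weighted ratio (rather than the mean of
per-site ratios) matches the #C/(#C+#T) definition applied to pooled
counts. Symmetric CG pairs are not collapsed; sites enter as reported.
High/low methylation classes always derive from wild-type CHG level at the
20% boundary (≥20% is high), never from mutants. For group comparisons,
TEs with undefined or exactly zero methylation in the context under test
are excluded (raw tables keep zeros). Group contrasts use the two-sided
Mann–Whitney U test with mean ± SE reported alongside.

## Downstream-transcription-defect test

Reads are counted per exon (genomic order of the representative
transcript); the TE-containing intron is the intron with maximal overlap
with the TE. Pre/post follow transcription: on the minus strand the
genomically downstream exons are *pre*. A (gene, TE, genotype) record is
tested only when wild-type pre and post counts and the mutant pre count
are all ≥10. The two-sided Fisher's exact p on
`[[pre_wt, post_wt], [pre_mut, post_mut]]` is BH-adjusted across all
tested genes of that genotype; the D label additionally requires a
directional downstream reduction, `ratio_change = (post/pre)_mut /
(post/pre)_wt < 1`, because a transcription *defect* is one-sided while
the test itself is not. "P ≤ 0.01 with BH correction" is read as adjusted
q ≤ 0.01. Multiple intronic TEs in one gene are tested independently; a
sensitivity mode deduplicates to one representative TE per gene (the
longest; ties broken by highest wild-type CHG methylation).

## Nei–Gojobori diversity

Expected synonymous sites per codon are the per-position fractions of the
three single-base changes that preserve the amino acid; changes to stop
codons count as nonsynonymous, so the synonymous and nonsynonymous sites
of every sense codon sum to 3. Multi-position codon differences average
the synonymous/nonsynonymous step counts over all orderings of the
single-base steps, excluding orderings that pass through a stop codon and
renormalizing (if every ordering hits a stop, all are used and the case is
logged). Both primitives are verified exhaustively against an independent
enumeration for all 61 sense codons and all sense-codon pairs, and are
compiled into 64×64 lookup tables for vectorized pairwise accumulation.

Codon screens: start and final stop codons are always removed; an internal
codon is excluded when any of its positions is missing (non-ACGT) in at
least `missing_threshold` accessions — literally "missing in ≥60 of 80",
generalized as `ceil(0.75 n)` for other panel sizes, with the alternative
"data present in ≥ threshold" reading available by passing an explicit
threshold — when any accession carries a complete premature stop codon
there, or when any position shows more than two alleles.

Diversity is averaged over unordered accession pairs with per-codon
pairwise deletion (both accessions complete at that codon), which is what
permits up to 59 missing accessions per position. Per pair, site counts
average the two sequences' NG86 site counts; πS is the mean over pairs of
`syn_diffs / syn_sites`, πN analogously. Genes with fewer than 100
expected synonymous sites (average over pairs) are discarded. Note that
with missing data the per-pair site totals cover only the codons shared by
that pair, so the site-conservation identity
`syn_sites + nonsyn_sites = 3 × n_codons_used` holds exactly only for
complete data. The group comparison takes the mean of per-gene πN/πS
ratios (genes with πS = 0 are excluded and counted); the permutation test
is two-sided on the absolute difference of group means with add-one
smoothing, `p = (x+1)/(n_perm+1)`, 10 000 permutations by default, seeded.

## Statistics

Two-sided alternatives everywhere; directionality is applied by callers
(the D label). The Mann–Whitney U test uses the exact permutation null for
total n ≤ 12 without ties and the tie-corrected normal approximation
otherwise. Fisher's exact two-sided p sums the probabilities of all
margin-fixed tables no more likely than the observed one. BH is the
standard step-up adjustment, permutation-invariant and capped at 1.
Bonferroni multiplies by the number of tests in the family (the number of
superfamilies tested, for insertion-bias contrasts). All four are
validated against brute-force enumeration oracles in the test suite.

## Synthetic data: what it emulates, and what it does not

The generator plants genes (1–10 exons, occasional second isoform,
protein-coding/ncRNA/excluded biotypes), TEs of known category with the
genome-wide default composition 88% intergenic / 3% intragenic / 9% other
and 85% of intragenic TEs intronic, a RepeatMasker-style file supporting a
configurable fraction (default 0.9) of TEs plus junk hits every screen
must remove, sub-50-bp decoy records, and deliberately split same-family
fragments (gap ≤ 50 bp) whose merge restores the planted span. Two
generator-level constraints keep the truth labels exact through the
reconciliation: planted TEs shorter than 100 bp are never marked
RepeatMasker-supported (a qualifying ≥100-bp hit cannot fit inside them),
and supported TEs get hits jittered only inward.

Methylomes place cytosines at 0.15/bp inside TEs (contexts 30/30/40%
CG/CHG/CHH), coverage Poisson(30), methylated counts binomial around the
per-TE true mean: a high/low class mean (e.g. CHG 0.40 vs 0.05) with small
per-TE jitter, times a per-genotype, per-context loss factor encoding the
known pathway dependencies (CG maintenance by MET1/DDM1; CHG by
CMT3/KYP/SUVH5-6; CHH by RdDM and CMT2; IBM1 neutral at TEs).

RNA-seq counts follow a gamma–Poisson model: each (gene, genotype) draws a
gamma abundance multiplier (mean 1, variance = dispersion, default 0.1)
shared by all exons of the transcript, and exon counts are Poisson around
`expression × exon_length × multiplier`. Each count is therefore
marginally negative binomial with variance `m + 0.1 m²`, while the
within-transcript pre/post ratio stays at its expectation — the standard
RNA-seq noise model, and the construction under which Fisher's exact test
on pre/post contrasts is calibrated. (Drawing each region's
overdispersion independently would make the Fisher test anticonservative
by construction and would model two regions of one transcript as if they
were independent libraries.) Genes planted as defective multiply the
means of transcriptionally downstream exons by the defect ratio (default
0.2) in the affected mutant.

Codon alignments sprinkle biallelic SNPs on distinct codon columns:
synonymous and nonsynonymous changes are placed so that expected pairwise
diversity per site matches the targets θS = 0.01 and θN = 0.004 (a SNP
with derived-allele count d among n accessions contributes
`d(n−d)/C(n,2)` expected pairwise differences; d is uniform on 1..n−1).
Missing NNN codons, premature-stop columns and tri-allelic columns are
injected on SNP-free columns to exercise the screens without perturbing
the targets. This is deliberate "mutation sprinkling", not a coalescent:
the estimator consumes pairwise diversity, so matching the pairwise target
suffices, and no linkage, recombination or demographic structure is
emulated.

Default problem sizes (60 genes, 300 TEs, 10 genotypes, 80 accessions ×
300 codons × 12 genes) keep a full simulate-plus-pipeline run in the
seconds range; recovery experiments in the tests use 500 codons and
coverage 50 where the properties call for them. Passing tests on this
generator demonstrate correct bookkeeping, calibration and parameter
recovery under the stated noise models — they do not demonstrate
robustness to features of real data the generator omits: mappability and
coverage biases, non-uniform cytosine density, isoform switching, reads
spanning exon junctions (counts are consumed per exon, attributed by
5′ end), TE nesting, or linkage among polymorphisms.

## Numerical and degenerate-input conventions

Methylation levels are undefined (NaN) with zero qualifying sites;
relative deltas are undefined at wild-type level 0. The defect caller
propagates NaN p/q for filtered records. χ² contingency tests use no
continuity correction (matching the textbook statistic); superfamilies
with empty margins are reported with p = 1 or skipped with a log entry.
Ties in Mann–Whitney fall back to the asymptotic path at any sample size.
Floating-point boundary comparisons that implement "kept at exactly the
threshold" use a 1e-12 tolerance. The permutation p never returns 0 by
construction. All generator randomness flows through one
`numpy.random.Generator`; identical seeds give byte-identical output
files.

## Known limitations

- Read alignment, DMR calling, isoform quantification and premature-poly(A)
  detection are out of scope; the pipeline consumes per-cytosine calls and
  per-region counts.
- The NG86 estimator uses no multiple-hit (Jukes–Cantor) correction, which
  is standard for within-species diversity at these levels but biases πS
  downward slightly at high divergence.
- Per-codon pairwise deletion can use different codon subsets for
  different pairs; site totals are reported as pair averages.
- The 2×2 enrichment χ² is asymptotic; very sparse superfamilies should be
  read with care (counts are reported alongside).
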