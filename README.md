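# intragenic-te

A tested, reusable pipeline for genome-wide analysis of **intragenic
transposable elements (TEs)** in *Arabidopsis thaliana*-style annotations:
how many TEs sit inside gene bodies, where they sit (introns vs exons), how
they are DNA-methylated across epigenetic-mutant genotypes, whether losing
CHG methylation at an intronic TE disrupts transcription of the exons
downstream of it, and whether TE-bearing genes show relaxed selective
constraint.

It is aimed at plant epigenomics / regulatory genomics researchers who have
a gene annotation (GFF3), TE annotations (GFF3/TSV plus RepeatMasker
`.out`), per-cytosine bisulfite call tables, per-exon RNA-seq counts and
multi-accession codon alignments — or who want to exercise the full
analysis on generated data with known ground truth before committing to
downloads.

## What it computes

1. **TE-set reconciliation** — same-family TE records within 50 bp are
   concatenated, records shorter than 50 bp dropped, and the result is
   intersected (≥1 bp overlap) with a screened RepeatMasker annotation
   (classes such as simple repeats and satellites excluded; hits <100 bp or
   covering <70% of the library consensus removed).
2. **Classification** — each TE is *intragenic* (fully inside a filtered
   protein-coding/ncRNA gene), *intergenic* (no overlap), or *other*
   (partial overlap). An intragenic TE is *intronic* when more than 95% of
   its length lies within introns of the host's longest isoform, else
   *exonic*. Per-superfamily insertion bias is tested with 2×2 χ²
   (Bonferroni-corrected); length contrasts with the Mann–Whitney U test.
3. **Methylation** — per-TE, per-context (CG/CHG/CHH) levels as the pooled
   ratio #C/(#C+#T) over cytosines covered by ≥3 reads; TEs are classed
   high/low from wild-type CHG methylation at 20%; per-genotype deltas
   quantify methylation loss in mutants.
4. **Downstream-transcription defects** — for a gene with an intronic TE,
   exonic reads are split into *pre* and *post* of the TE-containing intron
   (strand-aware). Wild type vs mutant is tested with a two-sided Fisher's
   exact test on `[[pre_wt, post_wt], [pre_mut, post_mut]]`; after
   Benjamini–Hochberg correction a gene is labeled **D** (defect) iff
   q ≤ 0.01 and `(post/pre)_mut < (post/pre)_wt`, subject to ≥10-read
   filters. The D/ND contrast in CHG-methylation loss is the pipeline's key
   association statistic.
5. **Selective constraint** — per-gene πN and πS by the Nei–Gojobori (NG86)
   method over all accession pairs, after codon screens (start/stop removed;
   codons with a position missing in ≥60 of 80 accessions, with a premature
   stop in any accession, or with >2 alleles at a position are excluded;
   genes with <100 expected synonymous sites discarded). Group means of
   πN/πS are compared by a seeded permutation test.

A synthetic-data generator (`intragenic_te.synthetic_data`) emits every
input format with recorded ground truth, so each stage is testable without
downloads.

## Worked example

```bash
intragenic-te simulate --seed 1 -o sim
intragenic-te report --inputs sim -o out
```

prints (output of the commands above):

```
intragenic-TE pipeline report
==============================
seed: 1
TE set: 236 TEs
  intergenic: 206 (87%)
  intragenic: 9 (4%)
  other: 21 (9%)
  intronic: 8 (89%)
  exonic: 1 (11%)
host genes: 9
  only-exonic: 1 (11.1%)
  only-intronic: 8 (88.9%)
defects[cmt3]: D=2 ND=3 filtered=3
defects[ddm1]: D=2 ND=3 filtered=3
defects[kypsuvh56]: D=1 ND=4 filtered=3
defects[met1]: D=3 ND=2 filtered=3
piN/piS: with_te=0.465 vs without_te=0.413 (permutation p=0.3864)
```

Reading this: of the 236 reconciled TEs, 9 lie fully inside gene bodies
(87% / 4% / 9% across intergenic / intragenic / other — the generator's
defaults plant the genome-wide 88/3/9 composition, and the small-sample
draw lands near it), and 8 of those 9 are intronic. In each mutant
genotype, the genes whose intronic-TE methylation the generator planted as
disrupted are flagged **D** when the downstream read drop is significant
after BH correction; shallowly covered genes are `filtered` by the 10-read
rules. The πN/πS group means are statistically indistinguishable
(permutation p = 0.39), as expected since both groups were generated with
the same synonymous/nonsynonymous diversity targets — no relaxation of
constraint on TE-bearing genes.

Per-stage artifacts (`te_set.tsv`, `classifications.tsv`,
`te_methylation.tsv`, `defects.tsv`, `diversity.tsv`, …) land next to the
report; each stage is also available as its own subcommand
(`build-te-set`, `classify`, `methylation`, `popgen`) or directly as
library functions.

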