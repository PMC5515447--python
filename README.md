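# amplihap

Deep-sequencing profiler for **intragenomic variation (IaGV)** of a
multi-copy amplicon such as the nuclear ribosomal **ITS2**.

The ITS2 spacer sits inside the tandemly repeated rRNA cistron, so one
genome carries hundreds of copies. When concerted evolution fails to
homogenize them — as suspected for largely asexual green algae like
*Haematococcus pluvialis* — different copies accumulate different
polymorphisms, and the "sequence" of an isolate is really a *frequency
spectrum of haplotypes*. `amplihap` estimates that spectrum from
paired-end (2×300 bp style) amplicon reads, quantifies its
reproducibility across replicate runs, compares diversity within and
between groups of haplotypes, and builds distance trees.

It is aimed at researchers profiling rRNA spacer variation who want a
scriptable, fully reproducible alternative to chains of point-and-click
vendor tools.

## Method

Given paired FASTQ files and a single-record reference FASTA, the
pipeline:

1. **filters** reads (length ≥ 250 bp, mean Phred quality ≥ 30; a pair
   is dropped if either mate fails) and trims 3′ adapter read-through;
2. **merges** each pair into one amplicon-spanning sequence — the
   overlap offset maximizing overlap length subject to a mismatch
   fraction ≤ 0.1 wins, and within the overlap the higher-quality base
   is taken;
3. **maps** every merged read to the reference by global affine-gap
   alignment (match +1, mismatch −2, gap open −5, gap extend −2) and
   extracts a canonical variant profile: runs of adjacent mismatched
   sites collapse into multi-nucleotide substitutions (DNPs), and
   indels are left-aligned; coordinates are 1-based reference sites;
4. **subsamples** the mapped reads — five independent random draws of
   10,000 reads without replacement — and within each draw groups reads
   by their variant set;
5. averages frequencies across the draws, keeps **demonstrable
   variants** (averaged site frequency ≥ 1%, inclusive), defines
   **haplotypes as unique sets of demonstrable variants**, and reports
   each retained haplotype (averaged frequency ≥ 1%) as H1, H2, … in
   descending frequency, with sub-threshold combinations pooled into a
   background bucket.

Haplotype frequencies are estimates of the relative copy number of each
ITS2 variant in the genome; for a sample with *n* retained haplotypes
at frequencies *f₁ ≥ f₂ ≥ …*, H1 is the dominant haplotype and the
sample is *co-dominant* when *f₁ − f₂* < 0.05.

Downstream, `amplihap` computes uncorrected **p-distances**
(differing sites / compared sites, gap columns excluded pairwise),
within/between-group mean distances with unweighted grand means,
pooled and Welch two-sample *t*-tests on group means, per-haplotype
replicate summaries (mean, sample SD, SE = SD/√n), and
**neighbor-joining trees** with column-resampling bootstrap supports.

A ground-truthed simulator (`amplihap simulate`) generates reference +
paired FASTQ + truth table for arbitrary haplotype mixtures with
per-base substitution/indel errors, so every estimate the pipeline
produces can be scored against known truth.

## Worked example

Simulate a 350 bp amplicon sequenced at 50,000 pairs with per-base
error 10⁻³, containing four haplotypes — the reference at 62%, a SNP
haplotype at 25%, a two-SNP haplotype at 9%, and a deletion haplotype
at 4%:

```sh
amplihap simulate --out-dir sim --length 350 --seed 7 \
    --haplotype "0.62:." --haplotype "0.25:61G>T" \
    --haplotype "0.09:61G>T;141G>A" --haplotype "0.04:220-T" \
    --error-rate 0.001 --n-pairs 50000

amplihap profile --r1 sim/sim_R1.fastq --r2 sim/sim_R2.fastq \
    --reference sim/reference.fasta --sample-id demo --seed 7 --out-dir prof
```

which prints

```
demo: 4 retained haplotype(s), background 0.0006
  H1    0.6206
  H2    0.2528
  H3    0.0877
  H4    0.0384
```

and writes `prof/demo_haplotypes.tsv` with the per-subsample
frequencies behind those means:

```
Haplotype  Variants       R1        R2        R3        R4        R5        Mean
H1         .              0.620200  0.616100  0.617500  0.623900  0.625100  0.620560
H2         61G>T          0.254900  0.255200  0.255700  0.250400  0.247600  0.252760
H3         61G>T;141G>A   0.086100  0.088100  0.087400  0.087700  0.089200  0.087700
H4         220-T          0.038000  0.040100  0.038800  0.037600  0.037300  0.038360
background .              -         -         -         -         -         0.000620
```

All four true haplotypes are recovered within a few parts per thousand
of their true frequencies, and the sequencing-error background (0.06%)
stays far below the 1% reporting threshold. `prof/demo_haplotypes.fasta`
holds the realized haplotype sequences for downstream comparisons:

```sh
amplihap stats --fasta haplotypes.fasta --groups groups.tsv --aligned \
    --seed 7 --out-dir stats
```

prints, for a small two-group example,

```
grand within-group mean p-distance:  0.100000000
grand between-group mean p-distance: 0.200000000
NJ tree written to stats/nj_tree.nwk
```

i.e. haplotypes differ on average at 10% of sites within a group and
20% between groups; the newick tree carries bootstrap percentages as
internal node labels.

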