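# Methods

## Problem setting

A multi-copy locus such as the rRNA ITS2 is amplified from one genomic
template and sequenced deeply with overlapping paired-end reads. Each
fragment is a faithful (up to PCR and sequencing error) copy of *one*
repeat unit, so the set of merged reads is a sample from the genome's
internal haplotype distribution. The estimand is that distribution: the
identity of each haplotype (its variant set relative to a single
reference) and its relative frequency.

## Haplotype model

A haplotype is identified with its set of variant events against the
reference: substitutions of length ≥ 1 (adjacent substituted sites are
one multi-nucleotide event — the DNP of site-table notation),
insertions anchored to the site they follow, and deletions. The empty
set is the reference haplotype. Coordinates are 1-based reference
sites throughout, matching the convention of published site tables
("a T at site 61"). Working with event sets rather than raw strings
makes haplotype identity insensitive to alignment presentation; two
full-length reads have the same event set exactly when they have the
same sequence.

Indels inside repeats have no unique alignment placement; published
site tables acknowledge placing them arbitrarily. Here every indel is
**left-aligned** to its lowest-position equivalent placement, which
replaces the arbitrariness with a deterministic canonical form.

## Frequency estimation

All merged reads are mapped once; subsampling then operates on the
mapped variant profiles. This is statistically identical to drawing
reads first and mapping each draw (mapping is a pure per-read
function) but is cheaper and exactly repeatable. Defaults follow the
deep-sequencing protocol this package reimplements: five replicate
draws of 10,000 reads, uniform, without replacement, with replicate
*i* seeded as `seed + i`. When fewer than 10,000 mapped reads exist,
the full set is used in every replicate and a warning is logged.

The reporting threshold (default 1%, **inclusive**) is applied to
frequencies *averaged over the replicate draws*, in two stages:

1. **Variant stage.** Every variant event's site frequency (share of
   reads carrying it) is averaged; events at or above the threshold
   are *demonstrable*.
2. **Haplotype stage.** Each read is characterized by the subset of
   its variants that are demonstrable; haplotypes are the distinct
   such subsets, their frequencies are re-averaged over the same
   draws, and those at or above the threshold are retained and
   labelled H1, H2, … by descending averaged frequency. Sub-threshold
   subsets are pooled into one background bucket.

The second stage is the load-bearing design choice. At a per-base
error of 10⁻³ on a 350 bp amplicon, roughly a quarter of merged reads
carry at least one surviving miscall. If haplotypes were equated with
*raw* event sets, each of those reads would form a private singleton
haplotype and every true haplotype's frequency would be deflated by
that same quarter — a dominant haplotype at 0.55 would be reported
near 0.39. Classifying reads by their demonstrable variants instead
makes the estimator unbiased at first order: a read with a private
sub-threshold miscall still counts toward the haplotype defined by its
demonstrable variants, retained frequencies sum to ≈ 1, and spurious
variants (each at ~error-rate/3 per specific substitution) never
approach the threshold. It also mirrors how site-frequency tables and
haplotype tables coexist in published intragenomic-variation reports:
haplotypes are *unique sets of demonstrable polymorphisms*, not unique
read strings. The cost is a small cross-talk term (a miscall at a
demonstrable site can move a read between retained haplotypes) of
order error-rate/3 per site, far inside the reported precision.

One consequence worth stating: a genuine haplotype whose frequency
sits below the threshold is not shunted to the background — its reads
are absorbed by the haplotype of its demonstrable variants (usually
the reference pattern). Distinguishing "rare true variant" from
"error" below the threshold is exactly what this class of protocol
declines to do.

A haplotype whose true frequency sits *exactly at* the threshold is
retained or not on a sampling coin flip: with 50,000 pairs the
realized frequency of a 1% haplotype has standard deviation ≈ 0.0005,
so the inclusive ≥ 0.01 test passes in about half of runs. The
acceptance script therefore reports boundary retention as a value
rather than asserting it.

Dominance: H1 is the dominant haplotype; the sample is flagged
co-dominant when at least two haplotypes are retained and the top two
averaged frequencies differ by less than 0.05 — the margin is chosen
so that the replicate-to-replicate wobble of frequency estimates
(empirically ≈ 0.03–0.04 for co-dominant samples) falls inside it; it
is configurable.

## Read preparation

The length/quality filter interprets "minimum quality 30" as a minimum
**mean** Phred score per read. A per-base floor of Q30 would discard
essentially all 2×300 data and is incompatible with the retained-read
counts such protocols report; the mean reading is recorded as an
assumption. Pairs are dropped whole if either mate fails.

Adapter trimming removes a 3′ suffix matching an adapter prefix over
at least 8 columns with at most one mismatch (longest such suffix
wins). With ≤ 1 mismatch over ≥ 8 columns, one of the adapter's first
two 4-mers must occur exactly, so candidate positions are found by
4-mer seeding rather than scanning every offset.

Merging scans overlap offsets and keeps the longest admissible overlap
(mismatch fraction ≤ 0.1), breaking ties by fewer mismatches, then by
smaller offset. In the overlap the higher-quality base wins; on equal
quality the forward base is taken (a documented deterministic
convention); consensus quality is the max of the two. `min_overlap`
defaults to 30 bp. An inadmissible pair is a merge *failure*, not an
error, and is counted.

## Alignment and variant extraction

Merged reads are globally aligned to the reference (amplicons span the
locus, so local alignment would be wrong) under affine-gap scoring
match +1, mismatch −2, gap open −5, gap extend −2, where a gap of
length *k* costs 5 + 2(*k* − 1). The first optimal alignment of the
deterministic traceback is used. Reads whose mismatched plus gapped
columns exceed 25% of the reference length, or whose alignment leaves
terminal gaps longer than 5 columns, are flagged unmapped and carry no
events; within-genus ITS2 distances stay below ~0.17, so genuine reads
map with ample margin. Since the profile is a pure function of the
read sequence, identical reads share one alignment — at depth 50,000 a
typical library has only ~10⁴ distinct merged sequences, which keeps
the mapping pass to seconds.

## Diversity and reproducibility statistics

p-distance is the proportion of differing sites among compared sites,
with columns containing a gap in either sequence excluded (pairwise
deletion — the treatment for gapped sites is an assumption, chosen to
keep indel-bearing haplotypes comparable). Unaligned pairs are first
aligned with the same affine scheme as mapping. Group summaries
average over all unordered within-group pairs and all cross pairs;
grand means are **unweighted** averages of the group-level values,
matching how published summary rows are computed. Replicate summaries
use the sample (n−1) standard deviation — confirmed against published
two-replicate rows, which are inconsistent with the n denominator —
and SE = SD/√n. Both pooled and Welch two-sample *t*-tests are
provided; Welch is the default because it reproduces the published
comparisons of group-mean distances.

## Trees

Neighbor joining is the classic Saitou–Nei agglomeration with the Q
criterion, ties broken on the lowest index pair, and the final three
nodes resolved by the three-point closed form. Negative branch
lengths are clamped to zero with the deficit moved to the sibling
edge. Bootstrap supports resample alignment columns with replacement,
rebuild the NJ tree per replicate, and report the percentage of
replicates containing each internal split of the original tree;
splits sitting on zero-length original edges are treated as unresolved
and receive no support. Sequence-only p-distance NJ stands in for
structure-guided reconstructions: secondary-structure homology
modeling, sequence–structure alignment, and likelihood searches are
out of scope, and the topological differences among such methods on
this kind of data are reported to lack robust support anyway.

## Synthetic data

The generator emulates the targeted study design: a 200–400 bp
amplicon, haplotype mixtures with a dominant frequency anywhere in
0.35–0.98, 2×300 bp pairs (forward = 5′ prefix, reverse = reverse
complement of the 3′ suffix), Nextera-style adapter read-through when
the fragment is shorter than the read, multinomial haplotype
assignment (so frequency-recovery tests face genuine sampling noise),
and a truth table naming each pair's source haplotype.

Errors are independent per base: substitutions at `error_rate`
(default 3×10⁻³) and 1-base indels at `indel_error_rate` (default
10⁻⁵). The substitution default is calibrated so the per-distinct-
variant background after merging lands near 0.1% — the empirical
error floor (5–15 reads per 10,000) below the 1% threshold. The indel
rate reflects Illumina chemistry, where indel miscalls are roughly two
orders of magnitude rarer than substitutions; an indel error near a
read's 3′ end shifts the overlap and can survive the equal-quality
consensus as a canonical junction artifact, so an unrealistically high
indel rate would manufacture a background with no real-data
counterpart. Base qualities are a constant Q37 and deliberately
uncoupled from the injected errors: the pipeline's filters act on
summary quality only, so a full error–quality coupling would add
machinery without exercising any additional code path.

What the simulator does **not** model: PCR amplification bias between
primer sets, chimera formation, quality decay along the read (beyond
an optional hook), and batch effects between runs. Passing the
recovery tests therefore shows the *computational* pipeline is
unbiased and well-calibrated under the stated error model, not that
wet-lab artifacts cannot distort real spectra.

## Problem sizes and determinism

The study-scale checks run 50,000 pairs on a 350 bp amplicon with
five haplotypes {0.55, 0.30, 0.10, 0.04, 0.01} at substitution error
10⁻³ — the dominant-to-threshold span observed in real isolates —
profiled with the default 5 × 10,000 subsampling; smaller fixtures
(2,000–20,000 pairs) cover threshold semantics and round trips. Every
random step (reference generation, multinomial assignment, error
injection, subsampling, bootstrap) flows from explicit integer seeds
through independent `numpy` generators; identical config plus inputs
give byte-identical reports, and each run writes a manifest with the
tool version, config hash, and seeds.

## Known limitations

* No denoising: sub-threshold reads are classified, never corrected;
  haplotypes below 1% are invisible by design.
* The mean-quality reading of the Q30 filter and the pairwise-deletion
  gap treatment are assumptions where the original tool semantics are
  not public.
* Per-read agreement with the vendor mapper the protocol originally
  used is not claimed; the affine-gap scheme is a documented
  substitute.
* Frequencies are relative to mapped, merged reads; systematic
  merge-failure biases (e.g. haplotypes with very long indels) would
  propagate into the spectrum.
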