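# Methods

This package processes 5'-anchored template-switching (nanoCAGE) sequencing
reads into transcription-start-site (TSS) signal and digital gene-expression
statistics, and ships a ground-truth simulator so every stage can be
validated end to end. This note documents the models, the defaults and the
reasoning behind the design choices; nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Read model

The template-switching oligo is

```
head (24 nt)  barcode (6 nt)  UMI (8 nt)  TATA  GGG
TAGTCGAACTGAAGGTCTCCAGCA  XXXXXX  NNNNNNNN  TATAGGG
```

The sequencing primer anneals to the constant head, so a read as sequenced
is `barcode + UMI + TATA + G-run + cDNA insert`. Fifteen barcodes are
built in, three per oligo chemistry (R3 = RNA 3' end, D3 = DNA,
L1/L2/L3 = 1–3 locked-nucleic-acid G's). Parsing:

* **Barcode** matched exactly by default (`barcode_max_mismatch`,
  configurable to 1 with ambiguity → unassigned). Unassigned reads are
  retained in their own stream; demultiplexing is a strict partition
  (assigned / unassigned / artifact).
* **UMI** (8 nt) is parsed and carried through but never used to
  deduplicate — it plays no role in any statistic here.
* **Linker** removal requires the literal `TATA` and then strips *every*
  following G (minimum three). Capped templates cause the reverse
  transcriptase to reverse-transcribe the cap and extend the cDNA with
  extra cytosines, which appear as extra G's on the read; stripping the
  whole run removes them. The cost is that a genuine 5' end whose first
  base is G cannot be distinguished from a cap-derived G — an intrinsic
  ambiguity of the chemistry, see *Limitations*.
* **Insert** trimmed to `trim_length` = 31 nt, the length used for
  alignment and everything downstream.

## Artifact (tag-dust) filter

Reads made of oligo/adapter sequence ("empty constructs") carry no genomic
information. A read is flagged when ≥ `artifact_fraction` (default 0.8) of
its insert positions are covered by 12-nt windows that match the artifact
library within `artifact_k` = 1 error (semi-global). The library holds the
instantiated oligo for every barcode (UMI segment excluded so random bases
never score), linker tilings and linker→head junction constructs, plus any
configured adapters, and all reverse complements. The criterion is
deterministic and directly testable, unlike an FDR-based screen.

## rRNA screen

An insert is discarded when it, or its reverse complement, matches a
contaminant record semi-globally within `k` errors; `k` defaults to 10% of
the insert length (3 errors at 31 nt). Both strands are searched because
rRNA contamination appears on both strands in practice. Inserts shorter
than 12 nt are never flagged (too little information) and are counted
separately. Multiple contaminant records are supported (e.g. adding
mitochondrial rRNA).

## Approximate matching core

All fuzzy matching is semi-global (whole pattern vs. any substring of the
text, unit costs, `N` never matches — conservative for contaminant
detection). Two routes:

* `edit_distance_semiglobal` — Wagner–Fischer recurrence vectorised over
  text positions; the insertion dependency is closed with a prefix-minimum
  scan. Valid for any pattern length; this is the reference route.
* `myers_search` — Myers' bit-parallel column update (patterns ≤ 64 nt,
  the machine word). This is the mechanism on all hot paths.

A pigeonhole accelerator (`seeded_search`) splits the pattern into `k + 1`
chunks; any alignment with ≤ `k` errors contains one chunk verbatim, so
exact chunk occurrences delimit candidate windows verified bit-parallelly.
The hit set at ≤ `k` is provably identical to a full scan; when no hit
exists only the bound `distance > k` is guaranteed. The test suite checks
hit-set equality against an independent DP oracle on 1,000 random
instances and cross-checks distances against edlib.

## Built-in aligner

`naive_align` finds the best semi-global hit of an insert over both strands
of the genome (guard rail 10 Mb), `max_errors` = 3 for 31-nt inserts. Exact
occurrences are collected first at C speed; only inexact reads pay for the
seeded scan. Tied best hits make the read a multimapper, which is
discarded — CTSS counting needs unique 5' positions. External alignments
can be imported instead (SAM/BAM via pysam, BED6); coordinates are 0-based
half-open throughout, and the 5' end is `start` on `+` and `end − 1` on
`−`.

## Strand-invasion filter

During reverse transcription the TS oligo can hybridise to a complementary
region of the nascent first-strand cDNA and terminate it prematurely. The
resulting tag is recognisable after alignment: the *genomic* sequence
immediately upstream of its 5' end resembles the oligo's 3' end. The
filter reads the `w` = 7 bases upstream of the 5' end on the tag's strand
(reverse-complemented for `−` tags), counts Hamming mismatches against the
motif `TATAGGG`, and flags the tag at ≤ 2 mismatches. Window content,
length and threshold are configurable (`--invasion-motif`,
`--invasion-max-mm`); Hamming rather than edit distance because the window
is anchored to the 5' end. Tags whose window would run off the contig are
never flagged and are counted as edge cases.

On an i.i.d. uniform genome the chance that a random window passes is
exactly `Σ_{i≤2} C(7,i)·3^i / 4^7 = 211/16384 ≈ 1.29%` — the filter's
false-positive rate, verified empirically in the acceptance suite.

Filtering is applied per alignment (composes cleanly, recorded per read); a
cluster-level variant that removes clusters in which *every* tag is flagged
is available (`remove_invaded_clusters`), and filtered outputs follow the
`_nw_<threshold>` naming convention. The per-sample invasion rate is
reported with a binomial standard error; an optional Rogan–Gladen
background correction `(rate − q)/(1 − q)` is available for analyses where
the background match rate `q` is known (e.g. uniform genomes).

## CTSS clustering

Tag 5' ends are tallied per (chromosome, position, strand, sample) into
CTSS. Clusters are single-linkage: consecutive CTSS on one
chromosome/strand join while the gap is ≤ `max_gap` (default 20 nt,
exposed as `--cluster-gap`); no expression threshold is applied. The
cluster peak is the CTSS with the largest summed count, ties broken toward
the smaller coordinate (deterministic output). Counts are scaled to tags
per million (TPM) over each library's total; per-sample TPM are averaged
across replicates for track display. Clustering is idempotent and
order-independent, and conserves tags exactly (Σ cluster counts = input
alignments), all property-tested against a connected-components oracle.

## Annotation baskets

Gene models come from GTF (exon lines grouped by transcript) or BED12 and
are indexed as strand-aware interval trees. The promoter is ±100 nt around
*every* transcript start of a gene, merged. A cluster is classified by its
peak CTSS base — a single position cannot straddle baskets — with
precedence promoter > exon > intron > other, same strand only (an
unstranded mode exists for antisense exploration, and `--annotate-by=hull`
classifies by the full cluster interval). The promoter/exon tag ratio is
the headline cap-specificity summary: capped reads pile up at transcript
starts, uncapped internal priming scatters over exons.

## Digital expression

Gene counts sum same-strand cluster tags (promoter + exon + intron
baskets). Pairwise Pearson correlations are computed on TPM (linear by
default; `--log10` with pseudocount 1 available — both are tested, the
choice of scale is a genuinely open convention). Rarefaction draws exactly
`n` tags without replacement (multivariate hypergeometric; default 30,000)
for fair detected-loci comparison. `common_loci` intersects detected-locus
sets across pooled replicates, and `resampling_null` answers "how many loci
would be common if all pools were subsamples of one library?" by replacing
each comparison pool with a same-depth without-replacement subsample of the
deepest pool. Because expression is scale-free, low-count loci are missed
even between samples identical by construction, so the null intersection
stays below the reference's detected count.

## Synthetic data: what it emulates, what it does not

`simulate_reference` draws an i.i.d. uniform genome, places non-overlapping
genes left to right (1–5 exons of 120–300 nt, introns 100–400 nt; exons
longer than any insert so uncapped reads stay exonic), one ≥ 2 kb
contaminant record, and plants invasion sites in intergenic space: the
7-nt flank upstream of the site's 5' end is overwritten with the motif
carrying 0–2 substitutions, so the artifact signal lives in the *flank*,
exactly what the filter tests. `simulate_library` mixes five read classes
per sample — capped TSS reads (with a geometric number of extra cap G's,
mean 0.5), uncapped internal reads, invasion reads, rRNA reads and
oligo-artifact reads — with Zipf (exponent 1.0) expression over genes and
i.i.d. substitution errors (default 0.1%). Chemistry presets set the
per-alignment invasion rate to the values measured on real libraries
(R3 9.1%, L3 35.9%, L2 38.6%, L1 48.6%, D3 73.6%) and the capped:uncapped
mix to 2:1 for R3 and 1:2 otherwise. Defaults: 1 Mb genome, 200 genes,
50,000 reads/sample, 60 invasion sites; tests and the acceptance script
run scaled-down instances (100–450 kb, 20–200 genes, 1–20 k reads) as
their stated example scale.

Two identifiability guarantees keep ground truth exact:

* every simulated 5' end starts on a non-G base (otherwise all-G stripping
  after TATA makes the position unrecoverable by construction);
* genuine (TSS/internal) 5' ends never sit behind a motif-like flank —
  TSS flanks are redrawn and internal starts rejection-sampled until they
  exceed the filter threshold. A "genuine" read behind an invasion-like
  flank would be an invasion read by the class definition, so excluding
  such flanks is what makes the class labels meaningful, and it makes the
  raw flagged fraction an unbiased estimate of the planted rate.

What the simulator does *not* model: spliced reads crossing exon junctions
(inserts are contiguous genomic sequence; real 31-nt tags occasionally
cross junctions), indel sequencing errors (substitutions only), realistic
quality scores, PCR duplicates, overlapping genes and antisense
transcription, promoter G-bias, and depth imbalance beyond what unequal
per-sample rates produce. Consequently, passing tests demonstrate the
correctness of the algorithms under the stated statistical model, not
pipeline performance on real libraries — in particular the real-data
promoter/exon ratios and locus counts depend on genome annotation quality
and sequencing depth in ways the toy genome cannot reproduce.

## Numerical and degenerate-input choices

* Ties in `naive_align` (equal best distance) → unmapped, tie count kept;
  match-start recovery prefers the shortest span.
* Empty text in semi-global matching → distance = pattern length, end 0;
  empty pattern → error.
* `rarefy` with total < n → error naming the shortfall; total = n →
  identity; n = 0 → zero vector.
* Zero-variance columns in correlations → NaN with a warning; zero library
  total in TPM → error; promoter/exon ratio with zero exon tags → inf
  (NaN when both are zero).
* All randomness flows through `numpy.random.Generator` seeded from the
  configuration; simulation output is byte-identical under a fixed seed.

## Limitations

The G-start ambiguity is fundamental to the chemistry: on real data a
fraction of 5' ends beginning with G are shifted downstream by linker
stripping; the simulator sidesteps it (documented above) rather than
modelling it. The built-in aligner is exhaustive and intended for toy
genomes only (≤ 10 Mb guard rail); real libraries should be aligned
externally and imported. The artifact filter is a deterministic stand-in
for library-specific screening and its coverage threshold (0.8) is a
convention, not a fitted value.
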