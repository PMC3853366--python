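# nanocage

Processing and validation of 5'-anchored template-switching (nanoCAGE)
sequencing tags: demultiplexing and linker trimming, oligonucleotide-artifact
and rRNA filtering, strand-invasion artifact removal, CTSS clustering,
promoter/exon/intron annotation, and digital gene-expression statistics —
with a ground-truth read simulator so the whole chain can be exercised and
tested at desk scale.

## The problem

nanoCAGE attaches a 5' adapter to cDNA during reverse transcription via
template switching, so each read's 5' end marks a transcription start site
(TSS) and read counts give digital expression. Two artifact classes
contaminate the signal:

* **tag dust** — reads made of oligo/adapter sequence (empty constructs);
* **strand invasion** — the template-switching (TS) oligo hybridises to a
  complementary region of the nascent first-strand cDNA and terminates it
  prematurely; the spurious tag is recognisable because the *genomic*
  sequence upstream of its 5' end resembles the oligo's 3' end
  (`TATAGGG`).

The strand-invasion filter flags a tag when the 7-nt genomic flank
upstream of its 5' end (read on the tag's strand) is within 2 Hamming
mismatches of the motif. On a uniform random genome its false-positive
rate is exactly

    sum_{i<=2} C(7,i) 3^i / 4^7  =  211/16384  ~  1.29%

Cap specificity of a library is summarised by the fraction of tags in
*promoter* baskets (±100 nt of annotated transcript starts, precedence
promoter > exon > intron > other, same strand only) and the
promoter/exon tag ratio. TS-oligo chemistries differ sharply: RNA-hybrid
3' ends (R3) are cap-specific, DNA (D3) and locked-nucleic-acid (L1–L3)
3' ends invade more and scatter reads over gene bodies. The simulator's
chemistry presets plant invasion reads at the per-alignment rates measured
on real libraries (R3 9.1%, L3 35.9%, L2 38.6%, L1 48.6%, D3 73.6%) so
end-to-end runs reproduce that ordering against known ground truth.

See `docs/methods.md` for the full model, parameters and limitations.

## Worked example

Simulate all 15 barcoded samples (triplicates of five chemistries,
2,000 reads each) and run every stage:

```sh
nanocage all --seed 7 --reads-per-sample 2000 --outdir demo --no-figure
nanocage report --report demo/report.json
```

which prints (real output):

```
 sample  extracted  mapped  invasion_rate  frac_promoter  promoter_exon  loci
D3_rep1       1917    1819         0.7444         0.1550       1.549451   121
D3_rep2       1903    1785         0.7176         0.1557       1.235556   135
D3_rep3       1916    1818         0.7558         0.1441       1.455556   119
L1_rep1       1920    1820         0.4824         0.2951       1.325926   160
L1_rep2       1927    1839         0.4802         0.3110       1.497382   162
L1_rep3       1924    1815         0.4898         0.2926       1.344304   156
L2_rep1       1919    1812         0.3836         0.3681       1.482222   169
L2_rep2       1905    1785         0.3888         0.3585       1.419069   173
L2_rep3       1893    1805         0.3983         0.3524       1.413333   166
L3_rep1       1906    1810         0.3508         0.3961       1.565502   169
L3_rep2       1906    1808         0.3606         0.3938       1.603604   168
L3_rep3       1919    1801         0.3493         0.3898       1.493617   177
R3_rep1       1918    1847         0.0888         0.7239       3.864162   180
R3_rep2       1914    1819         0.0896         0.7207       3.800000   181
R3_rep3       1914    1808         0.0907         0.7306       4.089783   179
```

Reading the table: of ~2,000 reads per sample, ~1,900 survive
demultiplexing and artifact/rRNA screening ("extracted") and ~1,800 map
uniquely. The measured invasion rate recovers each chemistry's planted
preset (R3 ≈ 0.09 … D3 ≈ 0.74), the promoter fraction falls monotonically
as invasion rises (R3 0.72 → D3 0.15), the promoter/exon ratio is highest
for the cap-specific R3 chemistry, and heavily-invaded libraries detect
fewer loci at equal depth. `demo/report.json` holds the complete report:
per-stage counts, invasion rate ± SE, basket fractions before and after
invasion filtering, detected loci raw and rarefied, and pairwise gene-wise
Pearson correlations, with every parameter and seed echoed.

Individual stages are also exposed as subcommands (`simulate`,
`preprocess`, `rrnadust`, `align`, `import-alignments`, `sifilter`,
`cluster`, `annotate`, `quantify`, `report`) operating on FASTQ /
FASTA / GTF / BED / TSV / JSON files, and the same operations are
available as a library:

```python
from nanocage import SimulationConfig, PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=7)))
```

## Layout

```
src/nanocage/
  approx_match.py     bit-parallel + DP semi-global matching, Hamming
  preprocess.py       read layout, demultiplexing, artifact filter
  rrna_filter.py      contaminant screening
  align_io.py         SAM/BAM/BED6 ingest, exhaustive toy-genome aligner
  strand_invasion.py  flank-motif post-filter and rate estimation
  ctss_cluster.py     CTSS counting, single-linkage clustering, TPM
  annotate.py         GTF/BED12 gene models, basket classification
  quantify.py         gene counts, correlation, rarefaction, common loci
  synthetic_data.py   ground-truth simulator (reference + libraries)
  pipeline.py, cli.py orchestration and command-line interface
```
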