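"""Ground-truth read simulator for the 5' tag pipeline.

Generates a toy reference (uniform random genome with non-overlapping
multi-exon genes, a contaminant record, and planted strand-invasion
sites) and per-sample FASTQ libraries mixing five read classes:

* ``tss`` — capped reads starting exactly at an annotated transcript
  start, with a geometric number of extra G's after the linker (the
  cap-templated C-addition read on the cDNA strand);
* ``internal`` — uncapped reads starting uniformly inside exons, no
  extra G's;
* ``invasion`` — reads whose 5' end sits immediately downstream of a
  genomic site planted to lie within the filter's mismatch threshold of
  the TS-oligo 3' end, so the artifact signal is carried by the flank
  sequence, exactly what the strand-invasion filter tests;
* ``rrna`` — substrings of the contaminant record, either strand;
* ``artifact`` — inserts tiled from TS-oligo/linker sequence (empty
  constructs).

Chemistry presets (R3 / L1 / L2 / L3 / D3) set the invasion rate to the
per-chemistry values observed on real libraries, and the capped:uncapped
mix to 2:1 for the RNA-hybrid oligo and 1:2 otherwise, reflecting its
superior cap specificity.  Every read is logged to a ground-truth table.
All output is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .approx_match import hamming_mismatches, revcomp
from .preprocess import DEFAULT_BARCODES, SampleSheet, TSOligoSpec
from .strand_invasion import DEFAULT_MAX_MISMATCH, DEFAULT_MOTIF

#: strand-invasion fraction per TS-oligo chemistry, as measured on real
#: rat-muscle libraries (percent of alignments flagged / 100)
CHEMISTRY_INVASION = {"R3": 0.091, "D3": 0.736, "L1": 0.486, "L2": 0.386, "L3": 0.359}

READ_CLASSES = ("tss", "internal", "invasion", "rrna", "artifact")

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def chemistry_rates(
    chemistry: str, p_rrna: float = 0.05, p_artifact: float = 0.03
) -> dict[str, float]:
    """Class-rate vector for a chemistry preset.

    The chemistry's measured invasion rate is a fraction *of alignments*,
    so it is apportioned within the genomic (mappable) classes; rRNA and
    artifact reads sit on top and never reach the aligner.  The genomic
    remainder is split between capped (tss) and uncapped (internal) reads
    2:1 for R3 and 1:2 for the DNA/LNA chemistries.
    """
    p_inv = CHEMISTRY_INVASION[chemistry]
    genomic = 1.0 - p_rrna - p_artifact
    if genomic <= 0:
        raise ValueError("rrna/artifact rates leave no room for genomic reads")
    tss_share = 2 / 3 if chemistry == "R3" else 1 / 3
    return {
        "tss": genomic * (1 - p_inv) * tss_share,
        "internal": genomic * (1 - p_inv) * (1 - tss_share),
        "invasion": genomic * p_inv,
        "rrna": p_rrna,
        "artifact": p_artifact,
    }


@dataclass
class SampleSpec:
    sample_id: str
    barcode: str
    class_rates: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.class_rates.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class rates sum to {total}, not 1")
        if any(not 0 <= v <= 1 for v in self.class_rates.values()):
            raise ValueError("class rates must lie in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 1_000_000
    n_genes: int = 200
    min_exons: int = 1
    max_exons: int = 5
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (100, 400)
    read_length: int = 64
    reads_per_sample: int = 50_000
    zipf_exponent: float = 1.0
    error_rate: float = 0.001
    n_invasion_sites: int = 60
    invasion_max_mismatch: int = DEFAULT_MAX_MISMATCH
    invasion_motif: str = DEFAULT_MOTIF
    contaminant_length: int = 2_500
    extra_g_mean: float = 0.5  # cap-templated extra G's on tss reads
    samples: list[SampleSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = default_samples()

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")


def default_samples() -> list[SampleSpec]:
    """One sample per printed barcode, rates from its chemistry preset."""
    sheet = SampleSheet.default()
    return [
        SampleSpec(sid, bc, chemistry_rates(chem))
        for bc, (sid, chem) in sheet.entries.items()
    ]


def preset_samples(chemistries: list[str], replicates: int = 1) -> list[SampleSpec]:
    """Samples for selected chemistry presets using their printed barcodes."""
    out = []
    for chem in chemistries:
        barcodes = [bc for bc, c in DEFAULT_BARCODES.items() if c == chem]
        for i in range(replicates):
            out.append(
                SampleSpec(f"{chem}_rep{i + 1}", barcodes[i], chemistry_rates(chem))
            )
    return out


@dataclass
class Reference:
    genome: dict[str, str]
    models: list[GeneModel]
    contaminants: list[tuple[str, str]]
    invasion_sites: list[tuple[str, int, str]]  # chrom, 5'-end pos, strand


@dataclass
class GroundTruthRecord:
    read_id: str
    sample_id: str
    barcode: str
    umi: str
    true_class: str
    chrom: str | None
    pos: int | None
    strand: str | None
    gene: str | None


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, n)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_reference(config: SimulationConfig) -> Reference:
    """Toy genome + gene models + contaminant + planted invasion sites.

    The genome background is i.i.d. uniform over ACGT; genes are placed
    left to right without overlap, each with 1-5 exons; invasion sites
    (flank windows within the filter threshold of the TS motif) are
    planted in intergenic space.  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    genome_arr = _random_seq(rng, config.genome_length)

    # ---- gene placement, left to right with random intergenic gaps
    models: list[GeneModel] = []
    insert_max = config.read_length  # safe upper bound on insert length
    cursor = 200
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(config.min_exons, config.max_exons + 1))
        ex_lens = rng.integers(*config.exon_length, size=n_ex)
        in_lens = rng.integers(*config.intron_length, size=max(0, n_ex - 1))
        span = int(ex_lens.sum() + in_lens.sum())
        gap = int(rng.integers(150, 400))
        start = cursor + gap
        if start + span + 200 > config.genome_length:
            raise ValueError(
                f"could only place {gi} of {config.n_genes} genes; "
                "increase genome_length"
            )
        exons = []
        p = start
        for i in range(n_ex):
            exons.append((p, p + int(ex_lens[i])))
            p += int(ex_lens[i])
            if i < n_ex - 1:
                p += int(in_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else exons[-1][1] - 1
        _force_non_g(genome_arr, tss, strand, rng)
        _scrub_motif_flank(
            genome_arr, tss, strand, config.invasion_motif,
            config.invasion_max_mismatch, rng,
        )
        models.append(GeneModel(f"gene{gi:04d}", "chr1", strand, [tss], exons))
        cursor = start + span
    assert insert_max < min(config.exon_length)  # internal reads stay exonic

    # ---- planted invasion sites in intergenic space
    gene_spans = [(m.span[0] - 150, m.span[1] + 150) for m in models]
    motif = config.invasion_motif
    w = len(motif)
    sites: list[tuple[str, int, str]] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(sites) < config.n_invasion_sites and attempts < 100_000:
        attempts += 1
        pos = int(rng.integers(insert_max + w, config.genome_length - insert_max - w))
        region = (pos - insert_max - w, pos + insert_max + w)
        if any(lo < region[1] and region[0] < hi for lo, hi in gene_spans):
            continue
        if any(lo < region[1] and region[0] < hi for lo, hi in taken):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        planted = _mutate_motif(motif, config.invasion_max_mismatch, rng)
        if strand == "+":
            genome_arr[pos - w : pos] = np.frombuffer(
                planted.encode(), dtype=np.uint8
            )
        else:
            genome_arr[pos + 1 : pos + 1 + w] = np.frombuffer(
                revcomp(planted).encode(), dtype=np.uint8
            )
        _force_non_g(genome_arr, pos, strand, rng)
        sites.append(("chr1", pos, strand))
        taken.append(region)
    if len(sites) < config.n_invasion_sites:
        raise ValueError("could not place all invasion sites; increase genome_length")

    contaminant = _to_str(_random_seq(rng, config.contaminant_length))
    return Reference(
        genome={"chr1": _to_str(genome_arr)},
        models=models,
        contaminants=[("rRNA_synthetic", contaminant)],
        invasion_sites=sites,
    )


def _flank_window(genome, pos: int, strand: str, w: int) -> str:
    """The upstream window the invasion filter inspects for a 5' end."""
    if strand == "+":
        seq = genome[pos - w : pos]
        return seq if isinstance(seq, str) else _to_str(seq)
    seq = genome[pos + 1 : pos + 1 + w]
    return revcomp(seq if isinstance(seq, str) else _to_str(seq))


def _scrub_motif_flank(
    genome_arr: np.ndarray,
    pos: int,
    strand: str,
    motif: str,
    max_mm: int,
    rng: np.random.Generator,
) -> None:
    """Redraw a 5' end's upstream flank until it no longer resembles the
    TS motif.

    Ground-truth classes must be identifiable: a capped read whose flank
    happens to lie within the filter threshold of the motif would be
    indistinguishable from a planted invasion read, so the generator
    excludes such flanks from genuine start sites.
    """
    w = len(motif)
    lo = pos - w if strand == "+" else pos + 1
    while hamming_mismatches(_flank_window(genome_arr, pos, strand, w), motif) <= max_mm:
        genome_arr[lo : lo + w] = _random_seq(rng, w)


def _force_non_g(genome_arr: np.ndarray, pos: int, strand: str, rng: np.random.Generator) -> None:
    """Ensure the first base read from (pos, strand) is not G.

    Linker removal strips every G following the TATA, so a 5' end whose
    first base is G cannot be recovered exactly; simulated start sites
    are therefore set to a non-G base (a stated simplification — see the
    package docs on cap-derived G ambiguity).
    """
    bad = ord("G") if strand == "+" else ord("C")
    if genome_arr[pos] == bad:
        options = _ALPHABET[_ALPHABET != bad]
        genome_arr[pos] = options[rng.integers(0, 3)]


def _mutate_motif(motif: str, max_mm: int, rng: np.random.Generator) -> str:
    """Motif copy with 0..max_mm substitutions (uniform over counts)."""
    n_mm = int(rng.integers(0, max_mm + 1))
    out = list(motif)
    for i in rng.choice(len(motif), size=n_mm, replace=False):
        out[i] = rng.choice([c for c in "ACGT" if c != motif[i]])
    planted = "".join(out)
    assert hamming_mismatches(planted, motif) <= max_mm
    return planted


def _gene_weights(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zipf (scale-free) expression over a random gene order."""
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** -exponent
    return w / w.sum()


def simulate_library(
    config: SimulationConfig, reference: Reference
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """FASTQ records and ground-truth table for every configured sample.

    Each read is ``barcode + UMI + TATA + GGG(+extras) + insert`` padded
    to ``read_length``, with i.i.d. substitution errors at
    ``error_rate``.  Returns (records, truth) where records are
    (read_id, sequence, qualities) and truth has one row per read.
    """
    rng = np.random.default_rng(config.seed + 1)
    genome = reference.genome["chr1"]
    oligo = TSOligoSpec()
    weights = _gene_weights(len(reference.models), config.zipf_exponent, rng)
    contaminant = reference.contaminants[0][1]
    artifact_source = (
        oligo.linker * 4 + oligo.head + config.samples[0].barcode + oligo.linker
    )
    extra_g_p = 1.0 / (1.0 + config.extra_g_mean)  # geometric on {0,1,2,...}

    records: list[tuple[str, str, str]] = []
    truth_rows: list[GroundTruthRecord] = []
    for spec in config.samples:
        rates = [spec.class_rates[c] for c in READ_CLASSES]
        classes = rng.choice(len(READ_CLASSES), size=config.reads_per_sample, p=rates)
        for i in range(config.reads_per_sample):
            cls = READ_CLASSES[classes[i]]
            umi = _to_str(_random_seq(rng, oligo.umi_length))
            extra_g = 0
            if cls == "tss":
                extra_g = int(rng.geometric(extra_g_p) - 1)
            prefix = spec.barcode + umi + "TATA" + "G" * (3 + extra_g)
            ins_len = config.read_length - len(prefix)
            chrom = pos = strand = gene = None
            if cls == "tss" or cls == "internal":
                gi = int(rng.choice(len(reference.models), p=weights))
                model = reference.models[gi]
                gene = model.gene_id
                chrom = model.chrom
                strand = model.strand
                if cls == "tss":
                    pos = model.transcript_starts[0]
                else:
                    exons = model.exons
                    ex = exons[int(rng.integers(0, len(exons)))]
                    bad = "G" if strand == "+" else "C"
                    w = len(config.invasion_motif)
                    # reject G-starts (see _force_non_g) and motif-like
                    # flanks (see _scrub_motif_flank): keep classes clean
                    for _ in range(100):
                        if strand == "+":
                            pos = int(rng.integers(ex[0], ex[1] - ins_len + 1))
                        else:
                            pos = int(rng.integers(ex[0] + ins_len - 1, ex[1]))
                        if genome[pos] == bad:
                            continue
                        flank = _flank_window(genome, pos, strand, w)
                        if (
                            hamming_mismatches(flank, config.invasion_motif)
                            > config.invasion_max_mismatch
                        ):
                            break
                insert = _genomic_insert(genome, pos, strand, ins_len)
            elif cls == "invasion":
                chrom, pos, strand = reference.invasion_sites[
                    int(rng.integers(0, len(reference.invasion_sites)))
                ]
                insert = _genomic_insert(genome, pos, strand, ins_len)
            elif cls == "rrna":
                start = int(rng.integers(0, len(contaminant) - ins_len))
                insert = contaminant[start : start + ins_len]
                if rng.random() < 0.5:
                    insert = revcomp(insert)
            else:  # artifact
                off = int(rng.integers(0, len(oligo.linker)))
                insert = artifact_source[off : off + ins_len]
            seq = (prefix + insert)[: config.read_length]
            seq = _apply_errors(seq, config.error_rate, rng)
            rid = f"{spec.sample_id}:{i:06d}"
            records.append((rid, seq, "I" * len(seq)))
            truth_rows.append(
                GroundTruthRecord(
                    rid, spec.sample_id, spec.barcode, umi, cls,
                    chrom, pos, strand, gene,
                )
            )
    truth = pd.DataFrame([asdict(t) for t in truth_rows])
    return records, truth


def _genomic_insert(genome: str, five_prime: int, strand: str, length: int) -> str:
    if strand == "+":
        return genome[five_prime : five_prime + length]
    return revcomp(genome[five_prime - length + 1 : five_prime + 1])


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _ALPHABET[_ALPHABET != arr[i]]
        arr[i] = rng.choice(choices)
    return _to_str(arr)


# ---------------------------------------------------------------- writers

def write_fasta(seqs: dict[str, str] | list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
                fh.write(
                    f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_library_fastq(records: list[tuple[str, str, str]], path: str | Path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
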