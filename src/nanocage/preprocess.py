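"""Read-layout parsing, demultiplexing and oligonucleotide-artifact removal.

The template-switching (TS) oligo is a constant 24 nt head, a 6 nt sample
barcode, an 8 nt unique molecular identifier, and a TATA linker ending in a
GGG tail.  The sequencing primer anneals to the constant head, so reads as
sequenced start at the barcode:

    [barcode 6][UMI 8][TATA][GGG...][cDNA insert ...]

Capped templates induce the reverse transcriptase to append extra
cytosines (read here as extra G's), so linker removal strips *all* G's
following the TATA, not exactly three.  Inserts are trimmed to a fixed
length (default 31 nt) before alignment.  The UMI is parsed and carried
through but not used for deduplication.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .approx_match import hamming_mismatches, revcomp, seeded_search

TS_HEAD = "TAGTCGAACTGAAGGTCTCCAGCA"
TS_LINKER = "TATAGGG"

#: printed barcode -> chemistry of the TS oligo 3' end
#: (R = RNA, D = DNA, L = locked nucleic acid; digit = number of modified G's)
DEFAULT_BARCODES: dict[str, str] = {
    "CACTGA": "R3", "GCTCTC": "R3", "TCGCGT": "R3",
    "ATCGTG": "D3", "CACGAT": "D3", "GTATAC": "D3",
    "ACAGAT": "L1", "CTGACG": "L1", "GAGTGA": "L1",
    "AGTAGC": "L2", "GCTGCA": "L2", "TCGAGC": "L2",
    "ATCATA": "L3", "CGATGA": "L3", "TATAGC": "L3",
}


@dataclass(frozen=True)
class TSOligoSpec:
    """Layout of the template-switching oligonucleotide."""

    head: str = TS_HEAD
    barcode_length: int = 6
    umi_length: int = 8
    linker: str = TS_LINKER  # terminal TATA + GGG tail

    def full_oligo(self, barcode: str, umi: str = "N" * 8) -> str:
        return self.head + barcode + umi + self.linker


@dataclass
class SampleSheet:
    """Barcode -> (sample_id, chemistry label) mapping."""

    entries: dict[str, tuple[str, str]]

    @classmethod
    def default(cls) -> "SampleSheet":
        """The 15 printed barcodes, three replicates per chemistry."""
        entries: dict[str, tuple[str, str]] = {}
        rep: Counter[str] = Counter()
        for bc, chem in DEFAULT_BARCODES.items():
            rep[chem] += 1
            entries[bc] = (f"{chem}_rep{rep[chem]}", chem)
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        entries: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c: i for i, c in enumerate(header)}
            for c in ("barcode", "sample_id", "chemistry"):
                if c not in cols:
                    raise ValueError(f"sample sheet missing column {c!r}")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                bc = f[cols["barcode"]].upper()
                if bc in entries:
                    raise ValueError(f"duplicate barcode {bc}")
                entries[bc] = (f[cols["sample_id"]], f[cols["chemistry"]])
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("barcode\tsample_id\tchemistry\n")
            for bc, (sid, chem) in self.entries.items():
                fh.write(f"{bc}\t{sid}\t{chem}\n")

    def lookup(self, barcode: str, max_mismatch: int = 0) -> tuple[str, str] | None:
        """Resolve a barcode; ambiguity at max_mismatch > 0 -> None."""
        barcode = barcode.upper()
        if max_mismatch == 0:
            return self.entries.get(barcode)
        hits = [
            v
            for bc, v in self.entries.items()
            if hamming_mismatches(bc, barcode) <= max_mismatch
        ]
        return hits[0] if len(hits) == 1 else None

    def barcode_length(self) -> int:
        return len(next(iter(self.entries)))


@dataclass
class PreprocessConfig:
    trim_length: int = 31
    barcode_max_mismatch: int = 0
    min_g_run: int = 3  # linker must end in at least this many G's
    head_included: bool = False  # reads carry the 24 nt constant head
    artifact_fraction: float = 0.8  # insert coverage triggering the artifact flag
    artifact_k: int = 1  # errors tolerated per matched word
    artifact_word: int = 12  # word size for coverage matching
    extra_adapters: tuple[str, ...] = ()


@dataclass
class ParsedRead:
    read_id: str
    sample_id: str | None
    umi: str | None
    insert: str
    insert_qualities: str
    unassigned: bool = False
    artifact: bool = False

    @property
    def assigned(self) -> bool:
        return not self.unassigned and not self.artifact


def parse_read(
    read_id: str,
    raw_sequence: str,
    raw_qualities: str,
    sheet: SampleSheet,
    config: PreprocessConfig | None = None,
) -> ParsedRead:
    """Split a raw read into barcode, UMI, linker and trimmed insert.

    The barcode is matched against the sheet at up to
    ``barcode_max_mismatch`` mismatches (default exact); no match leaves
    the read in the unassigned stream.  The linker is the literal TATA
    followed by a run of at least ``min_g_run`` G's; every following G is
    stripped because cap-templated reverse transcription appends extra
    cytosines.  Reads too short to contain barcode + UMI + linker, or with
    no recognizable linker, are flagged as artifacts.
    """
    cfg = config or PreprocessConfig()
    seq = raw_sequence.upper()
    qual = raw_qualities
    if cfg.head_included:
        head = TS_HEAD
        seq = seq[len(head):]
        qual = qual[len(head):]
    bl = sheet.barcode_length()
    spec = TSOligoSpec(barcode_length=bl)
    min_len = bl + spec.umi_length + 4 + cfg.min_g_run
    if len(seq) < min_len:
        return ParsedRead(read_id, None, None, "", "", artifact=True)

    barcode = seq[:bl]
    hit = sheet.lookup(barcode, cfg.barcode_max_mismatch)
    umi = seq[bl : bl + spec.umi_length]
    linker_at = bl + spec.umi_length
    if seq[linker_at : linker_at + 4] != "TATA":
        return ParsedRead(read_id, None, None, "", "", artifact=True)
    p = linker_at + 4
    g_run = 0
    while p < len(seq) and seq[p] == "G":
        g_run += 1
        p += 1
    if g_run < cfg.min_g_run:
        return ParsedRead(read_id, None, None, "", "", artifact=True)
    insert = seq[p : p + cfg.trim_length]
    insert_q = qual[p : p + cfg.trim_length]
    if hit is None:
        return ParsedRead(read_id, None, umi, insert, insert_q, unassigned=True)
    return ParsedRead(read_id, hit[0], umi, insert, insert_q)


def default_artifact_library(
    sheet: SampleSheet, extra_adapters: Iterable[str] = ()
) -> list[str]:
    """TS-oligo derived sequences an insert may spuriously contain.

    Includes the instantiated oligo for every barcode (UMI segment
    dropped so its random bases never score), the linker-to-linker empty
    construct, any configured adapters, and reverse complements.
    """
    spec = TSOligoSpec()
    seqs = {spec.head + bc + spec.linker for bc in sheet.entries}
    seqs.add(spec.linker * 4)  # linker tiling
    seqs.update(spec.linker + spec.head + bc + spec.linker for bc in sheet.entries)
    seqs.update(s.upper() for s in extra_adapters)
    seqs.update(revcomp(s) for s in list(seqs))
    return sorted(seqs)


@lru_cache(maxsize=8)
def _artifact_index(library: tuple[str, ...], gram: int) -> tuple[str, frozenset]:
    joined = "NN".join(library)  # NN never matches: safe separator
    grams = frozenset(
        joined[i : i + gram]
        for i in range(len(joined) - gram + 1)
        if "N" not in joined[i : i + gram]
    )
    return joined, grams


def artifact_coverage(
    insert: str, artifact_library: list[str], config: PreprocessConfig | None = None
) -> float:
    """Fraction of insert positions covered by artifact-library matches.

    Every ``artifact_word``-length window of the insert is searched
    semi-globally in the library with at most ``artifact_k`` errors;
    positions inside matching windows count as covered.  A q-gram filter
    (pigeonhole over ``k + 1`` chunks of the window) prunes windows that
    cannot match before any alignment is attempted.
    """
    cfg = config or PreprocessConfig()
    insert = insert.upper()
    w = cfg.artifact_word
    if not insert:
        return 0.0
    gram = w // (cfg.artifact_k + 1)
    joined, grams = _artifact_index(tuple(artifact_library), gram)
    if len(insert) <= w:
        windows = [(0, len(insert))]
    else:
        windows = [(i, i + w) for i in range(len(insert) - w + 1)]
    covered = [False] * len(insert)
    for lo, hi in windows:
        word = insert[lo:hi]
        if word in joined:
            hit = True
        else:
            chunks = [
                word[c * gram : (c + 1) * gram] for c in range(cfg.artifact_k + 1)
            ]
            if not any(c in grams for c in chunks):
                continue  # no exact chunk anywhere: distance > k guaranteed
            res = seeded_search(word, joined, cfg.artifact_k, first_hit=True)
            hit = bool(res.end_positions)
        if hit:
            for p in range(lo, hi):
                covered[p] = True
    return sum(covered) / len(insert)


def artifact_filter(
    parsed: ParsedRead,
    artifact_library: list[str],
    config: PreprocessConfig | None = None,
) -> ParsedRead:
    """Flag a read as artifact when its insert is mostly TS-oligo derived.

    The criterion is explicit coverage: the read is an artifact when at
    least ``artifact_fraction`` of the insert is covered by library
    matches (see :func:`artifact_coverage`).
    """
    cfg = config or PreprocessConfig()
    if not artifact_library:
        warnings.warn("empty artifact library: artifact filter is a no-op")
        return parsed
    if parsed.artifact or not parsed.insert:
        return parsed
    if artifact_coverage(parsed.insert, artifact_library, cfg) >= cfg.artifact_fraction:
        parsed.artifact = True
        parsed.unassigned = False  # artifact takes precedence in the partition
    return parsed


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, qualities) from a FASTQ file (.gz ok)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0].rstrip("\n"), seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], fh: TextIO) -> int:
    n = 0
    for rid, seq, qual in records:
        fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        n += 1
    return n


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    sheet: SampleSheet,
    config: PreprocessConfig | None = None,
    artifact_library: list[str] | None = None,
) -> tuple[list[ParsedRead], dict]:
    """Parse and artifact-screen a stream of reads.

    Returns the parsed reads and a summary-count dict; every input read
    lands in exactly one of assigned / unassigned / artifact.
    """
    cfg = config or PreprocessConfig()
    if artifact_library is None:
        artifact_library = default_artifact_library(sheet, cfg.extra_adapters)
    out: list[ParsedRead] = []
    counts: Counter[str] = Counter()
    per_sample: Counter[str] = Counter()
    for rid, seq, qual in reads:
        pr = parse_read(rid, seq, qual, sheet, cfg)
        pr = artifact_filter(pr, artifact_library, cfg)
        counts["input"] += 1
        if pr.artifact:
            counts["artifact"] += 1
        elif pr.unassigned:
            counts["unassigned"] += 1
        else:
            counts["assigned"] += 1
            per_sample[pr.sample_id] += 1  # type: ignore[arg-type]
        out.append(pr)
    summary = dict(counts)
    summary["assigned_per_sample"] = dict(per_sample)
    return out, summary


def write_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
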