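"""Alignment ingest (SAM/BAM, BED6) and a built-in exhaustive aligner.

All coordinates are 0-based half-open internally (BED native; SAM
converted on ingest).  The 5' end of a tag — the position that seeds all
downstream CTSS counting — is ``start`` on the plus strand and ``end - 1``
on the minus strand.

The built-in aligner performs an exhaustive semi-global search of the
insert over both strands of a (small) genome, so the pipeline is testable
without an external mapper.  Multimappers (tied best hits) are discarded
by default because CTSS counting requires unique 5' positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import pysam

from .approx_match import revcomp, seeded_search

MAX_GENOME = 10_000_000  # guard rail for the exhaustive aligner


@dataclass
class Alignment:
    read_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    sample_id: str | None = None
    n_best_hits: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}:{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class NaiveAlignResult:
    """Outcome of the exhaustive aligner: mapped, ambiguous or unmapped."""

    alignment: Alignment | None
    n_best_hits: int
    best_distance: int | None = None

    @property
    def mapped(self) -> bool:
        return self.alignment is not None


def read_alignments(path: str | Path, format: str | None = None) -> Iterator[Alignment]:
    """Stream alignments from SAM/BAM or BED6.

    SAM flags are decoded for strand; unmapped and secondary/supplementary
    records are skipped.  Malformed records raise with the line number.
    """
    path = str(path)
    if format is None:
        suffix = path.rsplit(".", 1)[-1].lower()
        format = {"sam": "sam", "bam": "bam", "bed": "bed6"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if format in ("sam", "bam"):
        mode = "rb" if format == "bam" else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                yield Alignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                )
    elif format == "bed6":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ValueError(f"{path}:{ln}: BED6 needs 6 columns, got {len(f)}")
                try:
                    yield Alignment(
                        read_id=f[3],
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        strand=f[5],
                    )
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{ln}: {exc}") from exc
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def write_bed6(alignments, path: str | Path, score_from: str = "n_best_hits") -> int:
    """Write alignments as BED6 (score column = n_best_hits by default)."""
    n = 0
    with open(path, "w") as fh:
        for aln in alignments:
            score = getattr(aln, score_from, 0)
            fh.write(
                f"{aln.chrom}\t{aln.start}\t{aln.end}\t{aln.read_id}\t{score}\t{aln.strand}\n"
            )
            n += 1
    return n


def _genome_items(genome) -> list[tuple[str, str]]:
    if isinstance(genome, Mapping):
        return [(c, str(s).upper()) for c, s in genome.items()]
    # pyfaidx.Fasta or similar
    return [(rec.name, str(rec[:]).upper()) for rec in genome]


def _match_start(insert: str, text: str, end: int, dist: int) -> int:
    """Recover the start of a semi-global match ending at ``end``."""
    lo = max(0, end - len(insert) - dist)
    window = text[lo:end]
    rres = seeded_search(insert[::-1], window[::-1], dist)
    if not rres.end_positions:  # pragma: no cover - defensive
        return end - len(insert)
    return end - rres.end_positions[0]


def naive_align(
    insert: str,
    genome,
    max_errors: int = 3,
    read_id: str = "",
    sample_id: str | None = None,
) -> NaiveAlignResult:
    """Best semi-global hit of an insert over both genome strands.

    A unique best hit within ``max_errors`` yields an Alignment; tied best
    hits leave the read unmapped with the tie count recorded.  Reported
    coordinates are those of the best alignment's genomic span.
    """
    items = _genome_items(genome)
    total = sum(len(s) for _, s in items)
    if total > MAX_GENOME:
        raise ValueError(f"genome of {total} bp exceeds the exhaustive-aligner guard rail")
    insert = insert.upper()
    if not insert:
        return NaiveAlignResult(None, 0)

    best = max_errors + 1
    hits: list[tuple[str, int, str, str]] = []  # chrom, end_offset, strand, query
    texts: dict[str, str] = {}
    # exact-occurrence fast path: a verbatim hit is always a best hit
    for chrom, seq in items:
        texts[chrom] = seq
        for strand, query in (("+", insert), ("-", revcomp(insert))):
            p = seq.find(query)
            while p != -1:
                hits.append((chrom, p + len(query), strand, query))
                p = seq.find(query, p + 1)
    if hits:
        best = 0
    elif max_errors > 0:
        for chrom, seq in items:
            for strand, query in (("+", insert), ("-", revcomp(insert))):
                res = seeded_search(query, seq, max_errors)
                if not res.end_positions:
                    continue
                if res.min_distance < best:
                    best = res.min_distance
                    hits = [(chrom, e, strand, query) for e in res.end_positions]
                elif res.min_distance == best:
                    hits.extend((chrom, e, strand, query) for e in res.end_positions)
    if best > max_errors or not hits:
        return NaiveAlignResult(None, 0)
    if len(hits) > 1:
        return NaiveAlignResult(None, len(hits), best)
    chrom, end, strand, query = hits[0]
    start = _match_start(query, texts[chrom], end, best)
    return NaiveAlignResult(
        Alignment(read_id, chrom, start, end, strand, sample_id), 1, best
    )
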