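"""Contaminant (rRNA) screening of trimmed inserts.

An insert is flagged when it — or its reverse complement — matches any
contaminant reference semi-globally (whole insert against a contaminant
substring) within ``k`` errors.  Both strands are screened because rRNA
contamination appears on both strands in practice.  ``k`` defaults to 10%
of the insert length.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Iterable

from pyfaidx import Fasta

from .approx_match import revcomp, seeded_search
from .preprocess import ParsedRead, read_fastq, write_fastq

MIN_INSERT = 12  # below this, matches are uninformative: never flagged


def default_k(insert_length: int) -> int:
    return insert_length // 10


def load_contaminants(path: str | Path) -> list[tuple[str, str]]:
    """Read contaminant records from FASTA as (name, sequence)."""
    fa = Fasta(str(path))
    return [(rec.name, str(rec[:]).upper()) for rec in fa]


def rrna_flag(
    insert: str,
    contaminants: list[tuple[str, str]] | list[str],
    k: int | None = None,
    counters: Counter | None = None,
) -> bool:
    """True iff the insert matches a contaminant within ``k`` errors.

    Inserts shorter than 12 nt are never flagged (counted as warnings).
    """
    if not contaminants:
        raise ValueError("contaminant list must be non-empty")
    seqs = [c[1] if isinstance(c, tuple) else c for c in contaminants]
    insert = insert.upper()
    if len(insert) < MIN_INSERT:
        if counters is not None:
            counters["too_short"] += 1
        return False
    if k is None:
        k = default_k(len(insert))
    for query in (insert, revcomp(insert)):
        for ref in seqs:
            if k == 0:
                if query in ref:
                    return True
                continue
            res = seeded_search(query, ref, k, first_hit=True)
            if res.end_positions:
                return True
    return False


def screen_reads(
    reads: Iterable[ParsedRead],
    contaminants: list[tuple[str, str]],
    k: int | None = None,
) -> tuple[list[ParsedRead], list[ParsedRead], dict]:
    """Partition reads into (kept, flagged) against the contaminant set."""
    kept: list[ParsedRead] = []
    flagged: list[ParsedRead] = []
    counters: Counter = Counter()
    for pr in reads:
        if rrna_flag(pr.insert, contaminants, k, counters):
            flagged.append(pr)
        else:
            kept.append(pr)
    stats = {
        "input": len(kept) + len(flagged),
        "flagged": len(flagged),
        "kept": len(kept),
        "too_short": counters.get("too_short", 0),
    }
    return kept, flagged, stats


def screen_fastq(
    in_path: str | Path,
    contaminant_path: str | Path,
    out_path: str | Path,
    k: int | None = None,
    drop: bool = True,
    stats_path: str | Path | None = None,
) -> dict:
    """Screen a FASTQ file; flagged reads are dropped or marked ``rRNA``."""
    contaminants = load_contaminants(contaminant_path)
    counters: Counter = Counter()
    n_in = n_flagged = 0

    def gen():
        nonlocal n_in, n_flagged
        for rid, seq, qual in read_fastq(in_path):
            n_in += 1
            if rrna_flag(seq, contaminants, k, counters):
                n_flagged += 1
                if drop:
                    continue
                rid = rid + " rRNA"
            yield rid, seq, qual

    with open(out_path, "w") as fh:
        write_fastq(gen(), fh)
    stats = {
        "input": n_in,
        "flagged": n_flagged,
        "kept": n_in - n_flagged,
        "too_short": counters.get("too_short", 0),
    }
    if stats_path:
        with open(stats_path, "w") as fh:
            json.dump(stats, fh, indent=2)
            fh.write("\n")
    return stats
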