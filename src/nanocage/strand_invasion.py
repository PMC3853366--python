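"""Strand-invasion post-filter.

Template-switching oligos can hybridize to complementary regions of the
nascent first-strand cDNA, terminating reverse transcription prematurely.
Such spurious tags are recognizable after alignment: the genomic sequence
immediately upstream of the tag's 5' end resembles the 3' end of the TS
oligo.  The filter compares the upstream window, read on the tag's strand,
with the oligo's terminal motif (default TATAGGG) and flags the tag when
the Hamming mismatch count is at or below a threshold (default 2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .align_io import Alignment
from .approx_match import hamming_mismatches, revcomp

DEFAULT_MOTIF = "TATAGGG"
DEFAULT_MAX_MISMATCH = 2


@dataclass
class InvasionCall:
    alignment: Alignment
    upstream_window: str | None  # None at a contig edge
    mismatches: int | None
    flagged: bool
    edge: bool = False


def _chrom_seq(genome, chrom: str) -> str:
    if isinstance(genome, Mapping):
        return str(genome[chrom]).upper()
    return str(genome[chrom][:]).upper()


def flag_strand_invasion(
    aln: Alignment,
    genome,
    oligo_end: str = DEFAULT_MOTIF,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    n_g: int = 0,
    first_base: str | None = None,
) -> InvasionCall:
    """Compare the tag's upstream genomic flank with the TS oligo 3' end.

    On the plus strand the window is the ``w`` bases before the 5' end; on
    the minus strand, the reverse complement of the ``w`` bases genomically
    after it.  Tags whose window would run off the contig are never
    flagged (edge case, counted separately).

    With ``n_g > 0`` and a tag whose first aligned base is G, up to
    ``n_g`` leading G's of the motif are excluded from the mismatch count,
    to avoid mistaking unencoded cap-derived G's for invasion evidence
    (off by default).
    """
    w = len(oligo_end)
    seq = _chrom_seq(genome, aln.chrom)
    fp = aln.five_prime_pos
    if aln.strand == "+":
        if fp < w:
            return InvasionCall(aln, None, None, False, edge=True)
        window = seq[fp - w : fp]
    else:
        if fp + 1 + w > len(seq):
            return InvasionCall(aln, None, None, False, edge=True)
        window = revcomp(seq[fp + 1 : fp + 1 + w])
    motif = oligo_end.upper()
    skip = 0
    if n_g > 0 and first_base == "G":
        while skip < n_g and skip < len(motif) and motif[skip] == "G":
            skip += 1
    # motif is compared 3'-anchored: its last base abuts the tag's 5' end
    mm = hamming_mismatches(window[skip:], motif[skip:]) if skip < w else 0
    return InvasionCall(aln, window, mm, mm <= max_mismatch)


def flag_alignments(
    alignments: Iterable[Alignment],
    genome,
    oligo_end: str = DEFAULT_MOTIF,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    n_g: int = 0,
) -> list[InvasionCall]:
    return [
        flag_strand_invasion(aln, genome, oligo_end, max_mismatch, n_g)
        for aln in alignments
    ]


def invasion_rate(
    calls: Iterable[InvasionCall],
    background_rate: float | None = None,
) -> dict[str | None, dict]:
    """Per-sample flagged fraction with binomial standard error.

    ``background_rate`` is the chance that a genuine (non-invasion) tag's
    flank matches the motif anyway; when given, a misclassification-
    corrected estimate ``(rate - q) / (1 - q)`` is reported alongside the
    raw one (on an i.i.d. uniform genome use
    :func:`analytic_false_positive_rate`; on a real genome the background
    is unknown and the raw rate is what comparable analyses report).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no invasion calls to summarize")
    by_sample: dict[str | None, list[InvasionCall]] = {}
    for c in calls:
        by_sample.setdefault(c.alignment.sample_id, []).append(c)
    out: dict[str | None, dict] = {}
    for sid, group in by_sample.items():
        n = len(group)
        flagged = sum(c.flagged for c in group)
        edge = sum(c.edge for c in group)
        p = flagged / n
        se = math.sqrt(p * (1 - p) / n)
        entry = {"n": n, "flagged": flagged, "edge": edge, "rate": p, "se": se}
        if background_rate is not None:
            q = background_rate
            entry["corrected_rate"] = max(0.0, (p - q) / (1 - q))
            entry["corrected_se"] = se / (1 - q)
        out[sid] = entry
    return out


def split_calls(calls: Iterable[InvasionCall]) -> tuple[list[Alignment], list[Alignment]]:
    """(kept, flagged) alignments after the invasion filter."""
    kept, flagged = [], []
    for c in calls:
        (flagged if c.flagged else kept).append(c.alignment)
    return kept, flagged


def remove_invaded_clusters(clusters, calls: Iterable[InvasionCall]):
    """Cluster-level variant: drop clusters in which EVERY tag is flagged.

    ``clusters`` is the DataFrame from :func:`nanocage.ctss_cluster.cluster_ctss`;
    a cluster survives when at least one member tag is not an invasion call.
    """
    keep_keys = set()
    for c in calls:
        if not c.flagged:
            aln = c.alignment
            keep_keys.add((aln.chrom, aln.strand, aln.five_prime_pos))
    import pandas as pd  # local import: keep module light for CLI startup

    def survives(row) -> bool:
        return any(
            (row.chrom, row.strand, pos) in keep_keys
            for pos in range(row.start, row.end)
        )

    mask = clusters.apply(survives, axis=1) if len(clusters) else pd.Series(dtype=bool)
    return clusters[mask].reset_index(drop=True)


def analytic_false_positive_rate(w: int = 7, max_mismatch: int = 2) -> float:
    """P(a uniform random window is within ``max_mismatch`` of the motif).

    On an i.i.d. uniform genome each window base matches with probability
    1/4, so the count of Hamming-<=k neighbours gives
    sum_{i<=k} C(w,i) 3^i / 4^w (211/16384 for w=7, k=2).
    """
    return sum(math.comb(w, i) * 3**i for i in range(max_mismatch + 1)) / 4**w


def write_stats(calls: Iterable[InvasionCall], path: str | Path) -> dict:
    calls = list(calls)
    n = len(calls)
    flagged = sum(c.flagged for c in calls)
    edge = sum(c.edge for c in calls)
    p = flagged / n if n else 0.0
    stats = {
        "n": n,
        "flagged": flagged,
        "kept": n - flagged,
        "edge": edge,
        "rate": p,
        "se": math.sqrt(p * (1 - p) / n) if n else 0.0,
    }
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2)
        fh.write("\n")
    return stats
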