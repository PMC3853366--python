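"""Genomic-basket annotation of tag clusters.

Clusters are classified against gene models into four baskets with fixed
precedence: *promoter* (within +/-100 nt of any transcript start) >
*exon* > *intron* (inside the gene span but not exonic) > *other*.
Classification is strand-matched — a cluster is only compared with gene
models on its own strand — and uses the cluster's peak CTSS position (a
single base) so a cluster can never straddle two baskets.

The promoter/exon tag ratio summarizes cap specificity: capped 5' ends
pile up at transcript starts, while uncapped internal priming scatters
over exons.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

PROMOTER_FLANK = 100  # nt on each side of a transcript start
BASKETS = ("promoter", "exon", "intron", "other")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcript_starts: list[int]  # 5'-most base of each transcript, 0-based
    exons: list[tuple[int, int]]  # half-open, merged

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def promoters(self, flank: int = PROMOTER_FLANK) -> list[tuple[int, int]]:
        """+/- flank around every transcript start, merged."""
        ivs = sorted(
            (max(0, ts - flank), ts + flank + 1) for ts in self.transcript_starts
        )
        merged = [list(ivs[0])]
        for lo, hi in ivs[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        return [tuple(iv) for iv in merged]

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i][1] < exons[i + 1][0]
        ]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [tuple(iv) for iv in out]


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Build gene models from GTF exon lines grouped by transcript.

    A transcript's start is its 5'-most exon base on the transcript
    strand; per gene, exons are merged and all transcript starts kept.
    """
    exons: dict[tuple[str, str, str], list[tuple[int, int, str]]] = {}
    for line in open(path):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9 or f[2] != "exon":
            continue
        attrs = dict(_GTF_ATTR.findall(f[8]))
        gene = attrs.get("gene_id", "?")
        tx = attrs.get("transcript_id", gene)
        key = (gene, f[0], f[6])
        exons.setdefault(key, []).append((int(f[3]) - 1, int(f[4]), tx))
    models = []
    for (gene, chrom, strand), recs in exons.items():
        by_tx: dict[str, list[tuple[int, int]]] = {}
        for s, e, tx in recs:
            by_tx.setdefault(tx, []).append((s, e))
        starts = []
        for ivs in by_tx.values():
            starts.append(
                min(s for s, _ in ivs) if strand == "+" else max(e for _, e in ivs) - 1
            )
        models.append(
            GeneModel(
                gene, chrom, strand,
                sorted(set(starts)),
                _merge([(s, e) for s, e, _ in recs]),
            )
        )
    return sorted(models, key=lambda m: (m.chrom, m.span[0]))


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12, one transcript per line, name = gene id."""
    models: dict[tuple[str, str, str], GeneModel] = {}
    for ln, line in enumerate(open(path), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ValueError(f"{path}:{ln}: BED12 needs 12 columns")
        chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        ts = start if strand == "+" else end - 1
        key = (name, chrom, strand)
        if key in models:
            m = models[key]
            m.transcript_starts = sorted(set(m.transcript_starts + [ts]))
            m.exons = _merge(m.exons + exons)
        else:
            models[key] = GeneModel(name, chrom, strand, [ts], _merge(exons))
    return sorted(models.values(), key=lambda m: (m.chrom, m.span[0]))


class AnnotationIndex:
    """Strand-aware interval trees over promoters, exons and gene spans."""

    def __init__(self, models: list[GeneModel], promoter_flank: int = PROMOTER_FLANK,
                 stranded: bool = True):
        self.stranded = stranded
        self.promoter: dict[tuple[str, str], IntervalTree] = {}
        self.exon: dict[tuple[str, str], IntervalTree] = {}
        self.gene: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            key = (m.chrom, m.strand)
            for trees, ivs in (
                (self.promoter, m.promoters(promoter_flank)),
                (self.exon, m.exons),
                (self.gene, [m.span]),
            ):
                tree = trees.setdefault(key, IntervalTree())
                for lo, hi in ivs:
                    if lo < hi:
                        tree.addi(lo, hi, m.gene_id)

    def _hits(self, trees, chrom: str, strand: str, lo: int, hi: int) -> list[str]:
        keys = [(chrom, strand)] if self.stranded else [(chrom, "+"), (chrom, "-")]
        genes = set()
        for key in keys:
            if key in trees:
                genes.update(iv.data for iv in trees[key].overlap(lo, hi))
        return sorted(genes)

    def classify(self, chrom: str, strand: str, lo: int, hi: int) -> tuple[str, str | None]:
        """(basket, gene_id) for an interval; smallest gene id on ties."""
        for basket, trees in (("promoter", self.promoter), ("exon", self.exon),
                              ("intron", self.gene)):
            genes = self._hits(trees, chrom, strand, lo, hi)
            if genes:
                return basket, genes[0]
        return "other", None


def classify_cluster(cluster, index: AnnotationIndex, by: str = "peak") -> tuple[str, str | None]:
    """Basket of one tag cluster (a row of the cluster table).

    ``by='peak'`` (default) tests the single peak CTSS base;
    ``by='hull'`` tests the whole cluster interval with the same
    promoter > exon > intron > other precedence.
    """
    if by == "peak":
        lo, hi = cluster.peak_pos, cluster.peak_pos + 1
    elif by == "hull":
        lo, hi = cluster.start, cluster.end
    else:
        raise ValueError(f"unknown mode {by!r}")
    return index.classify(cluster.chrom, cluster.strand, lo, hi)


def classify_clusters(clusters: pd.DataFrame, index: AnnotationIndex, by: str = "peak") -> pd.DataFrame:
    """Add ``basket`` and ``gene_id`` columns to a cluster table."""
    baskets, genes = [], []
    for row in clusters.itertuples():
        b, g = classify_cluster(row, index, by)
        baskets.append(b)
        genes.append(g)
    return clusters.assign(basket=baskets, gene_id=genes)


def basket_summary(
    classified: pd.DataFrame, sample_counts: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample tag counts, fractions and promoter/exon ratio.

    ``sample_counts`` is the cluster x sample matrix; without it the
    pooled ``count`` column is summarized as a single pseudo-sample.
    Fractions are over the four baskets and sum to 1; the ratio is
    promoter tags / exon tags (inf when no exon tags).
    """
    if sample_counts is None:
        sample_counts = classified.set_index("cluster_id")[["count"]].rename(
            columns={"count": "pooled"}
        )
    basket_of = classified.set_index("cluster_id")["basket"]
    rows = []
    for sample in sample_counts.columns:
        col = sample_counts[sample]
        totals = {b: 0 for b in BASKETS}
        for cid, cnt in col.items():
            totals[basket_of[cid]] += int(cnt)
        n = sum(totals.values())
        fr = {f"frac_{b}": (totals[b] / n if n else 0.0) for b in BASKETS}
        ratio = (
            totals["promoter"] / totals["exon"]
            if totals["exon"]
            else (float("inf") if totals["promoter"] else float("nan"))
        )
        rows.append(
            {"sample_id": sample, **{f"n_{b}": totals[b] for b in BASKETS},
             **fr, "n_total": n, "promoter_exon_ratio": ratio}
        )
    return pd.DataFrame(rows)
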