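"""CTSS counting and strand-specific single-linkage tag clustering.

A CTSS (CAGE transcription start site) is one (chrom, position, strand)
carrying the count of tag 5' ends per sample.  Nearby CTSS on the same
chromosome and strand are grouped into tag clusters by single linkage:
consecutive positions join one cluster while their gap is at most
``max_gap`` (default 20 nt).  No expression threshold is applied.
Counts are normalized to tags per million (TPM) over the library's total
mapped, filtered tags.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .align_io import Alignment

DEFAULT_MAX_GAP = 20

CTSS_COLUMNS = ["chrom", "pos", "strand", "sample_id", "count"]


def alignments_to_ctss(alignments: Iterable[Alignment]) -> pd.DataFrame:
    """Tally tag 5' ends per (chrom, pos, strand, sample)."""
    rows = [
        (a.chrom, a.five_prime_pos, a.strand, a.sample_id) for a in alignments
    ]
    if not rows:
        return pd.DataFrame(columns=CTSS_COLUMNS)
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS[:4])
    out = (
        df.groupby(CTSS_COLUMNS[:4], dropna=False)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["chrom", "strand", "pos", "sample_id"])
        .reset_index(drop=True)
    )
    return out


def cluster_ctss(ctss: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Single-linkage clustering of CTSS positions per (chrom, strand).

    Returns one row per cluster: cluster_id, chrom, strand, start, end
    (half-open hull of member positions), peak_pos (CTSS with maximal
    summed count, smallest coordinate on ties), count (total tags), and a
    ``cluster_id`` column is also added to a copy of the input CTSS table
    (returned as the second element).
    """
    if ctss.empty:
        empty = pd.DataFrame(
            columns=["cluster_id", "chrom", "strand", "start", "end", "peak_pos", "count"]
        )
        return empty, ctss.assign(cluster_id=pd.Series(dtype=object))

    per_pos = (
        ctss.groupby(["chrom", "strand", "pos"])["count"].sum().reset_index()
    )
    per_pos = per_pos.sort_values(["chrom", "strand", "pos"]).reset_index(drop=True)

    new_group = (
        (per_pos["chrom"] != per_pos["chrom"].shift())
        | (per_pos["strand"] != per_pos["strand"].shift())
        | ((per_pos["pos"] - per_pos["pos"].shift()) > max_gap)
    )
    per_pos["_gid"] = new_group.cumsum()

    records = []
    for gid, grp in per_pos.groupby("_gid", sort=True):
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        start = int(grp["pos"].min())
        end = int(grp["pos"].max()) + 1
        peak = int(grp.loc[grp["count"].idxmax(), "pos"])  # idxmax: first max
        records.append((chrom, strand, start, end, peak, int(grp["count"].sum())))
    clusters = pd.DataFrame(
        records, columns=["chrom", "strand", "start", "end", "peak_pos", "count"]
    )
    clusters = clusters.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)
    clusters.insert(
        0,
        "cluster_id",
        [
            f"{r.chrom}:{r.start}-{r.end},{r.strand}"
            for r in clusters.itertuples()
        ],
    )

    # map each CTSS back to its cluster
    key_to_cid = {}
    for r in clusters.itertuples():
        key_to_cid[(r.chrom, r.strand)] = key_to_cid.get((r.chrom, r.strand), [])
        key_to_cid[(r.chrom, r.strand)].append((r.start, r.end, r.cluster_id))
    cids = []
    for r in ctss.itertuples():
        cid = None
        for start, end, c in key_to_cid.get((r.chrom, r.strand), []):
            if start <= r.pos < end:
                cid = c
                break
        cids.append(cid)
    assigned = ctss.assign(cluster_id=cids)
    return clusters, assigned


def cluster_sample_counts(assigned_ctss: pd.DataFrame) -> pd.DataFrame:
    """Cluster x sample count matrix from a cluster-assigned CTSS table."""
    if assigned_ctss.empty:
        return pd.DataFrame()
    return (
        assigned_ctss.pivot_table(
            index="cluster_id", columns="sample_id", values="count", aggfunc="sum", fill_value=0
        )
        .astype(int)
    )


def tpm_normalize(counts, library_total_mapped: float):
    """Tags-per-million scaling: count * 1e6 / total mapped tags."""
    if library_total_mapped <= 0:
        raise ValueError("library total must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_total_mapped


def tpm_matrix(count_matrix: pd.DataFrame, totals: dict | pd.Series | None = None) -> pd.DataFrame:
    """Per-sample TPM of a feature x sample count matrix.

    ``totals`` defaults to the column sums (every tag in a cluster).
    """
    if totals is None:
        totals = count_matrix.sum(axis=0)
    out = count_matrix.astype(float).copy()
    for col in out.columns:
        out[col] = tpm_normalize(out[col].to_numpy(), float(totals[col]))
    return out


def write_ctss_bed(ctss: pd.DataFrame, path: str | Path) -> None:
    """CTSS as BED6 with the score column holding the tag count."""
    with open(path, "w") as fh:
        for r in ctss.itertuples():
            name = f"{r.sample_id}" if "sample_id" in ctss.columns else "ctss"
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{name}\t{r.count}\t{r.strand}\n"
            )


def write_clusters_tsv(clusters: pd.DataFrame, path: str | Path) -> None:
    clusters.to_csv(path, sep="\t", index=False)


def write_bedgraph(ctss: pd.DataFrame, strand: str, path: str | Path, tpm_total: float | None = None) -> None:
    """Per-strand bedGraph of CTSS counts (or TPM when a total is given)."""
    sub = ctss[ctss["strand"] == strand]
    per_pos = sub.groupby(["chrom", "pos"])["count"].sum().reset_index()
    with open(path, "w") as fh:
        for r in per_pos.itertuples():
            val = r.count if tpm_total is None else r.count * 1e6 / tpm_total
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{val}\n")
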