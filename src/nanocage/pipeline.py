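"""End-to-end orchestration: simulate/ingest -> demultiplex -> filter ->
align -> strand-invasion post-filter -> cluster -> annotate -> quantify.

The stage order mirrors the tag-processing chain used on real libraries:
barcode extraction and linker trimming, oligo-artifact removal, rRNA
screening, alignment, strand-invasion post-filtering, CTSS clustering,
basket annotation and digital-expression statistics.  Basket fractions
are reported both before the strand-invasion filter (the annotation view
in which artifact tags still dilute the promoter signal) and after it
(sets marked ``_nw_<threshold>`` by convention).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import ctss_cluster as cc
from . import quantify as qt
from .align_io import naive_align
from .preprocess import PreprocessConfig, SampleSheet, demultiplex
from .rrna_filter import rrna_flag
from .strand_invasion import (
    DEFAULT_MAX_MISMATCH,
    DEFAULT_MOTIF,
    flag_alignments,
    invasion_rate,
    split_calls,
)
from .synthetic_data import (
    Reference,
    SimulationConfig,
    simulate_library,
    simulate_reference,
)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, echoed verbatim into the report."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    rrna_k: int | None = None  # None -> 10% of insert length
    align_max_errors: int = 3
    invasion_motif: str = DEFAULT_MOTIF
    invasion_max_mismatch: int = DEFAULT_MAX_MISMATCH
    invasion_filter: bool = True
    cluster_max_gap: int = cc.DEFAULT_MAX_GAP
    promoter_flank: int = ann.PROMOTER_FLANK
    rarefy_depth: int = 30_000
    correlation_log10: bool = False
    seed: int = 0


def _log(msg: str, t0: float, verbose: bool) -> None:
    if verbose:
        print(f"[{time.time() - t0:7.1f}s] {msg}", file=sys.stderr)


def run_pipeline(
    config: PipelineConfig,
    reference: Reference | None = None,
    records: list[tuple[str, str, str]] | None = None,
    truth: pd.DataFrame | None = None,
    verbose: bool = False,
) -> dict:
    """Run every stage on simulated (or supplied) reads; return the report.

    When ``reference``/``records`` are not given they are generated from
    ``config.simulation``.  The report contains, per sample, the read
    counts surviving each stage, invasion rate with binomial SE, basket
    fractions before and after invasion filtering, the promoter/exon
    ratio, detected loci (raw and rarefied), and pairwise gene-level
    correlations; every parameter and seed is echoed.
    """
    t0 = time.time()
    sim = config.simulation
    if reference is None:
        reference = simulate_reference(sim)
        _log("reference simulated", t0, verbose)
    if records is None:
        records, truth = simulate_library(sim, reference)
        _log(f"{len(records)} reads simulated", t0, verbose)

    sheet = SampleSheet.default()
    parsed, pre_counts = demultiplex(records, sheet, config.preprocess)
    _log("demultiplexed", t0, verbose)

    per_sample: dict[str, dict] = {}
    for spec in sim.samples:
        per_sample[spec.sample_id] = {
            "counts": {
                "extracted": pre_counts["assigned_per_sample"].get(spec.sample_id, 0)
            }
        }

    assigned = [p for p in parsed if p.assigned]
    kept_reads = []
    for p in assigned:
        if rrna_flag(p.insert, reference.contaminants, config.rrna_k):
            c = per_sample[p.sample_id]["counts"]
            c["rrna_flagged"] = c.get("rrna_flagged", 0) + 1
        else:
            kept_reads.append(p)
    _log("rRNA screened", t0, verbose)

    alignments = []
    for p in kept_reads:
        res = naive_align(
            p.insert, reference.genome, config.align_max_errors, p.read_id, p.sample_id
        )
        if res.mapped:
            alignments.append(res.alignment)
    for a in alignments:
        c = per_sample[a.sample_id]["counts"]
        c["mapped"] = c.get("mapped", 0) + 1
    _log(f"{len(alignments)} mapped", t0, verbose)

    calls = flag_alignments(
        alignments, reference.genome, config.invasion_motif, config.invasion_max_mismatch
    )
    # genuine 5' ends in the simulated reference never sit behind
    # motif-like flanks (class identifiability), so the raw flagged
    # fraction estimates the invasion rate without background correction
    rates = invasion_rate(calls) if calls else {}
    if config.invasion_filter:
        kept_aln, flagged_aln = split_calls(calls)
    else:
        kept_aln, flagged_aln = alignments, []
    for sid, r in rates.items():
        per_sample[sid]["invasion"] = r
    for a in kept_aln:
        c = per_sample[a.sample_id]["counts"]
        c["invasion_filtered"] = c.get("invasion_filtered", 0) + 1
    _log("invasion filtered", t0, verbose)

    index = ann.AnnotationIndex(reference.models, config.promoter_flank)

    def annotate_set(alns):
        ctss = cc.alignments_to_ctss(alns)
        clusters, assigned_ctss = cc.cluster_ctss(ctss, config.cluster_max_gap)
        counts = cc.cluster_sample_counts(assigned_ctss)
        classified = ann.classify_clusters(clusters, index)
        summary = ann.basket_summary(classified, counts) if len(classified) else None
        return classified, counts, summary

    pre_classified, pre_counts_m, pre_summary = annotate_set(alignments)
    post_classified, post_counts_m, post_summary = annotate_set(kept_aln)
    _log("clustered + annotated", t0, verbose)

    for label, summary in (("baskets_prefilter", pre_summary), ("baskets", post_summary)):
        if summary is None:
            continue
        for row in summary.to_dict("records"):
            sid = row.pop("sample_id")
            if sid in per_sample:
                per_sample[sid][label] = _jsonable(row)

    genes = qt.gene_counts(post_classified, post_counts_m)
    report_quant: dict = {}
    if len(genes):
        rng = np.random.default_rng(config.seed)
        for sid in genes.columns:
            col = genes[sid]
            per_sample.setdefault(sid, {})["detected_loci"] = qt.detected_loci(col)
            if int(col.sum()) >= config.rarefy_depth:
                sub = qt.rarefy(col, config.rarefy_depth, rng)
                per_sample[sid]["detected_loci_rarefied"] = qt.detected_loci(sub)
            else:
                per_sample[sid]["detected_loci_rarefied"] = None
        if genes.shape[1] >= 2 and genes.shape[0] >= 2:
            corr = qt.pairwise_pearson(genes, log_scale=config.correlation_log10)
            report_quant["pearson"] = {
                f"{a}|{b}": _round(corr.loc[a, b])
                for a in corr.index
                for b in corr.columns
                if a < b
            }
        # pool replicates per chemistry (sample ids are "<chem>_rep<i>")
        pools: dict[str, pd.Series] = {}
        for sid in genes.columns:
            chem = sid.split("_rep")[0]
            pools[chem] = pools.get(chem, 0) + genes[sid]
        if len(pools) >= 2:
            sets = [qt.detected_set(v) for v in pools.values()]
            report_quant["pooled_detected"] = {k: qt.detected_loci(v) for k, v in pools.items()}
            report_quant["common_loci"] = qt.common_loci(sets)
            # null: replace every other pool by a same-depth subsample of
            # the deepest pool (so all requested depths are drawable)
            ref_name = max(pools, key=lambda n: int(pools[n].sum()))
            sizes = [
                int(pools[n].sum()) for n in pools if n != ref_name
            ]
            report_quant["common_loci_resampling_null"] = qt.resampling_null(
                pools[ref_name], sizes, np.random.default_rng(config.seed + 1)
            )
    _log("quantified", t0, verbose)

    report = {
        "schema_version": SCHEMA_VERSION,
        "config": _jsonable(asdict(config)),
        "totals": {k: v for k, v in pre_counts.items() if k != "assigned_per_sample"},
        "samples": _jsonable(per_sample),
        "quantification": _jsonable(report_quant),
    }
    if truth is not None:
        report["truth_class_counts"] = (
            truth.groupby(["sample_id", "true_class"]).size().unstack(fill_value=0)
            .to_dict("index")
        )
    return report


def _round(x, nd: int = 6):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), nd)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        if np.isnan(obj):
            return None
        if np.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return float(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def basket_figure(report: dict, path: str | Path) -> None:
    """Stacked basket-fraction bar chart per sample (prefilter view)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = [
        (sid, d["baskets_prefilter"])
        for sid, d in report["samples"].items()
        if "baskets_prefilter" in d
    ]
    if not samples:
        return
    fig, ax = plt.subplots(figsize=(max(4, len(samples)), 4))
    bottom = np.zeros(len(samples))
    for basket in ("promoter", "exon", "intron", "other"):
        vals = np.array([d[f"frac_{basket}"] for _, d in samples])
        ax.bar([s for s, _ in samples], vals, bottom=bottom, label=basket)
        bottom += vals
    ax.set_ylabel("fraction of tags")
    ax.legend(fontsize=8)
    plt.xticks(rotation=45, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
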