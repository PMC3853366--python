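"""Ground-truth simulator: determinism, class rates, reference structure."""

import numpy as np
import pandas as pd
import pytest

from nanocage.approx_match import hamming_mismatches, revcomp
from nanocage.synthetic_data import (
    CHEMISTRY_INVASION,
    SampleSpec,
    SimulationConfig,
    chemistry_rates,
    preset_samples,
    simulate_library,
    simulate_reference,
    write_fasta,
    write_gtf,
)


def _small(seed=0, **kw):
    kw.setdefault("genome_length", 60_000)
    kw.setdefault("n_genes", 12)
    kw.setdefault("n_invasion_sites", 10)
    kw.setdefault("reads_per_sample", 300)
    kw.setdefault("samples", preset_samples(["R3"]))
    return SimulationConfig(seed=seed, **kw)


def test_chemistry_presets_match_measured_invasion_rates():
    """Invasion rate is a fraction of alignments: check it within the
    genomic (mappable) classes."""
    for chem, expected in [("R3", 0.091), ("L3", 0.359), ("D3", 0.736)]:
        r = chemistry_rates(chem)
        genomic = r["tss"] + r["internal"] + r["invasion"]
        assert r["invasion"] / genomic == pytest.approx(expected)
    for chem in CHEMISTRY_INVASION:
        assert sum(chemistry_rates(chem).values()) == pytest.approx(1.0)


def test_rate_vector_must_sum_to_one():
    with pytest.raises(ValueError):
        SampleSpec("s", "CACTGA", {"tss": 0.5, "internal": 0.2,
                                   "invasion": 0.0, "rrna": 0.0, "artifact": 0.0})


def test_reference_deterministic_under_seed(tmp_path):
    a = simulate_reference(_small(seed=4))
    b = simulate_reference(_small(seed=4))
    assert a.genome == b.genome
    assert [(m.gene_id, m.exons) for m in a.models] == [
        (m.gene_id, m.exons) for m in b.models
    ]
    fa1, fa2 = tmp_path / "a.fa", tmp_path / "b.fa"
    write_fasta(a.genome, fa1)
    write_fasta(b.genome, fa2)
    assert fa1.read_bytes() == fa2.read_bytes()
    g1, g2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    write_gtf(a.models, g1)
    write_gtf(b.models, g2)
    assert g1.read_bytes() == g2.read_bytes()


def test_library_deterministic_under_seed():
    cfg = _small(seed=9)
    ref = simulate_reference(cfg)
    r1, t1 = simulate_library(cfg, ref)
    r2, t2 = simulate_library(cfg, ref)
    assert r1 == r2
    pd.testing.assert_frame_equal(t1, t2)


def test_genes_do_not_overlap_and_have_structure():
    ref = simulate_reference(_small())
    spans = sorted(m.span for m in ref.models)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2
    for m in ref.models:
        assert 1 <= len(m.exons) <= 5
        assert all(e > s for s, e in m.exons)


def test_zero_genes_gives_empty_annotation():
    ref = simulate_reference(_small(n_genes=0))
    assert ref.models == []
    assert len(ref.genome["chr1"]) == 60_000


def test_too_small_genome_raises():
    with pytest.raises(ValueError, match="genome_length"):
        simulate_reference(
            SimulationConfig(genome_length=5_000, n_genes=50,
                             samples=preset_samples(["R3"]))
        )


def test_gc_content_near_half():
    ref = simulate_reference(_small(genome_length=200_000, n_genes=0,
                                    n_invasion_sites=0))
    seq = ref.genome["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    se = 0.5 / np.sqrt(len(seq))
    assert abs(gc - 0.5) < 3 * se


def test_planted_sites_carry_the_motif():
    cfg = _small()
    ref = simulate_reference(cfg)
    genome = ref.genome["chr1"]
    for chrom, pos, strand in ref.invasion_sites:
        if strand == "+":
            window = genome[pos - 7 : pos]
        else:
            window = revcomp(genome[pos + 1 : pos + 8])
        assert hamming_mismatches(window, cfg.invasion_motif) <= 2


def test_all_tss_reads_start_at_transcript_starts():
    cfg = _small(
        error_rate=0.0,
        samples=[SampleSpec("s", "CACTGA",
                            {"tss": 1.0, "internal": 0.0, "invasion": 0.0,
                             "rrna": 0.0, "artifact": 0.0})],
    )
    ref = simulate_reference(cfg)
    _, truth = simulate_library(cfg, ref)
    starts = {m.gene_id: m.transcript_starts[0] for m in ref.models}
    assert (truth.true_class == "tss").all()
    assert all(truth.pos[i] == starts[truth.gene[i]] for i in truth.index)


def test_pure_invasion_library_fully_flagged():
    """p_invasion = 1, no errors: the filter flags every aligned read."""
    from nanocage.align_io import naive_align
    from nanocage.preprocess import SampleSheet, demultiplex
    from nanocage.strand_invasion import flag_strand_invasion

    cfg = _small(
        error_rate=0.0,
        reads_per_sample=200,
        samples=[SampleSpec("s", "CACTGA",
                            {"tss": 0.0, "internal": 0.0, "invasion": 1.0,
                             "rrna": 0.0, "artifact": 0.0})],
    )
    ref = simulate_reference(cfg)
    records, _ = simulate_library(cfg, ref)
    parsed, _ = demultiplex(records, SampleSheet.default())
    n = 0
    for p in parsed:
        if not p.assigned:
            continue
        res = naive_align(p.insert, ref.genome, 3, p.read_id)
        assert res.mapped
        assert flag_strand_invasion(res.alignment, ref.genome).flagged
        n += 1
    assert n > 150


def test_class_counts_within_multinomial_error(chem_sim):
    cfg, _, _, truth = chem_sim
    for spec in cfg.samples:
        sub = truth[truth.sample_id == spec.sample_id]
        n = len(sub)
        for cls, p in spec.class_rates.items():
            observed = (sub.true_class == cls).sum()
            se = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * se + 1


def test_reads_have_the_printed_layout(error_free_sim):
    cfg, _, records, truth = error_free_sim
    t = truth.set_index("read_id")
    for rid, seq, qual in records[:200]:
        row = t.loc[rid]
        assert seq.startswith(row.barcode + row.umi + "TATA")
        assert len(seq) == cfg.read_length == len(qual)
        tail = seq[len(row.barcode) + len(row.umi) + 4 :]
        assert tail.startswith("GGG")
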