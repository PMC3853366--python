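"""Read-layout parsing, demultiplexing and artifact screening."""

import random

import pytest

from nanocage.preprocess import (
    DEFAULT_BARCODES,
    PreprocessConfig,
    SampleSheet,
    TSOligoSpec,
    artifact_coverage,
    artifact_filter,
    default_artifact_library,
    demultiplex,
    parse_read,
)


@pytest.fixture(scope="module")
def sheet():
    return SampleSheet.default()


def test_default_sheet_has_the_printed_barcodes(sheet):
    assert len(sheet.entries) == 15
    assert sheet.entries["CACTGA"][1] == "R3"
    assert sheet.entries["GTATAC"][1] == "D3"
    assert sheet.entries["TATAGC"][1] == "L3"
    assert all(len(bc) == 6 for bc in sheet.entries)


def test_oligo_layout():
    spec = TSOligoSpec()
    oligo = spec.full_oligo("CACTGA")
    assert oligo.startswith("TAGTCGAACTGAAGGTCTCCAGCA")
    assert oligo.endswith("GGG")
    assert len(oligo) == 24 + 6 + 8 + 7


def _read(barcode="CACTGA", umi="AACCGGTT", linker="TATAGGG", insert="ACT" * 14):
    seq = barcode + umi + linker + insert
    return seq, "I" * len(seq)


def test_parse_read_example(sheet):
    """Barcode + UMI + linker + 40 nt insert -> trimmed 31 nt insert."""
    insert = ("ACTG" * 10)[:40]
    seq, qual = _read(insert=insert)
    pr = parse_read("r1", seq, qual, sheet)
    assert pr.sample_id == sheet.entries["CACTGA"][0]
    assert pr.umi == "AACCGGTT"
    assert pr.insert == insert[:31]
    assert len(pr.insert_qualities) == 31
    assert pr.assigned


def test_unknown_barcode_goes_unassigned(sheet):
    seq, qual = _read(barcode="NNNNNN")
    pr = parse_read("r1", seq, qual, sheet)
    assert pr.unassigned and pr.sample_id is None


def test_insert_exactly_trim_length_unchanged(sheet):
    insert = ("TAC" * 11)[:31]
    seq, qual = _read(barcode="TATAGC", insert=insert)
    pr = parse_read("r1", seq, qual, sheet)
    assert pr.sample_id == sheet.entries["TATAGC"][0]
    assert pr.insert == insert


def test_extra_cap_gs_are_stripped(sheet):
    # cap-templated C-addition shows up as extra G's after the linker
    seq, qual = _read(linker="TATAGGGGG", insert="ACTACTACT")
    pr = parse_read("r1", seq, qual, sheet)
    assert pr.insert == "ACTACTACT"


def test_short_or_linkerless_reads_are_artifacts(sheet):
    pr = parse_read("r1", "CACTGAAACC", "I" * 10, sheet)
    assert pr.artifact
    seq, qual = _read(linker="CCCCGGG")
    assert parse_read("r2", seq, qual, sheet).artifact


def test_barcode_single_mismatch_recovery(sheet):
    cfg = PreprocessConfig(barcode_max_mismatch=1)
    seq, qual = _read(barcode="CACTGT")  # 1 mismatch from CACTGA
    pr = parse_read("r1", seq, qual, sheet, cfg)
    assert pr.sample_id == sheet.entries["CACTGA"][0]


def test_head_included_layout(sheet):
    seq, qual = _read()
    full = TSOligoSpec().head + seq
    cfg = PreprocessConfig(head_included=True)
    pr = parse_read("r1", full, "I" * len(full), sheet, cfg)
    assert pr.sample_id == sheet.entries["CACTGA"][0]


def test_artifact_filter_flags_linker_repeats(sheet):
    lib = default_artifact_library(sheet)
    pr = parse_read("r1", *_read(insert="TATAGGG" * 6), sheet)
    pr = artifact_filter(pr, lib)
    assert pr.artifact


def test_artifact_filter_keeps_random_insert(sheet):
    lib = default_artifact_library(sheet)
    rng = random.Random(99)
    insert = "".join(rng.choice("ACGT") for _ in range(31))
    # seeded random insert shares no long word with the TS oligo library
    assert artifact_coverage(insert, lib) < 0.5
    pr = artifact_filter(parse_read("r1", *_read(insert=insert), sheet), lib)
    assert not pr.artifact


def test_partial_match_below_coverage_threshold(sheet):
    lib = default_artifact_library(sheet)
    rng = random.Random(7)
    tail = "".join(rng.choice("ACGT") for _ in range(15))
    insert = "TATAGGGTATAGGGTA" + tail  # 16 of 31 nt oligo-derived
    cov = artifact_coverage(insert, lib)
    assert cov < 0.8  # roughly 16/31
    pr = artifact_filter(parse_read("r1", *_read(insert=insert), sheet), lib)
    assert not pr.artifact


def test_empty_library_is_noop_with_warning(sheet):
    pr = parse_read("r1", *_read(), sheet)
    with pytest.warns(UserWarning):
        out = artifact_filter(pr, [])
    assert not out.artifact


def test_demultiplex_is_a_partition(chem_sim):
    """Every read lands in exactly one of assigned/unassigned/artifact."""
    _, _, records, _ = chem_sim
    parsed, summary = demultiplex(records, SampleSheet.default())
    assert len(parsed) == summary["input"] == len(records)
    states = [(p.assigned, p.unassigned, p.artifact) for p in parsed]
    assert all(sum(s) == 1 for s in states)
    assert (
        summary.get("assigned", 0)
        + summary.get("unassigned", 0)
        + summary.get("artifact", 0)
        == summary["input"]
    )


def test_roundtrip_recovers_barcode_and_umi(error_free_sim):
    """Error-free reads: (sample, UMI) recovered for 100% of reads."""
    _, _, records, truth = error_free_sim
    parsed, _ = demultiplex(records, SampleSheet.default())
    t = truth.set_index("read_id")
    checked = 0
    for p in parsed:
        row = t.loc[p.read_id]
        if row.true_class == "artifact":
            continue
        assert p.sample_id == row.sample_id
        assert p.umi == row.umi
        checked += 1
    assert checked > 1000


def test_insert_never_exceeds_trim_length(chem_sim):
    _, _, records, _ = chem_sim
    parsed, _ = demultiplex(records, SampleSheet.default())
    assert all(len(p.insert) <= 31 for p in parsed)


def test_sheet_tsv_roundtrip(tmp_path, sheet):
    path = tmp_path / "sheet.tsv"
    sheet.to_tsv(path)
    again = SampleSheet.from_tsv(path)
    assert again.entries == sheet.entries
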