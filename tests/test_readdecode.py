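"""Barcode/linker decoding: layout plumbing, correction rules, and exact
agreement with an independent brute-force Hamming oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spatac
from spatac.readdecode import (BarcodeWhitelist, STATUSES, correct_barcode,
                               decode_batch, decode_read, load_layout,
                               make_layout, match_linkers)

# ---------------------------------------------------------------------------
# independent per-read oracle (plain python, no shared code paths)
# ---------------------------------------------------------------------------

def _mm(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            n += 1
    return n


def oracle_status(seq: str, layout, wl_a, wl_b, max_mm: int, radius: int) -> str:
    lens = dict(layout.segments)
    fixed = lens["barcodeB"] + lens["linker2"] + lens["barcodeA"] + lens["linker1"]
    if len(seq) < fixed + 1:
        return "too_short"
    ob = seq[:lens["barcodeB"]]
    l2 = seq[lens["barcodeB"]:lens["barcodeB"] + lens["linker2"]]
    oa = seq[lens["barcodeB"] + lens["linker2"]:
             lens["barcodeB"] + lens["linker2"] + lens["barcodeA"]]
    l1 = seq[fixed - lens["linker1"]:fixed]
    if _mm(l2, layout.linker2_seq) > max_mm or _mm(l1, layout.linker1_seq) > max_mm:
        return "linker_fail"
    calls = []
    for obs, wl in ((ob, wl_b), (oa, wl_a)):
        dists = [_mm(obs, e) for e in wl.entries]
        best = min(dists)
        if best > radius:
            calls.append("unmatched")
        elif dists.count(best) > 1:
            calls.append("ambiguous")
        else:
            calls.append(dists.index(best) + 1)
    if "unmatched" in calls:
        return "barcode_unmatched"
    if "ambiguous" in calls:
        return "barcode_ambiguous"
    return "assigned"


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def test_layout_offsets_are_cumulative_lengths():
    layout = make_layout(8, "A" * 30, "C" * 30)
    assert layout.offsets["genomic"] == 8 + 30 + 8 + 30 == 76
    assert layout.fixed_length == 76
    assert layout.offsets["barcodeB"] == 0
    assert layout.offsets["barcodeA"] == 38


def test_layout_missing_linker_rejected():
    with pytest.raises(ValueError, match="linker1"):
        spatac.ReadLayout((("barcodeB", 8), ("linker2", 30), ("barcodeA", 8),
                           ("genomic", None)), "A" * 30, "C" * 30)


def test_layout_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        spatac.ReadLayout((("barcodeB", 8), ("linker2", 30), ("barcodeA", 8),
                           ("linker1", 30), ("genomic", None)),
                          "A" * 29, "C" * 30)


def test_layout_roundtrips_through_file(sim, tmp_path):
    path = tmp_path / "layout.yaml"
    sim["layout"].save(path)
    assert load_layout(path) == sim["layout"]


# ---------------------------------------------------------------------------
# linker matching and barcode correction
# ---------------------------------------------------------------------------

def test_linker_match_rules(sim):
    layout = sim["layout"]
    seq2id, id2seq = spatac.pixel_maps(sim["wl_a"], sim["wl_b"])
    combined = id2seq["A01B01"]
    read = (combined[8:] + layout.linker2_seq + combined[:8]
            + layout.linker1_seq + "ACGT" * 10)
    res = match_linkers(read, layout, 3)
    assert res.status == "pass" and res.mismatches == {"linker1": 0, "linker2": 0}
    # two substitutions in linker1, tolerance 1 -> fail
    l1 = list(layout.linker1_seq)
    l1[0] = "A" if l1[0] != "A" else "C"
    l1[5] = "A" if l1[5] != "A" else "C"
    bad = (combined[8:] + layout.linker2_seq + combined[:8]
           + "".join(l1) + "ACGT" * 10)
    assert match_linkers(bad, layout, 1).status == "linker_fail"
    assert match_linkers(bad, layout, 2).status == "pass"
    assert match_linkers("ACGT", layout, 3).status == "too_short"


def test_n_bases_count_as_mismatch(sim):
    layout = sim["layout"]
    read = ("N" * 8 + layout.linker2_seq + "N" * 8 + layout.linker1_seq + "ACGTACGT")
    assert match_linkers(read, layout, 0).status == "pass"
    read_n = read[:8] + "N" + layout.linker2_seq[1:] + read[38:]
    assert match_linkers(read_n, layout, 0).status == "linker_fail"


def test_correct_barcode_exact_and_radius(sim):
    wl = sim["wl_a"]
    assert correct_barcode(wl.sequence(5), wl, 1).index == 5
    mutated = list(wl.sequence(5))
    mutated[3] = "A" if mutated[3] != "A" else "C"
    call = correct_barcode("".join(mutated), wl, 1)
    assert call.index == 5 and call.distance == 1
    assert correct_barcode("".join(mutated), wl, 0).status == "unmatched"
    with pytest.raises(ValueError):
        correct_barcode("ACGT", wl, 1)


def test_correct_barcode_tie_is_ambiguous():
    # two entries at pairwise distance 2; midpoint is distance 1 from both
    wl = BarcodeWhitelist(round="A", entries=("AAAAAAAA", "AACCAAAA", "GGGGGGGG"))
    call = correct_barcode("AACAAAAA", wl, 1)
    assert call.status == "ambiguous" and call.index is None


# ---------------------------------------------------------------------------
# per-read decode and run-level conservation
# ---------------------------------------------------------------------------

def _build_read(layout, wl_a, wl_b, a, b, insert):
    return (wl_b.sequence(b) + layout.linker2_seq + wl_a.sequence(a)
            + layout.linker1_seq + insert)


def test_decode_read_recovers_truth_pixel(sim):
    layout, wl_a, wl_b = sim["layout"], sim["wl_a"], sim["wl_b"]
    insert = "ACGTTGCA" * 5
    seq = _build_read(layout, wl_a, wl_b, 5, 7, insert)
    res = decode_read((seq, "I" * len(seq)), ("ACGT", "IIII"), layout, wl_a, wl_b)
    assert res.status == "assigned"
    assert res.pixel.canonical_id == "A05B07"
    assert res.genomic_seq == insert
    assert res.pixel.combined_seq == wl_a.sequence(5) + wl_b.sequence(7)


def test_decode_read_linker_fail_propagates(sim):
    layout, wl_a, wl_b = sim["layout"], sim["wl_a"], sim["wl_b"]
    seq = _build_read(layout, wl_a, wl_b, 1, 1, "ACGT" * 10)
    corrupt = seq[:8] + "N" * 30 + seq[38:]
    res = decode_read((corrupt, "I" * len(corrupt)), ("A", "I"), layout, wl_a, wl_b)
    assert res.status == "linker_fail" and res.pixel is None


def test_decode_run_conserves_reads_and_matches_truth(pipeline):
    report = pipeline["report"]
    assert report.n_assigned + report.n_rejected == report.n_input
    assert sum(report.counts.values()) == report.n_input
    # error-free: everything assigned, and every assignment equals truth
    assert report.assigned_fraction == 1.0
    truth = pipeline["reads"].set_index("read_id")["barcode"]
    for rid, bc in pipeline["assignments"].items():
        assert truth[rid] == bc


def test_decode_run_empty_input(sim, tmp_path):
    for name in ("r1.fastq", "r2.fastq"):
        (tmp_path / name).write_text("")
    report, _ = spatac.decode_run(tmp_path / "r1.fastq", tmp_path / "r2.fastq",
                                  tmp_path / "o", sim["layout"], sim["wl_a"],
                                  sim["wl_b"])
    assert report.n_input == 0 and report.distinct_pixels == 0


def test_decode_run_truncated_fastq_names_record(sim, tmp_path):
    (tmp_path / "r1.fastq").write_text("@r1\nACGT\n+\n")
    (tmp_path / "r2.fastq").write_text("@r1\nACGT\n+\nIIII\n")
    with pytest.raises(ValueError, match="record 0"):
        spatac.decode_run(tmp_path / "r1.fastq", tmp_path / "r2.fastq",
                          tmp_path / "o", sim["layout"], sim["wl_a"], sim["wl_b"])


# ---------------------------------------------------------------------------
# oracle equivalence and monotonicity on noisy reads
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def noisy_reads(sim):
    rng = np.random.default_rng(11)
    layout, wl_a, wl_b = sim["layout"], sim["wl_a"], sim["wl_b"]
    reads = []
    for _ in range(2000):
        a = int(rng.integers(1, len(wl_a) + 1))
        b = int(rng.integers(1, len(wl_b) + 1))
        seq = list(_build_read(layout, wl_a, wl_b, a, b, "ACGT" * 10))
        k = rng.binomial(len(seq), 0.03)
        for p in rng.choice(len(seq), size=k, replace=False):
            seq[p] = "ACGTN"[rng.integers(5)]
        reads.append("".join(seq))
    return reads


def test_batch_decode_matches_oracle(sim, noisy_reads):
    layout, wl_a, wl_b = sim["layout"], sim["wl_a"], sim["wl_b"]
    status, _, _ = decode_batch(noisy_reads, layout, wl_a, wl_b, 3, 1)
    for seq, code in zip(noisy_reads, status):
        assert STATUSES[code] == oracle_status(seq, layout, wl_a, wl_b, 3, 1)


def test_scalar_decode_matches_oracle(sim, noisy_reads):
    layout, wl_a, wl_b = sim["layout"], sim["wl_a"], sim["wl_b"]
    for seq in noisy_reads[:300]:
        res = decode_read((seq, "I" * len(seq)), ("A", "I"), layout, wl_a, wl_b)
        assert res.status == oracle_status(seq, layout, wl_a, wl_b, 3, 1)


@pytest.mark.parametrize("param", ["linker", "radius"])
def test_tolerance_monotonicity(sim, noisy_reads, param):
    """Raising either tolerance never decreases the assigned count."""
    layout, wl_a, wl_b = sim["layout"], sim["wl_a"], sim["wl_b"]
    prev = -1
    for t in range(4):
        mm, rad = (t, 1) if param == "linker" else (3, t)
        status, _, _ = decode_batch(noisy_reads, layout, wl_a, wl_b, mm, rad)
        assigned = int((status == 0).sum())
        assert assigned >= prev
        prev = assigned


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=120))
def test_arbitrary_sequences_get_exactly_one_status(seq):
    layout, wl_a, wl_b = _ASSETS
    res = decode_read((seq, "I" * len(seq)), ("A", "I"), layout, wl_a, wl_b)
    assert res.status in STATUSES
    assert (res.pixel is not None) == (res.status == "assigned")
    assert res.status == oracle_status(seq, layout, wl_a, wl_b, 3, 1)


from spatac.simulate import default_assets as _da, SimConfig as _SC  # noqa: E402
_ASSETS = _da(_SC(seed=7))
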