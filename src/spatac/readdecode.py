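"""Decode spatially barcoded reads into pixel-tagged, aligner-ready reads.

Read 1 of a spatial ATAC-seq library carries, 5'->3', the ligation products of
two barcoding rounds followed by the genomic insert::

    [barcode B][linker 2][barcode A][linker 1][genomic ...]

Every segment before the genomic part has a fixed length, so linkers are
matched positionally by Hamming distance and barcodes are error-corrected
against their round's whitelist.  A read decodes to a spatial pixel
(barcode A x barcode B grid cell) or is rejected with a typed status; no read
is ever silently dropped.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

GENOMIC = "genomic"
FIXED_ROLES = ("barcodeB", "linker2", "barcodeA", "linker1")
STATUSES = ("assigned", "too_short", "linker_fail", "barcode_unmatched",
            "barcode_ambiguous")

_N = ord("N")


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; any N counts as mismatch."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def _seq_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# layout / whitelist / pixel types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadLayout:
    """Fixed segment structure of read 1.

    segments is an ordered list of (role, length); the single ``genomic``
    segment must come last and its length (None) means "rest of the read".
    """

    segments: tuple[tuple[str, int | None], ...]
    linker1_seq: str
    linker2_seq: str

    def __post_init__(self) -> None:
        roles = [r for r, _ in self.segments]
        if roles.count(GENOMIC) != 1 or roles[-1] != GENOMIC:
            raise ValueError("layout needs exactly one genomic segment, last")
        for role, length in self.segments[:-1]:
            if length is None or length <= 0:
                raise ValueError(f"segment {role!r} needs a positive length")
        for role in FIXED_ROLES:
            if role not in roles:
                raise ValueError(f"layout missing segment {role!r}")
        for name, seq in (("linker1", self.linker1_seq), ("linker2", self.linker2_seq)):
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"{name} sequence must be non-empty ACGTN")
        lens = dict(self.segments)
        if len(self.linker1_seq) != lens["linker1"]:
            raise ValueError("linker1 sequence length != declared length")
        if len(self.linker2_seq) != lens["linker2"]:
            raise ValueError("linker2 sequence length != declared length")

    @property
    def offsets(self) -> dict[str, int]:
        """Fixed start offset of every segment (cumulative lengths)."""
        out, pos = {}, 0
        for role, length in self.segments:
            out[role] = pos
            pos += length or 0
        return out

    @property
    def fixed_length(self) -> int:
        return sum(l for _, l in self.segments[:-1])

    def segment_length(self, role: str) -> int:
        return dict(self.segments)[role]

    def to_dict(self) -> dict:
        return {
            "segments": [{"role": r, "length": l} for r, l in self.segments],
            "linker1_seq": self.linker1_seq,
            "linker2_seq": self.linker2_seq,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_layout(path: str | Path) -> ReadLayout:
    """Load and validate a read layout from a YAML/JSON config file."""
    data = yaml.safe_load(Path(path).read_text())
    try:
        segments = tuple((s["role"], s.get("length")) for s in data["segments"])
        return ReadLayout(segments, data["linker1_seq"], data["linker2_seq"])
    except KeyError as exc:  # missing role / sequence key
        raise ValueError(f"layout file {path} missing key {exc}") from exc


def make_layout(barcode_len: int, linker1_seq: str, linker2_seq: str) -> ReadLayout:
    return ReadLayout(
        (
            ("barcodeB", barcode_len),
            ("linker2", len(linker2_seq)),
            ("barcodeA", barcode_len),
            ("linker1", len(linker1_seq)),
            (GENOMIC, None),
        ),
        linker1_seq=linker1_seq,
        linker2_seq=linker2_seq,
    )


@dataclass
class BarcodeWhitelist:
    """One barcoding round's ordered barcode set (index 1..n)."""

    round: str  # "A" or "B"
    entries: tuple[str, ...]
    min_pairwise_distance: int = field(init=False)

    def __post_init__(self) -> None:
        if self.round not in ("A", "B"):
            raise ValueError("round must be 'A' or 'B'")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("whitelist entries must be unique")
        if len({len(e) for e in self.entries}) != 1:
            raise ValueError("whitelist entries must share one length")
        d = min(
            (hamming(a, b) for i, a in enumerate(self.entries)
             for b in self.entries[i + 1:]),
            default=self.length,
        )
        object.__setattr__(self, "min_pairwise_distance", d)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def length(self) -> int:
        return len(self.entries[0])

    def sequence(self, index: int) -> str:
        """1-based lookup."""
        return self.entries[index - 1]

    @classmethod
    def from_csv(cls, path: str | Path, round: str) -> "BarcodeWhitelist":
        rows = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                rows.append((int(row[0]), row[1].strip().upper()))
        rows.sort()
        return cls(round=round, entries=tuple(seq for _, seq in rows))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            for i, seq in enumerate(self.entries, start=1):
                w.writerow([i, seq])

    def check_radius(self, radius: int) -> None:
        if self.min_pairwise_distance <= 2 * radius:
            warnings.warn(
                f"whitelist {self.round}: min pairwise distance "
                f"{self.min_pairwise_distance} <= 2*radius={2 * radius}; "
                "correction may be ambiguous", stacklevel=2)


@dataclass(frozen=True)
class SpatialPixel:
    """A grid coordinate with its canonical barcode identity."""

    a_index: int
    b_index: int
    canonical_id: str
    combined_seq: str

    @classmethod
    def from_indices(cls, a_index: int, b_index: int,
                     wl_a: BarcodeWhitelist, wl_b: BarcodeWhitelist) -> "SpatialPixel":
        if not (1 <= a_index <= len(wl_a) and 1 <= b_index <= len(wl_b)):
            raise ValueError(f"pixel ({a_index},{b_index}) outside grid")
        return cls(
            a_index=a_index,
            b_index=b_index,
            canonical_id=canonical_id(a_index, b_index),
            combined_seq=wl_a.sequence(a_index) + wl_b.sequence(b_index),
        )


def canonical_id(a_index: int, b_index: int) -> str:
    return f"A{a_index:02d}B{b_index:02d}"


def parse_canonical_id(cid: str) -> tuple[int, int]:
    ia = cid.index("A")
    ib = cid.index("B")
    return int(cid[ia + 1:ib]), int(cid[ib + 1:])


def pixel_maps(wl_a: BarcodeWhitelist, wl_b: BarcodeWhitelist
               ) -> tuple[dict[str, str], dict[str, str]]:
    """(combined_seq -> canonical_id, canonical_id -> combined_seq) maps."""
    seq2id, id2seq = {}, {}
    for a in range(1, len(wl_a) + 1):
        for b in range(1, len(wl_b) + 1):
            px = SpatialPixel.from_indices(a, b, wl_a, wl_b)
            seq2id[px.combined_seq] = px.canonical_id
            id2seq[px.canonical_id] = px.combined_seq
    return seq2id, id2seq


# ---------------------------------------------------------------------------
# per-read decoding (scalar reference path)
# ---------------------------------------------------------------------------

@dataclass
class LinkerMatch:
    status: str  # pass | linker_fail | too_short
    mismatches: dict[str, int]


def match_linkers(read1: str, layout: ReadLayout, max_linker_mismatch: int = 3
                  ) -> LinkerMatch:
    """Positional Hamming filter on both constant linkers."""
    if len(read1) < layout.fixed_length + 1:
        return LinkerMatch("too_short", {})
    off = layout.offsets
    mm = {}
    for role, seq in (("linker2", layout.linker2_seq), ("linker1", layout.linker1_seq)):
        o = off[role]
        mm[role] = hamming(read1[o:o + len(seq)], seq)
    ok = all(v <= max_linker_mismatch for v in mm.values())
    return LinkerMatch("pass" if ok else "linker_fail", mm)


@dataclass
class BarcodeCall:
    index: int | None  # 1-based whitelist index, None unless matched
    status: str        # matched | ambiguous | unmatched
    distance: int | None


def correct_barcode(observed: str, whitelist: BarcodeWhitelist, radius: int = 1
                    ) -> BarcodeCall:
    """Return the unique whitelist entry within Hamming ``radius``.

    Ties at the minimum distance are rejected as ambiguous, never guessed.
    """
    if len(observed) != whitelist.length:
        raise ValueError("observed barcode length != whitelist length")
    dists = [hamming(observed, e) for e in whitelist.entries]
    best = min(dists)
    if best > radius:
        return BarcodeCall(None, "unmatched", None)
    if dists.count(best) > 1:
        return BarcodeCall(None, "ambiguous", best)
    return BarcodeCall(dists.index(best) + 1, "matched", best)


@dataclass
class DecodeResult:
    status: str
    pixel: SpatialPixel | None = None
    genomic_seq: str | None = None
    genomic_quals: str | None = None
    mismatches: dict[str, int] = field(default_factory=dict)


def decode_read(read1: tuple[str, str], read2: tuple[str, str],
                layout: ReadLayout, wl_a: BarcodeWhitelist, wl_b: BarcodeWhitelist,
                max_linker_mismatch: int = 3, bc_radius: int = 1) -> DecodeResult:
    """Decode one read pair; read 2 (genomic mate) passes through untouched.

    Status precedence: too_short, linker_fail, barcode_unmatched (either
    round), barcode_ambiguous, assigned.
    """
    seq1, qual1 = read1
    lm = match_linkers(seq1, layout, max_linker_mismatch)
    if lm.status != "pass":
        return DecodeResult(lm.status, mismatches=lm.mismatches)
    off = layout.offsets
    ob = seq1[off["barcodeB"]:off["barcodeB"] + layout.segment_length("barcodeB")]
    oa = seq1[off["barcodeA"]:off["barcodeA"] + layout.segment_length("barcodeA")]
    call_b = correct_barcode(ob, wl_b, bc_radius)
    call_a = correct_barcode(oa, wl_a, bc_radius)
    mm = dict(lm.mismatches)
    if "unmatched" in (call_a.status, call_b.status):
        return DecodeResult("barcode_unmatched", mismatches=mm)
    if "ambiguous" in (call_a.status, call_b.status):
        return DecodeResult("barcode_ambiguous", mismatches=mm)
    mm["barcodeA"] = call_a.distance
    mm["barcodeB"] = call_b.distance
    g = off[GENOMIC]
    return DecodeResult(
        "assigned",
        pixel=SpatialPixel.from_indices(call_a.index, call_b.index, wl_a, wl_b),
        genomic_seq=seq1[g:],
        genomic_quals=qual1[g:],
        mismatches=mm,
    )


# ---------------------------------------------------------------------------
# batch decoding (vectorised engine)
# ---------------------------------------------------------------------------

def _barcode_dists(obs: np.ndarray, wl: BarcodeWhitelist) -> np.ndarray:
    """(n_reads, n_entries) Hamming distances; N counts as mismatch."""
    wlm = np.vstack([_seq_bytes(e) for e in wl.entries])  # (k, L)
    mm = (obs[:, None, :] != wlm[None, :, :]) | (obs[:, None, :] == _N) | (wlm[None, :, :] == _N)
    return mm.sum(axis=2)


def decode_batch(seqs: Sequence[str], layout: ReadLayout,
                 wl_a: BarcodeWhitelist, wl_b: BarcodeWhitelist,
                 max_linker_mismatch: int = 3, bc_radius: int = 1
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised decode of read-1 sequences.

    Returns (status codes indexing STATUSES, a_index, b_index); indices are
    1-based and 0 where unassigned.
    """
    n = len(seqs)
    fixed = layout.fixed_length
    status = np.zeros(n, dtype=np.int8)  # 0 = assigned until proven otherwise
    a_idx = np.zeros(n, dtype=np.int32)
    b_idx = np.zeros(n, dtype=np.int32)
    lens = np.fromiter((len(s) for s in seqs), count=n, dtype=np.int64)
    short = lens < fixed + 1
    status[short] = STATUSES.index("too_short")
    keep = np.flatnonzero(~short)
    if keep.size == 0:
        return status, a_idx, b_idx
    mat = np.vstack([_seq_bytes(seqs[i][:fixed]) for i in keep])
    off = layout.offsets
    linker_bad = np.zeros(keep.size, dtype=bool)
    for role, seq in (("linker2", layout.linker2_seq), ("linker1", layout.linker1_seq)):
        o = off[role]
        ref = _seq_bytes(seq)
        seg = mat[:, o:o + len(seq)]
        mm = ((seg != ref[None, :]) | (seg == _N) | (ref[None, :] == _N)).sum(axis=1)
        linker_bad |= mm > max_linker_mismatch
    status[keep[linker_bad]] = STATUSES.index("linker_fail")
    ok = np.flatnonzero(~linker_bad)
    if ok.size == 0:
        return status, a_idx, b_idx
    unmatched = np.zeros(ok.size, dtype=bool)
    ambiguous = np.zeros(ok.size, dtype=bool)
    calls = {}
    for role, wl in (("barcodeB", wl_b), ("barcodeA", wl_a)):
        o = off[role]
        L = layout.segment_length(role)
        d = _barcode_dists(mat[ok][:, o:o + L], wl)
        best = d.min(axis=1)
        ties = (d == best[:, None]).sum(axis=1)
        unmatched |= best > bc_radius
        ambiguous |= (best <= bc_radius) & (ties > 1)
        calls[role] = d.argmin(axis=1) + 1
    bad_u = unmatched
    bad_a = ~unmatched & ambiguous
    status[keep[ok[bad_u]]] = STATUSES.index("barcode_unmatched")
    status[keep[ok[bad_a]]] = STATUSES.index("barcode_ambiguous")
    good = ~(bad_u | bad_a)
    gi = keep[ok[good]]
    a_idx[gi] = calls["barcodeA"][good]
    b_idx[gi] = calls["barcodeB"][good]
    return status, a_idx, b_idx


# ---------------------------------------------------------------------------
# run-level driver
# ---------------------------------------------------------------------------

@dataclass
class DecodeReport:
    n_input: int = 0
    counts: Counter = field(default_factory=Counter)
    barcode_a_usage: Counter = field(default_factory=Counter)
    barcode_b_usage: Counter = field(default_factory=Counter)
    pixel_counts: Counter = field(default_factory=Counter)

    @property
    def n_assigned(self) -> int:
        return self.counts.get("assigned", 0)

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_assigned

    @property
    def distinct_pixels(self) -> int:
        return len(self.pixel_counts)

    @property
    def assigned_fraction(self) -> float:
        return self.n_assigned / self.n_input if self.n_input else 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "counts": {s: self.counts.get(s, 0) for s in STATUSES},
            "distinct_pixels": self.distinct_pixels,
            "assigned_fraction": self.assigned_fraction,
            "barcode_a_usage": dict(self.barcode_a_usage),
            "barcode_b_usage": dict(self.barcode_b_usage),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def pixel_table_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["canonical_id", "n_reads"])
            for cid in sorted(self.pixel_counts):
                w.writerow([cid, self.pixel_counts[cid]])


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _fastq_pairs(r1_path, r2_path) -> Iterator[tuple[tuple, tuple]]:
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        i = 0
        while True:
            try:
                rec1 = next(it1, None)
            except ValueError as exc:
                raise ValueError(f"truncated/malformed FASTQ record {i} in {r1_path}: {exc}")
            try:
                rec2 = next(it2, None)
            except ValueError as exc:
                raise ValueError(f"truncated/malformed FASTQ record {i} in {r2_path}: {exc}")
            if rec1 is None and rec2 is None:
                return
            if (rec1 is None) != (rec2 is None):
                raise ValueError(f"FASTQ pair out of sync at record {i}")
            yield rec1, rec2
            i += 1


def decode_run(r1_path, r2_path, out_prefix, layout: ReadLayout,
               wl_a: BarcodeWhitelist, wl_b: BarcodeWhitelist,
               max_linker_mismatch: int = 3, bc_radius: int = 1,
               chunk_size: int = 50_000, collect_assignments: bool = False,
               ) -> tuple[DecodeReport, dict[str, str] | None]:
    """Decode a FASTQ pair into assigned/rejected streams plus a report.

    Writes ``<prefix>.assigned.R1/R2.fastq`` (genomic read 1 trimmed to the
    insert, CB:Z: barcode in the title), ``<prefix>.rejected.R1/R2.fastq``
    (status in the title), ``<prefix>.report.json`` and
    ``<prefix>.pixels.csv``.  Every input read lands in exactly one stream.
    """
    wl_a.check_radius(bc_radius)
    wl_b.check_radius(bc_radius)
    out_prefix = str(out_prefix)
    report = DecodeReport()
    assignments: dict[str, str] | None = {} if collect_assignments else None
    goff = layout.offsets[GENOMIC]
    files = {
        "a1": open(f"{out_prefix}.assigned.R1.fastq", "w"),
        "a2": open(f"{out_prefix}.assigned.R2.fastq", "w"),
        "r1": open(f"{out_prefix}.rejected.R1.fastq", "w"),
        "r2": open(f"{out_prefix}.rejected.R2.fastq", "w"),
    }
    try:
        chunk: list[tuple[tuple, tuple]] = []
        for pair in _fastq_pairs(r1_path, r2_path):
            chunk.append(pair)
            if len(chunk) >= chunk_size:
                _decode_chunk(chunk, layout, wl_a, wl_b, max_linker_mismatch,
                              bc_radius, goff, report, assignments, files)
                chunk = []
        if chunk:
            _decode_chunk(chunk, layout, wl_a, wl_b, max_linker_mismatch,
                          bc_radius, goff, report, assignments, files)
    finally:
        for fh in files.values():
            fh.close()
    assert report.n_assigned + sum(
        report.counts[s] for s in STATUSES if s != "assigned") == report.n_input
    report.to_json(f"{out_prefix}.report.json")
    report.pixel_table_csv(f"{out_prefix}.pixels.csv")
    return report, assignments


def _decode_chunk(chunk, layout, wl_a, wl_b, max_mm, radius, goff,
                  report: DecodeReport, assignments, files) -> None:
    seqs = [p[0][1] for p in chunk]
    status, a_idx, b_idx = decode_batch(seqs, layout, wl_a, wl_b, max_mm, radius)
    report.n_input += len(chunk)
    for code, cnt in zip(*np.unique(status, return_counts=True)):
        report.counts[STATUSES[code]] += int(cnt)
    for ((t1, s1, q1), (t2, s2, q2)), st, a, b in zip(chunk, status, a_idx, b_idx):
        if st == 0:
            cid = canonical_id(a, b)
            combined = wl_a.sequence(int(a)) + wl_b.sequence(int(b))
            report.barcode_a_usage[int(a)] += 1
            report.barcode_b_usage[int(b)] += 1
            report.pixel_counts[cid] += 1
            name = t1.split()[0]
            if assignments is not None:
                assignments[name] = combined
            files["a1"].write(f"@{name} CB:Z:{combined}\n{s1[goff:]}\n+\n{q1[goff:]}\n")
            files["a2"].write(f"@{t2.split()[0]} CB:Z:{combined}\n{s2}\n+\n{q2}\n")
        else:
            label = STATUSES[st]
            files["r1"].write(f"@{t1.split()[0]} XS:Z:{label}\n{s1}\n+\n{q1}\n")
            files["r2"].write(f"@{t2.split()[0]} XS:Z:{label}\n{s2}\n+\n{q2}\n")
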