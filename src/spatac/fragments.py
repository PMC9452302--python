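"""Tn5 fragment construction, deduplication and the spatial fragments file.

A fragment is the genomic interval between two Tn5 insertion events, recovered
from an aligned proper read pair.  Coordinates are 0-based half-open (BED
convention).  The 9-bp Tn5 target-site duplication is corrected with the
standard +4/-5 shift (configurable).  The fragments file is a BED-like
5-column TSV: contig, start, end, pixel barcode, duplicate count — one record
per distinct (contig, start, end, pixel).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

FRAGMENT_COLUMNS = ["contig", "start", "end", "barcode", "dup_count"]


@dataclass(frozen=True)
class Fragment:
    contig: str
    start: int
    end: int
    barcode: str
    dup_count: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.dup_count < 1:
            raise ValueError("dup_count must be >= 1")


@dataclass(frozen=True)
class PairRejection:
    reason: str  # improper_pair | low_mapq | missing_barcode | bad_interval | secondary


def _barcode_of(read: pysam.AlignedSegment, tag: str) -> str | None:
    if read.has_tag(tag):
        return str(read.get_tag(tag))
    # fall back to a "name|CB:<bc>" read-name convention
    if "|CB:" in read.query_name:
        return read.query_name.rsplit("|CB:", 1)[1]
    return None


def pair_to_fragment(read1: pysam.AlignedSegment, read2: pysam.AlignedSegment,
                     shift_plus: int = 4, shift_minus: int = 5,
                     min_mapq: int = 30, barcode_tag: str = "CB",
                     ) -> Fragment | PairRejection:
    """Build a Tn5-corrected fragment from an aligned pair.

    The interval is [plus-strand 5' + shift_plus, minus-strand 5' + 1 -
    shift_minus): with defaults a pair with 5' ends at 100/199 yields
    [104, 195).
    """
    for r in (read1, read2):
        if r.is_secondary or r.is_supplementary:
            return PairRejection("secondary")
        if r.is_unmapped:
            return PairRejection("improper_pair")
    if (not read1.is_proper_pair or read1.reference_name != read2.reference_name
            or read1.is_reverse == read2.is_reverse):
        return PairRejection("improper_pair")
    if min(read1.mapping_quality, read2.mapping_quality) < min_mapq:
        return PairRejection("low_mapq")
    fwd, rev = (read2, read1) if read1.is_reverse else (read1, read2)
    barcode = _barcode_of(read1, barcode_tag) or _barcode_of(read2, barcode_tag)
    if barcode is None:
        return PairRejection("missing_barcode")
    start = fwd.reference_start + shift_plus
    end = (rev.reference_end - 1) + 1 - shift_minus
    if not (0 <= start < end):
        return PairRejection("bad_interval")
    return Fragment(read1.reference_name, start, end, barcode)


def sam_to_fragments(sam_path: str | Path, shift_plus: int = 4,
                     shift_minus: int = 5, min_mapq: int = 30,
                     barcode_tag: str = "CB",
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Stream a (queryname-grouped) SAM/BAM into raw fragments + rejections.

    Returns a non-deduplicated fragment table (dup_count 1 per accepted pair)
    and a counter of rejection reasons.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    rows: list[tuple] = []
    rejections: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        for read in af:
            if read.is_secondary or read.is_supplementary:
                rejections["secondary"] = rejections.get("secondary", 0) + 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
            res = pair_to_fragment(r1, r2, shift_plus, shift_minus,
                                   min_mapq, barcode_tag)
            if isinstance(res, Fragment):
                rows.append((res.contig, res.start, res.end, res.barcode, 1))
            else:
                rejections[res.reason] = rejections.get(res.reason, 0) + 1
    if pending:
        rejections["unpaired"] = rejections.get("unpaired", 0) + len(pending)
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    return df, rejections


def deduplicate(frags: pd.DataFrame, contig_order: list[str] | None = None
                ) -> pd.DataFrame:
    """Collapse to one record per (contig, start, end, pixel).

    dup_count sums input multiplicities, so the operation is idempotent.
    Identical coordinates in different pixels stay distinct.
    """
    if frags.empty:
        return frags.reindex(columns=FRAGMENT_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "dup_count": np.int64},
            errors="ignore")
    out = (frags.groupby(["contig", "start", "end", "barcode"], as_index=False,
                         sort=False)["dup_count"].sum())
    return sort_fragments(out, contig_order)


def sort_fragments(frags: pd.DataFrame, contig_order: list[str] | None = None
                   ) -> pd.DataFrame:
    order = contig_order or sorted(frags["contig"].unique())
    key = frags["contig"].map({c: i for i, c in enumerate(order)})
    return (frags.assign(_k=key)
            .sort_values(["_k", "start", "end", "barcode"], kind="mergesort")
            .drop(columns="_k").reset_index(drop=True))


def write_fragments(frags: pd.DataFrame, path: str | Path,
                    contig_order: list[str] | None = None) -> None:
    """Write the 5-column BED-like fragments TSV (gzip by .gz suffix)."""
    sort_fragments(frags[FRAGMENT_COLUMNS], contig_order).to_csv(
        path, sep="\t", header=False, index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read and validate a fragments TSV; malformed lines name their number."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS,
                         dtype={"contig": str, "barcode": str},
                         comment="#")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed fragments file: {exc}") from exc
    if df.empty:
        return df
    for col in ("start", "end", "dup_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            raise ValueError(
                f"{path}: non-integer {col} at line {int(bad.idxmax()) + 1}")
        df[col] = vals.astype(np.int64)
    bad = (df["end"] <= df["start"]) | (df["start"] < 0) | (df["dup_count"] < 1)
    if bad.any():
        raise ValueError(
            f"{path}: invalid record at line {int(bad.idxmax()) + 1} "
            f"(need 0 <= start < end, dup_count >= 1)")
    return df


def per_pixel_totals(frags: pd.DataFrame) -> pd.Series:
    """Unique fragments per pixel barcode."""
    return frags.groupby("barcode").size()


def canonicalize_barcodes(frags: pd.DataFrame, seq2id: Mapping[str, str]
                          ) -> pd.DataFrame:
    """Translate sequence barcodes (barcodeA+barcodeB) to canonical AxxByy ids."""
    mapped = frags["barcode"].map(seq2id)
    if mapped.isna().any():
        missing = frags.loc[mapped.isna(), "barcode"].iloc[0]
        raise ValueError(f"barcode {missing!r} not in pixel map")
    return frags.assign(barcode=mapped)


# ---------------------------------------------------------------------------
# truth aligner stand-in
# ---------------------------------------------------------------------------

def truth_align(truth_reads: pd.DataFrame, contig_sizes: Mapping[str, int],
                path: str | Path, read_len: int = 50,
                barcodes: Mapping[str, str] | None = None,
                shift_plus: int = 4, shift_minus: int = 5) -> int:
    """Emit perfectly aligned proper pairs at the true fragment coordinates.

    ``truth_reads`` needs columns read_id, contig, start, end, barcode and
    r1_is_plus (whether read 1 carries the plus-strand 5' end).  Truth
    fragments are Tn5-corrected intervals, so read 5' ends are placed
    ``shift_plus``/``shift_minus`` bases outside them — applying the same
    shifts in :func:`pair_to_fragment` recovers the truth exactly.  When
    ``barcodes`` (read_id -> barcode, e.g. a decoder's assignments) is given,
    only those reads are written and their CB tags come from it; otherwise the
    truth barcode is used.  Returns the number of pairs written.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_sizes.items()],
    })
    ref_id = {c: i for i, c in enumerate(contig_sizes)}
    missing = 0
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in truth_reads.itertuples(index=False):
            if barcodes is not None:
                bc = barcodes.get(row.read_id)
                if bc is None:
                    missing += 1
                    continue
            else:
                bc = row.barcode
            raw_start = row.start - shift_plus
            raw_end = row.end + shift_minus
            if raw_start < 0 or raw_end > contig_sizes[row.contig]:
                missing += 1
                continue
            flen = raw_end - raw_start
            L = min(read_len, flen)
            left_pos, right_pos = raw_start, raw_end - L
            for is_r1 in (True, False):
                a = pysam.AlignedSegment(header)
                a.query_name = row.read_id
                r1_left = bool(row.r1_is_plus)
                left = is_r1 == r1_left
                a.reference_id = ref_id[row.contig]
                a.reference_start = left_pos if left else right_pos
                a.mapping_quality = 60
                a.cigarstring = f"{L}M"
                a.query_sequence = "A" * L
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                a.flag = (0x1 | 0x2 | (0x40 if is_r1 else 0x80)
                          | (0x0 if left else 0x10) | (0x20 if left else 0x0))
                a.next_reference_id = ref_id[row.contig]
                a.next_reference_start = right_pos if left else left_pos
                a.template_length = flen if left else -flen
                a.set_tag("CB", bc)
                out.write(a)
            n += 1
    return n
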