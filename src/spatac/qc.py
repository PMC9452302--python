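"""Per-pixel and aggregate chromatin-accessibility quality metrics.

All metrics operate on the deduplicated spatial fragments table (one row per
unique fragment).  Insertions are the two Tn5 events of a fragment: positions
``start`` and ``end - 1``.

Metrics
-------
- unique nuclear fragments per pixel (mitochondrial contig excluded)
- fraction of fragments overlapping TSS +/- 2 kb windows
- TSS enrichment score: mean per-base insertion depth in the +/-50 bp core
  around TSSs over the mean depth in distal flanks (1,901-2,000 bp away),
  with a one-insertion pseudocount in the denominator
- FRiP: fraction of unique fragments overlapping a peak by >= 1 bp
- mitochondrial fragment fraction
- insert-size histogram (nucleosomal / subnucleosomal bimodality)
- on- vs off-tissue depth comparison (Wilcoxon rank-sum)
- single-nucleus pixel selection from an imaging-derived nucleus count
- a deterministic threshold-run peak caller used in place of a model-based
  caller for self-contained testing
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats

DEFAULT_MITO = "chrM"
TSS_CORE = 50                 # core window: TSS +/- 50 bp
TSS_FLANK = (1901, 2000)      # distal flanks, both sides


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED6 file into (contig, start, end[, name, score, strand])."""
    names = ["contig", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[:df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def _merged_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge possibly overlapping intervals per contig; sorted starts/ends."""
    out = {}
    for contig, sub in df.groupby("contig"):
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[contig] = (np.asarray(starts), np.asarray(ends))
    return out


def _overlaps_any(frags: pd.DataFrame, merged) -> np.ndarray:
    """Boolean mask: fragment [start, end) overlaps some interval by >= 1 bp."""
    hit = np.zeros(len(frags), dtype=bool)
    for contig, idx in frags.groupby("contig").groups.items():
        if contig not in merged:
            continue
        starts, ends = merged[contig]
        s = frags.loc[idx, "start"].to_numpy()
        e = frags.loc[idx, "end"].to_numpy()
        i = np.searchsorted(ends, s, side="right")
        ok = (i < len(starts)) & (starts[np.minimum(i, len(starts) - 1)] < e)
        hit[frags.index.get_indexer(idx)] = ok
    return hit


def insertions(frags: pd.DataFrame) -> pd.DataFrame:
    """Long table of Tn5 insertion sites: two rows (start, end-1) per fragment."""
    a = frags[["contig", "barcode"]].copy()
    a["pos"] = frags["start"].to_numpy()
    b = frags[["contig", "barcode"]].copy()
    b["pos"] = frags["end"].to_numpy() - 1
    return pd.concat([a, b], ignore_index=True)


# ---------------------------------------------------------------------------
# per-pixel counts and fractions
# ---------------------------------------------------------------------------

def unique_per_pixel(frags: pd.DataFrame, mito_contig: str = DEFAULT_MITO
                     ) -> pd.DataFrame:
    """Unique nuclear / total fragment counts and mito fraction per pixel."""
    is_mito = frags["contig"] == mito_contig
    total = frags.groupby("barcode").size()
    mito = frags[is_mito].groupby("barcode").size()
    out = pd.DataFrame({"total_fragments": total})
    out["mito_fragments"] = mito.reindex(total.index).fillna(0).astype(int)
    out["unique_nuclear_fragments"] = out["total_fragments"] - out["mito_fragments"]
    out["mito_fraction"] = out["mito_fragments"] / out["total_fragments"]
    return out


def tss_fraction(frags: pd.DataFrame, tss: pd.DataFrame, window_bp: int = 2000,
                 mito_contig: str = DEFAULT_MITO) -> pd.Series:
    """Per-pixel fraction of nuclear fragments overlapping TSS +/- window_bp."""
    if tss.empty:
        raise ValueError("TSS set is empty; fraction undefined")
    nuc = frags[frags["contig"] != mito_contig]
    pos = tss["start"].to_numpy()
    windows = pd.DataFrame({
        "contig": tss["contig"],
        "start": np.maximum(pos - window_bp, 0),
        "end": pos + window_bp + 1,
    })
    hit = _overlaps_any(nuc, _merged_intervals(windows))
    return pd.Series(hit, index=nuc["barcode"].to_numpy()).groupby(level=0).mean()


def frip(frags: pd.DataFrame, peaks: pd.DataFrame,
         mito_contig: str = DEFAULT_MITO) -> pd.Series:
    """Per-pixel fraction of unique nuclear fragments in peaks (>= 1 bp overlap)."""
    if peaks.empty:
        raise ValueError("peak set is empty; FRiP undefined")
    nuc = frags[frags["contig"] != mito_contig]
    hit = _overlaps_any(nuc, _merged_intervals(peaks))
    return pd.Series(hit, index=nuc["barcode"].to_numpy()).groupby(level=0).mean()


def tss_enrichment(frags: pd.DataFrame, tss: pd.DataFrame,
                   core_bp: int = TSS_CORE, flank: tuple[int, int] = TSS_FLANK,
                   pseudocount: float = 1.0, per_pixel: bool = True,
                   mito_contig: str = DEFAULT_MITO) -> pd.DataFrame:
    """TSS enrichment score from insertion counts around each TSS.

    score = (core insertions / core bases) / ((flank insertions + pseudocount)
    / flank bases), pairs aggregated over all TSSs.  Pixels with zero flank
    coverage keep a pseudocount-backed score and are flagged.
    With ``per_pixel=False`` a single pooled row (index "pooled") is returned.
    """
    if tss.empty:
        raise ValueError("TSS set is empty; enrichment undefined")
    ins = insertions(frags[frags["contig"] != mito_contig])
    core_bases = 2 * core_bp + 1
    flank_bases = 2 * (flank[1] - flank[0] + 1)
    tss_by_contig = {c: np.sort(sub["start"].to_numpy())
                     for c, sub in tss.groupby("contig")}
    if not per_pixel:
        ins = ins.assign(barcode="pooled")
    rows = []
    for bc, sub in ins.groupby("barcode"):
        core = 0
        fl = 0
        for contig, s2 in sub.groupby("contig"):
            if contig not in tss_by_contig:
                continue
            p = np.sort(s2["pos"].to_numpy())
            t = tss_by_contig[contig]
            core += int((np.searchsorted(p, t + core_bp + 1)
                         - np.searchsorted(p, t - core_bp)).sum())
            fl += int((np.searchsorted(p, t - flank[0] + 1)
                       - np.searchsorted(p, t - flank[1])).sum())
            fl += int((np.searchsorted(p, t + flank[1] + 1)
                       - np.searchsorted(p, t + flank[0])).sum())
        score = (core / core_bases) / ((fl + pseudocount) / flank_bases)
        rows.append((bc, score, core, fl, fl == 0))
    out = pd.DataFrame(rows, columns=["barcode", "tss_enrichment",
                                      "core_insertions", "flank_insertions",
                                      "flagged"]).set_index("barcode")
    return out


def insert_size_hist(frags: pd.DataFrame, max_len: int = 1000) -> pd.DataFrame:
    """1-bp insert-size histogram of unique fragments up to ``max_len``."""
    sizes = (frags["end"] - frags["start"]).to_numpy()
    sizes = sizes[sizes <= max_len]
    counts = np.bincount(sizes, minlength=max_len + 1)
    return pd.DataFrame({"size": np.arange(max_len + 1), "count": counts})


# ---------------------------------------------------------------------------
# tissue-level diagnostics
# ---------------------------------------------------------------------------

@dataclass
class OnOffComparison:
    defined: bool
    n_on: int = 0
    n_off: int = 0
    median_on: float = float("nan")
    median_off: float = float("nan")
    statistic: float = float("nan")
    pvalue: float = float("nan")
    reason: str | None = None


def on_off_tissue_compare(qc_table: pd.DataFrame,
                          value_col: str = "unique_nuclear_fragments",
                          ) -> OnOffComparison:
    """Rank-sum comparison of per-pixel depth on vs off tissue."""
    if "on_tissue" not in qc_table:
        raise ValueError("qc table lacks on_tissue column")
    on = qc_table.loc[qc_table["on_tissue"].astype(bool), value_col].to_numpy()
    off = qc_table.loc[~qc_table["on_tissue"].astype(bool), value_col].to_numpy()
    if len(on) == 0 or len(off) == 0:
        return OnOffComparison(False, len(on), len(off),
                               reason="need pixels on both sides of the mask")
    stat, p = stats.mannwhitneyu(on, off, alternative="two-sided")
    return OnOffComparison(True, len(on), len(off),
                           float(np.median(on)), float(np.median(off)),
                           float(stat), float(p))


def single_nucleus_pixels(qc_table: pd.DataFrame) -> list[str]:
    """Barcodes of pixels whose imaging nucleus count is exactly 1."""
    if "nucleus_count" not in qc_table:
        raise ValueError("qc table lacks nucleus_count column")
    sel = qc_table.index[qc_table["nucleus_count"] == 1]
    return list(sel)


# ---------------------------------------------------------------------------
# assembled per-pixel QC table
# ---------------------------------------------------------------------------

def pixel_qc(frags: pd.DataFrame, tss: pd.DataFrame | None = None,
             peaks: pd.DataFrame | None = None,
             mask: pd.DataFrame | None = None,
             mito_contig: str = DEFAULT_MITO, tss_window_bp: int = 2000,
             ) -> pd.DataFrame:
    """Assemble the per-pixel QC table (one row per pixel barcode).

    ``mask`` is the pixel-metadata CSV table indexed by canonical id with
    on_tissue and optionally nucleus_count columns; pixels absent from the
    fragments file get zero counts.
    """
    out = unique_per_pixel(frags, mito_contig)
    if tss is not None and not tss.empty:
        out["tss_fraction"] = tss_fraction(frags, tss, tss_window_bp,
                                           mito_contig).reindex(out.index).fillna(0.0)
        enr = tss_enrichment(frags, tss, mito_contig=mito_contig)
        out["tss_enrichment"] = enr["tss_enrichment"].reindex(out.index)
        out["tss_enrichment_flagged"] = enr["flagged"].reindex(out.index)
    if peaks is not None and not peaks.empty:
        out["frip"] = frip(frags, peaks, mito_contig).reindex(out.index).fillna(0.0)
    if mask is not None:
        out = out.reindex(out.index.union(mask.index))
        for col in ("total_fragments", "mito_fragments",
                    "unique_nuclear_fragments"):
            out[col] = out[col].fillna(0).astype(int)
        out["empty"] = out["total_fragments"] == 0
        out["on_tissue"] = mask["on_tissue"].reindex(out.index).fillna(False).astype(bool)
        if "nucleus_count" in mask:
            out["nucleus_count"] = mask["nucleus_count"].reindex(out.index)
    out.index.name = "barcode"
    return out


# ---------------------------------------------------------------------------
# naive peak caller (deterministic substitute for a model-based caller)
# ---------------------------------------------------------------------------

def call_peaks_naive(frags: pd.DataFrame, contig_sizes: Mapping[str, int],
                     threshold: float, min_width: int = 100,
                     smooth_bp: int = 150, mito_contig: str = DEFAULT_MITO,
                     ) -> pd.DataFrame:
    """Call peaks as runs of smoothed pooled insertion coverage above threshold.

    Runs must satisfy coverage >= threshold and > 0 (so threshold 0 yields the
    covered regions, not whole contigs) and be at least ``min_width`` wide.
    Fully deterministic.
    """
    ins = insertions(frags[frags["contig"] != mito_contig])
    rows = []
    k = 0
    for contig, size in contig_sizes.items():
        if contig == mito_contig:
            continue
        sub = ins[ins["contig"] == contig]
        cov = np.bincount(sub["pos"].to_numpy(dtype=np.int64),
                          minlength=size).astype(float)
        if smooth_bp > 1:
            cov = ndimage.uniform_filter1d(cov, size=smooth_bp, mode="constant")
        above = (cov >= threshold) & (cov > 0)
        edges = np.flatnonzero(np.diff(np.r_[False, above, False]))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_width:
                k += 1
                rows.append((contig, int(s), int(e), f"peak_{k}"))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])
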