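"""Synthetic spatial ATAC-seq data with full ground truth.

Generates a random genome with TSSs, peaks and gene bodies; a barcoded pixel
grid with region-structured accessibility (band or gradient layouts, an
off-tissue ring, imaging nucleus counts); per-pixel Tn5 fragments drawn from
a mixture of peak, background, TSS-proximal and mitochondrial components
with a bimodal (subnucleosomal + nucleosomal) length distribution; and raw
barcoded read pairs with duplicates and substitution errors.  Every stage
records its truth so the production pipeline can be checked end to end.

The TSS-proximal component is parameterised by the target core-vs-flank
insertion enrichment ``tss_mult``: the fraction of fragments placed in TSS
cores is derived from the genome geometry so that the expected pooled TSS
enrichment score equals ``tss_mult``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .readdecode import (BarcodeWhitelist, ReadLayout, canonical_id,
                         make_layout, pixel_maps)

_COMP = ("background", "peak", "tss", "mito")
_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for the simulator (defaults are the tested conditions)."""

    seed: int = 0
    # grid / barcoding
    n_a: int = 50
    n_b: int = 50
    barcode_len: int = 8
    linker_len: int = 30
    whitelist_min_dist: int = 3
    # genome
    contig_sizes: dict = field(default_factory=lambda: {
        "chr1": 1_000_000, "chr2": 1_000_000})
    mito_contig: str = "chrM"
    mito_len: int = 16_000
    n_genes: int = 60
    n_peaks: int = 60
    gene_len: int = 4_000
    peak_width: int = 400
    peak_offset: int = 2_500      # peak start relative to its gene's TSS
    # depth / library
    depth: float = 100.0          # mean unique fragments per on-tissue pixel
    off_tissue_depth_ratio: float = 0.01
    dup_rate: float = 0.3
    error_rate: float = 0.005
    mito_fraction: float = 0.05
    read_len: int = 50
    # accessibility structure
    peak_weight: float = 0.6      # peak : background mixture among nuclear frags
    region_peak_purity: float = 0.85
    tss_mult: float = 10.0        # target core/flank insertion enrichment
    # fragment-length mixture: subnucleosomal + mono-nucleosomal
    length_weights: tuple = (0.6, 0.4)
    length_means: tuple = (60.0, 200.0)
    length_sds: tuple = (15.0, 25.0)
    length_range: tuple = (20, 600)
    # tissue
    off_margin: int = 2           # off-tissue ring width in pixels
    single_nucleus_rate: float = 0.2

    @property
    def genome_size(self) -> int:
        return sum(self.contig_sizes.values())

    @property
    def tss_component_fraction(self) -> float:
        """Fraction of nuclear fragments in TSS cores achieving tss_mult."""
        if self.tss_mult <= 1.0:
            return 0.0
        core_area = 101 * self.n_genes
        ratio = ((self.tss_mult - 1.0) * (1.0 - self.peak_weight)
                 * core_area / self.genome_size)
        return ratio / (1.0 + ratio)


# ---------------------------------------------------------------------------
# barcoding assets
# ---------------------------------------------------------------------------

def make_whitelist(n: int, length: int, min_dist: int,
                   rng: np.random.Generator, round: str) -> BarcodeWhitelist:
    """Random barcodes with guaranteed minimum pairwise Hamming distance."""
    entries: list[np.ndarray] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    tries = 0
    while len(entries) < n:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("cannot build whitelist at requested distance")
        cand = rng.choice(bases, size=length)
        if all(int((cand != e).sum()) >= min_dist for e in entries):
            entries.append(cand)
    seqs = tuple(e.tobytes().decode("ascii") for e in entries)
    return BarcodeWhitelist(round=round, entries=seqs)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                      size=length).tobytes().decode("ascii")


def default_assets(config: SimConfig
                   ) -> tuple[ReadLayout, BarcodeWhitelist, BarcodeWhitelist]:
    """Deterministic layout + whitelists for a configuration seed."""
    rng = np.random.default_rng([101, config.seed])
    linker1 = _random_seq(rng, config.linker_len)
    linker2 = _random_seq(rng, config.linker_len)
    wl_a = make_whitelist(config.n_a, config.barcode_len,
                          config.whitelist_min_dist, rng, "A")
    wl_b = make_whitelist(config.n_b, config.barcode_len,
                          config.whitelist_min_dist, rng, "B")
    return make_layout(config.barcode_len, linker1, linker2), wl_a, wl_b


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    contigs: dict[str, str]          # name -> sequence (mito included)
    tss: pd.DataFrame                # contig, start(=TSS position), end, name, score, strand
    peaks: pd.DataFrame              # contig, start, end, name
    genes: pd.DataFrame              # contig, start, end, name, score, strand
    mito_contig: str

    @property
    def contig_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.contigs.items()}

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_beds(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        self.tss.to_csv(out / "tss.bed", sep="\t", header=False, index=False)
        self.peaks.to_csv(out / "peaks.bed", sep="\t", header=False, index=False)
        self.genes.to_csv(out / "genes.bed", sep="\t", header=False, index=False)


def make_genome(config: SimConfig) -> SyntheticGenome:
    """Random genome with lattice-placed genes/TSSs and non-overlapping peaks.

    Each gene's matched peak sits ``peak_offset`` bp downstream of its TSS,
    inside the gene body but outside the TSS QC windows, so peak-driven
    signal does not leak into TSS enrichment.
    """
    for size in config.contig_sizes.values():
        if size < 10_000:
            raise ValueError("contigs must be >= 10 kb")
    rng = np.random.default_rng([202, config.seed])
    contigs = {name: _random_seq(rng, size)
               for name, size in config.contig_sizes.items()}
    contigs[config.mito_contig] = _random_seq(rng, config.mito_len)
    names = list(config.contig_sizes)
    n_slots = max(config.n_genes, config.n_peaks)
    per = -(-n_slots // len(names))
    edge = 20_000
    gene_rows, tss_rows, peak_rows = [], [], []
    slot = 0
    for cname in names:
        size = config.contig_sizes[cname]
        pitch = (size - 2 * edge) // per
        if pitch < config.gene_len + config.peak_offset + config.peak_width + 5000:
            raise ValueError("contig too short for requested feature count")
        for i in range(per):
            if slot >= n_slots:
                break
            strand = "+" if slot % 2 == 0 else "-"
            anchor = edge + i * pitch
            if strand == "+":
                tss = anchor
                g_start, g_end = tss, tss + config.gene_len
                p_start = tss + config.peak_offset
            else:
                tss = anchor + config.gene_len
                g_start, g_end = tss - config.gene_len + 1, tss + 1
                p_start = tss - config.peak_offset - config.peak_width
            if slot < config.n_genes:
                gname = f"gene_{slot + 1}"
                gene_rows.append((cname, g_start, g_end, gname, 0, strand))
                tss_rows.append((cname, tss, tss + 1, gname, 0, strand))
            if slot < config.n_peaks:
                peak_rows.append((cname, p_start, p_start + config.peak_width,
                                  f"peak_{slot + 1}"))
            slot += 1
    return SyntheticGenome(
        contigs=contigs,
        tss=pd.DataFrame(tss_rows, columns=["contig", "start", "end", "name",
                                            "score", "strand"]),
        peaks=pd.DataFrame(peak_rows, columns=["contig", "start", "end", "name"]),
        genes=pd.DataFrame(gene_rows, columns=["contig", "start", "end", "name",
                                               "score", "strand"]),
        mito_contig=config.mito_contig,
    )


# ---------------------------------------------------------------------------
# tissue
# ---------------------------------------------------------------------------

@dataclass
class TissueGroundTruth:
    pixels: pd.DataFrame             # index canonical_id
    region_weights: dict[int, np.ndarray]
    layout: str
    gradient_anchors: tuple[np.ndarray, np.ndarray] | None = None

    def mask_table(self) -> pd.DataFrame:
        cols = ["row", "col", "on_tissue", "nucleus_count"]
        return self.pixels[cols].copy()

    def write_mask_csv(self, path: str | Path) -> None:
        self.mask_table().to_csv(path, index_label="canonical_id")

    def pixel_weights(self, cid: str) -> np.ndarray:
        """Per-pixel accessible-peak weight vector (sums to 1)."""
        row = self.pixels.loc[cid]
        if self.layout == "gradient":
            w0, w1 = self.gradient_anchors
            g = row["gradient"]
            return (1 - g) * w0 + g * w1
        return self.region_weights[int(row["region"])]


def _purity_weights(n_peaks: int, own: np.ndarray, purity: float) -> np.ndarray:
    w = np.full(n_peaks, 0.0)
    others = np.setdiff1d(np.arange(n_peaks), own)
    w[own] = purity / len(own)
    if len(others):
        w[others] = (1 - purity) / len(others)
    else:
        w[own] = 1.0 / len(own)
    return w


def make_tissue(config: SimConfig, layout: Literal["bands", "gradient"] = "bands",
                n_regions: int = 3) -> TissueGroundTruth:
    """Pixel grid with region labels, on-tissue mask and nucleus counts.

    ``bands``: vertical bands of equal width, one accessibility profile each.
    ``gradient``: peak weights interpolate smoothly along columns between two
    anchor profiles; region labels are the ``n_regions`` column bands (used
    as an ordered trajectory backbone).
    """
    if n_regions < 1 or n_regions > config.n_b:
        raise ValueError("invalid region count")
    rng = np.random.default_rng([303, config.seed])
    rows = []
    for a in range(1, config.n_a + 1):
        for b in range(1, config.n_b + 1):
            r, c = a - 1, b - 1
            on = (config.off_margin <= r < config.n_a - config.off_margin
                  and config.off_margin <= c < config.n_b - config.off_margin)
            region = min(c * n_regions // config.n_b, n_regions - 1)
            grad = c / (config.n_b - 1) if config.n_b > 1 else 0.0
            if on:
                if rng.random() < config.single_nucleus_rate:
                    nuc = 1
                else:
                    nuc = int(rng.poisson(2.0))
                    if nuc == 1:
                        nuc = 2
            else:
                nuc = 0
            depth = config.depth if on else config.depth * config.off_tissue_depth_ratio
            rows.append((canonical_id(a, b), a, b, r, c, region, on, nuc,
                         grad, depth))
    pixels = pd.DataFrame(rows, columns=[
        "canonical_id", "a_index", "b_index", "row", "col", "region",
        "on_tissue", "nucleus_count", "gradient", "depth"]).set_index("canonical_id")
    region_sizes = pixels.groupby("region").size()
    if (region_sizes == 0).any() or len(region_sizes) != n_regions:
        raise ValueError("a region received zero pixels")
    peak_region = np.arange(config.n_peaks) % n_regions
    weights = {r: _purity_weights(config.n_peaks,
                                  np.flatnonzero(peak_region == r),
                                  config.region_peak_purity)
               for r in range(n_regions)}
    anchors = None
    if layout == "gradient":
        half = config.n_peaks // 2
        w0 = _purity_weights(config.n_peaks, np.arange(half),
                             config.region_peak_purity)
        w1 = _purity_weights(config.n_peaks, np.arange(half, config.n_peaks),
                             config.region_peak_purity)
        anchors = (w0, w1)
    return TissueGroundTruth(pixels=pixels, region_weights=weights,
                             layout=layout, gradient_anchors=anchors)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def _draw_lengths(config: SimConfig, n: int, rng: np.random.Generator
                  ) -> np.ndarray:
    comp = rng.random(n) >= config.length_weights[0]
    means = np.where(comp, config.length_means[1], config.length_means[0])
    sds = np.where(comp, config.length_sds[1], config.length_sds[0])
    lens = np.rint(rng.normal(means, sds)).astype(np.int64)
    return np.clip(lens, *config.length_range)


def simulate_fragments(genome: SyntheticGenome, tissue: TissueGroundTruth,
                       config: SimConfig, seed: int | None = None,
                       min_per_pixel: int = 0) -> pd.DataFrame:
    """Draw the ground-truth unique fragment set per pixel.

    Returns a fragments table (contig, start, end, barcode=canonical id,
    dup_count=1) with provenance columns ``component`` and ``peak_id``.
    """
    rng = np.random.default_rng([404, config.seed if seed is None else seed])
    cids = tissue.pixels.index.to_numpy()
    depths = tissue.pixels["depth"].to_numpy()
    n_per = rng.poisson(depths)
    if min_per_pixel:
        n_per = np.maximum(n_per, min_per_pixel)
    N = int(n_per.sum())
    pix = np.repeat(np.arange(len(cids)), n_per)
    f_tss = config.tss_component_fraction
    u = rng.random(N)
    t_mito = config.mito_fraction
    t_tss = t_mito + (1 - t_mito) * f_tss
    t_peak = t_tss + (1 - t_mito) * (1 - f_tss) * config.peak_weight
    comp = np.full(N, 0, dtype=np.int8)        # background
    comp[u < t_peak] = 1                       # peak
    comp[u < t_tss] = 2                        # tss
    comp[u < t_mito] = 3                       # mito
    lens = _draw_lengths(config, N, rng)
    contig_arr = np.empty(N, dtype=object)
    start_arr = np.zeros(N, dtype=np.int64)
    peak_id = np.full(N, -1, dtype=np.int64)
    pad = 10  # keep pre-shift read coordinates inside the contig
    # mitochondrial
    m = np.flatnonzero(comp == 3)
    if m.size:
        contig_arr[m] = genome.mito_contig
        lens[m] = np.minimum(lens[m], config.mito_len - 2 * pad)
        start_arr[m] = rng.integers(pad, config.mito_len - lens[m] - pad + 1)
    # uniform background over nuclear contigs, weighted by length
    names = list(config.contig_sizes)
    sizes = np.array([config.contig_sizes[c] for c in names], dtype=float)
    bg = np.flatnonzero(comp == 0)
    if bg.size:
        ci = rng.choice(len(names), size=bg.size, p=sizes / sizes.sum())
        contig_arr[bg] = np.array(names, dtype=object)[ci]
        csz = sizes.astype(np.int64)[ci]
        start_arr[bg] = rng.integers(pad, csz - lens[bg] - pad + 1)
    # TSS-core component: both insertions within TSS +/- 50 bp
    ts = np.flatnonzero(comp == 2)
    if ts.size:
        lo_len = min(config.length_range[0], 80)
        hi_len = min(80, config.length_range[1])
        lens[ts] = rng.integers(lo_len, hi_len + 1, size=ts.size)
        which = rng.integers(0, len(genome.tss), size=ts.size)
        tpos = genome.tss["start"].to_numpy()[which]
        contig_arr[ts] = genome.tss["contig"].to_numpy(dtype=object)[which]
        lo = tpos - 50
        hi = tpos + 51 - lens[ts]
        start_arr[ts] = lo + (rng.random(ts.size) * (hi - lo)).astype(np.int64)
    # peak component: peak chosen by the pixel's weight vector
    pk = np.flatnonzero(comp == 1)
    if pk.size:
        pk_pix = pix[pk]
        pstart = genome.peaks["start"].to_numpy()
        pend = genome.peaks["end"].to_numpy()
        pcontig = genome.peaks["contig"].to_numpy(dtype=object)
        for pi in np.unique(pk_pix):
            sel = pk[pk_pix == pi]
            w = tissue.pixel_weights(cids[pi])
            choice = rng.choice(config.n_peaks, size=sel.size, p=w)
            peak_id[sel] = choice
            contig_arr[sel] = pcontig[choice]
            lo = pstart[choice]
            hi = np.maximum(pend[choice] - lens[sel], lo + 1)
            start_arr[sel] = lo + (rng.random(sel.size) * (hi - lo)).astype(np.int64)
    df = pd.DataFrame({
        "contig": contig_arr,
        "start": start_arr,
        "end": start_arr + lens,
        "barcode": cids[pix],
        "dup_count": 1,
        "component": pd.Categorical.from_codes(comp, list(_COMP)),
        "peak_id": peak_id,
    })
    df = (df.drop_duplicates(["contig", "start", "end", "barcode"])
          .sort_values(["contig", "start", "end", "barcode"], kind="mergesort")
          .reset_index(drop=True))
    return df


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def fragments_to_reads(truth_frags: pd.DataFrame, genome: SyntheticGenome,
                       layout: ReadLayout, wl_a: BarcodeWhitelist,
                       wl_b: BarcodeWhitelist, config: SimConfig,
                       r1_path: str | Path, r2_path: str | Path,
                       seed: int | None = None) -> pd.DataFrame:
    """Emit the barcoded FASTQ pair plus a per-read truth table.

    Read 1 = [barcode B][linker 2][barcode A][linker 1][genomic]; read 2 is
    the opposite-end genomic mate.  Each unique fragment yields a geometric
    number of copies (mean 1/(1 - dup_rate)); substitution errors hit every
    base at ``error_rate``.
    """
    rng = np.random.default_rng([505, config.seed if seed is None else seed])
    _, id2seq = pixel_maps(wl_a, wl_b)
    copies = rng.geometric(1.0 - config.dup_rate, size=len(truth_frags))
    rows = []
    serial = 0
    bases = "ACGT"
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for (frag, k) in zip(truth_frags.itertuples(index=False), copies):
            combined = id2seq[frag.barcode]
            bseq = combined[wl_a.length:]
            aseq = combined[:wl_a.length]
            fseq = genome.contigs[frag.contig][frag.start:frag.end]
            rc = revcomp(fseq)
            for copy_i in range(int(k)):
                serial += 1
                rid = f"sim{serial:08d}"
                r1_plus = bool(rng.random() < 0.5)
                g1 = (fseq if r1_plus else rc)[:config.read_len]
                g2 = (rc if r1_plus else fseq)[:config.read_len]
                truncated = len(fseq) < config.read_len
                s1 = bseq + layout.linker2_seq + aseq + layout.linker1_seq + g1
                s2 = g2
                if config.error_rate > 0:
                    s1 = _mutate(s1, rng, config.error_rate, bases)
                    s2 = _mutate(s2, rng, config.error_rate, bases)
                f1.write(f"@{rid}\n{s1}\n+\n{'I' * len(s1)}\n")
                f2.write(f"@{rid}\n{s2}\n+\n{'I' * len(s2)}\n")
                rows.append((rid, frag.contig, frag.start, frag.end,
                             combined, frag.barcode, r1_plus, copy_i > 0,
                             truncated))
    return pd.DataFrame(rows, columns=[
        "read_id", "contig", "start", "end", "barcode", "canonical_id",
        "r1_is_plus", "is_duplicate", "truncated"])


def _mutate(seq: str, rng: np.random.Generator, rate: float, bases: str) -> str:
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    s = list(seq)
    for p in pos:
        alts = bases.replace(s[p], "") or bases
        s[p] = alts[rng.integers(len(alts))]
    return "".join(s)
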