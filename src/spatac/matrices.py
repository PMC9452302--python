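"""Pixels x genomic-bin and pixels x gene accessibility matrices.

The tile matrix counts Tn5 insertions (two per fragment: start and end-1) in
fixed-width genomic bins (default 5 kb) that partition every nuclear contig;
the last bin of each contig is truncated.  Gene scores are distance-weighted
insertion sums around each gene: weight 1 inside the gene body extended 5 kb
upstream, exp(-d / 5000) for insertions up to 100 kb away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .qc import DEFAULT_MITO, insertions
from .readdecode import parse_canonical_id


# ---------------------------------------------------------------------------
# tissue mask
# ---------------------------------------------------------------------------

@dataclass
class TissueMask:
    """On-tissue pixel subset from the imaging metadata CSV."""

    table: pd.DataFrame  # index canonical_id; columns row, col, on_tissue, nucleus_count

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate pixel ids in mask")
        for cid in self.table.index:
            a, b = parse_canonical_id(cid)
            if a < 1 or b < 1:
                raise ValueError(f"invalid pixel id {cid!r}")

    @property
    def on_ids(self) -> set[str]:
        return set(self.table.index[self.table["on_tissue"].astype(bool)])

    @classmethod
    def from_csv(cls, path: str | Path) -> "TissueMask":
        df = pd.read_csv(path).set_index("canonical_id")
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="canonical_id")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Sparse pixels x features matrix with named rows and feature table."""

    X: sparse.csr_matrix
    barcodes: list[str]
    features: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.barcodes), len(self.features)):
            raise ValueError("matrix shape does not match sidecars")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def subset_rows(self, ids: list[str]) -> "FeatureMatrix":
        pos = {b: i for i, b in enumerate(self.barcodes)}
        idx = [pos[b] for b in ids]
        return replace(self, X=self.X[idx], barcodes=list(ids))


class TileMatrix(FeatureMatrix):
    """features columns: contig, start, end (fixed-width genomic bins)."""


class GeneScoreMatrix(FeatureMatrix):
    """features columns: name, contig, start, end, strand."""


def tile_index(contig_sizes: Mapping[str, int], tile_bp: int,
               mito_contig: str = DEFAULT_MITO) -> pd.DataFrame:
    """Fixed-width bins partitioning each nuclear contig (last bin truncated)."""
    rows = []
    for contig, size in contig_sizes.items():
        if contig == mito_contig:
            continue
        for start in range(0, size, tile_bp):
            rows.append((contig, start, min(start + tile_bp, size)))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def build_tile_matrix(frags: pd.DataFrame, contig_sizes: Mapping[str, int],
                      tile_bp: int = 5000, mito_contig: str = DEFAULT_MITO,
                      ) -> TileMatrix:
    """Count the two Tn5 insertions of every nuclear fragment into 5-kb tiles."""
    tiles = tile_index(contig_sizes, tile_bp, mito_contig)
    offsets = {}
    acc = 0
    for contig, size in contig_sizes.items():
        if contig == mito_contig:
            continue
        offsets[contig] = acc
        acc += -(-size // tile_bp)
    nuc = frags[frags["contig"] != mito_contig]
    bad = ~nuc["contig"].isin(offsets)
    if bad.any():
        raise ValueError(f"fragment contig {nuc.loc[bad, 'contig'].iloc[0]!r} "
                         "missing from contig sizes")
    for contig, sub in nuc.groupby("contig"):
        if (sub["end"] > contig_sizes[contig]).any():
            raise ValueError(f"fragment beyond end of {contig}")
    ins = insertions(nuc)
    barcodes = sorted(nuc["barcode"].unique())
    bc_codes = pd.Categorical(ins["barcode"], categories=barcodes).codes
    col = (ins["pos"].to_numpy() // tile_bp
           + ins["contig"].map(offsets).to_numpy())
    X = sparse.coo_matrix(
        (np.ones(len(ins), dtype=np.int64), (bc_codes, col)),
        shape=(len(barcodes), len(tiles))).tocsr()
    return TileMatrix(X, barcodes, tiles,
                      meta={"tile_bp": tile_bp, "rule": "insertions",
                            "mito_contig": mito_contig})


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Gene table (name, contig, start, end, strand) from BED6 or GTF."""
    path = str(path)
    if path.endswith((".gtf", ".gtf.gz")):
        raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                          names=["contig", "source", "feature", "start", "end",
                                 "score", "strand", "frame", "attribute"])
        genes = raw[raw["feature"] == "gene"].copy()
        genes["name"] = genes["attribute"].str.extract(r'gene_id "([^"]+)"')
        genes["start"] = genes["start"] - 1  # GTF is 1-based inclusive
        return genes[["name", "contig", "start", "end", "strand"]].reset_index(drop=True)
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["contig", "start", "end", "name", "score", "strand"])
    return df[["name", "contig", "start", "end", "strand"]]


def build_gene_scores(frags: pd.DataFrame, genes: pd.DataFrame,
                      decay_bp: int = 5000, max_distance_bp: int = 100_000,
                      upstream_bp: int = 5000, normalize_to: float | None = None,
                      mito_contig: str = DEFAULT_MITO) -> GeneScoreMatrix:
    """Distance-weighted insertion sums around each gene.

    w = 1 inside the gene body extended ``upstream_bp`` upstream of the TSS,
    exp(-d / decay_bp) for insertions at distance d <= max_distance_bp from
    the extended body.  With ``normalize_to`` set, every pixel's scores are
    scaled so its total insertion count maps to that constant.
    """
    nuc = frags[frags["contig"] != mito_contig]
    unknown = set(genes["contig"]) - set(nuc["contig"].unique())
    if unknown:
        import warnings
        warnings.warn(f"genes on contigs without fragments skipped: {sorted(unknown)}")
    ins = (insertions(nuc)
           .sort_values(["contig", "pos"], kind="mergesort")
           .reset_index(drop=True))
    barcodes = sorted(nuc["barcode"].unique())
    sorted_codes = pd.Categorical(ins["barcode"], categories=barcodes).codes
    scores = np.zeros((len(barcodes), len(genes)))
    pos_by_contig = {}
    for c, sub in ins.groupby("contig"):
        pos_by_contig[c] = (sub["pos"].to_numpy(), sorted_codes[sub.index.to_numpy()])
    for j, g in enumerate(genes.itertuples(index=False)):
        if g.contig not in pos_by_contig:
            continue
        pos, codes = pos_by_contig[g.contig]
        ext_start = g.start - (upstream_bp if g.strand == "+" else 0)
        ext_end = g.end + (upstream_bp if g.strand == "-" else 0)
        lo = np.searchsorted(pos, ext_start - max_distance_bp)
        hi = np.searchsorted(pos, ext_end + max_distance_bp)
        if lo == hi:
            continue
        p = pos[lo:hi]
        d = np.maximum.reduce([ext_start - p, p - (ext_end - 1),
                               np.zeros(len(p), dtype=np.int64)])
        w = np.where(d == 0, 1.0, np.exp(-d / decay_bp))
        w[d > max_distance_bp] = 0.0
        np.add.at(scores[:, j], codes[lo:hi], w)
    if normalize_to is not None:
        depth = np.bincount(sorted_codes, minlength=len(barcodes)).astype(float)
        depth[depth == 0] = 1.0
        scores = scores * (normalize_to / depth)[:, None]
    feats = genes[["name", "contig", "start", "end", "strand"]].reset_index(drop=True)
    return GeneScoreMatrix(sparse.csr_matrix(scores), barcodes, feats,
                           meta={"decay_bp": decay_bp,
                                 "max_distance_bp": max_distance_bp,
                                 "upstream_bp": upstream_bp,
                                 "normalize_to": normalize_to})


def apply_mask(matrix: FeatureMatrix, mask: TissueMask
               ) -> tuple[FeatureMatrix, int]:
    """Restrict rows to on-tissue pixels; returns (matrix, n_removed)."""
    keep = [b for b in matrix.barcodes if b in mask.on_ids]
    if not keep:
        raise ValueError("mask does not intersect matrix pixels")
    return matrix.subset_rows(keep), len(matrix.barcodes) - len(keep)


# ---------------------------------------------------------------------------
# sparse triplet export / import
# ---------------------------------------------------------------------------

def export_matrix(matrix: FeatureMatrix, prefix: str | Path) -> None:
    """Write triplets TSV + row/feature sidecars + meta JSON."""
    prefix = str(prefix)
    coo = matrix.X.tocoo()
    pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
        f"{prefix}.triplets.tsv", sep="\t", index=False)
    Path(f"{prefix}.rows.txt").write_text("\n".join(matrix.barcodes) + "\n")
    matrix.features.to_csv(f"{prefix}.features.tsv", sep="\t", index=False)
    Path(f"{prefix}.meta.json").write_text(json.dumps(
        {"shape": list(matrix.shape), "class": type(matrix).__name__,
         **matrix.meta}))


def import_matrix(prefix: str | Path) -> FeatureMatrix:
    prefix = str(prefix)
    meta = json.loads(Path(f"{prefix}.meta.json").read_text())
    barcodes = Path(f"{prefix}.rows.txt").read_text().splitlines()
    features = pd.read_csv(f"{prefix}.features.tsv", sep="\t")
    trip = pd.read_csv(f"{prefix}.triplets.tsv", sep="\t")
    n, m = meta["shape"]
    if len(barcodes) != n or len(features) != m:
        raise ValueError("sidecar dimensions disagree with meta")
    for col, bound in (("row", n), ("col", m)):
        vals = pd.to_numeric(trip[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals >= bound)
        if bad.any():
            raise ValueError(
                f"corrupt triplet at line {int(bad.idxmax()) + 2}: bad {col}")
        trip[col] = vals.astype(int)
    X = sparse.coo_matrix((trip["value"], (trip["row"], trip["col"])),
                          shape=(n, m)).tocsr()
    cls = {"TileMatrix": TileMatrix, "GeneScoreMatrix": GeneScoreMatrix
           }.get(meta.pop("class", ""), FeatureMatrix)
    meta.pop("shape", None)
    return cls(X, barcodes, features, meta=meta)
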