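# spatac

Spatial ATAC-seq maps chromatin accessibility across a tissue section by
deterministic microfluidic barcoding: Tn5 transposition in situ, then two
orthogonal rounds of barcode ligation (A1–A50 across one axis, B1–B50 across
the other), so each read carries a spatial identity — a *pixel*, the
intersection of one barcode A channel and one barcode B channel on a 50 × 50
grid (2,500 pixels).

`spatac` is the computational side of that assay, for people who have (or
want to prototype against) such libraries:

- **readdecode** — parse read 1 (`[barcode B][linker 2][barcode A]
  [linker 1][genomic]`), filter on the two constant linkers by positional
  Hamming distance, error-correct both barcodes against their whitelists,
  and emit pixel-tagged, aligner-ready reads. No read is silently dropped:
  each lands in the assigned or rejected stream with a typed status.
- **fragments** — turn aligned proper pairs into Tn5-corrected fragments
  (`[plus 5′ + 4, minus 5′ + 1 − 5)`), deduplicate per
  (contig, start, end, pixel), and read/write the BED-like 5-column
  fragments file.
- **qc** — per-pixel unique nuclear fragments, TSS fraction (± 2 kb), TSS
  enrichment score (± 50 bp core over 1,901–2,000 bp flanks), FRiP,
  mitochondrial fraction, insert-size histogram, on/off-tissue rank-sum
  comparison, single-nucleus pixel selection, and a deterministic
  threshold-run peak caller for self-contained testing.
- **matrices** — pixels × 5-kb-tile insertion-count matrix, exponential-decay
  gene accessibility scores, tissue masking, sparse triplet I/O.
- **analysis** — iterative LSI (TF-IDF + truncated SVD, depth-correlated
  component removal, cluster-guided feature re-selection), SNN/Leiden
  clustering, seeded UMAP, Wilcoxon + Benjamini–Hochberg marker detection,
  and backbone pseudotime with feature-vs-pseudotime curves.
- **simulate** — a fully seeded generator of synthetic genomes, tissue
  layouts (bands / gradient, off-tissue ring, nucleus counts), fragments and
  raw barcoded reads with complete ground truth, so the entire pipeline is
  testable without any downloads.

## Worked example

Simulate a default-strength run (50 × 50 grid, three tissue bands, ~100
unique fragments per on-tissue pixel, 0.5% per-base sequencing error), then
run the full production chain on it:

```python
import numpy as np
import spatac
from spatac import fragments as frg, qc, matrices as mtx, analysis as an
from spatac.simulate import (SimConfig, default_assets, make_genome,
                             make_tissue, simulate_fragments, fragments_to_reads)

config = SimConfig(seed=11)                       # 50x50 grid, 3 tissue bands
layout, wl_a, wl_b = default_assets(config)
genome = make_genome(config)
tissue = make_tissue(config, "bands", n_regions=3)
truth = simulate_fragments(genome, tissue, config)
reads = fragments_to_reads(truth, genome, layout, wl_a, wl_b, config,
                           "r1.fastq", "r2.fastq")
report, assigned = spatac.decode_run("r1.fastq", "r2.fastq", "run",
                                     layout, wl_a, wl_b,
                                     collect_assignments=True)

frg.truth_align(reads, genome.contig_sizes, "aln.sam",
                read_len=config.read_len, barcodes=assigned)
raw, _ = frg.sam_to_fragments("aln.sam")
seq2id, _ = spatac.pixel_maps(wl_a, wl_b)
frags = frg.canonicalize_barcodes(frg.deduplicate(raw), seq2id)

table = qc.pixel_qc(frags, genome.tss, genome.peaks, tissue.mask_table())
tm = mtx.build_tile_matrix(frags, genome.contig_sizes)
tm, removed = mtx.apply_mask(tm, mtx.TissueMask(tissue.mask_table()))
emb = an.iterative_lsi(tm, seed=11)
labels = an.cluster_graph(emb, resolution=0.2, seed=11)
```

which prints (exact numbers for this seed):

```
assigned 302397/302825 reads (99.86%), 2359 pixels
212079 unique fragments from 302397 pairs
median unique nuclear fragments (on tissue): 95
median TSS fraction 0.059, median FRiP 0.600, median mito fraction 0.048
pooled TSS enrichment 10.20
3 clusters on 2116 on-tissue pixels, ARI vs planted regions 1.000
```

Reading the output: 99.86% of reads decode to a pixel despite the injected
sequencing errors (the remainder fail the linker filter or barcode
correction); deduplication recovers the ~0.7 unique/total ratio implied by
the 0.3 duplicate rate; on-tissue pixels carry the configured ~100 unique
nuclear fragments with QC fractions matching the simulator's mixture
weights (FRiP ≈ 0.6 peak-component weight, mito ≈ 0.05); the pooled TSS
enrichment recovers the planted 10× core-to-flank insertion rate; and
clustering the LSI embedding reproduces the three planted tissue bands
exactly.

The same steps are available from the shell:
`spatac simulate | decode | fragments | qc | matrix | analyze` (see
`spatac --help`).

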