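# Methods

This note documents the models and procedures implemented in `spatac`, the
parameter choices that matter, what the simulator does and does not emulate,
and the numerical conventions used throughout.

## Read decoding

Read 1 of a spatially barcoded library is a fixed-length construct,
`[barcode B (8)][linker 2 (30)][barcode A (8)][linker 1 (30)][genomic]`,
produced by two successive ligation rounds. Because the ligation chemistry
yields fixed-length products, segments are located by offset, not alignment:

- **Linker filter.** Each constant linker is compared at its fixed offset by
  Hamming distance; a read passes if both linkers have at most
  `max_linker_mismatch` mismatches (default 3). `N` bases count as
  mismatches everywhere. No indel recovery is attempted — a truncated fixed
  region is unrecoverable by design.
- **Barcode correction.** Each observed barcode is matched against its
  round's whitelist within Hamming radius 1 (default). A tie at the minimum
  distance is rejected as ambiguous, never guessed. Whitelists report their
  minimum pairwise distance at load and warn when it is ≤ 2 × radius, the
  regime in which radius-level correction can be ambiguous.
- **Statuses.** Every read receives exactly one of `assigned`, `too_short`,
  `linker_fail`, `barcode_unmatched`, `barcode_ambiguous` (unmatched takes
  precedence over ambiguous when the two rounds disagree); assigned +
  rejected always equals input. The decoder is implemented twice — a scalar
  reference path and a vectorised batch engine — and the test suite holds
  both to exact agreement with an independent brute-force oracle.

The assigned stream carries the genomic portion of read 1, the untouched
genomic mate, and the 16-base `barcodeA + barcodeB` concatenation as a
`CB`-style cell barcode; the canonical grid identity `AxxByy` appears in the
decode report. Layouts are data (a YAML file), not code, because real
datasets must supply their own linker and barcode sequences.

## Fragments

Fragments use 0-based half-open (BED) coordinates. From an aligned proper
pair, the interval is `[plus-strand 5′ + 4, minus-strand 5′ + 1 − 5)`,
the standard correction for the 9-bp Tn5 target-site duplication; both
shifts are configurable since upstream pipelines differ in whether they
pre-apply them. Pairs failing MAPQ (default ≥ 30), properness, or barcode
presence are rejected with typed reasons. Duplicates are keyed on
(contig, start, end, pixel) — the assay has no UMIs — and `dup_count`
accumulates multiplicity, making deduplication idempotent and conserving
the accepted-pair count. The fragments file is a 5-column TSV
(contig, start, end, barcode, dup_count), gzip-aware, sorted by contig
order, start, end, barcode.

`truth_align` is the simulator-facing stand-in for an external aligner: it
emits perfect proper pairs whose 5′ ends sit 4/5 bp outside the true
(Tn5-corrected) fragment interval, so the production shift recovers truth
exactly. It can take a decoder's per-read assignments so that decoding
errors propagate realistically into downstream fragment files.

## QC metrics

All metrics are computed on unique fragments; insertions are the two Tn5
events per fragment (`start` and `end − 1`).

- **Unique nuclear fragments / mito fraction**: the mitochondrial contig
  (default `chrM`) is excluded from nuclear counts; the mito fraction is
  mito / total unique fragments per pixel.
- **TSS fraction**: fraction of nuclear fragments overlapping TSS ± 2,000 bp
  by ≥ 1 bp. The window is configurable; ±2 kb is the common convention.
- **TSS enrichment**: mean per-base insertion depth in the ± 50 bp core
  around TSSs, aggregated over all TSSs, divided by the mean depth in the
  distal flanks 1,901–2,000 bp away on both sides, with a one-insertion
  pseudocount in the flank count. Pixels with zero flank coverage keep a
  pseudocount-backed score and are flagged. These windows follow standard
  single-cell ATAC practice; with the default symmetric windows TSS strand
  does not change the score. Under uniform insertions the score converges
  to 1 with depth.
- **FRiP**: fraction of unique nuclear fragments overlapping any peak by
  ≥ 1 bp (merged peak intervals, so overlapping peaks never double-count).
- **Insert sizes**: 1-bp histogram of unique fragment lengths.
- **On/off tissue**: two-sided Wilcoxon rank-sum on per-pixel nuclear
  depth; the result is a typed record that reports "undefined" rather than
  a p-value when the mask is one-sided. When many metrics are compared, BH
  adjustment should be applied across them (the marker machinery exposes
  it).
- **Naive peak caller**: maximal runs of smoothed (150-bp moving average)
  pooled insertion coverage that are ≥ threshold, strictly positive, and at
  least `min_width` wide. It is deterministic and exists so the pipeline is
  testable end to end without an external model-based caller; it is not a
  statistical peak model and should not be used for discovery on real data.

## Matrices

The **tile matrix** counts insertions (two per fragment) into fixed 5-kb
bins partitioning each nuclear contig (last bin truncated). Insertion
counting, rather than interval overlap, reflects that Tn5 insertions are
the assayed events; the rule is recorded in the matrix metadata. The column
sum therefore equals exactly twice the unique nuclear fragment count — a
conservation law the tests enforce.

The **gene score** is a deliberately simple, fully specified model: weight
1 for insertions inside the gene body extended 5 kb upstream of the TSS,
`exp(−d / 5000)` for insertions at distance `d` up to 100 kb from the
extended body, summed per pixel. Published gene-activity models are more
elaborate (neighbour-gene masking, per-gene scaling, imputation); those
refinements are intentionally omitted and all three parameters are
configurable. Per-pixel depth normalisation (to 10⁴) is off by default so
conservation properties stay exact.

Masking consumes the imaging-derived pixel metadata CSV
(canonical_id, row, col, on_tissue, nucleus_count) and restricts matrix
rows to on-tissue pixels. Matrices round-trip through a plain-text triplet
TSV plus row/feature sidecars, with corrupt lines reported by number.

## Iterative LSI, clustering, markers, pseudotime

The TF-IDF variant is pinned: `tf = count / pixel total`,
`idf = log(1 + N_pixels / (1 + n_pixels_with_feature))`,
`x = log1p(tf · idf · 10⁴)`, followed by truncated SVD (scipy `svds` with a
seeded start vector and a deterministic sign convention, so a fixed seed
gives bit-identical embeddings). Components whose scores correlate with
log depth at |r| > 0.75 are dropped — the standard guard against
sequencing-depth dominance. Iteration 1 uses the most accessible
`var_features` features; an interim Leiden clustering (resolution 0.2) then
defines pseudo-bulk profiles (per-cluster sums, normalised to 10⁴, log1p)
whose cross-cluster variance selects features for iteration 2. Defaults:
2 iterations, 25,000 variable features, 30 dimensions. Note that with an
uncentred TF-IDF the leading SVD component is the shared global-scale
direction; when depths are balanced it survives the depth filter, and
biological contrasts begin at the next component.

Clustering builds a shared-nearest-neighbour graph (cosine k-NN, k = 30,
Jaccard edge weights, weak edges below 1/15 pruned) and runs seeded Leiden
(RB-configuration modularity) at a caller-chosen resolution. Labels are
relabelled deterministically by cluster size, so permuting pixels permutes
labels but not the partition. UMAP uses n_neighbors = 30, cosine metric,
min_dist = 0.5, and a fixed random state.

Markers are per-cluster two-sided Wilcoxon rank-sum tests of each feature
(cluster vs the rest), BH-adjusted within cluster, with
`log2FC = log2((mean_in + 1) / (mean_out + 1))`. The two conventional
cutoffs are supported: log2FC ≥ 0.25 (gene-level features) and ≥ 0.1
(peak-level features), both at FDR ≤ 0.05. Clusters smaller than 3 pixels
are skipped.

Pseudotime takes an ordered backbone of cluster labels, computes their
centroids in LSI space, and projects every backbone pixel onto the segment
from its cluster's centroid to the next (the last cluster projects onto
the preceding segment), clamping to [0, 1] and rescaling the arc position
to [0, 100]. This piecewise-linear projection replaces spline fitting used
by heavier trajectory tools; it preserves the property that cluster mean
pseudotimes increase along the backbone, which is what downstream
feature-dynamics plots rely on. Feature dynamics use equal-occupancy
pseudotime bins and a centred 3-bin rolling mean.

## Simulator

The simulator defines the study conditions under which the pipeline is
validated. Defaults: a 50 × 50 grid with a 2-pixel off-tissue ring
(2,116 on-tissue pixels), ~100 unique fragments per on-tissue pixel
(Poisson), off-tissue depth at 1% of on-tissue, duplicate rate 0.3
(geometric copies per unique fragment, so unique/total ≈ 0.7), per-base
substitution error 0.005, mitochondrial fraction 0.05, and a fragment-length
mixture of 60% subnucleosomal N(60, 15²) + 40% mono-nucleosomal N(200, 25²)
truncated to [20, 600] bp, reproducing the characteristic bimodal insert
profile. The synthetic genome is two 1-Mb contigs plus a 16-kb
mitochondrial contig, with 60 genes (alternating strand), their TSSs, and
60 non-overlapping 400-bp peaks placed inside gene bodies 2.5 kb from the
TSS — outside both the TSS ± 2 kb QC window and the enrichment flanks, so
peak signal does not leak into TSS metrics. These sizes keep every stage
(including raw-read simulation and decoding) runnable in seconds to a
couple of minutes on one CPU while preserving all the structure the
methods operate on; real-tissue depths (tens of thousands of fragments per
pixel on mammalian genomes) scale the same code without change of logic.

Accessibility structure: each region of a band layout concentrates 85% of
its peak-component weight on its own third of the peaks; a gradient layout
interpolates per-pixel weights between two anchor profiles along columns,
providing a 1-D ground-truth coordinate for pseudotime validation.
Nuclear fragments are a mixture of peak (weight 0.6), uniform background,
and a TSS-core component whose fraction is derived from the genome
geometry so that the expected pooled TSS enrichment equals the configured
multiplier (default 10): with multiplier m, peak weight p and core area
`101 · n_TSS` in a genome of size G, the core-component fraction f solves
`f / (1 − f) = (m − 1)(1 − p) · 101 · n_TSS / G`. TSS-component fragments
place both insertions inside the ± 50 bp core (short,
nucleosome-free-region-like fragments), so the planted enrichment is exact
in expectation rather than approximate.

Reads are emitted with the full barcode/linker construct on read 1,
strand-randomised genomic ends, geometric duplicates and substitution
errors; a per-read truth table records pixel, fragment, duplicate status
and truncation. All stages draw from `numpy` Generators seeded from the
configuration seed, so identical seeds give byte-identical FASTQ, truth
tables and genomes.

What the simulator does **not** emulate: PCR/GC bias, chimeric reads,
indels, mappability structure, doublet nuclei mixing across pixels, or a
real genome's repeat content. Consequently, passing tests demonstrate the
correctness of the decoding/counting/statistical machinery under the
declared generative model — not robustness to alignment artefacts or
sequence-composition biases of real libraries, which enter upstream of
this package through the external aligner.

## Numerical conventions and degenerate inputs

- Coordinates 0-based half-open everywhere; interval overlap means ≥ 1 bp.
- Empty pixels appear in QC tables with zero counts and an `empty` flag;
  empty TSS or peak sets make the dependent metric an error, not a 0.
- Zero flank coverage flags, rather than discards, a pixel's TSS
  enrichment (pseudocount 1 insertion).
- SVD dimensionality is capped at min(shape) − 1; embeddings with no
  retained between-pixel variation are flagged degenerate and warned about.
- Ties in barcode correction reject the read; ties in sorting are resolved
  by stable sorts; cluster relabelling breaks ties by smallest member
  index.
- Seeds: every stochastic operation takes an explicit seed; derived
  generator streams use fixed small tags alongside the user seed.

## Known limitations

- The naive peak caller is a testing substitute, not a discovery tool.
- The gene-score model omits neighbour-gene masking, so closely spaced
  genes share nearby signal within the 100-kb window.
- Pseudotime assumes the backbone geometry is roughly piecewise linear in
  LSI space; strongly curved trajectories within a single cluster are
  compressed onto one segment.
- Linker matching tolerates substitutions only; reads with indels in the
  fixed region are rejected rather than rescued.
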