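"""Shared fixtures: a small error-free simulated run pushed through the
whole pipeline once per session."""

from __future__ import annotations

import pytest

import spatac
from spatac import fragments as frg
from spatac.simulate import (SimConfig, default_assets, fragments_to_reads,
                             make_genome, make_tissue, simulate_fragments)


def small_config(**overrides) -> SimConfig:
    base = dict(seed=7, n_a=8, n_b=8, off_margin=1, depth=50.0,
                error_rate=0.0,
                contig_sizes={"chr1": 200_000, "chr2": 200_000},
                n_genes=20, n_peaks=20)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim():
    """Small error-free simulation: genome, tissue, truth fragments, assets."""
    config = small_config()
    layout, wl_a, wl_b = default_assets(config)
    genome = make_genome(config)
    tissue = make_tissue(config, "bands", n_regions=3)
    truth = simulate_fragments(genome, tissue, config)
    return {"config": config, "layout": layout, "wl_a": wl_a, "wl_b": wl_b,
            "genome": genome, "tissue": tissue, "truth": truth}


@pytest.fixture(scope="session")
def pipeline(sim, tmp_path_factory):
    """The small simulation decoded, aligned and reduced to fragments."""
    d = tmp_path_factory.mktemp("pipeline")
    config, genome = sim["config"], sim["genome"]
    reads = fragments_to_reads(sim["truth"], genome, sim["layout"],
                               sim["wl_a"], sim["wl_b"], config,
                               d / "r1.fastq", d / "r2.fastq")
    report, assignments = spatac.decode_run(
        d / "r1.fastq", d / "r2.fastq", d / "out", sim["layout"],
        sim["wl_a"], sim["wl_b"], collect_assignments=True)
    frg.truth_align(reads, genome.contig_sizes, d / "aln.sam",
                    read_len=config.read_len, barcodes=assignments)
    raw, rejections = frg.sam_to_fragments(d / "aln.sam")
    seq2id, _ = spatac.pixel_maps(sim["wl_a"], sim["wl_b"])
    dedup = frg.canonicalize_barcodes(frg.deduplicate(raw), seq2id)
    return {**sim, "dir": d, "reads": reads, "report": report,
            "assignments": assignments, "raw": raw, "rejections": rejections,
            "frags": dedup}
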