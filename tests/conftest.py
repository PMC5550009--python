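"""Shared fixtures: one moderately sized synthetic dataset reused across
the suite, plus small helpers."""

from __future__ import annotations

import numpy as np
import pytest

from thermedit.io_alignment import Genome, GenomeIndex, align_reads
from thermedit.hyper_editing import (
    HyperParams,
    TransformedRealigner,
    collect_sites,
    detect_editing,
)
from thermedit.simulate import (
    SimConfig,
    generate_genome,
    plant_editing_clusters,
    simulate_reads,
)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(
        genome_length=200_000,
        n_clusters=40,
        sites_per_cluster=(4, 8),
        per_site_edit_rate={"T18": 0.6, "T29": 0.2},
        coverage=30,
        seq_error_rate=0.001,
        ir_fraction=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """Genome + planted truth + per-condition reads for the default regimes."""
    genome, genes = generate_genome(sim_config)
    truth = plant_editing_clusters(genome, sim_config)
    reads = {
        cond: simulate_reads(genome, truth, cond, sim_config)[0]
        for cond in sim_config.condition_labels
    }
    return dict(genome=genome, genes=genes, truth=truth, reads=reads)


@pytest.fixture(scope="session")
def aligned_dataset(sim_dataset, sim_config):
    """First-pass alignments and editing detection for both conditions."""
    genome = sim_dataset["genome"]
    params = HyperParams()
    index = GenomeIndex(genome, params.align.seed_len)
    realigner = TransformedRealigner(genome, params.align)
    out = {}
    for cond, reads in sim_dataset["reads"].items():
        res = align_reads(reads, genome, params.align, index)
        clusters, stats = detect_editing(res.unaligned, genome, params, realigner)
        sites, summary = collect_sites(clusters)
        out[cond] = dict(
            alignment=res, clusters=clusters, sites=sites, summary=summary,
            stats=stats,
        )
    out["realigner"] = realigner
    out["index"] = index
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
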