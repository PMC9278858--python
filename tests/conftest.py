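import numpy as np
import pytest

from polterm.coverage import CoverageTrack
from polterm.genome_annotation import (
    GeneModel,
    GenomeSequence,
    annotate_secondary_terminators,
    assign_primary_terminator,
    find_t_tracts,
)
from polterm.synthetic_data import (
    SimulationConfig,
    simulate_genome,
    simulate_transcription,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic two-condition simulation shared across tests."""
    config = SimulationConfig(
        seed=42,
        n_genes=16,
        initiations_per_gene=600.0,
        pause_site_rate=0.03,
        primary_len_choices=(4, 5, 6, 7),
        background_noise_rate=0.005,
    )
    sim = simulate_genome(config)
    wt = simulate_transcription(sim, config, "WT")
    mut = simulate_transcription(sim, config, "mutant")
    return {"config": config, "sim": sim, "WT": wt, "mutant": mut}


@pytest.fixture(scope="session")
def small_sim_annos(small_sim):
    sim = small_sim["sim"]
    tracts = find_t_tracts(sim.genome)
    annos = []
    for gene in sim.genes:
        anno = assign_primary_terminator(gene, tracts)
        annotate_secondary_terminators(anno, tracts)
        annos.append(anno)
    return annos


def make_track(values, chrom="chrT", strand="+", **kw):
    """Build a one-chromosome track from a python list/array."""
    return CoverageTrack(
        kw.pop("sample_id", "t"), strand,
        {chrom: np.asarray(values, dtype=float)}, **kw,
    )


@pytest.fixture
def constant_pair():
    plus = make_track(np.ones(2000), strand="+")
    minus = make_track(np.ones(2000), strand="-")
    return plus, minus


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genome(rng, length=10_000, gc=0.5, chrom="chrR"):
    p_at = (1 - gc) / 2
    p_gc = gc / 2
    seq = "".join(
        rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
    )
    return GenomeSequence({chrom: seq})


@pytest.fixture
def plus_gene():
    return GeneModel("g1", "chrT", 10, 100, "+")
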