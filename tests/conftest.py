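from types import SimpleNamespace

import pytest

from clipsplice.annotation import extract_introns
from clipsplice.samio import read_alignments
from clipsplice.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_genome,
    simulate_clip_reads,
    simulate_rnaseq_reads,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_genes=12, n_reads_per_library=4000)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_model(small_config, small_genome):
    return generate_annotation(small_config, small_genome)


@pytest.fixture(scope="session")
def small_introns(small_model, small_genome):
    return extract_introns(small_model, small_genome.chroms)


@pytest.fixture(scope="session")
def clip_dataset(tmp_path_factory, small_config, small_genome, small_model):
    outdir = tmp_path_factory.mktemp("clip")
    libs, truth = simulate_clip_reads(small_config, small_genome, small_model, outdir)
    reads = {l.lib_id: read_alignments(l.path) for l in libs}
    return SimpleNamespace(libs=libs, truth=truth, reads=reads, genome=small_genome)


@pytest.fixture(scope="session")
def rna_dataset(tmp_path_factory, small_config, small_genome, small_model):
    outdir = tmp_path_factory.mktemp("rna")
    libs, truth = simulate_rnaseq_reads(small_config, small_genome, small_model, outdir)
    reads = {l.lib_id: read_alignments(l.path) for l in libs}
    return SimpleNamespace(libs=libs, truth=truth, reads=reads, genome=small_genome)
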