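import numpy as np
import pytest

from circexon.config import RunConfig
from circexon.formats_io import Genome, index_alignments
from circexon.simulator import (
    INSERT_PRESETS,
    SimParams,
    emit_reads,
    make_genome,
    simulate_circ_transcripts,
)


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def small_library():
    """One small simulated library shared by unit tests (seeded)."""
    rng = np.random.default_rng(1234)
    genome, genes = make_genome(rng, n_genes=25, n_long_genes=4)
    params = SimParams(
        n_circ=25,
        depth=30.0,
        insert=INSERT_PRESETS["mix280_370"],
        es_fraction=0.4,
        psi=0.5,
        linear_fold=10.0,
    )
    circles = simulate_circ_transcripts(genes, params, rng)
    result = emit_reads(circles, genes, genome, params, rng)
    return result


@pytest.fixture(scope="session")
def small_alignments(small_library):
    return index_alignments(small_library.segments)


@pytest.fixture()
def toy_genome():
    """230 bp toy contig with exons [21,60], [101,140], [181,220] on '+':
    introns read GT..AG, and back-splice signals flank the outer exons."""
    rng = np.random.default_rng(7)
    bases = "ACGT"
    seq = list(rng.choice(list(bases), 230))

    def put(pos, text):  # 1-based
        seq[pos - 1 : pos - 1 + len(text)] = list(text)

    put(19, "AG")   # acceptor signal before exon 1
    put(61, "GT")   # intron 1 donor
    put(99, "AG")   # intron 1 acceptor
    put(141, "GT")  # intron 2 donor
    put(179, "AG")  # intron 2 acceptor
    put(221, "GT")  # donor signal after exon 3
    return Genome({"toy": "".join(seq)})
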