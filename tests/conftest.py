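import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from dbgmap.graph import FORWARD_ONLY, build_cdbg, count_kmers, solid_kmers
from dbgmap.mapper import MappingParams
from dbgmap.overlap import build_overlap_index

TOY_READS = ["TAAGC", "CAAGC"]
TOY_K = 3


@pytest.fixture(scope="session")
def toy_graph():
    """k=3 graph of TAAGC/CAAGC at c=1: unitigs AAGC(u1), CAA(u2), TAA(u3)."""
    table = count_kmers(TOY_READS, TOY_K, FORWARD_ONLY)
    return build_cdbg(solid_kmers(table, 1), TOY_K, FORWARD_ONLY)


@pytest.fixture(scope="session")
def toy_index(toy_graph):
    return build_overlap_index(toy_graph)


@pytest.fixture(scope="session")
def no_rc_params():
    """Defaults (t=2, n=2) but forward-only, for deterministic toy traces."""
    return MappingParams(try_reverse_complement=False)


def random_kmer_graph(rng, k, length):
    """CDBG of all k-mers of a random genome (c=1, forward strand)."""
    from dbgmap.simulate import random_genome

    genome = random_genome(length, rng.integers(2**31))
    table = count_kmers([genome], k, FORWARD_ONLY)
    return genome, build_cdbg(set(table.counts), k, FORWARD_ONLY)
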