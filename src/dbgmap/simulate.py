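"""Read simulation with substitution errors and the accuracy methodology.

Reads are sampled uniformly from a random genome and corrupted with i.i.d.
substitutions at a fixed rate; the mutated positions are recorded so that
mapped reads can be scored by their "distance to optimum": the number of
mismatches between read and mapped path that fall on error-free positions.
A perfectly placed read therefore scores 0 no matter how many sequencing
errors it carries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .graph import CompactedGraph, reverse_complement, spell_walk
from .io_formats import ReadRecord
from .mapper import FORWARD, GraphMapping, MappingParams, map_reads
from .overlap import OverlapIndex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DIST_BINS = (0, 1, 2, 3)  # final bin collects >= 4


@dataclass(frozen=True)
class SimulatedRead:
    record: ReadRecord
    origin: int  # 0-based genome offset of the read start
    error_positions: frozenset


@dataclass(frozen=True)
class EvalRow:
    error_rate: float
    n_reads: int
    n_mapped: int
    recall: float
    dist_hist: Tuple[int, ...]  # counts at distance 0,1,2,3,>=4

    @property
    def dist_fractions(self) -> Tuple[float, ...]:
        if self.n_mapped == 0:
            return (0.0,) * len(self.dist_hist)
        return tuple(c / self.n_mapped for c in self.dist_hist)


def random_genome(length: int, seed) -> str:
    """Uniform i.i.d. DNA string, reproducible from the seed."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_reads(
    genome: str, n: int, read_len: int, error_rate: float, seed
) -> List[SimulatedRead]:
    """Sample ``n`` forward-strand reads with recorded substitution errors.

    Each position is independently substituted with probability
    ``error_rate`` to a base chosen uniformly among the three alternatives.
    """
    if read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    rng = np.random.default_rng(seed)
    origins = rng.integers(0, len(genome) - read_len + 1, size=n)
    garr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    base_index = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        base_index[b] = i
    reads = []
    for idx, origin in enumerate(origins):
        window = garr[origin : origin + read_len].copy()
        if error_rate > 0.0:
            err = np.nonzero(rng.random(read_len) < error_rate)[0]
        else:
            err = np.empty(0, dtype=np.int64)
        if err.size:
            # shift by 1..3 in base space: always a different base
            shifts = rng.integers(1, 4, size=err.size).astype(np.uint8)
            window[err] = _BASES[(base_index[window[err]] + shifts) % 4]
        reads.append(
            SimulatedRead(
                record=ReadRecord(id=f"sr{idx + 1}", seq=window.tobytes().decode("ascii")),
                origin=int(origin),
                error_positions=frozenset(int(p) for p in err),
            )
        )
    return reads


def distance_to_optimum(
    mapping: GraphMapping, sim: SimulatedRead, graph: CompactedGraph
) -> Optional[int]:
    """Mismatches between read and mapped path at error-free positions.

    Undefined (None) for unmapped reads.  For reverse-orientation mappings
    the walk spells the reverse complement of the read, so error positions
    are mirrored accordingly.
    """
    if not mapping.mapped:
        return None
    read = sim.record.seq
    if mapping.orientation == FORWARD:
        target = read
        errors = sim.error_positions
    else:
        target = reverse_complement(read)
        errors = {len(read) - 1 - p for p in sim.error_positions}
    spelled = spell_walk(graph, list(mapping.walk), mapping.start_offset)[: len(target)]
    return sum(
        1 for p, (a, b) in enumerate(zip(target, spelled)) if p not in errors and a != b
    )


def _dist_histogram(distances: Iterable[int]) -> Tuple[int, ...]:
    hist = [0] * (len(DIST_BINS) + 1)
    for d in distances:
        hist[d if d < len(DIST_BINS) else len(DIST_BINS)] += 1
    return tuple(hist)


def evaluate(
    graph: CompactedGraph,
    index: OverlapIndex,
    params: MappingParams,
    genome: str,
    error_rates: Sequence[float],
    n_per_rate: int,
    read_len: int,
    seed: int,
) -> List[EvalRow]:
    """Recall and distance-to-optimum table, one row per error rate."""
    children = np.random.SeedSequence(seed).spawn(len(error_rates))
    rows = []
    for rate, child in zip(error_rates, children):
        sims = simulate_reads(genome, n_per_rate, read_len, rate, child)
        mappings, _ = map_reads([s.record for s in sims], graph, index, params)
        distances = []
        for m, s in zip(mappings, sims):
            d = distance_to_optimum(m, s, graph)
            if d is not None:
                distances.append(d)
        rows.append(
            EvalRow(
                error_rate=rate,
                n_reads=n_per_rate,
                n_mapped=len(distances),
                recall=len(distances) / n_per_rate if n_per_rate else 0.0,
                dist_hist=_dist_histogram(distances),
            )
        )
    return rows


def summarize_rows(rows: Iterable[EvalRow]) -> str:
    lines = ["error_rate\tn_reads\tn_mapped\trecall\td0\td1\td2\td3\td4plus"]
    for r in rows:
        lines.append(
            f"{r.error_rate:g}\t{r.n_reads}\t{r.n_mapped}\t{r.recall:.6f}\t"
            + "\t".join(str(c) for c in r.dist_hist)
        )
    return "\n".join(lines)
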