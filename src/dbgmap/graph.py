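"""k-mer counting, abundance filtering and compacted de Bruijn graph construction.

The graph of order ``k`` has one node per solid k-mer and a directed edge
``d -> d'`` whenever the length-(k-1) suffix of ``d`` equals the length-(k-1)
prefix of ``d'``.  Maximal non-branching paths are merged into unitigs; the
compacted graph stores only the unitigs, adjacency being implied by shared
(k-1)-mer boundaries.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import WalkError

FORWARD_ONLY = "forward_only"
WITH_RC = "with_reverse_complements"

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ACGT_RUN = re.compile("[^ACGT]+")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class KmerTable:
    """Exact k-mer counts over the {A,C,G,T} alphabet."""

    k: int
    counts: Counter = field(default_factory=Counter)


def _seq_of(record) -> str:
    return record.seq if hasattr(record, "seq") else record


def count_kmers(sequences: Iterable, k: int, strand_mode: str = FORWARD_ONLY) -> KmerTable:
    """Count every length-k window over {A,C,G,T}.

    Windows containing any other character (N in particular) are skipped.
    With ``strand_mode=with_reverse_complements`` each sequence additionally
    contributes the k-mers of its reverse complement.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if strand_mode not in (FORWARD_ONLY, WITH_RC):
        raise ValueError(f"unknown strand_mode: {strand_mode!r}")
    counts: Counter = Counter()
    for record in sequences:
        seq = _seq_of(record).upper()
        strands = (seq,) if strand_mode == FORWARD_ONLY else (seq, reverse_complement(seq))
        for strand in strands:
            for chunk in _ACGT_RUN.split(strand):
                for i in range(len(chunk) - k + 1):
                    counts[chunk[i : i + k]] += 1
    return KmerTable(k=k, counts=counts)


def solid_kmers(table: KmerTable, c: int) -> set:
    """k-mers whose count is at least the abundance threshold ``c``."""
    if c < 1:
        raise ValueError(f"abundance threshold must be >= 1, got {c}")
    return {kmer for kmer, n in table.counts.items() if n >= c}


@dataclass(frozen=True)
class Unitig:
    """Spelled sequence of a maximal non-branching path."""

    id: str
    seq: str
    prefix_ov: str
    suffix_ov: str

    @property
    def rank(self) -> int:
        return int(self.id[1:])


def _make_unitig(rank: int, seq: str, k: int) -> Unitig:
    return Unitig(id=f"u{rank}", seq=seq, prefix_ov=seq[: k - 1], suffix_ov=seq[len(seq) - (k - 1) :])


class CompactedGraph:
    """A compacted de Bruijn graph: order ``k`` plus a set of unitigs.

    Unitig ids are assigned ``u1, u2, ...`` by ascending unitig sequence so
    that construction is reproducible regardless of set iteration order.
    """

    def __init__(self, k: int, unitig_seqs: Sequence[str], strand_mode: str = FORWARD_ONLY):
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        self.k = k
        self.strand_mode = strand_mode
        ordered = sorted(unitig_seqs)
        self.unitigs = [_make_unitig(i + 1, seq, k) for i, seq in enumerate(ordered)]
        self._by_id = {u.id: u for u in self.unitigs}
        # boundary maps drive both adjacency and the seed index
        self._starting: dict = {}
        self._ending: dict = {}
        for u in self.unitigs:
            self._starting.setdefault(u.prefix_ov, []).append(u.id)
            self._ending.setdefault(u.suffix_ov, []).append(u.id)

    def __len__(self) -> int:
        return len(self.unitigs)

    def __iter__(self):
        return iter(self.unitigs)

    def unitig(self, unitig_id: str) -> Unitig:
        try:
            return self._by_id[unitig_id]
        except KeyError:
            raise KeyError(f"unknown unitig id: {unitig_id!r}") from None

    def starting_with(self, word: str) -> list:
        """Ids of unitigs whose prefix (k-1)-mer equals ``word`` (ascending id)."""
        return list(self._starting.get(word, ()))

    def ending_with(self, word: str) -> list:
        return list(self._ending.get(word, ()))

    def neighbors(self, unitig_id: str, direction: str = "out") -> list:
        u = self.unitig(unitig_id)
        if direction == "out":
            return self.starting_with(u.suffix_ov)
        if direction == "in":
            return self.ending_with(u.prefix_ov)
        raise ValueError(f"direction must be 'out' or 'in', got {direction!r}")

    def adjacent(self, a: str, b: str) -> bool:
        return self.unitig(a).suffix_ov == self.unitig(b).prefix_ov


def build_cdbg(kmers: Iterable[str], k: int, strand_mode: str = FORWARD_ONLY) -> CompactedGraph:
    """Compact the de Bruijn graph of ``kmers`` into maximal unitigs.

    A path is extended through a node only while it has in-degree 1 and its
    predecessor out-degree 1; isolated simple cycles (every node degree 1/1)
    are broken at their lexicographically smallest k-mer and emitted as one
    linear unitig.
    """
    kmers = set(kmers)
    for d in kmers:
        if len(d) != k:
            raise ValueError(f"k-mer {d!r} does not have length k={k}")

    def outs(d: str) -> list:
        suf = d[1:]
        return [suf + b for b in _BASES if suf + b in kmers]

    def ins(d: str) -> list:
        pre = d[:-1]
        return [b + pre for b in _BASES if b + pre in kmers]

    out_deg = {d: len(outs(d)) for d in kmers}
    in_deg = {d: len(ins(d)) for d in kmers}

    seqs = []
    visited = set()
    for d in kmers:
        if in_deg[d] == 1:
            pred = ins(d)[0]
            if out_deg[pred] == 1 and pred != d:
                continue  # interior node (or self-loop handled as cycle below)
        # d starts a unitig
        path = [d]
        on_path = {d}
        cur = d
        while out_deg[cur] == 1:
            nxt = outs(cur)[0]
            if in_deg[nxt] != 1 or nxt in on_path:
                break
            path.append(nxt)
            on_path.add(nxt)
            cur = nxt
        visited.update(on_path)
        seqs.append(path[0] + "".join(p[-1] for p in path[1:]))

    # leftovers are pure cycles: all nodes have in/out degree exactly 1
    leftover = kmers - visited
    while leftover:
        start = min(leftover)
        cycle = [start]
        cur = outs(start)[0]
        while cur != start:
            cycle.append(cur)
            cur = outs(cur)[0]
        leftover.difference_update(cycle)
        seqs.append(cycle[0] + "".join(p[-1] for p in cycle[1:]))

    return CompactedGraph(k=k, unitig_seqs=seqs, strand_mode=strand_mode)


def build_from_reads(
    sequences: Iterable, k: int, c: int = 2, strand_mode: str = WITH_RC
) -> CompactedGraph:
    """Convenience pipeline: count, filter at abundance ``c``, compact."""
    table = count_kmers(sequences, k, strand_mode)
    return build_cdbg(solid_kmers(table, c), k, strand_mode)


def spell_walk(graph: CompactedGraph, walk: Sequence[str], entry_offset: int = 0) -> str:
    """Spell the sequence generated by a walk of unitigs.

    Consecutive unitigs are glued on their shared (k-1)-mer; the first unitig
    contributes its sequence from ``entry_offset`` on.  For a walk of ``l``
    single-k-mer unitigs at offset 0 the result has length ``k + l - 1``.
    """
    if not walk:
        raise WalkError("empty walk")
    first = graph.unitig(walk[0])
    if not 0 <= entry_offset < len(first.seq):
        raise ValueError(f"entry_offset {entry_offset} out of range for {first.id}")
    parts = [first.seq[entry_offset:]]
    prev = first
    for uid in walk[1:]:
        u = graph.unitig(uid)
        if prev.suffix_ov != u.prefix_ov:
            raise WalkError(f"unitigs {prev.id} and {u.id} are not adjacent")
        parts.append(u.seq[graph.k - 1 :])
        prev = u
    return "".join(parts)
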