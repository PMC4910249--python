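"""Greedy seed-and-extend mapping of reads onto branching paths of a CDBG.

A read is anchored by exact boundary (k-1)-mer hits at both of its
extremities, then rewritten left-to-right as a succession of unitigs while
the cumulative Hamming mismatch count stays within the budget ``t``.  The
approach is greedy: at each step the best candidate is kept and backtracking
is excluded.  An exhaustive mode replaces the greedy extension with a
depth-first search over all candidate successions (pruned only on the
budget) and returns the minimum-mismatch walk.  Reads that cannot be mapped
across unitig boundaries may still map entirely inside a single unitig via
the containment stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple

from .errors import SearchLimitExceeded
from .graph import CompactedGraph, reverse_complement, spell_walk
from .overlap import OverlapIndex

EXHAUSTIVE_STATE_CAP = 10**6


class Status(str, Enum):
    MAPPED_PATH = "MAPPED_PATH"
    MAPPED_UNITIG = "MAPPED_UNITIG"
    UNMAPPED_TOO_SHORT = "UNMAPPED_TOO_SHORT"
    UNMAPPED_UNANCHORED = "UNMAPPED_UNANCHORED"
    UNMAPPED_OVER_BUDGET = "UNMAPPED_OVER_BUDGET"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class MappingParams:
    """Knobs of the mapper; defaults follow the tool's standard settings."""

    max_mismatches: int = 2  # cumulative Hamming budget t
    anchor_failures: int = 2  # allowed failed anchors per direction n
    exhaustive: bool = False
    try_reverse_complement: bool = True


@dataclass(frozen=True)
class Anchor:
    pos: int  # 0-based read position of the (k-1)-mer
    word: str
    starters: Tuple[str, ...]
    enders: Tuple[str, ...]


@dataclass(frozen=True)
class GraphMapping:
    read_id: str
    status: Status
    orientation: str = FORWARD
    walk: Tuple[str, ...] = ()
    start_offset: Optional[int] = None
    mismatches: Optional[int] = None

    @property
    def mapped(self) -> bool:
        return self.status in (Status.MAPPED_PATH, Status.MAPPED_UNITIG)


@dataclass
class MappingSummary:
    n_reads: int = 0
    n_mapped_path: int = 0
    n_mapped_unitig: int = 0
    n_too_short: int = 0
    n_unanchored: int = 0
    n_over_budget: int = 0

    def add(self, mapping: GraphMapping) -> None:
        self.n_reads += 1
        if mapping.status is Status.MAPPED_PATH:
            self.n_mapped_path += 1
        elif mapping.status is Status.MAPPED_UNITIG:
            self.n_mapped_unitig += 1
        elif mapping.status is Status.UNMAPPED_TOO_SHORT:
            self.n_too_short += 1
        elif mapping.status is Status.UNMAPPED_UNANCHORED:
            self.n_unanchored += 1
        else:
            self.n_over_budget += 1

    @property
    def n_mapped(self) -> int:
        return self.n_mapped_path + self.n_mapped_unitig

    def __str__(self) -> str:
        return (
            f"{self.n_reads} reads: {self.n_mapped_path} on branching paths, "
            f"{self.n_mapped_unitig} on single unitigs, "
            f"{self.n_too_short} too short, {self.n_unanchored} unanchored, "
            f"{self.n_over_budget} over mismatch budget"
        )


@dataclass
class StepStats:
    """Instrumentation: candidate-set size of every greedy extension step."""

    candidates_per_step: List[int] = field(default_factory=list)

    @property
    def max_candidates(self) -> int:
        return max(self.candidates_per_step, default=0)


def hamming_cost(a: str, b: str) -> int:
    """Positions where ``a`` and ``b`` differ; N mismatches everything."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def find_anchors(read: str, index: OverlapIndex) -> List[Anchor]:
    """All positions of the read whose (k-1)-mer is an indexed overlap."""
    w = index.k - 1
    anchors = []
    for pos in range(len(read) - w + 1):
        word = read[pos : pos + w]
        entry = index.entries.get(word)
        if entry is not None:
            anchors.append(Anchor(pos=pos, word=word, starters=entry.starters, enders=entry.enders))
    return anchors


def _extremity_candidates(
    read: str,
    anchors: Sequence[Anchor],
    graph: CompactedGraph,
    params: MappingParams,
    side: str,
) -> Optional[Tuple[Anchor, List[Tuple[str, int]]]]:
    """First usable extremal anchor with the candidates that align under it.

    Left side: scan anchors left to right; a candidate unitig must end with
    the anchor word and its suffix must cover and align the whole read prefix
    within the budget.  Right side is symmetric.  An anchor with no viable
    candidate counts one failure; after ``n`` failures the side gives up.
    """
    k = graph.k
    t = params.max_mismatches
    ordered = anchors if side == "left" else list(reversed(anchors))
    failures = 0
    for anchor in ordered:
        viable: List[Tuple[str, int]] = []
        if side == "left":
            span = anchor.pos + k - 1  # read[:span] must lie on the unitig suffix
            for uid in anchor.enders:
                u = graph.unitig(uid)
                if len(u.seq) >= span:
                    mm = hamming_cost(read[:span], u.seq[len(u.seq) - span :])
                    if mm <= t:
                        viable.append((uid, mm))
        else:
            span = len(read) - anchor.pos  # read[pos:] must lie on the unitig prefix
            for uid in anchor.starters:
                u = graph.unitig(uid)
                if len(u.seq) >= span:
                    mm = hamming_cost(read[anchor.pos :], u.seq[:span])
                    if mm <= t:
                        viable.append((uid, mm))
        if viable:
            return anchor, viable
        failures += 1
        if failures >= params.anchor_failures:
            return None
    return None


def anchor_extremity(
    read: str,
    anchors: Sequence[Anchor],
    graph: CompactedGraph,
    params: MappingParams,
    side: str,
) -> Optional[Tuple[Anchor, str, int]]:
    """Greedy extremity anchoring: best (min-mismatch, then smallest-id)
    candidate at the first usable extremal anchor, or None on failure."""
    found = _extremity_candidates(read, anchors, graph, params, side)
    if found is None:
        return None
    anchor, viable = found
    uid, mm = min(viable, key=lambda c: (c[1], int(c[0][1:])))
    return anchor, uid, mm


def _finalize_path(
    read_id: str,
    graph: CompactedGraph,
    orientation: str,
    walk: Sequence[str],
    start_offset: int,
    mismatches: int,
) -> GraphMapping:
    """Canonicalize a covering walk into a mapping.

    A leading unitig that contributes only the shared (k-1)-mer overlap is
    dropped (the read then starts at offset 0 of the next unitig, spelling
    unchanged).  A walk reduced to a single unitig means the read lies
    entirely inside it: that is a containment, not a branching-path mapping.
    """
    walk = list(walk)
    k = graph.k
    while len(walk) > 1 and start_offset == len(graph.unitig(walk[0]).seq) - (k - 1):
        walk.pop(0)
        start_offset = 0
    status = Status.MAPPED_PATH if len(walk) > 1 else Status.MAPPED_UNITIG
    return GraphMapping(read_id, status, orientation, tuple(walk), start_offset, mismatches)


def _segment_mismatches(read: str, covered: int, seg: str) -> Tuple[int, int]:
    """Mismatches of a unitig tail ``seg`` against the read from ``covered``,
    truncated at the read end; returns (mismatches, new covered)."""
    avail = len(read) - covered
    cmp_len = min(len(seg), avail)
    mm = hamming_cost(read[covered : covered + cmp_len], seg[:cmp_len])
    return mm, covered + cmp_len


def _map_oriented_greedy(
    read_id: str,
    read: str,
    graph: CompactedGraph,
    index: OverlapIndex,
    params: MappingParams,
    orientation: str,
    stats: Optional[StepStats],
) -> GraphMapping:
    k = graph.k
    t = params.max_mismatches
    anchors = find_anchors(read, index)
    unanchored = GraphMapping(read_id, Status.UNMAPPED_UNANCHORED, orientation)
    if not anchors:
        return unanchored
    left = anchor_extremity(read, anchors, graph, params, "left")
    right = anchor_extremity(read, anchors, graph, params, "right")
    if left is None or right is None:
        return unanchored

    anchor, first_uid, mm = left
    first = graph.unitig(first_uid)
    covered = anchor.pos + k - 1
    start_offset = len(first.seq) - covered
    walk = [first_uid]
    anchor_words = {a.pos: a.word for a in anchors}
    first_pos, last_pos = anchors[0].pos, anchors[-1].pos

    while covered < len(read):
        current = graph.unitig(walk[-1])
        overlap_pos = covered - (k - 1)
        entry = index.get(current.suffix_ov)
        candidates = entry.starters if entry is not None else ()
        if stats is not None:
            stats.candidates_per_step.append(len(candidates))

        chosen = None
        # tested-first shortcut: a candidate whose own end-overlap coincides
        # with the next anchor detected on the read is accepted outright if it
        # keeps the budget; disabled at the first and last overlap of the read
        if overlap_pos not in (first_pos, last_pos):
            for uid in candidates:
                u = graph.unitig(uid)
                end_pos = overlap_pos + len(u.seq) - (k - 1)
                if anchor_words.get(end_pos) == u.suffix_ov:
                    seg_mm, new_covered = _segment_mismatches(read, covered, u.seq[k - 1 :])
                    if mm + seg_mm <= t:
                        chosen = (uid, seg_mm, new_covered)
                    break
        if chosen is None:
            best = None
            for uid in candidates:
                u = graph.unitig(uid)
                seg_mm, new_covered = _segment_mismatches(read, covered, u.seq[k - 1 :])
                if mm + seg_mm > t:
                    continue
                key = (seg_mm, int(uid[1:]))
                if best is None or key < best[0]:
                    best = (key, (uid, seg_mm, new_covered))
            if best is None:
                return GraphMapping(read_id, Status.UNMAPPED_OVER_BUDGET, orientation)
            chosen = best[1]

        uid, seg_mm, covered = chosen
        mm += seg_mm
        walk.append(uid)
        if len(walk) > len(read):  # safety cap against degenerate cycles
            return GraphMapping(read_id, Status.UNMAPPED_OVER_BUDGET, orientation)

    return _finalize_path(read_id, graph, orientation, walk, start_offset, mm)


def _map_oriented_exhaustive(
    read_id: str,
    read: str,
    graph: CompactedGraph,
    index: OverlapIndex,
    params: MappingParams,
    orientation: str,
) -> GraphMapping:
    k = graph.k
    t = params.max_mismatches
    anchors = find_anchors(read, index)
    unanchored = GraphMapping(read_id, Status.UNMAPPED_UNANCHORED, orientation)
    if not anchors:
        return unanchored
    left = _extremity_candidates(read, anchors, graph, params, "left")
    right = _extremity_candidates(read, anchors, graph, params, "right")
    if left is None or right is None:
        return unanchored

    anchor, viable = left
    covered0 = anchor.pos + k - 1
    best: Optional[Tuple[int, Tuple[int, ...], Tuple[str, ...]]] = None
    states = 0

    def consider(mm: int, walk: Tuple[str, ...]) -> None:
        nonlocal best
        key = (mm, tuple(int(u[1:]) for u in walk))
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], walk)

    def dfs(walk: Tuple[str, ...], covered: int, mm: int) -> None:
        nonlocal states
        states += 1
        if states > EXHAUSTIVE_STATE_CAP:
            raise SearchLimitExceeded(
                f"exhaustive search for read {read_id!r} exceeded "
                f"{EXHAUSTIVE_STATE_CAP} states"
            )
        if covered >= len(read):
            consider(mm, walk)
            return
        current = graph.unitig(walk[-1])
        entry = index.get(current.suffix_ov)
        if entry is None:
            return
        for uid in entry.starters:
            u = graph.unitig(uid)
            seg_mm, new_covered = _segment_mismatches(read, covered, u.seq[k - 1 :])
            if mm + seg_mm <= t:  # prune only on the budget
                dfs(walk + (uid,), new_covered, mm + seg_mm)

    for uid, mm0 in viable:
        dfs((uid,), covered0, mm0)

    if best is None:
        return GraphMapping(read_id, Status.UNMAPPED_OVER_BUDGET, orientation)
    walk = best[2]
    start_offset = len(graph.unitig(walk[0]).seq) - covered0
    return _finalize_path(read_id, graph, orientation, walk, start_offset, best[0])


def _better(fwd: GraphMapping, rev: GraphMapping) -> GraphMapping:
    if fwd.mapped and rev.mapped:
        return rev if rev.mismatches < fwd.mismatches else fwd  # tie -> forward
    if rev.mapped:
        return rev
    return fwd


def map_read_greedy(
    read_id: str,
    read: str,
    graph: CompactedGraph,
    index: OverlapIndex,
    params: MappingParams = MappingParams(),
    stats: Optional[StepStats] = None,
) -> GraphMapping:
    """Map one read on a branching path of the graph, greedily."""
    read = read.upper()
    if len(read) < graph.k:
        return GraphMapping(read_id, Status.UNMAPPED_TOO_SHORT)
    fwd = _map_oriented_greedy(read_id, read, graph, index, params, FORWARD, stats)
    if not params.try_reverse_complement:
        return fwd
    rev = _map_oriented_greedy(
        read_id, reverse_complement(read), graph, index, params, REVERSE, stats
    )
    return _better(fwd, rev)


def map_read_exhaustive(
    read_id: str,
    read: str,
    graph: CompactedGraph,
    index: OverlapIndex,
    params: MappingParams = MappingParams(),
) -> GraphMapping:
    """Minimum-mismatch branching-path mapping by exhaustive search.

    Anchoring is identical to the greedy mapper; all candidate successions
    are then explored depth-first, pruned only when the cumulative mismatch
    count exceeds the budget.  Ties break on the lexicographically smallest
    walk (by unitig rank)."""
    read = read.upper()
    if len(read) < graph.k:
        return GraphMapping(read_id, Status.UNMAPPED_TOO_SHORT)
    fwd = _map_oriented_exhaustive(read_id, read, graph, index, params, FORWARD)
    if not params.try_reverse_complement:
        return fwd
    rev = _map_oriented_exhaustive(
        read_id, reverse_complement(read), graph, index, params, REVERSE
    )
    return _better(fwd, rev)


class UnitigKmerIndex:
    """Auxiliary index of every unitig k-mer position, for containment."""

    def __init__(self, graph: CompactedGraph):
        self.k = graph.k
        self.positions: dict = {}
        for u in graph:
            for i in range(len(u.seq) - graph.k + 1):
                self.positions.setdefault(u.seq[i : i + graph.k], []).append((u.id, i))

    def get(self, kmer: str):
        return self.positions.get(kmer, ())


def _contain_oriented(
    read: str, graph: CompactedGraph, kindex: UnitigKmerIndex, t: int
) -> Optional[Tuple[int, int, str, int]]:
    """Best (mm, rank, uid, offset) full containment of ``read``, or None.

    Seeds with the read's first k-mer; if that k-mer carries an error the
    seeding is retried at positions k and 2k."""
    k = graph.k
    for seed_pos in (0, k, 2 * k):
        if seed_pos + k > len(read):
            break
        best = None
        for uid, pos in kindex.get(read[seed_pos : seed_pos + k]):
            off = pos - seed_pos
            u = graph.unitig(uid)
            if off < 0 or off + len(read) > len(u.seq):
                continue
            mm = hamming_cost(read, u.seq[off : off + len(read)])
            if mm <= t:
                key = (mm, int(uid[1:]), uid, off)
                if best is None or key < best:
                    best = key
        if best is not None:
            return best
    return None


def map_on_unitigs(
    read_id: str,
    read: str,
    graph: CompactedGraph,
    params: MappingParams = MappingParams(),
    kindex: Optional[UnitigKmerIndex] = None,
) -> GraphMapping:
    """Containment stage: map a read entirely inside one unitig."""
    read = read.upper()
    if len(read) < graph.k:
        return GraphMapping(read_id, Status.UNMAPPED_TOO_SHORT)
    if kindex is None:
        kindex = UnitigKmerIndex(graph)
    t = params.max_mismatches
    fwd = _contain_oriented(read, graph, kindex, t)
    rev = (
        _contain_oriented(reverse_complement(read), graph, kindex, t)
        if params.try_reverse_complement
        else None
    )
    choice, orientation = fwd, FORWARD
    if rev is not None and (fwd is None or rev[0] < fwd[0]):
        choice, orientation = rev, REVERSE
    if choice is None:
        return GraphMapping(read_id, Status.UNMAPPED_UNANCHORED)
    mm, _, uid, off = choice
    return GraphMapping(read_id, Status.MAPPED_UNITIG, orientation, (uid,), off, mm)


def map_reads(
    reads: Iterable,
    graph: CompactedGraph,
    index: OverlapIndex,
    params: MappingParams = MappingParams(),
    stats: Optional[StepStats] = None,
) -> Tuple[List[GraphMapping], MappingSummary]:
    """Full pipeline: branching-path mapping first, then containment for the
    reads the path stage could not place; returns per-read mappings and a
    tally of outcomes."""
    kindex = UnitigKmerIndex(graph)
    mappings: List[GraphMapping] = []
    summary = MappingSummary()
    for record in reads:
        read_id = getattr(record, "id", None) or f"r{len(mappings) + 1}"
        seq = record.seq if hasattr(record, "seq") else str(record)
        if params.exhaustive:
            m = map_read_exhaustive(read_id, seq, graph, index, params)
        else:
            m = map_read_greedy(read_id, seq, graph, index, params, stats)
        if m.status is not Status.MAPPED_PATH:
            contained = map_on_unitigs(read_id, seq, graph, params, kindex)
            if contained.mapped and (not m.mapped or contained.mismatches <= m.mismatches):
                m = contained
        mappings.append(m)
        summary.add(m)
    return mappings, summary


def check_mapping(mapping: GraphMapping, read: str, graph: CompactedGraph) -> None:
    """Soundness assertion: re-spell the walk and verify the mismatch count."""
    if not mapping.mapped:
        return
    target = read.upper() if mapping.orientation == FORWARD else reverse_complement(read.upper())
    spelled = spell_walk(graph, list(mapping.walk), mapping.start_offset)
    if len(spelled) < len(target):
        raise AssertionError(f"walk of {mapping.read_id} does not cover the read")
    observed = hamming_cost(target, spelled[: len(target)])
    if observed != mapping.mismatches:
        raise AssertionError(
            f"{mapping.read_id}: reported {mapping.mismatches} mismatches, re-spelling gives {observed}"
        )
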