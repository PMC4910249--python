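"""Seed index over unitig-boundary (k-1)-mers.

Only the prefix and suffix (k-1)-mers of unitigs ("overlaps") are indexed:
they are the words spelled across graph edges, and each can be shared by at
most four unitigs starting with it and four ending with it (one per extending
base).  Interior words are deliberately not indexed; reads falling entirely
inside a long unitig are handled by the containment stage instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from .graph import CompactedGraph


@dataclass(frozen=True)
class OverlapEntry:
    starters: Tuple[str, ...]  # unitig ids whose prefix (k-1)-mer is the key
    enders: Tuple[str, ...]  # unitig ids whose suffix (k-1)-mer is the key


@dataclass
class OverlapIndex:
    k: int
    entries: dict = field(default_factory=dict)

    def get(self, word: str) -> Optional[OverlapEntry]:
        return self.entries.get(word)


def build_overlap_index(graph: CompactedGraph) -> OverlapIndex:
    """Index every distinct boundary (k-1)-mer of the graph's unitigs."""
    starting: dict = {}
    ending: dict = {}
    for u in graph:
        starting.setdefault(u.prefix_ov, []).append(u.id)
        ending.setdefault(u.suffix_ov, []).append(u.id)
    by_rank = lambda uid: int(uid[1:])
    entries = {}
    for word in set(starting) | set(ending):
        entries[word] = OverlapEntry(
            starters=tuple(sorted(starting.get(word, ()), key=by_rank)),
            enders=tuple(sorted(ending.get(word, ()), key=by_rank)),
        )
    return OverlapIndex(k=graph.k, entries=entries)


def query_overlap(index: OverlapIndex, word: str) -> Optional[OverlapEntry]:
    """Exact lookup of a boundary (k-1)-mer; None for non-boundary words."""
    if len(word) != index.k - 1:
        raise ValueError(f"query word must have length k-1={index.k - 1}, got {len(word)}")
    return index.entries.get(word)
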