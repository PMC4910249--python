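"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's algorithms: compaction is done by
repeated pairwise merging, adjacency by exhaustive pair scanning, and
mapping by plain enumeration of all walks.
"""

from __future__ import annotations

from itertools import product


def brute_force_compaction(kmers, k):
    """Repeatedly merge any mergeable edge until fixpoint.

    An edge a->b is mergeable when the last k-mer of a has out-degree 1 and
    the first k-mer of b has in-degree 1, degrees taken in the underlying
    k-mer graph (merging through a branching k-mer is never allowed, even if
    the branch target was already absorbed into another sequence).  Returns
    the unitig sequences as a sorted list; sequences collapsed from isolated
    cycles are rotated to start at their lexicographically smallest k-mer so
    results are canonical and comparable.
    """
    kmers = set(kmers)
    out_deg = {d: sum(d[1:] + b in kmers for b in "ACGT") for d in kmers}
    in_deg = {d: sum(b + d[:-1] in kmers for b in "ACGT") for d in kmers}
    seqs = set(kmers)

    def merge_step():
        for a in seqs:
            if out_deg[a[len(a) - k :]] != 1:
                continue
            for b in seqs:
                if b == a or a[len(a) - k + 1 :] != b[: k - 1]:
                    continue
                if in_deg[b[:k]] == 1:
                    seqs.remove(a)
                    seqs.remove(b)
                    seqs.add(a + b[k - 1 :])
                    return True
        return False

    while merge_step():
        pass

    out = []
    for s in seqs:
        windows = [s[i : i + k] for i in range(len(s) - k + 1)]
        # a fully collapsed *isolated* cycle self-overlaps and every one of
        # its k-mers has in/out degree 1; canonicalize its rotation (a linear
        # unitig may self-overlap by coincidence and must not be rotated)
        if (
            len(s) > k
            and s[len(s) - k + 1 :] == s[: k - 1]
            and len(set(windows)) == len(windows)
            and all(in_deg[w] == 1 and out_deg[w] == 1 for w in windows)
        ):
            j = windows.index(min(windows))
            rotated = windows[j:] + windows[:j]
            s = rotated[0] + "".join(w[-1] for w in rotated[1:])
        out.append(s)
    return sorted(out)


def overlapping_pairs(unitigs, k):
    """All ordered unitig pairs (a, b) with suffix(k-1)(a) == prefix(k-1)(b)."""
    pairs = []
    for a, b in product(unitigs, repeat=2):
        if a.seq[len(a.seq) - (k - 1) :] == b.seq[: k - 1]:
            pairs.append((a.id, b.id))
    return pairs


def hamming(a, b):
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def enumerate_anchored_mappings(graph, read, t, left_anchor_pos, left_candidates):
    """All walks that start at a viable left-extremity unitig and cover the
    read within budget ``t``; returns the best (mismatches, rank-walk, walk).

    Walk extension uses raw adjacency scanning (no index), and mismatch
    counts come from full re-spelling, so this stays independent of the
    mapper's incremental bookkeeping.
    """
    from dbgmap.graph import spell_walk

    k = graph.k
    covered0 = left_anchor_pos + k - 1
    best = None

    def score(walk):
        first = graph.unitig(walk[0])
        offset = len(first.seq) - covered0
        spelled = spell_walk(graph, list(walk), offset)
        if len(spelled) < len(read):
            return None
        return hamming(read, spelled[: len(read)])

    def extend(walk, spelled_len):
        nonlocal best
        if spelled_len >= len(read):
            mm = score(walk)
            if mm is not None and mm <= t:
                key = (mm, tuple(int(u[1:]) for u in walk))
                if best is None or key < best[:2]:
                    best = (key[0], key[1], tuple(walk))
            return
        last = graph.unitig(walk[-1])
        for u in graph:  # raw scan instead of the overlap index
            if last.suffix_ov == u.prefix_ov:
                added = len(u.seq) - (k - 1)
                partial = walk + [u.id]
                # prune on the mismatches of the spelled prefix so cycles stop
                first = graph.unitig(partial[0])
                offset = len(first.seq) - covered0
                spelled = spell_walk(graph, partial, offset)
                upto = min(len(read), len(spelled))
                if hamming(read[:upto], spelled[:upto]) <= t:
                    extend(partial, spelled_len + added)

    for uid in left_candidates:
        extend([uid], covered0)
    return best
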