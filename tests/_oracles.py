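"""Independent oracles used by the test suite.

Everything here is deliberately written *differently* from the package
implementation: plain recursions and exhaustive searches whose
correctness is checkable by eye, used only to generate expected values.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from ehmine.alignment import AlignmentParams, DEFAULT_PARAMS, load_matrix, _INDEX


def gap_run_cost(length: int, params: AlignmentParams = DEFAULT_PARAMS) -> float:
    return params.gap_open + (length - 1) * params.gap_extend


def score_alignment_string(a_aln: str, b_aln: str,
                           params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Score an explicit alignment string pair: substitution sums plus a
    run-based affine cost for every maximal gap run in either row."""
    sub = load_matrix(params.matrix)
    score = 0.0
    for x, y in zip(a_aln, b_aln):
        if x != "-" and y != "-":
            score += sub[_INDEX[x], _INDEX[y]]
    for row in (a_aln, b_aln):
        run = 0
        for ch in row:
            if ch == "-":
                run += 1
            elif run:
                score -= gap_run_cost(run, params)
                run = 0
        if run:
            score -= gap_run_cost(run, params)
    return score


def all_alignments(a: str, b: str):
    """Every alignment string pair (no gap-gap columns).  Exponential;
    keep len(a), len(b) <= 5."""
    def rec(i: int, j: int):
        if i == len(a) and j == len(b):
            yield ("", "")
            return
        if i < len(a):
            for x, y in rec(i + 1, j):
                yield (a[i] + x, "-" + y)
        if j < len(b):
            for x, y in rec(i, j + 1):
                yield ("-" + x, b[j] + y)
        if i < len(a) and j < len(b):
            for x, y in rec(i + 1, j + 1):
                yield (a[i] + x, b[j] + y)
    return rec(0, 0)


def brute_force_score_tiny(a: str, b: str,
                           params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Literal enumeration over all alignment strings (lengths <= 5)."""
    return max(score_alignment_string(x, y, params) for x, y in all_alignments(a, b))


def enumeration_score(a: str, b: str,
                      params: AlignmentParams = DEFAULT_PARAMS) -> float:
    """Best alignment score by plain recursion over the three column
    types, memoised on (i, j, preceding column type).

    ``state``: 0 = previous column was a match/mismatch or start,
    1 = previous column gapped b, 2 = previous column gapped a.
    Extending the same gap costs ``gap_extend``; anything else opening a
    gap costs ``gap_open``.  Equivalent to exhaustive enumeration of all
    alignment strings under the run-based affine cost.
    """
    sub = load_matrix(params.matrix)
    go, ge = params.gap_open, params.gap_extend

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub[_INDEX[a[i]], _INDEX[b[j]]] + best(i + 1, j + 1, 0))
        if i < len(a):  # column gaps b
            cost = ge if state == 1 else go
            options.append(-cost + best(i + 1, j, 1))
        if j < len(b):  # column gaps a
            cost = ge if state == 2 else go
            options.append(-cost + best(i, j + 1, 2))
        return max(options)

    result = best(0, 0, 0)
    best.cache_clear()
    return float(result)


# ---------------------------------------------------------------------------
# exhaustive least-squares tree search (NJ oracle for n <= 6)


def all_unrooted_topologies(ids: list[str]):
    """All unrooted binary topologies as sets of canonical bipartitions.

    Built by inserting leaves one at a time on every existing edge.
    Counts: 1, 3, 15, 105 for 4..7 leaves.
    """
    n = len(ids)
    # edges as (u, v) over node labels; leaves are ids, internal nodes ints
    def insert(edges, leaf, next_internal):
        for k in range(len(edges)):
            u, v = edges[k]
            rest = edges[:k] + edges[k + 1:]
            w = next_internal
            yield rest + [(u, w), (w, v), (leaf, w)], next_internal + 1

    topologies = [([(ids[0], 0), (ids[1], 0), (ids[2], 0)], 1)]
    for leaf in ids[3:]:
        topologies = [new
                      for edges, nxt in topologies
                      for new in insert(edges, leaf, nxt)]
    for edges, _ in topologies:
        yield edges


def topology_bipartitions(edges, ids: list[str]) -> set[frozenset]:
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    anchor = min(ids)
    out = set()
    id_set = set(ids)
    for u, v in edges:
        if u in id_set or v in id_set:
            continue  # pendant edge
        seen = {u, v}
        stack = [u]
        side = set()
        while stack:
            node = stack.pop()
            if node in id_set:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if anchor in side:
            side = id_set - side
        out.add(frozenset(side))
    return out


def least_squares_fit(edges, ids: list[str], D: np.ndarray) -> float:
    """Unconstrained LS fit of branch lengths to pairwise distances;
    returns the residual sum of squares."""
    edge_index = {tuple(sorted(e, key=str)): k for k, e in enumerate(edges)}
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path_edges(src, dst):
        # DFS path in a tree
        stack = [(src, [])]
        seen = {src}
        while stack:
            node, path = stack.pop()
            if node == dst:
                return path
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    key = tuple(sorted((node, nb), key=str))
                    stack.append((nb, path + [edge_index[key]]))
        raise AssertionError("disconnected topology")

    rows, targets = [], []
    for i, j in itertools.combinations(range(len(ids)), 2):
        row = np.zeros(len(edges))
        for e in path_edges(ids[i], ids[j]):
            row[e] = 1.0
        rows.append(row)
        targets.append(D[i, j])
    A = np.array(rows)
    y = np.array(targets)
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ lengths - y) ** 2).sum())


def best_ls_topology(ids: list[str], D: np.ndarray) -> set[frozenset]:
    """Bipartitions of the minimum-RSS topology (exhaustive search)."""
    best_rss, best_bps = None, None
    for edges in all_unrooted_topologies(ids):
        rss = least_squares_fit(edges, ids, D)
        if best_rss is None or rss < best_rss - 1e-12:
            best_rss, best_bps = rss, topology_bipartitions(edges, ids)
    return best_bps
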