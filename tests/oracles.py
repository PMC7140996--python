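"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over definitions, deliberately
avoiding the vectorized/heuristic code paths of the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def nodf_brute(m) -> float:
    """NODF by looping over every ordered row pair and column pair."""
    m = np.asarray(m)
    total = 0.0

    def line_terms(lines):
        s = 0.0
        for hi, lo in itertools.permutations(range(len(lines)), 2):
            fill_hi = sum(lines[hi])
            fill_lo = sum(lines[lo])
            if fill_hi > fill_lo > 0:
                shared = sum(
                    1 for k in range(len(lines[hi])) if lines[hi][k] and lines[lo][k]
                )
                s += 100.0 * shared / fill_lo
        return s

    rows = [list(r) for r in m]
    cols = [list(c) for c in m.T]
    n_pairs = len(rows) * (len(rows) - 1) / 2 + len(cols) * (len(cols) - 1) / 2
    total = line_terms(rows) + line_terms(cols)
    return total / n_pairs


def wnodf_brute(m) -> float:
    """Weighted NODF by looping over ordered line pairs."""
    m = np.asarray(m, dtype=float)

    def line_terms(lines):
        s = 0.0
        for hi, lo in itertools.permutations(range(len(lines)), 2):
            if sum(lines[hi]) > sum(lines[lo]):
                nz = [k for k in range(len(lines[lo])) if lines[lo][k] > 0]
                if not nz:
                    continue
                smaller = sum(1 for k in nz if lines[lo][k] < lines[hi][k])
                s += 100.0 * smaller / len(nz)
        return s

    rows = [list(r) for r in m]
    cols = [list(c) for c in m.T]
    n_pairs = len(rows) * (len(rows) - 1) / 2 + len(cols) * (len(cols) - 1) / 2
    return (line_terms(rows) + line_terms(cols)) / n_pairs


def discrepancy_brute(m) -> int:
    """Minimal misplaced 1s over every maximal nested matrix with the
    observed row sums (each candidate packs rows under one column order)."""
    m = np.asarray(m, dtype=int)
    r, c = m.shape
    row_sums = [int(m[i].sum()) for i in range(r)]
    best = None
    for perm in itertools.permutations(range(c)):
        nested = np.zeros((r, c), dtype=int)
        for i in range(r):
            for pos in range(row_sums[i]):
                nested[i, perm[pos]] = 1
        misplaced = int(((m == 1) & (nested == 0)).sum())
        if best is None or misplaced < best:
            best = misplaced
    return best


def spectral_brute(m) -> float:
    """Largest eigenvalue of the symmetric (r+c) x (r+c) bipartite adjacency."""
    m = np.asarray(m, dtype=float)
    r, c = m.shape
    adj = np.zeros((r + c, r + c))
    adj[:r, r:] = m
    adj[r:, :r] = m.T
    return float(np.max(np.linalg.eigvalsh(adj)))


def max_nodf_brute(r: int, c: int, links: int) -> float:
    """Exhaustive max NODF over every placement of ``links`` cells."""
    best = 0.0
    for combo in itertools.combinations(itertools.product(range(r), range(c)), links):
        m = np.zeros((r, c), dtype=int)
        for i, j in combo:
            m[i, j] = 1
        best = max(best, nodf_brute(m))
    return best


def _canon(sub: np.ndarray) -> tuple:
    """Side-respecting canonical form: minimal bit tuple over permutations."""
    p, a = sub.shape
    return min(
        tuple(int(x) for x in sub[list(rp), :][:, list(cp)].ravel())
        for rp in itertools.permutations(range(p))
        for cp in itertools.permutations(range(a))
    )


def motif_counts_brute(m) -> dict[tuple, int]:
    """Counts of connected induced subgraphs of 2-5 nodes, keyed by
    (n_plants, n_pollinators, canonical bits), via full subset enumeration."""
    m = np.asarray(m, dtype=int)
    r, c = m.shape
    counts: dict[tuple, int] = {}
    nodes = list(range(r + c))
    for size in range(2, 6):
        for subset in itertools.combinations(nodes, size):
            plants = [v for v in subset if v < r]
            polls = [v - r for v in subset if v >= r]
            if not plants or not polls:
                continue
            sub = m[np.ix_(plants, polls)]
            if not _subset_connected(sub):
                continue
            key = (len(plants), len(polls), _canon(sub))
            counts[key] = counts.get(key, 0) + 1
    return counts


def _subset_connected(sub: np.ndarray) -> bool:
    p, a = sub.shape
    n = p + a
    seen = {0}
    frontier = [0]
    while frontier:
        v = frontier.pop()
        if v < p:
            nxt = [p + j for j in range(a) if sub[v, j]]
        else:
            nxt = [i for i in range(p) if sub[i, v - p]]
        for u in nxt:
            if u not in seen:
                seen.add(u)
                frontier.append(u)
    return len(seen) == n


def modularity_q_brute(m, row_labels, col_labels) -> float:
    """Barber bipartite modularity evaluated cell by cell."""
    m = np.asarray(m, dtype=float)
    E = m.sum()
    q = 0.0
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if row_labels[i] == col_labels[j]:
                q += m[i, j] / E - m[i].sum() * m[:, j].sum() / E**2
    return q


def _set_partitions(items: list):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_brute(m) -> float:
    """Maximum Barber modularity over every partition of all taxa."""
    m = np.asarray(m, dtype=float)
    r, c = m.shape
    best = -np.inf
    for part in _set_partitions(list(range(r + c))):
        g = [0] * r
        h = [0] * c
        for lab, block in enumerate(part):
            for v in block:
                if v < r:
                    g[v] = lab
                else:
                    h[v - r] = lab
        best = max(best, modularity_q_brute(m, g, h))
    return best
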