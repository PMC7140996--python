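"""Census of the 17 connected bipartite motifs with up to five nodes.

A motif is a connected two-mode graph whose plant and pollinator sides are
distinguishable (a 1-plant/2-pollinator star differs from a 2-plant/
1-pollinator star).  Exhaustive generation over 2-5 nodes, deduplicated by
within-side permutation isomorphism, yields exactly 17 motifs: one with 2
nodes, two with 3, four with 4, and ten with 5.

Occurrences use induced-subgraph semantics: a node subset counts for
exactly the one motif formed by the edges it induces, and only connected
subsets count.  Per-motif frequencies are normalized within each node-count
class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .network import BipartiteNetwork, NetworkError

MAX_MOTIF_NODES = 5


@dataclass(frozen=True)
class Motif:
    motif_id: int
    n_nodes: int
    n_plants: int
    n_pollinators: int
    #: canonical incidence bits, row-major over the n_plants x n_pollinators grid
    canonical: tuple[int, ...]


def _canonical_bits(matrix: np.ndarray) -> tuple[int, ...]:
    """Lexicographically smallest bit string over within-side permutations."""
    p, a = matrix.shape
    best = None
    for rp in itertools.permutations(range(p)):
        sub = matrix[list(rp), :]
        for cp in itertools.permutations(range(a)):
            bits = tuple(int(x) for x in sub[:, list(cp)].ravel())
            if best is None or bits < best:
                best = bits
    return best


def _is_connected(matrix: np.ndarray) -> bool:
    p, a = matrix.shape
    n = p + a
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        if v < p:
            nbrs = [p + j for j in range(a) if matrix[v, j]]
        else:
            nbrs = [i for i in range(p) if matrix[i, v - p]]
        for u in nbrs:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


@lru_cache(maxsize=1)
def build_catalogue() -> tuple[Motif, ...]:
    """Enumerate all side-labelled connected bipartite motifs on 2-5 nodes."""
    found: dict[tuple[int, int, tuple[int, ...]], None] = {}
    for n in range(2, MAX_MOTIF_NODES + 1):
        for p in range(1, n):
            a = n - p
            for bits in itertools.product((0, 1), repeat=p * a):
                m = np.array(bits).reshape(p, a)
                if (m.sum(axis=1) == 0).any() or (m.sum(axis=0) == 0).any():
                    continue
                if not _is_connected(m):
                    continue
                found.setdefault((p, a, _canonical_bits(m)))
    ordered = sorted(found, key=lambda k: (k[0] + k[1], k[0], k[2]))
    return tuple(
        Motif(
            motif_id=i + 1,
            n_nodes=p + a,
            n_plants=p,
            n_pollinators=a,
            canonical=bits,
        )
        for i, (p, a, bits) in enumerate(ordered)
    )


@lru_cache(maxsize=1)
def _catalogue_lookup() -> dict[tuple[int, int, tuple[int, ...]], int]:
    return {
        (m.n_plants, m.n_pollinators, m.canonical): m.motif_id
        for m in build_catalogue()
    }


@dataclass(frozen=True)
class MotifCensus:
    counts: dict[int, int]
    frequencies: dict[int, float]

    def as_rows(self):
        cat = build_catalogue()
        return [
            {
                "motif_id": m.motif_id,
                "nodes": m.n_nodes,
                "count": self.counts[m.motif_id],
                "frequency": self.frequencies[m.motif_id],
            }
            for m in cat
        ]


def _connected_subsets(adj: list[set[int]], max_size: int):
    """Yield every connected node subset of size 2..max_size exactly once.

    Standard ESU enumeration: grow from each root v using only nodes with
    id > v, extending with exclusive neighbors so each subset appears once.
    """
    n = len(adj)
    for v in range(n):
        sub = [v]
        ext = sorted(u for u in adj[v] if u > v)
        yield from _esu_extend(adj, v, sub, ext, max_size)


def _esu_extend(adj, root, sub, ext, max_size):
    if len(sub) >= 2:
        yield tuple(sub)
    if len(sub) == max_size:
        return
    seen_nbrs = set().union(*(adj[x] for x in sub))
    ext = list(ext)
    while ext:
        u = ext.pop()
        new_ext = ext + [
            w for w in adj[u] if w > root and w not in seen_nbrs and w not in sub
        ]
        yield from _esu_extend(adj, root, sub + [u], new_ext, max_size)


def motif_census(net: BipartiteNetwork) -> MotifCensus:
    """Exact induced-subgraph motif counts and within-size frequencies."""
    if net.weighted:
        raise NetworkError("motif census requires a binary network")
    m = net.matrix
    r, c = m.shape
    adj: list[set[int]] = [set() for _ in range(r + c)]
    for i, j in zip(*np.nonzero(m)):
        adj[i].add(r + j)
        adj[r + j].add(int(i))

    lookup = _catalogue_lookup()
    cat = build_catalogue()
    counts = {mot.motif_id: 0 for mot in cat}
    canon_cache: dict[tuple, int] = {}
    for subset in _connected_subsets(adj, MAX_MOTIF_NODES):
        plants = [v for v in subset if v < r]
        polls = [v - r for v in subset if v >= r]
        if not plants or not polls:
            continue
        sub = m[np.ix_(plants, polls)].astype(int)
        key = (len(plants), len(polls), tuple(sub.ravel()))
        mid = canon_cache.get(key)
        if mid is None:
            mid = lookup[(len(plants), len(polls), _canonical_bits(sub))]
            canon_cache[key] = mid
        counts[mid] += 1

    class_totals: dict[int, int] = {}
    for mot in cat:
        class_totals[mot.n_nodes] = class_totals.get(mot.n_nodes, 0) + counts[mot.motif_id]
    freqs = {
        mot.motif_id: (
            counts[mot.motif_id] / class_totals[mot.n_nodes]
            if class_totals[mot.n_nodes] > 0
            else 0.0
        )
        for mot in cat
    }
    return MotifCensus(counts=counts, frequencies=freqs)
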