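"""Network indices defined on presence/absence matrices.

Connectance, NODF nestedness, Brualdi-Sanderson discrepancy, spectral
radius, robustness to pollinator loss, and normalized-degree quartiles.
"""

from __future__ import annotations

import itertools

import numpy as np

from .network import BipartiteNetwork, NetworkError


def _binary_matrix(net: BipartiteNetwork) -> np.ndarray:
    if net.weighted:
        raise NetworkError("index requires a binary network (binarize first)")
    return net.matrix


def connectance(net: BipartiteNetwork) -> float:
    """Realized links divided by possible links, F / (r*c)."""
    m = _binary_matrix(net)
    return float(m.sum() / m.size)


def nodf_matrix(matrix: np.ndarray) -> float:
    """NODF of a 0/1 array (rows and columns both >= 2).

    For every ordered line pair whose first line has strictly greater fill
    (and the poorer line nonzero fill), the pair contributes
    100 * overlap / poorer-fill; all other pairs contribute 0.  NODF is the
    mean over the r*(r-1)/2 row pairs and c*(c-1)/2 column pairs.  Empty
    lines simply contribute zero-valued pairs, so null-model draws with
    empty rows keep a size-consistent denominator.
    """
    m = np.asarray(matrix, dtype=float)
    r, c = m.shape
    if r < 2 or c < 2:
        raise NetworkError("NODF needs at least 2 rows and 2 columns")

    def _pair_sum(a: np.ndarray) -> float:
        fills = a.sum(axis=1)
        overlap = a @ a.T
        fi = fills[:, None]
        fj = fills[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where((fi > fj) & (fj > 0), overlap / np.where(fj > 0, fj, 1), 0.0)
        return float(terms.sum())

    n_pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return 100.0 * (_pair_sum(m) + _pair_sum(m.T)) / n_pairs


def nodf(net: BipartiteNetwork) -> float:
    """Nestedness based on overlap and decreasing fill, in [0, 100]."""
    return nodf_matrix(_binary_matrix(net))


def _packed_mismatch(m: np.ndarray, col_order: np.ndarray) -> int:
    """Ones of ``m`` falling outside the row-sum-packed nested matrix."""
    row_sums = m.sum(axis=1).astype(int)
    ordered = m[:, col_order]
    # packed matrix: row i has ones in the first row_sums[i] ordered columns
    cols = np.arange(m.shape[1])[None, :]
    packed = cols < row_sums[:, None]
    return int(np.logical_and(ordered > 0, ~packed).sum())


def discrepancy(net: BipartiteNetwork, exact_max_cols: int = 7) -> int:
    """Brualdi-Sanderson discrepancy BR.

    The minimal number of 1s that must move to turn the matrix into a
    perfectly nested one with the same dimensions, link count, and row
    sums.  Candidate nested matrices pack each row's links into a prefix of
    some common column order; for up to ``exact_max_cols`` columns every
    order is tried (exact), beyond that columns are sorted by decreasing
    column total and a hill climb over swaps of equal-total columns refines
    the order.
    """
    m = _binary_matrix(net)
    c = m.shape[1]
    if c <= exact_max_cols:
        return min(
            _packed_mismatch(m, np.array(perm))
            for perm in itertools.permutations(range(c))
        )
    col_sums = m.sum(axis=0)
    order = np.argsort(-col_sums, kind="stable")
    best = _packed_mismatch(m, order)
    improved = True
    while improved:
        improved = False
        for i in range(c - 1):
            for j in range(i + 1, c):
                if col_sums[order[i]] != col_sums[order[j]]:
                    continue
                cand = order.copy()
                cand[i], cand[j] = cand[j], cand[i]
                val = _packed_mismatch(m, cand)
                if val < best:
                    best, order, improved = val, cand, True
    return best


def spectral_radius(net: BipartiteNetwork) -> float:
    """Largest eigenvalue of the symmetric bipartite adjacency matrix.

    Computed as the largest singular value of the plants x pollinators
    matrix, which is numerically identical and works for binary (SR_Bin)
    and weighted (SR_Qua) input alike.
    """
    m = net.matrix
    if not m.any():
        raise NetworkError("spectral radius of an all-zero matrix is undefined")
    return float(np.linalg.svd(m, compute_uv=False)[0])


def robustness(
    net: BipartiteNetwork,
    n_sequences: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Area under the attack tolerance curve for random pollinator loss.

    Pollinators are removed one at a time in uniformly random order; a
    plant goes extinct once all its partners are gone (static preferences).
    The curve plots the surviving-plant fraction against the
    remaining-pollinator fraction (c-j)/c for j = 0..c and is integrated by
    the trapezoidal rule; the result is averaged over ``n_sequences``
    random removal orders and lies in [0, 1].
    """
    m = _binary_matrix(net)
    if (m.sum(axis=1) == 0).any():
        raise NetworkError("robustness requires no all-zero plant rows")
    if n_sequences < 1:
        raise NetworkError("n_sequences must be >= 1")
    rng = np.random.default_rng(seed)
    r, c = m.shape
    areas = np.empty(n_sequences)
    support = m > 0
    for s in range(n_sequences):
        perm = rng.permutation(c)
        # removal step (1-based) at which each pollinator disappears
        step = np.empty(c, dtype=int)
        step[perm] = np.arange(1, c + 1)
        # a plant survives until its last partner is removed
        death = np.where(support, step[None, :], 0).max(axis=1)
        # survivors after j removals, j = 0..c
        y = (death[None, :] > np.arange(c + 1)[:, None]).sum(axis=1) / r
        x = (c - np.arange(c + 1)) / c
        areas[s] = np.trapezoid(y[::-1], x[::-1])
    return float(areas.mean())


def normalized_degree_quartiles(net: BipartiteNetwork) -> tuple[float, float, float]:
    """(Q1, median, Q3) of normalized degree, pooled over both guilds.

    Each plant's normalized degree is its row sum over the number of
    pollinators, and vice versa; quartiles use linear interpolation between
    order statistics.
    """
    m = _binary_matrix(net)
    r, c = m.shape
    degrees = np.concatenate([m.sum(axis=1) / c, m.sum(axis=0) / r])
    q1, med, q3 = np.quantile(degrees, [0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)
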