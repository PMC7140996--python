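"""Null-model ensembles and nestedness standardization.

Three randomizations are provided:

* ``DD`` (degreeprobable-degreeprobable) for binary matrices: each cell is
  an independent Bernoulli draw with p_ij = (d_j/r + k_i/c)/2, where d_j is
  the column degree, k_i the row degree, and r, c the matrix dimensions.
* ``RTCA`` (row and column total average) for weighted matrices: the mean
  of a matrix that redistributes each row total over its row by a uniform
  random composition and one that does the same per column.
* ``r2dtable`` (Patefield): uniform random contingency tables with exactly
  the observed integer row and column totals.

Observed index values are standardized as Z = (observed - null mean) /
null standard deviation over a default ensemble of 500 draws, and NODF can
additionally be normalized as NODF_c = (NODF / max NODF) / (C * ln S) with
C the connectance and S the geometric mean of the two guild richnesses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import random_table

from .binary_indices import connectance, discrepancy, nodf, nodf_matrix
from .network import BipartiteNetwork, NetworkError, binarize
from .weighted_indices import wnodf_matrix

N_NULL_DEFAULT = 500

#: null model used for each standardized index; weighted indices are
#: standardized under both weighted nulls
INDEX_NULL_PAIRING = {
    "NODF": ("DD",),
    "BR": ("DD",),
    "SR_Bin": ("DD",),
    "WNODF": ("RTCA", "r2dtable"),
    "SR_Qua": ("RTCA", "r2dtable"),
}


def null_dd(
    net: BipartiteNetwork,
    n_null: int = N_NULL_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Binary degree-probable nulls; returns an (n_null, r, c) 0/1 array.

    Cell probabilities follow the observed degree distribution, so the
    expected fill of every draw equals the observed fill exactly.  Draws
    may contain empty rows or columns; dimensions are never altered.
    """
    if net.weighted:
        raise NetworkError("DD null model applies to binary networks")
    m = net.matrix
    r, c = m.shape
    k = m.sum(axis=1)  # row degrees
    d = m.sum(axis=0)  # column degrees
    p = 0.5 * (d[None, :] / r + k[:, None] / c)
    rng = np.random.default_rng(seed)
    return (rng.random((n_null, r, c)) < p[None, :, :]).astype(float)


def null_rtca(
    net: BipartiteNetwork,
    n_null: int = N_NULL_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Row-and-column-total-average weighted nulls, (n_null, r, c).

    Each draw averages a row-conserving matrix (every row total split by a
    uniform random composition) and the analogous column-conserving matrix,
    so entries are non-negative and the grand total is preserved exactly.
    """
    if not net.weighted:
        raise NetworkError("RTCA null model applies to weighted networks")
    m = net.matrix
    r, c = m.shape
    rng = np.random.default_rng(seed)
    row_tot = m.sum(axis=1)
    col_tot = m.sum(axis=0)
    out = np.empty((n_null, r, c))
    for t in range(n_null):
        u = rng.random((r, c))
        by_row = u / u.sum(axis=1, keepdims=True) * row_tot[:, None]
        v = rng.random((r, c))
        by_col = v / v.sum(axis=0, keepdims=True) * col_tot[None, :]
        out[t] = 0.5 * (by_row + by_col)
    return out


def null_patefield(
    net: BipartiteNetwork,
    n_null: int = N_NULL_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Patefield r2dtable nulls: uniform tables with the observed margins."""
    m = net.matrix
    if not np.allclose(m, np.round(m)):
        raise NetworkError("r2dtable requires integer counts")
    counts = np.round(m).astype(int)
    if 1 in m.shape:
        # the margins force the table
        return np.broadcast_to(counts, (n_null,) + m.shape).astype(float).copy()
    rng = np.random.default_rng(seed)
    tables = random_table(counts.sum(axis=1), counts.sum(axis=0)).rvs(
        n_null, method="patefield", random_state=rng
    )
    return np.asarray(tables, dtype=float).reshape((n_null,) + m.shape)


def z_score(observed: float, null_values) -> float:
    """(observed - null mean) / null sample standard deviation (ddof=1)."""
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size < 2:
        raise NetworkError("z-score needs at least 2 null values")
    sd = nulls.std(ddof=1)
    if sd == 0:
        raise NetworkError("degenerate null: zero standard deviation")
    return float((observed - nulls.mean()) / sd)


@dataclass(frozen=True)
class NullEnsemble:
    observed_value: float
    null_values: tuple[float, ...]
    null_model: str
    index_name: str
    z_score: float


def _sr_matrix(m: np.ndarray) -> float:
    return float(np.linalg.svd(m, compute_uv=False)[0])


def _discrepancy_matrix(m: np.ndarray) -> float:
    from .network import BipartiteNetwork

    if not m.any():
        return 0.0
    return float(
        discrepancy(
            BipartiteNetwork(
                m, tuple(map(str, range(m.shape[0]))),
                tuple(map(str, range(m.shape[1]))), weighted=False,
            )
        )
    )


_INDEX_FUNCS = {
    "NODF": nodf_matrix,
    "BR": _discrepancy_matrix,
    "SR_Bin": _sr_matrix,
    "SR_Qua": _sr_matrix,
    "WNODF": wnodf_matrix,
}

_NULL_FUNCS = {"DD": null_dd, "RTCA": null_rtca, "r2dtable": null_patefield}


def null_ensemble(
    net: BipartiteNetwork,
    index_name: str,
    null_model: str,
    n_null: int = N_NULL_DEFAULT,
    seed: int | np.random.Generator | None = None,
) -> NullEnsemble:
    """Standardize one nestedness index against one null model."""
    if index_name not in _INDEX_FUNCS:
        raise NetworkError(f"no null standardization for index {index_name!r}")
    if null_model not in _NULL_FUNCS:
        raise NetworkError(f"unknown null model {null_model!r}")
    if null_model not in INDEX_NULL_PAIRING[index_name]:
        raise NetworkError(
            f"null model {null_model!r} is not paired with {index_name!r}"
        )
    func = _INDEX_FUNCS[index_name]
    observed = float(func(net.matrix))
    draws = _NULL_FUNCS[null_model](net, n_null=n_null, seed=seed)
    nulls = tuple(float(func(d)) for d in draws)
    return NullEnsemble(
        observed_value=observed,
        null_values=nulls,
        null_model=null_model,
        index_name=index_name,
        z_score=z_score(observed, nulls),
    )


# ---------------------------------------------------------------------------
# maximal NODF and the connectance/size-corrected NODF_c


def _young_diagram_nodf(fills: np.ndarray, c: int) -> float:
    """NODF of the staircase matrix whose row i fills its first fills[i] cells."""
    r = len(fills)
    m = (np.arange(c)[None, :] < fills[:, None]).astype(float)
    return nodf_matrix(m)


def max_nodf(r: int, c: int, links: int, exact_max_cells: int = 16) -> float:
    """Maximal NODF attainable with r rows, c columns, and ``links`` links.

    Exhaustive over all cell placements when r*c <= ``exact_max_cells``;
    otherwise a nested staircase is built greedily (cells added in order of
    increasing (i+1)*(j+1)) and refined by hill-climbing single-cell moves
    between staircase corners.
    """
    if r < 2 or c < 2:
        raise NetworkError("max NODF needs at least 2 rows and 2 columns")
    if links < 1 or links > r * c:
        raise NetworkError(f"infeasible link count {links} for a {r}x{c} matrix")

    if r * c <= exact_max_cells:
        best = 0.0
        cells = list(itertools.product(range(r), range(c)))
        for combo in itertools.combinations(cells, links):
            m = np.zeros((r, c))
            for i, j in combo:
                m[i, j] = 1.0
            best = max(best, nodf_matrix(m))
        return best

    # greedy nested fill: cells ranked by (i+1)(j+1) form a Young diagram
    order = sorted(
        itertools.product(range(r), range(c)),
        key=lambda ij: ((ij[0] + 1) * (ij[1] + 1), ij[0] + ij[1], ij[0]),
    )
    fills = np.zeros(r, dtype=int)
    for i, _ in order[:links]:
        fills[i] += 1
    fills[::-1].sort()
    best = _young_diagram_nodf(fills, c)
    improved = True
    while improved:
        improved = False
        for src in range(r):
            for dst in range(r):
                if src == dst:
                    continue
                f = fills.copy()
                f[src] -= 1
                f[dst] += 1
                if f[src] < 0 or f[dst] > c:
                    continue
                f[::-1].sort()
                val = _young_diagram_nodf(f, c)
                if val > best + 1e-12:
                    best, fills, improved = val, f, True
    return best


@dataclass(frozen=True)
class NodfcResult:
    nodf: float
    max_nodf: float
    nodf_n: float
    connectance: float
    s_geometric: float
    nodf_c: float


def nodf_c(net: BipartiteNetwork) -> NodfcResult:
    """Connectance- and size-corrected NODF: (NODF/maxNODF) / (C * ln S)."""
    bnet = binarize(net)
    r, c = bnet.matrix.shape
    s = float(np.sqrt(r * c))
    if s <= 1:
        raise NetworkError("NODF_c undefined for S <= 1")
    observed = nodf(bnet)
    links = int(bnet.matrix.sum())
    mx = max_nodf(r, c, links)
    conn = connectance(bnet)
    nodf_n = observed / mx if mx > 0 else 0.0
    return NodfcResult(
        nodf=observed,
        max_nodf=mx,
        nodf_n=nodf_n,
        connectance=conn,
        s_geometric=s,
        nodf_c=nodf_n / (conn * np.log(s)),
    )
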