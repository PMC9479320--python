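"""Persistent homology: boundary-matrix reduction, oracles, distances.

The engine computes persistence diagrams of a :class:`FilteredComplex` over
Z/2 with the standard column-reduction algorithm (columns as Python integer
bitmasks; the low of a column is its highest set bit).  Complexes here are
small enough that the plain algorithm is preferable to twist/clearing
optimizations.

Two independent routes guard correctness:

* :func:`betti_at` recomputes β0 by union-find and β1 by GF(2) rank (or the
  planar Euler formula) at a single threshold, without touching the
  reduction.
* :func:`cubical_persistence` computes cubical diagrams directly from the
  pixel grid by two union-find sweeps — the ascending sweep pairs components
  (dim 0), the descending sweep on the complement of the sublevel set pairs
  loops (dim 1) via planar duality.  It is the fast path for large patches
  and must agree with :func:`reduce_complex` on the cell complex.

Diagrams exclude zero-persistence intervals by default (``keep_zero=True``
retains them); essential classes carry death = +inf.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, InvariantViolation, SizeError, UsageError
from .filtration import FilteredComplex, lower_star_cubical
from .preprocess import as_patch

__all__ = [
    "PersistenceDiagram",
    "reduce_complex",
    "betti_at",
    "diagram_to_betti_curve",
    "cubical_persistence",
    "bottleneck_distance",
]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (dimension, birth, death) intervals; death may be +inf."""

    dims: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    source_label: str = ""
    shift: float = 0.0  # additive shift applied to the underlying filtration

    def __post_init__(self):
        object.__setattr__(self, "dims", np.asarray(self.dims, dtype=int))
        object.__setattr__(self, "births", np.asarray(self.births, dtype=float))
        object.__setattr__(self, "deaths", np.asarray(self.deaths, dtype=float))
        if not (len(self.dims) == len(self.births) == len(self.deaths)):
            raise InputError("diagram arrays have inconsistent lengths")
        if np.any(self.births > self.deaths):
            raise InputError("diagram has an interval with birth > death")

    def __len__(self) -> int:
        return len(self.dims)

    def intervals(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(births, deaths) of all dim-k intervals."""
        sel = self.dims == k
        return self.births[sel], self.deaths[sel]

    def finite(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        sel = (self.dims == k) & np.isfinite(self.deaths)
        return self.births[sel], self.deaths[sel]

    def n_essential(self, k: int) -> int:
        return int(np.sum((self.dims == k) & np.isinf(self.deaths)))

    def _sorted_key(self):
        order = np.lexsort((self.deaths, self.births, self.dims))
        return (
            self.dims[order],
            self.births[order],
            np.where(np.isinf(self.deaths[order]), np.inf, self.deaths[order]),
        )

    def same_intervals(self, other: "PersistenceDiagram", tol: float = 1e-9) -> bool:
        """True when the two multisets of intervals agree up to ``tol``."""
        if len(self) != len(other):
            return False
        d1, b1, e1 = self._sorted_key()
        d2, b2, e2 = other._sorted_key()
        if not np.array_equal(d1, d2):
            return False
        fin = np.isfinite(e1)
        if not np.array_equal(fin, np.isfinite(e2)):
            return False
        return bool(
            np.allclose(b1, b2, atol=tol)
            and np.allclose(e1[fin], e2[fin], atol=tol)
        )

    def to_tsv(self, path) -> None:
        """TSV columns dim, birth, death; essential deaths rendered 'inf'."""
        with open(path, "w") as fh:
            fh.write("dim\tbirth\tdeath\n")
            order = np.lexsort((self.deaths, self.births, self.dims))
            for i in order:
                death = "inf" if np.isinf(self.deaths[i]) else f"{self.deaths[i]:.10g}"
                fh.write(f"{self.dims[i]}\t{self.births[i]:.10g}\t{death}\n")

    @classmethod
    def from_tsv(cls, path, source_label: str = "") -> "PersistenceDiagram":
        dims, births, deaths = [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("dim"):
                raise InputError(f"{path}: missing diagram header")
            for line in fh:
                d, b, dd = line.split("\t")
                dims.append(int(d))
                births.append(float(b))
                deaths.append(float(dd))
        return cls(np.array(dims), np.array(births), np.array(deaths),
                   source_label=source_label)


# ---------------------------------------------------------------------------
# Standard reduction


def reduce_complex(
    fc: FilteredComplex, keep_zero: bool = False, validate: bool = True,
    source_label: str = "",
) -> PersistenceDiagram:
    """Persistence diagram of a filtered complex by Z/2 column reduction.

    Cells are processed in (value, dim, id) order; each column is reduced by
    earlier columns sharing its lowest nonzero row until empty (positive
    cell) or a new pivot (pairing the pivot row's cell as birth with the
    current cell as death).  Unpaired positive cells of dimension ≤ 1 become
    essential intervals.
    """
    if validate:
        fc.validate()
    order = fc.sorted_order()
    pos_of = np.empty(fc.n_cells, dtype=int)
    pos_of[order] = np.arange(fc.n_cells)

    columns: dict[int, int] = {}  # pivot row -> reduced column (bitmask)
    pivot_death: dict[int, int] = {}  # pivot row -> death position
    paired: set[int] = set()
    pairs: list[tuple[int, int]] = []

    for pos in range(fc.n_cells):
        cid = order[pos]
        col = 0
        for b in fc.boundaries[cid]:
            col ^= 1 << int(pos_of[b])
        while col:
            low = col.bit_length() - 1
            if low not in columns:
                break
            col ^= columns[low]
        if col:
            low = col.bit_length() - 1
            columns[low] = col
            pivot_death[low] = pos
            paired.add(low)
            pairs.append((low, pos))
        # else: positive cell, may be paired later or stay essential

    dims, births, deaths = [], [], []
    for birth_pos, death_pos in pairs:
        b_id, d_id = order[birth_pos], order[death_pos]
        k = int(fc.dims[b_id])
        if k > 1:
            continue
        b, d = float(fc.values[b_id]), float(fc.values[d_id])
        if not keep_zero and b == d:
            continue
        dims.append(k)
        births.append(b)
        deaths.append(d)
    death_positions = set(pivot_death.values())
    for pos in range(fc.n_cells):
        if pos in paired or pos in death_positions:
            continue
        cid = order[pos]
        k = int(fc.dims[cid])
        if k > 1:
            continue
        dims.append(k)
        births.append(float(fc.values[cid]))
        deaths.append(math.inf)
    return PersistenceDiagram(
        np.array(dims, dtype=int),
        np.array(births),
        np.array(deaths),
        source_label=source_label,
        shift=fc.shift,
    )


# ---------------------------------------------------------------------------
# Brute-force oracles


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]  # path halving
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _gf2_rank(columns: list[int]) -> int:
    """Rank of a GF(2) matrix whose columns are integer bitmasks."""
    pivots: dict[int, int] = {}
    rank = 0
    for col in columns:
        while col:
            low = col.bit_length() - 1
            if low not in pivots:
                pivots[low] = col
                rank += 1
                break
            col ^= pivots[low]
    return rank


def betti_at(fc: FilteredComplex, k: int, t: float) -> int:
    """β_k of the sublevel complex at threshold t — independent oracle.

    β0 by union-find over present vertices and edges; β1 as
    (#edges − rank ∂1) − rank ∂2 over GF(2).  Shares no code with
    :func:`reduce_complex`.
    """
    if k not in (0, 1):
        raise UsageError(f"k must be 0 or 1, got {k}")
    present = fc.values <= t
    vert_ids = np.nonzero(present & (fc.dims == 0))[0]
    if k == 0:
        index = {int(v): i for i, v in enumerate(vert_ids)}
        uf = _UnionFind(len(vert_ids))
        n_comp = len(vert_ids)
        for e in np.nonzero(present & (fc.dims == 1))[0]:
            u, v = fc.boundaries[e]
            if uf.union(index[int(u)], index[int(v)]):
                n_comp -= 1
        return n_comp
    vindex = {int(v): i for i, v in enumerate(vert_ids)}
    edge_ids = np.nonzero(present & (fc.dims == 1))[0]
    eindex = {int(e): i for i, e in enumerate(edge_ids)}
    d1 = []
    for e in edge_ids:
        u, v = fc.boundaries[e]
        d1.append((1 << vindex[int(u)]) | (1 << vindex[int(v)]))
    d2 = []
    for f in np.nonzero(present & (fc.dims == 2))[0]:
        col = 0
        for e in fc.boundaries[f]:
            col ^= 1 << eindex[int(e)]
        d2.append(col)
    return (len(edge_ids) - _gf2_rank(d1)) - _gf2_rank(d2)


# ---------------------------------------------------------------------------
# Betti curves from diagrams


def diagram_to_betti_curve(diagram: PersistenceDiagram, k: int, thresholds):
    """β_k(t) = #{intervals of dim k with birth ≤ t < death} on a grid.

    ``thresholds`` must be strictly increasing.  Returns a
    :class:`fatph.summaries.BettiCurve`.
    """
    from .summaries import BettiCurve

    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise InputError("thresholds must be a nonempty 1D sequence")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise InputError("thresholds must be strictly increasing")
    births, deaths = diagram.intervals(k)
    b = np.sort(births)
    d = np.sort(deaths[np.isfinite(deaths)])
    values = np.searchsorted(b, t, side="right") - np.searchsorted(d, t, side="right")
    return BettiCurve(k=k, thresholds=t, values=values.astype(int))


# ---------------------------------------------------------------------------
# Fast cubical persistence (union-find, both dimensions)


def _pairs_from_merges(uf: _UnionFind, birth_of_root, merges, keep_zero: bool):
    """Shared elder-rule merge loop.

    ``merges`` yields (value, a, b); the younger root (larger birth in the
    ascending sweep) dies at the merge value.
    """
    births, deaths = [], []
    for value, a, b in merges:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        if birth_of_root[ra] <= birth_of_root[rb]:
            elder, younger = ra, rb
        else:
            elder, younger = rb, ra
        uf.parent[younger] = elder
        b_y = birth_of_root[younger]
        if keep_zero or b_y != value:
            births.append(b_y)
            deaths.append(value)
    return births, deaths


def cubical_persistence(
    patch, keep_zero: bool = False, apply_shift: bool = True, source_label: str = "",
) -> PersistenceDiagram:
    """Persistence diagram of the sublevel cubical filtration of a patch.

    Dimension 0 is computed by Kruskal-style union-find over pixels and
    4-adjacent edges with the elder rule.  Dimension 1 uses planar duality:
    a loop of the sublevel set encloses a bounded component of its
    complement, so dim-1 intervals are read off a descending union-find
    sweep over the complement squares of the (+inf-padded) image — a loop
    born at b and filled at d corresponds to a complement component created
    at d that merges into an older one at b.

    Agrees with ``reduce_complex(lower_star_cubical(patch))`` up to
    zero-persistence intervals; used as the fast path on large patches.
    """
    arr = as_patch(patch)
    shift = 0.0
    if apply_shift and arr.min() < 0:
        shift = -float(arr.min())
        arr = arr + shift
    r, c = arr.shape
    flat = arr.ravel()

    # --- dimension 0: ascending sweep over pixels and 4-adjacency edges
    edges_u: list[int] = []
    edges_v: list[int] = []
    if c > 1:
        left = (np.arange(r * c).reshape(r, c)[:, :-1]).ravel()
        edges_u.extend(left.tolist())
        edges_v.extend((left + 1).tolist())
    if r > 1:
        top = (np.arange(r * c).reshape(r, c)[:-1, :]).ravel()
        edges_u.extend(top.tolist())
        edges_v.extend((top + c).tolist())
    eu = np.array(edges_u, dtype=int)
    ev = np.array(edges_v, dtype=int)
    evals = np.maximum(flat[eu], flat[ev]) if len(eu) else np.empty(0)
    order = np.argsort(evals, kind="stable")

    uf = _UnionFind(r * c)
    births0, deaths0 = _pairs_from_merges(
        uf,
        flat,
        ((float(evals[i]), int(eu[i]), int(ev[i])) for i in order),
        keep_zero,
    )
    dims = [0] * len(births0)
    births = list(births0)
    deaths = list(deaths0)
    # single essential dim-0 class at the global minimum
    dims.append(0)
    births.append(float(flat.min()))
    deaths.append(math.inf)

    # --- dimension 1: descending sweep over complement squares of the
    # padded image (dual graph: edge-adjacent squares connect through their
    # two shared pixels, corner-adjacent through the one shared pixel).
    big = float(flat.max()) + 1.0
    pad = np.full((r + 2, c + 2), big)
    pad[1:-1, 1:-1] = arr
    # squares of the padded grid: (r+1) x (c+1), value = max of 4 pixels
    sq = np.maximum(
        np.maximum(pad[:-1, :-1], pad[:-1, 1:]),
        np.maximum(pad[1:, :-1], pad[1:, 1:]),
    )
    R, C = sq.shape
    sid = np.arange(R * C).reshape(R, C)
    sflat = sq.ravel()

    conn_u: list[np.ndarray] = []
    conn_v: list[np.ndarray] = []
    conn_w: list[np.ndarray] = []
    # horizontal neighbors (i,j)-(i,j+1): shared pixels pad[i, j+1], pad[i+1, j+1]
    conn_u.append(sid[:, :-1].ravel())
    conn_v.append(sid[:, 1:].ravel())
    conn_w.append(np.maximum(pad[:-1, 1:-1], pad[1:, 1:-1]).ravel())
    # vertical neighbors (i,j)-(i+1,j): shared pixels pad[i+1, j], pad[i+1, j+1]
    conn_u.append(sid[:-1, :].ravel())
    conn_v.append(sid[1:, :].ravel())
    conn_w.append(np.maximum(pad[1:-1, :-1], pad[1:-1, 1:]).ravel())
    # diagonal (i,j)-(i+1,j+1): shared pixel pad[i+1, j+1]
    conn_u.append(sid[:-1, :-1].ravel())
    conn_v.append(sid[1:, 1:].ravel())
    conn_w.append(pad[1:-1, 1:-1].ravel())
    # anti-diagonal (i,j+1)-(i+1,j): shared pixel pad[i+1, j+1]
    conn_u.append(sid[:-1, 1:].ravel())
    conn_v.append(sid[1:, :-1].ravel())
    conn_w.append(pad[1:-1, 1:-1].ravel())
    cu = np.concatenate(conn_u)
    cv = np.concatenate(conn_v)
    cw = np.concatenate(conn_w)
    order1 = np.argsort(-cw, kind="stable")

    uf1 = _UnionFind(R * C)
    # descending elder rule: the component created at the LARGER square value
    # is the elder; pass negated creation values so the shared merge loop's
    # "smaller birth is elder" convention applies.
    neg_creation = -sflat
    b1, d1 = _pairs_from_merges(
        uf1,
        neg_creation,
        ((-float(cw[i]), int(cu[i]), int(cv[i])) for i in order1),
        keep_zero,
    )
    # complement pair (merge value m, creation value cr) -> H1 interval [m, cr)
    for merge_neg, creation_neg in zip(d1, b1):
        birth = -merge_neg
        death = -creation_neg
        if death >= big:  # padding artifacts: never a real loop
            continue
        dims.append(1)
        births.append(birth)
        deaths.append(death)
    return PersistenceDiagram(
        np.array(dims, dtype=int),
        np.array(births),
        np.array(deaths),
        source_label=source_label,
        shift=shift,
    )


# ---------------------------------------------------------------------------
# Bottleneck distance


def _finite_points(diagram: PersistenceDiagram, k: int) -> np.ndarray:
    b, d = diagram.finite(k)
    pts = np.column_stack([b, d])
    return pts[d > b]  # zero-persistence points sit on the diagonal


def _essential_cost(d1: PersistenceDiagram, d2: PersistenceDiagram, k: int) -> float:
    b1 = np.sort(d1.intervals(k)[0][np.isinf(d1.intervals(k)[1])])
    b2 = np.sort(d2.intervals(k)[0][np.isinf(d2.intervals(k)[1])])
    if len(b1) != len(b2):
        return math.inf
    if len(b1) == 0:
        return 0.0
    return float(np.max(np.abs(b1 - b2)))


def _bottleneck_exhaustive(p: np.ndarray, q: np.ndarray) -> float:
    """Exact bottleneck of two finite point sets by enumerating matchings."""
    diag_p = (p[:, 1] - p[:, 0]) / 2 if len(p) else np.empty(0)
    diag_q = (q[:, 1] - q[:, 0]) / 2 if len(q) else np.empty(0)
    if len(p) == 0 and len(q) == 0:
        return 0.0
    cost = (
        np.max(np.abs(p[:, None, :] - q[None, :, :]), axis=2)
        if len(p) and len(q)
        else np.empty((len(p), len(q)))
    )
    best = math.inf

    def recurse(i: int, used: int, cur: float) -> None:
        nonlocal best
        if cur >= best:
            return
        if i == len(p):
            rest = max(
                (diag_q[j] for j in range(len(q)) if not used >> j & 1),
                default=0.0,
            )
            best = min(best, max(cur, rest))
            return
        recurse(i + 1, used, max(cur, diag_p[i]))  # p[i] to the diagonal
        for j in range(len(q)):
            if not used >> j & 1:
                recurse(i + 1, used | 1 << j, max(cur, cost[i, j]))

    recurse(0, 0, 0.0)
    return float(best)


def _bottleneck_matching(p: np.ndarray, q: np.ndarray) -> float:
    """Exact bottleneck via binary search over candidate costs plus
    Hopcroft–Karp feasibility on the augmented bipartite graph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    n, m = len(p), len(q)
    if n == 0 and m == 0:
        return 0.0
    diag_p = (p[:, 1] - p[:, 0]) / 2 if n else np.empty(0)
    diag_q = (q[:, 1] - q[:, 0]) / 2 if m else np.empty(0)
    cost = (
        np.max(np.abs(p[:, None, :] - q[None, :, :]), axis=2)
        if n and m
        else np.empty((n, m))
    )
    candidates = np.unique(np.concatenate([cost.ravel(), diag_p, diag_q, [0.0]]))

    def feasible(eps: float) -> bool:
        # left: p points + m diagonal slots; right: q points + n diagonal slots
        rows, cols = [], []
        for i in range(n):
            for j in range(m):
                if cost[i, j] <= eps:
                    rows.append(i)
                    cols.append(j)
            if diag_p[i] <= eps:
                rows.append(i)
                cols.append(m + i)
        for j in range(m):
            if diag_q[j] <= eps:
                rows.append(n + j)
                cols.append(j)
        for j in range(m):  # diagonal-diagonal pairs are always allowed
            for i2 in range(n):
                rows.append(n + j)
                cols.append(m + i2)
        graph = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n + m, m + n)
        )
        match = maximum_bipartite_matching(graph, perm_type="column")
        return int(np.sum(match >= 0)) == n + m

    lo, hi = 0, len(candidates) - 1
    if not feasible(candidates[hi]):
        return math.inf
    while lo < hi:
        mid = (lo + hi) // 2
        if feasible(candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def bottleneck_distance(
    d1: PersistenceDiagram,
    d2: PersistenceDiagram,
    k: int,
    method: str = "auto",
) -> float:
    """Exact bottleneck distance between the dim-k parts of two diagrams.

    Off-diagonal finite points are matched (L∞ cost) to each other or
    projected to the diagonal (cost persistence/2); essential intervals must
    match in count and are paired by sorted births.  ``method``:

    * ``"auto"`` — exhaustive enumeration for ≤ 8 off-diagonal points per
      diagram, otherwise exact binary search with bipartite matching.
    * ``"exhaustive"`` — enumeration only; raises :class:`SizeError` beyond
      8 points per diagram.
    * ``"matching"`` — always the matching-based solver.
    """
    p = _finite_points(d1, k)
    q = _finite_points(d2, k)
    ess = _essential_cost(d1, d2, k)
    if method == "exhaustive" and (len(p) > 8 or len(q) > 8):
        raise SizeError(
            "exhaustive bottleneck is capped at 8 off-diagonal points per "
            "diagram; use method='matching'"
        )
    if method not in ("auto", "exhaustive", "matching"):
        raise UsageError(f"unknown method {method!r}")
    if method == "matching" or (method == "auto" and (len(p) > 8 or len(q) > 8)):
        finite_part = _bottleneck_matching(p, q)
    else:
        finite_part = _bottleneck_exhaustive(p, q)
    return max(finite_part, ess)
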