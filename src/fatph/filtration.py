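"""Filtered complexes: Vietoris–Rips from point clouds, cubical from images.

Two filtrations feed the persistence engine:

* ``vietoris_rips`` — the flag complex of a planar point cloud, parameterized
  by inter-point *distance* (the diameter convention: growing balls of radius
  ε/2 touch when the distance is ε), truncated at ``eps_max`` and at
  dimension ≤ 2.
* ``lower_star_cubical`` — the sublevel-set filtration of a grayscale patch
  under the vertex construction: one vertex per pixel at the pixel value, an
  edge per 4-adjacent pair, a square per 2×2 block, each higher cell entering
  at the maximum of its vertices.

A :class:`FilteredComplex` stores cells with stable integer ids, dimensions,
boundaries and filtration values; cells are processed in (value, dim, id)
order, which respects filtration monotonicity by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, InputError, InvariantViolation
from .preprocess import as_patch, as_point_cloud

__all__ = [
    "FilteredComplex",
    "vietoris_rips",
    "lower_star_cubical",
    "cubical_cell_counts",
    "euler_characteristic",
]

_BOUNDARY_SIZES = {0: (0,), 1: (2,), 2: (3, 4)}


@dataclass
class FilteredComplex:
    """A filtered cell complex of dimension ≤ 2.

    Attributes
    ----------
    dims : (n,) int array — cell dimensions in {0, 1, 2}.
    values : (n,) float array — filtration values, ≥ max over boundary.
    boundaries : list of tuples — ids of (dim−1)-faces of each cell.
    eps_max : truncation scale for Rips complexes (+inf when untruncated).
    shift : additive shift applied to raw input values (cubical only).
    """

    dims: np.ndarray
    values: np.ndarray
    boundaries: list
    eps_max: float = math.inf
    shift: float = 0.0

    def __post_init__(self):
        self.dims = np.asarray(self.dims, dtype=np.int8)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_cells(self) -> int:
        return len(self.dims)

    def cell_count(self, dim: int) -> int:
        return int(np.sum(self.dims == dim))

    def sorted_order(self) -> np.ndarray:
        """Cell ids in filtration order (value, dim, id) — deterministic."""
        n = self.n_cells
        return np.lexsort((np.arange(n), self.dims, self.values))

    def validate(self) -> None:
        """Check boundary closure and filtration monotonicity."""
        n = self.n_cells
        if not (len(self.values) == len(self.boundaries) == n):
            raise InvariantViolation("cell arrays have inconsistent lengths")
        if not np.all(np.isfinite(self.values)):
            raise InvariantViolation("non-finite filtration values")
        for i in range(n):
            d = int(self.dims[i])
            bnd = self.boundaries[i]
            if d not in _BOUNDARY_SIZES:
                raise InvariantViolation(f"cell {i} has unsupported dimension {d}")
            if len(bnd) not in _BOUNDARY_SIZES[d]:
                raise InvariantViolation(
                    f"{d}-cell {i} has {len(bnd)} boundary cells"
                )
            for b in bnd:
                if not (0 <= b < n):
                    raise InvariantViolation(f"cell {i} has dangling face id {b}")
                if self.dims[b] != d - 1:
                    raise InvariantViolation(
                        f"face {b} of {d}-cell {i} has dimension {self.dims[b]}"
                    )
                if self.values[b] > self.values[i] + 1e-12:
                    raise InvariantViolation(
                        f"cell {i} (value {self.values[i]}) precedes its face "
                        f"{b} (value {self.values[b]})"
                    )

    def to_tsv(self, path) -> None:
        """Serialize as TSV: id, dim, filtration_value, boundary_ids."""
        with open(path, "w") as fh:
            fh.write("id\tdim\tfiltration_value\tboundary_ids\n")
            for i in range(self.n_cells):
                bnd = ";".join(str(b) for b in self.boundaries[i])
                fh.write(f"{i}\t{self.dims[i]}\t{self.values[i]:.17g}\t{bnd}\n")


def vietoris_rips(cloud, eps_max: float = 10.0, max_dim: int = 2) -> FilteredComplex:
    """Vietoris–Rips filtration of a planar point cloud.

    Vertices enter at ε = 0, each edge at the Euclidean distance of its
    endpoints (≤ ``eps_max``), each triangle at the largest of its three edge
    lengths.  The filtration axis is inter-point distance: balls of radius
    ε/2 around two points intersect exactly when their distance is ≤ ε.
    """
    pts = as_point_cloud(cloud)
    n = len(pts)
    if n == 0:
        raise InputError("empty point cloud")
    if not (eps_max > 0):
        raise ConfigurationError(f"eps_max must be positive, got {eps_max}")
    if max_dim not in (0, 1, 2):
        raise ConfigurationError(f"max_dim must be in {{0, 1, 2}}, got {max_dim}")

    dims = [0] * n
    values = [0.0] * n
    boundaries: list = [()] * n

    if max_dim >= 1 and n > 1:
        dist = squareform(pdist(pts))
        edge_id: dict = {}
        ii, jj = np.nonzero(np.triu(dist <= eps_max, k=1))
        # deterministic edge order: by (distance, i, j)
        order = np.lexsort((jj, ii, dist[ii, jj]))
        for i, j in zip(ii[order], jj[order]):
            edge_id[(int(i), int(j))] = len(dims)
            dims.append(1)
            values.append(float(dist[i, j]))
            boundaries.append((int(i), int(j)))
        if max_dim >= 2:
            neighbors = [np.nonzero((dist[i] <= eps_max) & (np.arange(n) > i))[0]
                         for i in range(n)]
            for i in range(n):
                for j in neighbors[i]:
                    common = np.intersect1d(neighbors[int(i)], neighbors[int(j)])
                    for k in common:
                        if dist[j, k] <= eps_max:
                            dims.append(2)
                            values.append(float(max(dist[i, j], dist[i, k], dist[j, k])))
                            boundaries.append(
                                (
                                    edge_id[(int(i), int(j))],
                                    edge_id[(int(i), int(k))],
                                    edge_id[(int(j), int(k))],
                                )
                            )
    return FilteredComplex(
        dims=np.array(dims),
        values=np.array(values),
        boundaries=boundaries,
        eps_max=float(eps_max),
    )


def lower_star_cubical(patch, apply_shift: bool = True) -> FilteredComplex:
    """Sublevel-set cubical filtration of a grayscale patch (V-construction).

    One vertex per pixel at its value, an edge per 4-adjacent pixel pair at
    the max of its endpoints, a square per 2×2 block at the max of its four
    pixels.  When the patch contains negative values and ``apply_shift`` is
    true, all filtration values are shifted so the minimum maps to 0; the
    shift is recorded on the returned complex.
    """
    arr = as_patch(patch)
    shift = 0.0
    if apply_shift and arr.min() < 0:
        shift = -float(arr.min())
        arr = arr + shift
    r, c = arr.shape

    vid = np.arange(r * c).reshape(r, c)
    dims = [0] * (r * c)
    values = list(arr.ravel())
    boundaries: list = [()] * (r * c)

    # horizontal then vertical edges, row-major — stable ids
    h_eid = np.full((r, c - 1), -1, dtype=int) if c > 1 else np.empty((r, 0), int)
    v_eid = np.full((r - 1, c), -1, dtype=int) if r > 1 else np.empty((0, c), int)
    for i in range(r):
        for j in range(c - 1):
            h_eid[i, j] = len(dims)
            dims.append(1)
            values.append(float(max(arr[i, j], arr[i, j + 1])))
            boundaries.append((int(vid[i, j]), int(vid[i, j + 1])))
    for i in range(r - 1):
        for j in range(c):
            v_eid[i, j] = len(dims)
            dims.append(1)
            values.append(float(max(arr[i, j], arr[i + 1, j])))
            boundaries.append((int(vid[i, j]), int(vid[i + 1, j])))
    for i in range(r - 1):
        for j in range(c - 1):
            dims.append(2)
            values.append(float(arr[i : i + 2, j : j + 2].max()))
            boundaries.append(
                (
                    int(h_eid[i, j]),
                    int(h_eid[i + 1, j]),
                    int(v_eid[i, j]),
                    int(v_eid[i, j + 1]),
                )
            )
    return FilteredComplex(
        dims=np.array(dims),
        values=np.array(values),
        boundaries=boundaries,
        shift=shift,
    )


def cubical_cell_counts(n_rows: int, n_cols: int) -> tuple[int, int, int]:
    """(vertices, edges, squares) of the full r×c grid complex."""
    v = n_rows * n_cols
    e = n_rows * (n_cols - 1) + n_cols * (n_rows - 1)
    f = (n_rows - 1) * (n_cols - 1)
    return v, e, f


def euler_characteristic(fc: FilteredComplex, t: float = math.inf) -> int:
    """χ = #V − #E + #F of the sublevel complex at threshold t."""
    present = fc.values <= t
    signs = np.array([1, -1, 1])
    return int(sum(signs[d] * int(np.sum(present & (fc.dims == d))) for d in (0, 1, 2)))
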