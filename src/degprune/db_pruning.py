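"""Density-based pruning (DB Pruning) of non-differentially expressed genes.

Genes are points in the (AG, AD) plane. For each gene, count the other genes
within Euclidean distance strictly less than a radius ``r0``; a gene with at
least ``n0`` such neighbors sits in a dense region and is pruned. What
survives is the sparse boundary population where true differentially
expressed genes concentrate.

Implementation notes
--------------------
* The neighbor predicate is evaluated on squared distances, d^2 < r0^2, with
  one shared pairwise-d^2 routine everywhere, so every code path (direct
  counting, radius search) agrees exactly — including points at distance
  exactly r0, which are *not* neighbors ("smaller than" is strict). r0 = 0
  is therefore always a no-op.
* Counting is O(N^2) but chunked and vectorized; N ~ 2e4 takes seconds and
  needs ~tens of MB. An approximate spatial index is deliberately avoided:
  results must equal the definition bit-for-bit.
* ``search_radius`` bisects r0 over [0, max(AD)]: a useful radius never
  exceeds the AD spread, since the dense core lives at AD ~ 0.
  Survivor counts along the way come from each gene's n0-th smallest
  neighbor distance: a gene survives at r0 iff that distance^2 >= r0^2,
  which is exactly "fewer than n0 neighbors". This makes each bisection step
  O(log N) after one O(N^2) pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PruningParams",
    "PruningResult",
    "count_neighbors",
    "prune",
    "search_radius",
]


@dataclass(frozen=True)
class PruningParams:
    """Radius ``r0`` (feature units, >= 0) and neighbor threshold ``n0`` (>= 1)."""

    r0: float
    n0: int

    def __post_init__(self) -> None:
        if self.r0 < 0:
            raise ValueError(f"r0 must be >= 0, got {self.r0}")
        if self.n0 < 1:
            raise ValueError(f"n0 must be >= 1, got {self.n0}")


@dataclass
class PruningResult:
    """Neighbor counts, kept/pruned mask, and the parameters that produced them."""

    neighbor_counts: np.ndarray
    survivor_mask: np.ndarray
    params: PruningParams

    @property
    def n_survivors(self) -> int:
        return int(self.survivor_mask.sum())

    @property
    def n_pruned(self) -> int:
        return int((~self.survivor_mask).sum())


def _as_points(features) -> np.ndarray:
    if hasattr(features, "points"):
        return np.ascontiguousarray(features.points(), dtype=float)
    pts = np.asarray(features, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected GeneFeatures or an (N, 2) point array")
    return pts


def _pairwise_sq(chunk: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances from each chunk row to every point.

    Kept as the single source of distance arithmetic so all callers see
    identical floating-point results.
    """
    dx = chunk[:, 0][:, None] - pts[:, 0][None, :]
    dy = chunk[:, 1][:, None] - pts[:, 1][None, :]
    return dx * dx + dy * dy


def _chunk_rows(n: int) -> int:
    # ~32 MB of float64 scratch per chunk
    return max(16, min(n, 4_000_000 // max(n, 1)))


def count_neighbors(features, r0: float) -> np.ndarray:
    """Per-gene count of other genes at distance strictly below ``r0``.

    Symmetric by construction; self is excluded; coincident genes are mutual
    neighbors for any r0 > 0.
    """
    if r0 < 0:
        raise ValueError(f"r0 must be >= 0, got {r0}")
    pts = _as_points(features)
    n = pts.shape[0]
    r2 = r0 * r0
    counts = np.empty(n, dtype=np.int64)
    step = _chunk_rows(n)
    # self distance 0 passes the strict test iff r0^2 > 0 (r0^2, not r0:
    # a subnormal r0 can square-underflow to exactly 0)
    self_hit = 1 if r2 > 0 else 0
    for start in range(0, n, step):
        sq = _pairwise_sq(pts[start : start + step], pts)
        counts[start : start + sq.shape[0]] = (sq < r2).sum(axis=1) - self_hit
    return counts


def prune(features, params: PruningParams) -> PruningResult:
    """Apply the pruning rule: genes with >= ``n0`` neighbors within ``r0`` go."""
    counts = count_neighbors(features, params.r0)
    return PruningResult(counts, counts < params.n0, params)


def kth_neighbor_sq_distances(features, k: int) -> np.ndarray:
    """Each gene's k-th smallest squared distance to another gene.

    A gene survives pruning at radius r0 with threshold n0 = k exactly when
    this value is >= r0^2. Exposed for the radius search and diagnostics.
    """
    pts = _as_points(features)
    n = pts.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in 1..{n - 1}, got {k}")
    out = np.empty(n, dtype=float)
    step = _chunk_rows(n)
    for start in range(0, n, step):
        sq = _pairwise_sq(pts[start : start + step], pts)
        rows = np.arange(sq.shape[0])
        sq[rows, start + rows] = np.inf  # mask self; coincident others keep 0
        out[start : start + sq.shape[0]] = np.partition(sq, k - 1, axis=1)[:, k - 1]
    return out


def search_radius(
    features,
    n0: int,
    target_k: int,
    max_iter: int = 64,
) -> tuple[float, PruningResult]:
    """Bisect ``r0`` in [0, max(AD)] toward a desired survivor count.

    The survivor count is a non-increasing step function of r0, so an exact
    hit may be impossible; among visited radii (endpoints included) the count
    closest to ``target_k`` wins, ties broken toward more survivors — the
    conservative side, keeping more candidate DEGs.
    """
    pts = _as_points(features)
    n = pts.shape[0]
    if not 1 <= target_k <= n:
        raise ValueError(f"target_k must be in 1..{n}, got {target_k}")
    if n0 > n - 1:
        # nobody can have n0 neighbors: every radius keeps everything
        return 0.0, prune(features, PruningParams(0.0, n0))

    kth_sq = np.sort(kth_neighbor_sq_distances(pts, n0))

    def survivors(r: float) -> int:
        # genes with kth_sq >= r*r survive
        return n - int(np.searchsorted(kth_sq, r * r, side="left"))

    lo, hi = 0.0, float(pts[:, 1].max())
    best_r, best_count = 0.0, survivors(0.0)  # r0=0 prunes nothing: count == n

    def consider(r: float, c: int) -> None:
        nonlocal best_r, best_count
        if (abs(c - target_k), -c) < (abs(best_count - target_k), -best_count):
            best_r, best_count = r, c

    consider(hi, survivors(hi))
    if best_count != target_k:
        for _ in range(max_iter):
            mid = (lo + hi) / 2.0
            c = survivors(mid)
            consider(mid, c)
            if c == target_k:
                break
            if c > target_k:  # too many survivors -> widen the radius
                lo = mid
            else:
                hi = mid
    result = prune(features, PruningParams(best_r, n0))
    assert result.n_survivors == best_count  # kth-distance shortcut is exact
    return best_r, result
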