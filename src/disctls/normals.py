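"""Per-point normal estimation by local quadratic-patch fitting, with
globally consistent orientation via minimum-spanning-tree propagation.

For each point, the k nearest neighbours (default k = 6) plus the point
itself form a neighbourhood.  In a local frame — the PCA frame of the
neighbourhood, least-variance axis as local z, centred at the query point —
a quadric height function

    z = a x² + b y² + c x y + d x + e y + f

is fitted by least squares, and the surface normal follows from its gradient:

    N = (−∂z/∂x, −∂z/∂y, 1) = (−d, −e, 1)   at the origin,

normalised to unit length.  The local frame makes the height-function model
valid on steep surfaces where a global-frame fit would be rank-deficient.

Signs from independent local fits are arbitrary, so a second pass propagates
a consistent orientation over the minimum spanning tree of the k-NN graph
with edge weights 1 − |n_i · n_j| (nearly parallel normals are cheap to
traverse), flipping each normal to agree with its tree parent.  Finally the
whole cloud is flipped outward if the majority of normals point toward the
centroid — outward normals are what the divergence-theorem volume requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = [
    "QuadraticPatch",
    "OrientedPointCloud",
    "DegenerateNeighborhoodError",
    "fit_quadratic_patch",
    "patch_normal",
    "estimate_normals",
    "orient_normals_mst",
]


class DegenerateNeighborhoodError(ValueError):
    """Neighbourhood does not determine a quadric (e.g. collinear in xy)."""


@dataclass
class QuadraticPatch:
    """Coefficients of z = ax² + by² + cxy + dx + ey + f in a local frame."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    residual: float = 0.0

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])


@dataclass
class OrientedPointCloud:
    """Points plus one unit normal per point."""

    points: np.ndarray
    normals: np.ndarray
    unit: str = "m"
    id: str = ""
    fallback_count: int = 0     # neighbourhoods that fell back to the PCA normal
    n_components: int = 1       # connected components seen during orientation
    degenerate: Optional[np.ndarray] = None  # line-like neighbourhoods (unreliable normals)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.normals = np.asarray(self.normals, dtype=np.float64)
        if self.points.shape != self.normals.shape:
            raise ValueError("points and normals must have matching shapes")

    def __len__(self) -> int:
        return self.points.shape[0]

    def as_point_cloud(self) -> PointCloud:
        """Repackage as a :class:`PointCloud` with nx/ny/nz extras (for PLY output)."""
        extra = {"nx": self.normals[:, 0], "ny": self.normals[:, 1], "nz": self.normals[:, 2]}
        return PointCloud(self.points, unit=self.unit, id=self.id, extra=extra)


def _design(xy: np.ndarray) -> np.ndarray:
    x, y = xy[..., 0], xy[..., 1]
    return np.stack([x * x, y * y, x * y, x, y, np.ones_like(x)], axis=-1)


def fit_quadratic_patch(neighborhood: np.ndarray) -> QuadraticPatch:
    """Least-squares quadric fit to ≥6 points given in the local frame."""
    pts = np.asarray(neighborhood, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise ValueError("neighborhood must be (m>=6, 3)")
    A = _design(pts[:, :2])
    coef, _, rank, _ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    if rank < 6:
        raise DegenerateNeighborhoodError(
            f"design rank {rank} < 6: neighbourhood does not determine a quadric")
    resid = float(np.linalg.norm(A @ coef - pts[:, 2]))
    return QuadraticPatch(*coef, residual=resid)


def patch_normal(patch: QuadraticPatch, at: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Unit normal of the fitted quadric at local point ``at``.

    The gradient of the height function is (2a·x + c·y + d, 2b·y + c·x + e);
    the (unnormalised) normal is its negation with z-component 1, which is
    never the zero vector.
    """
    x, y = at
    n = np.array([-(2 * patch.a * x + patch.c * y + patch.d),
                  -(2 * patch.b * y + patch.c * x + patch.e),
                  1.0])
    return n / np.linalg.norm(n)


def _pca_frames(neigh: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Batched PCA frames: rotation matrices (n,3,3) whose last column is the
    least-variance axis (local z), plus the covariance eigenvalues (n,3)."""
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / neigh.shape[1]
    evals, evecs = np.linalg.eigh(cov)          # ascending eigenvalues
    # columns: [mid, max, min] variance → local (x, y, z)
    frames = evecs[:, :, [1, 2, 0]]
    return frames, evals


def estimate_normals(cloud: PointCloud, k: int = 6,
                     method: str = "quadric") -> OrientedPointCloud:
    """One unit normal per point over its k-NN neighbourhood.

    ``method="quadric"`` (default) fits the local height quadric and takes
    the gradient normal; with the minimal k = 6 the fit interpolates and is
    noise-sensitive, so larger k is advisable on real scans.
    ``method="pca"`` takes the least-variance covariance axis of the
    neighbourhood (the estimator classically paired with Poisson
    reconstruction, usually at k = 8).

    Signs are arbitrary until :func:`orient_normals_mst` runs.  Quadric
    neighbourhoods whose design is numerically rank-deficient fall back to
    the PCA normal; the count is reported on the returned cloud.
    """
    if method not in ("quadric", "pca"):
        raise ValueError(f"unknown method {method!r}")
    pts = cloud.points
    n = pts.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)           # includes the point itself
    neigh = pts[idx]                            # (n, k+1, 3)

    frames, evals = _pca_frames(neigh)
    # line-like neighbourhoods (e.g. the dense rim ring a bottom-fill
    # projection creates) have no well-defined normal: the two smaller
    # eigenvalues are both negligible against the largest.
    with np.errstate(invalid="ignore", divide="ignore"):
        linearity = (evals[:, 2] - evals[:, 1]) / evals[:, 2]
    degenerate = ~np.isfinite(linearity) | (linearity > 0.98)

    if method == "pca":
        normals = frames[:, :, 2].copy()        # least-variance axis
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        return OrientedPointCloud(pts.copy(), normals, unit=cloud.unit, id=cloud.id,
                                  degenerate=degenerate)

    local = np.einsum("nkj,nji->nki", neigh - pts[:, None, :], frames)  # to local coords

    A = _design(local[..., :2])                 # (n, k+1, 6)
    z = local[..., 2]
    AtA = np.einsum("nki,nkj->nij", A, A)
    Atz = np.einsum("nki,nk->ni", A, z)
    # Regular solve where well-conditioned; flag the rest for PCA fallback.
    dets_ok = np.linalg.cond(AtA) < 1e10
    coef = np.zeros((n, 6))
    if dets_ok.any():
        coef[dets_ok] = np.linalg.solve(AtA[dets_ok], Atz[dets_ok][..., None])[..., 0]
    n_local = np.column_stack([-coef[:, 3], -coef[:, 4], np.ones(n)])
    n_local /= np.linalg.norm(n_local, axis=1, keepdims=True)
    normals = np.einsum("nij,nj->ni", frames, n_local)

    fallback = ~dets_ok
    if fallback.any():
        normals[fallback] = frames[fallback][:, :, 2]  # PCA least-variance axis
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return OrientedPointCloud(pts.copy(), normals, unit=cloud.unit, id=cloud.id,
                              fallback_count=int(fallback.sum()), degenerate=degenerate)


def orient_normals_mst(cloud: OrientedPointCloud, k_graph: int = 10,
                       confidence_threshold: float = 0.85) -> OrientedPointCloud:
    """Flip normal signs for global consistency by MST propagation.

    Builds the k-NN graph with edge weight 1 − |n_i · n_j|, extracts its
    minimum spanning tree, and propagates signs from each component's root by
    breadth-first traversal so that adjacent normals agree.  A disconnected
    graph is oriented per component with a warning.

    The final outward sign is resolved per *confident* patch: edges whose
    normals are nearly orthogonal (|n_i · n_j| below ``confidence_threshold``)
    carry no reliable sign information — they occur across sharp folds and in
    degenerate, line-like point concentrations such as the dense rim ring a
    bottom-fill projection creates — so the graph restricted to confident
    edges is split into components and each is flipped outward (away from the
    cloud centroid) by majority vote.  On smooth well-sampled clouds every
    edge is confident and this reduces to the single global outward flip.
    """
    pts, normals = cloud.points, cloud.normals.copy()
    n = len(cloud)
    if n == 1:
        out = normals
        if np.dot(out[0], pts[0] - pts.mean(axis=0)) < 0:
            out = -out
        return OrientedPointCloud(pts.copy(), out, unit=cloud.unit, id=cloud.id,
                                  fallback_count=cloud.fallback_count)
    k_eff = min(k_graph, n - 1)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k_eff + 1)
    rows = np.repeat(np.arange(n), k_eff)
    cols = idx[:, 1:].ravel()
    dots = np.abs(np.einsum("ij,ij->i", normals[rows], normals[cols]))
    w = (1.0 - dots) + 1e-9                     # strictly positive so edges survive sparsity
    deg = cloud.degenerate if cloud.degenerate is not None else np.zeros(n, bool)
    # edges touching a degenerate (line-like) point carry no reliable sign;
    # penalise them so the MST attaches such points as leaves
    w = w + (deg[rows] | deg[cols]) * 1.0
    graph = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    graph = graph.maximum(graph.T)              # symmetrize; keeps one-directional edges
    mst = minimum_spanning_tree(graph)
    mst = mst + mst.T

    n_comp, labels = connected_components(mst, directed=False)
    if n_comp > 1:
        warnings.warn(f"k-NN graph has {n_comp} components; orienting each independently")
    for comp in range(n_comp):
        root = int(np.flatnonzero(labels == comp)[0])
        order, pred = breadth_first_order(mst, root, directed=False)
        for node in order[1:]:
            p = pred[node]
            if np.dot(normals[node], normals[p]) < 0:
                normals[node] = -normals[node]

    # outward resolution on confident patches
    conf_dots = np.abs(np.einsum("ij,ij->i", normals[rows], normals[cols]))
    conf_mask = (conf_dots >= confidence_threshold) & ~deg[rows] & ~deg[cols]
    conf_graph = coo_matrix((np.ones(int(conf_mask.sum())),
                             (rows[conf_mask], cols[conf_mask])), shape=(n, n))
    n_patch, patch = connected_components(conf_graph, directed=False)
    centroid = pts.mean(axis=0)
    outwardness = np.einsum("ij,ij->i", normals, pts - centroid)
    patch_sum = np.bincount(patch, weights=outwardness, minlength=n_patch)
    flip = patch_sum[patch] < 0
    normals[flip] = -normals[flip]
    return OrientedPointCloud(pts.copy(), normals, unit=cloud.unit, id=cloud.id,
                              fallback_count=cloud.fallback_count, n_components=n_comp,
                              degenerate=None if cloud.degenerate is None else cloud.degenerate.copy())
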