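"""Bottom-surface repair for ground-occluded disc point clouds.

A disc scanned while resting on the ground has no returns from its bottom
face.  The repair duplicates every point onto the horizontal plane through
the cloud's lowest point — keeping x and y unchanged, setting z to the global
minimum — and merges the projection with the original cloud:

    z_min      = min_i z_i
    T(p_i)     = (x_i, y_i, z_min)
    P_complete = P_original ∪ P_projected

Because *all* points are projected (not just the rim), the repaired base is a
dense filled disc; this follows the method as stated and is kept as the
default.  Coincident duplicates (points already lying at z_min) would appear
twice under a literal union; by default exact duplicates of original points
are dropped from the projection (``dedupe_tol=0``), which preserves union
semantics while avoiding degenerate coincident points that destabilise
normal estimation.  Pass ``dedupe_tol=None`` to keep the literal reading, in
which the merged cloud has exactly twice the original cardinality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud

__all__ = ["FilledCloud", "detect_lowest", "project_to_base", "fill_bottom"]


@dataclass
class FilledCloud:
    """Audit bundle for one bottom-fill run: original, projected and merged clouds."""

    original: PointCloud
    projected: PointCloud
    complete: PointCloud
    z_min: float
    n_deduped: int = 0

    def audit(self) -> dict:
        return {
            "z_min": self.z_min,
            "n_original": len(self.original),
            "n_projected": len(self.projected),
            "n_deduped": self.n_deduped,
            "n_complete": len(self.complete),
            "unit": self.original.unit,
        }


def detect_lowest(cloud: PointCloud) -> float:
    """Global minimum z over all points (the ground-contact reference plane)."""
    return float(cloud.points[:, 2].min())


def project_to_base(cloud: PointCloud, z_min: float) -> PointCloud:
    """Copy every point to the base plane: (x, y, z) ↦ (x, y, z_min).

    ``z_min`` must not exceed the cloud's lowest z — a higher plane would cut
    through the interior rather than seal the bottom.
    """
    lowest = detect_lowest(cloud)
    if z_min > lowest + 1e-12 * max(1.0, abs(lowest)):
        raise ValueError(
            f"z_min={z_min} lies above the lowest point ({lowest}); "
            "projection would create an interior plane")
    proj = cloud.points.copy()
    proj[:, 2] = z_min
    return PointCloud(proj, unit=cloud.unit, id=cloud.id + "/projected")


def fill_bottom(cloud: PointCloud, dedupe_tol: Optional[float] = 0.0) -> FilledCloud:
    """Repair the missing bottom face by planar projection and merging.

    Parameters
    ----------
    cloud : the occluded disc cloud (any unit).
    dedupe_tol : projected points within this XYZ distance of an original
        point are dropped before the union.  ``0.0`` (default) removes exact
        coincidences only; ``None`` disables deduplication entirely, giving
        ``|complete| = 2 |original|``.

    The operation is idempotent under the default policy: filling an
    already-filled cloud adds no points.
    """
    if dedupe_tol is not None and dedupe_tol < 0:
        raise ValueError("dedupe_tol must be >= 0 or None")
    z_min = detect_lowest(cloud)
    projected = project_to_base(cloud, z_min)

    proj_pts = projected.points
    n_deduped = 0
    if dedupe_tol is not None:
        tree = cKDTree(cloud.points)
        if dedupe_tol == 0.0:
            dist, _ = tree.query(proj_pts, k=1)
            keep = dist > 0.0
        else:
            dist, _ = tree.query(proj_pts, k=1)
            keep = dist > dedupe_tol
        n_deduped = int((~keep).sum())
        proj_pts = proj_pts[keep]

    merged = np.vstack([cloud.points, proj_pts]) if proj_pts.shape[0] else cloud.points.copy()
    complete = PointCloud(merged, unit=cloud.unit, id=cloud.id + "/complete")
    # `projected` keeps the full projected set; dedupe applies only at the merge,
    # so the audit can report both the projection and what the union retained.
    return FilledCloud(original=cloud, projected=projected, complete=complete,
                       z_min=z_min, n_deduped=n_deduped)
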