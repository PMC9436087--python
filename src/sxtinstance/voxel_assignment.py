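"""Voxel-to-blob assignment and instance relabelling (pipeline stages 10-12).

Every semantic-mask voxel is scored against every blob of its cluster with
``score = ||voxel - blob centre|| / blob radius`` and assigned to the blob of
lowest score (ties to the lower blob id); the voxel then inherits the
instance label of that blob's group.  Larger blobs claim proportionally
farther voxels, so two touching organelles split along the surface where the
radius-normalized distances balance.
"""

from __future__ import annotations

import numpy as np

from .blob_detection import Blob, Cluster
from .columnar_grouping import InstanceGroup

__all__ = ["voxel_scores", "assign_voxels", "synthetic_centroid_blob"]


def voxel_scores(coords: np.ndarray, blobs: list[Blob], offset=(0, 0, 0)) -> np.ndarray:
    """Score matrix (n_voxels, n_blobs): centre distance over blob radius.

    ``coords`` are crop-frame voxel coordinates; blob centres are shifted by
    ``offset`` into the same frame.
    """
    centers = np.asarray([b.center for b in blobs], dtype=float) - np.asarray(offset, dtype=float)
    radii = np.asarray([b.radius for b in blobs], dtype=float)
    diff = coords[:, None, :].astype(float) - centers[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2)) / radii[None, :]


def synthetic_centroid_blob(cluster: Cluster, r_min: float = 1.5) -> Blob:
    """Fallback blob for a cluster where detection found no maxima.

    Placed at the intensity-weighted centroid of the cluster mask (rounded to
    the nearest voxel) so the cluster can still be emitted as one instance.
    """
    coords = np.argwhere(cluster.mask_crop)
    weights = cluster.tomo_crop[cluster.mask_crop].astype(float)
    if weights.sum() <= 0 or not np.all(np.isfinite(weights)):
        weights = np.ones(len(coords))
    centroid = (coords * weights[:, None]).sum(axis=0) / weights.sum()
    center = tuple(int(round(c)) + int(o) for c, o in zip(centroid, cluster.offset))
    value = float(cluster.tomo_crop[tuple(int(round(c)) for c in centroid)])
    return Blob(blob_id=1, center=center, center_intensity=value,
                radius=r_min, source_sigma=None)


def assign_voxels(mask_crop: np.ndarray, blobs: list[Blob],
                  groups: list[InstanceGroup], offset=(0, 0, 0)) -> np.ndarray:
    """Label every mask voxel with the instance id of its best-scoring blob.

    Returns an int32 crop-frame label grid: background 0, mask voxels carry
    the group instance id of their minimum-score blob (ties to the lower blob
    id).  Blobs must be partitioned by the groups.
    """
    if not blobs:
        raise ValueError("assign_voxels requires at least one blob")
    blob_to_group: dict[int, int] = {}
    for g in groups:
        for bid in g.blob_ids:
            if bid in blob_to_group:
                raise ValueError(f"blob {bid} appears in more than one group")
            blob_to_group[bid] = g.instance_id
    missing = [b.blob_id for b in blobs if b.blob_id not in blob_to_group]
    if missing:
        raise ValueError(f"blobs without a group: {missing}")
    ordered = sorted(blobs, key=lambda b: b.blob_id)
    coords = np.argwhere(mask_crop)
    out = np.zeros(mask_crop.shape, dtype=np.int32)
    if coords.size == 0:
        return out
    scores = voxel_scores(coords, ordered, offset)
    winner = scores.argmin(axis=1)  # first minimum -> lowest blob id
    labels = np.asarray([blob_to_group[b.blob_id] for b in ordered], dtype=np.int32)
    out[tuple(coords.T)] = labels[winner]
    return out
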