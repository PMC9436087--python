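"""Grouping of blobs into columnar organelle instances (pipeline stages 7-9).

Columnar organelles (mitochondria, modelled as chains of blobs) are nucleated
from near-collinear blob triplets.  For a blob ``B_i`` with nearest
unassigned neighbours ``B_i1`` and ``B_i2``, the adjacent angle ``theta_adj``
between the two centre-to-centre vectors measures local collinearity; a
candidate reference vector exists when ``|cos(theta_adj)| > cos(30 deg)`` and
equals the vector sum for ``theta_adj <= 90 deg``, the difference otherwise.
The globally most collinear triplet seeds an instance, which then grows by
admitting blobs whose testing vector to any current member is (i) within
30 deg of the reference axis (sign-insensitive) and (ii) shorter than the sum
of the two blob radii, i.e. the candidate's probe sphere overlaps a member's.
Once no further triplet qualifies, leftover blobs are clustered on their
coordinates with K-Means, K picked by an elbow rule on the within-cluster sum
of squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .blob_detection import Blob

__all__ = [
    "GroupingParams",
    "ReferenceVector",
    "InstanceGroup",
    "candidate_reference_vector",
    "locate_reference_vector",
    "grow_instance",
    "kmeans_residual",
    "group_blobs_columnar",
]


@dataclass(frozen=True)
class GroupingParams:
    angle_threshold_deg: float = 30.0
    kmeans_max_k: int = 8
    kmeans_seed: int = 0
    kmeans_restarts: int = 10

    @property
    def cos_threshold(self) -> float:
        return math.cos(math.radians(self.angle_threshold_deg))


@dataclass
class ReferenceVector:
    """Dominant axis of a columnar instance, nucleated from a blob triplet."""

    vector: np.ndarray  # (z, y, x) direction, not normalized
    seed_blobs: tuple[int, int, int]
    cos_adj: float  # |cos(theta_adj)| of the winning triplet


@dataclass
class InstanceGroup:
    """Ordered blob set carrying one instance label."""

    instance_id: int
    blob_ids: list[int]
    reference: ReferenceVector | None = None


def _centers(blobs: list[Blob]) -> dict[int, np.ndarray]:
    return {b.blob_id: np.asarray(b.center, dtype=float) for b in blobs}


def candidate_reference_vector(blob: Blob, unassigned: list[Blob],
                               params: GroupingParams = GroupingParams()):
    """Candidate reference vector for one blob from its two nearest neighbours.

    Returns ``(vector, cos_adj, (id1, id2))`` or None when fewer than two
    other unassigned blobs exist or the triplet is not collinear enough
    (``|cos(theta_adj)| <= cos(30 deg)``).
    """
    others = [b for b in unassigned if b.blob_id != blob.blob_id]
    if len(others) < 2:
        return None
    c0 = np.asarray(blob.center, dtype=float)
    others.sort(key=lambda b: (math.dist(blob.center, b.center), b.blob_id))
    b1, b2 = others[0], others[1]
    v1 = np.asarray(b1.center, dtype=float) - c0
    v2 = np.asarray(b2.center, dtype=float) - c0
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return None
    cos_t = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    if abs(cos_t) <= params.cos_threshold:
        return None
    vector = v1 + v2 if cos_t >= 0 else v1 - v2
    return vector, abs(cos_t), (b1.blob_id, b2.blob_id)


def locate_reference_vector(unassigned: list[Blob],
                            params: GroupingParams = GroupingParams(),
                            next_instance_id: int = 1):
    """Pick the most collinear triplet among unassigned blobs as a new seed.

    Returns ``(ReferenceVector, InstanceGroup)`` whose group holds the three
    seed blobs, or None when fewer than three blobs remain or no triplet
    passes the angular threshold (the termination condition of the
    nucleate/grow loop).  Ties on ``|cos|`` break towards the lowest blob id.
    """
    if len(unassigned) < 3:
        return None
    best = None
    for blob in sorted(unassigned, key=lambda b: b.blob_id):
        cand = candidate_reference_vector(blob, unassigned, params)
        if cand is None:
            continue
        vector, cos_adj, (i1, i2) = cand
        if best is None or cos_adj > best[0] + 1e-15:
            best = (cos_adj, blob.blob_id, vector, (i1, i2))
    if best is None:
        return None
    cos_adj, bid, vector, (i1, i2) = best
    ref = ReferenceVector(vector=vector, seed_blobs=(bid, i1, i2), cos_adj=cos_adj)
    group = InstanceGroup(instance_id=next_instance_id, blob_ids=[bid, i1, i2], reference=ref)
    return ref, group


def grow_instance(group: InstanceGroup, unassigned: list[Blob],
                  params: GroupingParams = GroupingParams()) -> tuple[InstanceGroup, list[Blob]]:
    """Admit proximal, axis-aligned blobs into a nucleated group.

    A blob joins when ANY testing vector from its centre to a current member
    satisfies (i) ``|cos(angle to reference)| > cos(30 deg)`` and (ii) length
    < sum of the two blob radii (overlapping probe spheres).  The member
    list updates after every addition; passes repeat until one adds nothing.
    Returns the grown group and the still-unassigned remainder.
    """
    if group.reference is None:
        raise ValueError("grow_instance requires a group with a reference vector")
    ref = group.reference.vector
    ref_norm = np.linalg.norm(ref)
    by_id = {b.blob_id: b for b in unassigned}
    members = list(group.blob_ids)
    member_blobs: dict[int, Blob] = {}
    pool = {b.blob_id: b for b in unassigned if b.blob_id not in members}
    # seed blobs may be passed inside `unassigned`; keep their geometry at hand
    for b in unassigned:
        if b.blob_id in members:
            member_blobs[b.blob_id] = b
            pool.pop(b.blob_id, None)
    added = True
    while added:
        added = False
        for bid in sorted(pool):
            blob = pool[bid]
            c = np.asarray(blob.center, dtype=float)
            for mid, member in member_blobs.items():
                t = np.asarray(member.center, dtype=float) - c
                length = np.linalg.norm(t)
                if length == 0 or ref_norm == 0:
                    continue
                cos_t = abs(float(np.dot(t, ref)) / (length * ref_norm))
                if cos_t > params.cos_threshold and length < blob.radius + member.radius:
                    members.append(bid)
                    member_blobs[bid] = blob
                    del pool[bid]
                    added = True
                    break
    group = InstanceGroup(group.instance_id, members, group.reference)
    return group, [by_id[i] for i in sorted(pool)]


def _elbow_k(coords: np.ndarray, params: GroupingParams) -> tuple[int, dict[int, float]]:
    """K maximizing the second difference of the within-cluster sum of squares."""
    n = coords.shape[0]
    if n <= 2 or np.allclose(coords, coords[0]):
        return 1, {1: 0.0}
    k_max = min(params.kmeans_max_k, n)
    wss: dict[int, float] = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=params.kmeans_restarts,
                    random_state=params.kmeans_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate points trigger convergence chatter
            km.fit(coords)
        wss[k] = float(km.inertia_)
    interior = range(2, k_max)
    if not len(list(interior)):
        return k_max, wss
    best_k, best_curv = None, -np.inf
    for k in range(2, k_max):
        curv = wss[k - 1] - 2.0 * wss[k] + wss[k + 1]
        if curv > best_curv + 1e-12:
            best_k, best_curv = k, curv
    return best_k, wss


def kmeans_residual(unassigned: list[Blob],
                    params: GroupingParams = GroupingParams(),
                    next_instance_id: int = 1) -> list[InstanceGroup]:
    """Cluster leftover blobs (no reference vector found) by K-Means.

    K ranges over 1..min(8, n) and is chosen by the elbow rule; n <= 2 blobs
    collapse to a single group.  Groups carry no reference vector and are
    ordered by their smallest member blob id.
    """
    if not unassigned:
        return []
    blobs = sorted(unassigned, key=lambda b: b.blob_id)
    coords = np.asarray([b.center for b in blobs], dtype=float)
    k, _ = _elbow_k(coords, params)
    if k == 1:
        return [InstanceGroup(next_instance_id, [b.blob_id for b in blobs])]
    km = KMeans(n_clusters=k, n_init=params.kmeans_restarts, random_state=params.kmeans_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assignment = km.fit_predict(coords)
    buckets: dict[int, list[int]] = {}
    for blob, lab in zip(blobs, assignment):
        buckets.setdefault(int(lab), []).append(blob.blob_id)
    ordered = sorted(buckets.values(), key=lambda ids: ids[0])
    return [
        InstanceGroup(next_instance_id + i, ids) for i, ids in enumerate(ordered)
    ]


def group_blobs_columnar(blobs: list[Blob],
                         params: GroupingParams = GroupingParams()) -> list[InstanceGroup]:
    """Full stage 7-9 loop: nucleate and grow instances, then K-Means leftovers.

    Every blob ends in exactly one group; each nucleation consumes at least
    three blobs, so the loop terminates.
    """
    unassigned = sorted(blobs, key=lambda b: b.blob_id)
    groups: list[InstanceGroup] = []
    while True:
        located = locate_reference_vector(unassigned, params, next_instance_id=len(groups) + 1)
        if located is None:
            break
        _, group = located
        group, unassigned = grow_instance(group, unassigned, params)
        groups.append(group)
    groups.extend(kmeans_residual(unassigned, params, next_instance_id=len(groups) + 1))
    return groups
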