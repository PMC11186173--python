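"""Ward clustering with a dynamic hybrid tree cut.

Cluster gating for the redundancy penalty: a patient's retained features
are clustered on the dissimilarity d = 1 - K (K the Otsuka-Ochiai
similarity) with Ward linkage (scipy's ``ward``, the ``ward.D2`` variant
on a precomputed distance), and cluster labels come from a dynamic,
shape-aware branch cut in the spirit of the hybrid ``cutreeDynamic``
family:

* merges are replayed bottom-up; when two branches join, each is kept as
  a separate cluster if it is big enough (``min_cluster_size``), its
  within-branch mean dissimilarity (core scatter) is low enough, and the
  gap between the cross-branch and within-branch mean dissimilarity is
  large enough — otherwise the branches fuse and growing continues;
* scatter and gap thresholds are controlled by ``deep_split`` (0 =
  conservative, 4 = aggressive) through the core-scatter interpolation
  used by the dynamic tree cut family; because d is bounded in [0, 1]
  the thresholds live on that scale rather than on Ward's unbounded
  merge heights;
* merges above ``cut_height_fraction`` of the top merge height never
  fuse (the static cut);
* members with no similarity at all to the rest of their cluster, and
  clusters smaller than ``min_cluster_size``, are detached: unassigned
  features become singleton clusters, so every feature gets a label.

The implementation is self-contained and deterministic; it is written
for the modest per-patient feature counts this model clusters (tens to
a few hundred features at a time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

__all__ = ["ward_linkage", "dynamic_hybrid_cut", "cluster_feature_labels"]

# core-scatter interpolation of the dynamic tree cut family, indexed by
# deep_split in 0..4; min_gap = (1 - max_core_scatter) * 3/4
_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


def ward_linkage(similarity: np.ndarray) -> np.ndarray:
    """Ward linkage on the dissimilarity 1 - K (condensed)."""
    d = 1.0 - np.asarray(similarity, dtype=np.float64)
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, None, out=d)
    condensed = ssd.squareform(d, checks=False)
    return sch.linkage(condensed, method="ward")


@dataclass
class _Branch:
    members: list[int]
    within_sum: float = 0.0  # sum of pairwise d among members
    locked: bool = False  # members already emitted as clusters
    tagged: list[list[int]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def within_mean(self) -> float:
        npairs = self.size * (self.size - 1) // 2
        return self.within_sum / npairs if npairs else 0.0


def dynamic_hybrid_cut(
    similarity: np.ndarray,
    deep_split: int = 2,
    min_cluster_size: int = 2,
    cut_height_fraction: float = 0.99,
) -> np.ndarray:
    """Cluster labels for a similarity matrix; singletons get unique labels.

    Returns an integer label per feature.  Labels are assigned in feature
    order and carry no meaning beyond grouping.
    """
    sim = np.asarray(similarity, dtype=np.float64)
    n = sim.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.intp)
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    np.clip(dist, 0.0, None, out=dist)
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="ward")
    heights = linkage[:, 2]
    top = float(heights.max())
    if top <= 0:  # all features identical: one cluster
        return np.zeros(n, dtype=np.intp)
    cut_height = cut_height_fraction * top
    max_core_scatter = _CORE_SCATTER[deep_split]
    min_gap = (1.0 - max_core_scatter) * 0.75

    def qualifies(branch: _Branch, cross_mean: float) -> bool:
        return (
            branch.size >= min_cluster_size
            and branch.within_mean <= max_core_scatter
            and (cross_mean - branch.within_mean) >= min_gap
        )

    clusters: list[list[int]] = []

    def emit(branch: _Branch) -> None:
        # an unlocked branch leaving the growth process becomes a cluster
        # if large enough; its members otherwise stay unassigned
        if branch.size >= min_cluster_size:
            clusters.append(branch.members)

    nodes: dict[int, _Branch] = {i: _Branch([i]) for i in range(n)}
    for m, (left, right, h, _) in enumerate(linkage):
        b_left, b_right = nodes.pop(int(left)), nodes.pop(int(right))
        cross_sum = float(dist[np.ix_(b_left.members, b_right.members)].sum())
        cross_mean = cross_sum / (b_left.size * b_right.size)
        union = _Branch(
            b_left.members + b_right.members,
            b_left.within_sum + b_right.within_sum + cross_sum,
        )
        if b_left.locked or b_right.locked or h > cut_height:
            # no further fusing across this merge: close the open sides
            for b in (b_left, b_right):
                if not b.locked:
                    emit(b)
            union.locked = True
        elif qualifies(b_left, cross_mean) and qualifies(b_right, cross_mean):
            # a genuine cluster boundary: both branches stand on their own
            clusters.append(b_left.members)
            clusters.append(b_right.members)
            union.locked = True
        nodes[n + m] = union
    (root,) = nodes.values()
    if not root.locked:
        emit(root)

    # detach members with zero similarity to every other member of their
    # cluster: they share no co-occurrence with the cluster core
    final: list[list[int]] = []
    for members in clusters:
        idx = np.array(members, dtype=np.intp)
        block = sim[np.ix_(idx, idx)].copy()
        np.fill_diagonal(block, 0.0)
        connected = block.max(axis=1) > 0
        core = [m for m, c in zip(members, connected) if c]
        if len(core) >= min_cluster_size:
            final.append(core)

    labels = np.full(n, -1, dtype=np.intp)
    next_label = 0
    for members in final:
        for m in members:
            labels[m] = next_label
        next_label += 1
    for i in range(n):  # unassigned / undersized -> singleton clusters
        if labels[i] < 0:
            labels[i] = next_label
            next_label += 1
    return labels


def cluster_feature_labels(
    similarity: np.ndarray,
    deep_split: int = 2,
    min_cluster_size: int = 2,
    cut_height_fraction: float = 0.99,
) -> np.ndarray:
    """Alias with the gating module's vocabulary."""
    return dynamic_hybrid_cut(similarity, deep_split, min_cluster_size, cut_height_fraction)
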