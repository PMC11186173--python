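"""Per-patient redundancy penalization of genomic features.

Each feature carried by a patient gets a penalization factor

    eps_i = sum_j K_ij

summed over the patient's features j that share feature i's cluster
(including j = i, so eps_i >= 1 and division is always safe).  Clustering
is recomputed per patient on that patient's own feature subset (the
penalty is defined against the redundancy a *specific* patient carries),
and coefficients to features outside a feature's own cluster are excluded
so that many small chance overlaps cannot accumulate into a penalty.
eps_i estimates how many effectively-identical copies of feature i the
patient carries: 1 for an isolated feature, k for k exact duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix
from .treecut import dynamic_hybrid_cut

__all__ = ["PenaltyVector", "cluster_patient_features", "epsilon_vector"]


@dataclass
class PenaltyVector:
    """Redundancy penalties for one patient's retained features."""

    feature_ids: list[str]
    epsilon: np.ndarray  # >= 1 per feature
    cluster_labels: np.ndarray

    @property
    def n(self) -> int:
        """Number of retained features the patient carries."""
        return len(self.feature_ids)

    @property
    def epsilon_bar(self) -> float:
        """Mean penalty over the patient's retained features."""
        return float(self.epsilon.mean())


def cluster_patient_features(
    sim_sub: SimilarityMatrix,
    deep_split: int = 2,
    min_cluster_size: int = 2,
    cut_height_fraction: float = 0.99,
) -> dict[str, int]:
    """Cluster one patient's retained features on 1 - K with Ward linkage.

    Labels come from the dynamic hybrid tree cut; features the cut leaves
    unassigned are singleton clusters.
    """
    labels = dynamic_hybrid_cut(
        sim_sub.values, deep_split=deep_split,
        min_cluster_size=min_cluster_size, cut_height_fraction=cut_height_fraction,
    )
    return dict(zip(sim_sub.feature_ids, (int(v) for v in labels)))


def epsilon_vector(
    patient_features: list[str],
    sim: SimilarityMatrix,
    deep_split: int = 2,
    min_cluster_size: int = 2,
    cut_height_fraction: float = 0.99,
) -> PenaltyVector:
    """Penalization factors for a patient's retained feature list."""
    if not patient_features:
        raise ValueError("patient carries no retained features; cannot compute penalties")
    sub = sim.submatrix(patient_features)
    labels = dynamic_hybrid_cut(
        sub.values, deep_split=deep_split,
        min_cluster_size=min_cluster_size, cut_height_fraction=cut_height_fraction,
    )
    same_cluster = labels[:, None] == labels[None, :]
    eps = np.where(same_cluster, sub.values, 0.0).sum(axis=1)
    eps = np.maximum(eps, 1.0)  # K_ii = 1 is always in the sum
    return PenaltyVector(list(patient_features), eps, labels)
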