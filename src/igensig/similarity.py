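"""Otsuka-Ochiai co-occurrence similarity from an unlabeled reference cohort.

The Otsuka-Ochiai coefficient of two features is the cosine similarity of
their carrier sets in the reference cohort:

    K_ij = |A_i & A_j| / sqrt(|A_i| * |A_j|)

where A_i is the set of reference patients carrying feature i.  The
reference cohort contributes only co-occurrence structure, never labels;
in practice it is a large tumor collection profiled on the same feature
universe.  Features absent from every reference patient are treated as
non-redundant: K_ii = 1 and K_ij = 0 for j != i, so the downstream
redundancy penalty degrades gracefully to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .matrix import FeatureMatrix

__all__ = ["SimilarityMatrix", "ochiai_matrix", "similarity_submatrix"]


@dataclass
class SimilarityMatrix:
    """Symmetric Otsuka-Ochiai coefficients over an ordered feature list."""

    feature_ids: list[str]
    values: np.ndarray  # float64, shape (n, n), symmetric, in [0, 1]

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.feature_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match feature list")
        self._index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def submatrix(self, feature_ids: Sequence[str]) -> "SimilarityMatrix":
        try:
            idx = np.array([self._index[f] for f in feature_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from None
        return SimilarityMatrix(list(feature_ids), self.values[np.ix_(idx, idx)])

    # -- text serialization (upper triangle triplets) ------------------

    def write_tsv(self, path: str | Path) -> None:
        lines = ["feature_i\tfeature_j\tK"]
        n = self.n_features
        for i in range(n):
            for j in range(i, n):
                k = self.values[i, j]
                if k > 0:
                    lines.append(f"{self.feature_ids[i]}\t{self.feature_ids[j]}\t{k:.10g}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def read_tsv(cls, path: str | Path, feature_ids: Sequence[str]) -> "SimilarityMatrix":
        idx = {f: i for i, f in enumerate(feature_ids)}
        values = np.zeros((len(idx), len(idx)))
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n")
            if header != "feature_i\tfeature_j\tK":
                raise ValueError(f"{path}: bad similarity header {header!r}")
            for line in fh:
                fi, fj, k = line.rstrip("\n").split("\t")
                values[idx[fi], idx[fj]] = values[idx[fj], idx[fi]] = float(k)
        return cls(list(feature_ids), values)


def ochiai_matrix(reference: FeatureMatrix, features: Sequence[str] | None = None) -> SimilarityMatrix:
    """Otsuka-Ochiai similarity of features over a reference cohort.

    Features in ``features`` missing from the reference universe (or
    carried by no reference patient) get the graceful-degradation
    convention K_ii = 1, K_ij = 0.
    """
    if reference.n_patients == 0:
        raise ValueError("reference cohort is empty")
    if features is None:
        features = reference.feature_ids
    aligned = reference.align_features(features)
    x = aligned.incidence.astype(np.float64)
    counts = x.sum(axis=0)
    co = x.T @ x  # |A_i & A_j|
    norm = np.sqrt(np.outer(counts, counts))
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(norm > 0, co / np.maximum(norm, 1e-300), 0.0)
    np.fill_diagonal(values, 1.0)
    np.clip(values, 0.0, 1.0, out=values)
    return SimilarityMatrix(list(features), values)


def similarity_submatrix(sim: SimilarityMatrix, features: Sequence[str]) -> SimilarityMatrix:
    """Principal submatrix in the requested feature order."""
    return sim.submatrix(features)
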