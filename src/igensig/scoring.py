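"""Integral genomic signature scores and the Youden D-line.

A patient's class score aggregates the phi weights of the retained
features it carries for one response class (sensitive or resistant),
penalizing redundancy:

    EW_i  = |omega_i| / eps_i          (effective weight)
    EFN   = sum_i 1 / eps_i            (effective feature number)
    score = sum_i EW_i / EFN

where eps_i is the per-patient redundancy penalty of the i-th retained
class feature the patient carries.  EFN — the sum of the penalty
reciprocals, equivalently n over the *harmonic* mean penalty — counts
how many effectively distinct features the patient carries (a block of
k near-copies counts once), so the score is the penalty-weighted mean
|omega| per effective feature.  With no redundancy (all eps = 1) it
reduces to the plain mean |omega| of the carried class features;
duplicating every feature k-fold leaves it unchanged.

Each patient therefore gets a (resistant, sensitive) score pair.  A
dividing line ("D-line") through the origin of that plane is fitted on
training data by maximizing the Youden index J = TPR - FPR over an angle
grid, and the final score is the signed perpendicular distance to the
D-line: positive above the line = predicted sensitive (pCR).

Training patients are scored with leave-one-out reweighting so their own
labels never inform their scores; the D-line is fitted on those
leave-one-out score pairs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .features import prune_level1, prune_same_trend
from .matrix import (
    FeatureMatrix,
    read_feature_matrix,
    read_labels,
    write_feature_matrix,
    write_labels,
)
from .penalty import epsilon_vector
from .similarity import SimilarityMatrix, ochiai_matrix
from .weighting import DEFAULT_CUTOFF, compute_weights, read_weight_table, weights_from_counts, write_weight_table

__all__ = [
    "ModelConfig",
    "DLine",
    "ModelArtifact",
    "class_score",
    "fit_dline",
    "final_score",
    "train",
    "score_cohort",
]

SENSITIVE, RESISTANT = "sensitive", "resistant"


@dataclass(frozen=True)
class ModelConfig:
    """Algorithm parameters; defaults are the model's standard settings."""

    cutoff: float = DEFAULT_CUTOFF         # |phi| retention threshold
    deep_split: int = 2                    # dynamic tree cut aggressiveness (0..4)
    min_cluster_size: int = 2
    cut_height_fraction: float = 0.99      # static cut as fraction of top merge
    angle_step_deg: float = 0.5            # D-line Youden grid resolution
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass(frozen=True)
class DLine:
    """Dividing line S = m * R through the origin of score space."""

    slope: float
    theta_deg: float
    youden_j: float
    angle_step_deg: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DLine":
        return cls(**d)


def class_score(
    patient_features: Sequence[str],
    weights: pd.DataFrame,
    sim: SimilarityMatrix,
    klass: str,
    deep_split: int = 2,
    min_cluster_size: int = 2,
    cut_height_fraction: float = 0.99,
) -> float:
    """Redundancy-penalized class score for one patient.

    ``patient_features`` is the patient's full carried feature list; it is
    restricted here to the retained features of ``klass``.  Returns 0.0
    when the patient carries no retained features of that class.
    """
    if klass not in (SENSITIVE, RESISTANT):
        raise ValueError(f"unknown class {klass!r}")
    ids = [
        f
        for f in patient_features
        if f in weights.index and weights.at[f, "retained"] and weights.at[f, "klass"] == klass
    ]
    if not ids:
        return 0.0
    omega = np.abs(weights.loc[ids, "omega"].to_numpy(dtype=float))
    pen = epsilon_vector(
        ids, sim, deep_split=deep_split,
        min_cluster_size=min_cluster_size, cut_height_fraction=cut_height_fraction,
    )
    ew_sum = float((omega / pen.epsilon).sum())
    efn = float((1.0 / pen.epsilon).sum())  # n over the harmonic mean penalty
    return ew_sum / efn


def fit_dline(
    resistant: np.ndarray,
    sensitive: np.ndarray,
    labels: np.ndarray,
    angle_step_deg: float = 0.5,
) -> DLine:
    """Fit the D-line slope by maximizing the training Youden index.

    Classification rule at angle theta: sensitive iff S > tan(theta) * R.
    The grid runs from ``angle_step_deg/..`` below 90 degrees; ties go to
    the smallest angle.
    """
    r = np.asarray(resistant, dtype=float)
    s = np.asarray(sensitive, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (np.isfinite(r).all() and np.isfinite(s).all()):
        raise ValueError("non-finite class scores")
    if y.min() == y.max():
        raise ValueError("both response classes required to fit the D-line")
    thetas = np.arange(angle_step_deg, 90.0, angle_step_deg)
    slopes = np.tan(np.deg2rad(thetas))
    pred = s[None, :] > slopes[:, None] * r[None, :]  # (n_angles, n_patients)
    pos, neg = y == 1, y == 0
    tpr = pred[:, pos].mean(axis=1)
    fpr = pred[:, neg].mean(axis=1)
    j = tpr - fpr
    best = int(np.argmax(j))  # argmax takes the first (smallest) angle on ties
    if np.ptp(r) == 0 and np.ptp(s) == 0:
        warnings.warn("degenerate identical scores; D-line slope defaults to 1", stacklevel=2)
        theta = 45.0
        return DLine(1.0, theta, float(j[np.argmin(np.abs(thetas - theta))]), angle_step_deg)
    return DLine(float(slopes[best]), float(thetas[best]), float(j[best]), angle_step_deg)


def final_score(resistant: float, sensitive: float, dline: DLine) -> float:
    """Signed perpendicular distance to the D-line; positive = sensitive side."""
    m = dline.slope
    return float((sensitive - m * resistant) / np.sqrt(1.0 + m * m))


# ---------------------------------------------------------------------
# model artifact: everything needed to score a new cohort
# ---------------------------------------------------------------------


@dataclass
class ModelArtifact:
    """Self-contained trained model.

    Scoring an external cohort needs only the weight table, the reference
    similarity over the model's feature universe, the D-line and the
    config.  The training incidence and labels are kept so that training
    patients can be re-scored with leave-one-out weights.
    """

    weights: pd.DataFrame
    similarity: SimilarityMatrix
    dline: DLine
    config: ModelConfig
    train_features: FeatureMatrix
    train_labels: pd.Series
    training_scores: pd.DataFrame = field(repr=False, default=None)

    @property
    def retained_features(self) -> list[str]:
        return list(self.weights.index[self.weights["retained"]])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_weight_table(self.weights, directory / "weights.tsv")
        self.similarity.write_tsv(directory / "similarity.tsv")
        (directory / "similarity_features.txt").write_text(
            "\n".join(self.similarity.feature_ids) + "\n", encoding="utf-8"
        )
        (directory / "dline.json").write_text(json.dumps(self.dline.to_dict(), indent=2) + "\n")
        (directory / "config.yaml").write_text(yaml.safe_dump(self.config.to_dict()))
        write_feature_matrix(self.train_features, directory / "train_features.tsv")
        write_labels(self.train_labels, directory / "train_labels.tsv")
        if self.training_scores is not None:
            self.training_scores.to_csv(directory / "training_scores.tsv", sep="\t", index=False, lineterminator="\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelArtifact":
        directory = Path(directory)
        feature_ids = (directory / "similarity_features.txt").read_text(encoding="utf-8").splitlines()
        scores_path = directory / "training_scores.tsv"
        return cls(
            weights=read_weight_table(directory / "weights.tsv"),
            similarity=SimilarityMatrix.read_tsv(directory / "similarity.tsv", feature_ids),
            dline=DLine.from_dict(json.loads((directory / "dline.json").read_text())),
            config=ModelConfig.from_dict(yaml.safe_load((directory / "config.yaml").read_text())),
            train_features=read_feature_matrix(directory / "train_features.tsv"),
            train_labels=read_labels(directory / "train_labels.tsv"),
            training_scores=pd.read_csv(scores_path, sep="\t") if scores_path.exists() else None,
        )


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------


def _loo_weight_table(
    fm: FeatureMatrix, labels: pd.Series, patient: str, cutoff: float
) -> pd.DataFrame:
    """Leave-one-out weights via contingency-count adjustment (fast path)."""
    x = fm.subset_patients(list(labels.index)).incidence.astype(np.int64)
    y = labels.to_numpy(dtype=np.int64)
    i = list(labels.index).index(patient)
    a = x.T @ y - x[i] * y[i]
    n1 = x.sum(axis=0) - x[i]
    m1 = int(y.sum()) - int(y[i])
    return weights_from_counts(fm.feature_ids, a, n1, m1, len(y) - 1, cutoff)


def train(
    fm: FeatureMatrix,
    labels: pd.Series,
    reference: FeatureMatrix,
    config: ModelConfig | None = None,
) -> ModelArtifact:
    """Fit the full model on a labeled cohort plus an unlabeled reference.

    Pipeline: prune level-1 expression features, compute phi weights,
    prune same-trend genes, build the reference co-occurrence similarity
    over every feature any weighting (full or leave-one-out) retains,
    score each training patient with leave-one-out weights, and fit the
    D-line on those scores.
    """
    config = config or ModelConfig()
    fm = prune_level1(fm)
    w0 = compute_weights(fm, labels, config.cutoff)
    fm = prune_same_trend(fm, w0)
    weights = w0.loc[fm.feature_ids]
    if not weights["retained"].any():
        raise ValueError("no features retained after pruning; cannot train")

    # leave-one-out weight tables per training patient (fast count update)
    sub = fm.subset_patients(list(labels.index))
    x = sub.incidence.astype(np.int64)
    y = labels.to_numpy(dtype=np.int64)
    a_full = x.T @ y
    n1_full = x.sum(axis=0)
    m1_full = int(y.sum())
    n_full = len(y)
    loo_tables: dict[str, pd.DataFrame] = {}
    for i, patient in enumerate(labels.index):
        if (m1_full - y[i]) == 0 or (n_full - 1 - (m1_full - y[i])) == 0:
            raise ValueError(f"removing {patient!r} leaves a single response class")
        loo_tables[patient] = weights_from_counts(
            fm.feature_ids,
            a_full - x[i] * y[i],
            n1_full - x[i],
            m1_full - int(y[i]),
            n_full - 1,
            config.cutoff,
        )

    universe = set(weights.index[weights["retained"]])
    for t in loo_tables.values():
        universe.update(t.index[t["retained"]])
    universe = sorted(universe)
    sim = ochiai_matrix(reference, universe)

    # leave-one-out training scores and the D-line
    rows = []
    for i, patient in enumerate(labels.index):
        carried = [fm.feature_ids[j] for j in np.flatnonzero(x[i])]
        w_p = loo_tables[patient]
        r = _patient_class_score(carried, w_p, sim, RESISTANT, config)
        s = _patient_class_score(carried, w_p, sim, SENSITIVE, config)
        rows.append((patient, s, r, int(y[i])))
    scores = pd.DataFrame(rows, columns=["patient_id", "sensitive_score", "resistant_score", "response"])
    dline = fit_dline(
        scores["resistant_score"].to_numpy(),
        scores["sensitive_score"].to_numpy(),
        scores["response"].to_numpy(),
        config.angle_step_deg,
    )
    scores["final_score"] = [
        final_score(r, s, dline)
        for r, s in zip(scores["resistant_score"], scores["sensitive_score"])
    ]
    scores["predicted"] = (scores["final_score"] > 0).astype(int)
    return ModelArtifact(
        weights=weights,
        similarity=sim,
        dline=dline,
        config=config,
        train_features=sub,
        train_labels=labels,
        training_scores=scores.drop(columns=["response"]),
    )


def _patient_class_score(
    carried: Sequence[str], weights: pd.DataFrame, sim: SimilarityMatrix, klass: str, config: ModelConfig
) -> float:
    known = [f for f in carried if f in sim._index]
    return class_score(
        known, weights, sim, klass,
        deep_split=config.deep_split,
        min_cluster_size=config.min_cluster_size,
        cut_height_fraction=config.cut_height_fraction,
    )


def score_cohort(artifact: ModelArtifact, fm: FeatureMatrix, loo: bool = False) -> pd.DataFrame:
    """Score every patient in a cohort against a trained model.

    With ``loo=True`` (training patients only) each patient is scored
    with the weight table recomputed without that patient, reproducing
    the scores the D-line was fitted on.  Patients carrying none of the
    model's retained features score (0, 0) and are predicted non-sensitive.
    """
    config = artifact.config
    rows = []
    for patient in fm.patient_ids:
        carried = fm.patient_features(patient)
        if loo:
            if patient not in artifact.train_labels.index:
                raise KeyError(f"{patient!r} is not a training patient; loo scoring unavailable")
            w = _loo_weight_table(
                artifact.train_features, artifact.train_labels, patient, config.cutoff
            )
        else:
            w = artifact.weights
        r = _patient_class_score(carried, w, artifact.similarity, RESISTANT, config)
        s = _patient_class_score(carried, w, artifact.similarity, SENSITIVE, config)
        d = final_score(r, s, artifact.dline)
        rows.append((patient, s, r, d, int(d > 0)))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sensitive_score", "resistant_score", "final_score", "predicted"],
    )


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    out = scores.copy()
    for col in ("sensitive_score", "resistant_score", "final_score"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
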