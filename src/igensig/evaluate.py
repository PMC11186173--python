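"""Evaluation harness: AUROC, split/repeat experiments, error robustness.

AUROC is computed as the scaled Mann-Whitney U statistic (ties count
half), which equals the trapezoidal area under the ROC curve.  The split
experiment repeats stratified 90/10 train/test partitions; the
robustness experiment corrupts either the training or the validation
features at increasing error rates and contrasts the signature model
with an L1-regularized logistic ("lasso") baseline fitted directly on
the binary features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedShuffleSplit

from .matrix import FeatureMatrix
from .scoring import ModelConfig, score_cohort, train
from .simulate import ErrorSpec, inject_errors

__all__ = [
    "EvalReport",
    "auroc",
    "split_experiment",
    "robustness_experiment",
    "l1_baseline",
]

DEFAULT_ERROR_RATES = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass
class EvalReport:
    """Aggregate AUROC over repeated train/test splits."""

    auroc_mean: float
    auroc_sd: float | None
    per_repeat: pd.DataFrame
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auroc_mean": self.auroc_mean,
            "auroc_sd": self.auroc_sd,
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "config": self.config,
        }


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the scaled Mann-Whitney U statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes")
    ranks = scipy.stats.rankdata(s)  # average ranks: ties count 0.5
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _stratified_splits(labels: pd.Series, train_fraction: float, repeats: int, seed: int):
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, train_size=train_fraction, random_state=seed
    )
    y = labels.to_numpy(dtype=int)
    idx = np.arange(len(labels))
    for train_idx, test_idx in splitter.split(idx.reshape(-1, 1), y):
        if len(set(y[train_idx])) < 2 or len(set(y[test_idx])) < 2:
            raise ValueError(
                "stratified split left a single response class in one part; "
                "cohort too small or too unbalanced"
            )
        yield (
            [labels.index[i] for i in sorted(train_idx)],
            [labels.index[i] for i in sorted(test_idx)],
        )


def split_experiment(
    fm: FeatureMatrix,
    labels: pd.Series,
    reference: FeatureMatrix,
    train_fraction: float = 0.9,
    repeats: int = 10,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> EvalReport:
    """Repeated stratified train/test splits; held-out AUROC per repeat."""
    config = config or ModelConfig(seed=seed)
    rows = []
    for rep, (train_ids, test_ids) in enumerate(
        _stratified_splits(labels, train_fraction, repeats, seed)
    ):
        artifact = train(fm.subset_patients(train_ids), labels.loc[train_ids], reference, config)
        scored = score_cohort(artifact, fm.subset_patients(test_ids))
        a = auroc(scored["final_score"].to_numpy(), labels.loc[test_ids].to_numpy())
        rows.append({"repeat": rep, "auroc": a, "youden_j": artifact.dline.youden_j})
    per_repeat = pd.DataFrame(rows)
    return EvalReport(
        auroc_mean=float(per_repeat["auroc"].mean()),
        auroc_sd=float(per_repeat["auroc"].std(ddof=1)) if repeats > 1 else None,
        per_repeat=per_repeat,
        config={"train_fraction": train_fraction, "repeats": repeats, "seed": seed},
    )


def l1_baseline(
    fm: FeatureMatrix,
    labels: pd.Series,
    test_fm: FeatureMatrix,
    seed: int = 0,
) -> np.ndarray:
    """Lasso-style logistic baseline on the raw binary features.

    L1-regularized logistic regression with the penalty chosen by
    internal cross-validation; returns decision-function scores for the
    test cohort, aligned to the training feature universe.
    """
    y = labels.to_numpy(dtype=int)
    if len(set(y)) < 2:
        raise ValueError("baseline needs both classes in training labels")
    x = fm.subset_patients(list(labels.index)).incidence.astype(np.float64)
    model = LogisticRegressionCV(
        l1_ratios=(1.0,), solver="liblinear", Cs=10, cv=3,
        scoring="roc_auc", random_state=seed, max_iter=1000,
        use_legacy_attributes=False,
    )
    model.fit(x, y)
    x_test = test_fm.align_features(fm.feature_ids).incidence.astype(np.float64)
    return model.decision_function(x_test)


def robustness_experiment(
    fm: FeatureMatrix,
    labels: pd.Series,
    reference: FeatureMatrix,
    rates: tuple[float, ...] = DEFAULT_ERROR_RATES,
    target: str = "validation",
    baseline: bool = True,
    error_seeds: int = 5,
    mode: str = "false_negative",
    train_fraction: float = 0.9,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Feature-error robustness: AUROC vs error rate, signature vs lasso.

    For each error rate and error seed a stratified train/test split is
    drawn, errors are injected into the ``target`` matrix (training or
    validation side), models are retrained/rescored, and held-out AUROC
    recorded.  Returns a tidy table (rate, method, auroc mean/sd).

    Errors are injected in one direction at a time; the default,
    ``false_negative``, emulates features lost to insufficient depth or
    dropout — the error mechanism feature redundancy is designed to
    absorb.  ``false_positive`` floods the matrix with spurious carried
    features instead, a qualitatively different (and for an integral
    scoring model harsher) corruption.
    """
    if target not in ("train", "validation"):
        raise ValueError(f"unknown target {target!r}")
    config = config or ModelConfig(seed=seed)
    splits = list(_stratified_splits(labels, train_fraction, error_seeds, seed))
    records = []
    for rate in rates:
        for es, (train_ids, test_ids) in enumerate(splits):
            err_seed = (seed * 100003 + es * 1009 + int(rate * 1000)) % (2**31 - 1)
            train_fm = fm.subset_patients(train_ids)
            test_fm = fm.subset_patients(test_ids)
            spec = ErrorSpec(rate=rate, mode=mode, target=target, seed=err_seed)
            if target == "train":
                train_fm = inject_errors(train_fm, spec)
            else:
                test_fm = inject_errors(test_fm, spec)
            y_test = labels.loc[test_ids].to_numpy()
            artifact = train(train_fm, labels.loc[train_ids], reference, config)
            scored = score_cohort(artifact, test_fm)
            records.append(
                {"rate": rate, "method": "igensig", "error_seed": es,
                 "auroc": auroc(scored["final_score"].to_numpy(), y_test)}
            )
            if baseline:
                base_scores = l1_baseline(train_fm, labels.loc[train_ids], test_fm, seed=err_seed)
                records.append(
                    {"rate": rate, "method": "lasso", "error_seed": es,
                     "auroc": auroc(base_scores, y_test)}
                )
    tidy = pd.DataFrame(records)
    summary = (
        tidy.groupby(["rate", "method"], as_index=False)["auroc"]
        .agg(auroc_mean="mean", auroc_sd="std")
    )
    summary.attrs["per_seed"] = tidy
    return summary
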