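"""Phi-coefficient feature weights against binary therapeutic response.

The weight of a genomic feature is its phi coefficient (Pearson product-
moment correlation of two 0/1 vectors, a.k.a. mean square contingency
coefficient) with the pCR label.  Features pass the significance cutoff
when |omega| >= cutoff (default 0.13); the sign assigns the class:
positive = sensitive (enriched in pCR), negative = resistant.

Weight tables are plain pandas DataFrames indexed by feature_id with
columns ``omega`` (float), ``klass`` ("sensitive"/"resistant") and
``retained`` (bool).

When scoring a *training* patient the model re-derives the weights with
that patient held out (leave-one-out), so no patient's own label leaks
into its score; external cohorts are scored with the full-cohort weights.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix

__all__ = [
    "DEFAULT_CUTOFF",
    "phi_coefficient",
    "compute_weights",
    "loo_adjusted_weights",
    "weights_from_counts",
    "read_weight_table",
    "write_weight_table",
]

DEFAULT_CUTOFF = 0.13


def phi_coefficient(feature_column: np.ndarray, labels: np.ndarray) -> float:
    """Phi coefficient of a binary feature with binary labels.

    From the 2x2 contingency table (a = both 1, b = feature only,
    c = label only, d = neither):

        phi = (a*d - b*c) / sqrt((a+b) * (c+d) * (a+c) * (b+d))

    A constant feature column has zero variance and gets phi = 0; labels
    containing a single class are a hard error.
    """
    f = np.asarray(feature_column, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)
    if f.shape != y.shape or f.ndim != 1 or f.size < 2:
        raise ValueError("feature and labels must be 1-D vectors of equal length >= 2")
    if y.min() == y.max():
        raise ValueError("labels contain a single class")
    a = int(f @ y)
    n1 = int(f.sum())
    m1 = int(y.sum())
    n = f.size
    b, c = n1 - a, m1 - a
    d = n - a - b - c
    denom = n1 * (n - n1) * m1 * (n - m1)
    if denom == 0:
        return 0.0
    return float((a * d - b * c) / np.sqrt(denom))


def weights_from_counts(
    feature_ids: list[str],
    a: np.ndarray,
    n1: np.ndarray,
    m1: int,
    n: int,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Vectorized weight table from per-feature contingency counts.

    ``a`` = carriers among responders, ``n1`` = carriers overall,
    ``m1`` = responders, ``n`` = cohort size.
    """
    a = a.astype(np.float64)
    n1 = n1.astype(np.float64)
    denom = n1 * (n - n1) * float(m1) * float(n - m1)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(denom > 0, (a * n - n1 * m1) / np.sqrt(np.maximum(denom, 1e-300)), 0.0)
    retained = np.abs(omega) >= cutoff
    return pd.DataFrame(
        {
            "omega": omega,
            "klass": np.where(omega > 0, "sensitive", "resistant"),
            "retained": retained,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def _counts(fm: FeatureMatrix, labels: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    missing = [p for p in labels.index if p not in fm._patient_index]
    if missing:
        raise KeyError(f"labeled patients missing from feature matrix: {missing[:5]}")
    sub = fm.subset_patients(list(labels.index))
    x = sub.incidence.astype(np.int64)
    y = labels.to_numpy(dtype=np.int64)
    if y.min() == y.max():
        raise ValueError("labels contain a single class")
    return x, x.T @ y, x.sum(axis=0), int(y.sum())


def compute_weights(
    fm: FeatureMatrix, labels: pd.Series, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Per-feature phi weights with the |omega| >= cutoff retention rule."""
    if fm.n_features == 0:
        warnings.warn("empty feature set: weight table is empty", stacklevel=2)
        return weights_from_counts([], np.zeros(0), np.zeros(0), 1, 2, cutoff)
    _, a, n1, m1 = _counts(fm, labels)
    return weights_from_counts(fm.feature_ids, a, n1, m1, len(labels), cutoff)


def loo_adjusted_weights(
    fm: FeatureMatrix, labels: pd.Series, held_out: str, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Weights recomputed with one training patient removed.

    Identical to :func:`compute_weights` on the remaining cohort; used to
    score the held-out patient itself without label leakage.
    """
    if held_out not in labels.index:
        raise KeyError(f"{held_out!r} is not a labeled patient")
    rest = labels.drop(held_out)
    if rest.min() == rest.max():
        raise ValueError(f"removing {held_out!r} leaves a single response class")
    return compute_weights(fm, rest, cutoff)


def read_weight_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    df["retained"] = df["retained"].astype(bool)
    return df


def write_weight_table(weights: pd.DataFrame, path) -> None:
    out = weights.copy()
    out["omega"] = out["omega"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", lineterminator="\n")
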