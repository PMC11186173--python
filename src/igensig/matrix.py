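"""Binary patient x feature incidence matrices and their on-disk dialects.

The central container is :class:`FeatureMatrix`, a dense 0/1 matrix of
patients (rows) by genomic features (columns).  Feature identifiers are
namespaced opaque strings, e.g. ``EXPR:ERBB2|Up_L3``, ``MUT:TP53`` or
``AGR:BCAS3-BCAS4``; absence of a (patient, feature) record means 0.

Two text dialects are supported:

* ``long-tsv`` — header ``patient_id<TAB>feature_id`` followed by one row
  per set bit.  Writing is canonical (patients, then features, in matrix
  order), so write/read round-trips are byte-identical.
* ``mtx-triplet`` — a MatrixMarket ``coordinate pattern`` file plus two
  sidecar label files (``<stem>.rows.txt`` / ``<stem>.cols.txt``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "FeatureMatrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
    "read_expression",
]


@dataclass
class FeatureMatrix:
    """Dense binary incidence of patients (rows) by features (columns)."""

    patient_ids: list[str]
    feature_ids: list[str]
    incidence: np.ndarray  # uint8, shape (n_patients, n_features)

    _patient_index: dict[str, int] = field(init=False, repr=False)
    _feature_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.patient_ids = list(self.patient_ids)
        self.feature_ids = list(self.feature_ids)
        self.incidence = np.ascontiguousarray(self.incidence, dtype=np.uint8)
        if self.incidence.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise ValueError(
                f"incidence shape {self.incidence.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.incidence.size and self.incidence.max() > 1:
            raise ValueError("incidence values must be 0 or 1")
        self._patient_index = {p: i for i, p in enumerate(self.patient_ids)}
        self._feature_index = {f: j for j, f in enumerate(self.feature_ids)}

    # -- basic queries -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def patient_row(self, patient_id: str) -> np.ndarray:
        return self.incidence[self._patient_index[patient_id]]

    def feature_column(self, feature_id: str) -> np.ndarray:
        return self.incidence[:, self._feature_index[feature_id]]

    def feature_indices(self, feature_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._feature_index[f] for f in feature_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from None

    def patient_features(self, patient_id: str) -> list[str]:
        """Feature ids carried by one patient."""
        row = self.patient_row(patient_id)
        return [self.feature_ids[j] for j in np.flatnonzero(row)]

    # -- subsetting ----------------------------------------------------

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        idx = self.feature_indices(feature_ids)
        return FeatureMatrix(self.patient_ids, list(feature_ids), self.incidence[:, idx])

    def subset_patients(self, patient_ids: Sequence[str]) -> "FeatureMatrix":
        try:
            idx = np.array([self._patient_index[p] for p in patient_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown patient id {exc.args[0]!r}") from None
        return FeatureMatrix(list(patient_ids), self.feature_ids, self.incidence[idx])

    def align_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        """Project onto an external feature universe; absent features become 0."""
        out = np.zeros((self.n_patients, len(feature_ids)), dtype=np.uint8)
        for j, f in enumerate(feature_ids):
            k = self._feature_index.get(f)
            if k is not None:
                out[:, j] = self.incidence[:, k]
        return FeatureMatrix(self.patient_ids, list(feature_ids), out)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.patient_ids, self.feature_ids, self.incidence.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.patient_ids == other.patient_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.incidence, other.incidence)
        )

    # -- construction --------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        patient_ids: Sequence[str] | None = None,
        feature_ids: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        """Build from (patient, feature) set-bit pairs.

        Duplicate pairs are a hard error: on-disk duplicates usually mean a
        corrupt export rather than an intentional idempotent record.
        """
        pairs = list(pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (patient_id, feature_id) pair in input")
        if patient_ids is None:
            patient_ids = sorted({p for p, _ in pairs})
        if feature_ids is None:
            feature_ids = sorted({f for _, f in pairs})
        fm = cls(
            list(patient_ids),
            list(feature_ids),
            np.zeros((len(patient_ids), len(feature_ids)), dtype=np.uint8),
        )
        for p, f in pairs:
            if p not in fm._patient_index or f not in fm._feature_index:
                raise ValueError(f"pair ({p!r}, {f!r}) references an undeclared id")
            fm.incidence[fm._patient_index[p], fm._feature_index[f]] = 1
        return fm


# ---------------------------------------------------------------------
# long-tsv / mtx-triplet dialects
# ---------------------------------------------------------------------

_LONG_TSV_HEADER = "patient_id\tfeature_id"


def read_feature_matrix(path: str | Path, format: str = "long-tsv") -> FeatureMatrix:
    """Read a binary feature matrix in the named dialect."""
    path = Path(path)
    if format == "long-tsv":
        return _read_long_tsv(path)
    if format == "mtx-triplet":
        return _read_mtx_triplet(path)
    raise ValueError(f"unknown feature matrix format {format!r}")


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, format: str = "long-tsv") -> None:
    path = Path(path)
    if format == "long-tsv":
        _write_long_tsv(fm, path)
    elif format == "mtx-triplet":
        _write_mtx_triplet(fm, path)
    else:
        raise ValueError(f"unknown feature matrix format {format!r}")


def _read_long_tsv(path: Path) -> FeatureMatrix:
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or lines[0] != _LONG_TSV_HEADER:
        raise ValueError(f"{path}: expected header {_LONG_TSV_HEADER!r}")
    pairs: list[tuple[str, str]] = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{ln}: malformed row {line!r}")
        pairs.append((parts[0], parts[1]))
    return FeatureMatrix.from_pairs(pairs)


def _write_long_tsv(fm: FeatureMatrix, path: Path) -> None:
    buf = io.StringIO()
    buf.write(_LONG_TSV_HEADER + "\n")
    # canonical order: sorted ids, matching from_pairs' reconstruction
    for p in sorted(fm.patient_ids):
        row = fm.patient_row(p)
        for f in sorted(fm.feature_ids):
            if row[fm._feature_index[f]]:
                buf.write(f"{p}\t{f}\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def _read_mtx_triplet(path: Path) -> FeatureMatrix:
    rows_path, cols_path = _sidecar_paths(path)
    for p in (path, rows_path, cols_path):
        if not p.exists():
            raise FileNotFoundError(f"missing mtx-triplet component: {p}")
    mat = scipy.io.mmread(str(path)).tocoo()
    if len(set(zip(mat.row.tolist(), mat.col.tolist()))) != mat.nnz:
        raise ValueError(f"{path}: duplicate (patient, feature) entry")
    patient_ids = rows_path.read_text(encoding="utf-8").splitlines()
    feature_ids = cols_path.read_text(encoding="utf-8").splitlines()
    dense = np.zeros((len(patient_ids), len(feature_ids)), dtype=np.uint8)
    dense[mat.row, mat.col] = 1
    return FeatureMatrix(patient_ids, feature_ids, dense)


def _write_mtx_triplet(fm: FeatureMatrix, path: Path) -> None:
    rows_path, cols_path = _sidecar_paths(path)
    sparse = scipy.sparse.coo_matrix(fm.incidence)
    scipy.io.mmwrite(str(path), sparse, field="pattern", symmetry="general")
    rows_path.write_text("\n".join(fm.patient_ids) + ("\n" if fm.patient_ids else ""), encoding="utf-8")
    cols_path.write_text("\n".join(fm.feature_ids) + ("\n" if fm.feature_ids else ""), encoding="utf-8")


# ---------------------------------------------------------------------
# labels and expression tables
# ---------------------------------------------------------------------


def read_labels(path: str | Path) -> pd.Series:
    """Read a response label vector: TSV ``patient_id<TAB>response`` in {0,1}.

    1 = pathological complete response (treatment-sensitive), 0 = non-pCR.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if list(df.columns) != ["patient_id", "response"]:
        raise ValueError(f"{path}: expected columns patient_id, response")
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patient id")
    if not df["response"].isin([0, 1]).all():
        raise ValueError(f"{path}: responses must be 0 or 1")
    return pd.Series(df["response"].to_numpy(dtype=np.int8), index=df["patient_id"], name="response")


def write_labels(labels: Mapping[str, int] | pd.Series, path: str | Path) -> None:
    s = pd.Series(labels, name="response")
    df = pd.DataFrame({"patient_id": s.index, "response": s.to_numpy(dtype=np.int8)})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x patients continuous expression table (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene id")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite expression value")
    return df
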