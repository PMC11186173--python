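"""Deriving binary genomic features from omics tables, and pruning rules.

Continuous gene expression is discretized into *nested* binary features at
twelve stringency levels per direction: ``EXPR:<gene>|Up_Lk`` is set when a
patient's within-cohort percentile rank for that gene reaches the level-k
up-cutoff, ``EXPR:<gene>|Down_Lk`` when it falls below the level-k
down-cutoff.  Nesting (membership at level k+1 implies level k) makes the
levels deliberately redundant; the scoring model penalizes that redundancy
rather than pruning it.

Somatic variant tables become one feature per mutated gene (``MUT:<gene>``)
or adjacent gene rearrangement (``AGR:<geneA>-<geneB>``).

Two pruning rules clean the expression features before modeling:

* level-1 features (the weakest up/down stringency) are dropped outright;
* genes whose up- and down-regulation features both predict response in the
  same direction are dropped entirely (internally inconsistent signal).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .matrix import FeatureMatrix

__all__ = [
    "LevelScheme",
    "derive_expression_features",
    "derive_variant_features",
    "prune_level1",
    "prune_same_trend",
]

_N_LEVELS = 12

_EXPR_RE = re.compile(r"^EXPR:(?P<gene>.+)\|(?P<dir>Up|Down)_L(?P<level>\d+)$")


@dataclass(frozen=True)
class LevelScheme:
    """Percentile cutoffs for the twelve nested up/down expression levels.

    ``up_cutoffs[k-1]`` is the minimum percentile for membership in
    ``Up_Lk``; ``down_cutoffs[k-1]`` the maximum percentile for ``Down_Lk``.
    Defaults are evenly spaced: Up >= 52, 56, ..., 96 and Down <= 48, 44,
    ..., 4, so level 1 is the weakest call and level 12 the most extreme
    4% tail.
    """

    up_cutoffs: tuple[float, ...] = tuple(48.0 + 4.0 * k for k in range(1, _N_LEVELS + 1))
    down_cutoffs: tuple[float, ...] = tuple(52.0 - 4.0 * k for k in range(1, _N_LEVELS + 1))

    def __post_init__(self) -> None:
        up, down = self.up_cutoffs, self.down_cutoffs
        if len(up) != _N_LEVELS or len(down) != _N_LEVELS:
            raise ValueError(f"level scheme needs exactly {_N_LEVELS} cutoffs per direction")
        if not all(50 < u < 100 for u in up) or list(up) != sorted(set(up)):
            raise ValueError("up cutoffs must be strictly increasing in (50, 100)")
        if not all(0 < d < 50 for d in down) or list(down) != sorted(set(down), reverse=True):
            raise ValueError("down cutoffs must be strictly decreasing in (0, 50)")

    @classmethod
    def from_dict(cls, d: dict) -> "LevelScheme":
        return cls(tuple(float(x) for x in d["up_cutoffs"]), tuple(float(x) for x in d["down_cutoffs"]))

    def to_dict(self) -> dict:
        return {"up_cutoffs": list(self.up_cutoffs), "down_cutoffs": list(self.down_cutoffs)}


def parse_expression_feature(feature_id: str) -> tuple[str, str, int] | None:
    """Split ``EXPR:<gene>|<Up|Down>_L<k>`` into (gene, direction, level)."""
    m = _EXPR_RE.match(feature_id)
    if m is None:
        return None
    return m.group("gene"), m.group("dir"), int(m.group("level"))


def derive_expression_features(
    expr: pd.DataFrame, scheme: LevelScheme | None = None
) -> FeatureMatrix:
    """Discretize a genes x patients expression table into level features.

    Percentiles are average ranks across the cohort scaled to (0, 100]
    (ties share a rank), so the result does not depend on measurement
    units.  Genes constant across the cohort are uninformative and emit
    no features.  Only features carried by at least one patient are kept.
    """
    scheme = scheme or LevelScheme()
    if expr.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 patients")
    patients = [str(p) for p in expr.columns]
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression values must be finite")

    columns: dict[str, np.ndarray] = {}
    n = len(patients)
    for gene, row in zip(expr.index.astype(str), values):
        if np.ptp(row) == 0:  # constant gene: percentile carries no signal
            continue
        pct = scipy.stats.rankdata(row, method="average") * (100.0 / n)
        for k, cut in enumerate(scheme.up_cutoffs, start=1):
            mask = pct >= cut
            if mask.any():
                columns[f"EXPR:{gene}|Up_L{k}"] = mask
        for k, cut in enumerate(scheme.down_cutoffs, start=1):
            mask = pct <= cut
            if mask.any():
                columns[f"EXPR:{gene}|Down_L{k}"] = mask

    feature_ids = list(columns)
    inc = (
        np.column_stack([columns[f] for f in feature_ids]).astype(np.uint8)
        if feature_ids
        else np.zeros((n, 0), dtype=np.uint8)
    )
    return FeatureMatrix(patients, feature_ids, inc)


def derive_variant_features(variants: pd.DataFrame) -> FeatureMatrix:
    """Binarize a variant table with columns (patient_id, gene_or_pair, class).

    ``class`` is ``MUT`` for somatic mutations or ``AGR`` for adjacent gene
    rearrangements; repeated records for the same (patient, feature) are
    idempotent.
    """
    required = ["patient_id", "gene_or_pair", "class"]
    if list(variants.columns) != required:
        raise ValueError(f"variant table must have columns {required}")
    pairs: set[tuple[str, str]] = set()
    for i, row in enumerate(variants.itertuples(index=False), start=1):
        patient, gene, klass = (str(row[0]), str(row[1]), str(row[2]))
        if klass not in ("MUT", "AGR") or not patient or not gene or gene == "nan":
            raise ValueError(f"malformed variant row {i}: {tuple(row)!r}")
        pairs.add((patient, f"{klass}:{gene}"))
    return FeatureMatrix.from_pairs(sorted(pairs))


def prune_level1(fm: FeatureMatrix) -> FeatureMatrix:
    """Drop all level-1 expression features (weakest up/down calls)."""
    keep = []
    for f in fm.feature_ids:
        parsed = parse_expression_feature(f)
        if parsed is not None and parsed[2] == 1:
            continue
        keep.append(f)
    return fm.subset_features(keep)


def prune_same_trend(fm: FeatureMatrix, weights: pd.DataFrame) -> FeatureMatrix:
    """Drop genes whose up and down features predict response the same way.

    If any retained ``Up`` feature and any retained ``Down`` feature of a
    gene carry same-signed weights, the gene's expression signal is
    internally inconsistent and *all* its expression features are removed.
    ``weights`` is a weight table (see :mod:`igensig.weighting`) computed on
    ``fm``'s features.
    """
    sign_sets: dict[str, dict[str, set[int]]] = {}
    for f in fm.feature_ids:
        parsed = parse_expression_feature(f)
        if parsed is None or f not in weights.index or not weights.at[f, "retained"]:
            continue
        gene, direction, _ = parsed
        omega = weights.at[f, "omega"]
        if omega == 0:
            continue
        sign_sets.setdefault(gene, {"Up": set(), "Down": set()})[direction].add(
            1 if omega > 0 else -1
        )
    bad_genes = {
        gene for gene, s in sign_sets.items() if s["Up"] & s["Down"]
    }
    keep = []
    for f in fm.feature_ids:
        parsed = parse_expression_feature(f)
        if parsed is not None and parsed[0] in bad_genes:
            continue
        keep.append(f)
    return fm.subset_features(keep)
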