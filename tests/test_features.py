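"""Expression/variant feature derivation and pruning rules."""

import numpy as np
import pandas as pd
import pytest

from igensig import (
    LevelScheme,
    compute_weights,
    derive_expression_features,
    derive_variant_features,
    prune_level1,
    prune_same_trend,
)
from igensig.features import parse_expression_feature


def expr_table(values, patients=None, gene="G1"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    patients = patients or [f"P{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=[gene] if values.shape[0] == 1 else None, columns=patients)


class TestExpressionLevels:
    def test_hand_ranked_four_patients(self):
        # values (1,2,3,4): average-rank percentiles are 25, 50, 75, 100
        fm = derive_expression_features(expr_table([1, 2, 3, 4]))
        # top patient reaches every up level (L12 cutoff 96 <= 100)
        assert fm.feature_column("EXPR:G1|Up_L12").tolist() == [0, 0, 0, 1]
        # percentile 75 reaches up levels with cutoff <= 75: L1..L6 (72)
        assert fm.feature_column("EXPR:G1|Up_L6").tolist() == [0, 0, 1, 1]
        assert "EXPR:G1|Up_L7" in fm.feature_ids  # cutoff 76: only the top patient
        assert fm.feature_column("EXPR:G1|Up_L7").tolist() == [0, 0, 0, 1]
        # percentile 25 falls below down cutoffs >= 25: L1..L6 (28)
        assert fm.feature_column("EXPR:G1|Down_L6").tolist() == [1, 0, 0, 0]

    def test_custom_scheme_strict_top_level(self):
        up = tuple(list(LevelScheme().up_cutoffs[:11]) + [99.0])
        fm = derive_expression_features(expr_table([1, 2, 3, 4]), LevelScheme(up_cutoffs=up))
        # only the maximum patient (percentile 100 >= 99) carries the top level
        assert fm.feature_column("EXPR:G1|Up_L12").tolist() == [0, 0, 0, 1]

    def test_constant_gene_emits_nothing(self):
        fm = derive_expression_features(expr_table([5, 5, 5, 5]))
        assert fm.n_features == 0

    def test_membership_is_nested_and_directions_exclusive(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 30)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"P{i}" for i in range(30)],
        )
        fm = derive_expression_features(expr)
        cols = {f: fm.feature_column(f) for f in fm.feature_ids}
        for f, col in cols.items():
            gene, direction, level = parse_expression_feature(f)
            if level > 1:
                lower = f"EXPR:{gene}|{direction}_L{level - 1}"
                assert not np.any(col & ~cols[lower]), "level k+1 must imply level k"
            opposite = "Down" if direction == "Up" else "Up"
            for k in range(1, 13):
                other = cols.get(f"EXPR:{gene}|{opposite}_L{k}")
                if other is not None:
                    assert not np.any(col & other), "up and down are mutually exclusive"

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError, match="2 patients"):
            derive_expression_features(expr_table([[1.0]], patients=["P0"]))


class TestVariantFeatures:
    def test_idempotent_and_namespaced(self):
        table = pd.DataFrame(
            [("P1", "TP53", "MUT"), ("P1", "TP53", "MUT"), ("P1", "A-B", "AGR")],
            columns=["patient_id", "gene_or_pair", "class"],
        )
        fm = derive_variant_features(table)
        assert sorted(fm.feature_ids) == ["AGR:A-B", "MUT:TP53"]
        assert fm.patient_row("P1").tolist() == [1, 1]

    def test_empty_table(self):
        table = pd.DataFrame(columns=["patient_id", "gene_or_pair", "class"])
        assert derive_variant_features(table).n_features == 0

    def test_malformed_row_reports_row_number(self):
        table = pd.DataFrame(
            [("P1", "TP53", "MUT"), ("P2", "X", "WEIRD")],
            columns=["patient_id", "gene_or_pair", "class"],
        )
        with pytest.raises(ValueError, match="row 2"):
            derive_variant_features(table)


class TestPruning:
    def _fm(self, feature_ids, incidence):
        from igensig import FeatureMatrix

        inc = np.asarray(incidence, dtype=np.uint8)
        return FeatureMatrix([f"P{i}" for i in range(inc.shape[0])], feature_ids, inc)

    def test_prune_level1_keeps_higher_levels(self):
        fm = self._fm(["EXPR:g|Up_L1", "EXPR:g|Up_L2", "MUT:g"], np.ones((2, 3)))
        out = prune_level1(fm)
        assert out.feature_ids == ["EXPR:g|Up_L2", "MUT:g"]
        assert prune_level1(out).feature_ids == out.feature_ids  # idempotent

    def test_prune_level1_no_expression_features_noop(self):
        fm = self._fm(["MUT:a", "AGR:a-b"], np.ones((2, 2)))
        assert prune_level1(fm).feature_ids == fm.feature_ids

    def test_prune_level1_can_empty_the_matrix(self):
        fm = self._fm(["EXPR:g|Up_L1", "EXPR:h|Down_L1"], np.ones((2, 2)))
        assert prune_level1(fm).n_features == 0

    def _weights(self, mapping):
        rows = {
            f: {"omega": w, "klass": "sensitive" if w > 0 else "resistant", "retained": abs(w) >= 0.13}
            for f, w in mapping.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("feature_id")

    def test_same_trend_gene_fully_removed(self):
        ids = ["EXPR:g|Up_L3", "EXPR:g|Down_L2", "EXPR:g|Up_L5", "MUT:g"]
        fm = self._fm(ids, np.ones((2, 4)))
        w = self._weights({"EXPR:g|Up_L3": 0.2, "EXPR:g|Down_L2": 0.15, "EXPR:g|Up_L5": 0.3, "MUT:g": 0.4})
        out = prune_same_trend(fm, w)
        assert out.feature_ids == ["MUT:g"]
        assert prune_same_trend(out, w).feature_ids == ["MUT:g"]  # idempotent

    def test_opposite_trend_kept(self):
        ids = ["EXPR:g|Up_L3", "EXPR:g|Down_L2"]
        fm = self._fm(ids, np.ones((2, 2)))
        w = self._weights({"EXPR:g|Up_L3": 0.2, "EXPR:g|Down_L2": -0.2})
        assert prune_same_trend(fm, w).feature_ids == ids

    def test_single_direction_kept(self):
        ids = ["EXPR:g|Up_L3", "EXPR:g|Up_L7"]
        fm = self._fm(ids, np.ones((2, 2)))
        w = self._weights({"EXPR:g|Up_L3": 0.2, "EXPR:g|Up_L7": 0.5})
        assert prune_same_trend(fm, w).feature_ids == ids

    def test_non_retained_conflict_does_not_trigger(self):
        ids = ["EXPR:g|Up_L3", "EXPR:g|Down_L2"]
        fm = self._fm(ids, np.ones((2, 2)))
        w = self._weights({"EXPR:g|Up_L3": 0.2, "EXPR:g|Down_L2": 0.05})
        assert prune_same_trend(fm, w).feature_ids == ids


def test_prunes_inside_training_pipeline(small_cohort):
    # simulated features carry no expression namespace: pruning is a no-op there
    fm, labels, _, _ = small_cohort
    w = compute_weights(fm, labels)
    assert prune_level1(fm).feature_ids == fm.feature_ids
    assert prune_same_trend(fm, w).feature_ids == fm.feature_ids
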