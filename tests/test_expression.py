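"""Expression floor, de-regulation calling, profile correlation/clustering
and relative quantitation."""

import numpy as np
import pandas as pd
import pytest

from tilechip.expression import (
    DifferentialExpression,
    ExpressionMatrix,
    apply_expression_floor,
    call_de,
    cluster_profiles,
    profile_correlation,
    relative_quantitation,
)


def _matrix(rows: dict[str, list[float]], strains=("wild_type", "mutant"), reps=3):
    columns = [f"{s}_r{r}" for s in strains for r in range(1, reps + 1)]
    values = pd.DataFrame(rows, index=columns).T
    values.index.name = "gene"
    samples = pd.DataFrame(
        {
            "sample": columns,
            "strain": [c.rsplit("_r", 1)[0] for c in columns],
            "replicate": [c.rsplit("_r", 1)[1] for c in columns],
        }
    )
    return ExpressionMatrix(values, samples)


class TestExpressionFloor:
    def test_below_floor_everywhere(self):
        m = _matrix({"g1": [500.0] * 6})
        retained, filtered = apply_expression_floor(m)
        assert filtered == ["g1"] and retained == []

    def test_above_floor_everywhere(self):
        m = _matrix({"g1": [700.0] * 6})
        retained, filtered = apply_expression_floor(m)
        assert retained == ["g1"]

    def test_exactly_half_the_samples_is_filtered(self):
        m = _matrix({"g1": [500.0, 500.0, 500.0, 700.0, 700.0, 700.0]})
        _, filtered = apply_expression_floor(m)
        assert filtered == ["g1"]  # "at least 50%" boundary


class TestCallDe:
    def test_up_call_passes_all_three_filters(self):
        m = _matrix({"g1": [1000.0, 1010.0, 990.0, 1600.0, 1620.0, 1580.0]})
        (rec,) = call_de(m, "wild_type", "mutant")
        assert rec.call == "up"
        assert rec.fold_change == pytest.approx(1.6)
        assert rec.abs_difference == pytest.approx(600.0)

    def test_small_fold_change_unchanged(self):
        m = _matrix({"g1": [1000.0, 1001.0, 999.0, 1090.0, 1091.0, 1089.0]})
        (rec,) = call_de(m, "wild_type", "mutant")
        assert rec.call == "unchanged"

    def test_noisy_replicates_fail_p_filter(self):
        m = _matrix({"g1": [400.0, 1000.0, 1600.0, 300.0, 1600.0, 2900.0]})
        (rec,) = call_de(m, "wild_type", "mutant", floor=0.0)
        assert rec.fold_change >= 1.5
        assert rec.p_value >= 0.05
        assert rec.call == "unchanged"

    def test_down_call_symmetric_threshold(self):
        m = _matrix({"g1": [1500.0, 1510.0, 1490.0, 900.0, 905.0, 895.0]})
        (rec,) = call_de(m, "wild_type", "mutant")
        assert rec.call == "down"

    def test_swapping_strains_maps_up_to_down(self):
        m = _matrix(
            {
                "g1": [1000.0, 1010.0, 990.0, 1600.0, 1620.0, 1580.0],
                "g2": [1600.0, 1620.0, 1580.0, 1000.0, 1010.0, 990.0],
            }
        )
        fwd = {r.gene_id: r.call for r in call_de(m, "wild_type", "mutant")}
        rev = {r.gene_id: r.call for r in call_de(m, "mutant", "wild_type")}
        assert fwd == {"g1": "up", "g2": "down"}
        assert rev == {"g1": "down", "g2": "up"}

    def test_column_order_invariance(self):
        m = _matrix({"g1": [1000.0, 990.0, 1010.0, 1600.0, 1580.0, 1620.0]})
        shuffled_cols = list(m.values.columns[::-1])
        m2 = ExpressionMatrix(
            m.values[shuffled_cols],
            m.samples.set_index("sample").loc[shuffled_cols].reset_index(),
        )
        r1 = call_de(m, "wild_type", "mutant")[0]
        r2 = call_de(m2, "wild_type", "mutant")[0]
        assert r1.call == r2.call
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_single_replicate_is_error(self):
        m = _matrix({"g1": [1000.0, 1600.0]}, reps=1)
        with pytest.raises(ValueError, match="replicates"):
            call_de(m, "wild_type", "mutant")

    def test_filtered_low_not_tested(self):
        m = _matrix({"g1": [300.0, 310.0, 290.0, 480.0, 490.0, 470.0]})
        (rec,) = call_de(m, "wild_type", "mutant")
        assert rec.call == "filtered_low"


class TestResultsObject:
    def test_fit_summary_reports_counts(self):
        m = _matrix(
            {
                "g1": [1000.0, 1010.0, 990.0, 1600.0, 1620.0, 1580.0],
                "g2": [1000.0, 1010.0, 990.0, 1000.0, 1010.0, 990.0],
                "g3": [300.0] * 6,
            }
        )
        res = DifferentialExpression(m, "wild_type", "mutant").fit()
        assert res.counts == {"up": 1, "down": 0, "unchanged": 1, "filtered_low": 1}
        text = res.summary()
        assert "up-regulated        1" in text
        assert res.genes("up") == ["g1"]


class TestProfileCorrelation:
    def test_identity_and_antisymmetry(self):
        fc = {"g1": 2.0, "g2": 0.5, "g3": 1.5, "g4": 3.0}
        neg = {g: 1.0 / v for g, v in fc.items()}
        assert profile_correlation(fc, fc) == pytest.approx(1.0)
        assert profile_correlation(fc, neg) == pytest.approx(-1.0)

    def test_too_few_shared_genes(self):
        with pytest.raises(ValueError, match="shared genes"):
            profile_correlation({"g1": 2.0, "g2": 1.0}, {"g1": 2.0, "g2": 1.0})


class TestClusterProfiles:
    def test_copies_merge_first_at_zero_height(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=40)
        frame = pd.DataFrame(
            {"A": a, "A_copy": a, "neg_A": -a},
            index=[f"g{i}" for i in range(40)],
        )
        res = cluster_profiles(frame, top_fraction=1.0)
        first = res.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}  # A with A_copy
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        # the negated profile joins last, at distance ~2
        assert res.linkage_matrix[-1][2] == pytest.approx(2.0, abs=1e-9)

    def test_two_profiles_single_merge(self):
        frame = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.5, 2.9]})
        res = cluster_profiles(frame, top_fraction=1.0)
        assert res.linkage_matrix.shape[0] == 1
        assert set(res.leaf_order) == {"A", "B"}

    def test_top_fraction_selects_largest_changes(self):
        frame = pd.DataFrame(
            {"A": [5.0, 0.1, 4.0, 0.2], "B": [4.8, 0.05, 4.1, 0.15]},
            index=["g1", "g2", "g3", "g4"],
        )
        res = cluster_profiles(frame, top_fraction=0.5)
        assert sorted(res.kept_genes) == ["g1", "g3"]

    def test_zero_variance_profile_is_named_in_error(self):
        frame = pd.DataFrame({"A": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            cluster_profiles(frame, top_fraction=1.0)


class TestRelativeQuantitation:
    def test_target_equal_to_normalizer(self):
        res = relative_quantitation([3.0, 5.0, 7.0], [3.0, 5.0, 7.0])
        np.testing.assert_allclose(res.values, 1.0)

    def test_normalized_to_reference_condition(self):
        res = relative_quantitation(
            [4.0, 4.0], [1.0, 1.0], reference_target=[2.0, 2.0], reference_normalizer=[1.0, 1.0]
        )
        assert res.mean == pytest.approx(2.0)

    def test_mean_and_sem(self):
        res = relative_quantitation([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert res.mean == pytest.approx(2.0)
        assert res.sem == pytest.approx(0.577, abs=1e-3)  # sd/sqrt(3), sample sd

    def test_zero_normalizer_is_error(self):
        with pytest.raises(ValueError, match="non-zero"):
            relative_quantitation([1.0], [0.0])


class TestRoundTrip:
    def test_tsv_roundtrip(self, tmp_path):
        m = _matrix({"g1": [1000.0, 1010.0, 990.0, 1600.0, 1620.0, 1580.0]})
        path = tmp_path / "expr.tsv"
        m.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path)
        np.testing.assert_allclose(back.values.to_numpy(), m.values.to_numpy())
        assert list(back.samples["strain"]) == list(m.samples["strain"])
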