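"""Cohort loading, outcome arithmetic, normalization and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barilearn.cohort import (
    Cohort,
    MissingDataError,
    VariableSpec,
    compute_twl,
    fit_norm_stats,
    label_success,
    load_cohort,
    load_schema,
    normalize,
    split_cohort,
    write_schema,
)

TOY_SPECS = [
    VariableSpec(name="Gender", index=1, kind="binary", units="1=male"),
    VariableSpec(name="Age", index=2, kind="continuous", units="years"),
    VariableSpec(name="HOMA-IR", index=3, kind="continuous"),
    VariableSpec(name="Uric acid", index=4, kind="continuous", units="mg/dL"),
]


def _toy_csv(tmp_path, rows):
    path = tmp_path / "toy.csv"
    header = "patient_id,basal_weight_kg,weight_1y_kg,Gender,Age,HOMA-IR,Uric acid"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestComputeTwl:
    @pytest.mark.parametrize(
        "basal, one_year, expected",
        [
            (100.0, 70.0, 30.0),
            (100.0, 100.0, 0.0),
            (144.4, 89.8, 37.8116),  # male mean baseline weight, plausible pairing
            (80.0, 88.0, -10.0),  # weight gain is legal and negative
        ],
    )
    def test_examples(self, basal, one_year, expected):
        assert compute_twl(basal, one_year) == pytest.approx(expected, abs=1e-4)

    @given(
        basal=st.floats(min_value=50, max_value=250),
        one_year=st.floats(min_value=40, max_value=250),
        c=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, basal, one_year, c):
        assert compute_twl(c * basal, c * one_year) == pytest.approx(
            compute_twl(basal, one_year), abs=1e-9
        )

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError, match="strictly positive"):
            compute_twl(0.0, 70.0)
        with pytest.raises(ValueError, match="strictly positive"):
            compute_twl(100.0, -1.0)


class TestLabelSuccess:
    def test_cutoff_is_inclusive(self):
        assert label_success(30.0) is True
        assert label_success(29.999) is False
        assert label_success(-5.0) is False

    def test_vectorized(self):
        out = label_success(np.array([30.0, 29.999, 45.0]))
        assert out.tolist() == [True, False, True]


class TestNormalization:
    def test_two_point_population_sd(self):
        stats = fit_norm_stats(np.array([[1.0], [3.0]]))
        assert stats.mean[0] == 2.0
        assert stats.sd[0] == 1.0  # population convention: denominator n

    def test_zero_variance_column_named(self):
        X = np.column_stack([np.arange(3.0), np.full(3, 5.0)])
        with pytest.raises(ValueError, match="Platelets"):
            fit_norm_stats(X, names=["Age", "Platelets"])

    def test_normalize_then_refit_is_standard(self, rng):
        X = rng.normal(size=(50, 5)) * [1, 2, 5, 0.1, 10] + [0, 3, -2, 1, 100]
        norm = normalize(X, fit_norm_stats(X))
        refit = fit_norm_stats(norm.Y)
        np.testing.assert_allclose(refit.mean, 0.0, atol=1e-10)
        np.testing.assert_allclose(refit.sd, 1.0, atol=1e-10)

    def test_scalar_anchors(self):
        stats = fit_norm_stats(np.array([[1.0], [3.0]]))
        assert normalize(np.array([[2.0]]), stats).Y[0, 0] == 0.0
        assert normalize(np.array([[3.0]]), stats).Y[0, 0] == 1.0

    def test_training_stats_apply_to_held_out_row(self, rng):
        X = rng.normal(size=(20, 3))
        train = np.arange(15)
        stats = fit_norm_stats(X, rows=train)
        held = X[17]
        y = normalize(held[None, :], stats).Y[0]
        np.testing.assert_allclose(y, (held - stats.mean) / stats.sd, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        stats = fit_norm_stats(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="columns"):
            normalize(rng.normal(size=(5, 4)), stats)

    def test_stats_json_roundtrip(self, tmp_path, rng):
        stats = fit_norm_stats(rng.normal(size=(10, 3)), source="whole-sample")
        stats.to_json(tmp_path / "s.json", names=["a", "b", "c"])
        back = type(stats).from_json(tmp_path / "s.json")
        np.testing.assert_array_equal(back.mean, stats.mean)
        np.testing.assert_array_equal(back.sd, stats.sd)
        assert back.source == "whole-sample"


class TestSplit:
    def test_study_dimensions_give_83_training(self):
        split = split_cohort(118, fraction=0.7, seed=0)
        assert split.train_idx.size == 83
        assert split.valid_idx.size == 35

    def test_deterministic_and_exhaustive(self):
        a = split_cohort(118, seed=9)
        b = split_cohort(118, seed=9)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        union = np.union1d(a.train_idx, a.valid_idx)
        np.testing.assert_array_equal(union, np.arange(118))
        assert np.intersect1d(a.train_idx, a.valid_idx).size == 0

    def test_uniformity_over_seeds(self):
        counts = np.zeros(10)
        for seed in range(1000):
            counts[split_cohort(10, fraction=0.7, seed=seed).train_idx] += 1
        # each index is in training w.p. 0.7: binomial(1000, 0.7), sd ~ 14.5
        assert np.all(np.abs(counts - 700) < 5 * 14.5)

    def test_stratified_split_balances_classes(self, default_cohort):
        cohort, _ = default_cohort
        split = split_cohort(cohort, seed=3, stratify=True)
        frac_train = cohort.label[split.train_idx].mean()
        frac_all = cohort.label.mean()
        assert abs(frac_train - frac_all) < 0.05

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(2, seed=0)
        with pytest.raises(ValueError, match="fraction"):
            split_cohort(100, fraction=1.5, seed=0)


class TestLoadCohort:
    def test_toy_roundtrip(self, tmp_path):
        path = _toy_csv(
            tmp_path,
            [
                "P1,120.0,80.0,1,45.0,5.5,6.1",
                "P2,100.0,72.0,0,50.0,3.2,4.9",
                "P3,140.0,98.0,0,39.0,8.1,7.0",  # exactly 30%: boundary success
            ],
        )
        cohort = load_cohort(path, TOY_SPECS)
        assert cohort.n == 3 and cohort.n_variables == 4
        assert cohort.patients == ["P1", "P2", "P3"]
        assert cohort.twl[0] == pytest.approx(100 * (120 - 80) / 120)
        assert cohort.label.tolist() == [True, False, True]

    def test_missing_cell_names_patient_and_variable(self, tmp_path):
        path = _toy_csv(
            tmp_path,
            ["P1,120.0,80.0,1,45.0,,6.1", "P2,100.0,72.0,0,50.0,3.2,4.9"],
        )
        with pytest.raises(MissingDataError, match="HOMA-IR.*P1"):
            load_cohort(path, TOY_SPECS)

    def test_non_numeric_cell_reported(self, tmp_path):
        path = _toy_csv(tmp_path, ["P1,120.0,80.0,1,forty,5.5,6.1"])
        with pytest.raises(ValueError, match="non-numeric.*Age"):
            load_cohort(path, TOY_SPECS)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,basal_weight_kg\nP1,100\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_cohort(path, TOY_SPECS)

    def test_schema_yaml_roundtrip(self, tmp_path):
        write_schema(TOY_SPECS, tmp_path / "schema.yaml")
        back = load_schema(tmp_path / "schema.yaml")
        assert back == TOY_SPECS


class TestCohortInvariants:
    def test_binary_values_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            Cohort(
                patients=["a", "b", "c"],
                X=np.array([[2.0], [0.0], [1.0]]),
                specs=[VariableSpec(name="Diabetes", index=1, kind="binary")],
                basal_weight=np.full(3, 100.0),
                weight_1y=np.full(3, 70.0),
            )

    def test_labels_consistent_with_twl(self, default_cohort):
        cohort, _ = default_cohort
        np.testing.assert_array_equal(cohort.label, cohort.twl >= 30.0)
        recomputed = compute_twl(cohort.basal_weight, cohort.weight_1y)
        np.testing.assert_allclose(cohort.twl, recomputed, atol=1e-12)
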