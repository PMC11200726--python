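"""Threshold sweep, ROC/AUC, consensus relevance and pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barilearn.evaluation import (
    classify_at,
    confusion_at,
    prune_and_reembed,
    rank_variables,
    sweep_thresholds,
)
from barilearn.weighting import AlphaVector


def concordance_oracle(w2, labels):
    """Exhaustive pair counting: P(failure scored below success), ties 0.5."""
    fail = w2[~labels]
    succ = w2[labels]
    total = 0.0
    for f in fail:
        for s in succ:
            if f < s:
                total += 1.0
            elif f == s:
                total += 0.5
    return total / (len(fail) * len(succ))


class TestClassifyAt:
    def test_boundary_is_success(self):
        assert classify_at(0.4178, 0.4178) is True
        assert classify_at(0.4178 - 1e-9, 0.4178) is False

    def test_minus_inf_sentinel_all_success(self, rng):
        w2 = rng.normal(size=30)
        assert classify_at(w2, -np.inf).all()


class TestSweepThresholds:
    def test_perfect_separation(self):
        w2 = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        labels = np.array([False, False, False, True, True, True])
        roc = sweep_thresholds(w2, labels)
        assert roc.auc == 1.0
        assert roc.sensitivity == 1.0
        assert roc.false_positive_rate == 0.0
        assert -1.0 < roc.best_threshold < 1.0

    def test_six_point_toy_matches_pair_counting(self):
        # one overlapping pair: a failure scoring above a success
        w2 = np.array([-1.0, -0.5, 0.6, 0.2, 0.9, 1.4])
        labels = np.array([False, False, False, True, True, True])
        roc = sweep_thresholds(w2, labels)
        assert roc.auc == concordance_oracle(w2, labels)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, derandomize=True)
    def test_auc_equals_concordance_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        w2 = rng.normal(size=20)
        labels = np.zeros(20, dtype=bool)
        labels[rng.choice(20, size=8, replace=False)] = True
        roc = sweep_thresholds(w2, labels)
        assert roc.auc == pytest.approx(concordance_oracle(w2, labels), abs=1e-12)

    def test_matches_reference_roc_auc(self, rng):
        roc_auc_score = pytest.importorskip("sklearn.metrics").roc_auc_score
        w2 = rng.normal(size=50)
        labels = rng.random(50) < 0.6
        roc = sweep_thresholds(w2, labels)
        # failure is the positive class and is predicted for *low* w2
        expected = roc_auc_score(~labels, -w2)
        assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_centers_on_half(self, rng):
        w2 = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        aucs = []
        for _ in range(200):
            aucs.append(sweep_thresholds(w2, rng.permutation(labels)).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_confusion_counts_sum_and_recompute(self, rng):
        w2 = rng.normal(size=40)
        labels = rng.random(40) < 0.6
        roc = sweep_thresholds(w2, labels)
        c = roc.confusion
        assert sum(c.values()) == 40
        at = confusion_at(w2, labels, roc.best_threshold)
        assert at == c
        # sweep-stored point at the best threshold matches the counts
        i = np.argwhere(roc.points[:, 0] == roc.best_threshold)[0][0]
        assert roc.points[i, 1] == pytest.approx(c["TP"] / (c["TP"] + c["FN"]))
        assert roc.points[i, 2] == pytest.approx(c["FP"] / (c["FP"] + c["TN"]))

    def test_flip_symmetries(self, rng):
        # negating the score reverses the ranking: AUC -> 1 - AUC; so does
        # swapping the class roles alone; doing both recovers the original
        w2 = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        auc = sweep_thresholds(w2, labels).auc
        assert sweep_thresholds(-w2, labels).auc == pytest.approx(1.0 - auc, abs=1e-12)
        assert sweep_thresholds(w2, ~labels).auc == pytest.approx(1.0 - auc, abs=1e-12)
        assert sweep_thresholds(-w2, ~labels).auc == pytest.approx(auc, abs=1e-12)

    def test_monotone_curve_in_threshold(self, rng):
        w2 = rng.normal(size=25)
        labels = rng.random(25) < 0.4
        roc = sweep_thresholds(w2, labels)
        assert np.all(np.diff(roc.points[:, 0]) > 0)
        assert np.all(np.diff(roc.points[:, 1]) >= 0)
        assert np.all(np.diff(roc.points[:, 2]) >= 0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both"):
            sweep_thresholds(rng.normal(size=10), np.ones(10, dtype=bool))


class TestRankVariables:
    def test_single_run_reduces_to_thresholding(self):
        alphas = [np.array([3.0, 0.0, -3.0, 1.0])]
        table = rank_variables(alphas, names=list("abcd")).table
        assert table.set_index("name")["consensus"].to_dict() == {
            "a": "high", "b": "mixed", "c": "low", "d": "mixed",
        }

    def test_consensus_high_requires_all_runs(self):
        runs = [np.array([3.0, 3.0]), np.array([3.0, 1.0]), np.array([3.0, 3.0])]
        rel = rank_variables(runs, names=["x", "y"])
        assert rel.consensus_high() == ["x"]

    def test_planted_consensus_beats_random_draws(self, rng):
        # variables 0..4 planted with systematically higher exponents
        informative = set(range(5))
        runs = []
        for _ in range(3):
            a = rng.uniform(-4, 1.5, size=20)
            a[:5] = rng.uniform(2.5, 4.0, size=5)
            runs.append(a)
        rel = rank_variables(runs, names=[f"v{i}" for i in range(20)])
        high_idx = {int(n[1:]) for n in rel.consensus_high()}
        overlap = len(high_idx & informative)
        null = [
            len(set(rng.choice(20, size=len(high_idx), replace=False)) & informative)
            for _ in range(1000)
        ]
        assert overlap > np.quantile(null, 0.95)


class TestPruneAndReembed:
    @pytest.fixture
    def setting(self, small_cohort):
        from barilearn.cohort import fit_norm_stats, normalize, split_cohort

        cohort, _ = small_cohort
        split = split_cohort(cohort, seed=2)
        stats = fit_norm_stats(cohort.X, rows=split.train_idx)
        Y = normalize(cohort.X, stats).Y
        return (
            Y[split.train_idx],
            Y[split.valid_idx],
            cohort.twl[split.train_idx],
            cohort.label[split.valid_idx],
        )

    def test_noop_cutoff_preserves_results(self, setting, rng):
        Yt, Yv, twl, labels = setting
        alpha = rng.uniform(-2, 2, size=12)
        alpha[0] = 0.0
        av = AlphaVector(alpha=alpha)
        full = prune_and_reembed(av, Yt, Yv, twl, labels, cutoff=-4.0, mode="reuse", k=5, m=5)
        assert full.surviving.size == 12
        again = prune_and_reembed(av, Yt, Yv, twl, labels, cutoff=-4.0, mode="reuse", k=5, m=5)
        assert full.roc.auc == again.roc.auc

    def test_overpruning_is_an_error(self, setting):
        Yt, Yv, twl, labels = setting
        av = AlphaVector.zeros(12)
        with pytest.raises(ValueError, match="need >= 2"):
            prune_and_reembed(av, Yt, Yv, twl, labels, cutoff=4.1, mode="reuse")

    def test_reuse_mode_drops_low_alpha_variables(self, setting):
        Yt, Yv, twl, labels = setting
        alpha = np.array([0.0, 3.0, 3.5, 2.8, -1, -1, -1, -1, -1, -1, 3.1, -1.0])
        av = AlphaVector(alpha=alpha)
        pruned = prune_and_reembed(av, Yt, Yv, twl, labels, cutoff=2.4, mode="reuse", k=5, m=5)
        np.testing.assert_array_equal(pruned.surviving, [1, 2, 3, 10])
        assert 0.0 <= pruned.roc.auc <= 1.0

    def test_refit_mode_runs_reduced_search(self, setting):
        from barilearn.evolve import EAConfig

        Yt, Yv, twl, labels = setting
        alpha = np.zeros(12)
        alpha[1:6] = 3.0
        av = AlphaVector(alpha=alpha)
        config = EAConfig(population=10, max_generations=5, runs=1, seed=0)
        pruned = prune_and_reembed(
            av, Yt, Yv, twl, labels, cutoff=2.4, mode="refit",
            ea_config=config, k=4, m=4,
        )
        assert pruned.surviving.size == 5
        assert pruned.alphas.n_variables == 5
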