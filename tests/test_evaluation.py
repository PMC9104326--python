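import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_auc
from disbench.evaluation import (bootstrap_summary, confusion,
                                 disorder_content, mcc, pr_fmax,
                                 predictor_correlation, protein_class,
                                 residue_rmsd, roc_auc)


class TestConfusion:
    def test_perfect_and_inverted(self):
        ref = np.array([1, 1, 0, 0])
        c = confusion(ref, ref)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)
        c = confusion(ref, 1 - ref)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 2, 2)

    def test_mask_excludes_middle(self):
        ref = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        pred = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        mask = np.array([0, 0, 1, 1, 1, 1, 0, 0], dtype=bool)
        c = confusion(ref, pred, mask)
        assert c.total == 4
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMcc:
    def test_hand_value(self):
        from disbench.evaluation import ConfusionCounts
        c = ConfusionCounts(tp=4, tn=3, fp=2, fn=1)
        assert mcc(c) == pytest.approx(10 / np.sqrt(600), abs=1e-9)

    def test_perfect_and_inverted(self):
        ref = np.array([1, 1, 0, 0])
        assert mcc(confusion(ref, ref)) == 1.0
        assert mcc(confusion(ref, 1 - ref)) == -1.0

    def test_single_class_reference_undefined(self):
        assert mcc(confusion([1, 1], [1, 0])) is None

    def test_zero_factor_with_both_classes_is_zero(self):
        # all residues called disordered: tn = fn = 0
        assert mcc(confusion([1, 0], [1, 1])) == 0.0

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import matthews_corrcoef
        for _ in range(20):
            ref = rng.integers(0, 2, 200)
            pred = rng.integers(0, 2, 200)
            if ref.min() == ref.max():
                continue
            ours = mcc(confusion(ref, pred))
            assert ours == pytest.approx(matthews_corrcoef(ref, pred),
                                         abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert res.summary == 1.0

    def test_partial_concordance_hand_value(self):
        # 3 of 4 positive/negative pairs concordant
        res = roc_auc([1, 1, 0, 0], [0.9, 0.6, 0.65, 0.2])
        assert res.summary == pytest.approx(0.75)

    def test_equals_brute_force_concordance(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 500))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice(np.linspace(0, 1, 20), size=n)  # many ties
            res = roc_auc(labels, scores)
            assert res.summary == pytest.approx(
                brute_force_auc(labels, scores), abs=1e-12)

    def test_uninformative_scores_near_half(self, rng):
        labels = rng.integers(0, 2, 10_000)
        scores = rng.random(10_000)
        assert roc_auc(labels, scores).summary == pytest.approx(0.5,
                                                                abs=0.02)

    def test_single_class_undefined(self):
        assert roc_auc([1, 1], [0.2, 0.4]) is None


class TestPrFmax:
    def test_perfect_separation(self):
        assert pr_fmax([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]).summary == 1.0

    def test_constant_score_prevalence_bound(self):
        # everything called disordered at prevalence 0.25 -> F1 = 0.4
        labels = np.array([1] + [0] * 3)
        res = pr_fmax(labels, np.full(4, 0.7))
        assert res.summary >= 0.4 - 1e-12

    def test_single_positive_ranked_first(self, rng):
        scores = np.linspace(0.1, 0.9, 10)
        labels = np.zeros(10, dtype=int)
        labels[np.argmax(scores)] = 1
        assert pr_fmax(labels, scores).summary == 1.0

    def test_fmax_upper_bounds_any_threshold_f1(self, rng):
        from disbench.evaluation import confusion, f1_from_counts
        labels = rng.integers(0, 2, 300)
        scores = rng.random(300)
        fmax = pr_fmax(labels, scores).summary
        prevalence = labels.mean()
        assert fmax >= 2 * prevalence / (1 + prevalence) - 1e-12
        for thr in rng.random(10):
            f1 = f1_from_counts(confusion(labels,
                                          (scores >= thr).astype(int)))
            assert fmax >= f1 - 1e-12

    def test_no_positives_undefined(self):
        assert pr_fmax([0, 0], [0.1, 0.9]) is None


class TestRmsd:
    def test_identity_and_maximal_discordance(self):
        v = np.array([1, 0, 1, 0], dtype=float)
        assert residue_rmsd(v, v) == 0.0
        assert residue_rmsd(v, 1 - v) == 1.0

    def test_equals_root_hamming_on_binary(self, rng):
        v = rng.integers(0, 2, 200).astype(float)
        w = rng.integers(0, 2, 200).astype(float)
        hamming = np.sum(v != w)
        assert residue_rmsd(v, w) == pytest.approx(
            np.sqrt(hamming / 200), abs=1e-12)

    def test_random_binary_pair_near_0707(self, rng):
        v = rng.integers(0, 2, 10_000).astype(float)
        w = rng.integers(0, 2, 10_000).astype(float)
        assert residue_rmsd(v, w) == pytest.approx(np.sqrt(0.5), abs=0.01)

    def test_empty_after_masking_undefined(self):
        assert residue_rmsd([1.0], [0.0], mask=[True]) is None


class TestContentAndClasses:
    def test_content_worked_example(self):
        assert disorder_content([0, 0, 1, 1, 1, 1, 0, 0, 0, 0]) == 0.4

    def test_content_respects_mask(self):
        labels = [1, 0, 0, 0]
        mask = [False, True, True, True]
        assert disorder_content(labels, mask) == 1.0

    @pytest.mark.parametrize("content,expected", [
        (0.95, "highly_disordered"), (0.05, "highly_ordered"),
        (0.90, "other"), (0.10, "other"), (0.5, "other")])
    def test_class_boundaries_strict(self, content, expected):
        assert protein_class(content) == expected


class TestBootstrap:
    def test_constant_vector(self):
        s = bootstrap_summary(np.full(30, 3.25), 100, 10, seed=1)
        assert s.mean == 3.25 and s.stderr == 0.0

    def test_seed_reproducibility(self, rng):
        vals = rng.normal(size=100)
        a = bootstrap_summary(vals, 1000, 60, seed=7)
        b = bootstrap_summary(vals, 1000, 60, seed=7)
        assert (a.mean, a.stderr) == (b.mean, b.stderr)
        c = bootstrap_summary(vals, 1000, 60, seed=8)
        assert (a.mean, a.stderr) != (c.mean, c.stderr)

    def test_stderr_close_to_closed_form(self, rng):
        vals = rng.normal(size=5000)          # unit variance
        s = bootstrap_summary(vals, 4000, 60, seed=3)
        assert s.stderr == pytest.approx(1 / np.sqrt(60), rel=0.2)


class TestPredictorCorrelation:
    def test_identical_and_negated_columns(self, rng):
        x = rng.random(20)
        table = pd.DataFrame({"a": x, "b": x, "c": 1 - x})
        res = predictor_correlation(table)
        r = {(row.predictor_a, row.predictor_b): row.pearson_r
             for row in res.itertuples()}
        assert r[("a", "b")] == pytest.approx(1.0)
        assert r[("a", "c")] == pytest.approx(-1.0)

    def test_recovers_linear_slope(self, rng):
        x = rng.random(100)
        y = 2 * x + rng.normal(0, 1e-6, 100)
        res = predictor_correlation(pd.DataFrame({"x": x, "y": y}))
        assert res.slope.iloc[0] == pytest.approx(2.0, abs=1e-3)

    def test_too_few_shared_proteins_undefined(self):
        res = predictor_correlation(
            pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}))
        assert res.pearson_r.iloc[0] is None
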