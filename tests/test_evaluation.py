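import numpy as np
import pytest
from scipy.stats import kstest, rankdata

from epheclass import (ValidationError, confusion_metrics, roc_auc,
                       venkatraman_paired, venkatraman_unpaired)
from epheclass.evaluation import (_paired_statistic, _unpaired_statistic,
                                  cv_evaluate, report)
from epheclass.model_pool import ClassifierSpec, grid_tune, small_grids


class TestConfusionMetrics:
    def test_forced_arithmetic(self):
        # TP=3 FP=1 FN=1 TN=5
        y = ["D"] * 4 + ["NotD"] * 6
        pred = ["D", "D", "D", "NotD", "D"] + ["NotD"] * 5
        m = confusion_metrics(np.array(y), np.array(pred))
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_all_correct(self):
        y = np.array(["D", "NotD", "D"])
        m = confusion_metrics(y, y)
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_convention(self):
        y = np.array(["D", "NotD"])
        pred = np.array(["NotD", "NotD"])
        m = confusion_metrics(y, pred)
        assert m["precision"] == 0.0 and m["recall"] == 0.0 and m["f1"] == 0.0

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 40)
            pred = rng.integers(0, 2, 40)
            if y.min() == y.max():
                continue
            m = confusion_metrics(y, pred)
            if m["precision"] + m["recall"] > 0:
                h = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
                assert m["f1"] == pytest.approx(h, abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            confusion_metrics(np.array([]), np.array([]))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc(np.array([1, 1, 0, 0]),
                            np.array([0.9, 0.8, 0.4, 0.3]))
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc, _, _ = roc_auc(np.array([1, 0, 1, 0]), np.full(4, 0.5))
        assert auc == 0.5

    def test_matches_mann_whitney_pair_counting(self, rng):
        """Brute-force oracle: AUC = fraction of (pos, neg) pairs where the
        positive outscores the negative, ties counting half."""
        for _ in range(500):
            n = int(rng.integers(4, 25))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            auc, _, _ = roc_auc(y, s)
            pos = s[y == 1]
            neg = s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (pos.size * neg.size), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            roc_auc(np.ones(4), np.random.default_rng(0).random(4))


class TestVenkatramanPaired:
    def test_identical_scores(self):
        y = np.array([1] * 10 + [0] * 10)
        s = np.random.default_rng(0).random(20)
        r = venkatraman_paired(s, s, y, n_permutations=99, seed=0)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_statistic_matches_reference_implementation(self):
        """Frozen cross-check against the pROC implementation of the same
        rank statistic (venkatraman.paired.stat) on a fixed fixture."""
        gen = np.random.default_rng(42)
        y = np.array([1] * 20 + [0] * 20)
        a = gen.normal(0, 1, 40) + 0.8 * y
        b = gen.normal(0, 1, 40) + 0.3 * y
        R = rankdata(a, method="ordinal")
        S = rankdata(b, method="ordinal")
        assert _paired_statistic(R, S, y.astype(bool)) == pytest.approx(78.0)

    def test_monotone_invariance(self, rng):
        y = np.array([1] * 15 + [0] * 15)
        a = rng.normal(0, 1, 30) + y
        b = rng.normal(0, 1, 30)
        r1 = venkatraman_paired(a, b, y, n_permutations=199, seed=9)
        r2 = venkatraman_paired(np.exp(3 * a), b ** 3, y,
                                n_permutations=199, seed=9)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_p_lower_bound(self):
        y = np.array([1] * 50 + [0] * 50)
        gen = np.random.default_rng(1)
        a = y * 3.0 + gen.normal(0, 0.5, 100)
        b = gen.normal(0, 1, 100)
        r = venkatraman_paired(a, b, y, n_permutations=49, seed=0)
        assert r.p_value >= 1 / 50

    def test_bad_permutation_count(self):
        y = np.array([1, 0])
        with pytest.raises(ValidationError):
            venkatraman_paired(np.array([1.0, 0.0]), np.array([0.0, 1.0]), y,
                               n_permutations=0)


class TestVenkatramanUnpaired:
    def test_same_sample_twice(self):
        gen = np.random.default_rng(2)
        y = np.array([1] * 10 + [0] * 10)
        s = gen.random(20)
        r = venkatraman_unpaired(s, y, s, y, n_permutations=99, seed=0)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_statistic_matches_reference_implementation(self):
        """Frozen cross-check of the integral statistic against pROC's
        venkatraman.unpaired.stat on a fixed equal-size fixture."""
        gen = np.random.default_rng(42)
        y1 = np.array([1] * 20 + [0] * 20)
        a = gen.normal(0, 1, 40) + 0.8 * y1
        _ = gen.normal(0, 1, 40)  # advance the stream as in the freeze run
        y2 = np.array([1] * 15 + [0] * 25)
        c = gen.normal(0, 1, 40) + 1.2 * y2
        mp = (y1.sum() + y2.sum()) / 80
        stat = _unpaired_statistic(rankdata(a, method="ordinal"),
                                   rankdata(c, method="ordinal"),
                                   y1.astype(bool), y2.astype(bool), mp)
        assert stat == pytest.approx(0.0676621094, abs=1e-9)

    def test_power_distinguishes_strong_from_weak(self):
        gen = np.random.default_rng(1)
        y = np.array([1] * 100 + [0] * 100)
        a = y * 2.33 + gen.normal(0, 1, 200)  # AUC ~ 0.95
        b = y * 0.18 + gen.normal(0, 1, 200)  # AUC ~ 0.55
        r = venkatraman_unpaired(a, y, b, y, n_permutations=999, seed=0)
        assert r.p_value <= 0.01


def test_paired_null_p_values_are_uniform():
    """Under an exchangeable null (two equally noisy copies of one latent
    marker) the permutation p-values are Uniform(0,1): KS test at alpha 0.01,
    100 replicates of n=100 with 300 permutations."""
    gen = np.random.default_rng(7)
    ps = []
    for rep in range(100):
        y = np.array([1] * 50 + [0] * 50)
        latent = gen.normal(0, 1, 100) + 0.7 * y
        a = latent + gen.normal(0, 0.8, 100)
        b = latent + gen.normal(0, 0.8, 100)
        ps.append(venkatraman_paired(a, b, y, n_permutations=300,
                                     seed=rep).p_value)
    assert kstest(ps, "uniform").pvalue > 0.01


@pytest.fixture(scope="module")
def fixture_data():
    gen = np.random.default_rng(3)
    n, p = 60, 10
    y = np.array(["D"] * 30 + ["NotD"] * 30, dtype=object)
    base = gen.random(p) + 0.1
    comp = np.empty((n, p))
    for i in range(n):
        w = base * np.exp(gen.normal(0, 0.2, p))
        if y[i] == "D":
            w[:3] *= np.exp(2.0)
        comp[i] = w / w.sum()
    X = np.log(comp)
    tuned = [grid_tune(ClassifierSpec(f, small_grids()[f]),
                       X - X.mean(axis=1, keepdims=True), y, folds=3)
             for f in ("knn", "random_forest")]
    return comp, y, tuned


class TestCvEvaluate:
    def test_deterministic_rerun(self, fixture_data):
        comp, y, tuned = fixture_data
        a = cv_evaluate(comp, y, tuned, folds=5, seed=2, k=5)
        b = cv_evaluate(comp, y, tuned, folds=5, seed=2, k=5)
        assert a.equals(b)

    def test_strong_signal_high_auc(self, fixture_data):
        comp, y, tuned = fixture_data
        out = cv_evaluate(comp, y, tuned, folds=5, seed=0, k=5)
        des = out[out.model.str.startswith("des_")]
        assert (des.roc_auc >= 0.9).all()

    def test_label_permutation_near_chance(self, fixture_data):
        comp, y, tuned = fixture_data
        gen = np.random.default_rng(11)
        y_perm = np.asarray(y, dtype=object)[gen.permutation(y.size)]
        out = cv_evaluate(comp, y_perm, tuned, folds=5, seed=0, k=5)
        desp = out[out.model == "des_desp"].roc_auc.iloc[0]
        assert 0.25 <= desp <= 0.75  # wide band: n=60 null AUC is noisy


class TestReport:
    def test_single_cell(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame([{"model": "knn", "nsf": 5, "split": "test",
                            "f1": 0.8, "precision": 0.8, "recall": 0.8,
                            "accuracy": 0.8, "roc_auc": 0.9}])
        avg = report(df, [5], tmp_path)
        assert avg.iloc[0]["roc_auc"] == pytest.approx(0.9)
        assert (tmp_path / "metrics_nsf5.tsv").exists()
        assert (tmp_path / "auc_vs_nsf_test.png").exists()

    def test_missing_nsf_excluded_from_average(self, tmp_path):
        import pandas as pd
        rows = [{"model": "knn", "nsf": n, "split": "test", "f1": 0.5,
                 "precision": 0.5, "recall": 0.5, "accuracy": 0.5,
                 "roc_auc": auc} for n, auc in [(2, 0.8), (4, 0.6)]]
        avg = report(pd.DataFrame(rows), [2, 3, 4], tmp_path)
        assert avg.iloc[0]["roc_auc"] == pytest.approx(0.7)

    def test_averages_match_hand_means(self, tmp_path, rng):
        import pandas as pd
        rows = []
        for model in ("a", "b"):
            for n in range(2, 16):
                rows.append({"model": model, "nsf": n, "split": "cv",
                             "f1": 0.5, "precision": 0.5, "recall": 0.5,
                             "accuracy": 0.5,
                             "roc_auc": float(rng.random())})
        df = pd.DataFrame(rows)
        avg = report(df, list(range(2, 16)), tmp_path)
        for model in ("a", "b"):
            expect = df[df.model == model].roc_auc.mean()
            got = avg[(avg.model == model)].roc_auc.iloc[0]
            assert got == pytest.approx(expect)
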