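import numpy as np
import pytest

from epheclass import ValidationError, combine, region_of_competence, \
    select_desc, select_desp, select_knorae, select_knorau, tune_k
from epheclass.des_ensembles import DESEnsemble
from epheclass.model_pool import ModelPool, TunedModel


# ---------------------------------------------------------------------------
# brute-force oracles: plain-python re-implementations of the selection
# rules' verbal definitions, kept deliberately naive and separate from the
# package's vectorised code paths
# ---------------------------------------------------------------------------

def oracle_desp(corr):
    n_models, k = corr.shape
    selected = []
    for m in range(n_models):
        acc = sum(corr[m]) / k
        if acc > 0.5:  # strictly better than a random binary classifier
            selected.append(m)
    if not selected:
        return list(range(n_models)), True
    return selected, False


def oracle_knorae(corr):
    n_models, k0 = corr.shape
    for k in range(k0, 0, -1):
        perfect = [m for m in range(n_models)
                   if all(corr[m][j] for j in range(k))]
        if perfect:
            return perfect, k, False
    return list(range(n_models)), k0, True


def oracle_knorau(corr):
    n_models = corr.shape[0]
    selected, weights = [], []
    for m in range(n_models):
        c = int(sum(corr[m]))
        if c > 0:
            selected.append(m)
            weights.append(c)
    if not selected:
        return list(range(n_models)), [1] * n_models, True
    return selected, weights, False


def oracle_desc(cluster_labels, correct, query_cluster, frac_acc, frac_div):
    n_models = correct.shape[0]
    members = [i for i, c in enumerate(cluster_labels) if c == query_cluster]
    acc = [sum(correct[m][i] for i in members) / len(members)
           for m in range(n_models)]
    ranked = sorted(range(n_models), key=lambda m: (-acc[m], m))
    n_acc = int(np.ceil(frac_acc * n_models))
    pool = ranked[:n_acc]
    n_div = min(int(np.ceil(frac_div * n_models)), len(pool))

    def diversity(a, b):
        both_wrong = sum((1 - correct[a][i]) * (1 - correct[b][i])
                         for i in members) / len(members)
        return 1.0 - both_wrong

    chosen = [pool[0]]
    remaining = pool[1:]
    while len(chosen) < n_div and remaining:
        best = max(remaining,
                   key=lambda m: (sum(diversity(m, c) for c in chosen) / len(chosen),
                                  acc[m], -m))
        chosen.append(best)
        remaining.remove(best)
    return sorted(chosen)


# ---------------------------------------------------------------------------
# rule unit examples
# ---------------------------------------------------------------------------

class TestRuleExamples:
    def test_desp_strict_inequality(self):
        # accuracies 0.6, 0.5, 0.2 over 10 neighbours: only the first beats
        # the 0.5 random rate (0.5 is not strictly better)
        corr = np.array([[1] * 6 + [0] * 4, [1] * 5 + [0] * 5, [1] * 2 + [0] * 8])
        sel, fb = select_desp(corr)
        assert sel.tolist() == [0] and not fb

    def test_desp_all_perfect(self):
        sel, fb = select_desp(np.ones((3, 5), dtype=int))
        assert sel.tolist() == [0, 1, 2] and not fb

    def test_desp_fallback(self):
        sel, fb = select_desp(np.zeros((3, 5), dtype=int))
        assert sel.tolist() == [0, 1, 2] and fb

    def test_knorae_perfect_model(self):
        corr = np.vstack([np.ones(7, dtype=int),
                          np.array([1, 1, 1, 0, 1, 1, 1])])
        sel, k, fb = select_knorae(corr)
        assert sel.tolist() == [0] and k == 7 and not fb

    def test_knorae_region_shrinks(self):
        # nobody perfect at k=3; models 0 and 1 perfect on the 2 nearest
        corr = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1]])
        sel, k, fb = select_knorae(corr)
        assert sel.tolist() == [0, 1] and k == 2 and not fb

    def test_knorae_fallback(self):
        corr = np.array([[0, 1], [0, 0]])
        sel, k, fb = select_knorae(corr)
        assert sel.tolist() == [0, 1] and fb

    def test_knorau_weights(self):
        corr = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]])
        sel, w, fb = select_knorau(corr)
        assert sel.tolist() == [0, 1] and w.tolist() == [2.0, 1.0] and not fb

    def test_knorau_all_correct(self):
        sel, w, fb = select_knorau(np.ones((4, 5), dtype=int))
        assert sel.tolist() == [0, 1, 2, 3] and set(w) == {5.0}

    def test_knorau_fallback(self):
        sel, w, fb = select_knorau(np.zeros((2, 3), dtype=int))
        assert sel.tolist() == [0, 1] and fb

    def test_desc_cluster_specialists(self):
        # 2 clusters; model 0 perfect on cluster 0 only, model 1 on cluster 1
        cluster_labels = np.array([0, 0, 0, 1, 1, 1])
        correct = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])
        sel0 = select_desc(cluster_labels, correct, 0, 0.5, 0.5)
        sel1 = select_desc(cluster_labels, correct, 1, 0.5, 0.5)
        assert sel0.tolist() == [0] and sel1.tolist() == [1]


class TestCombine:
    def test_uniform_majority(self):
        d = combine(np.array([0.9, 0.8, 0.1]))
        assert d.label == 1

    def test_weighted_majority(self):
        d = combine(np.array([0.9, 0.1]), np.array([1.0, 2.0]))
        assert d.label == 0

    def test_tie_broken_by_mean_probability(self):
        d = combine(np.array([0.9, 0.2]))
        assert d.label == 1  # mean 0.55 > 0.5

    def test_residual_tie_goes_negative(self):
        d = combine(np.array([0.8, 0.2]))
        assert d.label == 0  # tie, mean exactly 0.5

    def test_score_is_weighted_mean(self):
        d = combine(np.array([1.0, 0.5]), np.array([3.0, 1.0]))
        assert d.score == pytest.approx(0.875)

    def test_empty_selection_errors(self):
        with pytest.raises(ValidationError):
            combine(np.array([]))


class TestRegionOfCompetence:
    def test_query_on_dsel_row_is_self(self):
        dsel = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        roc = region_of_competence(dsel[1], dsel, k=1)
        assert roc.neighbor_idx.tolist() == [1]
        assert roc.distances[0] == 0.0

    def test_k_bounds(self):
        dsel = np.zeros((3, 2))
        with pytest.raises(ValidationError):
            region_of_competence(np.zeros(2), dsel, k=4)
        with pytest.raises(ValidationError):
            region_of_competence(np.zeros(2), dsel, k=0)

    def test_matches_bruteforce_sort(self, rng):
        dsel = rng.normal(0, 1, (30, 4))
        for i in range(100):
            q = rng.normal(0, 1, 4)
            roc = region_of_competence(q, dsel, k=7)
            d = np.sqrt(((dsel - q) ** 2).sum(axis=1))
            expected = sorted(range(30), key=lambda j: (d[j], j))[:7]
            assert roc.neighbor_idx.tolist() == expected


# ---------------------------------------------------------------------------
# oracle equivalence on randomised instances
# ---------------------------------------------------------------------------

def test_rules_match_bruteforce_oracles_on_random_instances():
    """200 random correctness matrices (<=5 models, k<=7): every rule's
    selection, weights and fallback flag match the naive re-implementation
    exactly, fallback branches included."""
    gen = np.random.default_rng(123)
    for case in range(200):
        n_models = int(gen.integers(2, 6))
        k = int(gen.integers(1, 8))
        # bias towards all-wrong/all-right rows so fallbacks happen often
        p = gen.choice([0.1, 0.3, 0.5, 0.8])
        corr = (gen.random((n_models, k)) < p).astype(int)

        sel, fb = select_desp(corr)
        osel, ofb = oracle_desp(corr)
        assert sel.tolist() == osel and fb == ofb

        sel, keff, fb = select_knorae(corr)
        osel, okeff, ofb = oracle_knorae(corr)
        assert sel.tolist() == osel and keff == okeff and fb == ofb

        sel, w, fb = select_knorau(corr)
        osel, ow, ofb = oracle_knorau(corr)
        assert sel.tolist() == osel and fb == ofb
        if not fb:
            assert w.tolist() == [float(x) for x in ow]


def test_desc_matches_bruteforce_oracle_on_random_instances():
    """DES-C selection equals the naive accuracy-then-diversity oracle on
    random clusterings and correctness patterns."""
    gen = np.random.default_rng(7)
    for case in range(200):
        n_models = int(gen.integers(2, 6))
        n_dsel = int(gen.integers(6, 31))
        n_clusters = int(gen.integers(1, 5))
        cluster_labels = gen.integers(0, n_clusters, n_dsel)
        qc = int(gen.integers(0, n_clusters))
        if not np.any(cluster_labels == qc):
            cluster_labels[0] = qc
        correct = (gen.random((n_models, n_dsel)) < 0.6).astype(int)
        fa, fd = 0.5, 0.33
        mine = select_desc(cluster_labels, correct, qc, fa, fd)
        theirs = oracle_desc(cluster_labels, correct, qc, fa, fd)
        assert mine.tolist() == theirs


# ---------------------------------------------------------------------------
# ensemble-level properties
# ---------------------------------------------------------------------------

class _FuncClassifier:
    """Deterministic stand-in estimator returning a fixed probability map."""

    classes_ = np.array([0, 1])

    def __init__(self, fn):
        self.fn = fn

    def predict_proba(self, X):
        p = np.array([self.fn(np.asarray(x)) for x in np.asarray(X)])
        return np.column_stack([1 - p, p])


def _tuned(fn, name="m"):
    return TunedModel(family="knn", chosen_params={}, cv_auc_mean=0.5,
                      estimator=_FuncClassifier(fn))


def _toy_pool(fns, n_dsel=20, seed=0):
    gen = np.random.default_rng(seed)
    X = gen.normal(0, 1, (n_dsel, 3))
    y = (X[:, 0] > 0).astype(int)
    if y.min() == y.max():  # ensure both classes
        y[0] = 1 - y[0]
    return ModelPool([_tuned(f) for f in fns], X, y)


def _true_fn(x):
    return 0.9 if x[0] > 0 else 0.1


def _wrong_fn(x):
    return 0.1 if x[0] > 0 else 0.9


@pytest.mark.parametrize("rule", ["desp", "desc", "knorae", "knorau"])
def test_degenerate_pool_equals_single_model(rule, rng):
    """If all base models are identical, every rule's decision equals the
    single model's prediction on every query."""
    pool = _toy_pool([_true_fn, _true_fn, _true_fn])
    ens = DESEnsemble(pool, rule, k=5, seed=0)
    queries = rng.normal(0, 1, (100, 3))
    base = np.array([_true_fn(q) >= 0.5 for q in queries]).astype(int)
    assert np.array_equal(ens.predict(queries), base)
    assert np.allclose(ens.predict_proba(queries),
                       [_true_fn(q) for q in queries])


@pytest.mark.parametrize("rule", ["desp", "knorae"])
def test_single_competent_model_dominates(rule, rng):
    """With one model correct on every DSEL row and the rest always wrong,
    DES-P and KNORA-E reproduce the competent model's predictions."""
    pool = _toy_pool([_wrong_fn, _true_fn, _wrong_fn])
    ens = DESEnsemble(pool, rule, k=7, seed=0)
    queries = rng.normal(0, 1, (50, 3))
    expected = np.array([_true_fn(q) >= 0.5 for q in queries]).astype(int)
    assert np.array_equal(ens.predict(queries), expected)


def test_scores_always_valid_probabilities(rng):
    pool = _toy_pool([_true_fn, _wrong_fn,
                      lambda x: 0.5, lambda x: float(abs(np.tanh(x[1])))])
    for rule in ("desp", "desc", "knorae", "knorau"):
        s = DESEnsemble(pool, rule, k=5, seed=0).predict_proba(
            rng.normal(0, 1, (30, 3)))
        assert np.all((s >= 0) & (s <= 1))


class TestTuneK:
    def test_single_element_grid(self):
        pool = _toy_pool([_true_fn, _wrong_fn])
        assert tune_k(pool, "desp", [5]) == 5

    def test_deterministic(self):
        pool = _toy_pool([_true_fn, _wrong_fn, lambda x: 0.5], n_dsel=40)
        a = tune_k(pool, "knorau", [1, 3, 5, 7], seed=3)
        b = tune_k(pool, "knorau", [1, 3, 5, 7], seed=3)
        assert a == b

    def test_noisy_dsel_prefers_larger_k(self):
        """With label noise in DSEL, k=1 regions are unreliable, so tuning
        picks a larger neighbourhood in most seeds."""
        wins = 0
        for seed in range(5):
            gen = np.random.default_rng(100 + seed)
            X = gen.normal(0, 1, (60, 3))
            y = (X[:, 0] > 0).astype(int)
            flip = gen.random(60) < 0.25
            y_noisy = np.where(flip, 1 - y, y)
            pool = ModelPool([_tuned(_true_fn), _tuned(_wrong_fn),
                              _tuned(lambda x: 0.5 + 0.4 * np.tanh(x[0]))],
                             X, y_noisy)
            if tune_k(pool, "desp", [1, 3, 5, 7], seed=seed) > 1:
                wins += 1
        assert wins >= 3
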