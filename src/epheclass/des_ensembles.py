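"""Dynamic ensemble selection (DES) over a pool of trained classifiers.

For each query, a region of competence — its k nearest neighbours in the
labelled DSEL reference set — is inspected, and a selection rule picks the
base models judged locally competent:

* **DES-P**: models whose accuracy in the region beats a random classifier
  (strictly above 1/n_classes).
* **KNORA-E** (eliminate): models perfect on the whole region, shrinking the
  region one neighbour at a time (dropping the farthest) until at least one
  perfect model exists.
* **KNORA-U** (union): models correct on at least one region sample, each
  weighted by its number of correct classifications.
* **DES-C** (clustering): DSEL is partitioned by seeded k-means; within the
  query's nearest cluster the most accurate models are kept and then pruned
  to the most mutually diverse ones under the double-fault measure (fraction
  of cluster samples misclassified by both models of a pair).

When a rule selects nothing even after its own fallbacks, the whole pool
votes with uniform weights and the decision is flagged. Selected models cast
weighted hard votes; the ensemble score is the weighted mean of the models'
class-D probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .model_pool import ModelPool

RULES = ("desp", "desc", "knorae", "knorau")


@dataclass
class RegionOfCompetence:
    """The k DSEL samples nearest to a query, in ascending distance order."""

    query_id: int
    neighbor_idx: np.ndarray
    distances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.neighbor_idx = np.asarray(self.neighbor_idx, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.neighbor_idx.size != self.k or self.distances.size != self.k:
            raise ValidationError("region size does not match k")
        if np.any(np.diff(self.distances) < 0):
            raise ValidationError("distances must be non-decreasing")
        if len(set(self.neighbor_idx.tolist())) != self.k:
            raise ValidationError("neighbor indices must be unique")


def region_of_competence(query: np.ndarray, dsel_X: np.ndarray, k: int,
                         query_id: int = 0) -> RegionOfCompetence:
    """Euclidean k-nearest DSEL neighbours; distance ties broken by index."""
    dsel_X = np.asarray(dsel_X, dtype=float)
    if not 1 <= k <= dsel_X.shape[0]:
        raise ValidationError(f"k={k} outside [1, {dsel_X.shape[0]}]")
    d = np.sqrt(np.sum((dsel_X - np.asarray(query, dtype=float)) ** 2, axis=1))
    order = np.argsort(d, kind="stable")[:k]
    return RegionOfCompetence(query_id, order, d[order], k)


def correctness_matrix(dsel_predictions: np.ndarray, dsel_y: np.ndarray,
                       neighbor_idx: np.ndarray) -> np.ndarray:
    """Binary (n_models, k) matrix: model m correct on neighbour j.

    Columns follow the region's ascending-distance neighbour order, which
    KNORA-E relies on when shrinking the region.
    """
    dsel_predictions = np.asarray(dsel_predictions)
    dsel_y = np.asarray(dsel_y)
    return (dsel_predictions[:, neighbor_idx] == dsel_y[neighbor_idx]).astype(int)


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

def select_desp(corr: np.ndarray, n_classes: int = 2) -> tuple[np.ndarray, bool]:
    """Models with region accuracy strictly above the random rate 1/n_classes."""
    corr = np.asarray(corr)
    if corr.size == 0:
        raise ValidationError("empty correctness matrix")
    competence = corr.mean(axis=1) - 1.0 / n_classes
    selected = np.flatnonzero(competence > 0)
    if selected.size == 0:
        return np.arange(corr.shape[0]), True
    return selected, False


def select_knorae(corr: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Models perfect on the region, shrinking it until some model is perfect.

    Returns (selected ids, effective k, fallback flag). Columns of ``corr``
    must be in ascending distance order.
    """
    corr = np.asarray(corr)
    if corr.size == 0:
        raise ValidationError("empty correctness matrix")
    for k in range(corr.shape[1], 0, -1):
        perfect = np.flatnonzero(corr[:, :k].all(axis=1))
        if perfect.size:
            return perfect, k, False
    return np.arange(corr.shape[0]), corr.shape[1], True


def select_knorau(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Models correct on >= 1 region sample, weighted by their correct count."""
    corr = np.asarray(corr)
    if corr.size == 0:
        raise ValidationError("empty correctness matrix")
    counts = corr.sum(axis=1)
    selected = np.flatnonzero(counts > 0)
    if selected.size == 0:
        return np.arange(corr.shape[0]), np.ones(corr.shape[0]), True
    return selected, counts[selected].astype(float), False


def select_desc(
    cluster_labels: np.ndarray,
    correct: np.ndarray,
    query_cluster: int,
    frac_accurate: float = 0.5,
    frac_diverse: float = 0.33,
) -> np.ndarray:
    """DES-Clustering selection inside the query's cluster.

    Rank models by accuracy on the cluster's DSEL samples and keep the top
    ceil(frac_accurate * n_models); among those, greedily retain the
    ceil(frac_diverse * n_models) most diverse models, where pairwise
    diversity = 1 - double-fault rate. The greedy pass is seeded from the most
    accurate model; ties favour higher accuracy, then the lower model index.
    """
    if not (0 < frac_accurate <= 1 and 0 < frac_diverse <= 1):
        raise ValidationError("fractions must be in (0, 1]")
    cluster_labels = np.asarray(cluster_labels)
    correct = np.asarray(correct)
    n_models = correct.shape[0]
    members = np.flatnonzero(cluster_labels == query_cluster)
    if members.size == 0:
        raise ValidationError("query assigned to an empty cluster")
    sub = correct[:, members]
    acc = sub.mean(axis=1)
    n_acc = int(np.ceil(frac_accurate * n_models))
    # descending accuracy, ties by lower model index (stable sort)
    acc_order = np.argsort(-acc, kind="stable")[:n_acc]
    n_div = min(int(np.ceil(frac_diverse * n_models)), acc_order.size)
    both_wrong = (1 - sub) @ (1 - sub.T) / members.size  # double-fault rates
    diversity = 1.0 - both_wrong
    chosen = [int(acc_order[0])]
    remaining = [int(m) for m in acc_order[1:]]
    while len(chosen) < n_div and remaining:
        gains = [float(np.mean([diversity[m, c] for c in chosen])) for m in remaining]
        best = max(range(len(remaining)),
                   key=lambda i: (gains[i], acc[remaining[i]], -remaining[i]))
        chosen.append(remaining.pop(best))
    return np.sort(np.asarray(chosen, dtype=np.int64))


@dataclass
class EnsembleDecision:
    """Outcome of one query: who voted, how, and the combined call."""

    selected_models: list[int]
    weights: np.ndarray
    label: int  # 1 = positive class D
    score: float  # weighted mean of class-D probabilities
    fallback_used: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != len(self.selected_models):
            raise ValidationError("weights must align with selected_models")
        if np.any(self.weights <= 0):
            raise ValidationError("weights must be positive")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError("score must be in [0, 1]")


def combine(probs_positive: np.ndarray, weights: np.ndarray | None = None,
            selected_models: list[int] | None = None,
            fallback_used: bool = False) -> EnsembleDecision:
    """Weighted hard vote with a soft tie-break.

    Each selected model votes D iff its class-D probability is >= 0.5; the
    label is the weighted majority. A vote tie goes to the label favoured by
    the weighted mean probability; a residual tie (mean exactly 0.5) goes to
    NotD. The ensemble score is the weighted mean class-D probability.
    """
    probs = np.asarray(probs_positive, dtype=float)
    if probs.size == 0:
        raise ValidationError("combine needs at least one selected model")
    w = np.ones(probs.size) if weights is None else np.asarray(weights, dtype=float)
    votes = (probs >= 0.5).astype(int)
    w_pos = float(w[votes == 1].sum())
    w_neg = float(w[votes == 0].sum())
    score = float(np.clip((w * probs).sum() / w.sum(), 0.0, 1.0))
    if w_pos > w_neg:
        label = 1
    elif w_neg > w_pos:
        label = 0
    else:
        label = 1 if score > 0.5 else 0
    ids = list(range(probs.size)) if selected_models is None else list(selected_models)
    return EnsembleDecision(ids, w, label, score, fallback_used)


# ---------------------------------------------------------------------------
# ensemble classifier
# ---------------------------------------------------------------------------

class DESEnsemble:
    """Applies one DES rule over a :class:`~epheclass.model_pool.ModelPool`.

    Parameters
    ----------
    pool
        Trained base models plus DSEL.
    rule
        One of ``desp``, ``desc``, ``knorae``, ``knorau``.
    k
        Region-of-competence size for the kNN-based rules.
    n_clusters, frac_accurate, frac_diverse, seed
        DES-C parameters; the k-means partition of DSEL is seeded.
    """

    def __init__(self, pool: ModelPool, rule: str, k: int = 7,
                 n_clusters: int = 5, frac_accurate: float = 0.5,
                 frac_diverse: float = 0.33, seed: int = 0):
        if rule not in RULES:
            raise ValidationError(f"unknown DES rule {rule!r}")
        self.pool = pool
        self.rule = rule
        self.k = int(min(k, pool.dsel_y.size))
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        self.seed = seed
        self.frac_accurate = frac_accurate
        self.frac_diverse = frac_diverse
        self._dsel_preds = pool.predictions_on_dsel()
        self._correct = (self._dsel_preds == pool.dsel_y[None, :]).astype(int)
        self._kmeans = None
        if rule == "desc":
            n_clusters = int(min(n_clusters, pool.dsel_y.size))
            self._kmeans = KMeans(n_clusters=n_clusters, random_state=seed,
                                  n_init=10).fit(pool.dsel_X)
            self._cluster_labels = self._kmeans.labels_

    def decide(self, x: np.ndarray, query_id: int = 0) -> EnsembleDecision:
        probs = np.array([
            float(m.predict_proba_positive(np.asarray(x, dtype=float)[None, :])[0])
            for m in self.pool.models
        ])
        fallback = False
        weights = None
        if self.rule == "desc":
            centres = self._kmeans.cluster_centers_
            d = np.sqrt(np.sum((centres - x) ** 2, axis=1))
            cluster = int(np.argmin(d))
            selected = select_desc(self._cluster_labels, self._correct, cluster,
                                   self.frac_accurate, self.frac_diverse)
        else:
            roc = region_of_competence(x, self.pool.dsel_X, self.k, query_id)
            corr = correctness_matrix(self._dsel_preds, self.pool.dsel_y,
                                      roc.neighbor_idx)
            if self.rule == "desp":
                selected, fallback = select_desp(corr, n_classes=2)
            elif self.rule == "knorae":
                selected, _, fallback = select_knorae(corr)
            else:
                selected, weights, fallback = select_knorau(corr)
        w = np.ones(selected.size) if weights is None else weights
        return combine(probs[selected], w, [int(i) for i in selected], fallback)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.decide(x, i).score for i, x in enumerate(X)])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.decide(x, i).label for i, x in enumerate(X)])


def tune_k(pool: ModelPool, rule: str, k_grid: list[int] | None = None,
           folds: int = 5, seed: int = 0) -> int:
    """Choose the region size k by cross-validated AUC over the DSEL set.

    DSEL is split into stratified folds; each fold in turn provides the
    queries while the remaining DSEL rows form the competence regions. The k
    maximising the pooled out-of-fold AUC wins; ties go to the smallest k.
    """
    from sklearn.metrics import roc_auc_score

    k_grid = sorted(k_grid or [3, 5, 7, 9, 11])
    if not k_grid:
        raise ValidationError("k_grid must be non-empty")
    if len(k_grid) == 1:
        return k_grid[0]
    y = pool.dsel_y
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        return k_grid[0]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_k, best_auc = k_grid[0], -np.inf
    for k in k_grid:
        scores = np.zeros(y.size)
        for held_out, _ in ((te, tr) for tr, te in skf.split(pool.dsel_X, y)):
            rest = np.setdiff1d(np.arange(y.size), held_out)
            sub_pool = ModelPool(pool.models, pool.dsel_X[rest], y[rest])
            ens = DESEnsemble(sub_pool, rule, k=min(k, rest.size), seed=seed)
            scores[held_out] = ens.predict_proba(pool.dsel_X[held_out])
        auc = roc_auc_score(y, scores)
        if auc > best_auc + 1e-12:
            best_k, best_auc = k, auc
    return best_k
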