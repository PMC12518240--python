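"""Metrics, cross-validated evaluation, and permutation-based ROC comparison.

Classification quality is summarised by F1, precision, recall, accuracy and
ROC AUC (positive class = ``D``). Cross-validated numbers come from pooled
out-of-fold predictions of a stratified k-fold loop in which augmentation is
re-planned inside each training fold and the fold's validation part doubles
as the DSEL reference set for the DES rules.

Two ROC curves are compared with rank-based permutation tests: the paired
variant permutes, per sample, which curve each of its two rank scores belongs
to; the unpaired variant permutes group membership of the pooled records
within each class. The statistic is the integrated absolute difference
between the two empirical curves over threshold ranks, and the p-value uses
the add-one permutation formula, so its lower bound is 1/(1+B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.metrics import (accuracy_score, precision_recall_fscore_support,
                             roc_auc_score, roc_curve)
from sklearn.model_selection import StratifiedKFold

from .augmentation import augment, downsample_majority, plan_balancing
from .des_ensembles import RULES, DESEnsemble
from .errors import ValidationError
from .model_pool import ModelPool, TunedModel, _base_estimator, _encode_labels
from .preprocessing import CompositionMatrix, clr_transform

METRIC_NAMES = ("f1", "precision", "recall", "accuracy", "roc_auc")


def confusion_metrics(labels: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """F1, precision, recall and accuracy from the 2x2 confusion table.

    The positive class is ``D``; zero-denominator cases follow the convention
    precision = recall = f1 = 0.
    """
    y = _encode_labels(np.asarray(labels))
    yhat = _encode_labels(np.asarray(predicted))
    if y.size == 0:
        raise ValidationError("empty input")
    p, r, f1, _ = precision_recall_fscore_support(
        y, yhat, pos_label=1, average="binary", zero_division=0
    )
    return {
        "f1": float(f1),
        "precision": float(p),
        "recall": float(r),
        "accuracy": float(accuracy_score(y, yhat)),
    }


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal area under the empirical ROC, plus the curve points.

    Tied scores advance the curve diagonally (equivalently, Mann-Whitney with
    half credit for ties).
    """
    y = _encode_labels(np.asarray(labels))
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC AUC needs both classes")
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y, scores)
    return float(roc_auc_score(y, scores)), fpr, tpr


def _scores_to_metrics(y, scores, hard_labels) -> dict[str, float]:
    out = confusion_metrics(y, hard_labels)
    out["roc_auc"] = roc_auc(y, scores)[0]
    return out


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def cv_evaluate(
    comp_values: np.ndarray,
    y: np.ndarray,
    tuned: list[TunedModel],
    feature_idx: np.ndarray | None = None,
    stratum: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    imbalance_strategy: str = "none",
    p_mask: float = 0.5,
    des_rules: tuple[str, ...] = RULES,
    k: int = 7,
    desc_params: dict | None = None,
) -> pd.DataFrame:
    """Stratified k-fold evaluation of base models and DES rules.

    ``comp_values`` are training compositions (strictly positive rows over
    the abundance-filtered feature set). Per fold the training part is
    rebalanced according to ``imbalance_strategy`` (``augment`` /
    ``downsample`` / ``none``), CLR-transformed, reduced to ``feature_idx``
    and used to fit the tuned models; the validation part serves both as the
    DSEL reference set and the scoring queries. Out-of-fold scores are pooled
    before computing metrics.
    """
    comp_values = np.asarray(comp_values, dtype=float)
    y_enc = _encode_labels(np.asarray(y))
    strat = None if stratum is None else np.asarray(stratum, dtype=object)
    feat = (np.arange(comp_values.shape[1]) if feature_idx is None
            else np.asarray(feature_idx, dtype=np.int64))
    folds = min(folds, int(np.bincount(y_enc).min()))
    if folds < 2:
        raise ValidationError("cannot stratify: a class has < 2 samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    names = [m.family for m in tuned] + [f"des_{r}" for r in des_rules]
    pooled_scores = {n: np.zeros(y_enc.size) for n in names}
    pooled_labels = {n: np.zeros(y_enc.size, dtype=int) for n in names}
    for fold_i, (tr, va) in enumerate(skf.split(comp_values, y_enc)):
        Xc_tr, y_tr = comp_values[tr], y_enc[tr]
        st_tr = None if strat is None else strat[tr]
        Xc_tr, y_tr, st_tr = _rebalance(
            Xc_tr, y_tr, st_tr, imbalance_strategy, p_mask,
            seed=seed * 1000 + fold_i,
        )
        X_tr = _clr_reduce(Xc_tr, feat)
        X_va = _clr_reduce(comp_values[va], feat)
        y_tr = _encode_labels(y_tr)
        fold_models = []
        for m in tuned:
            est = clone(_base_estimator(m.family, m.seed))
            est.set_params(**m.chosen_params)
            est.fit(X_tr, y_tr)
            fold_models.append(TunedModel(m.family, dict(m.chosen_params),
                                          m.cv_auc_mean, est, m.seed))
        for m in fold_models:
            s = m.predict_proba_positive(X_va)
            pooled_scores[m.family][va] = s
            pooled_labels[m.family][va] = (s >= 0.5).astype(int)
        pool = ModelPool(fold_models, X_va, y_enc[va])
        for rule in des_rules:
            ens = DESEnsemble(pool, rule, k=min(k, va.size), seed=seed,
                              **(desc_params or {}))
            s = ens.predict_proba(X_va)
            pooled_scores[f"des_{rule}"][va] = s
            pooled_labels[f"des_{rule}"][va] = ens.predict(X_va)
    rows = []
    for n in names:
        m = _scores_to_metrics(y_enc, pooled_scores[n], pooled_labels[n])
        rows.append({"model": n, **m})
    return pd.DataFrame(rows)


def _rebalance(values, y, stratum, strategy, p_mask, seed):
    """Apply the configured class-imbalance strategy to a training partition."""
    if strategy in (None, "none"):
        return values, y, stratum
    if strategy == "augment":
        plan = plan_balancing(y, stratum, seed=seed, p_mask=p_mask)
        return augment(values, y, plan, stratum)
    if strategy == "downsample":
        keep = downsample_majority(y, stratum, seed=seed)
        return (values[keep], np.asarray(y)[keep],
                None if stratum is None else np.asarray(stratum)[keep])
    raise ValidationError(f"unknown imbalance strategy {strategy!r}")


def _clr_reduce(comp_values: np.ndarray, feature_idx: np.ndarray) -> np.ndarray:
    """CLR over the full composition, then column-subset to selected features."""
    clr = clr_transform(CompositionMatrix(comp_values))
    return clr.values[:, feature_idx]


# ---------------------------------------------------------------------------
# Venkatraman permutation tests for ROC equality
# ---------------------------------------------------------------------------

@dataclass
class RocComparison:
    """Curve-difference statistic, permutation count, and add-one p-value."""

    statistic: float
    n_permutations: int
    p_value: float
    mode: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValidationError("statistic must be non-negative")
        if not 0 < self.p_value <= 1:
            raise ValidationError("p-value must be in (0, 1]")


def _paired_statistic(R: np.ndarray, S: np.ndarray, case: np.ndarray) -> float:
    """Sum over cutoff ranks of |error-count difference| between the curves.

    R, S are rank vectors (a permutation of 1..n each); case is the boolean
    positive-class indicator. The error count at cutoff x is
    (#cases ranked <= x) + (#controls ranked > x).
    """
    n = case.size
    n_controls = int((~case).sum())
    e = []
    for ranks in (R, S):
        case_at = np.zeros(n)
        ctrl_at = np.zeros(n)
        case_at[ranks - 1] = case
        ctrl_at[ranks - 1] = ~case
        fn = np.cumsum(case_at)
        fp = n_controls - np.cumsum(ctrl_at)
        e.append(fn + fp)
    return float(np.abs(e[0] - e[1]).sum())


def venkatraman_paired(scores_a, scores_b, labels, n_permutations: int = 999,
                       seed: int = 0) -> RocComparison:
    """Permutation test for equality of two ROC curves on the same samples.

    Scores are rank-transformed; the null is generated by swapping, per
    sample and with probability 1/2, which curve each of its two rank scores
    belongs to, re-ranking after each swap (non-swapped ranks are jittered
    before re-ranking so swapped-in values interleave randomly).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    case = _encode_labels(np.asarray(labels)).astype(bool)
    if a.shape != b.shape or a.shape != case.shape:
        raise ValidationError("scores and labels must have equal length")
    if case.all() or not case.any():
        raise ValidationError("both classes required")
    R = rankdata(a, method="ordinal").astype(float)
    S = rankdata(b, method="ordinal").astype(float)
    observed = _paired_statistic(R.astype(int), S.astype(int), case)
    rng = np.random.default_rng(seed)
    n = case.size
    exceed = 0
    for _ in range(n_permutations):
        jr = R + rng.uniform(-0.5, 0.5, n)
        js = S + rng.uniform(-0.5, 0.5, n)
        swap = rng.integers(0, 2, n).astype(bool)
        r3 = np.where(swap, S, jr)
        s3 = np.where(swap, R, js)
        stat = _paired_statistic(rankdata(r3, method="ordinal"),
                                 rankdata(s3, method="ordinal"), case)
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return RocComparison(observed, n_permutations, p, "paired", seed)


def _ecdf_at_cutoffs(ranks: np.ndarray, n: int) -> np.ndarray:
    """Fraction of ``ranks`` at or below each cutoff 1..n."""
    if ranks.size == 0:
        return np.zeros(n)
    srt = np.sort(ranks)
    return np.searchsorted(srt, np.arange(1, n + 1), side="right") / ranks.size


def _unpaired_statistic(R, S, case1, case2, mp) -> float:
    """Integrated |difference| between the two curves on a common abscissa.

    Each group's curve is parameterised by the pooled classification
    proportion p = mp*F + (1-mp)*G and the expected accuracy
    mp*F + (1-mp)*(1-G); the absolute difference is integrated by trapezoid
    over the union of both groups' abscissa points, skipping segments outside
    either curve's range.
    """
    curves = []
    for ranks, case in ((R, case1), (S, case2)):
        n = case.size
        fx = _ecdf_at_cutoffs(ranks[case], n)
        gx = _ecdf_at_cutoffs(ranks[~case], n)
        p = mp * fx + (1 - mp) * gx
        expd = mp * fx + (1 - mp) * (1 - gx)
        curves.append((p, expd))
    xs = np.sort(np.concatenate([curves[0][0], curves[1][0]]))
    ys = np.abs(_interp_na(xs, *curves[0]) - _interp_na(xs, *curves[1]))
    dx = np.diff(xs)
    terms = (ys[1:] + ys[:-1]) * dx / 2
    return float(np.nansum(terms))


def _interp_na(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Linear interpolation, NaN outside the data range, mean-collapsed ties."""
    xp = np.asarray(xp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    order = np.argsort(xp, kind="stable")
    xp, fp = xp[order], fp[order]
    ux, inverse = np.unique(xp, return_inverse=True)
    uf = np.bincount(inverse, weights=fp) / np.bincount(inverse)
    y = np.interp(x, ux, uf)
    y[(x < ux[0]) | (x > ux[-1])] = np.nan
    return y


def venkatraman_unpaired(scores_a, labels_a, scores_b, labels_b,
                         n_permutations: int = 999, seed: int = 0) -> RocComparison:
    """Permutation test for ROC equality between two independent samples.

    The null permutes group membership of the pooled (score, label) records
    within each class, re-ranking within each group and recomputing the
    curve-difference statistic each time.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    case1 = _encode_labels(np.asarray(labels_a)).astype(bool)
    case2 = _encode_labels(np.asarray(labels_b)).astype(bool)
    for s, c in ((a, case1), (b, case2)):
        if s.shape != c.shape:
            raise ValidationError("scores and labels must have equal length")
        if c.all() or not c.any():
            raise ValidationError("both classes required in each group")
    mp = (case1.sum() + case2.sum()) / (case1.size + case2.size)
    R = rankdata(a, method="ordinal").astype(float)
    S = rankdata(b, method="ordinal").astype(float)
    observed = _unpaired_statistic(R.astype(int), S.astype(int), case1, case2, mp)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        jr = R + rng.uniform(-0.5, 0.5, R.size)
        js = S + rng.uniform(-0.5, 0.5, S.size)
        r_new, s_new = jr.copy(), js.copy()
        for case_flag in (True, False):
            ia = np.flatnonzero(case1 == case_flag)
            ib = np.flatnonzero(case2 == case_flag)
            pooled = np.concatenate([jr[ia], js[ib]])
            pooled = pooled[rng.permutation(pooled.size)]
            r_new[ia] = pooled[:ia.size]
            s_new[ib] = pooled[ia.size:]
        stat = _unpaired_statistic(rankdata(r_new, method="ordinal"),
                                   rankdata(s_new, method="ordinal"),
                                   case1, case2, mp)
        if stat >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return RocComparison(observed, n_permutations, p, "unpaired", seed)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(metrics: pd.DataFrame, nsf_list: list[int], out_dir) -> pd.DataFrame:
    """Write per-NSF tables, the NSF-averaged table and AUC-vs-NSF plots.

    ``metrics`` has columns model, nsf, split plus the five metric names.
    NSF cells absent from the table (consensus unattainable) are simply
    excluded from the averages. Returns the averaged table.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for nsf in sorted(set(metrics["nsf"])):
        sub = metrics[metrics["nsf"] == nsf]
        sub.to_csv(out_dir / f"metrics_nsf{nsf}.tsv", sep="\t", index=False,
                   float_format="%.6f")
    avg = (metrics.groupby(["model", "split"], as_index=False)[list(METRIC_NAMES)]
           .mean().sort_values(["split", "model"], kind="stable"))
    avg.to_csv(out_dir / "metrics_nsf_averaged.tsv", sep="\t", index=False,
               float_format="%.6f")
    for split in sorted(set(metrics["split"])):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        sub = metrics[metrics["split"] == split]
        for model in sorted(set(sub["model"])):
            ms = sub[sub["model"] == model].sort_values("nsf")
            ax.plot(ms["nsf"], ms["roc_auc"], marker="o", label=model)
        ax.set_xlabel("number of selected features (NSF)")
        ax.set_ylabel("ROC AUC")
        ax.set_title(f"AUC vs NSF ({split})")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out_dir / f"auc_vs_nsf_{split}.png", dpi=120)
        plt.close(fig)
    return avg
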