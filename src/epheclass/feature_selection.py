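"""Consensus recursive feature elimination (RFE) over three estimator families.

RFE repeatedly fits an estimator, ranks the surviving features by importance
(impurity importance for random forests, absolute coefficients for the linear
models) and removes the least important ones until a target count remains.
Three estimators are run at a shared target t — random forest, linear-kernel
SVM and logistic regression — and only the features selected by all three are
kept. Because an intersection of three size-t sets is rarely of a round size,
the target t is scanned upward until the intersection has exactly the
requested final number of features (NSF); some NSF values are unattainable
when the intersection size jumps past them, which is reported as an error
carrying the scan trace.

The elimination step removes max(1, floor(step_fraction * current)) features
per iteration, truncated so the loop lands exactly on the target. For the
scan, one elimination path per estimator is computed down to the NSF and the
survivor set at any larger target is reconstructed from the recorded
rankings; this is fit-for-fit identical to running RFE at each target
separately, because the two runs only diverge at the final truncated removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .errors import ConsensusUnattainableError, ValidationError
from .preprocessing import ClrMatrix


@dataclass
class ConsensusSelection:
    """Result of the consensus scan.

    ``consensus`` is the intersection of the three per-estimator sets obtained
    at the shared target ``target_t``; ``search_trace`` records
    (t, intersection size) for every target tried.
    """

    nsf: int
    target_t: int
    per_estimator_sets: dict[str, list[int]]
    consensus: list[int]
    search_trace: list[tuple[int, int]] = field(default_factory=list)
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.consensus) != self.nsf:
            raise ValidationError("consensus size does not equal nsf")
        if self.nsf > self.target_t:
            raise ValidationError("nsf cannot exceed target_t")


def default_rfe_estimators(seed: int = 0) -> dict[str, object]:
    """The three RFE estimator families: RF, linear SVM, logistic regression."""
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "svm": LinearSVC(C=1.0, dual="auto", max_iter=20000, tol=1e-3,
                         random_state=seed),
        "logistic_regression": LogisticRegression(C=1.0, max_iter=2000),
    }


def _importances(fitted) -> np.ndarray:
    if hasattr(fitted, "feature_importances_"):
        return np.asarray(fitted.feature_importances_, dtype=float)
    if hasattr(fitted, "coef_"):
        coef = np.asarray(fitted.coef_, dtype=float)
        return np.abs(coef).sum(axis=0)
    raise ValidationError(
        f"estimator {type(fitted).__name__} exposes no per-feature importance"
    )


def _step_size(current: int, step: int | float) -> int:
    if isinstance(step, float):
        if not 0 < step < 1:
            raise ValidationError("fractional step must be in (0, 1)")
        return max(1, int(np.floor(step * current)))
    if step < 1:
        raise ValidationError("integer step must be >= 1")
    return int(step)


@dataclass
class _PathNode:
    """One RFE fit: surviving count and survivors ranked by ascending importance."""

    count: int
    ranked: np.ndarray  # original feature indices, least important first


def _rfe_path(estimator, X: np.ndarray, y: np.ndarray,
              min_target: int, step: int | float) -> list[_PathNode]:
    """Eliminate down to ``min_target``, recording each fit's ranking."""
    n_features = X.shape[1]
    surviving = np.arange(n_features)
    nodes: list[_PathNode] = []
    while surviving.size > min_target:
        fitted = clone(estimator).fit(X[:, surviving], y)
        imp = _importances(fitted)
        # ascending importance; ties keep the lower original feature index
        order = surviving[np.argsort(imp, kind="stable")]
        nodes.append(_PathNode(surviving.size, order))
        n_remove = min(_step_size(surviving.size, step),
                       surviving.size - min_target)
        surviving = np.sort(order[n_remove:])
    return nodes


def _set_at_target(nodes: list[_PathNode], n_features: int, target: int) -> np.ndarray:
    """Survivor set at ``target``, identical to a standalone RFE run there."""
    if target == n_features:
        return np.arange(n_features)
    # last fit with more than `target` survivors decides the truncated removal
    node = None
    for cand in nodes:
        if cand.count > target:
            node = cand
        else:
            break
    if node is None:  # pragma: no cover - guarded by caller
        raise ValidationError("elimination path does not reach target")
    return np.sort(node.ranked[node.count - target:])


def rfe(estimator, X: np.ndarray, y: np.ndarray,
        target: int, step: int | float = 0.05) -> np.ndarray:
    """Recursive feature elimination to exactly ``target`` surviving features.

    Returns the sorted original column indices of the survivors. ``step`` is
    either an integer (features removed per iteration) or a fraction of the
    *current* feature count; the final removal is truncated to land on
    ``target``. Deterministic given the estimator's random_state.
    """
    X = np.asarray(X, dtype=float)
    if target < 1:
        raise ValidationError("target must be >= 1")
    if target > X.shape[1]:
        raise ValidationError(f"target {target} exceeds {X.shape[1]} features")
    if target == X.shape[1]:
        return np.arange(X.shape[1])
    nodes = _rfe_path(estimator, X, y, target, step)
    return _set_at_target(nodes, X.shape[1], target)


def consensus_select(
    X: np.ndarray | ClrMatrix,
    y: np.ndarray,
    nsf: int,
    t_max: int | None = None,
    step: int | float = 0.05,
    seed: int = 0,
    estimators: dict[str, object] | None = None,
) -> ConsensusSelection:
    """Scan the shared RFE target t upward until the 3-way intersection
    has exactly ``nsf`` features.

    The scan starts at t = nsf (an intersection can never exceed t) and stops
    at the first t whose intersection size equals nsf. If the intersection
    size skips over nsf for every t <= t_max, a
    :class:`~epheclass.errors.ConsensusUnattainableError` carrying the trace
    is raised.
    """
    feature_ids = None
    if isinstance(X, ClrMatrix):
        feature_ids = list(X.feature_ids)
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    if nsf < 1:
        raise ValidationError("nsf must be >= 1")
    if nsf > n_features:
        raise ValidationError(f"nsf {nsf} exceeds {n_features} features")
    if t_max is None:
        t_max = min(200, n_features)
    t_max = min(t_max, n_features)
    if t_max < nsf:
        raise ValidationError("t_max must be >= nsf")
    estimators = estimators or default_rfe_estimators(seed)
    paths = {
        name: _rfe_path(est, X, y, nsf, step)
        for name, est in estimators.items()
    }
    trace: list[tuple[int, int]] = []
    for t in range(nsf, t_max + 1):
        sets = {
            name: _set_at_target(nodes, n_features, t)
            for name, nodes in paths.items()
        }
        consensus = sorted(set.intersection(*(set(s.tolist()) for s in sets.values())))
        trace.append((t, len(consensus)))
        if len(consensus) == nsf:
            return ConsensusSelection(
                nsf=nsf,
                target_t=t,
                per_estimator_sets={k: np.sort(v).tolist() for k, v in sets.items()},
                consensus=consensus,
                search_trace=trace,
                feature_ids=feature_ids,
            )
    raise ConsensusUnattainableError(nsf, trace)
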