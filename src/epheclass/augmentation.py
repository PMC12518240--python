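"""Compositional CutMix: same-class augmentation on the simplex.

A synthetic sample is built by splicing two training compositions of the same
class (and same stratum, when strata such as collection sites are present):
a Bernoulli feature mask takes each feature's value from one parent or the
other, and the spliced vector is re-closed to sum 1. Because the downstream
CLR transform is scale-invariant per row, the closure constant is harmless
even when parents were cut to a top-k subcomposition.

Augmentation only ever sees training rows; the plan adds to the minority
class, per stratum, exactly the deficit against the majority class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

_NO_STRATUM = "__all__"


@dataclass
class AugmentationPlan:
    """Number of synthetic samples to create per (class, stratum) cell."""

    cells: dict[tuple[str, str], int]
    seed: int = 0
    p_mask: float = 0.5

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.cells.values()):
            raise ValidationError("synthetic counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.cells.values())


def plan_balancing(
    labels: np.ndarray,
    stratum: np.ndarray | None = None,
    seed: int = 0,
    p_mask: float = 0.5,
) -> AugmentationPlan:
    """Plan per-stratum class balancing for a training set.

    Within each stratum the minority class is topped up to the majority class
    count. A stratum where the minority class has zero samples cannot be
    balanced (nothing to synthesize from) and raises.
    """
    labels = np.asarray(labels, dtype=object)
    strat = (np.full(labels.shape, _NO_STRATUM, dtype=object)
             if stratum is None else np.asarray(stratum, dtype=object))
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValidationError("plan_balancing expects exactly two classes")
    cells: dict[tuple[str, str], int] = {}
    for s in sorted(set(strat), key=str):
        in_s = strat == s
        counts = {c: int(np.sum(labels[in_s] == c)) for c in classes}
        target = max(counts.values())
        for c, n in counts.items():
            deficit = target - n
            if deficit > 0:
                if n == 0:
                    raise ValidationError(
                        f"stratum {s!r} has no {c!r} samples to synthesize from"
                    )
                cells[(c, s)] = deficit
    return AugmentationPlan(cells, seed=seed, p_mask=p_mask)


def cutmix_pair(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Splice two positive compositions feature-wise and re-close to sum 1.

    ``child_j`` is proportional to ``x_j`` where ``mask_j`` is 1 and to
    ``y_j`` where it is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask)
    if x.shape != y.shape or mask.shape != x.shape:
        raise ValidationError("cutmix_pair: length mismatch")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("cutmix_pair: parents must be strictly positive")
    child = np.where(mask.astype(bool), x, y)
    return child / child.sum()


def augment(
    values: np.ndarray,
    labels: np.ndarray,
    plan: AugmentationPlan,
    stratum: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Append the planned synthetic rows to a training composition matrix.

    Parents are drawn uniformly with replacement from the (class, stratum)
    cell (a parent may pair with itself, yielding a copy); the feature mask is
    i.i.d. Bernoulli(p_mask). Deterministic given ``plan.seed``; original rows
    are returned untouched. Returns (values, labels, stratum) with synthetic
    rows appended.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    strat = (np.full(labels.shape, _NO_STRATUM, dtype=object)
             if stratum is None else np.asarray(stratum, dtype=object))
    rng = np.random.default_rng(plan.seed)
    new_rows, new_labels, new_strat = [], [], []
    for (cls, s), n_new in sorted(plan.cells.items()):
        pool = np.flatnonzero((labels == cls) & (strat == s))
        if pool.size == 0:
            raise ValidationError(
                f"plan demands class {cls!r} in stratum {s!r} absent from data"
            )
        for _ in range(n_new):
            i, j = rng.choice(pool, size=2, replace=True)
            mask = rng.random(values.shape[1]) < plan.p_mask
            new_rows.append(cutmix_pair(values[i], values[j], mask))
            new_labels.append(cls)
            new_strat.append(s)
    if not new_rows:
        return values, labels, strat
    out_values = np.vstack([values, np.asarray(new_rows)])
    out_labels = np.concatenate([labels, np.asarray(new_labels, dtype=object)])
    out_strat = np.concatenate([strat, np.asarray(new_strat, dtype=object)])
    return out_values, out_labels, out_strat


def downsample_majority(
    labels: np.ndarray,
    stratum: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Indices keeping, per stratum, a majority-class subsample of minority size.

    The comparator strategy to augmentation: instead of synthesizing minority
    samples, randomly discard majority samples until classes balance.
    """
    labels = np.asarray(labels, dtype=object)
    strat = (np.full(labels.shape, _NO_STRATUM, dtype=object)
             if stratum is None else np.asarray(stratum, dtype=object))
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for s in sorted(set(strat), key=str):
        in_s = np.flatnonzero(strat == s)
        classes = sorted(set(labels[in_s]), key=str)
        n_min = min(int(np.sum(labels[in_s] == c)) for c in classes)
        for c in classes:
            idx = in_s[labels[in_s] == c]
            if idx.size > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep.extend(idx.tolist())
    return np.sort(np.asarray(keep, dtype=np.int64))
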