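"""Compositional preprocessing: sample filtering, closure, top-k cut, split, CLR.

Count tables from amplicon sequencing carry only relative information, so the
pipeline works on the simplex: a pseudocount removes zeros, total-sum scaling
closes each sample to relative frequencies, and the centred log-ratio (CLR)
transform maps each row into a zero-sum Euclidean representation where
standard classifiers are well behaved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .abundance_io import AbundanceTable
from .errors import EmptyDatasetError, ValidationError

logger = logging.getLogger("epheclass")


@dataclass
class PreprocessConfig:
    """Constants of the data-processing stage.

    min_total_counts
        Minimum per-sample sequencing depth; samples below are discarded.
    pseudocount
        Added to every count before closure so log-ratios are defined.
    top_k_features
        Number of most-abundant features retained (by mean relative
        frequency over all samples).
    train_fraction
        Fraction of samples assigned to the training split, stratified by
        class.
    """

    min_total_counts: int = 2500
    pseudocount: int = 1
    top_k_features: int = 1500
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_total_counts < 0:
            raise ValidationError("min_total_counts must be >= 0")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.top_k_features < 1:
            raise ValidationError("top_k_features must be >= 1")


@dataclass
class CompositionMatrix:
    """Strictly positive relative-frequency matrix, one composition per row.

    Rows sum to 1 after :func:`to_relative`; after a top-k feature cut the
    retained columns keep their values, so row sums may drop slightly below 1
    (the closure constant is irrelevant to CLR, which is scale-invariant).
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("composition values must be 2-D")
        if np.any(self.values <= 0):
            raise ValidationError("composition entries must be strictly positive")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.values.shape[0])]
        if not self.feature_ids:
            self.feature_ids = [f"F{j}" for j in range(self.values.shape[1])]


@dataclass
class ClrMatrix:
    """Centred log-ratio coordinates; every row sums to 0 (within 1e-9)."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and np.max(np.abs(self.values.sum(axis=1))) > 1e-9:
            raise ValidationError("CLR rows must sum to 0")


@dataclass
class SplitSpec:
    """A stratified train/test partition of sample indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.test_idx = np.asarray(self.test_idx, dtype=np.int64)
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValidationError("train and test indices overlap")


def filter_samples(table: AbundanceTable, min_total_counts: int) -> AbundanceTable:
    """Keep samples whose total count is at least ``min_total_counts``.

    The threshold is inclusive: a sample at exactly the minimum depth is
    retained. Idempotent.
    """
    totals = table.counts.sum(axis=1)
    keep = np.flatnonzero(totals >= min_total_counts)
    discarded = table.n_samples - keep.size
    if keep.size == 0:
        raise EmptyDatasetError(
            f"no samples reach {min_total_counts} total counts"
        )
    logger.info("filter_samples: discarded %d of %d samples below %d counts",
                discarded, table.n_samples, min_total_counts)
    return table.select_samples(keep)


def to_relative(table: AbundanceTable, pseudocount: int = 1) -> CompositionMatrix:
    """Pseudocount + total-sum scaling: counts to strictly positive closures."""
    if table.n_samples == 0 or table.n_features == 0:
        raise EmptyDatasetError("empty table")
    shifted = table.counts.astype(float) + float(pseudocount)
    row_sums = shifted.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValidationError(
            "degenerate all-zero row with pseudocount 0; use a positive pseudocount"
        )
    return CompositionMatrix(shifted / row_sums[:, None],
                             list(table.sample_ids), list(table.feature_ids))


def top_abundant_features(comp: CompositionMatrix, k: int) -> CompositionMatrix:
    """Keep the ``k`` features with highest mean relative frequency.

    Ties at rank k are broken in favour of the earlier (lower) feature id, via
    a stable sort. Values of retained columns are not re-closed.
    """
    n_features = comp.values.shape[1]
    if k > n_features:
        raise ValidationError(f"k={k} exceeds {n_features} features")
    means = comp.values.mean(axis=0)
    order = np.argsort(-means, kind="stable")
    keep = np.sort(order[:k])
    return CompositionMatrix(
        comp.values[:, keep],
        list(comp.sample_ids),
        [comp.feature_ids[j] for j in keep],
    )


def _largest_remainder_counts(class_sizes: list[int], fraction: float) -> list[int]:
    """Per-class train counts: floors plus largest-remainder top-up so the
    global train size equals round(fraction * n)."""
    total = int(round(fraction * sum(class_sizes)))
    exact = [fraction * s for s in class_sizes]
    base = [int(np.floor(e)) for e in exact]
    short = total - sum(base)
    # distribute remaining slots by descending fractional remainder;
    # ties resolved toward the larger class, then first listed
    order = sorted(
        range(len(class_sizes)),
        key=lambda c: (-(exact[c] - base[c]), -class_sizes[c], c),
    )
    for c in order[:max(short, 0)]:
        base[c] += 1
    return base


def stratified_split(labels: np.ndarray, train_fraction: float, seed: int) -> SplitSpec:
    """Deterministic stratified split preserving class proportions.

    Each class contributes round(train_fraction * class size) training samples
    within 1 (floor with largest-remainder correction so the global fraction
    is met exactly).
    """
    labels = np.asarray(labels, dtype=object)
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must be in (0, 1)")
    classes = sorted(set(labels), key=str)
    if len(classes) < 2:
        raise ValidationError("both classes must be present to stratify")
    sizes = [int(np.sum(labels == c)) for c in classes]
    if min(sizes) < 2:
        raise ValidationError("each class needs at least 2 samples to stratify")
    n_train = _largest_remainder_counts(sizes, train_fraction)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c, n_tr in zip(classes, n_train):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        train.extend(perm[:n_tr])
        test.extend(perm[n_tr:])
    return SplitSpec(np.sort(train), np.sort(test), train_fraction, seed)


def clr_transform(comp: CompositionMatrix) -> ClrMatrix:
    """Centred log-ratio: ln(x_ij / g_i), g_i the geometric mean of row i.

    Rows sum to 0 by construction; the transform is applied per sample, so it
    never mixes information across rows, and it is invariant to per-row
    rescaling (the closure constant drops out).
    """
    x = np.asarray(comp.values, dtype=float)
    if np.any(x <= 0):
        raise ValidationError(
            "CLR requires strictly positive entries; apply a pseudocount first"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(clr, list(comp.sample_ids), list(comp.feature_ids))


def clr_inverse(clr: ClrMatrix) -> CompositionMatrix:
    """Exponentiate and close each row back onto the unit simplex."""
    expd = np.exp(np.asarray(clr.values, dtype=float))
    return CompositionMatrix(expd / expd.sum(axis=1, keepdims=True),
                             list(clr.sample_ids), list(clr.feature_ids))
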