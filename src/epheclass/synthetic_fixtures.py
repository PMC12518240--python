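"""Synthetic 16S-like count tables with known discriminative structure.

Real amplicon tables are sparse non-negative integer matrices with strongly
heavy-tailed rank-abundance curves, heterogeneous library sizes and class
imbalance. The generator emulates those traits with a log-normal base
composition (sigma controls the tail), a per-class log-fold shift planted on
a known set of informative features, per-sample log-normal noise, structural
zeros imposed by class-independent Bernoulli thinning, and multinomial count
draws at a uniformly random library size. The planted feature ids are
returned, so recovery by the feature-selection stage is directly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abundance_io import NEGATIVE_LABEL, POSITIVE_LABEL, AbundanceTable
from .errors import ValidationError


@dataclass
class SyntheticConfig:
    """Generator settings.

    effect
        Total log-fold shift (natural log) between classes at informative
        features: class D compositions are multiplied by exp(+effect/2) and
        NotD by exp(-effect/2) at those features, before closure.
    imbalance
        Minority-class (D) fraction of samples.
    sparsity
        Probability that a (sample, feature) proportion is structurally
        zeroed before counts are drawn; independent of class.
    sigma_base / sigma_sample
        Log-normal spread of the shared base composition (heavy right tail)
        and of the per-sample perturbation.
    """

    n_samples: int = 300
    n_features: int = 200
    n_informative: int = 10
    effect: float = 2.0
    imbalance: float = 0.5
    library_size_range: tuple[int, int] = (5000, 50000)
    sparsity: float = 0.3
    strata: dict[str, float] | None = None
    seed: int = 0
    sigma_base: float = 1.5
    sigma_sample: float = 1.0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if self.n_informative > self.n_features:
            raise ValidationError("n_informative cannot exceed n_features")
        if not 0 < self.imbalance <= 1:
            raise ValidationError("imbalance must be in (0, 1]")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValidationError("library sizes must be >= 1 and ordered")
        if not 0 <= self.sparsity < 1:
            raise ValidationError("sparsity must be in [0, 1)")


def generate(config: SyntheticConfig) -> tuple[AbundanceTable, list[str]]:
    """Draw a labelled count table; returns (table, informative feature ids)."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    base_log = rng.normal(0.0, config.sigma_base, p)
    informative = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    shift = np.zeros(p)
    shift[informative] = config.effect / 2.0

    n_pos = int(round(config.imbalance * n)) if config.imbalance < 1 else n
    n_pos = min(max(n_pos, 1), n)
    labels = np.array([POSITIVE_LABEL] * n_pos + [NEGATIVE_LABEL] * (n - n_pos),
                      dtype=object)
    labels = labels[rng.permutation(n)]

    stratum = None
    if config.strata:
        names = sorted(config.strata)
        probs = np.array([config.strata[s] for s in names], dtype=float)
        probs = probs / probs.sum()
        stratum = np.asarray(rng.choice(names, size=n, p=probs), dtype=object)

    counts = np.zeros((n, p), dtype=np.int64)
    lo, hi = config.library_size_range
    for i in range(n):
        sign = 1.0 if labels[i] == POSITIVE_LABEL else -1.0
        logits = base_log + sign * shift + rng.normal(0.0, config.sigma_sample, p)
        props = np.exp(logits - logits.max())
        if config.sparsity > 0:
            zero = rng.random(p) < config.sparsity
            if zero.all():  # never zero out a whole sample
                zero[rng.integers(p)] = False
            props = np.where(zero, 0.0, props)
        props = props / props.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[i] = rng.multinomial(depth, props)

    table = AbundanceTable(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        feature_ids=[f"ASV{j:04d}" for j in range(p)],
        counts=counts,
        labels=labels,
        stratum=stratum,
    )
    return table, [table.feature_ids[j] for j in informative]


PRESETS: dict[str, SyntheticConfig] = {
    # strongly imbalanced two-site cohort with a clear planted signal
    "pd_like": SyntheticConfig(
        n_samples=240, n_features=150, n_informative=10, effect=3.0,
        imbalance=0.3, library_size_range=(3000, 30000), sparsity=0.3,
        strata={"supragingival": 0.5, "subgingival": 0.5}, seed=0,
    ),
    # larger, moderately imbalanced single-site cohort, weaker effect
    "ibd_like": SyntheticConfig(
        n_samples=400, n_features=300, n_informative=15, effect=2.0,
        imbalance=0.25, library_size_range=(5000, 50000), sparsity=0.4, seed=0,
    ),
    # label-free null: no planted effect at all; sized so a 30% test split
    # estimates a null AUC with binormal sd ~0.04
    "null": SyntheticConfig(
        n_samples=600, n_features=100, n_informative=0, effect=0.0,
        imbalance=0.5, library_size_range=(3000, 30000), sparsity=0.3, seed=0,
    ),
    # strong, balanced signal for end-to-end smoke runs
    "strong_signal": SyntheticConfig(
        n_samples=200, n_features=100, n_informative=10, effect=4.0,
        imbalance=0.5, library_size_range=(3000, 30000), sparsity=0.3, seed=0,
    ),
}


def preset(name: str, seed: int | None = None, **overrides) -> SyntheticConfig:
    """A named preset configuration, optionally re-seeded / tweaked."""
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[name]
    kwargs = {**cfg.__dict__, **overrides}
    if seed is not None:
        kwargs["seed"] = seed
    return SyntheticConfig(**kwargs)


# ---------------------------------------------------------------------------
# adversarial edge-case fixtures
# ---------------------------------------------------------------------------

def make_edge_fixtures(seed: int = 0) -> dict[str, AbundanceTable]:
    """Small constructed tables exercising documented edge branches.

    * ``boundary_depth``: row totals straddle the 2,500-count threshold,
      including one row at exactly 2,500 (which must be retained).
    * ``rank_tie``: two features tie exactly at the top-k cut rank, so the
      documented lower-feature-id tie-break decides.
    * ``single_class_stratum``: one stratum contains only one class, so
      per-stratum balancing has nothing to synthesize from.
    * ``consensus_skip``: features built so the three RFE estimators disagree
      about the 7th feature (one non-linear feature invisible to the linear
      models), making a 7-feature consensus unattainable; see
      tests for the deterministic trigger.
    """
    rng = np.random.default_rng(seed)
    fixtures: dict[str, AbundanceTable] = {}

    totals = [2499, 2500, 2501, 7000, 100]
    counts = np.zeros((len(totals), 4), dtype=np.int64)
    for i, t in enumerate(totals):
        row = rng.multinomial(t, [0.4, 0.3, 0.2, 0.1])
        counts[i] = row
    fixtures["boundary_depth"] = AbundanceTable(
        [f"B{i}" for i in range(len(totals))], [f"F{j}" for j in range(4)], counts
    )

    # features 0 and 1 have identical totals per sample -> identical mean
    # relative frequency; feature 2 clearly larger, feature 3 clearly smaller
    tie = np.array([[10, 10, 40, 1], [20, 20, 60, 2], [30, 30, 80, 3]])
    fixtures["rank_tie"] = AbundanceTable(
        ["T0", "T1", "T2"], ["F0", "F1", "F2", "F3"], tie
    )

    n = 12
    counts = rng.integers(1, 50, size=(n, 5))
    fixtures["single_class_stratum"] = AbundanceTable(
        [f"U{i}" for i in range(n)], [f"F{j}" for j in range(5)], counts,
        labels=np.array([POSITIVE_LABEL] * 6 + [NEGATIVE_LABEL] * 6, dtype=object),
        stratum=np.array(["siteA"] * 6 + ["siteB"] * 6, dtype=object),
    )

    fixtures["consensus_skip"] = consensus_skip_table(seed)
    return fixtures


def consensus_skip_table(seed: int = 0, n: int = 200) -> AbundanceTable:
    """A table where no RFE target yields a 7-feature three-way consensus.

    Eight features carry signal: six strong linear effects every estimator
    ranks highly, one weak linear effect, and one purely non-linear effect
    (class-dependent spread with equal means) that tree importance ranks above
    the weak linear feature while linear-model coefficients rank it last.
    At a shared target of 7 the per-estimator sets therefore intersect in 6
    features, and at 8 (= all features) in 8 — skipping 7.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    y = np.array([POSITIVE_LABEL] * half + [NEGATIVE_LABEL] * (n - half),
                 dtype=object)
    sign = np.where(y == POSITIVE_LABEL, 1.0, -1.0)
    cols = []
    for _ in range(6):  # strong linear
        cols.append(sign * 3.0 + rng.normal(0, 1, n))
    cols.append(sign * 0.5 + rng.normal(0, 1, n))  # weak linear
    spread = np.where(sign > 0, 5.0, 0.2)  # non-linear: variance signal only
    cols.append(rng.normal(0, 1, n) * spread)
    z = np.column_stack(cols)
    counts = np.round(np.exp((z - z.min()) / 2) * 50).astype(np.int64)
    return AbundanceTable(
        [f"C{i}" for i in range(n)], [f"F{j}" for j in range(8)], counts,
        labels=y,
    )
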