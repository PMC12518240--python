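"""End-to-end orchestration: counts in, tuned dynamic ensembles and reports out.

The run order follows the two-module design: sample filtering, pseudocount +
closure, top-k abundance cut, stratified 70/30 split, optional per-stratum
rebalancing of the training data, CLR, per-NSF consensus feature selection,
grid tuning, cross-validated evaluation, final training with a DSEL carve-out
and test-set evaluation. Every random draw derives from the config seeds (the
per-NSF seed is a fixed function of the master seed and the NSF), so reruns
with the same config are bit-identical.

The test split is created once and guarded: training-only stages assert that
no test row ever reaches them, and an optional :class:`StageAudit` records
the sample ids each stage consumed so the guarantee is externally checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance_io import AbundanceTable
from .des_ensembles import RULES, DESEnsemble, tune_k
from .errors import ConsensusUnattainableError, ValidationError
from .evaluation import (METRIC_NAMES, _clr_reduce, _rebalance,
                         _scores_to_metrics, cv_evaluate, report,
                         venkatraman_unpaired)
from .feature_selection import ConsensusSelection, consensus_select
from .model_pool import (ClassifierSpec, FAMILIES, ModelPool, TunedModel,
                         _base_estimator, _encode_labels, default_grids,
                         grid_tune, small_grids)
from .preprocessing import (CompositionMatrix, PreprocessConfig, clr_transform,
                            filter_samples, stratified_split,
                            top_abundant_features, to_relative)

logger = logging.getLogger("epheclass")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; see docs/methods.md for rationale."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    nsf_list: list[int] = field(default_factory=lambda: list(range(2, 16)))
    imbalance_strategy: str = "none"  # augment | none | downsample
    p_mask: float = 0.5
    fs_step: float | int = 0.05
    t_max: int | None = None
    grids: dict[str, dict] | None = None  # None -> default_grids()
    families: tuple[str, ...] = FAMILIES
    tune_folds: int = 10
    cv_folds: int = 10
    dsel_fraction: float = 0.1
    des_rules: tuple[str, ...] = RULES
    des_k: int = 7
    tune_k_grid: list[int] | None = None  # None -> keep des_k fixed
    topk_on_train_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.nsf_list:
            raise ValidationError("nsf_list must be non-empty")
        if sorted(set(self.nsf_list)) != list(self.nsf_list):
            raise ValidationError("nsf_list must be strictly increasing")
        if any(n < 1 for n in self.nsf_list):
            raise ValidationError("nsf values must be positive")
        if self.imbalance_strategy not in ("augment", "none", "downsample"):
            raise ValidationError(
                f"unknown imbalance strategy {self.imbalance_strategy!r}"
            )
        unknown = set(self.des_rules) - set(RULES)
        if unknown:
            raise ValidationError(f"unknown DES rules {sorted(unknown)}")

    def nsf_seed(self, nsf: int) -> int:
        """Per-NSF seed: stable function of (master seed, nsf), < 2^31."""
        return (self.seed * 10007 + nsf * 101 + 1) % (2**31 - 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        d["des_rules"] = list(self.des_rules)
        return d


class StageAudit:
    """Records which original sample ids each pipeline stage consumed."""

    def __init__(self) -> None:
        self.stages: dict[str, set[str]] = defaultdict(set)

    def record(self, stage: str, sample_ids) -> None:
        self.stages[stage].update(str(s) for s in sample_ids)


@dataclass
class RunResult:
    """Metrics, per-NSF consensus selections, test scores and the manifest."""

    metrics: pd.DataFrame
    selections: dict[int, ConsensusSelection]
    test_scores: pd.DataFrame
    manifest: dict
    skipped_nsf: list[int] = field(default_factory=list)


def _manifest_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run(config: RunConfig, table: AbundanceTable,
        out_dir: str | Path | None = None,
        audit: StageAudit | None = None) -> RunResult:
    """Execute the full pipeline on a labelled count table."""
    if table.labels is None:
        raise ValidationError("run() needs a labelled table")
    pp = config.preprocess

    table = filter_samples(table, pp.min_total_counts)
    comp = to_relative(table, pp.pseudocount)
    y_all = table.labels
    strat_all = table.stratum

    split = stratified_split(y_all, pp.train_fraction, pp.seed)
    train_idx, test_idx = split.train_idx, split.test_idx
    test_ids = {table.sample_ids[i] for i in test_idx}

    k_top = min(pp.top_k_features, comp.values.shape[1])
    if config.topk_on_train_only:
        ranking_basis = CompositionMatrix(
            comp.values[train_idx], [comp.sample_ids[i] for i in train_idx],
            list(comp.feature_ids))
        kept = top_abundant_features(ranking_basis, k_top).feature_ids
        keep_idx = [comp.feature_ids.index(f) for f in kept]
        comp = CompositionMatrix(comp.values[:, keep_idx],
                                 list(comp.sample_ids), kept)
    else:
        comp = top_abundant_features(comp, k_top)

    train_ids = [comp.sample_ids[i] for i in train_idx]
    comp_train = comp.values[train_idx]
    y_train = y_all[train_idx]
    strat_train = None if strat_all is None else strat_all[train_idx]
    comp_test = comp.values[test_idx]
    y_test = y_all[test_idx]

    def _guard(stage: str, ids) -> None:
        leaked = set(map(str, ids)) & test_ids
        if leaked:
            raise ValidationError(f"test samples leaked into {stage}: {sorted(leaked)[:5]}")
        if audit is not None:
            audit.record(stage, ids)

    metrics_rows: list[dict] = []
    score_rows: list[dict] = []
    selections: dict[int, ConsensusSelection] = {}
    skipped: list[int] = []
    grids = config.grids if config.grids is not None else default_grids()
    nsf_log: dict[int, dict] = {}

    for nsf in config.nsf_list:
        nsf_seed = config.nsf_seed(nsf)
        _guard("augmentation", train_ids)
        aug_values, aug_y, aug_strat = _rebalance(
            comp_train, y_train, strat_train, config.imbalance_strategy,
            config.p_mask, seed=nsf_seed,
        )
        X_aug = clr_transform(CompositionMatrix(aug_values)).values

        _guard("feature_selection", train_ids)
        try:
            sel = consensus_select(X_aug, aug_y, nsf, t_max=config.t_max,
                                   step=config.fs_step, seed=nsf_seed)
        except ConsensusUnattainableError as exc:
            logger.warning("nsf=%d unattainable, skipping: %s", nsf, exc)
            skipped.append(nsf)
            nsf_log[nsf] = {"status": "unattainable", "trace": exc.trace}
            continue
        sel.feature_ids = [comp.feature_ids[j] for j in sel.consensus]
        selections[nsf] = sel
        feat = np.asarray(sel.consensus)

        _guard("tuning", train_ids)
        y_enc = _encode_labels(aug_y)
        tune_folds = min(config.tune_folds, int(np.bincount(y_enc).min()))
        tuned = [
            grid_tune(ClassifierSpec(f, grids[f], seed=nsf_seed),
                      X_aug[:, feat], aug_y, folds=tune_folds, seed=nsf_seed)
            for f in config.families
        ]

        cv = cv_evaluate(comp_train, y_train, tuned, feature_idx=feat,
                         stratum=strat_train, folds=config.cv_folds,
                         seed=nsf_seed,
                         imbalance_strategy=config.imbalance_strategy,
                         p_mask=config.p_mask, des_rules=config.des_rules,
                         k=config.des_k)
        for row in cv.to_dict("records"):
            metrics_rows.append({"nsf": nsf, "split": "cv", **row})

        # final training: DSEL carved from un-augmented training rows, the
        # remainder rebalanced and used to refit the tuned models
        dsel_split = stratified_split(y_train, 1.0 - config.dsel_fraction,
                                      nsf_seed)
        fit_rows, dsel_rows = dsel_split.train_idx, dsel_split.test_idx
        _guard("dsel", [train_ids[i] for i in dsel_rows])
        fit_values, fit_y, fit_strat = _rebalance(
            comp_train[fit_rows], y_train[fit_rows],
            None if strat_train is None else strat_train[fit_rows],
            config.imbalance_strategy, config.p_mask, seed=nsf_seed + 1,
        )
        X_fit = _clr_reduce(fit_values, feat)
        X_dsel = _clr_reduce(comp_train[dsel_rows], feat)
        X_test = _clr_reduce(comp_test, feat)
        final_models = []
        for m in tuned:
            from sklearn.base import clone
            est = clone(_base_estimator(m.family, m.seed))
            est.set_params(**m.chosen_params)
            est.fit(X_fit, _encode_labels(fit_y))
            final_models.append(TunedModel(m.family, dict(m.chosen_params),
                                           m.cv_auc_mean, est, m.seed))
        pool = ModelPool(final_models, X_dsel, _encode_labels(y_train[dsel_rows]))

        y_test_enc = _encode_labels(y_test)
        for m in final_models:
            s = m.predict_proba_positive(X_test)
            metrics_rows.append({
                "nsf": nsf, "split": "test", "model": m.family,
                **_scores_to_metrics(y_test_enc, s, (s >= 0.5).astype(int)),
            })
            score_rows.extend(
                {"nsf": nsf, "model": m.family,
                 "sample_id": comp.sample_ids[test_idx[i]],
                 "label": int(y_test_enc[i]), "score": float(s[i])}
                for i in range(len(test_idx))
            )
        for rule in config.des_rules:
            k = config.des_k
            if config.tune_k_grid:
                k = tune_k(pool, rule, config.tune_k_grid, seed=nsf_seed)
            ens = DESEnsemble(pool, rule, k=k, seed=nsf_seed)
            s = ens.predict_proba(X_test)
            hard = ens.predict(X_test)
            name = f"des_{rule}"
            metrics_rows.append({
                "nsf": nsf, "split": "test", "model": name,
                **_scores_to_metrics(y_test_enc, s, hard),
            })
            score_rows.extend(
                {"nsf": nsf, "model": name,
                 "sample_id": comp.sample_ids[test_idx[i]],
                 "label": int(y_test_enc[i]), "score": float(s[i])}
                for i in range(len(test_idx))
            )
        nsf_log[nsf] = {
            "status": "ok", "target_t": sel.target_t,
            "trace": sel.search_trace,
            "consensus_features": sel.feature_ids,
            "tuned_params": {m.family: m.chosen_params for m in tuned},
        }

    if not metrics_rows:
        raise ValidationError(
            f"no NSF in {config.nsf_list} was attainable; nothing to report"
        )
    metrics = pd.DataFrame(metrics_rows)
    cols = ["model", "nsf", "split", *METRIC_NAMES]
    metrics = metrics[cols]
    test_scores = pd.DataFrame(score_rows)

    manifest = {
        "config": config.to_dict(),
        "config_hash": _manifest_hash(config),
        "n_samples": table.n_samples,
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
        "n_features_after_topk": comp.values.shape[1],
        "nsf_log": nsf_log,
        "skipped_nsf": skipped,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report(metrics, config.nsf_list, out_dir)
        test_scores.to_csv(out_dir / "test_scores.tsv", sep="\t", index=False,
                           float_format="%.6f")
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return RunResult(metrics, selections, test_scores, manifest, skipped)


def compare_partitions(config: RunConfig, table: AbundanceTable,
                       partition_seeds: list[int],
                       reference_model: str = "des_desp",
                       n_permutations: int = 999) -> dict:
    """Re-run the pipeline under several split seeds and compare test ROCs.

    Returns per-seed averaged metrics and, for the reference model at each
    NSF, unpaired permutation p-values between every pair of partitions
    (different partitions have different test samples, hence unpaired).
    """
    if len(partition_seeds) < 2:
        raise ValidationError("compare_partitions needs at least 2 seeds")
    results: dict[int, RunResult] = {}
    for s in partition_seeds:
        cfg = dataclasses.replace(
            config,
            preprocess=dataclasses.replace(config.preprocess, seed=s),
        )
        results[s] = run(cfg, table)
    per_seed = {
        s: r.metrics[r.metrics["split"] == "test"]
        .groupby("model", as_index=False)[list(METRIC_NAMES)].mean()
        for s, r in results.items()
    }
    comparisons = []
    seeds = list(partition_seeds)
    for i, s1 in enumerate(seeds):
        for s2 in seeds[i + 1:]:
            t1, t2 = results[s1].test_scores, results[s2].test_scores
            for nsf in sorted(set(t1["nsf"]) & set(t2["nsf"])):
                a = t1[(t1["model"] == reference_model) & (t1["nsf"] == nsf)]
                b = t2[(t2["model"] == reference_model) & (t2["nsf"] == nsf)]
                cmp = venkatraman_unpaired(
                    a["score"].to_numpy(), a["label"].to_numpy(),
                    b["score"].to_numpy(), b["label"].to_numpy(),
                    n_permutations=n_permutations, seed=min(s1, s2),
                )
                comparisons.append({"seed_a": s1, "seed_b": s2, "nsf": nsf,
                                    "statistic": cmp.statistic,
                                    "p_value": cmp.p_value})
    return {"per_seed_metrics": per_seed, "results": results,
            "comparisons": pd.DataFrame(comparisons)}


def compare_imbalance_strategies(config: RunConfig, table: AbundanceTable,
                                 reference_model: str = "des_desp",
                                 n_permutations: int = 999) -> dict:
    """Run augment / none / downsample on the same split and compare ROCs."""
    if table.labels is None:
        raise ValidationError("needs a labelled table")
    counts = np.bincount(_encode_labels(table.labels))
    strategies = ["augment", "none", "downsample"]
    if counts.size == 2 and counts[0] == counts[1]:
        logger.warning("classes already balanced; running 'none' only")
        strategies = ["none"]
    results: dict[str, RunResult] = {}
    for strategy in strategies:
        cfg = dataclasses.replace(config, imbalance_strategy=strategy)
        results[strategy] = run(cfg, table)
    comparisons = []
    for i, sa in enumerate(strategies):
        for sb in strategies[i + 1:]:
            ta, tb = results[sa].test_scores, results[sb].test_scores
            for nsf in sorted(set(ta["nsf"]) & set(tb["nsf"])):
                a = ta[(ta["model"] == reference_model) & (ta["nsf"] == nsf)]
                b = tb[(tb["model"] == reference_model) & (tb["nsf"] == nsf)]
                cmp = venkatraman_unpaired(
                    a["score"].to_numpy(), a["label"].to_numpy(),
                    b["score"].to_numpy(), b["label"].to_numpy(),
                    n_permutations=n_permutations, seed=config.seed,
                )
                comparisons.append({"strategy_a": sa, "strategy_b": sb,
                                    "nsf": nsf, "statistic": cmp.statistic,
                                    "p_value": cmp.p_value})
    summary = {
        s: r.metrics[r.metrics["split"] == "test"]
        .groupby("model", as_index=False)[list(METRIC_NAMES)].mean()
        for s, r in results.items()
    }
    return {"per_strategy_metrics": summary, "results": results,
            "comparisons": pd.DataFrame(comparisons)}
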