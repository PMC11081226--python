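"""Experiment protocol runner.

Mirrors the standard evaluation protocol for feature-selection methods on
small high-dimensional data: repeat R times (default 50) — fresh stratified
70/30 train/test split, run the configured pipeline stages
(impute -> filter -> select -> construct -> evaluate) on the training side,
score on the held-out side — then aggregate mean accuracy, maximum accuracy
and mean selected-feature count over the repeats.  Per-repeat seeds are
derived from a master seed via a counter and recorded, so a summary is fully
reproducible from its log.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from . import __version__
from .chi2_filter import rank_features, select as chi2_select
from .construction import GPConfig, construct_multi, augment_dataset
from .data import LabeledDataset, stratified_split
from .ga_knn import select_features
from .imputation import impute
from .knn import DEFAULT_K, DistanceSpec, evaluate_knn
from .mga import GAConfig

__all__ = ["ExperimentConfig", "ExperimentSummary", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Pipeline stages and repeat protocol.

    Stages are applied in the fixed order impute -> filter -> select ->
    construct -> evaluate; a stage is skipped when its switch is off.
    """

    repeats: int = 50
    train_fraction: float = 0.7
    master_seed: int = 0
    seeds: list[int] | None = None

    impute_missing: bool = True
    impute_k: int = DEFAULT_K

    filter_top_m: int | None = None
    filter_alpha: float | None = None

    select_scheme: str | None = None
    ga: GAConfig = field(default_factory=lambda: GAConfig(generations=40))

    construct_runs: int = 0
    gp: GPConfig = field(default_factory=lambda: GPConfig(
        population_size=200, generations=20))

    knn_k: int = DEFAULT_K

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.filter_top_m is not None and self.filter_alpha is not None:
            raise ValueError("give at most one of filter_top_m / filter_alpha")

    def repeat_seeds(self) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) < self.repeats:
                raise ValueError("seed list shorter than repeats")
            return [int(s) for s in self.seeds[: self.repeats]]
        # counter-derived, kept well below 2**31
        return [(self.master_seed * 10_007 + r) % (2 ** 31 - 1)
                for r in range(self.repeats)]


@dataclass
class ExperimentSummary:
    mean_accuracy: float
    max_accuracy: float
    mean_feature_count: float
    completed: int
    failed: int
    rows: list[dict[str, Any]]
    log: dict[str, Any]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "mean_accuracy": self.mean_accuracy,
                "max_accuracy": self.max_accuracy,
                "mean_feature_count": self.mean_feature_count,
                "completed": self.completed,
                "failed": self.failed,
                "rows": self.rows,
                "log": self.log,
            }, fh, indent=2)


def _one_repeat(cfg: ExperimentConfig, ds: LabeledDataset, seed: int
                ) -> dict[str, Any]:
    train, test = stratified_split(ds, cfg.train_fraction, seed=seed)

    if cfg.filter_top_m is not None or cfg.filter_alpha is not None:
        ranked = rank_features(train)
        keep = chi2_select(ranked, top_m=cfg.filter_top_m, alpha=cfg.filter_alpha)
        if keep:
            train = train.take_features(keep)
            test = test.take_features(keep)

    weights = None
    if cfg.select_scheme is not None:
        result = select_features(train, scheme=cfg.select_scheme,
                                 ga_cfg=cfg.ga, k=cfg.knn_k, seed=seed)
        if result.selected:
            sel = sorted(result.selected)
            weights = result.best_chromosome.weights[sel]
            train = train.take_features(sel)
            test = test.take_features(sel)

    if cfg.construct_runs > 0:
        gp = GPConfig(**{**asdict(cfg.gp), "runs": cfg.construct_runs,
                         "seed": seed})
        tr_in, val_in = stratified_split(train, cfg.train_fraction, seed=seed)
        trees = construct_multi(tr_in, val_in, range(train.n_features), gp,
                                k=cfg.knn_k)
        train, test = augment_dataset(train, test, trees)
        weights = None  # constructed columns carry no wrapper weights

    spec = (DistanceSpec(kind="minkowski", p=2.0, weights=weights)
            if weights is not None and np.any(weights > 0)
            else DistanceSpec(kind="minkowski", p=2.0))
    acc = evaluate_knn(train, test, cfg.knn_k, spec)
    return {"seed": seed, "accuracy": acc, "n_features_used": train.n_features,
            "status": "ok"}


def run_experiment(cfg: ExperimentConfig, ds: LabeledDataset
                   ) -> ExperimentSummary:
    """Run the repeated-split protocol and aggregate the repeat metrics.

    A failing repeat is logged and excluded from the aggregates; the summary
    reports how many repeats completed.
    """
    ds.require_classification()
    if cfg.impute_missing and ds.has_missing:
        ds = impute(ds, k=cfg.impute_k)

    rows: list[dict[str, Any]] = []
    for r, seed in enumerate(cfg.repeat_seeds()):
        try:
            row = _one_repeat(cfg, ds, seed)
        except Exception as exc:  # noqa: BLE001 - stage failure marks the repeat
            row = {"seed": seed, "accuracy": None, "n_features_used": None,
                   "status": f"failed: {exc}"}
        row["repeat"] = r
        rows.append(row)

    ok = [r for r in rows if r["status"] == "ok"]
    if not ok:
        raise RuntimeError("every repeat failed")
    accs = [r["accuracy"] for r in ok]
    counts = [r["n_features_used"] for r in ok]
    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seeds": [r["seed"] for r in rows],
        "config": {
            "repeats": cfg.repeats,
            "train_fraction": cfg.train_fraction,
            "master_seed": cfg.master_seed,
            "impute_missing": cfg.impute_missing,
            "impute_k": cfg.impute_k,
            "filter_top_m": cfg.filter_top_m,
            "filter_alpha": cfg.filter_alpha,
            "select_scheme": cfg.select_scheme,
            "ga": asdict(cfg.ga),
            "construct_runs": cfg.construct_runs,
            "gp": asdict(cfg.gp),
            "knn_k": cfg.knn_k,
        },
    }
    return ExperimentSummary(
        mean_accuracy=float(np.mean(accs)),
        max_accuracy=float(np.max(accs)),
        mean_feature_count=float(np.mean(counts)),
        completed=len(ok),
        failed=len(rows) - len(ok),
        rows=rows,
        log=log,
    )
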