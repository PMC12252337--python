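"""Cross-dataset evaluation scenarios and multi-seed experiments.

Three scenarios control which data trains a model evaluated on one held-out
user (the *target user*):

* ``single`` — leave-one-participant-out within each dataset;
* ``mixed`` — datasets pooled, leave-one-participant-out over the pool;
* ``multiple`` — leave-one-dataset-out: the target user's entire dataset is
  excluded from training.

Offline models (population, RG, BRG) are evaluated by hold-out on the
target user's chronologically ordered stream; online models (personalized,
PBRG) are evaluated prequentially on the same stream — the
prequential–leave-out protocol. Experiments repeat over random seeds and
aggregate to mean accuracy ± standard error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cbpm as _cbpm
from .models import (
    ClassifierSpec,
    LabelDistribution,
    SingleClassError,
    brg_predict,
    pbrg_run,
    prequential_personalized,
    rg_predict,
    train_population,
)
from .shift import EffectSize, cliffs_delta
from .types import META_COLUMNS, DatasetTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSplit",
    "EvalResult",
    "build_scenarios",
    "run_experiment",
    "compare_models",
    "MODEL_KINDS",
    "SCENARIOS",
]

SCENARIOS = ("single", "mixed", "multiple")
MODEL_KINDS = ("population", "personalized", "rg", "brg", "pbrg", "cbpm")


@dataclass
class ScenarioSplit:
    """One train set plus one held-out user's chronological test stream."""

    scenario: str
    train: pd.DataFrame
    test_user: str
    test_stream: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        train_keys = set(zip(self.train["dataset_id"], self.train["user_id"]))
        test_keys = set(zip(self.test_stream["dataset_id"], self.test_stream["user_id"]))
        if train_keys & test_keys:
            raise ValueError("test user leaks into the training set")
        order = self.test_stream["session_index"].to_numpy()
        if len(order) > 1 and np.any(np.diff(order) <= 0):
            raise ValueError("test stream is not chronologically ordered")

    def train_Xy(self, columns=None):
        cols = list(columns) if columns is not None else self.feature_names
        return (
            self.train[cols].to_numpy(dtype=float),
            self.train["label"].to_numpy(),
        )

    def stream_Xy(self, columns=None):
        cols = list(columns) if columns is not None else self.feature_names
        return (
            self.test_stream[cols].to_numpy(dtype=float),
            self.test_stream["label"].to_numpy(),
        )


def _user_key(dataset_id: str, user_id: str) -> str:
    return f"{dataset_id}:{user_id}"


def build_scenarios(
    datasets: list[DatasetTable], scenario: str
) -> list[ScenarioSplit]:
    """Construct every train/test-user split of the requested scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not datasets:
        raise ValueError("need at least one dataset")
    schema = datasets[0].feature_names
    for t in datasets[1:]:
        if t.feature_names != schema:
            raise ValueError("all datasets must share the feature schema")
    if scenario == "multiple" and len(datasets) < 2:
        raise ValueError("the multiple-dataset scenario needs at least 2 datasets")

    splits: list[ScenarioSplit] = []
    if scenario == "single":
        for table in datasets:
            for user in table.users:
                stream = table.user_stream(user)
                train = table.df[table.df["user_id"] != user]
                splits.append(
                    ScenarioSplit(scenario, train, _user_key(table.dataset_id, user),
                                  stream, schema)
                )
    elif scenario == "mixed":
        pool = pd.concat([t.df for t in datasets], ignore_index=True)
        keys = pool["dataset_id"].str.cat(pool["user_id"], sep=":")
        for key in sorted(keys.unique()):
            mask = keys == key
            stream = pool[mask].sort_values("session_index", kind="mergesort")
            splits.append(ScenarioSplit(scenario, pool[~mask], key, stream, schema))
    else:  # multiple
        for i, held_out in enumerate(datasets):
            others = pd.concat(
                [t.df for j, t in enumerate(datasets) if j != i], ignore_index=True
            )
            for user in held_out.users:
                stream = held_out.user_stream(user)
                splits.append(
                    ScenarioSplit(scenario, others,
                                  _user_key(held_out.dataset_id, user), stream, schema)
                )
    return splits


@dataclass
class EvalResult:
    """Per-(user, seed) accuracies of one model in one scenario."""

    model: str
    scenario: str
    modality: str
    records: pd.DataFrame  # columns: user, seed, accuracy
    excluded: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.records["accuracy"].mean())

    @property
    def standard_error(self) -> float:
        """Std of per-seed user-means divided by sqrt(#seeds)."""
        seed_means = self.records.groupby("seed")["accuracy"].mean()
        if len(seed_means) < 2:
            return 0.0
        return float(seed_means.std(ddof=1) / np.sqrt(len(seed_means)))

    def user_means(self) -> pd.Series:
        return self.records.groupby("user")["accuracy"].mean().sort_index()

    def summary(self) -> dict:
        return {
            "model": self.model,
            "scenario": self.scenario,
            "modality": self.modality,
            "mean_accuracy": self.mean_accuracy,
            "standard_error": self.standard_error,
            "n_users": int(self.records["user"].nunique()),
            "n_seeds": int(self.records["seed"].nunique()),
            "excluded_splits": self.excluded,
        }


def _select_columns(feature_names: list[str], modality: str | None) -> list[str]:
    if modality in (None, "", "all"):
        return feature_names
    pref = f"{modality}."
    cols = [c for c in feature_names if c.startswith(pref)]
    if not cols:
        raise ValueError(f"no feature columns for modality {modality!r}")
    return cols


def run_experiment(
    datasets: list[DatasetTable],
    scenario: str,
    model_kind: str,
    spec: ClassifierSpec | None = None,
    seeds: int = 50,
    modality: str | None = None,
    base_seed: int = 0,
    cbpm_grids: tuple | None = None,
) -> EvalResult:
    """Evaluate one model kind over every split of a scenario, across seeds.

    Offline models predict the whole held-out stream at once; online models
    run prequentially over the same stream. Splits whose training set holds a
    single class are skipped, logged, and recorded in the result. The
    cluster-based population model tunes its clustering once per split (the
    structure does not depend on the classifier seed) and refits its
    per-cluster classifiers per seed.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    spec = spec or ClassifierSpec()
    splits = build_scenarios(datasets, scenario)
    columns = _select_columns(splits[0].feature_names, modality)

    cbpm_configs: dict[int, object] = {}
    records = []
    excluded: list[str] = []
    for split_idx, split in enumerate(splits):
        X_tr, y_tr = split.train_Xy(columns)
        X_te, y_te = split.stream_Xy(columns)
        if model_kind in ("population", "personalized", "cbpm") and len(
            np.unique(y_tr)
        ) < 2:
            logger.warning(
                "skipping split %s: single-class training set", split.test_user
            )
            excluded.append(split.test_user)
            continue
        if model_kind == "cbpm" and split_idx not in cbpm_configs:
            grids = cbpm_grids or (_cbpm.DEFAULT_MIN_CLUSTER_SIZES,
                                   _cbpm.DEFAULT_MIN_SAMPLES)
            try:
                cbpm_configs[split_idx] = _cbpm.tune_hdbscan(X_tr, *grids)
            except _cbpm.NoClusterStructureError:
                logger.warning(
                    "skipping split %s: no cluster structure in training set",
                    split.test_user,
                )
                excluded.append(split.test_user)
                continue
        for s in range(seeds):
            model_seed = int((base_seed * 100003 + s * 1009 + spec.seed) % (2**31 - 1))
            rng = np.random.default_rng(model_seed)
            if model_kind == "population":
                acc = float(
                    np.mean(train_population(X_tr, y_tr, spec, model_seed).predict(X_te)
                            == y_te)
                )
            elif model_kind == "personalized":
                res = prequential_personalized(
                    X_tr, y_tr, X_te, y_te, spec, model_seed,
                    stream_order=split.test_stream["session_index"].to_numpy(),
                )
                acc = res.accuracy if res.accuracy is not None else np.nan
            elif model_kind == "rg":
                acc = float(np.mean(rg_predict(len(y_te), rng) == y_te))
            elif model_kind == "brg":
                dist = LabelDistribution.from_labels(y_tr)
                acc = float(np.mean(brg_predict(dist, len(y_te), rng) == y_te))
            elif model_kind == "pbrg":
                dist = LabelDistribution.from_labels(y_tr)
                acc = float(np.mean(pbrg_run(dist, y_te, rng) == y_te))
            else:  # cbpm
                bank = _cbpm.fit_cbpm(
                    X_tr, y_tr, cbpm_configs[split_idx], spec, model_seed
                )
                acc = float(np.mean(_cbpm.cbpm_predict(bank, X_te) == y_te))
            records.append({"user": split.test_user, "seed": s, "accuracy": acc})
    if not records:
        raise ValueError("every split was excluded; no results")
    return EvalResult(
        model=model_kind,
        scenario=scenario,
        modality=modality or "all",
        records=pd.DataFrame(records),
        excluded=excluded,
    )


def compare_models(a: EvalResult, b: EvalResult) -> tuple[EffectSize, float]:
    """Cliff's delta and paired Wilcoxon p-value between two results.

    The effect size is computed over per-(user, seed) accuracy samples; the
    Wilcoxon test pairs user-level means (accuracy averaged over seeds).
    Both results must cover the same (user, seed) grid.
    """
    grid_a = set(zip(a.records["user"], a.records["seed"]))
    grid_b = set(zip(b.records["user"], b.records["seed"]))
    if grid_a != grid_b:
        raise ValueError("results cover different (user, seed) grids")
    effect = cliffs_delta(a.records["accuracy"], b.records["accuracy"])
    ua, ub = a.user_means(), b.user_means()
    diffs = ua - ub
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.wilcoxon(ua, ub).pvalue)
    return effect, p
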