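"""Covariate-shift diagnostics between two feature datasets.

Given two datasets of per-session feature vectors collected for the same
task, these tools quantify how far apart their marginal feature
distributions are:

* per-feature Spearman correlation profiles against the reported sleep
  quality, whose disagreement across datasets hints at shift;
* per-feature two-sample Kolmogorov–Smirnov tests with Bonferroni
  correction (``alpha_n = alpha / n`` over ``n`` features);
* the name-the-dataset (NED) task: a linear max-margin classifier trained to
  predict which dataset a feature vector came from, evaluated with balanced
  accuracy on user-disjoint splits — above-chance performance evidences a
  distribution mismatch;
* Cliff's delta effect sizes with Vargha–Delaney magnitude labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import DatasetTable

__all__ = [
    "EffectSize",
    "ShiftReport",
    "NedCurve",
    "bonferroni_alpha",
    "spearman_profile",
    "ks_feature_tests",
    "name_the_dataset",
    "balanced_accuracy",
    "cliffs_delta",
]

#: Vargha–Delaney magnitude thresholds on |delta|.
DELTA_THRESHOLDS = (0.147, 0.33, 0.474)


@dataclass(frozen=True)
class EffectSize:
    """Cliff's delta in [-1, 1] with its magnitude label."""

    delta: float
    magnitude: str


def _magnitude(delta: float) -> str:
    d = abs(delta)
    if d < DELTA_THRESHOLDS[0]:
        return "negligible"
    if d < DELTA_THRESHOLDS[1]:
        return "small"
    if d < DELTA_THRESHOLDS[2]:
        return "medium"
    return "large"


def cliffs_delta(xs, ys) -> EffectSize:
    """Cliff's delta: (#{x>y} − #{x<y}) / (|xs|·|ys|) over all cross-pairs."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    # Rank-based O((m+n) log(m+n)) formulation; exact, no pair enumeration.
    combined = np.concatenate([xs, ys])
    ranks = stats.rankdata(combined)
    rx = ranks[: xs.size]
    n_x, n_y = xs.size, ys.size
    # sum over x of (#y < x) - (#y > x), via midranks
    rank_within_x = stats.rankdata(xs)
    greater_minus_less = 2.0 * (np.sum(rx) - np.sum(rank_within_x)) - n_x * n_y
    delta = float(greater_minus_less / (n_x * n_y))
    return EffectSize(delta=delta, magnitude=_magnitude(delta))


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(y_true)
    if len(classes) < 2:
        warnings.warn(
            "only one class present in y_true; absent class excluded",
            stacklevel=2,
        )
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """The Bonferroni-corrected significance level alpha / n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def spearman_profile(table: DatasetTable, scores) -> pd.DataFrame:
    """Spearman rank correlation between each feature and the quality score.

    Returns a frame indexed by feature with columns ``rho`` and ``defined``;
    zero-variance features are flagged undefined (``rho`` is NaN) instead of
    returning a number.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != table.n_sessions:
        raise ValueError(
            f"need one score per session: {len(scores)} scores, "
            f"{table.n_sessions} sessions"
        )
    if table.n_sessions < 3:
        raise ValueError("need at least 3 sessions for a correlation profile")
    rows = []
    for name in table.feature_names:
        x = table.df[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(scores) == 0:
            rows.append({"rho": np.nan, "defined": False})
        else:
            rho, _ = stats.spearmanr(x, scores)
            rows.append({"rho": float(rho), "defined": True})
    return pd.DataFrame(rows, index=pd.Index(table.feature_names, name="feature"))


@dataclass
class ShiftReport:
    """Per-feature covariate-shift diagnostics between two datasets."""

    per_feature: pd.DataFrame
    alpha: float
    alpha_n: float
    n_tests: int

    @property
    def fraction_significant(self) -> float:
        return float(self.per_feature["significant"].mean())

    @property
    def fraction_significant_bonferroni(self) -> float:
        return float(self.per_feature["significant_bonferroni"].mean())

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_n": self.alpha_n,
            "n_tests": self.n_tests,
            "n_features": int(len(self.per_feature)),
            "fraction_significant": self.fraction_significant,
            "fraction_significant_bonferroni": self.fraction_significant_bonferroni,
        }

    def to_csv(self, path: str | Path) -> None:
        self.per_feature.to_csv(path)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def ks_feature_tests(
    table_a: DatasetTable,
    table_b: DatasetTable,
    alpha: float = 0.05,
    n_tests: int | None = None,
    scores_a=None,
    scores_b=None,
) -> ShiftReport:
    """Two-sided two-sample Kolmogorov–Smirnov test per feature.

    Features are flagged at the nominal level ``alpha`` and at the
    Bonferroni-corrected level ``alpha / n_tests`` (``n_tests`` defaults to
    the number of feature columns). If per-session quality ``scores`` are
    given for both sides, Spearman correlation profiles are attached.
    """
    if table_a.feature_names != table_b.feature_names:
        raise ValueError("feature schemas of the two tables differ")
    names = table_a.feature_names
    if n_tests is None:
        n_tests = len(names)
    alpha_n = bonferroni_alpha(alpha, n_tests)

    rows = []
    for name in names:
        xa = table_a.df[name].to_numpy(dtype=float)
        xb = table_b.df[name].to_numpy(dtype=float)
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"feature {name!r} has fewer than 2 finite values")
        res = stats.ks_2samp(xa, xb, method="asymp")
        rows.append(
            {
                "ks_stat": float(res.statistic),
                "p_value": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
                "significant_bonferroni": bool(res.pvalue < alpha_n),
            }
        )
    per_feature = pd.DataFrame(rows, index=pd.Index(names, name="feature"))
    if scores_a is not None and scores_b is not None:
        per_feature["rho_a"] = spearman_profile(table_a, scores_a)["rho"]
        per_feature["rho_b"] = spearman_profile(table_b, scores_b)["rho"]
    return ShiftReport(per_feature=per_feature, alpha=alpha, alpha_n=alpha_n,
                       n_tests=n_tests)


@dataclass
class NedCurve:
    """Name-the-dataset learning curve: balanced accuracy vs sample size."""

    sizes: list[int]
    accuracy_mean: list[float]
    accuracy_se: list[float]
    baseline_mean: list[float]
    baseline_se: list[float]
    p_value: float
    per_round: pd.DataFrame = field(repr=False)

    def summary(self) -> dict:
        return {
            "sizes": self.sizes,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_se": self.accuracy_se,
            "baseline_mean": self.baseline_mean,
            "baseline_se": self.baseline_se,
            "wilcoxon_p_value": self.p_value,
        }


def _user_disjoint_sample(
    table: DatasetTable, size: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample ``size`` sessions and split them train/test with disjoint users."""
    users = list(table.users)
    if len(users) < 2:
        raise ValueError(
            f"dataset {table.dataset_id!r} has a single user; "
            "user-disjoint split impossible"
        )
    if size > table.n_sessions:
        raise ValueError(
            f"requested {size} sessions from {table.dataset_id!r}, "
            f"only {table.n_sessions} available"
        )
    idx = rng.choice(table.n_sessions, size=size, replace=False)
    sample = table.df.iloc[np.sort(idx)]
    perm = rng.permutation(users)
    n_test = max(1, len(users) // 2)
    test_users = set(perm[:n_test])
    train = sample[~sample["user_id"].isin(test_users)]
    test = sample[sample["user_id"].isin(test_users)]
    return train, test


def name_the_dataset(
    table_a: DatasetTable,
    table_b: DatasetTable,
    sizes,
    rounds: int = 10,
    seed: int = 0,
) -> NedCurve:
    """The name-the-dataset (NED) task at increasing per-dataset sample sizes.

    For each size and round: sample that many sessions from each dataset,
    split users disjointly into train/test, fit a linear-kernel max-margin
    classifier (features standardized by training-set statistics) with the
    dataset identity as the label, and score balanced accuracy on the
    held-out users. A uniform random-guess baseline is scored on the same
    test sets; classifier and baseline accuracies are compared with a
    two-sided paired Wilcoxon test.
    """
    if table_a.feature_names != table_b.feature_names:
        raise ValueError("feature schemas of the two tables differ")
    sizes = sorted(int(s) for s in sizes)
    rng = np.random.default_rng(seed)
    feature_names = table_a.feature_names
    records = []
    for size in sizes:
        for r in range(rounds):
            frames_train, frames_test = [], []
            for table in (table_a, table_b):
                tr, te = _user_disjoint_sample(table, size, rng)
                frames_train.append(tr)
                frames_test.append(te)
            train = pd.concat(frames_train)
            test = pd.concat(frames_test)
            if train["dataset_id"].nunique() < 2 or test["dataset_id"].nunique() < 2:
                continue  # a side lost one dataset entirely; skip this round
            scaler = StandardScaler().fit(train[feature_names])
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(scaler.transform(train[feature_names]), train["dataset_id"])
            pred = clf.predict(scaler.transform(test[feature_names]))
            acc = balanced_accuracy(test["dataset_id"].to_numpy(), pred)
            guess = rng.choice(
                [table_a.dataset_id, table_b.dataset_id], size=len(test)
            )
            base = balanced_accuracy(test["dataset_id"].to_numpy(), guess)
            records.append(
                {"size": size, "round": r, "accuracy": acc, "baseline": base}
            )
    per_round = pd.DataFrame(records)
    if per_round.empty:
        raise ValueError("no valid rounds; check sizes and user counts")
    diffs = per_round["accuracy"] - per_round["baseline"]
    if np.allclose(diffs, 0):
        p_value = 1.0
    else:
        p_value = float(stats.wilcoxon(per_round["accuracy"],
                                       per_round["baseline"]).pvalue)
    grouped = per_round.groupby("size")
    sizes_out = [int(s) for s in grouped.groups]

    def _se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    return NedCurve(
        sizes=sizes_out,
        accuracy_mean=[float(g["accuracy"].mean()) for _, g in grouped],
        accuracy_se=[_se(g["accuracy"]) for _, g in grouped],
        baseline_mean=[float(g["baseline"].mean()) for _, g in grouped],
        baseline_se=[_se(g["baseline"]) for _, g in grouped],
        p_value=p_value,
        per_round=per_round,
    )
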