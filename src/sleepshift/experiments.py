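"""End-to-end study drivers on the synthetic paired datasets.

Each function generates its own data under stated conditions, runs the
relevant part of the toolkit, and returns the headline quantities. They are
what the acceptance machinery and the worked examples execute; all
randomness derives from the single ``seed`` argument.

Experiment sizing (cohorts of 8 users per dataset, 12–30 nights, a dozen
features, the linear passive-aggressive classifier, a handful of model seeds
per data replicate) is chosen so each study completes in seconds while the
planted effects remain clearly resolvable; replicates over independent data
draws average out the random alignment between the shift direction and the
label rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cbpm import tune_hdbscan
from .models import ClassifierSpec
from .scenarios import run_experiment
from .shift import cliffs_delta, ks_feature_tests, name_the_dataset
from .synthetic import SyntheticConfig, generate_feature_pair

__all__ = [
    "ned_experiment",
    "scenario_shift_experiment",
    "cbpm_experiment",
    "ks_calibration_experiment",
    "archetype_recovery_experiment",
]


def ned_experiment(
    seed: int = 0,
    sizes: tuple[int, ...] = (50, 100, 200),
    rounds: int = 6,
) -> dict:
    """Name-the-dataset on a null pair and on a strongly shifted pair.

    The null pair shares one generating distribution (chance-level balanced
    accuracy is expected); the shifted pair offsets 30 % of the features by
    two noise SDs, which a linear classifier should detect almost perfectly
    at 200 sessions per side.
    """
    null_cfg = SyntheticConfig(shift_delta=0.0, seed=seed)
    null_pair = generate_feature_pair(null_cfg)
    null_curve = name_the_dataset(*null_pair.tables, sizes=[max(sizes) // 2],
                                  rounds=rounds + 2, seed=seed + 1)
    shift_cfg = SyntheticConfig(shift_delta=2.0, shift_fraction=0.3, seed=seed)
    shift_pair = generate_feature_pair(shift_cfg)
    curve = name_the_dataset(*shift_pair.tables, sizes=list(sizes),
                             rounds=rounds, seed=seed + 1)
    return {
        "null_balanced_accuracy": null_curve.accuracy_mean[0],
        "shifted_balanced_accuracy": curve.accuracy_mean[-1],
        "curve_sizes": curve.sizes,
        "curve_means": curve.accuracy_mean,
        "wilcoxon_p": curve.p_value,
        "n_sessions_per_side": max(sizes),
    }


def _shift_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_users=(8, 8),
        sessions_per_user=30,
        n_features=12,
        n_archetypes=1,
        shift_delta=4.0,
        shift_fraction=0.5,
        user_effect_sd=0.3,
        label_noise=0.1,
        seed=seed,
    )


def scenario_shift_experiment(
    seed: int = 0, n_replicates: int = 12, model_seeds: int = 2
) -> dict:
    """Population vs personalized accuracy across evaluation scenarios.

    On each replicate (an independent shifted pair) both models are evaluated
    in the single-dataset and multiple-dataset scenarios. Reports the mean
    population-accuracy drop (percentage points) between scenarios, and the
    cross-scenario Cliff's delta of each model computed over the pooled
    per-(user, seed) accuracies of all replicates.
    """
    pools: dict[tuple[str, str], list[pd.DataFrame]] = {}
    drops = []
    for rep in range(n_replicates):
        rep_seed = int(seed + 7919 * rep) % (2**31 - 1)
        datasets = list(generate_feature_pair(_shift_config(rep_seed)).tables)
        spec = ClassifierSpec("passive-aggressive", seed=rep_seed)
        results = {}
        for model in ("population", "personalized"):
            for scenario in ("single", "multiple"):
                res = run_experiment(datasets, scenario, model, spec,
                                     seeds=model_seeds, base_seed=rep_seed)
                results[(model, scenario)] = res
                pools.setdefault((model, scenario), []).append(res.records)
        drops.append(
            results[("population", "single")].mean_accuracy
            - results[("population", "multiple")].mean_accuracy
        )
    pooled = {k: pd.concat(v, ignore_index=True)["accuracy"] for k, v in pools.items()}
    pop_delta = cliffs_delta(pooled[("population", "single")],
                             pooled[("population", "multiple")])
    per_delta = cliffs_delta(pooled[("personalized", "single")],
                             pooled[("personalized", "multiple")])
    return {
        "population_drop_points": 100.0 * float(np.mean(drops)),
        "population_cross_scenario_delta": pop_delta.delta,
        "population_delta_magnitude": pop_delta.magnitude,
        "personalized_cross_scenario_delta": per_delta.delta,
        "personalized_delta_magnitude": per_delta.magnitude,
        "n_replicates": n_replicates,
    }


def _archetype_config(seed: int, separation: float = 6.0) -> SyntheticConfig:
    return SyntheticConfig(
        n_users=(8, 8),
        sessions_per_user=12,
        n_features=8,
        n_archetypes=3,
        archetype_separation=separation,
        user_effect_sd=0.2,
        label_noise=0.05,
        seed=seed,
    )


def cbpm_experiment(
    seed: int = 0, n_replicates: int = 10, model_seeds: int = 2
) -> dict:
    """CBPM vs the global population model under planted session archetypes.

    Each replicate plants three well-separated archetypes carrying distinct
    (mutually orthogonal) label rules — a regime a single linear population
    model cannot represent but per-cluster models can. Both models are
    evaluated in the multiple-dataset scenario.
    """
    gains = []
    for rep in range(n_replicates):
        rep_seed = int(seed + 104729 * rep) % (2**31 - 1)
        datasets = list(generate_feature_pair(_archetype_config(rep_seed)).tables)
        spec = ClassifierSpec("passive-aggressive", seed=rep_seed)
        res_cbpm = run_experiment(datasets, "multiple", "cbpm", spec,
                                  seeds=model_seeds, base_seed=rep_seed)
        res_pop = run_experiment(datasets, "multiple", "population", spec,
                                 seeds=model_seeds, base_seed=rep_seed)
        gains.append(res_cbpm.mean_accuracy - res_pop.mean_accuracy)
    return {
        "cbpm_gain_points": 100.0 * float(np.mean(gains)),
        "per_replicate_gains": [100.0 * g for g in gains],
        "n_replicates": n_replicates,
    }


def archetype_recovery_experiment(seed: int = 0, n_seeds: int = 10) -> dict:
    """How often the tuned clusterer recovers the planted archetype count.

    Uses three archetypes at pairwise separation 5 (in noise-SD units); a
    recovery counts when the selected configuration finds K ± 1 clusters.
    """
    k_true = 3
    hits = 0
    found = []
    for i in range(n_seeds):
        cfg = _archetype_config(int(seed + 15485863 * i) % (2**31 - 1),
                                separation=5.0)
        pair = generate_feature_pair(cfg)
        try:
            config = tune_hdbscan(pair.table_a.features())
        except ValueError:
            found.append(0)
            continue
        found.append(config.n_clusters)
        if abs(config.n_clusters - k_true) <= 1:
            hits += 1
    return {"recovery_rate": hits / n_seeds, "clusters_found": found,
            "n_seeds": n_seeds}


def ks_calibration_experiment(seed: int = 0, n_features: int = 500) -> dict:
    """False-positive rate of the per-feature KS test with no planted shift.

    Sessions are i.i.d. (no user effects, one archetype) so the nominal level
    should be attained: the rejection rate at alpha = 0.05 should sit inside
    the binomial 99 % band around 0.05.
    """
    cfg = SyntheticConfig(
        n_users=(8, 8),
        sessions_per_user=15,
        n_features=n_features,
        n_archetypes=1,
        shift_delta=0.0,
        user_effect_sd=0.0,
        seed=seed,
    )
    pair = generate_feature_pair(cfg)
    report = ks_feature_tests(*pair.tables, alpha=0.05)
    return {
        "rejection_rate": report.fraction_significant,
        "rejection_rate_bonferroni": report.fraction_significant_bonferroni,
        "n_features": n_features,
    }
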