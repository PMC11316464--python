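"""Replicate-study calibration experiments on synthetic data.

The printed group allometry (slope 0.74 with four group intercepts) cannot
be re-derived without the original specimen compilation, so the package
validates itself the other way around: data are *generated* at exactly
those coefficients under the assumed residual and tree models, and the
estimators are required to recover them with correct frequentist behaviour
— CI coverage of the generating slope, type-I error of the elevation
contrasts at the nominal level, and calibrated imputation of withheld
fossil MMR values under the joint OU model.

Every experiment takes a seed and is deterministic given it; replicate
streams are spawned from a single SeedSequence.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg

from . import mvou, pgls
from .simulate import SimulationConfig, simulate_allometry, simulate_mvou_traits, simulate_tree

__all__ = [
    "slope_recovery_experiment",
    "ancova_type_i_experiment",
    "interaction_power_experiment",
    "imputation_experiment",
]


def _study_tree(config: SimulationConfig, rng: np.random.Generator):
    tree, meta = simulate_tree(config, rng)
    tree.shared_times()  # warm the kernel cache shared by all replicates
    return tree, meta["fossil_tips"]


def slope_recovery_experiment(
    n_reps: int = 100, seed: int = 0, config: SimulationConfig | None = None
) -> dict:
    """Does the PGLS 95% CI cover the generating slope?

    One study-design tree; ``n_reps`` independent trait tables generated at
    the configured slope/intercepts; each fitted with the common-slope
    group PGLS (corMartins alpha profiled).  Returns the coverage count and
    the mean fitted slope.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng_tree, *rng_reps = [np.random.default_rng(s) for s in ss.spawn(n_reps + 1)]
    tree, fossil = _study_tree(config, rng_tree)
    covered = 0
    slopes = []
    for rng in rng_reps:
        tab = simulate_allometry(tree, config, rng, fossil_tips=fossil)
        fit = pgls.pgls_fit(tree, tab, "log_qdot", "log_bm", group="group")
        b = float(fit.coef[fit.slope_col])
        se = float(np.sqrt(fit.vcov.loc[fit.slope_col, fit.slope_col]))
        if b - 1.96 * se <= config.slope <= b + 1.96 * se:
            covered += 1
        slopes.append(b)
    return {
        "n_reps": n_reps,
        "covered": covered,
        "coverage": covered / n_reps,
        "mean_slope": float(np.mean(slopes)),
        "true_slope": config.slope,
    }


def ancova_type_i_experiment(
    n_reps: int = 100,
    seed: int = 0,
    config: SimulationConfig | None = None,
    pair: tuple[str, str] = ("Epitheria", "Xenarthra"),
) -> dict:
    """Rejection rate of an elevation contrast when intercepts are equal.

    All group intercepts are set to a common value, so any significant
    contrast is a false positive; the raw (un-adjusted) p-value of the given
    pair is tested at the nominal 5% level.
    """
    config = config or SimulationConfig()
    equal = dataclasses.replace(
        config, intercepts={g: -5.5 for g in config.intercepts}
    )
    ss = np.random.SeedSequence(seed)
    rng_tree, *rng_reps = [np.random.default_rng(s) for s in ss.spawn(n_reps + 1)]
    tree, fossil = _study_tree(equal, rng_tree)
    rejections = 0
    for rng in rng_reps:
        tab = simulate_allometry(tree, equal, rng, fossil_tips=fossil)
        fit = pgls.pgls_fit(tree, tab, "log_qdot", "log_bm", group="group")
        contrasts = {
            frozenset((c.group_a, c.group_b)): c for c in pgls.pairwise_ancova(fit)
        }
        if contrasts[frozenset(pair)].p_raw < 0.05:
            rejections += 1
    return {
        "n_reps": n_reps,
        "rejections": rejections,
        "rate": rejections / n_reps,
        "nominal": 0.05,
    }


def interaction_power_experiment(
    n_reps: int = 50,
    seed: int = 0,
    delta_slope: float = 0.3,
    group: str = "Prototheria+Metatheria",
    config: SimulationConfig | None = None,
) -> dict:
    """Detection rate of a genuine slope difference of ``delta_slope``.

    With ``delta_slope=0`` this measures the false-positive rate of the
    interaction test instead.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng_tree, *rng_reps = [np.random.default_rng(s) for s in ss.spawn(n_reps + 1)]
    tree, fossil = _study_tree(config, rng_tree)
    detected = 0
    for rng in rng_reps:
        tab = simulate_allometry(tree, config, rng, fossil_tips=fossil)
        sel = tab["group"] == group
        tab.loc[sel, "log_qdot"] += delta_slope * tab.loc[sel, "log_bm"]
        fit_cs = pgls.pgls_fit(tree, tab, "log_qdot", "log_bm", group="group")
        fit_int = pgls.pgls_fit(
            tree, tab, "log_qdot", "log_bm", group="group", interaction=True
        )
        result = pgls.compare_models(fit_cs, fit_int)
        if result["interaction_p"] <= 0.05:
            detected += 1
    return {"n_reps": n_reps, "detected": detected, "rate": detected / n_reps}


def imputation_experiment(
    n_reps: int = 200,
    seed: int = 0,
    config: SimulationConfig | None = None,
    mode: str = "diagonal",
) -> dict:
    """Recovery of withheld fossil MMR under the fitted joint OU model.

    Per replicate: tip traits drawn exactly from the configured joint OU
    kernel on one study-design tree; MMR masked at the fossil tips; the
    model refitted from scratch; the masked entries imputed.  Reports the
    per-replicate R² of imputed vs withheld values (median across
    replicates) and the pooled empirical coverage of the 95% intervals.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng_tree, *rng_reps = [np.random.default_rng(s) for s in ss.spawn(n_reps + 1)]
    tree, fossil = _study_tree(config, rng_tree)
    r2s = []
    hits = 0
    total = 0
    for rng in rng_reps:
        traits = simulate_mvou_traits(
            tree, config.mvou_A, config.mvou_Sigma, config.mvou_theta, rng
        )
        masked = traits.copy()
        masked.loc[fossil, "log_mmr"] = np.nan
        fit = mvou.mvou_fit(tree, masked, mode=mode)
        est = mvou.estimate_missing(fit, tree, masked)
        miss = est[(est["trait"] == "log_mmr") & (~est["observed"])]
        truth = traits.loc[miss["node"], "log_mmr"].to_numpy()
        r2s.append(mvou.prediction_r2(miss["mean"], truth))
        inside = (truth >= miss["ci_low"].to_numpy()) & (
            truth <= miss["ci_high"].to_numpy()
        )
        hits += int(inside.sum())
        total += inside.size
    return {
        "n_reps": n_reps,
        "n_fossil": len(fossil),
        "median_r2": float(np.median(r2s)),
        "ci_coverage": hits / total,
    }
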