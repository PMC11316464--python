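"""One-call replication of the full analysis graph on an input bundle.

Stages, in order: aggregate specimens to taxon flow estimates; fit BM/OU/WN
to log10 Bm and log10 Q̇ and pick the PGLS correlation structure by Akaike
weight; common-slope vs interaction PGLS with AIC/BIC comparison; whitened-
residual normality; pairwise phylogenetic ANCOVA with Bonferroni adjustment
and flow ratios; multivariate OU vs BM on (log MMR, log Q̇, log Bm); missing
MMR imputation, ancestral states, leave-one-out R² and mass-independent
MMR.  All randomness (the Lilliefors Monte-Carlo null) consumes the given
seed; rerunning with the same inputs and seed reproduces the JSON report
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import evomodels, hemodynamics, mvou, pgls
from .tree import PhyloTree

__all__ = ["PipelineError", "PipelineReport", "run_pipeline", "load_bundle"]

SCHEMA_VERSION = "1"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, partial: "PipelineReport", cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial
        self.cause = cause


@dataclass
class PipelineReport:
    schema_version: str = SCHEMA_VERSION
    provenance: dict = field(default_factory=dict)
    flow_table: list = field(default_factory=list)
    model_selection: dict = field(default_factory=dict)
    correlation_structure: dict = field(default_factory=dict)
    group_equations: dict = field(default_factory=dict)
    model_comparison: dict = field(default_factory=dict)
    residual_normality: dict = field(default_factory=dict)
    contrasts: list = field(default_factory=list)
    mvou_model_comparison: dict = field(default_factory=dict)
    mmr_estimates: list = field(default_factory=list)
    ancestral_states: list = field(default_factory=list)
    prediction_r2: float | None = None
    stages_completed: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _round(x: float, nd: int = 10) -> float:
    return float(np.round(float(x), nd))


def load_bundle(directory) -> dict:
    """Read tree.nwk, taxa.csv and specimens.csv from a bundle directory."""
    d = Path(directory)
    return {
        "tree": PhyloTree.from_newick((d / "tree.nwk").read_text()),
        "taxa": pd.read_csv(d / "taxa.csv"),
        "specimens": hemodynamics.read_specimen_csv(d / "specimens.csv"),
    }


def run_pipeline(
    tree: PhyloTree,
    specimens: list[hemodynamics.SpecimenRecord],
    taxa: pd.DataFrame,
    seed: int = 0,
    index: str = "qdot",
    mvou_mode: str = "full",
    lilliefors_mc: int = 10_000,
    normalize_height: bool = False,
) -> PipelineReport:
    """Run the full analysis and return a structured report.

    ``taxa`` needs columns ``taxon, group, bm_g`` and optionally ``mmr``
    (total, mL O2 h^-1).  ``index="qi"`` replicates every stage on the
    legacy flow index instead of Q̇.
    """
    report = PipelineReport(
        provenance={
            "package": "foramenflow",
            "version": _version,
            "seed": int(seed),
            "index": index,
            "mvou_mode": mvou_mode,
            "normalize_height": bool(normalize_height),
            "n_tips": tree.n_tips,
            "n_extinct_tips": len(tree.extinct_tips()),
            "ultrametric": tree.is_ultrametric(),
        }
    )
    stage = "aggregate"
    try:
        flow = hemodynamics.aggregate_table(specimens)
        report.flow_table = [
            {k: (_round(v) if isinstance(v, float) else v) for k, v in row.items()}
            for row in flow.to_dict("records")
        ]
        tab = taxa.copy()
        tab["taxon"] = tab["taxon"].astype(str).str.strip()
        tab = tab.merge(flow, on="taxon", how="inner")
        tab["log_bm"] = np.log10(tab["bm_g"].astype(float))
        resp_col = "qdot_cm3_s" if index == "qdot" else "qi"
        tab["log_qdot"] = np.log10(tab[resp_col].astype(float))
        if "mmr" in tab.columns:
            tab["log_mmr"] = np.log10(tab["mmr"].astype(float))
        tab = tab.set_index("taxon")
        not_covered = sorted(set(tree.tip_labels) - set(tab.index))
        if not_covered:
            raise ValueError(
                f"tree tips without a usable taxon row: {not_covered}"
            )
        report.stages_completed.append(stage)

        stage = "model_selection"
        sel = {}
        for trait in ("log_bm", "log_qdot"):
            fits = evomodels.fit_all(tree, tab[trait])
            sel[trait] = {
                name: {
                    "lnL": _round(f.lnL),
                    "aic": _round(f.aic),
                    "aic_weight": _round(f.aic_weight),
                    "parameters": {k: _round(v) for k, v in f.parameters.items()},
                }
                for name, f in fits.items()
            }
        report.model_selection = sel
        best = max(sel["log_qdot"], key=lambda m: sel["log_qdot"][m]["aic_weight"])
        correlation = {"OU": "martins", "BM": "brownian", "WN": "identity"}[best]
        alpha_init = (
            sel["log_qdot"]["OU"]["parameters"].get("alpha")
            if correlation == "martins"
            else None
        )
        report.correlation_structure = {
            "selected_model": best,
            "correlation": correlation,
        }
        report.stages_completed.append(stage)

        stage = "pgls"
        fit_cs = pgls.pgls_fit(
            tree, tab, "log_qdot", "log_bm", group="group",
            correlation=correlation, alpha_init=alpha_init,
            normalize_height=normalize_height,
        )
        fit_int = pgls.pgls_fit(
            tree, tab, "log_qdot", "log_bm", group="group", interaction=True,
            correlation=correlation, alpha_init=alpha_init,
            normalize_height=normalize_height,
        )
        slope = float(fit_cs.coef[fit_cs.slope_col])
        report.group_equations = {
            "slope": _round(slope),
            "slope_se": _round(
                float(np.sqrt(fit_cs.vcov.loc[fit_cs.slope_col, fit_cs.slope_col]))
            ),
            "alpha": None if fit_cs.alpha is None else _round(fit_cs.alpha),
            "intercepts": {
                g: _round(fit_cs.coef[c]) for g, c in fit_cs.intercept_cols.items()
            },
            "n_per_group": {
                g: int((tab["group"] == g).sum()) for g in fit_cs.groups
            },
        }
        report.model_comparison = {
            k: (v if not isinstance(v, float) else _round(v))
            for k, v in pgls.compare_models(fit_cs, fit_int).items()
        }
        report.stages_completed.append(stage)

        stage = "residual_normality"
        norm = pgls.whitened_residual_normality(
            fit_cs, n_mc=lilliefors_mc, seed=seed
        )
        report.residual_normality = {
            "statistic": _round(norm.statistic),
            "p_value": _round(norm.p_value),
            "n": norm.n,
            "method": norm.method,
        }
        report.stages_completed.append(stage)

        stage = "ancova"
        report.contrasts = [
            {
                "group_a": c.group_a,
                "group_b": c.group_b,
                "delta_intercept": _round(c.delta_intercept),
                "se": _round(c.se),
                "z": _round(c.z),
                "p_raw": _round(c.p_raw),
                "p_bonferroni": _round(c.p_bonferroni),
                "flow_ratio": _round(c.flow_ratio),
            }
            for c in pgls.pairwise_ancova(fit_cs)
        ]
        report.stages_completed.append(stage)

        if "log_mmr" in tab.columns and tab["log_mmr"].notna().sum() >= 2:
            stage = "mvou"
            traits = tab[["log_mmr", "log_qdot", "log_bm"]]
            fit_ou_mv = mvou.mvou_fit(tree, traits, mode=mvou_mode)
            fit_bm_mv = mvou.mvbm_fit(tree, traits)
            best_mv = fit_ou_mv if fit_ou_mv.aic <= fit_bm_mv.aic else fit_bm_mv
            report.mvou_model_comparison = {
                "mvOU_aic": _round(fit_ou_mv.aic),
                "mvBM_aic": _round(fit_bm_mv.aic),
                "delta_aic_bm_minus_ou": _round(fit_bm_mv.aic - fit_ou_mv.aic),
                "selected": best_mv.model,
                "theta": [_round(t) for t in best_mv.theta],
            }
            report.stages_completed.append(stage)

            stage = "mmr_estimates"
            est = mvou.estimate_missing(best_mv, tree, traits)
            est_mmr = est[est["trait"] == "log_mmr"].merge(
                tab[["log_bm"]], left_on="node", right_index=True
            )
            mi = mvou.mass_independent_mmr(
                10.0 ** est_mmr["mean"].to_numpy(),
                10.0 ** est_mmr["log_bm"].to_numpy(),
            )
            report.mmr_estimates = [
                {
                    "taxon": r["node"],
                    "log_mmr_mean": _round(r["mean"]),
                    "log_mmr_sd": _round(r["sd"]),
                    "log_mmr_ci_low": _round(r["ci_low"]),
                    "log_mmr_ci_high": _round(r["ci_high"]),
                    "observed": bool(r["observed"]),
                    "mass_independent_mmr": _round(m),
                }
                for (_, r), m in zip(est_mmr.iterrows(), mi)
            ]
            anc = mvou.ancestral_states(best_mv, tree, traits)
            report.ancestral_states = [
                {
                    "node": r["node"],
                    "trait": r["trait"],
                    "mean": _round(r["mean"]),
                    "sd": _round(r["sd"]),
                }
                for _, r in anc.iterrows()
            ]
            loo = mvou.loo_predictions(best_mv, tree, traits, "log_mmr")
            report.prediction_r2 = _round(
                mvou.prediction_r2(loo["predicted"], loo["observed_value"]), 6
            )
            report.stages_completed.append(stage)
    except Exception as exc:  # abort carrying the stage and partial report
        raise PipelineError(stage, report, exc) from exc
    return report
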