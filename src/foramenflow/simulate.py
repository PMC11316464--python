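"""Synthetic study generator: trees, trait tables and specimen tables.

Emulates the statistical design of a femoral blood-flow study of mammals:
an 88-tip time-calibrated phylogeny (69 extant, 19 extinct tips ending
before the present), log10 body mass evolving by Brownian motion, log10 Q̇
following a common-slope group-intercept allometry with phylogenetically
(OU-) correlated residuals, log10 MMR drawn from the conditional of a
multivariate OU model so the three traits carry the assumed joint
structure, and specimen-level foramen diameters that invert exactly through
the 20 %-lumen + polynomial measurement chain.

Default parameter values are the study conditions: slope 0.74 with group
intercepts (−5.31, −5.47, −5.77, −5.35) for Epitheria, Prototheria+
Metatheria, extant Xenarthra and fossil Xenarthra respectively; 69 extant +
19 fossil tips.  Every operation is a pure function of its inputs and a
seed/generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .hemodynamics import LUMEN_OCCUPANCY, QDOT_COEFFS, SpecimenRecord
from .mvou import mvou_covariance
from .tree import PhyloTree

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "assign_groups",
    "simulate_allometry",
    "simulate_mvou_traits",
    "inverse_qdot",
    "emit_specimens",
    "write_bundle",
    "GROUPS",
]

GROUPS = ("Epitheria", "Prototheria+Metatheria", "Xenarthra", "Xenarthra_fossil")

#: vertex of the flow polynomial: log10 Q̇ increases for log10 r below this
_QDOT_VERTEX = 1.91 / (2 * 0.20)  # = 4.775


@dataclass
class SimulationConfig:
    """Generating parameters of one synthetic study (defaults = study design)."""

    n_extant: int = 69
    n_fossil: int = 19
    tree_height: float = 180.0          # Ma, crown-mammal scale
    fossil_age_range: tuple = (0.01, 0.6)  # fossil tip age, fraction of height

    slope: float = 0.74                 # common allometric slope
    intercepts: dict = field(
        default_factory=lambda: {
            "Epitheria": -5.31,
            "Prototheria+Metatheria": -5.47,
            "Xenarthra": -5.77,
            "Xenarthra_fossil": -5.35,
        }
    )
    group_targets: dict = field(        # extant clade sizes to paint
        default_factory=lambda: {"Prototheria+Metatheria": 26, "Xenarthra": 14}
    )
    resid_alpha: float = 0.02           # OU pull of allometric residuals, /Ma
    resid_sd: float = 0.25              # stationary residual sd, log10 units

    bm_root: float = 3.5                # log10 g at the root
    bm_sigma2: float = 0.0125           # BM rate of log10 Bm, /Ma

    # joint (log MMR, log Q̇, log Bm) OU model used for MMR generation
    mvou_A: np.ndarray = field(
        default_factory=lambda: np.diag([0.03, 0.03, 0.02])
    )
    mvou_Sigma: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0384, 0.0432, 0.0559],
                [0.0432, 0.0600, 0.0625],
                [0.0559, 0.0625, 0.0900],
            ]
        )
    )
    mvou_theta: np.ndarray = field(
        default_factory=lambda: np.array([4.30, -2.72, 3.50])
    )
    mmr_missing: str = "fossil"         # which tips lack MMR

    specimens_per_taxon: int = 2
    noise_sd: float = 0.02              # log10 mm measurement noise on radius
    occupancy: float = LUMEN_OCCUPANCY
    two_foramen_p: float = 0.04         # ~3/70 femora carry two foramina
    femur_intercept: float = 1.0        # log10 L = (1/3) log10 Bm + c + noise
    femur_noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.n_extant < 2 or self.n_fossil < 0:
            raise ValueError("need at least two extant tips")
        if self.tree_height <= 0 or self.resid_alpha < 0 or self.resid_sd < 0:
            raise ValueError("rates and scales must be positive")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed (or Generator) is required")
    return np.random.default_rng(seed)


# ------------------------------------------------------------------- trees


def simulate_tree(
    config: SimulationConfig, seed
) -> tuple[PhyloTree, dict]:
    """Pure-birth tree with extant tips at the present and truncated fossils.

    A Yule tree is grown to ``n_extant + n_fossil`` tips, rescaled to
    ``tree_height``, and ``n_fossil`` randomly chosen tips are shortened so
    they end at an age drawn uniform on ``fossil_age_range``·height before
    the present.  Returns the tree and metadata naming the fossil tips.
    """
    rng = _rng(seed)
    n_total = config.n_extant + config.n_fossil

    # grow: node records (parent, birth_time); active lineages split at exp times
    parent = [-1]
    birth = [0.0]
    active = [0]
    t = 0.0
    while len(active) < n_total:
        k = len(active)
        t += rng.exponential(1.0 / k)
        which = int(rng.integers(k))
        node = active.pop(which)
        for _ in range(2):
            parent.append(node)
            birth.append(t)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / n_total)

    n_nodes = len(parent)
    death = [t_end] * n_nodes
    is_tip = [True] * n_nodes
    for i in range(1, n_nodes):
        is_tip[parent[i]] = False
    for i in range(n_nodes):
        if not is_tip[i]:
            children = [j for j in range(n_nodes) if parent[j] == i]
            death[i] = birth[children[0]]

    # height is measured from the crown (first split); the root carries no stem
    scale = config.tree_height / (t_end - death[0] if not is_tip[0] else t_end)
    birth = [b * scale for b in birth]
    death = [d * scale for d in death]

    # reindex to preorder
    order: list[int] = []
    stack = [0]
    children_of: dict[int, list[int]] = {}
    for i in range(1, n_nodes):
        children_of.setdefault(parent[i], []).append(i)
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children_of.get(node, [])))
    newidx = {old: new for new, old in enumerate(order)}
    pre_parent = [(-1 if parent[o] == -1 else newidx[parent[o]]) for o in order]
    lengths = [death[o] - birth[o] if parent[o] != -1 else 0.0 for o in order]
    tips = [k for k, o in enumerate(order) if is_tip[o]]

    fossil_pos = sorted(rng.choice(len(tips), size=config.n_fossil, replace=False))
    fossil_set = {tips[p] for p in fossil_pos}
    lo, hi = config.fossil_age_range
    for node in sorted(fossil_set):
        age = rng.uniform(lo, hi) * config.tree_height
        cut = min(age, 0.9 * lengths[node])  # keep the branch positive
        lengths[node] -= cut

    labels: list[str | None] = [None] * len(order)
    i_ext = i_fos = 0
    fossil_labels = []
    for node in tips:
        if node in fossil_set:
            i_fos += 1
            labels[node] = f"F{i_fos:02d}"
            fossil_labels.append(labels[node])
        else:
            i_ext += 1
            labels[node] = f"T{i_ext:03d}"
    tree = PhyloTree(pre_parent, lengths, labels)
    return tree, {"fossil_tips": fossil_labels}


def assign_groups(
    tree: PhyloTree, fossil_tips: list[str], config: SimulationConfig
) -> pd.Series:
    """Clade-based group painting of extant tips; fossils form their own group.

    The internal node whose extant-descendant count is closest to each
    target paints that clade; remaining extant tips are Epitheria.  Painting
    whole clades confounds group with phylogeny on purpose — that is the
    structure of the real design.
    """
    fossil = set(fossil_tips)
    labels = tree.tip_labels
    tip_idx = tree.tip_indices
    extant_mask = {labels[k]: labels[k] not in fossil for k in range(tree.n_tips)}

    group = {lbl: ("Xenarthra_fossil" if lbl in fossil else "Epitheria") for lbl in labels}
    assigned: set[str] = set()
    for gname, target in config.group_targets.items():
        best_node, best_err, best_clade = None, None, None
        for node in range(1, tree.n_nodes):
            clade = [
                labels[k]
                for k, i in enumerate(tip_idx)
                if tree.is_ancestor(node, i) and extant_mask[labels[k]]
            ]
            clade = [c for c in clade if c not in assigned]
            if not 2 <= len(clade) <= max(2, tree.n_tips - len(assigned) - 4):
                continue
            err = abs(len(clade) - target)
            if best_err is None or err < best_err:
                best_node, best_err, best_clade = node, err, clade
        if best_clade:
            for lbl in best_clade:
                group[lbl] = gname
                assigned.add(lbl)
    return pd.Series(group, name="group").loc[labels]


# ------------------------------------------------------------------ traits


def simulate_allometry(
    tree: PhyloTree,
    config: SimulationConfig,
    seed,
    fossil_tips: list[str] | None = None,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Generate the taxon-level trait table under the assumed allometry.

    log10 Bm is BM from ``bm_root``; log10 Q̇ = slope·log10 Bm + a_g + eps
    with eps a zero-mean OU-correlated deviate of stationary sd
    ``resid_sd``; log10 MMR is drawn from its conditional distribution given
    (log Q̇, log Bm) under the configured joint OU model, and withheld for
    fossil tips (``mmr_missing="fossil"``).
    """
    rng = _rng(seed)
    labels = tree.tip_labels
    n = tree.n_tips
    if fossil_tips is None:
        fossil_tips = tree.extinct_tips()
    if groups is None:
        groups = assign_groups(tree, fossil_tips, config)
    missing_int = [g for g in groups.unique() if g not in config.intercepts]
    if missing_int:
        raise ValueError(f"no intercept configured for group(s) {missing_int}")

    S = tree.shared_times()
    D = tree.patristic()

    # BM body mass
    Lbm = linalg.cholesky(config.bm_sigma2 * S + 1e-10 * np.eye(n), lower=True)
    log_bm = config.bm_root + Lbm @ rng.standard_normal(n)

    # OU-correlated allometric residuals (stationary sd resid_sd)
    if config.resid_sd > 0:
        Corr = np.exp(-config.resid_alpha * D)
        Lr = linalg.cholesky(
            config.resid_sd**2 * Corr + 1e-10 * np.eye(n), lower=True
        )
        eps = Lr @ rng.standard_normal(n)
    else:
        eps = np.zeros(n)
    a_g = np.array([config.intercepts[groups[lbl]] for lbl in labels])
    log_qdot = config.slope * log_bm + a_g + eps

    # MMR from the joint-OU conditional given (Q̇, Bm)
    T = tree.tip_depths
    C = mvou_covariance(T, S, config.mvou_A, config.mvou_Sigma)
    theta = np.asarray(config.mvou_theta, dtype=float)
    mean = np.repeat(theta, n)
    obs = np.zeros(3 * n, dtype=bool)
    obs[n:] = True
    x = np.concatenate([np.zeros(n), log_qdot, log_bm])
    Coo = C[np.ix_(obs, obs)] + 1e-9 * np.eye(2 * n)
    Cqo = C[:n, obs]
    cho = linalg.cho_factor(Coo, lower=True)
    w = linalg.cho_solve(cho, x[obs] - mean[obs])
    cmean = mean[:n] + Cqo @ w
    ccov = C[:n, :n] - Cqo @ linalg.cho_solve(cho, Cqo.T)
    Lm = linalg.cholesky(0.5 * (ccov + ccov.T) + 1e-9 * np.eye(n), lower=True)
    log_mmr = cmean + Lm @ rng.standard_normal(n)

    table = pd.DataFrame(
        {
            "taxon": labels,
            "group": groups.loc[labels].to_numpy(),
            "log_bm": log_bm,
            "log_qdot": log_qdot,
            "log_mmr": log_mmr,
            "log_mmr_true": log_mmr,
        }
    ).set_index("taxon")
    if config.mmr_missing == "fossil":
        table.loc[table.index.isin(fossil_tips), "log_mmr"] = np.nan
    elif config.mmr_missing != "none":
        raise ValueError("mmr_missing must be 'fossil' or 'none'")
    table["bm_g"] = 10.0 ** table["log_bm"]
    table["qdot_cm3_s"] = 10.0 ** table["log_qdot"]
    table["mmr"] = 10.0 ** table["log_mmr"]
    return table


def simulate_mvou_traits(
    tree: PhyloTree,
    A: np.ndarray,
    Sigma: np.ndarray,
    theta: np.ndarray,
    seed,
    trait_names: tuple = ("log_mmr", "log_qdot", "log_bm"),
) -> pd.DataFrame:
    """Draw tip traits exactly from the joint OU kernel (root at theta)."""
    rng = _rng(seed)
    n = tree.n_tips
    p = len(trait_names)
    C = mvou_covariance(tree.tip_depths, tree.shared_times(), A, Sigma)
    L = linalg.cholesky(C + 1e-10 * np.eye(p * n), lower=True)
    flat = np.repeat(np.asarray(theta, dtype=float), n) + L @ rng.standard_normal(p * n)
    return pd.DataFrame(
        flat.reshape(p, n).T, index=pd.Index(tree.tip_labels, name="taxon"),
        columns=list(trait_names),
    )


# ------------------------------------------------------------ measurement


def inverse_qdot(qdot_value) -> float | np.ndarray:
    """Lumen radius (mm) producing a given Q̇ under the flow polynomial.

    Solves ``0.20 x² − 1.91 x + (log10 Q̇ − 1.82) = 0`` for ``x = log10 r``
    and keeps the root on the increasing branch (``x < 4.775``).
    """
    q = np.asarray(qdot_value, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Q̇ must be > 0")
    c2, c1, c0 = QDOT_COEFFS  # (-0.20, 1.91, 1.82)
    y = np.log10(q)
    disc = c1**2 - 4 * c2 * (c0 - y)  # discriminant of c2 x² + c1 x + (c0 - y)
    if np.any(disc < 0):
        raise ValueError("Q̇ beyond the range of the flow polynomial")
    x = (c1 - np.sqrt(disc)) / (2 * -c2)  # increasing-branch root (x < vertex)
    out = 10.0**x
    return float(out) if out.ndim == 0 else out


def emit_specimens(
    table: pd.DataFrame, config: SimulationConfig, seed
) -> list[SpecimenRecord]:
    """Specimen-level femora consistent with the taxon Q̇ values.

    Per specimen the lumen radius is ``inverse_qdot(Q̇ * 10**N(0, noise_sd))``
    — measurement noise is expressed on the log10 flow scale, the scale of
    every downstream analysis, so ``noise_sd`` is directly the specimen-level
    sd of log10 Q̇.  The radius is converted back to foramen minor
    diameter(s) by inverting the occupancy and circular-area rules exactly;
    a small fraction of femora carry two foramina splitting the same total
    area.  Femur length follows geometric
    similarity, ``log10 L = (1/3) log10 Bm + c + noise`` — a device to
    exercise the Qi index, not a biological claim.
    """
    rng = _rng(seed)
    records = []
    for taxon, row in table.iterrows():
        for s in range(config.specimens_per_taxon):
            r_lumen = inverse_qdot(
                row["qdot_cm3_s"] * 10.0 ** rng.normal(0.0, config.noise_sd)
            )
            area_total = math.pi * r_lumen**2 / config.occupancy
            if rng.uniform() < config.two_foramen_p:
                u = rng.uniform(0.3, 0.7)
                areas = [u * area_total, (1 - u) * area_total]
            else:
                areas = [area_total]
            diams = [2.0 * math.sqrt(a / math.pi) for a in areas]
            log_len = (
                row["log_bm"] / 3.0
                + config.femur_intercept
                + rng.normal(0.0, config.femur_noise_sd)
            )
            records.append(
                SpecimenRecord(
                    taxon=str(taxon),
                    specimen_id=f"{taxon}-{s + 1}",
                    foramen_minor_diameters=diams,
                    femur_length=10.0**log_len,
                    adult=True,
                )
            )
    return records


# ------------------------------------------------------------------ bundle


def write_bundle(out_dir, config: SimulationConfig, seed: int) -> dict:
    """Write tree.nwk, taxa.csv, specimens.csv and truth.json to a directory.

    The three child stages consume independent streams spawned from the seed
    so the bundle is reproducible end to end.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_tree, s_traits, s_spec = ss.spawn(3)
    tree, meta = simulate_tree(config, np.random.default_rng(s_tree))
    table = simulate_allometry(
        tree, config, np.random.default_rng(s_traits), fossil_tips=meta["fossil_tips"]
    )
    records = emit_specimens(table, config, np.random.default_rng(s_spec))

    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    taxa = table.reset_index()[["taxon", "group", "bm_g", "mmr"]]
    taxa.to_csv(out / "taxa.csv", index=False)
    pd.DataFrame(
        {
            "taxon": [r.taxon for r in records],
            "specimen_id": [r.specimen_id for r in records],
            "foramen_minor_diameters_mm": [
                ";".join(f"{d:.8g}" for d in r.foramen_minor_diameters)
                for r in records
            ],
            "femur_length_mm": [r.femur_length for r in records],
            "adult": [r.adult for r in records],
        }
    ).to_csv(out / "specimens.csv", index=False)

    truth = {
        "seed": seed,
        "slope": config.slope,
        "intercepts": config.intercepts,
        "resid_alpha": config.resid_alpha,
        "resid_sd": config.resid_sd,
        "fossil_tips": meta["fossil_tips"],
        "mvou_theta": np.asarray(config.mvou_theta).tolist(),
        "log_qdot": {t: float(v) for t, v in table["log_qdot"].items()},
        "log_mmr_true": {t: float(v) for t, v in table["log_mmr_true"].items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"tree": tree, "table": table, "records": records, "truth": truth}
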