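"""Phylogenetic generalized least squares, ANCOVA contrasts and diagnostics.

The allometry of femoral blood flow is modelled on the log10 scale,

    log10 Q̇ = b * log10 Bm + a_g + eps,

with one intercept ``a_g`` per mammal group (a common slope ``b``), or with
per-group slopes in the "interaction" variant.  Residuals ``eps`` are
correlated across taxa through the phylogeny: the working correlation is the
OU-derived ``corMartins`` structure ``exp(-alpha d_ij)`` on patristic
distances, with ``alpha`` either fixed or profiled by maximum likelihood
(plain ML, not REML, so AIC/BIC remain comparable across fixed-effect
structures).  ``alpha -> inf`` reduces the fit to ordinary least squares.

Group differences in elevation are tested by pairwise Wald contrasts of
intercepts with Bonferroni adjustment; a difference of ``D`` log10 units is
a flow ratio of ``10**D`` at equal body mass.  Residual normality is checked
on Cholesky-whitened residuals with a Monte-Carlo Lilliefors test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .tree import PhyloTree, ou_correlation_matrix, shared_path_matrix

__all__ = [
    "GLSFit",
    "ContrastResult",
    "NormalityTest",
    "pgls_fit",
    "compare_models",
    "whitened_residual_normality",
    "pairwise_ancova",
    "flow_ratio",
    "ols_reference",
    "lilliefors_statistic",
    "lilliefors_mc_pvalue",
]

_LOG_ALPHA_BOUNDS = (-10.0, 10.0)


@dataclass
class GLSFit:
    """One fitted (phylogenetic) GLS regression."""

    formula: str                       # "common-slope" | "interaction" | "simple"
    coef: pd.Series
    vcov: pd.DataFrame                 # coefficient covariance (unbiased sigma2)
    correlation: str                   # "martins" | "brownian" | "identity"
    alpha: float | None                # corMartins rate (None unless martins)
    alpha_estimated: bool
    sigma2: float                      # ML residual variance (whitened scale)
    lnL: float
    k: int
    n: int
    aic: float = field(init=False)
    bic: float = field(init=False)
    taxa: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    intercept_cols: dict[str, str] = field(default_factory=dict)
    slope_col: str | None = None
    interaction_cols: list[str] = field(default_factory=list)
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None
    V: np.ndarray | None = None        # working correlation in `taxa` order
    response: str | None = None

    def __post_init__(self) -> None:
        self.aic = 2 * self.k - 2 * self.lnL
        self.bic = self.k * np.log(self.n) - 2 * self.lnL


@dataclass
class ContrastResult:
    """A pairwise elevation (intercept) contrast between two groups."""

    group_a: str
    group_b: str
    delta_intercept: float   # log10 units, a - b
    se: float
    z: float
    p_raw: float
    p_bonferroni: float
    flow_ratio: float        # 10**delta, flow of A relative to B at equal mass


@dataclass
class NormalityTest:
    statistic: float
    p_value: float
    n: int
    n_mc: int
    method: str = "Lilliefors (Monte-Carlo)"


# ------------------------------------------------------------------ design


def _prepare_table(tree: PhyloTree, table: pd.DataFrame) -> pd.DataFrame:
    tab = table.copy()
    if "taxon" in tab.columns:
        tab = tab.set_index("taxon")
    tab.index = [str(t).strip() for t in tab.index]
    missing = [t for t in tab.index if t not in set(tree.tip_labels)]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    order = [t for t in tree.tip_labels if t in set(tab.index)]
    return tab.loc[order]


def _design(
    tab: pd.DataFrame,
    response: str,
    covariate: str,
    group: str | None,
    interaction: bool,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, str], str | None, list[str], list[str]]:
    y = tab[response].to_numpy(dtype=float)
    x = tab[covariate].to_numpy(dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("response and covariate must be finite")
    if group is None:
        X = np.column_stack([np.ones_like(x), x])
        names = ["intercept", covariate]
        return X, y, names, {"all": "intercept"}, covariate, [], ["all"]
    g = tab[group].astype(str)
    groups = sorted(g.unique())
    cols, names = [], []
    icols: dict[str, str] = {}
    for gr in groups:  # cell-means coding: one intercept per group
        cols.append((g == gr).to_numpy(dtype=float))
        names.append(f"intercept[{gr}]")
        icols[gr] = names[-1]
    cols.append(x)
    names.append(covariate)
    inter_names: list[str] = []
    if interaction:  # slope deviations from the first (reference) group
        for gr in groups[1:]:
            cols.append(x * (g == gr).to_numpy(dtype=float))
            inter_names.append(f"{covariate}:[{gr}]")
            names.append(inter_names[-1])
    return np.column_stack(cols), y, names, icols, covariate, inter_names, groups


def _gls_profile(
    L: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, float, float, np.ndarray, np.ndarray]:
    """GLS given the lower Cholesky factor of the working correlation.

    Returns (beta, sigma2_ml, lnL, XtViX_inv, resid) with lnL the ML
    log-likelihood profiled over beta and sigma2.
    """
    n, p = X.shape
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    q, r = np.linalg.qr(Xw)
    rdiag = np.abs(np.diag(r))
    if np.any(rdiag < 1e-10 * max(1.0, rdiag.max())):
        bad = np.where(rdiag < 1e-10 * max(1.0, rdiag.max()))[0]
        raise ValueError(f"rank-deficient design; aliased column indices {bad.tolist()}")
    beta = linalg.solve_triangular(r, q.T @ yw, lower=False)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2 = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2 <= 0:
        lnL = np.inf
    else:
        lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdetV + n)
    rinv = linalg.solve_triangular(r, np.eye(p), lower=False)
    xtvix_inv = rinv @ rinv.T
    return beta, sigma2, float(lnL), xtvix_inv, y - X @ beta


def _correlation_matrix(
    tree: PhyloTree,
    taxa: list[str],
    correlation: str,
    alpha: float | None,
    normalize_height: bool,
) -> np.ndarray:
    tip_order = tree.tip_labels
    idx = np.array([tip_order.index(t) for t in taxa])
    if correlation == "identity":
        return np.eye(len(taxa))
    if correlation == "brownian":
        C = shared_path_matrix(tree).matrix[np.ix_(idx, idx)]
        return C / tree.height  # scale absorbed by sigma2; keeps O(1) diagonal
    if correlation == "martins":
        if alpha is None:
            raise ValueError("martins correlation needs alpha")
        V = ou_correlation_matrix(tree, alpha, normalize_height=normalize_height)
        return V.matrix[np.ix_(idx, idx)]
    raise ValueError(f"unknown correlation {correlation!r}")


def pgls_fit(
    tree: PhyloTree,
    table: pd.DataFrame,
    response: str,
    covariate: str,
    group: str | None = None,
    interaction: bool = False,
    correlation: str = "martins",
    alpha: float | str | None = "estimate",
    alpha_init: float | None = None,
    normalize_height: bool = False,
) -> GLSFit:
    """Fit a (phylogenetic) GLS allometry of ``response`` on ``covariate``.

    With ``group`` given, every group gets its own intercept; with
    ``interaction=True`` also its own slope deviation.  ``correlation`` is
    ``"martins"`` (OU, ``alpha`` fixed or ``"estimate"`` to profile by ML),
    ``"brownian"`` (shared-path covariance) or ``"identity"`` (OLS).
    ``alpha_init`` seeds the profile search, typically with the pull rate of
    a univariate OU fit to the response.
    """
    tab = _prepare_table(tree, table)
    taxa = list(tab.index)
    X, y, names, icols, slope_col, inter_cols, groups = _design(
        tab, response, covariate, group, interaction
    )
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many taxa ({n}) as coefficients ({p})")

    estimated = correlation == "martins" and (alpha == "estimate" or alpha is None)

    def fit_given(V: np.ndarray):
        L = linalg.cholesky(V, lower=True)
        return _gls_profile(L, X, y), V

    if correlation == "martins":
        if estimated:
            def negll(log_alpha: float) -> float:
                V = _correlation_matrix(
                    tree, taxa, "martins", float(np.exp(log_alpha)), normalize_height
                )
                try:
                    return -_gls_profile(linalg.cholesky(V, lower=True), X, y)[2]
                except linalg.LinAlgError:
                    return np.inf

            lo, hi = _LOG_ALPHA_BOUNDS
            cand = list(np.linspace(lo, hi, 31))
            if alpha_init is not None and alpha_init > 0:
                cand.append(float(np.clip(np.log(alpha_init), lo, hi)))
            vals = [negll(c) for c in cand]
            best = cand[int(np.argmin(vals))]
            res = optimize.minimize_scalar(
                negll,
                bounds=(max(lo, best - 1.0), min(hi, best + 1.0)),
                method="bounded",
                options={"xatol": 1e-7},
            )
            log_a = float(res.x) if res.fun <= min(vals) else float(best)
            alpha_hat: float | None = float(np.exp(log_a))
        else:
            alpha_hat = float(alpha)
            if alpha_hat < 0:
                raise ValueError("alpha must be non-negative")
        V = _correlation_matrix(tree, taxa, "martins", alpha_hat, normalize_height)
    else:
        alpha_hat = None
        V = _correlation_matrix(tree, taxa, correlation, None, normalize_height)

    (beta, sigma2, lnL, xtvix_inv, resid), V = fit_given(V)

    # unbiased scale for Wald inference (undefined for a saturated fit)
    sigma2_unb = sigma2 * n / (n - p) if n > p else np.nan
    vcov = pd.DataFrame(sigma2_unb * xtvix_inv, index=names, columns=names)
    k = p + 1 + (1 if estimated else 0)
    formula = (
        "simple" if group is None else ("interaction" if interaction else "common-slope")
    )
    return GLSFit(
        formula=formula,
        coef=pd.Series(beta, index=names),
        vcov=vcov,
        correlation=correlation,
        alpha=alpha_hat,
        alpha_estimated=estimated,
        sigma2=sigma2,
        lnL=lnL,
        k=k,
        n=n,
        taxa=taxa,
        groups=groups,
        intercept_cols=icols,
        slope_col=slope_col,
        interaction_cols=inter_cols,
        residuals=resid,
        fitted=y - resid,
        V=V,
        response=response,
    )


# --------------------------------------------------------- model comparison


def compare_models(fit_common: GLSFit, fit_interaction: GLSFit) -> dict:
    """Compare common-slope vs per-group-slope fits on the same data.

    Reports delta AIC/BIC (interaction minus common-slope; positive favours
    the common slope), a joint Wald test of all slope-deviation terms, and
    the selected structure: the interaction is kept only when jointly
    significant at 0.05.
    """
    if fit_common.n != fit_interaction.n or fit_common.taxa != fit_interaction.taxa:
        raise ValueError("fits are not on the same data")
    if not fit_interaction.interaction_cols:
        raise ValueError("second fit has no interaction terms")
    cols = fit_interaction.interaction_cols
    c = fit_interaction.coef[cols].to_numpy()
    Vc = fit_interaction.vcov.loc[cols, cols].to_numpy()
    W = float(c @ np.linalg.solve(Vc, c))
    q = len(cols)
    p_joint = float(stats.chi2.sf(W, q))
    per_coef = {
        name: {
            "estimate": float(fit_interaction.coef[name]),
            "z": float(fit_interaction.coef[name] / np.sqrt(fit_interaction.vcov.loc[name, name])),
            "p": float(
                2 * stats.norm.sf(abs(fit_interaction.coef[name]) / np.sqrt(fit_interaction.vcov.loc[name, name]))
            ),
        }
        for name in cols
    }
    delta_aic = fit_interaction.aic - fit_common.aic
    delta_bic = fit_interaction.bic - fit_common.bic
    return {
        "delta_aic": float(delta_aic),
        "delta_bic": float(delta_bic),
        "interaction_wald": W,
        "interaction_df": q,
        "interaction_p": p_joint,
        "interaction_terms": per_coef,
        "selected": "interaction" if p_joint <= 0.05 else "common-slope",
    }


# -------------------------------------------------- residual normality test


def lilliefors_statistic(x: np.ndarray) -> float:
    """Kolmogorov–Smirnov distance to a Normal with estimated mean and sd."""
    x = np.asarray(x, dtype=float)
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    F = special.ndtr(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - F)
    d_minus = np.max(F - (i - 1) / n)
    return float(max(d_plus, d_minus))


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    key = (n, n_mc, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n_mc, n))
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        Z.sort(axis=1)
        F = special.ndtr(Z)
        i = np.arange(1, n + 1)
        d_plus = np.max(i / n - F, axis=1)
        d_minus = np.max(F - (i - 1) / n, axis=1)
        _NULL_CACHE[key] = np.sort(np.maximum(d_plus, d_minus))
    return _NULL_CACHE[key]


def lilliefors_mc_pvalue(
    statistic: float, n: int, n_mc: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo p-value of the Lilliefors statistic under normality."""
    null = _lilliefors_null(n, n_mc, seed)
    exceed = int(np.sum(null >= statistic))
    return float((exceed + 1) / (n_mc + 1))


def whitened_residual_normality(
    fit: GLSFit, n_mc: int = 10_000, seed: int = 0
) -> NormalityTest:
    """Lilliefors normality test on phylogenetically whitened residuals.

    Residuals are decorrelated as ``u = L^{-1} (y - X beta)`` where the
    working correlation factors as ``V = L L'`` — equivalently, multiplying
    by a Cholesky square root of ``V^{-1}``.  Under a correct model ``u`` is
    an iid Normal sample.
    """
    if fit.residuals is None or fit.V is None:
        raise ValueError("fit carries no residuals/correlation matrix")
    try:
        L = linalg.cholesky(fit.V, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "working correlation is not positive definite; consider adding "
            "a 1e-10 diagonal jitter"
        ) from exc
    u = linalg.solve_triangular(L, fit.residuals, lower=True)
    stat = lilliefors_statistic(u)
    p = lilliefors_mc_pvalue(stat, u.size, n_mc=n_mc, seed=seed)
    return NormalityTest(statistic=stat, p_value=p, n=u.size, n_mc=n_mc)


# ------------------------------------------------------- pairwise contrasts


def pairwise_ancova(
    fit: GLSFit, m: int | None = None, reference: str = "z"
) -> list[ContrastResult]:
    """Pairwise elevation contrasts between all groups of a common-slope fit.

    For each ordered pair (a, b) of group labels, the intercept difference
    ``a_a - a_b`` is tested two-sided against a normal reference (the
    general-linear-hypothesis convention; ``reference="t"`` uses a
    t(n - p) reference instead) and the p-values Bonferroni-adjusted over
    all ``m = G(G-1)/2`` pairs.
    """
    if len(fit.groups) < 2:
        raise ValueError("pairwise contrasts need at least two groups")
    if fit.formula == "interaction":
        raise ValueError("elevation contrasts require the common-slope fit")
    pairs = list(itertools.combinations(fit.groups, 2))
    if m is None:
        m = len(pairs)
    df = fit.n - len(fit.coef)
    out = []
    for ga, gb in pairs:
        ca, cb = fit.intercept_cols[ga], fit.intercept_cols[gb]
        delta = float(fit.coef[ca] - fit.coef[cb])
        var = float(
            fit.vcov.loc[ca, ca] + fit.vcov.loc[cb, cb] - 2 * fit.vcov.loc[ca, cb]
        )
        se = float(np.sqrt(var))
        z = delta / se
        if reference == "z":
            p_raw = float(2 * stats.norm.sf(abs(z)))
        elif reference == "t":
            p_raw = float(2 * stats.t.sf(abs(z), df))
        else:
            raise ValueError("reference must be 'z' or 't'")
        out.append(
            ContrastResult(
                group_a=ga,
                group_b=gb,
                delta_intercept=delta,
                se=se,
                z=z,
                p_raw=p_raw,
                p_bonferroni=float(min(1.0, m * p_raw)),
                flow_ratio=float(10.0 ** delta),
            )
        )
    return out


def flow_ratio(intercept_a: float, intercept_b: float) -> float:
    """Flow of group A relative to group B at equal body mass, ``10**(a-b)``.

    Intercepts are log10 allometric elevations from a common-slope model.
    """
    return float(10.0 ** (intercept_a - intercept_b))


def ols_reference(
    table: pd.DataFrame, response: str = "log_qdot", covariate: str = "log_bm"
) -> tuple[float, float]:
    """Plain OLS slope and intercept across all taxa, ignoring phylogeny."""
    y = table[response].to_numpy(dtype=float)
    x = table[covariate].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least three taxa")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
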