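"""Univariate trait-evolution models: BM, single-optimum OU, and white noise.

These are the candidate models for the phylogenetic signal of a continuous
trait (here log10 body mass and log10 femoral blood flow).  All three are
Gaussian, so fitting reduces to generalized least squares with a structured
covariance:

* **BM** — ``x ~ MVN(z0 * 1, sigma2 * C)`` with ``C`` the shared-path matrix.
* **OU** — mean-reverting walk with pull ``alpha`` toward an optimum equal to
  the root state; on a possibly non-ultrametric tree
  ``Cov(i, j) = sigma2 / (2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))``
  with ``d_ij`` the patristic distance and ``t_ij`` the root-to-MRCA time.
  As ``alpha -> 0`` this recovers BM.
* **WN** — iid Normal, no phylogenetic structure at all.

Model comparison uses AIC (k = 2, 3, 2 respectively) and Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .tree import PhyloTree

__all__ = [
    "EvoModelFit",
    "fit_bm",
    "fit_ou",
    "fit_wn",
    "akaike_weights",
    "fit_all",
]

_LOG_ALPHA_BOUNDS = (-10.0, 10.0)  # natural-log bounds on the OU pull (per Ma)


@dataclass
class EvoModelFit:
    """Maximum-likelihood fit of one evolutionary model to one trait."""

    model: str                 # "BM" | "OU" | "WN"
    parameters: dict
    lnL: float
    k: int
    aic: float = field(init=False)
    aic_weight: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.aic = 2 * self.k - 2 * self.lnL

    def aicc(self, n: int) -> float:
        """Small-sample corrected AIC; negligible vs AIC at n ~ 88."""
        if n - self.k - 1 <= 0:
            raise ValueError("AICc undefined for n <= k + 1")
        return self.aic + 2 * self.k * (self.k + 1) / (n - self.k - 1)


def _profile_mvn(C: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Profile ML of ``x ~ MVN(z0*1, sigma2*C)``: returns (z0, sigma2, lnL)."""
    n = x.size
    cho = linalg.cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    Cix = linalg.cho_solve(cho, x)
    z0 = float(ones @ Cix / (ones @ Ci1))
    r = x - z0
    q = float(r @ linalg.cho_solve(cho, r))
    sigma2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    if sigma2 <= 0:
        return z0, 0.0, np.inf
    lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return z0, sigma2, float(lnL)


def _check_distinct_tips(tree: PhyloTree) -> None:
    D = tree.patristic()
    np.fill_diagonal(D, np.inf)
    i, j = np.unravel_index(np.argmin(D), D.shape)
    if D[i, j] <= 0:
        labels = tree.tip_labels
        raise ValueError(
            f"tips {labels[i]!r} and {labels[j]!r} are at zero patristic "
            "distance; the BM covariance is singular"
        )


def _align(tree: PhyloTree, trait) -> np.ndarray:
    """Coerce a trait (array in tip order, or mapping/Series by taxon)."""
    if hasattr(trait, "reindex"):  # pandas Series
        x = np.asarray(trait.reindex(tree.tip_labels), dtype=float)
    elif isinstance(trait, dict):
        x = np.array([trait[t] for t in tree.tip_labels], dtype=float)
    else:
        x = np.asarray(trait, dtype=float)
        if x.size != tree.n_tips:
            raise ValueError("trait length does not match tip count")
    if not np.all(np.isfinite(x)):
        raise ValueError("every tip needs a finite trait value")
    return x


def fit_bm(tree: PhyloTree, trait) -> EvoModelFit:
    """ML Brownian-motion fit (root state z0 and rate sigma2 profiled)."""
    x = _align(tree, trait)
    C = tree.shared_times()
    try:
        z0, sigma2, lnL = _profile_mvn(C, x)
    except linalg.LinAlgError:
        _check_distinct_tips(tree)
        raise
    degenerate = sigma2 <= 1e-12 * max(1.0, float(np.var(x)))
    return EvoModelFit(
        model="BM",
        parameters={"sigma2": sigma2, "z0": z0},
        lnL=lnL,
        k=2,
        degenerate=degenerate,
    )


def _ou_structure(D: np.ndarray, S: np.ndarray, alpha: float) -> np.ndarray:
    """Unit-rate OU covariance on a (possibly non-ultrametric) tree.

    ``exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij)) / (2 alpha)``; the
    ``alpha -> 0`` limit is the shared-time matrix (BM).
    """
    if alpha < 1e-12:
        return S.copy()
    return np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)


def fit_ou(tree: PhyloTree, trait, alpha: float | None = None) -> EvoModelFit:
    """Single-optimum OU fit; the optimum equals the root state.

    The pull rate ``alpha`` is profiled by bounded ML over ``log alpha`` in
    [-10, 10] (per Ma) from a deterministic coarse grid unless given.
    """
    x = _align(tree, trait)
    D = tree.patristic()
    S = tree.shared_times()

    def negprof(log_alpha: float) -> float:
        C = _ou_structure(D, S, float(np.exp(log_alpha)))
        try:
            return -_profile_mvn(C, x)[2]
        except linalg.LinAlgError:
            return np.inf

    if alpha is None:
        lo, hi = _LOG_ALPHA_BOUNDS
        grid = np.linspace(lo, hi, 41)
        vals = np.array([negprof(g) for g in grid])
        best = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            negprof,
            bounds=(max(lo, best - 1.0), min(hi, best + 1.0)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_alpha = float(res.x) if res.fun <= np.min(vals) else float(best)
        alpha_hat = float(np.exp(log_alpha))
    else:
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        alpha_hat = float(alpha)

    C = _ou_structure(D, S, alpha_hat)
    z0, sigma2, lnL = _profile_mvn(C, x)
    return EvoModelFit(
        model="OU",
        parameters={"alpha": alpha_hat, "sigma2": sigma2, "z0": z0},
        lnL=lnL,
        k=3,
        degenerate=sigma2 <= 1e-12 * max(1.0, float(np.var(x))),
    )


def fit_wn(trait) -> EvoModelFit:
    """White-noise (iid Normal) fit — no phylogenetic structure, tree-free."""
    x = np.asarray(trait, dtype=float)
    if hasattr(trait, "to_numpy"):
        x = trait.to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("white-noise fit needs at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("every value must be finite")
    n = x.size
    mu = float(x.mean())
    sigma2 = float(np.mean((x - mu) ** 2))
    degenerate = sigma2 <= 0
    lnL = (
        -np.inf
        if degenerate
        else -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    )
    return EvoModelFit(
        model="WN",
        parameters={"sigma2": sigma2, "z0": mu},
        lnL=float(lnL),
        k=2,
        degenerate=degenerate,
    )


def akaike_weights(fits: list[EvoModelFit], n: int | None = None) -> np.ndarray:
    """Akaike weights ``exp(-dAIC/2)`` normalized over the compared fits.

    With ``n`` given the small-sample AICc is used instead of AIC.  Also
    writes each weight back onto its fit.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    aics = np.array([f.aic if n is None else f.aicc(n) for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    for f, wi in zip(fits, w):
        f.aic_weight = float(wi)
    return w


def fit_all(tree: PhyloTree, trait) -> dict[str, EvoModelFit]:
    """Fit BM, OU and WN to one trait and attach Akaike weights."""
    fits = {
        "BM": fit_bm(tree, trait),
        "OU": fit_ou(tree, trait),
        "WN": fit_wn(_align(tree, trait)),
    }
    akaike_weights(list(fits.values()))
    return fits
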