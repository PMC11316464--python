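"""Multivariate Ornstein–Uhlenbeck trait model on a non-ultrametric tree.

Jointly models p correlated continuous traits — here (log10 MMR, log10 Q̇,
log10 Bm) — as a mean-reverting diffusion along the phylogeny:

    dX(t) = -A (X(t) - theta) dt + R dW(t),     Sigma = R R',

with a symmetric positive-definite pull matrix ``A``, diffusion ``Sigma``
and optimum ``theta``; the process starts at ``theta`` at the root.  For two
nodes at depths ``T_u, T_v`` whose paths separate at depth ``s``,

    Cov(X_u, X_v) = e^{-A (T_u - s)} V(s) e^{-A' (T_v - s)},
    V(s) = ∫_0^s e^{-A w} Sigma e^{-A' w} dw,

evaluated in the eigenbasis of ``A``.  Tips with any subset of trait entries
missing (fossils lack MMR but keep Q̇ and Bm) are handled by marginalizing
the joint Gaussian to the observed entries; missing tip values and ancestral
states are the exact conditional means of that Gaussian, with ±1.96 sd
intervals conditional on the fitted parameters.

Fitting is maximum likelihood over log-Cholesky factors of ``A`` and
``Sigma`` with ``theta`` profiled out in closed form; a multivariate BM fit
(the ``A -> 0`` analogue) provides the AIC reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .tree import PhyloTree

__all__ = [
    "MvOUFit",
    "mvou_covariance",
    "mvbm_covariance",
    "mvou_loglik",
    "mvbm_loglik",
    "mvou_fit",
    "mvbm_fit",
    "estimate_missing",
    "ancestral_states",
    "loo_predictions",
    "prediction_r2",
    "mass_independent_mmr",
]

_JITTER = 1e-9


@dataclass
class MvOUFit:
    """Fitted multivariate OU (or BM) model."""

    model: str                 # "mvOU" | "mvBM"
    trait_names: list[str]
    A: np.ndarray | None       # pull matrix (None for mvBM)
    Sigma: np.ndarray
    theta: np.ndarray          # optimum / root state vector
    lnL: float
    k: int
    converged: bool
    n_obs: int                 # observed tip-by-trait entries
    aic: float = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.aic = 2 * self.k - 2 * self.lnL


# ------------------------------------------------------------------ kernels


def _check_spd(M: np.ndarray, name: str) -> None:
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.min(linalg.eigvalsh(M)) <= 0:
        raise ValueError(f"{name} must be positive definite")


def mvou_covariance(
    depths: np.ndarray,
    shared: np.ndarray,
    A: np.ndarray,
    Sigma: np.ndarray,
    root: str = "fixed",
) -> np.ndarray:
    """(p·m)×(p·m) mvOU covariance over m nodes, trait-major ordering.

    ``depths`` are root-to-node times, ``shared`` the pairwise MRCA depths.
    Row/column ``k*m + i`` is trait k at node i.  ``root="fixed"`` starts
    the process at the optimum (no variance at the root); ``"stationary"``
    draws the root from the stationary distribution, in which case the
    accumulated-variance term saturates at its infinite-time limit.
    """
    A = np.asarray(A, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = A.shape[0]
    m = depths.size
    lam, Q = linalg.eigh(A)
    St = Q.T @ Sigma @ Q
    # E[a] = exp(-lam_a * (T_i - s_ij)); its transpose covers the j index
    E = [np.exp(-lam[a] * (depths[:, None] - shared)) for a in range(p)]
    B = np.empty((p, p, m, m))
    for a in range(p):
        for b in range(a, p):
            mu = lam[a] + lam[b]
            if root == "stationary":
                if mu <= 1e-12:
                    raise ValueError("stationary root needs a positive-definite A")
                G = np.full_like(shared, 1.0 / mu)
            elif abs(mu) > 1e-12:
                G = -np.expm1(-mu * shared) / mu
            else:
                G = shared.copy()
            blk = St[a, b] * E[a] * E[b].T * G
            B[a, b] = blk
            if b != a:
                B[b, a] = blk.T
    full = np.einsum("ka,lb,abij->kilj", Q, Q, B).reshape(p * m, p * m)
    return 0.5 * (full + full.T)


def mvbm_covariance(shared: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Multivariate-BM covariance: Kronecker of the diffusion with shared times."""
    return np.kron(np.asarray(Sigma, dtype=float), np.asarray(shared, dtype=float))


# ------------------------------------------------------------- data plumbing


def _trait_matrix(tree: PhyloTree, traits: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Align a taxon-indexed trait table to tip order; NaN marks missing."""
    tab = traits.copy()
    if "taxon" in tab.columns:
        tab = tab.set_index("taxon")
    tab.index = [str(t).strip() for t in tab.index]
    missing = [t for t in tab.index if t not in set(tree.tip_labels)]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    tab = tab.reindex(tree.tip_labels)
    X = tab.to_numpy(dtype=float)
    names = list(tab.columns)
    obs_per_trait = np.sum(np.isfinite(X), axis=0)
    bad = [names[j] for j in range(len(names)) if obs_per_trait[j] < 2]
    if bad:
        raise ValueError(f"trait(s) observed for fewer than two tips: {bad}")
    return X, names


def _flatten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trait-major flatten; returns (values, observed mask, trait-of-entry)."""
    n, p = X.shape
    flat = X.T.reshape(-1)
    obs = np.isfinite(flat)
    trait_of = np.repeat(np.arange(p), n)
    return flat, obs, trait_of


def _gaussian_loglik(C: np.ndarray, resid: np.ndarray) -> float:
    m = resid.size
    cho = linalg.cho_factor(C + _JITTER * np.eye(m), lower=True)
    q = float(resid @ linalg.cho_solve(cho, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return -0.5 * (m * np.log(2 * np.pi) + logdet + q)


def _profiled_theta_loglik(
    C_obs: np.ndarray, x_obs: np.ndarray, trait_of_obs: np.ndarray, p: int
) -> tuple[np.ndarray, float]:
    """Closed-form GLS optimum vector and the resulting log-likelihood."""
    m = x_obs.size
    cho = linalg.cho_factor(C_obs + _JITTER * np.eye(m), lower=True)
    M = np.zeros((m, p))
    M[np.arange(m), trait_of_obs] = 1.0
    CiM = linalg.cho_solve(cho, M)
    Cix = linalg.cho_solve(cho, x_obs)
    theta = linalg.solve(M.T @ CiM, M.T @ Cix, assume_a="pos")
    r = x_obs - M @ theta
    q = float(r @ linalg.cho_solve(cho, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    lnL = -0.5 * (m * np.log(2 * np.pi) + logdet + q)
    return theta, float(lnL)


# --------------------------------------------------------------- likelihoods


def mvou_loglik(
    tree: PhyloTree,
    traits: pd.DataFrame,
    A: np.ndarray,
    Sigma: np.ndarray,
    theta: np.ndarray,
    root: str = "fixed",
) -> float:
    """Log-likelihood of the observed tip entries under a given mvOU model."""
    _check_spd(A, "A")
    _check_spd(Sigma, "Sigma")
    X, names = _trait_matrix(tree, traits)
    n, p = X.shape
    if A.shape != (p, p) or Sigma.shape != (p, p) or np.size(theta) != p:
        raise ValueError("parameter dimensions do not match trait count")
    T = tree.tip_depths
    S = tree.shared_times()
    C = mvou_covariance(T, S, A, Sigma, root=root)
    flat, obs, trait_of = _flatten(X)
    mean = np.asarray(theta, dtype=float)[trait_of]
    return _gaussian_loglik(C[np.ix_(obs, obs)], flat[obs] - mean[obs])


def mvbm_loglik(
    tree: PhyloTree, traits: pd.DataFrame, Sigma: np.ndarray, theta: np.ndarray
) -> float:
    """Log-likelihood under multivariate BM with root state ``theta``."""
    _check_spd(Sigma, "Sigma")
    X, _ = _trait_matrix(tree, traits)
    S = tree.shared_times()
    C = mvbm_covariance(S, Sigma)
    flat, obs, trait_of = _flatten(X)
    mean = np.asarray(theta, dtype=float)[trait_of]
    return _gaussian_loglik(C[np.ix_(obs, obs)], flat[obs] - mean[obs])


# ------------------------------------------------------------------ fitting


def _pack_chol(M: np.ndarray) -> np.ndarray:
    L = linalg.cholesky(M, lower=True)
    p = M.shape[0]
    out = [np.log(L[i, i]) for i in range(p)]
    out += [L[i, j] for i in range(p) for j in range(i)]
    return np.array(out)


def _unpack_chol(v: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    for i in range(p):
        L[i, i] = np.exp(np.clip(v[i], -20.0, 15.0))
    k = p
    for i in range(p):
        for j in range(i):
            L[i, j] = v[k]
            k += 1
    return L @ L.T


def _univariate_ou_init(
    D: np.ndarray, S: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Cheap grid-profiled univariate OU (alpha, diffusion rate, mean)."""
    obs = np.isfinite(x)
    Ds, Ss, xs = D[np.ix_(obs, obs)], S[np.ix_(obs, obs)], x[obs]
    ns = xs.size
    best = (1e-3, float(np.var(xs)) / max(S.max(), 1.0), float(xs.mean()), -np.inf)
    for la in np.linspace(-8.0, 2.0, 15):
        a = float(np.exp(la))
        C = np.exp(-a * Ds) * (-np.expm1(-2.0 * a * Ss)) / (2.0 * a)
        try:
            cho = linalg.cho_factor(C + _JITTER * np.eye(ns), lower=True)
        except linalg.LinAlgError:
            continue
        ones = np.ones(ns)
        z0 = float(ones @ linalg.cho_solve(cho, xs) / (ones @ linalg.cho_solve(cho, ones)))
        r = xs - z0
        s2 = float(r @ linalg.cho_solve(cho, r)) / ns
        if s2 <= 0:
            continue
        lnL = -0.5 * (
            ns * np.log(2 * np.pi)
            + ns * np.log(s2)
            + 2 * np.sum(np.log(np.diag(cho[0])))
            + ns
        )
        if lnL > best[3]:
            best = (a, s2, z0, lnL)
    return best[0], best[1], best[2]


def mvou_fit(
    tree: PhyloTree,
    traits: pd.DataFrame,
    mode: str = "full",
    maxiter: int = 300,
    root: str = "fixed",
) -> MvOUFit:
    """ML multivariate-OU fit with theta profiled out.

    ``mode="full"`` parameterizes a symmetric positive-definite pull matrix
    through its log-Cholesky factor (k = 15 for p = 3); ``mode="diagonal"``
    restricts the pull to a diagonal matrix (k = 12), trading flexibility
    for speed and stability — trait coupling then enters through the
    diffusion alone.
    """
    X, names = _trait_matrix(tree, traits)
    n, p = X.shape
    T = tree.tip_depths
    S = tree.shared_times()
    D = T[:, None] + T[None, :] - 2.0 * S
    flat, obs, trait_of = _flatten(X)
    x_obs, trait_obs = flat[obs], trait_of[obs]

    # univariate-OU moment start + empirical cross-correlations
    inits = [_univariate_ou_init(D, S, X[:, j]) for j in range(p)]
    alpha0 = np.clip([i[0] for i in inits], 1e-4, 5.0)
    sig0 = np.clip([i[1] for i in inits], 1e-8, None)
    complete = np.all(np.isfinite(X), axis=1)
    if complete.sum() >= 3:
        corr = np.corrcoef(X[complete].T)
        corr = np.nan_to_num(corr, nan=0.0)
    else:
        corr = np.eye(p)
    Sigma0 = 0.6 * corr * np.sqrt(np.outer(sig0, sig0))
    np.fill_diagonal(Sigma0, sig0)
    for _ in range(8):  # shrink off-diagonals until PD
        try:
            linalg.cholesky(Sigma0, lower=True)
            break
        except linalg.LinAlgError:
            off = Sigma0 - np.diag(np.diag(Sigma0))
            Sigma0 = np.diag(np.diag(Sigma0)) + 0.5 * off

    n_chol = p + p * (p - 1) // 2

    if mode == "full":
        x0 = np.concatenate([_pack_chol(np.diag(alpha0)), _pack_chol(Sigma0)])

        def unpack(v):
            return _unpack_chol(v[:n_chol], p), _unpack_chol(v[n_chol:], p)

        k = 2 * n_chol + p
    elif mode == "diagonal":
        x0 = np.concatenate([np.log(alpha0), _pack_chol(Sigma0)])

        def unpack(v):
            return (
                np.diag(np.exp(np.clip(v[:p], -20.0, 5.0))),
                _unpack_chol(v[p:], p),
            )

        k = p + n_chol + p
    else:
        raise ValueError("mode must be 'full' or 'diagonal'")

    def negll(v: np.ndarray) -> float:
        A, Sigma = unpack(v)
        try:
            C = mvou_covariance(T, S, A, Sigma, root=root)
            _, lnL = _profiled_theta_loglik(
                C[np.ix_(obs, obs)], x_obs, trait_obs, p
            )
        except (linalg.LinAlgError, FloatingPointError):
            return 1e12
        if not np.isfinite(lnL):
            return 1e12
        return -lnL

    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-8}
    )
    v = res.x if res.fun <= negll(x0) else x0
    A, Sigma = unpack(v)
    C = mvou_covariance(T, S, A, Sigma, root=root)
    theta, lnL = _profiled_theta_loglik(C[np.ix_(obs, obs)], x_obs, trait_obs, p)
    return MvOUFit(
        model="mvOU",
        trait_names=names,
        A=A,
        Sigma=Sigma,
        theta=theta,
        lnL=float(lnL),
        k=k,
        converged=bool(res.success),
        n_obs=int(obs.sum()),
        diagnostics={"mode": mode, "root": root, "n_iter": int(res.nit), "message": str(res.message)},
    )


def mvbm_fit(tree: PhyloTree, traits: pd.DataFrame, maxiter: int = 300) -> MvOUFit:
    """ML multivariate-BM fit (no pull); the AIC reference for mvOU."""
    X, names = _trait_matrix(tree, traits)
    n, p = X.shape
    S = tree.shared_times()
    flat, obs, trait_of = _flatten(X)
    x_obs, trait_obs = flat[obs], trait_of[obs]

    complete = np.all(np.isfinite(X), axis=1)
    base = X[complete] if complete.sum() >= 3 else np.nan_to_num(X)
    Sigma0 = np.cov(base.T) / max(S.max(), 1.0) + 1e-8 * np.eye(p)
    x0 = _pack_chol(Sigma0)

    def negll(v: np.ndarray) -> float:
        Sigma = _unpack_chol(v, p)
        try:
            C = mvbm_covariance(S, Sigma)
            _, lnL = _profiled_theta_loglik(C[np.ix_(obs, obs)], x_obs, trait_obs, p)
        except (linalg.LinAlgError, FloatingPointError):
            return 1e12
        return -lnL if np.isfinite(lnL) else 1e12

    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-8}
    )
    v = res.x if res.fun <= negll(x0) else x0
    Sigma = _unpack_chol(v, p)
    C = mvbm_covariance(S, Sigma)
    theta, lnL = _profiled_theta_loglik(C[np.ix_(obs, obs)], x_obs, trait_obs, p)
    n_chol = p + p * (p - 1) // 2
    return MvOUFit(
        model="mvBM",
        trait_names=names,
        A=None,
        Sigma=Sigma,
        theta=theta,
        lnL=float(lnL),
        k=n_chol + p,
        converged=bool(res.success),
        n_obs=int(obs.sum()),
        diagnostics={"n_iter": int(res.nit), "message": str(res.message)},
    )


# ----------------------------------------------------- conditional estimates


def _fit_covariance(fit: MvOUFit, depths: np.ndarray, shared: np.ndarray) -> np.ndarray:
    if fit.model == "mvOU":
        root = fit.diagnostics.get("root", "fixed")
        return mvou_covariance(depths, shared, fit.A, fit.Sigma, root=root)
    return mvbm_covariance(shared, fit.Sigma)


def _conditional(
    C: np.ndarray,
    mean: np.ndarray,
    x: np.ndarray,
    obs: np.ndarray,
    query: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional mean and sd of `query` entries given `obs` entries."""
    Coo = C[np.ix_(obs, obs)] + _JITTER * np.eye(int(obs.sum()))
    Cqo = C[np.ix_(query, obs)]
    cho = linalg.cho_factor(Coo, lower=True)
    w = linalg.cho_solve(cho, x[obs] - mean[obs])
    cmean = mean[query] + Cqo @ w
    half = linalg.cho_solve(cho, Cqo.T)
    cvar = np.diag(C[np.ix_(query, query)]) - np.einsum("ij,ji->i", Cqo, half)
    return cmean, np.sqrt(np.clip(cvar, 0.0, None))


def estimate_missing(
    fit: MvOUFit, tree: PhyloTree, traits: pd.DataFrame
) -> pd.DataFrame:
    """Exact conditional-Gaussian estimates for every tip-by-trait entry.

    Missing entries get the conditional mean and sd given all observed
    entries under the fitted model; observed entries are returned as-is with
    sd 0.  CIs are ``mean ± 1.96 sd``, conditional on the point estimates of
    (A, Sigma, theta) — parameter uncertainty is not propagated.
    """
    X, names = _trait_matrix(tree, traits)
    n, p = X.shape
    if names != fit.trait_names:
        raise ValueError("trait columns do not match the fitted model")
    T = tree.tip_depths
    S = tree.shared_times()
    C = _fit_covariance(fit, T, S)
    flat, obs, trait_of = _flatten(X)
    mean = fit.theta[trait_of]
    rows = []
    if np.any(~obs):
        cmean, csd = _conditional(C, mean, flat, obs, ~obs)
    miss_iter = iter(zip(cmean, csd)) if np.any(~obs) else iter(())
    labels = tree.tip_labels
    for k in range(p):
        for i in range(n):
            idx = k * n + i
            if obs[idx]:
                mu, sd = float(flat[idx]), 0.0
            else:
                mu, sd = next(miss_iter)
                mu, sd = float(mu), float(sd)
            rows.append(
                {
                    "node": labels[i],
                    "trait": names[k],
                    "mean": mu,
                    "sd": sd,
                    "ci_low": mu - 1.96 * sd,
                    "ci_high": mu + 1.96 * sd,
                    "observed": bool(obs[idx]),
                }
            )
    return pd.DataFrame(rows)


def ancestral_states(
    fit: MvOUFit, tree: PhyloTree, traits: pd.DataFrame
) -> pd.DataFrame:
    """Conditional means and 95% CIs of every trait at every internal node."""
    X, names = _trait_matrix(tree, traits)
    n, p = X.shape
    tip_idx = tree.tip_indices
    internal = np.array(
        [i for i in range(tree.n_nodes) if i not in set(tip_idx.tolist())], dtype=int
    )
    nodes = np.concatenate([tip_idx, internal])
    depths = tree.depths[nodes]
    S = tree.shared_times(nodes)
    C = _fit_covariance(fit, depths, S)

    m = nodes.size
    flat_obs_mask = np.zeros(p * m, dtype=bool)
    x_full = np.zeros(p * m)
    query = np.zeros(p * m, dtype=bool)
    trait_of = np.repeat(np.arange(p), m)
    for k in range(p):
        for a in range(m):
            idx = k * m + a
            if a < n:  # tip block, in tip order
                v = X[a, k]
                if np.isfinite(v):
                    flat_obs_mask[idx] = True
                    x_full[idx] = v
            else:
                query[idx] = True
    mean = fit.theta[trait_of]
    cmean, csd = _conditional(C, mean, x_full, flat_obs_mask, query)
    rows = []
    it = iter(zip(cmean, csd))
    for k in range(p):
        for a in range(n, m):
            node = int(nodes[a])
            lbl = tree.labels[node] or f"node{node}"
            mu, sd = next(it)
            rows.append(
                {
                    "node": lbl,
                    "node_index": node,
                    "trait": names[k],
                    "mean": float(mu),
                    "sd": float(sd),
                    "ci_low": float(mu - 1.96 * sd),
                    "ci_high": float(mu + 1.96 * sd),
                }
            )
    return pd.DataFrame(rows)


def loo_predictions(
    fit: MvOUFit, tree: PhyloTree, traits: pd.DataFrame, trait: str
) -> pd.DataFrame:
    """Leave-one-out predictions of one trait at tips where it is observed.

    Each observed entry is masked in turn and re-estimated from everything
    else under the fitted model; this is the observed-vs-predicted check of
    the model's ability to recover a tip value it has not seen.
    """
    X, names = _trait_matrix(tree, traits)
    n, p = X.shape
    j = names.index(trait)
    T = tree.tip_depths
    S = tree.shared_times()
    C = _fit_covariance(fit, T, S)
    flat, obs, trait_of = _flatten(X)
    mean = fit.theta[trait_of]
    rows = []
    for i in range(n):
        idx = j * n + i
        if not obs[idx]:
            continue
        obs_i = obs.copy()
        obs_i[idx] = False
        query = np.zeros_like(obs)
        query[idx] = True
        cmean, csd = _conditional(C, mean, flat, obs_i, query)
        rows.append(
            {
                "node": tree.tip_labels[i],
                "trait": trait,
                "observed_value": float(flat[idx]),
                "predicted": float(cmean[0]),
                "sd": float(csd[0]),
            }
        )
    return pd.DataFrame(rows)


def prediction_r2(estimates, observed) -> float:
    """Squared Pearson correlation of observed vs predicted values."""
    e = np.asarray(estimates, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.size != o.size or e.size < 3:
        raise ValueError("need at least three paired values")
    if np.var(e) == 0 or np.var(o) == 0:
        raise ValueError("zero variance: R^2 undefined")
    r = np.corrcoef(e, o)[0, 1]
    return float(r * r)


def mass_independent_mmr(mmr_total, bm, exponent: float = 0.67):
    """Mass-independent MMR, ``mmr / Bm**0.67`` (mL O2 h^-1 g^-0.67).

    Dividing by ``Bm**0.67`` removes the allometric size effect so metabolic
    capacity can be compared across body sizes.
    """
    mmr_total = np.asarray(mmr_total, dtype=float)
    bm = np.asarray(bm, dtype=float)
    if np.any(mmr_total <= 0) or np.any(bm <= 0):
        raise ValueError("MMR and body mass must be > 0")
    out = mmr_total / bm**exponent
    return float(out) if out.ndim == 0 else out
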