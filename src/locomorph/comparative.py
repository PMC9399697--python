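"""Discrete and continuous trait evolution on dated trees.

Discrete side: the k-state equal-rates Markov model (Mk/ER) fitted by
maximum likelihood with Felsenstein pruning, and marginal ancestral-state
probabilities ("scaled likelihoods") from a two-pass algorithm with a flat
root prior.

Continuous side: five Gaussian models of trait evolution — Brownian motion
(BM), Ornstein-Uhlenbeck (OU), early burst (EB), a linear rate trend, and
directional drift — fitted by ML through their multivariate-normal tip
distributions, compared by AICc and Akaike weights, plus GLS/ML ancestral
reconstruction under BM.  All models reduce to at most a one-dimensional
profile optimization because the rate scale and the mean parameters are
profiled out analytically.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

import dendropy

from . import treeops

logger = logging.getLogger(__name__)

CONTINUOUS_MODELS = ("BM", "OU", "EB", "trend", "drift")


# ---------------------------------------------------------------------------
# Mk / ER discrete model

def _er_transition(q: float, k: int, t: float) -> np.ndarray:
    """Closed-form transition matrix of the equal-rates Mk model."""
    e = np.exp(-k * q * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, (1.0 + (k - 1) * e) / k)
    return P


def _states_vector(states, state_list: list[str] | None):
    s = pd.Series(states)
    levels = sorted(s.unique()) if state_list is None else list(state_list)
    unknown = set(s.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown state label(s): {sorted(unknown)}")
    return s, levels


def _prune(tree, s: pd.Series, levels: list[str], q: float):
    """Postorder conditional likelihoods, log-scaled. Returns (D, logscale)."""
    k = len(levels)
    idx = {lab: i for i, lab in enumerate(levels)}
    D: dict[dendropy.Node, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            d = np.zeros(k)
            d[idx[s[node.taxon.label]]] = 1.0
            D[node] = d
        else:
            d = np.ones(k)
            for c in node.child_nodes():
                P = _er_transition(q, k, c.edge.length or 0.0)
                d *= P @ D[c]
            m = d.max()
            if m <= 0:
                return D, -np.inf
            d /= m
            logscale += np.log(m)
            D[node] = d
    return D, logscale


def mk_loglik(tree, states, q: float, state_list: list[str] | None = None) -> float:
    """Log-likelihood of tip states under the ER Mk model, flat root prior."""
    if q < 0:
        raise ValueError("q must be >= 0")
    s, levels = _states_vector(states, state_list)
    missing = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon.label not in s]
    if missing:
        raise ValueError(f"tips without states: {missing}")
    D, logscale = _prune(tree, s, levels, q)
    root = D[tree.seed_node]
    return float(np.log(root.mean()) + logscale)


@dataclass
class MkModel:
    states: list[str]
    q: float            # per Myr, equal-rates
    loglik: float
    converged: bool


def fit_mk(tree, states, state_list: list[str] | None = None) -> MkModel:
    """ML estimate of the single ER rate q (bounded 1-D optimization)."""
    s, levels = _states_vector(states, state_list)
    if s.nunique() < 2:
        warnings.warn(
            "all tips share one state; q is at its lower bound", stacklevel=2
        )
        qlo = 1e-9
        return MkModel(levels, qlo, mk_loglik(tree, s, qlo, levels), True)
    depth = max(treeops.node_depths(tree).values())
    lo, hi = np.log(1e-7 / depth), np.log(1e3 / depth)
    res = optimize.minimize_scalar(
        lambda lq: -mk_loglik(tree, s, np.exp(lq), levels),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    q = float(np.exp(res.x))
    logger.debug("fit_mk: q=%.6g, lnL=%.4f, converged=%s", q, -res.fun, res.success)
    return MkModel(levels, q, float(-res.fun), bool(res.success))


def _node_key(node: dendropy.Node, counter: list[int]) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    return f"N{counter[0]}"


@dataclass
class AncestralStates:
    probabilities: pd.DataFrame     # node x state, rows sum to 1
    argmax: pd.Series
    descendants: pd.Series          # comma-joined tip labels per node


def marginal_states(tree, states, model: MkModel) -> AncestralStates:
    """Marginal ancestral probabilities at every internal node.

    Standard two-pass computation: conditional (subtree) likelihoods from
    the pruning pass are combined with outside likelihoods propagated from
    the root (flat prior); the ER matrix is symmetric so transition
    directions need no reversal.
    """
    s, levels = _states_vector(states, model.states)
    k, q = len(levels), model.q
    D, _ = _prune(tree, s, levels, q)
    L: dict[dendropy.Node, np.ndarray] = {}  # per-child partial: P @ D
    for node in tree.preorder_node_iter():
        for c in node.child_nodes():
            P = _er_transition(q, k, c.edge.length or 0.0)
            L[c] = P @ D[c]
    U: dict[dendropy.Node, np.ndarray] = {tree.seed_node: np.full(k, 1.0 / k)}
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        for c in kids:
            out = U[node].copy()
            for b in kids:
                if b is not c:
                    out *= L[b]
            P = _er_transition(q, k, c.edge.length or 0.0)
            u = P.T @ out
            m = u.max()
            U[c] = u / m if m > 0 else u
    counter = [0]
    rows, argmax, desc = {}, {}, {}
    for node in tree.preorder_internal_node_iter():
        p = U[node] * D[node]
        p = p / p.sum()
        key = _node_key(node, counter)
        rows[key] = p
        argmax[key] = levels[int(np.argmax(p))]
        desc[key] = ",".join(sorted(l.taxon.label for l in node.leaf_iter()))
    probs = pd.DataFrame.from_dict(rows, orient="index", columns=levels)
    return AncestralStates(
        probabilities=probs,
        argmax=pd.Series(argmax),
        descendants=pd.Series(desc),
    )


# ---------------------------------------------------------------------------
# Continuous models

def model_cov(tree, model: str, params: dict) -> tuple[np.ndarray, pd.DataFrame]:
    """Expected tip mean vector and covariance matrix for one model.

    With t_i the root-to-tip depth and t_ij the MRCA depth:
    BM     V_ij = s2 t_ij,                        mu_i = z0
    drift  V as BM,                               mu_i = z0 + h t_i
    trend  V_ij = s2 t_ij + b t_ij^2 / 2,         mu_i = z0   (rate linear in t)
    EB     V_ij = s2 (e^{a t_ij} - 1)/a,          mu_i = z0   (a -> 0 is BM)
    OU     V_ij = s2/(2a) e^{-a(t_i+t_j-2 t_ij)} (1 - e^{-2a t_ij}), mu_i = z0
    """
    C = treeops.vcv_matrix(tree)
    Cv = C.to_numpy(float)
    t = np.diag(Cv)
    z0 = float(params.get("z0", 0.0))
    s2 = float(params.get("sigma2", params.get("s2", 1.0)))
    if s2 < 0:
        raise ValueError("sigma2 must be >= 0")
    mu = np.full(len(t), z0)
    if model == "BM":
        V = s2 * Cv
    elif model == "drift":
        h = float(params["h"])
        V = s2 * Cv
        mu = z0 + h * t
    elif model == "trend":
        b = float(params["b"])
        T = t.max()
        if s2 + b * T <= 0:
            raise ValueError(
                f"trend rate sigma2 + b*t must stay positive over the tree "
                f"span (sigma2={s2}, b={b}, span={T})"
            )
        V = s2 * Cv + b * Cv**2 / 2.0
    elif model == "EB":
        a = float(params["a"])
        V = s2 * _eb_kernel(Cv, a)
    elif model == "OU":
        alpha = float(params["alpha"])
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        V = s2 * _ou_kernel(Cv, t, alpha)
    else:
        raise ValueError(f"unknown model {model!r}; choose from {CONTINUOUS_MODELS}")
    return mu, pd.DataFrame(V, index=C.index, columns=C.columns)


def _eb_kernel(C: np.ndarray, a: float) -> np.ndarray:
    if a == 0.0:
        return C.copy()
    return np.expm1(a * C) / a  # expm1 keeps the a -> 0 limit exact


def _ou_kernel(C: np.ndarray, t: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return C.copy()
    D = t[:, None] + t[None, :] - 2.0 * C
    return np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * C)) / (2.0 * alpha)


@dataclass
class TraitModelFit:
    model: str
    params: dict
    loglik: float
    n_params: int
    n: int
    aic: float
    aicc: float
    weight: float | None = None
    data_hash: str = ""


def _gls_profile(V0: np.ndarray, X: np.ndarray, y: np.ndarray):
    """ML-profile the mean coefficients and the rate scale out of a
    MVN(X beta, s2 V0) model. Returns (lnL, beta, s2)."""
    n = len(y)
    try:
        L = linalg.cholesky(V0, lower=True)
    except linalg.LinAlgError:
        return -np.inf, None, None
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    s2 = float(r @ r) / n
    if s2 <= 0:
        s2 = 1e-300
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
    return float(lnL), beta, s2


def _hash_trait(trait: pd.Series) -> str:
    payload = trait.sort_index().to_csv().encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def fit_continuous(tree, trait: pd.Series, model: str) -> TraitModelFit:
    """ML fit of one trait-evolution model to tip values (e.g. log10 LTRL).

    The mean parameters and sigma^2 are profiled analytically; the single
    remaining shape parameter (alpha, a or b) is optimized by a coarse grid
    followed by bounded local refinement, which is deterministic and robust
    on these small, near-flat likelihood surfaces.
    """
    C = treeops.vcv_matrix(tree)
    labels = list(C.index)
    missing = [l for l in labels if l not in trait.index]
    if missing:
        raise ValueError(f"tips without trait values: {missing}")
    y = trait[labels].to_numpy(float)
    Cv = C.to_numpy(float)
    t = np.diag(Cv)
    T = float(t.max())
    n = len(y)
    ones = np.ones((n, 1))

    if model == "BM":
        lnL, beta, s2 = _gls_profile(Cv, ones, y)
        if beta is None:
            raise ValueError("singular phylogenetic covariance (zero branches?)")
        params = {"sigma2": s2, "z0": float(beta[0])}
        k = 2
    elif model == "drift":
        X = np.column_stack([np.ones(n), t])
        lnL, beta, s2 = _gls_profile(Cv, X, y)
        if beta is None:
            raise ValueError("singular phylogenetic covariance (zero branches?)")
        params = {"sigma2": s2, "z0": float(beta[0]), "h": float(beta[1])}
        k = 3
    else:
        if model == "OU":
            lo, hi = 1e-9, 50.0 / T
            kernel = lambda th: _ou_kernel(Cv, t, th)
            name = "alpha"
        elif model == "EB":
            lo, hi = -10.0 / T, -1e-9
            kernel = lambda th: _eb_kernel(Cv, th)
            name = "a"
        elif model == "trend":
            # V = s2 (C + beta C^2/2); b = s2*beta; sigma2(t) > 0 over the span
            lo, hi = -0.999 / T, 50.0 / T
            kernel = lambda th: Cv + th * Cv**2 / 2.0
            name = "beta"
        else:
            raise ValueError(
                f"unknown model {model!r}; choose from {CONTINUOUS_MODELS}"
            )

        def nll(th):
            lnL, _, _ = _gls_profile(kernel(th), ones, y)
            return -lnL

        grid = np.linspace(lo, hi, 40)
        vals = np.array([nll(g) for g in grid])
        if not np.isfinite(vals).any():
            raise ValueError(f"non-finite likelihood across {model} grid")
        i = int(np.nanargmin(vals))
        blo = grid[max(i - 1, 0)]
        bhi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            nll, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-10}
        )
        th = float(res.x) if res.fun <= vals[i] else float(grid[i])
        lnL, beta, s2 = _gls_profile(kernel(th), ones, y)
        params = {"sigma2": s2, "z0": float(beta[0])}
        if model == "trend":
            params["b"] = s2 * th
        else:
            params[name] = th
        k = 3

    if not np.isfinite(lnL):
        raise ValueError(f"non-finite likelihood for model {model}: {params}")
    aic = -2.0 * lnL + 2.0 * k
    if n - k - 1 <= 0:
        raise ValueError(f"too few tips (n={n}) for AICc with k={k}")
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    return TraitModelFit(
        model=model, params=params, loglik=float(lnL), n_params=k, n=n,
        aic=aic, aicc=aicc, data_hash=_hash_trait(trait[labels]),
    )


def akaike_weights(
    fits: list[TraitModelFit], criterion: str = "aicc"
) -> list[TraitModelFit]:
    """Akaike weights w_m = exp(-Delta_m/2) / sum over the candidate set."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted models")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different data")
    ic = np.array([f.aicc if criterion == "aicc" else f.aic for f in fits])
    delta = ic - ic.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return fits


def fit_all_models(
    tree, trait: pd.Series, models=CONTINUOUS_MODELS, criterion: str = "aicc"
) -> list[TraitModelFit]:
    return akaike_weights([fit_continuous(tree, trait, m) for m in models], criterion)


# ---------------------------------------------------------------------------
# Continuous ancestral reconstruction (BM / GLS)

@dataclass
class ContinuousAncestralStates:
    estimates: pd.Series      # per internal node
    variances: pd.Series      # conditional variance of the estimate
    descendants: pd.Series
    z0: float                 # root estimate = GLS grand mean
    sigma2: float


def ancestral_continuous(tree, trait: pd.Series) -> ContinuousAncestralStates:
    """ML/GLS ancestral values under Brownian motion.

    The root estimate is the GLS grand mean of the tip values; every other
    internal node gets its conditional expectation given the tips under the
    fitted BM process, with the conditional variance reported.
    """
    depths = treeops.node_depths(tree)
    tips = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in tips]
    missing = [l for l in labels if l not in trait.index]
    if missing:
        raise ValueError(f"tips without trait values: {missing}")
    y = trait[labels].to_numpy(float)
    Ctt = treeops.vcv_matrix(tree, labels).to_numpy()

    tipset: dict[dendropy.Node, set[str]] = {}
    for node in tree.postorder_node_iter():
        tipset[node] = (
            {node.taxon.label}
            if node.is_leaf()
            else set().union(*(tipset[c] for c in node.child_nodes()))
        )
    internals = list(tree.preorder_internal_node_iter())
    Cnt = np.zeros((len(internals), len(labels)))
    Cnn = np.zeros(len(internals))
    for i, node in enumerate(internals):
        Cnn[i] = depths[node]
        for j, lab in enumerate(labels):
            anc = node
            while lab not in tipset[anc]:
                anc = anc.parent_node
            Cnt[i, j] = depths[anc]

    L = linalg.cholesky(Ctt + 1e-12 * np.eye(len(y)), lower=True)
    ones = np.ones(len(y))
    wy = linalg.cho_solve((L, True), y)
    w1 = linalg.cho_solve((L, True), ones)
    z0 = float(ones @ wy) / float(ones @ w1)
    r = y - z0
    sigma2 = float(r @ linalg.cho_solve((L, True), r)) / len(y)
    est = z0 + Cnt @ linalg.cho_solve((L, True), r)
    var = sigma2 * (Cnn - np.sum(Cnt * linalg.cho_solve((L, True), Cnt.T).T, axis=1))
    var = np.clip(var, 0.0, None)

    counter = [0]
    keys, desc = [], {}
    for node in internals:
        key = _node_key(node, counter)
        keys.append(key)
        desc[key] = ",".join(sorted(tipset[node]))
    return ContinuousAncestralStates(
        estimates=pd.Series(est, index=keys),
        variances=pd.Series(var, index=keys),
        descendants=pd.Series(desc),
        z0=z0,
        sigma2=sigma2,
    )
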