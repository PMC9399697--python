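"""Phylogenetically informed flexible discriminant analysis (pFDA).

Shared ancestry makes species non-independent: under Brownian motion the
expected covariance of a trait between two tips is the root-to-MRCA path
length.  Pagel's lambda scales the off-diagonal of that matrix, from 0 (no
phylogenetic signal) to 1 (full Brownian signal).  The pFDA estimates a
common lambda for the predictors by maximum likelihood, whitens the data by
the inverse Cholesky factor of C(lambda), and runs the discriminant
analysis on the whitened rows; fossil targets participate in the whitening
(their tree position matters) but never in lambda estimation or the
discriminant fit.  Repeating this over an ensemble of candidate trees
propagates topological and dating uncertainty into the posterior
probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

import dendropy

from . import treeops
from .discriminant import (
    ClassificationResult,
    DiscriminantModel,
    JackknifeReport,
    classify,
    fit_cva,
    jackknife_rates,
)
from .morphometrics import SpeciesMeans

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.0, 1.01, 0.1), 10)
EIG_TOL = 1e-10


def lambda_cov(tree, lam: float, labels: list[str] | None = None) -> pd.DataFrame:
    """Pagel's-lambda-scaled Brownian covariance structure.

    Off-diagonal shared path lengths are multiplied by ``lam``; diagonal
    root-to-tip depths are untouched, so lam=1 is the plain Brownian matrix
    and lam=0 is diagonal.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = (
        tree.copy()
        if isinstance(tree, pd.DataFrame)
        else treeops.vcv_matrix(tree, labels)
    )
    if labels is not None and isinstance(tree, pd.DataFrame):
        C = C.loc[labels, labels]
    vals = C.to_numpy(float)
    if np.any(np.diag(vals) <= 0):
        raise ValueError("non-positive tip depth in covariance structure")
    out = lam * vals
    np.fill_diagonal(out, np.diag(vals))
    return pd.DataFrame(out, index=C.index, columns=C.columns)


def _whitener(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Return (L_inv, logdet C) with L_inv @ C @ L_inv.T = I.

    Cholesky when possible; symmetric eigendecomposition fallback with
    eigenvalues floored at EIG_TOL when near-singular.
    """
    try:
        L = linalg.cholesky(C, lower=True)
        Linv = linalg.solve_triangular(L, np.eye(len(C)), lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
    except linalg.LinAlgError:
        w, U = linalg.eigh(C)
        w = np.clip(w, EIG_TOL, None)
        Linv = (U / np.sqrt(w)).T
        logdet = float(np.sum(np.log(w)))
    return Linv, logdet


@dataclass
class LambdaEstimate:
    lam: float
    grid: np.ndarray
    loglik: np.ndarray
    tree_id: str | None = None


def estimate_lambda(
    tree,
    table: SpeciesMeans | pd.DataFrame,
    grid=DEFAULT_GRID,
    tree_id: str | None = None,
) -> LambdaEstimate:
    """Profile Pagel's lambda for the predictor matrix on one tree.

    For each grid value the GLS log-likelihood of a single-mean model with
    covariance sigma^2_t C(lambda) is evaluated per trait, with sigma^2_t
    profiled out analytically, and summed over traits (a common lambda, one
    variance per trait).  The estimate is the grid argmax.
    """
    X = table.values if isinstance(table, SpeciesMeans) else table
    labels = list(X.index)
    Cfull = treeops.vcv_matrix(tree, labels) if not isinstance(tree, pd.DataFrame) else tree.loc[labels, labels]
    Xv = X.to_numpy(float)
    n, p = Xv.shape
    grid = np.asarray(grid, float)
    loglik = np.empty(len(grid))
    for g, lam in enumerate(grid):
        C = lambda_cov(Cfull, lam).to_numpy()
        Linv, logdet = _whitener(C)
        Z = Linv @ Xv
        w = Linv @ np.ones(n)
        denom = w @ w
        ll = 0.0
        for t in range(p):
            mu = (w @ Z[:, t]) / denom
            r = Z[:, t] - mu * w
            s2 = (r @ r) / n
            s2 = max(s2, 1e-300)
            ll += -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
        loglik[g] = ll
    best = int(np.argmax(loglik))
    return LambdaEstimate(
        lam=float(grid[best]), grid=grid, loglik=loglik, tree_id=tree_id
    )


@dataclass
class PFDAResult:
    lam: float
    model: DiscriminantModel
    target_results: dict[str, ClassificationResult]
    jackknife: JackknifeReport
    variance_share: np.ndarray
    trait_correlations: pd.DataFrame


def fit_pfda(
    tree,
    table: SpeciesMeans,
    targets: pd.DataFrame | None = None,
    lam: float | None = None,
    priors_mode: str = "proportional",
    grid=DEFAULT_GRID,
) -> PFDAResult:
    """Whiten by C(lambda) over training + target tips and run the CVA.

    All rows (training and targets) are whitened by L^-1 where
    L L^T = C(lambda); the whitened intercept (the transformed ones vector)
    is projected out of the whitened predictors, which is the GLS analogue
    of mean-centring and reduces exactly to the ordinary CVA whenever
    C is proportional to the identity (star phylogeny / lambda = 0 on an
    equal-depths tree).  The discriminant is then fit on training rows only
    and targets are classified a posteriori.
    """
    if lam is None:
        lam = estimate_lambda(tree, table, grid).lam
    train_labels = list(table.values.index)
    target_labels = list(targets.index) if targets is not None else []
    overlap = set(train_labels) & set(target_labels)
    if overlap:
        raise ValueError(
            f"targets must be disjoint from the training set: {sorted(overlap)}"
        )
    labels = train_labels + target_labels
    C = lambda_cov(tree, lam, labels).to_numpy()
    Linv, _ = _whitener(C)

    cols = list(table.values.columns)
    X = np.vstack(
        [table.values.to_numpy(float)]
        + ([targets[cols].to_numpy(float)] if target_labels else [])
    )
    Z = Linv @ X
    w = Linv @ np.ones(len(labels))
    Zc = Z - np.outer(w, (w @ Z) / (w @ w))

    Zdf = pd.DataFrame(Zc, index=labels, columns=cols)
    wtable = SpeciesMeans(
        values=Zdf.loc[train_labels],
        n=table.n,
        locomotion=table.locomotion,
        columns=tuple(cols),
    )
    model = fit_cva(wtable, priors_mode)
    jack = jackknife_rates(wtable, priors_mode)
    target_results = {
        t: classify(model, Zdf.loc[t]) for t in target_labels
    }
    return PFDAResult(
        lam=lam,
        model=model,
        target_results=target_results,
        jackknife=jack,
        variance_share=model.variance_share,
        trait_correlations=model.trait_correlations,
    )


@dataclass
class EnsembleClassification:
    lambdas: list[float]
    rates: list[float]
    posteriors: pd.DataFrame          # (tree, target) x class
    mean_posteriors: pd.DataFrame     # target x class, arithmetic over trees
    argmax_counts: pd.DataFrame       # target x class, trees where class wins
    failures: list[tuple[int, str]] = field(default_factory=list)


def ensemble_pfda(
    trees: list[dendropy.Tree],
    table: SpeciesMeans,
    targets: pd.DataFrame,
    grid=DEFAULT_GRID,
    priors_mode: str = "proportional",
    max_failure_fraction: float = 0.1,
) -> EnsembleClassification:
    """Estimate lambda, fit and classify on every tree; aggregate.

    Single-tree failures are logged and surfaced; the run aborts if more
    than ``max_failure_fraction`` of trees fail.
    """
    lambdas, rates, rows, keys, failures = [], [], [], [], []
    for i, tree in enumerate(trees):
        try:
            res = fit_pfda(tree, table, targets, lam=None, priors_mode=priors_mode, grid=grid)
        except Exception as exc:  # surfaced in the report
            logger.warning("pFDA failed on tree %d: %s", i, exc)
            failures.append((i, str(exc)))
            continue
        lambdas.append(res.lam)
        rates.append(res.jackknife.overall)
        for t, r in res.target_results.items():
            rows.append(r.posteriors)
            keys.append((i, t))
    if len(failures) > max_failure_fraction * len(trees):
        raise RuntimeError(
            f"{len(failures)}/{len(trees)} trees failed: {failures[:3]}..."
        )
    post = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(keys, names=["tree", "target"]))
    mean_post = post.groupby(level="target").mean()
    winners = post.idxmax(axis=1)
    argmax = (
        winners.groupby(level="target")
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=post.columns, fill_value=0)
    )
    return EnsembleClassification(
        lambdas=lambdas,
        rates=rates,
        posteriors=post,
        mean_posteriors=mean_post,
        argmax_counts=argmax,
        failures=failures,
    )
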