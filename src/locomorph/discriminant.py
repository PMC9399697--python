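"""Canonical variate analysis of log-shape data with jackknife validation.

The discriminant machinery is deliberately explicit: class means, a pooled
within-class covariance, canonical axes as eigenvectors of W^-1 B, Gaussian
posterior classification, and leave-one-species-out (jackknife) correct-
classification rates.  Fossil targets are never part of the fit; they are
added a posteriori through :func:`classify`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .morphometrics import SpeciesMeans

logger = logging.getLogger(__name__)


@dataclass
class DiscriminantModel:
    classes: list[str]
    means: pd.DataFrame                 # class x p
    pooled_cov: pd.DataFrame            # p x p (rank = subspace dimension)
    priors: pd.Series                   # per class, sums to 1
    axes: pd.DataFrame                  # p x m canonical coefficients
    eigenvalues: np.ndarray             # m
    variance_share: np.ndarray          # percent, sums to 100 over m axes
    trait_correlations: pd.DataFrame    # p x m Pearson r (traits vs scores)
    scores: pd.DataFrame                # training rows x m
    grand_mean: pd.Series
    # log-shape data are compositional (rows sum to 0), so the p variables
    # span at most p-1 dimensions; the model works in the data-carrying
    # subspace and maps axes back to the original variables.
    basis: np.ndarray = None            # p x r orthonormal
    pooled_sub: np.ndarray = None       # r x r, positive definite

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = (X[self.means.columns] - self.grand_mean) @ self.axes
        Z.columns = self.axes.columns
        return Z


@dataclass
class ClassificationResult:
    posteriors: pd.Series     # per class, >= 0, sums to 1
    predicted: str
    scores: pd.Series         # canonical axis scores


def _priors(labels: pd.Series, classes: list[str], mode: str) -> pd.Series:
    if mode == "proportional":
        p = labels.value_counts(normalize=True).reindex(classes).fillna(0.0)
    elif mode == "equal":
        p = pd.Series(1.0 / len(classes), index=classes)
    else:
        raise ValueError(f"unknown priors mode {mode!r}")
    return p / p.sum()


def fit_cva(
    table: SpeciesMeans,
    priors_mode: str = "proportional",
    regularization: float = 0.0,
) -> DiscriminantModel:
    """Fit a canonical variate analysis on a species-mean table.

    Axes are eigenvectors of ``W^-1 B`` ordered by decreasing eigenvalue;
    the variance share of axis j is its eigenvalue over the eigenvalue sum.
    Each axis is oriented so its largest-|r| trait correlation is positive.
    ``regularization`` shrinks the pooled covariance toward its diagonal
    for rank-deficient problems (off by default).
    """
    X = table.values.to_numpy(float)
    labels = table.locomotion
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    cols = list(table.values.columns)

    means = np.vstack([X[(labels == c).to_numpy()].mean(axis=0) for c in classes])
    counts = np.array([(labels == c).sum() for c in classes])
    grand = X.mean(axis=0)

    # restrict to the subspace actually carrying the data (log-shape rows
    # sum to zero, so the full space is rank-deficient by construction)
    Xc = X - grand
    _, sv, Vt = linalg.svd(Xc, full_matrices=False)
    r = int(np.sum(sv > max(sv[0], 1e-30) * 1e-9))
    if r < 1:
        raise ValueError("data matrix has no variation")
    basis = Vt[:r].T                     # p x r
    Y = Xc @ basis                       # n x r
    mean_sub = (means - grand) @ basis

    W = np.zeros((r, r))
    for c, mu in zip(classes, mean_sub):
        R = Y[(labels == c).to_numpy()] - mu
        W += R.T @ R
    dof = n - len(classes)
    if dof <= 0:
        raise ValueError("more classes than rows; cannot pool covariance")
    W /= dof
    if regularization > 0:
        W = (1 - regularization) * W + regularization * np.diag(np.diag(W))
    B = np.zeros((r, r))
    for cnt, mu in zip(counts, mean_sub):
        d = mu[:, None]
        B += cnt * (d @ d.T)
    B /= max(len(classes) - 1, 1)

    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; enable regularization or reduce "
            "variables"
        ) from exc
    order = np.argsort(evals)[::-1]
    m = min(len(classes) - 1, r)
    evals = np.clip(evals[order][:m], 0.0, None)
    A_sub = evecs[:, order][:, :m]
    A = basis @ A_sub                    # canonical coefficients, original vars

    scores = Xc @ A
    # orient each axis so its strongest trait correlation is positive
    with np.errstate(invalid="ignore"):
        corr = np.array(
            [[_pearson(X[:, i], scores[:, j]) for j in range(m)] for i in range(p)]
        )
    for j in range(m):
        i = np.nanargmax(np.abs(corr[:, j]))
        if corr[i, j] < 0:
            A[:, j] *= -1
            scores[:, j] *= -1
            corr[:, j] *= -1

    share = 100.0 * evals / evals.sum() if evals.sum() > 0 else np.zeros(m)
    axis_names = [f"CV{j + 1}" for j in range(m)]
    return DiscriminantModel(
        classes=classes,
        means=pd.DataFrame(means, index=classes, columns=cols),
        pooled_cov=pd.DataFrame(basis @ W @ basis.T, index=cols, columns=cols),
        priors=_priors(labels, classes, priors_mode),
        axes=pd.DataFrame(A, index=cols, columns=axis_names),
        eigenvalues=evals,
        variance_share=share,
        trait_correlations=pd.DataFrame(corr, index=cols, columns=axis_names),
        scores=pd.DataFrame(scores, index=table.values.index, columns=axis_names),
        grand_mean=pd.Series(grand, index=cols),
        basis=basis,
        pooled_sub=W,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def classify(model: DiscriminantModel, x) -> ClassificationResult:
    """Gaussian posterior classification with the pooled covariance.

    posterior_c is proportional to prior_c * exp(-Mahalanobis^2(x, mean_c)/2);
    computed with log-sum-exp for stability.
    """
    cols = list(model.means.columns)
    if isinstance(x, pd.Series):
        missing = [c for c in cols if c not in x.index]
        if missing:
            raise ValueError(f"input lacks variables {missing}")
        xv = x[cols].to_numpy(float)
    else:
        xv = np.asarray(x, float)
        if xv.shape != (len(cols),):
            raise ValueError(
                f"expected {len(cols)} variables, got shape {xv.shape}"
            )
    Winv = linalg.inv(model.pooled_sub)
    logp = np.empty(len(model.classes))
    for i, c in enumerate(model.classes):
        d = (xv - model.means.loc[c].to_numpy()) @ model.basis
        maha2 = float(d @ Winv @ d)
        prior = model.priors[c]
        logp[i] = (np.log(prior) if prior > 0 else -np.inf) - 0.5 * maha2
    logp -= logp.max()
    post = np.exp(logp)
    post /= post.sum()
    posteriors = pd.Series(post, index=model.classes)
    scores = pd.Series(
        (xv - model.grand_mean.to_numpy()) @ model.axes.to_numpy(),
        index=model.axes.columns,
    )
    return ClassificationResult(
        posteriors=posteriors, predicted=posteriors.idxmax(), scores=scores
    )


@dataclass
class JackknifeReport:
    per_class: pd.Series      # correct-classification rate per class
    overall: float            # fraction of all rows classified correctly
    predictions: pd.Series    # per-row predicted class
    skipped: list[str]        # singleton-class rows that could not be tested


def jackknife_rates(
    table: SpeciesMeans,
    priors_mode: str = "proportional",
    regularization: float = 0.0,
) -> JackknifeReport:
    """Leave-one-species-out correct-classification rates.

    Each species is removed, the CVA refit on the rest, and the held-out
    species classified.  Species whose class would vanish from the training
    set (singleton classes) are skipped with a warning.
    """
    labels = table.locomotion
    counts = labels.value_counts()
    skipped, preds = [], {}
    for sp in table.species:
        if counts[labels[sp]] < 2:
            skipped.append(sp)
            continue
        rest = SpeciesMeans(
            values=table.values.drop(index=sp),
            n=table.n.drop(index=sp),
            locomotion=labels.drop(index=sp),
            columns=table.columns,
        )
        model = fit_cva(rest, priors_mode, regularization)
        preds[sp] = classify(model, table.values.loc[sp]).predicted
    if skipped:
        warnings.warn(
            f"skipped singleton-class species in jackknife: {skipped}",
            stacklevel=2,
        )
    predictions = pd.Series(preds)
    correct = predictions == labels[predictions.index]
    per_class = correct.groupby(labels[predictions.index]).mean()
    per_class = per_class.reindex(sorted(labels.unique()))
    return JackknifeReport(
        per_class=per_class,
        overall=float(correct.mean()),
        predictions=predictions,
        skipped=skipped,
    )


def posterior_to_prior_ratio(
    rates: pd.Series, priors: pd.Series
) -> tuple[float, float]:
    """Mean and median over classes of (correct rate / prior class share).

    A ratio of 1 means the classifier does no better than assigning by
    class frequency.
    """
    common = rates.dropna().index.intersection(priors.index)
    pri = priors[common]
    if (pri <= 0).any():
        raise ValueError("zero prior for a class with a classification rate")
    ratio = rates[common] / pri
    return float(ratio.mean()), float(ratio.median())


def group_separation_tests(
    table: SpeciesMeans, n_axes: int = 4, priors_mode: str = "proportional"
) -> dict:
    """MANOVA across locomotor classes plus per-axis ANOVA and Tukey HSD.

    The multivariate test (Pillai's trace by default, Wilks also reported)
    runs on the log-shape variables; univariate follow-ups run on the first
    ``n_axes`` canonical axes.
    """
    from statsmodels.multivariate.manova import MANOVA
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = table.locomotion
    if labels.nunique() < 2:
        raise ValueError("need at least 2 classes")
    X = table.values.to_numpy(float)
    n, p = X.shape
    if n - labels.nunique() < p:
        raise ValueError("too few rows for a MANOVA on all variables")
    frame = table.values.copy()
    frame.columns = [f"v{i}" for i in range(p)]
    frame["group"] = labels.to_numpy()
    mv = MANOVA.from_formula(
        " + ".join(frame.columns[:-1]) + " ~ group", data=frame
    )
    res = mv.mv_test().results["group"]["stat"]
    report = {
        "manova": {
            "pillai": {
                "statistic": float(res.loc["Pillai's trace", "Value"]),
                "F": float(res.loc["Pillai's trace", "F Value"]),
                "p": float(res.loc["Pillai's trace", "Pr > F"]),
            },
            "wilks": {
                "statistic": float(res.loc["Wilks' lambda", "Value"]),
                "F": float(res.loc["Wilks' lambda", "F Value"]),
                "p": float(res.loc["Wilks' lambda", "Pr > F"]),
            },
        },
        "axes": {},
    }
    model = fit_cva(table, priors_mode)
    m = min(n_axes, model.n_axes)
    for j in range(m):
        axis = model.scores.iloc[:, j]
        groups = [axis[(labels == c).to_numpy()] for c in model.classes]
        F, pval = stats.f_oneway(*[g.to_numpy() for g in groups if len(g)])
        tukey = pairwise_tukeyhsd(axis.to_numpy(), labels.to_numpy())
        tk = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        report["axes"][model.scores.columns[j]] = {
            "anova_F": float(F),
            "anova_p": float(pval),
            "tukey": tk,
        }
    return report
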