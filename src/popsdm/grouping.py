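"""Climatic population delineation: PCA, hierarchical clustering with
linkage selection by agglomerative coefficient, and repeated-split linear
discriminant validation.

The PCA operates on the correlation matrix (standardized variables) and
reports loadings as variable-component correlations, the convention used in
climate-niche tables. Hierarchical clustering candidates are scored by the
agglomerative coefficient AC = mean_i (1 - d_first(i) / d_final), where
d_first(i) is the height at which observation i first merges; higher AC
means crisper structure. Population distinctness is validated by repeatedly
fitting a two-class pooled-covariance linear discriminant on a random 50%
of sites and scoring the misclassification ("misjudgment") rate on the
held-out half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger("popsdm")

DEFAULT_LINKAGES = ("single", "complete", "average", "weighted", "ward")


# ---------------------------------------------------------------------------
# PCA on the correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA with loadings as variable-component correlations."""

    loadings: pd.DataFrame          # variables x components
    eigenvalues: np.ndarray         # non-increasing
    percent_variance: np.ndarray
    cumulative_percent: np.ndarray
    scores: np.ndarray              # observations x components

    def table(self) -> pd.DataFrame:
        """Loadings plus the eigenvalue / percent-variance footer rows."""
        out = self.loadings.copy()
        out.loc["Eigenvalues"] = self.eigenvalues
        out.loc["Percent of variance"] = self.percent_variance
        out.loc["Cumulative percent of variance"] = self.cumulative_percent
        return out


def pca(X: pd.DataFrame) -> PCAResult:
    """PCA of standardized variables.

    Constant columns are dropped with a warning. Loadings are reported as
    eigenvector element x sqrt(eigenvalue), i.e. the correlation between
    each variable and each component; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    X = pd.DataFrame(X)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 observations")
    keep = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) > 0]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        logger.warning("pca: dropping constant column(s) %s", dropped)
    X = X[keep]
    A = X.to_numpy(dtype=float)
    Z = (A - A.mean(axis=0)) / A.std(axis=0, ddof=1)
    corr = np.corrcoef(Z, rowvar=False)
    w, V = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for c in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, c]))
        if V[j, c] < 0:
            V[:, c] = -V[:, c]
    load = V * np.sqrt(w)
    pct = 100.0 * w / w.sum()
    comps = [f"PC{i + 1}" for i in range(len(w))]
    return PCAResult(
        loadings=pd.DataFrame(load, index=X.columns, columns=comps),
        eigenvalues=w,
        percent_variance=pct,
        cumulative_percent=np.cumsum(pct),
        scores=Z @ V,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering with linkage selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    method: str
    coefficients: dict[str, float]   # agglomerative coefficient per candidate
    merge_tree: np.ndarray           # scipy linkage matrix of the winner
    labels: np.ndarray               # 1..k cluster labels


def agglomerative_coefficient(Z: np.ndarray, n: int) -> float:
    """AC = mean over observations of (1 - d_first / d_final)."""
    d_first = np.full(n, np.nan)
    for a, b, height, _ in Z:
        for child in (int(a), int(b)):
            if child < n and np.isnan(d_first[child]):
                d_first[child] = height
    d_final = Z[-1, 2]
    if d_final == 0:
        return 0.0
    return float(np.mean(1.0 - d_first / d_final))


def hca(X: pd.DataFrame, k: int = 2,
        candidate_linkages: tuple[str, ...] = DEFAULT_LINKAGES) -> ClusterResult:
    """Agglomerative clustering on Euclidean distances; the linkage with the
    highest agglomerative coefficient wins (ties: first in candidate order),
    and its tree is cut into k groups."""
    X = pd.DataFrame(X)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"cannot cut {n} observations into {k} groups")
    A = X.to_numpy(dtype=float)
    coefs: dict[str, float] = {}
    trees: dict[str, np.ndarray] = {}
    for method in candidate_linkages:
        Z = linkage(A, method=method, metric="euclidean")
        trees[method] = Z
        coefs[method] = agglomerative_coefficient(Z, n)
    best = max(candidate_linkages, key=lambda m: coefs[m])  # first max wins
    labels = fcluster(trees[best], t=k, criterion="maxclust")
    return ClusterResult(best, coefs, trees[best], labels)


# ---------------------------------------------------------------------------
# Repeated-split linear discriminant validation
# ---------------------------------------------------------------------------

@dataclass
class LDAValidation:
    n_reps: int
    split: float
    rates: np.ndarray
    mean: float
    sd: float


@dataclass
class _Discriminant:
    classes: np.ndarray
    means: np.ndarray        # 2 x p
    precision: np.ndarray    # pooled inverse covariance
    log_priors: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        # linear discriminant score per class
        scores = np.empty((X.shape[0], 2))
        for k in range(2):
            w = self.precision @ self.means[k]
            scores[:, k] = X @ w - 0.5 * self.means[k] @ w + self.log_priors[k]
        return self.classes[np.argmax(scores, axis=1)]


def fit_discriminant(X: np.ndarray, y: np.ndarray,
                     priors: str = "proportional") -> _Discriminant:
    """Two-class linear discriminant with pooled within-class covariance.

    A singular pooled covariance is ridge-regularized with
    lambda = 1e-8 * trace (warned)."""
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    groups = [X[y == c] for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each class needs at least 2 members")
    means = np.stack([g.mean(axis=0) for g in groups])
    n0, n1 = len(groups[0]), len(groups[1])
    pooled = (np.cov(groups[0], rowvar=False, ddof=1) * (n0 - 1) +
              np.cov(groups[1], rowvar=False, ddof=1) * (n1 - 1)) / (n0 + n1 - 2)
    pooled = np.atleast_2d(pooled)
    try:
        precision = np.linalg.inv(pooled)
        if not np.all(np.isfinite(precision)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        lam = 1e-8 * np.trace(pooled)
        logger.warning("lda: singular pooled covariance; ridge lambda=%.3g", lam)
        precision = np.linalg.inv(pooled + lam * np.eye(pooled.shape[0]))
    if priors == "proportional":
        pri = np.array([n0, n1], dtype=float) / (n0 + n1)
    elif priors == "equal":
        pri = np.array([0.5, 0.5])
    else:
        raise ValueError("priors must be 'proportional' or 'equal'")
    return _Discriminant(classes, means, precision, np.log(pri))


def lda_misjudgment(X: pd.DataFrame, labels, n_reps: int = 1000,
                    split: float = 0.5, seed: int = 0,
                    priors: str = "proportional") -> LDAValidation:
    """Mean misclassification rate of a two-class linear discriminant over
    repeated unstratified random splits.

    Each repetition draws a random ``split`` fraction for training (redrawn
    if a class is absent from the training half) and scores the held-out
    remainder. Deterministic given ``seed``.
    """
    X = pd.DataFrame(X).to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly two label classes required")
    n = len(y)
    n_train = int(round(n * split))
    if not 0 < n_train < n:
        raise ValueError("split leaves an empty train or test half")
    rng = np.random.default_rng(seed)
    rates = np.empty(n_reps)
    for r in range(n_reps):
        while True:
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if len(np.unique(y[train])) == 2:
                break
        model = fit_discriminant(X[train], y[train], priors=priors)
        pred = model.predict(X[test])
        rates[r] = np.mean(pred != y[test])
    return LDAValidation(n_reps, split, rates, float(rates.mean()),
                         float(rates.std(ddof=1)) if n_reps > 1 else 0.0)
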