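"""Per-feature Kruskal-Wallis screening, canonical linear discriminant
analysis with standardized coefficients, biplot coordinate export, and
complete-linkage heatmap ordering."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


class ScreenError(ValueError):
    pass


@dataclass
class KwResult:
    feature_id: str
    h: float
    p: float
    group_sizes: dict[str, int]


def kruskal_wallis(values, groups, feature_id: str = "") -> KwResult:
    """Kruskal-Wallis H with midranks and the standard tie correction.

    p is the chi-square upper tail with df = (#groups - 1).  All-identical
    values yield H = 0, p = 1 (constant features are silently
    non-significant rather than an error).
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise ScreenError("values and groups must have equal length")
    labels, inverse = np.unique(g, return_inverse=True)
    if len(labels) < 2:
        raise ScreenError("need at least 2 groups")
    sizes = np.bincount(inverse)
    if np.any(sizes == 0):
        raise ScreenError("every group must be nonempty")
    n = x.size
    if n < 3:
        raise ScreenError("need total N >= 3")

    ranks = stats.rankdata(x)  # midranks
    s = sum(ranks[inverse == k].sum() ** 2 / sizes[k] for k in range(len(labels)))
    # single division keeps exact-rank cases exact in floating point
    h = (12.0 * s - 3.0 * n * (n + 1) ** 2) / (n * (n + 1))
    _, tie_counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    denom = 1.0 - tie_term / (n ** 3 - n)
    df = len(labels) - 1
    if denom <= 0:  # all values identical
        h, p = 0.0, 1.0
    else:
        h = max(h / denom, 0.0)
        # df = 2 has the exact closed-form tail exp(-h/2)
        p = math.exp(-h / 2.0) if df == 2 else float(stats.chi2.sf(h, df=df))
    return KwResult(feature_id=feature_id, h=float(h), p=float(p),
                    group_sizes={str(l): int(s) for l, s in zip(labels, sizes)})


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * m / rank)
        adj[order[i]] = running
    return adj


def screen_features(
    data: pd.DataFrame,
    groups: Sequence[str],
    threshold: float = 0.05,
    bh: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """KW test each row of ``data``; retain features with p < threshold
    (strict).  ``bh`` switches the decision to BH-adjusted p-values."""
    if not 0 < threshold <= 1:
        raise ScreenError(f"threshold must be in (0, 1], got {threshold}")
    results = [kruskal_wallis(data.loc[f].values, groups, feature_id=str(f))
               for f in data.index]
    frame = pd.DataFrame({
        "feature_id": [r.feature_id for r in results],
        "h": [r.h for r in results],
        "p": [r.p for r in results],
    }).set_index("feature_id")
    decision_p = benjamini_hochberg(frame["p"].values) if bh else frame["p"].values
    frame["p_adjusted"] = benjamini_hochberg(frame["p"].values)
    frame["retained"] = decision_p < threshold
    retained = list(frame.index[frame["retained"]])
    return retained, frame


_SHRINKAGE_LADDER = (0.0, 1e-8, 1e-6, 1e-4, 1e-2)
_COND_LIMIT = 1e12


@dataclass
class DiscriminantModel:
    features: list[str]
    group_labels: list[str]
    case_ids: list[str]
    groups: list[str]                    # per case
    raw_coef: pd.DataFrame               # features x axes
    std_coef: pd.DataFrame               # features x axes
    scores: pd.DataFrame                 # cases x axes
    centroids: pd.DataFrame              # group x axes
    eigenvalues: np.ndarray
    proportions: np.ndarray
    shrinkage: float
    axis_names: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.raw_coef.shape[1]

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "group_labels": self.group_labels,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "proportions": [float(v) for v in self.proportions],
            "shrinkage": self.shrinkage,
            "raw_coef": {a: [float(v) for v in self.raw_coef[a]] for a in self.raw_coef},
            "std_coef": {a: [float(v) for v in self.std_coef[a]] for a in self.std_coef},
        }


def _scatter_matrices(X: np.ndarray, groups: np.ndarray):
    labels = list(dict.fromkeys(groups))  # first-appearance order
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in labels:
        Xg = X[groups == lab]
        mg = Xg.mean(axis=0)
        D = Xg - mg
        W += D.T @ D
        d = (mg - grand)[:, None]
        B += Xg.shape[0] * (d @ d.T)
    return labels, W, B, grand


def fit_lda(
    data: pd.DataFrame,
    groups: Sequence[str],
    shrinkage: Optional[float] = None,
) -> DiscriminantModel:
    """Canonical discriminant analysis of features x cases ``data``.

    Solves the generalized eigenproblem of between-group scatter against
    the (optionally shrunk) pooled within-group covariance
    ``W_l = (1 - l) W + l (tr(W)/p) I``.  When ``shrinkage`` is None the
    smallest ladder value giving condition number < 1e12 is used — needed
    for many-features/few-cases inputs whose within scatter is singular.
    Case scores carry canonical scaling (pooled within-group covariance of
    scores is the identity on full-rank inputs); axis signs are fixed so
    each axis's largest-|standardized coefficient| is positive.
    """
    if data.shape[0] == 0:
        raise ScreenError("no features to fit")
    groups = np.asarray(groups)
    if groups.size != data.shape[1]:
        raise ScreenError("groups must align with data columns")
    if len(set(groups.tolist())) < 2:
        raise ScreenError("need at least 2 groups")

    X = data.values.T.astype(float)          # cases x features
    n, p = X.shape
    labels, W, B, grand = _scatter_matrices(X, groups)
    g = len(labels)
    dof = max(n - g, 1)
    Sw = W / dof

    if shrinkage is None:
        for lam in _SHRINKAGE_LADDER:
            Swl = (1 - lam) * Sw + lam * (np.trace(Sw) / p) * np.eye(p)
            if np.linalg.cond(Swl) < _COND_LIMIT:
                shrinkage = lam
                break
        else:
            shrinkage = _SHRINKAGE_LADDER[-1]
            Swl = (1 - shrinkage) * Sw + shrinkage * (np.trace(Sw) / p) * np.eye(p)
    else:
        Swl = (1 - shrinkage) * Sw + shrinkage * (np.trace(Sw) / p) * np.eye(p)

    evals, evecs = sla.eigh(B / dof, Swl)    # ascending; evecs' Swl evecs = I
    order = np.argsort(evals)[::-1]
    k = min(g - 1, p)
    order = order[:k]
    evals = np.clip(evals[order], 0.0, None)
    A = evecs[:, order]                      # features x axes, a' Swl a = 1

    within_sd = np.sqrt(np.diag(Sw))
    std = A * within_sd[:, None]
    # axis sign: largest-|std coef| positive
    for j in range(A.shape[1]):
        i = int(np.argmax(np.abs(std[:, j])))
        if std[i, j] < 0:
            A[:, j] *= -1
            std[:, j] *= -1

    scores = (X - grand) @ A
    axis_names = [f"LD{j + 1}" for j in range(k)]
    feat = list(data.index.astype(str))
    case_ids = list(data.columns.astype(str))
    score_df = pd.DataFrame(scores, index=case_ids, columns=axis_names)
    centroids = score_df.groupby(pd.Series(list(groups), index=score_df.index)).mean()
    centroids = centroids.loc[labels]
    total = evals.sum()
    proportions = evals / total if total > 0 else np.zeros_like(evals)
    return DiscriminantModel(
        features=feat,
        group_labels=[str(l) for l in labels],
        case_ids=case_ids,
        groups=[str(x) for x in groups],
        raw_coef=pd.DataFrame(A, index=feat, columns=axis_names),
        std_coef=pd.DataFrame(std, index=feat, columns=axis_names),
        scores=score_df,
        centroids=centroids,
        eigenvalues=evals,
        proportions=proportions,
        shrinkage=float(shrinkage),
        axis_names=axis_names,
    )


@dataclass
class BiplotCoordinates:
    case_scores: pd.DataFrame      # cases x (LD1, LD2)
    centroids: pd.DataFrame        # groups x (LD1, LD2)
    feature_vectors: pd.DataFrame  # features x (LD1, LD2), standardized coefs


def biplot_coordinates(model: DiscriminantModel) -> BiplotCoordinates:
    """Export 2-D biplot coordinates; LD2 zero-filled for 1-axis models."""

    def pad(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        if "LD1" not in out:
            raise ScreenError("model has no axes")
        if "LD2" not in out:
            out["LD2"] = 0.0
        return out[["LD1", "LD2"]]

    return BiplotCoordinates(
        case_scores=pad(model.scores),
        centroids=pad(model.centroids),
        feature_vectors=pad(model.std_coef),
    )


@dataclass
class HclustOrder:
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def _complete_linkage(points: np.ndarray) -> np.ndarray:
    if points.shape[0] < 2:
        raise ScreenError("need at least 2 rows to cluster")
    return hierarchy.linkage(pdist(points, metric="euclidean"), method="complete")


def hclust_complete_order(matrix: pd.DataFrame) -> HclustOrder:
    """Complete-linkage / Euclidean leaf orders for heatmap rows and columns."""
    values = np.asarray(matrix, dtype=float)
    zr = _complete_linkage(values)
    zc = _complete_linkage(values.T)
    return HclustOrder(
        row_order=[int(i) for i in hierarchy.leaves_list(zr)],
        col_order=[int(i) for i in hierarchy.leaves_list(zc)],
        row_linkage=zr,
        col_linkage=zc,
    )
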