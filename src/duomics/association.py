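"""Cross-omic association for unpaired experiments.

Protein and microbe experiments were run separately, so per-substrate
Cartesian products of experiment indices serve as pseudo-paired cases
("bootstrap pairing").  On those cases the module computes Pearson
correlation, a plug-in mutual information on equal-frequency bins,
ridge-regularized canonical correlation analysis with interset/intraset
structure correlations, thresholded edge lists, top-k signed
correlations, and the 2h->24h microbe-microbe association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .data_model import Experiment, FeatureTable

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

@dataclass
class PairIndex:
    """Substrate-matched Cartesian pairing of two experiment designs."""

    x_indices: np.ndarray
    y_indices: np.ndarray
    substrates: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.x_indices)


def build_pair_index(design_x: Sequence[Experiment],
                     design_y: Sequence[Experiment]) -> PairIndex:
    """All (i, j) with matching substrate, ordered by (substrate, i, j)."""
    subs_x = sorted({e.substrate for e in design_x})
    subs_y = {e.substrate for e in design_y}
    common = [s for s in subs_x if s in subs_y]
    if not common:
        raise AssociationError("designs share no substrate")
    xi, yj, ss = [], [], []
    for s in common:
        ix = [i for i, e in enumerate(design_x) if e.substrate == s]
        jy = [j for j, e in enumerate(design_y) if e.substrate == s]
        for i in ix:
            for j in jy:
                xi.append(i)
                yj.append(j)
                ss.append(s)
    return PairIndex(np.array(xi), np.array(yj), np.array(ss, dtype=object))


@dataclass
class PairSet:
    """One protein-microbe pair's pseudo-paired observations."""

    x_id: str
    y_id: str
    x_values: np.ndarray
    y_values: np.ndarray
    substrates: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.x_values)


def build_pair_set(x_table: FeatureTable, x_id: str,
                   y_table: FeatureTable, y_id: str,
                   index: Optional[PairIndex] = None) -> PairSet:
    if index is None:
        index = build_pair_index(x_table.design, y_table.design)
    xv = x_table.data.loc[x_id].to_numpy(dtype=float)[index.x_indices]
    yv = y_table.data.loc[y_id].to_numpy(dtype=float)[index.y_indices]
    return PairSet(str(x_id), str(y_id), xv, yv, index.substrates)


# ---------------------------------------------------------------------------
# per-pair measures
# ---------------------------------------------------------------------------

def pearson_r(pairs: PairSet) -> float:
    """Product-moment correlation over the pair list (pairs equally
    weighted).  Returns NaN for a constant coordinate (flagged undefined
    downstream)."""
    if pairs.n_pairs < 3:
        raise AssociationError("need at least 3 pairs")
    x, y = pairs.x_values, pairs.y_values
    if x.std() == 0 or y.std() == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


def mi_bins(n: int) -> int:
    """Equal-frequency bin count b = clamp(floor(sqrt(n/5)), 2, 10)."""
    return int(min(10, max(2, math.floor(math.sqrt(n / 5)))))


def _quantile_bins(values: np.ndarray, b: int) -> np.ndarray:
    """Assign each value to one of b equal-frequency bins; ties broken by
    (stable) rank order so bins stay as balanced as possible."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=int)
    edges = (np.arange(n) * b) // n
    bins[order] = edges
    return bins


def mutual_information(pairs: PairSet) -> float:
    """Plug-in MI (nats) on a b x b equal-frequency contingency table."""
    n = pairs.n_pairs
    if n < 10:
        raise AssociationError("need at least 10 pairs for MI")
    b = mi_bins(n)
    if n < b * b * 5:
        logger.warning("MI for (%s, %s): n=%d is small for %d bins",
                       pairs.x_id, pairs.y_id, n, b)
    bx = _quantile_bins(pairs.x_values, b)
    by = _quantile_bins(pairs.y_values, b)
    joint = np.zeros((b, b))
    np.add.at(joint, (bx, by), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


@dataclass
class AssociationResult:
    x_id: str
    y_id: str
    r: float
    mi: Optional[float]
    n_pairs: int
    high_threshold: float = 0.7
    strong_threshold: float = 0.8

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)

    @property
    def high(self) -> bool:
        return self.defined and abs(self.r) > self.high_threshold

    @property
    def strong(self) -> bool:
        return self.defined and abs(self.r) > self.strong_threshold

    @property
    def sign(self) -> int:
        if not self.defined or self.r == 0:
            return 0
        return 1 if self.r > 0 else -1


def pairwise_associations(
    x_table: FeatureTable,
    y_table: FeatureTable,
    compute_mi: bool = True,
    high_threshold: float = 0.7,
    strong_threshold: float = 0.8,
) -> list[AssociationResult]:
    """Pearson r (vectorized) and optional MI for every feature pair."""
    index = build_pair_index(x_table.design, y_table.design)
    X = x_table.data.to_numpy(dtype=float)[:, index.x_indices]  # px x n
    Y = y_table.data.to_numpy(dtype=float)[:, index.y_indices]  # py x n
    n = index.n_pairs
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = Xc.std(axis=1)
    ys = Yc.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc / np.where(xs == 0, np.nan, xs)[:, None]) @ \
            (Yc / np.where(ys == 0, np.nan, ys)[:, None]).T / n
    R = np.clip(R, -1.0, 1.0)
    results = []
    for a, x_id in enumerate(x_table.feature_ids):
        for b_, y_id in enumerate(y_table.feature_ids):
            mi = None
            if compute_mi:
                ps = PairSet(str(x_id), str(y_id), X[a], Y[b_], index.substrates)
                mi = mutual_information(ps) if n >= 10 else None
            results.append(AssociationResult(
                str(x_id), str(y_id), float(R[a, b_]), mi, n,
                high_threshold, strong_threshold))
    return results


def associations_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "x_id": [r.x_id for r in results],
        "y_id": [r.y_id for r in results],
        "n_pairs": [r.n_pairs for r in results],
        "r": [r.r for r in results],
        "mi": [r.mi if r.mi is not None else math.nan for r in results],
        "high": [r.high for r in results],
        "strong": [r.strong for r in results],
        "sign": [r.sign for r in results],
    })


def threshold_associations(
    results: Sequence[AssociationResult], tau: float = 0.7,
    strong_tau: float = 0.8,
) -> pd.DataFrame:
    """Edge list with |r| > tau (strict), grouped per microbe for chord
    export; edges above ``strong_tau`` are labeled strong."""
    rows = []
    for r in results:
        if r.defined and abs(r.r) > tau:
            rows.append({
                "source": r.x_id, "target": r.y_id, "weight": r.r,
                "sign": r.sign, "strong": abs(r.r) > strong_tau,
            })
    frame = pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "strong"])
    return frame.sort_values(["target", "source"], kind="stable").reset_index(drop=True)


def top_k_signed(results: Sequence[AssociationResult], k: int = 3
                 ) -> tuple[list[AssociationResult], list[AssociationResult]]:
    """k most negative and k most positive correlations.

    Sorted by signed r; ties broken lexicographically by (x_id, y_id).
    Returns fewer (with a log line) when a sign is underrepresented.
    """
    defined = [r for r in results if r.defined]
    key_neg = sorted((r for r in defined if r.r < 0),
                     key=lambda r: (r.r, r.x_id, r.y_id))
    key_pos = sorted((r for r in defined if r.r > 0),
                     key=lambda r: (-r.r, r.x_id, r.y_id))
    if len(key_neg) < k:
        logger.warning("only %d negative correlations available (k=%d)", len(key_neg), k)
    if len(key_pos) < k:
        logger.warning("only %d positive correlations available (k=%d)", len(key_pos), k)
    return key_neg[:k], key_pos[:k]


def cross_timepoint_association(
    table_2h: FeatureTable,
    table_24h: FeatureTable,
    tau: float = 0.5,
    compute_mi: bool = False,
) -> tuple[list[AssociationResult], pd.DataFrame]:
    """Microbe (2h) x microbe (24h) association via the same pairing
    construction; returns all results and the |r| > tau (strict) edge list."""
    results = pairwise_associations(table_2h, table_24h, compute_mi=compute_mi,
                                    high_threshold=tau)
    edges = threshold_associations(results, tau=tau, strong_tau=tau)
    return results, edges


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

@dataclass
class CcaModel:
    x_features: list[str]
    y_features: list[str]
    correlations: np.ndarray
    x_weights: pd.DataFrame   # features x dims
    y_weights: pd.DataFrame
    x_scores: pd.DataFrame    # cases x dims (unit variance)
    y_scores: pd.DataFrame
    lambda_x: float
    lambda_y: float

    @property
    def n_dims(self) -> int:
        return len(self.correlations)

    def to_dict(self) -> dict:
        return {
            "x_features": self.x_features,
            "y_features": self.y_features,
            "correlations": [float(v) for v in self.correlations],
            "lambda_x": self.lambda_x,
            "lambda_y": self.lambda_y,
            "x_weights": {c: [float(v) for v in self.x_weights[c]] for c in self.x_weights},
            "y_weights": {c: [float(v) for v in self.y_weights[c]] for c in self.y_weights},
        }


def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(S)
    tol = max(S.shape[0], 1) * np.finfo(float).eps * max(evals.max(), 0.0)
    keep = evals > tol
    inv = np.zeros_like(evals)
    inv[keep] = 1.0 / np.sqrt(evals[keep])
    return (evecs * inv) @ evecs.T


def _needs_ridge(S: np.ndarray) -> bool:
    evals = np.linalg.eigvalsh(S)
    return evals.min() <= max(S.shape[0], 1) * np.finfo(float).eps * max(evals.max(), 0.0) \
        or (evals.max() / max(evals.min(), np.finfo(float).tiny)) > 1e12


_DEFAULT_RIDGE = 1e-3


def fit_cca(
    X,
    Y,
    lambda_x: Optional[float] = None,
    lambda_y: Optional[float] = None,
) -> CcaModel:
    """Canonical correlation analysis via whitened cross-covariance SVD.

    Covariance blocks get a ridge ``S + l * mean(diag(S)) * I``; when a
    lambda is None it defaults to 0 for a well-conditioned block and to
    1e-3 for a rank-deficient one.  Canonical correlations are sorted
    descending and clipped to [0, 1]; each dimension's sign is fixed so
    its largest-|weight| x-feature has positive weight.
    """
    Xd = pd.DataFrame(X)
    Yd = pd.DataFrame(Y)
    if Xd.shape[0] != Yd.shape[0]:
        raise AssociationError("X and Y must share the same case axis")
    n = Xd.shape[0]
    if n < 2:
        raise AssociationError("need at least 2 cases")
    Xc = Xd.to_numpy(dtype=float)
    Yc = Yd.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    Yc = Yc - Yc.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    if lambda_x is None:
        lambda_x = _DEFAULT_RIDGE if _needs_ridge(Sxx) else 0.0
    if lambda_y is None:
        lambda_y = _DEFAULT_RIDGE if _needs_ridge(Syy) else 0.0
    dx = float(np.mean(np.diag(Sxx))) or 1.0
    dy = float(np.mean(np.diag(Syy))) or 1.0
    Sxx_r = Sxx + lambda_x * dx * np.eye(Sxx.shape[0])
    Syy_r = Syy + lambda_y * dy * np.eye(Syy.shape[0])
    Wx_half = _inv_sqrt(Sxx_r)
    Wy_half = _inv_sqrt(Syy_r)
    K = Wx_half @ Sxy @ Wy_half
    U, svals, Vt = np.linalg.svd(K)
    k = min(Xc.shape[1], Yc.shape[1], n - 1, len(svals))
    rho = np.clip(svals[:k], 0.0, 1.0)
    A = Wx_half @ U[:, :k]
    Bm = Wy_half @ Vt.T[:, :k]
    # unit-variance variates (exact when lambda = 0; rescaled otherwise)
    for j in range(k):
        sx = float(np.sqrt(A[:, j] @ Sxx @ A[:, j]))
        sy = float(np.sqrt(Bm[:, j] @ Syy @ Bm[:, j]))
        if sx > 0:
            A[:, j] /= sx
        if sy > 0:
            Bm[:, j] /= sy
        i = int(np.argmax(np.abs(A[:, j])))
        if A[i, j] < 0:
            A[:, j] *= -1
            Bm[:, j] *= -1
    dims = [f"CC{j + 1}" for j in range(k)]
    x_feats = [str(c) for c in Xd.columns]
    y_feats = [str(c) for c in Yd.columns]
    case_index = Xd.index
    return CcaModel(
        x_features=x_feats,
        y_features=y_feats,
        correlations=rho,
        x_weights=pd.DataFrame(A, index=x_feats, columns=dims),
        y_weights=pd.DataFrame(Bm, index=y_feats, columns=dims),
        x_scores=pd.DataFrame(Xc @ A, index=case_index, columns=dims),
        y_scores=pd.DataFrame(Yc @ Bm, index=case_index, columns=dims),
        lambda_x=float(lambda_x),
        lambda_y=float(lambda_y),
    )


@dataclass
class StructureCorrelations:
    x_intraset: pd.DataFrame
    x_interset: pd.DataFrame
    y_intraset: pd.DataFrame
    y_interset: pd.DataFrame


def _corr_with_scores(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    Bc = block - block.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    bs = Bc.std(axis=0)
    ss = Sc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Bc / np.where(bs == 0, np.nan, bs)).T @ (Sc / np.where(ss == 0, np.nan, ss))
    return out / block.shape[0]


def structure_correlations(model: CcaModel, X, Y) -> StructureCorrelations:
    """Intraset correlations (feature vs own-block variate) computed
    directly; interset = rho_k * intraset, the CCA stationarity identity."""
    Xd = pd.DataFrame(X).to_numpy(dtype=float)
    Yd = pd.DataFrame(Y).to_numpy(dtype=float)
    dims = list(model.x_scores.columns)
    xi = _corr_with_scores(Xd, model.x_scores.to_numpy())
    yi = _corr_with_scores(Yd, model.y_scores.to_numpy())
    rho = model.correlations
    return StructureCorrelations(
        x_intraset=pd.DataFrame(xi, index=model.x_features, columns=dims),
        x_interset=pd.DataFrame(xi * rho, index=model.x_features, columns=dims),
        y_intraset=pd.DataFrame(yi, index=model.y_features, columns=dims),
        y_interset=pd.DataFrame(yi * rho, index=model.y_features, columns=dims),
    )


def paired_blocks(x_table: FeatureTable, y_table: FeatureTable,
                  x_features: Optional[Sequence[str]] = None,
                  y_features: Optional[Sequence[str]] = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame, PairIndex]:
    """Assemble the consistent CCA case axis: per substrate, every
    (x-experiment, y-experiment) index pair, with every included feature
    read at those indices."""
    index = build_pair_index(x_table.design, y_table.design)
    xf = list(x_features) if x_features is not None else x_table.feature_ids
    yf = list(y_features) if y_features is not None else y_table.feature_ids
    Xb = x_table.data.loc[xf].to_numpy(dtype=float)[:, index.x_indices].T
    Yb = y_table.data.loc[yf].to_numpy(dtype=float)[:, index.y_indices].T
    cases = [f"{s}:{i}:{j}" for s, i, j in
             zip(index.substrates, index.x_indices, index.y_indices)]
    return (pd.DataFrame(Xb, index=cases, columns=xf),
            pd.DataFrame(Yb, index=cases, columns=yf), index)
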