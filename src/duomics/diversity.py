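"""Descriptive microbiome statistics: Shannon diversity, Bray-Curtis
dissimilarity, principal coordinates analysis, and the per-taxon log2
median-proportion differential."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AsvAbundanceTable


class DiversityError(ValueError):
    pass


def shannon(counts, base: float = math.e) -> float:
    """H = -sum p_i log p_i over taxa with positive counts (natural log by
    default; ``base`` switches the logarithm)."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise DiversityError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise DiversityError("all-zero count vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base != math.e:
        h /= math.log(base)
    return h


def bray_curtis(u, v) -> float:
    """sum|u - v| / sum(u + v); 0 for identical, 1 for disjoint supports."""
    a = np.asarray(u, dtype=float)
    b = np.asarray(v, dtype=float)
    if a.shape != b.shape:
        raise DiversityError("vectors must have equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise DiversityError("vectors must be nonnegative")
    denom = (a + b).sum()
    if denom <= 0:
        raise DiversityError("both vectors are all-zero")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(table: AsvAbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between experiment columns."""
    cols = table.experiment_ids
    vals = table.data.to_numpy(dtype=float)
    n = len(cols)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(vals[:, i], vals[:, j])
    return pd.DataFrame(D, index=cols, columns=cols)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # cases x axes (positive eigenvalues only)
    eigenvalues: np.ndarray         # all, sorted descending
    proportions: np.ndarray         # over positive eigenvalues, per kept axis
    negative_mass: float            # sum |negative eigenvalues| (diagnostic)


def pcoa(distance: pd.DataFrame | np.ndarray, k: int | None = None) -> OrdinationResult:
    """Classical PCoA: Gower double-centering of -D^2/2, eigendecomposition,
    coordinates scaled by sqrt(eigenvalue) on positive axes.  Negative
    eigenvalues are reported, not corrected."""
    if isinstance(distance, pd.DataFrame):
        labels = list(distance.index)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        labels = list(range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DiversityError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise DiversityError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise DiversityError("distance matrix must have zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = 1e-12 * max(abs(evals[0]), 1.0) if n else 0.0
    positive = evals > tol
    coords = evecs[:, positive] * np.sqrt(evals[positive])
    if k is not None:
        coords = coords[:, :k]
    pos_sum = evals[positive].sum()
    kept = coords.shape[1]
    proportions = (evals[positive][:kept] / pos_sum) if pos_sum > 0 else np.zeros(kept)
    axes = [f"PCo{j + 1}" for j in range(kept)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=evals,
        proportions=proportions,
        negative_mass=float(np.abs(evals[evals < -tol]).sum()),
    )


#: output cap for the log2 median-proportion differential
_LOG2_CAP = 20.0


def log2_median_proportion(
    proportions: pd.DataFrame,
    group_a_columns: list[str],
    group_b_columns: list[str],
) -> pd.Series:
    """Per-taxon log2((median_A + d) / (median_B + d)) on a proportion
    table; d = 0.1 * smallest nonzero proportion guards the zero medians.
    Output is capped at +/-20.  Positive values mark group-A dominance."""
    if not group_a_columns or not group_b_columns:
        raise DiversityError("both groups must be nonempty")
    vals = proportions.to_numpy(dtype=float)
    nonzero = vals[vals > 0]
    delta = 0.1 * float(nonzero.min()) if nonzero.size else 1e-12
    med_a = proportions[group_a_columns].median(axis=1)
    med_b = proportions[group_b_columns].median(axis=1)
    out = np.log2((med_a + delta) / (med_b + delta))
    return out.clip(-_LOG2_CAP, _LOG2_CAP)
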