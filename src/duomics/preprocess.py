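"""Preprocessing: skewness-minimizing constant imputation, offset-log
transform with a closed-form offset, proportion scaling, annotation
aggregation, and replicate averaging.

The imputation replaces every missing intensity with one global constant
``c`` in ``(0, min present value]`` chosen to minimize the absolute value
of Pearson's second skewness coefficient of the pooled distribution
(pooled over all substrates and replicates).  When ``mean(c) - median(c)``
changes sign on the interval the minimizer is its root (mean equals
median there and the skewness coefficient is exactly zero); otherwise a
bounded scalar search finds the boundary argmin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import (
    AnnotationMap,
    AsvAbundanceTable,
    FeatureTable,
    ProteinIntensityTable,
    TransformedTable,
)


class PreprocessError(ValueError):
    pass


def pearson_second_skewness(values) -> float:
    """3 * (mean - median) / sd with sample sd (denominator n-1).

    Location-invariant; raises for fewer than 2 values or zero sd.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise PreprocessError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise PreprocessError("degenerate distribution: sd is zero")
    return float(3.0 * (x.mean() - np.median(x)) / sd)


@dataclass
class ImputationResult:
    constant: Optional[float]
    sk2_before: Optional[float]
    sk2_after: Optional[float]
    n_imputed: int
    search_interval: Optional[tuple[float, float]]
    sign_change: bool = False
    scale: str = "raw"

    @property
    def applicable(self) -> bool:
        return self.constant is not None

    def to_dict(self) -> dict:
        return {
            "constant": self.constant,
            "sk2_before": self.sk2_before,
            "sk2_after": self.sk2_after,
            "n_imputed": self.n_imputed,
            "search_interval": list(self.search_interval) if self.search_interval else None,
            "sign_change": self.sign_change,
            "scale": self.scale,
        }


def _pooled_stats(present: np.ndarray, n_missing: int, c: float, scale: str):
    fill = math.log10(c) if scale == "log10" else c
    pooled = np.concatenate([present, np.full(n_missing, fill)])
    return pooled


def _sk2_at(present: np.ndarray, n_missing: int, c: float, scale: str) -> float:
    return pearson_second_skewness(_pooled_stats(present, n_missing, c, scale))


def _mean_minus_median(present: np.ndarray, n_missing: int, c: float, scale: str) -> float:
    pooled = _pooled_stats(present, n_missing, c, scale)
    return float(pooled.mean() - np.median(pooled))


# relative lower bound of the search interval: strictly positive so the
# log10 objective stays defined
_LOW_FACTOR = 1e-9
_TOL = 1e-9


def fit_imputation_constant(
    table: ProteinIntensityTable, scale: str = "raw"
) -> ImputationResult:
    """Fit the single global imputation constant.

    ``scale`` selects the space in which skewness is minimized: ``"raw"``
    (default) or ``"log10"``.
    """
    if scale not in ("raw", "log10"):
        raise PreprocessError(f"unknown skewness scale {scale!r}")
    vals = table.data.values
    mask = np.isnan(vals)
    n_missing = int(mask.sum())
    present_raw = vals[~mask]
    if n_missing == 0:
        return ImputationResult(None, None, None, 0, None, scale=scale)
    if present_raw.size < 2:
        raise PreprocessError("need at least 2 present values to fit imputation")

    high = float(present_raw.min())
    low = _LOW_FACTOR * high
    present = np.log10(present_raw) if scale == "log10" else present_raw

    # baseline: every missing cell held at the detection-limit proxy (the
    # minimum present value) — the "no imputation choice" endpoint of the
    # search interval, so the fitted constant can never be worse
    try:
        sk2_before = _sk2_at(present, n_missing, high, scale)
    except PreprocessError:
        sk2_before = None

    def g(c: float) -> float:
        return _mean_minus_median(present, n_missing, c, scale)

    g_low, g_high = g(low), g(high)
    sign_change = (g_low == 0.0) or (g_high == 0.0) or (g_low * g_high < 0)
    if sign_change:
        if g_low == 0.0:
            c = low
        elif g_high == 0.0:
            c = high
        else:
            c = float(optimize.brentq(g, low, high,
                                      xtol=_TOL * (high - low), rtol=1e-15))
    else:
        # no root: boundary argmin of |Sk2| via coarse grid + local refinement
        grid = np.linspace(low, high, 4001)
        obj = np.array([abs(_sk2_at(present, n_missing, c, scale)) for c in grid])
        k = int(np.argmin(obj))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda c: abs(_sk2_at(present, n_missing, c, scale)),
            bounds=(lo, hi), method="bounded",
            options={"xatol": _TOL * (high - low)})
        c = float(res.x) if res.fun <= obj[k] else float(grid[k])

    c = min(max(c, low), high)
    sk2_after = _sk2_at(present, n_missing, c, scale)
    return ImputationResult(
        constant=float(c),
        sk2_before=sk2_before,
        sk2_after=float(sk2_after),
        n_imputed=n_missing,
        search_interval=(float(low), float(high)),
        sign_change=bool(sign_change),
        scale=scale,
    )


def apply_imputation(table: ProteinIntensityTable, c: float) -> ProteinIntensityTable:
    """Replace every missing cell with the constant ``c``.

    ``c`` must lie in (0, min present value]; idempotent on complete tables.
    """
    vals = table.data.values
    present = vals[~np.isnan(vals)]
    if present.size and not (0 < c <= present.min() * (1 + 1e-12)):
        raise PreprocessError(
            f"imputation constant {c} outside (0, {present.min()}]"
        )
    data = table.data.fillna(c)
    return ProteinIntensityTable(data, table.design)


@dataclass
class OffsetSpec:
    alpha: float
    min_nonzero: float
    base: int = 10
    bracket: str = "floor"

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "min_nonzero": self.min_nonzero,
                "base": self.base, "bracket": self.bracket}


def offset_alpha_from_values(values, bracket: str = "floor") -> OffsetSpec:
    """Closed-form offset from a bare array of abundances."""
    vals = np.asarray(values, dtype=float)
    positive = vals[vals > 0]
    if positive.size == 0:
        raise PreprocessError("no nonzero minimum exists: all abundances are zero")
    m = float(positive.min())
    if bracket == "floor":
        k = math.floor(math.log10(m))
    elif bracket == "round":
        k = round(math.log10(m))
    else:
        raise PreprocessError(f"unknown bracket convention {bracket!r}")
    return OffsetSpec(alpha=10.0 ** (k - 1), min_nonzero=m, bracket=bracket)


def offset_alpha(table: AsvAbundanceTable, bracket: str = "floor") -> OffsetSpec:
    """Closed-form offset: alpha = 10^(floor(log10(m)) - 1) where m is the
    smallest strictly positive abundance in the table.  ``bracket="round"``
    swaps the floor for round-half-even.
    """
    return offset_alpha_from_values(table.data.values, bracket)


def offset_log(table: AsvAbundanceTable, spec: OffsetSpec) -> TransformedTable:
    """x -> log10(alpha + x), applied cellwise; strictly monotone in x.

    The result may contain negative values (zeros map to log10(alpha)),
    so it is returned as an unconstrained :class:`TransformedTable`.
    """
    return TransformedTable(offset_log_frame(table.data, spec), table.design)


def offset_log_frame(data: pd.DataFrame, spec: OffsetSpec) -> pd.DataFrame:
    if spec.alpha <= 0:
        raise PreprocessError("alpha must be > 0")
    return np.log10(spec.alpha + data)


def total_sum_scale(table: AsvAbundanceTable) -> AsvAbundanceTable:
    """Scale each experiment column to proportions summing to 1."""
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if not zero.empty:
        raise PreprocessError(f"zero-sum experiment column(s): {list(zero.index)}")
    return AsvAbundanceTable(table.data / sums, table.design, taxonomy=table.taxonomy)


def aggregate_by_annotation(
    table: ProteinIntensityTable, amap: AnnotationMap, category: str
) -> pd.DataFrame:
    """Sum imputed intensities over each annotation label's member proteins.

    Proteins carrying k labels contribute to all k sums; labels with no
    member present in the table are omitted.  Requires a complete table.
    """
    if table.n_missing:
        raise PreprocessError("aggregate_by_annotation requires an imputed table")
    members = amap.category(category)
    rows = {}
    for label in amap.labels(category):
        pids = [p for p, labels in members.items() if label in labels and p in table.data.index]
        if pids:
            rows[label] = table.data.loc[pids].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "label"
    if out.empty:
        out = pd.DataFrame(columns=table.data.columns)
        out.index.name = "label"
    return out


def average_replicates(table: FeatureTable, by_timepoint: bool = True) -> pd.DataFrame:
    """Arithmetic mean per (feature, substrate[, timepoint]) group.

    Column labels are the substrate, or ``substrate:timepoint`` when the
    design carries timepoints and ``by_timepoint`` is true.  Missing values
    propagate (mean over present values only is NOT taken: impute first).
    """
    groups: dict[str, list[str]] = {}
    for e in table.design:
        if by_timepoint and e.timepoint is not None:
            key = f"{e.substrate}:{e.timepoint}"
        else:
            key = e.substrate
        groups.setdefault(key, []).append(e.experiment_id)
    out = pd.DataFrame({key: table.data[cols].mean(axis=1) for key, cols in groups.items()})
    out.index.name = table.data.index.name
    return out
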