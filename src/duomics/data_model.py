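"""Typed feature tables, experiment design metadata, and TSV I/O.

Two table flavours are supported: protein intensity tables (missing values
allowed, encoded as NaN internally and as empty cells / ``NA`` in TSV) and
ASV abundance tables (zeros allowed, missing values are not).  Experiment
metadata (substrate, optional timepoint, replicate) lives in a sidecar
design TSV.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default substrate vocabulary; extensible by passing ``vocabulary=`` to
#: the readers / constructors.
SUBSTRATES = ("dentine", "enamel", "titanium")

TIMEPOINTS = ("2h", "24h")

#: Annotation categories accepted by :func:`read_annotation_map`.
MOLECULAR_FUNCTION = "molecular_function"
BIOLOGICAL_PROCESS = "biological_process"
ANNOTATION_CATEGORIES = (MOLECULAR_FUNCTION, BIOLOGICAL_PROCESS)

MISSING_TOKEN = "NA"


class DataModelError(ValueError):
    """Raised on malformed tables, designs, or annotation files."""


def canonical_substrate(label: str, vocabulary: Sequence[str] = SUBSTRATES) -> str:
    """Canonicalize a substrate label: strip whitespace, lowercase ASCII.

    Raises :class:`DataModelError` if the canonical form is not in the
    vocabulary.
    """
    canon = str(label).strip().lower()
    if canon not in vocabulary:
        raise DataModelError(
            f"unknown substrate label {label!r} (canonical {canon!r}); "
            f"expected one of {sorted(vocabulary)}"
        )
    return canon


@dataclass(frozen=True)
class Experiment:
    """One measured experiment (a table column)."""

    experiment_id: str
    substrate: str
    timepoint: Optional[str] = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise DataModelError(
                f"experiment {self.experiment_id!r}: unknown timepoint "
                f"{self.timepoint!r}; expected one of {TIMEPOINTS}"
            )


def validate_design(
    design: Sequence[Experiment],
    *,
    require_timepoint: bool = False,
    forbid_timepoint: bool = False,
) -> None:
    ids = [e.experiment_id for e in design]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataModelError(f"duplicate experiment ids in design: {dupes}")
    for e in design:
        if require_timepoint and e.timepoint is None:
            raise DataModelError(
                f"experiment {e.experiment_id!r}: timepoint required for microbial experiments"
            )
        if forbid_timepoint and e.timepoint is not None:
            raise DataModelError(
                f"experiment {e.experiment_id!r}: timepoint must be absent for proteomic experiments"
            )


class FeatureTable:
    """Base class: features x experiments matrix plus aligned design."""

    kind = "feature"

    def __init__(self, data: pd.DataFrame, design: Sequence[Experiment]):
        if list(data.columns) != [e.experiment_id for e in design]:
            raise DataModelError("table columns do not match design experiment ids")
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise DataModelError(f"duplicate feature ids: {dupes}")
        self.data = data.astype(float)
        self.design = list(design)
        self._validate()

    # subclasses override
    def _validate(self) -> None:  # pragma: no cover - abstract hook
        pass

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def substrates(self) -> np.ndarray:
        return np.array([e.substrate for e in self.design])

    @property
    def timepoints(self) -> np.ndarray:
        return np.array([e.timepoint for e in self.design], dtype=object)

    def experiments_for(self, substrate: str, timepoint: Optional[str] = None) -> list[str]:
        out = []
        for e in self.design:
            if e.substrate != substrate:
                continue
            if timepoint is not None and e.timepoint != timepoint:
                continue
            out.append(e.experiment_id)
        return out

    def subset_experiments(self, experiment_ids: Sequence[str]) -> "FeatureTable":
        keep = set(experiment_ids)
        design = [e for e in self.design if e.experiment_id in keep]
        data = self.data[[e.experiment_id for e in design]]
        return type(self)(data, design, **self._subset_kwargs())

    def _subset_kwargs(self) -> dict:
        return {}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.design == other.design
            and self.data.index.equals(other.data.index)
            and np.array_equal(self.data.values, other.data.values, equal_nan=True)
        )


class ProteinIntensityTable(FeatureTable):
    """Nonnegative intensities with NaN as the explicit missing marker."""

    kind = "protein"

    def _validate(self) -> None:
        validate_design(self.design, forbid_timepoint=True)
        vals = self.data.values
        present = ~np.isnan(vals)
        if np.any(vals[present] <= 0):
            bad = self.data.index[np.nanmin(np.where(present, vals, np.inf), axis=1) <= 0]
            raise DataModelError(
                f"protein intensities must be strictly positive; offending: {list(bad)[:5]}"
            )
        if np.any(~present.any(axis=1)):
            empty = list(self.data.index[~present.any(axis=1)])
            raise DataModelError(f"proteins with no present value: {empty[:5]}")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.data.values).sum())


class AsvAbundanceTable(FeatureTable):
    """Nonnegative abundances (zeros allowed); optional taxonomy labels."""

    kind = "asv"

    def __init__(
        self,
        data: pd.DataFrame,
        design: Sequence[Experiment],
        taxonomy: Optional[Mapping[str, str]] = None,
    ):
        self.taxonomy = dict(taxonomy) if taxonomy else {}
        super().__init__(data, design)

    def _validate(self) -> None:
        validate_design(self.design, require_timepoint=True)
        vals = self.data.values
        if np.any(np.isnan(vals)):
            raise DataModelError("ASV tables may not contain missing values")
        if np.any(vals < 0):
            bad = list(self.data.index[(vals < 0).any(axis=1)])
            raise DataModelError(f"negative abundance for: {bad[:5]}")

    def _subset_kwargs(self) -> dict:
        return {"taxonomy": self.taxonomy}

    def split_timepoints(self) -> dict[str, "AsvAbundanceTable"]:
        """Return one table per timepoint present in the design."""
        out: dict[str, AsvAbundanceTable] = {}
        for tp in TIMEPOINTS:
            ids = [e.experiment_id for e in self.design if e.timepoint == tp]
            if ids:
                out[tp] = self.subset_experiments(ids)  # type: ignore[assignment]
        return out


class TransformedTable(FeatureTable):
    """Unconstrained real-valued matrix produced by a transform stage.

    Keeps the feature x experiment layout and design alignment but drops
    the nonnegativity/missingness contracts of the source tables.
    """

    kind = "transformed"

    def _validate(self) -> None:
        validate_design(self.design)
        if np.any(np.isnan(self.data.values)):
            raise DataModelError("transformed tables may not contain missing values")


@dataclass
class AnnotationMap:
    """protein -> label sets, per annotation category."""

    molecular_function: dict[str, set[str]] = field(default_factory=dict)
    biological_process: dict[str, set[str]] = field(default_factory=dict)

    def category(self, name: str) -> dict[str, set[str]]:
        if name == MOLECULAR_FUNCTION:
            return self.molecular_function
        if name == BIOLOGICAL_PROCESS:
            return self.biological_process
        raise DataModelError(
            f"unknown annotation category {name!r}; expected one of {ANNOTATION_CATEGORIES}"
        )

    def add(self, protein_id: str, category: str, label: str) -> None:
        label = str(label).strip()
        if not label:
            raise DataModelError(f"empty annotation label for protein {protein_id!r}")
        self.category(category).setdefault(protein_id, set()).add(label)

    def labels(self, category: str) -> list[str]:
        out: set[str] = set()
        for labels in self.category(category).values():
            out |= labels
        return sorted(out)


@dataclass
class DetectionSummary:
    """Per-substrate detection counts and Venn-region decomposition.

    A protein counts as detected on a substrate iff it has at least one
    present (non-missing) value among that substrate's experiments.
    """

    detected: dict[str, set[str]]

    @property
    def substrates(self) -> list[str]:
        return sorted(self.detected)

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(v) for s, v in sorted(self.detected.items())}

    @property
    def pairwise_shared(self) -> dict[tuple[str, str], int]:
        return {
            (a, b): len(self.detected[a] & self.detected[b])
            for a, b in combinations(self.substrates, 2)
        }

    @property
    def all_shared(self) -> int:
        sets = list(self.detected.values())
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return len(out)

    @property
    def union_count(self) -> int:
        out: set[str] = set()
        for s in self.detected.values():
            out |= s
        return len(out)

    @property
    def exclusives(self) -> dict[str, list[str]]:
        out = {}
        for s in self.substrates:
            others: set[str] = set()
            for t, v in self.detected.items():
                if t != s:
                    others |= v
            out[s] = sorted(self.detected[s] - others)
        return out

    def region_counts(self) -> dict[str, int]:
        """Counts of every exact Venn region, keyed by '+'-joined substrates."""
        subs = self.substrates
        out: dict[str, int] = {}
        for r in range(1, len(subs) + 1):
            for combo in combinations(subs, r):
                members = set(self.detected[combo[0]])
                for s in combo[1:]:
                    members &= self.detected[s]
                for s in subs:
                    if s not in combo:
                        members -= self.detected[s]
                out["+".join(combo)] = len(members)
        return out

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "pairwise_shared": {f"{a}+{b}": n for (a, b), n in self.pairwise_shared.items()},
            "all_shared": self.all_shared,
            "union": self.union_count,
            "exclusive": self.exclusives,
            "regions": self.region_counts(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": k, "count": v} for k, v in sorted(self.region_counts().items())]
        return pd.DataFrame(rows)


def summarize_detection(table: ProteinIntensityTable) -> DetectionSummary:
    """Venn decomposition of per-substrate detected protein sets."""
    subs = sorted(set(table.substrates))
    if len(subs) < 2:
        raise DataModelError("detection summary requires >=2 substrates")
    detected: dict[str, set[str]] = {}
    for s in subs:
        cols = table.experiments_for(s)
        present = table.data[cols].notna().any(axis=1)
        detected[s] = set(table.data.index[present])
    return DetectionSummary(detected=detected)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_design(path: str | Path, vocabulary: Sequence[str] = SUBSTRATES) -> list[Experiment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"experiment_id", "substrate"}
    if not required.issubset(df.columns):
        raise DataModelError(f"design file {path} must have columns {sorted(required)}")
    design = []
    for _, row in df.iterrows():
        tp = row.get("timepoint", "")
        tp = tp.strip() if isinstance(tp, str) else ""
        rep = row.get("replicate", "")
        design.append(
            Experiment(
                experiment_id=row["experiment_id"].strip(),
                substrate=canonical_substrate(row["substrate"], vocabulary),
                timepoint=tp or None,
                replicate=int(rep) if str(rep).strip() else 1,
            )
        )
    validate_design(design)
    return design


def write_design(design: Sequence[Experiment], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "experiment_id": [e.experiment_id for e in design],
            "substrate": [e.substrate for e in design],
            "timepoint": [e.timepoint or "" for e in design],
            "replicate": [e.replicate for e in design],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _parse_cell(raw: str, feature: str, column: str, allow_missing: bool) -> float:
    text = raw.strip()
    if text == "" or text == MISSING_TOKEN:
        if allow_missing:
            return math.nan
        raise DataModelError(
            f"missing value not allowed at feature {feature!r}, column {column!r}"
        )
    try:
        value = float(text)
    except ValueError:
        raise DataModelError(
            f"non-numeric cell {raw!r} at feature {feature!r}, column {column!r}"
        ) from None
    if value < 0:
        raise DataModelError(
            f"negative value {value} at feature {feature!r}, column {column!r}"
        )
    return value


def read_feature_table(
    path: str | Path,
    schema: str,
    design: str | Path | Sequence[Experiment],
    vocabulary: Sequence[str] = SUBSTRATES,
) -> FeatureTable:
    """Read a TSV feature table with its (path or in-memory) design.

    The first column is the feature id; for ASV tables an optional second
    column named ``taxonomy`` carries taxonomy labels.  Remaining columns
    must match the design's experiment ids (order preserved).
    """
    if schema not in ("protein", "asv"):
        raise DataModelError(f"unknown schema {schema!r}; expected 'protein' or 'asv'")
    if isinstance(design, (str, Path)):
        design = read_design(design, vocabulary)
    design = list(design)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise DataModelError(f"feature table {path} has no experiment columns")
    id_col = raw.columns[0]
    ids = [s.strip() for s in raw[id_col]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataModelError(f"duplicate feature id(s): {dupes}")
    taxonomy: dict[str, str] = {}
    value_cols = list(raw.columns[1:])
    if schema == "asv" and value_cols and value_cols[0] == "taxonomy":
        taxonomy = {
            fid: tax.strip() for fid, tax in zip(ids, raw["taxonomy"]) if tax.strip()
        }
        value_cols = value_cols[1:]
    expected = [e.experiment_id for e in design]
    if value_cols != expected:
        raise DataModelError(
            f"experiment columns {value_cols} do not match design {expected}"
        )
    allow_missing = schema == "protein"
    values = np.empty((len(ids), len(value_cols)))
    for j, col in enumerate(value_cols):
        for i, cell in enumerate(raw[col]):
            values[i, j] = _parse_cell(cell, ids[i], col, allow_missing)
    data = pd.DataFrame(values, index=pd.Index(ids, name="feature_id"), columns=value_cols)
    if schema == "protein":
        return ProteinIntensityTable(data, design)
    return AsvAbundanceTable(data, design, taxonomy=taxonomy)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    design_path: Optional[str | Path] = None,
) -> None:
    """Write a feature table (and optionally its design) to TSV.

    Missing protein intensities are written as the ``NA`` token.
    """
    df = table.data.copy()
    out = pd.DataFrame(index=df.index)
    out.index.name = "feature_id"
    if isinstance(table, AsvAbundanceTable) and table.taxonomy:
        out["taxonomy"] = [table.taxonomy.get(f, "") for f in df.index]
    for col in df.columns:
        # repr round-trips float64 exactly
        out[col] = [MISSING_TOKEN if math.isnan(v) else repr(v) for v in df[col]]
    out.to_csv(path, sep="\t")
    if design_path is not None:
        write_design(table.design, design_path)


def read_annotation_map(path: str | Path) -> AnnotationMap:
    """Read (protein_id, category, label) rows into an :class:`AnnotationMap`."""
    amap = AnnotationMap()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return amap
    if df.empty and df.shape[1] == 0:
        return amap
    required = {"protein_id", "category", "label"}
    if not required.issubset(df.columns):
        raise DataModelError(f"annotation file {path} must have columns {sorted(required)}")
    for _, row in df.iterrows():
        amap.add(row["protein_id"].strip(), row["category"].strip(), row["label"])
    return amap


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    rows = []
    for category in ANNOTATION_CATEGORIES:
        for pid, labels in sorted(amap.category(category).items()):
            for label in sorted(labels):
                rows.append({"protein_id": pid, "category": category, "label": label})
    pd.DataFrame(rows, columns=["protein_id", "category", "label"]).to_csv(
        path, sep="\t", index=False
    )


def log_unmatched_annotations(amap: AnnotationMap, table: ProteinIntensityTable) -> list[str]:
    """Log (and return) annotated proteins absent from the intensity table.

    They stay in the map; aggregation simply never sees them.
    """
    known = set(table.feature_ids)
    annotated = set(amap.molecular_function) | set(amap.biological_process)
    unmatched = sorted(annotated - known)
    if unmatched:
        logger.info("annotation map has %d proteins absent from table: %s",
                    len(unmatched), unmatched[:10])
    return unmatched
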