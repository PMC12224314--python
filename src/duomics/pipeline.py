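"""Pipeline orchestration: simulate/read -> impute/transform -> screen ->
LDA -> associate -> CCA -> diversity -> report bundle.

Every stage is a pure function of (inputs, config, seed); the bundle is
byte-identical across repeats at a fixed seed.  Thresholds live in the
config; stage code never hard-codes them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association, diversity, preprocess, screen
from .data_model import (
    AsvAbundanceTable,
    ProteinIntensityTable,
    read_annotation_map,
    read_feature_table,
    summarize_detection,
    write_feature_table,
    MOLECULAR_FUNCTION,
    BIOLOGICAL_PROCESS,
)
from .synthetic import SyntheticConfig, simulate_all

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Thresholds:
    kw_protein: float = 0.05
    kw_microbe: float = 0.01
    corr_high: float = 0.7
    corr_strong: float = 0.8
    corr_cross_time: float = 0.5
    top_k: int = 3

    def validate(self) -> None:
        for name in ("kw_protein", "kw_microbe"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        for name in ("corr_high", "corr_strong", "corr_cross_time"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.top_k < 1:
            raise ConfigError(f"top_k must be >= 1, got {self.top_k}")


@dataclass
class TransformOptions:
    skewness_scale: str = "raw"          # or "log10"
    alpha_bracket: str = "floor"         # or "round"
    lda_shrinkage: Optional[float] = None
    cca_lambda: Optional[float] = None
    # scale on which imputed protein levels enter association/CCA; LFQ
    # intensities are lognormal, so log10 is the default correlation scale
    association_protein_scale: str = "log10"

    def validate(self) -> None:
        if self.skewness_scale not in ("raw", "log10"):
            raise ConfigError(f"skewness_scale must be raw|log10, got {self.skewness_scale!r}")
        if self.alpha_bracket not in ("floor", "round"):
            raise ConfigError(f"alpha_bracket must be floor|round, got {self.alpha_bracket!r}")
        if self.association_protein_scale not in ("raw", "log10"):
            raise ConfigError(
                f"association_protein_scale must be raw|log10, "
                f"got {self.association_protein_scale!r}")


#: natural (biotic) vs artificial (abiotic) substrate grouping
DEFAULT_GROUP_MAP = {"dentine": "natural", "enamel": "natural", "titanium": "artificial"}


@dataclass
class RunConfig:
    simulate: Optional[SyntheticConfig] = None
    protein_path: Optional[str] = None
    protein_design_path: Optional[str] = None
    asv_2h_path: Optional[str] = None
    asv_2h_design_path: Optional[str] = None
    asv_24h_path: Optional[str] = None
    asv_24h_design_path: Optional[str] = None
    annotation_path: Optional[str] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    transform: TransformOptions = field(default_factory=TransformOptions)
    group_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))
    seed: int = 0

    def validate(self) -> None:
        self.thresholds.validate()
        self.transform.validate()
        if self.simulate is None:
            needed = [self.protein_path, self.protein_design_path,
                      self.asv_2h_path, self.asv_2h_design_path,
                      self.asv_24h_path, self.asv_24h_design_path]
            if any(p is None for p in needed):
                raise ConfigError("either a simulate block or all input paths are required")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = raw.get("simulate")
        simulate = SyntheticConfig(**sim) if isinstance(sim, dict) else None
        inputs = raw.get("inputs", {})
        cfg = cls(
            simulate=simulate,
            protein_path=inputs.get("protein"),
            protein_design_path=inputs.get("protein_design"),
            asv_2h_path=inputs.get("asv_2h"),
            asv_2h_design_path=inputs.get("asv_2h_design"),
            asv_24h_path=inputs.get("asv_24h"),
            asv_24h_design_path=inputs.get("asv_24h_design"),
            annotation_path=inputs.get("annotation"),
            thresholds=Thresholds(**raw.get("thresholds", {})),
            transform=TransformOptions(**raw.get("transform", {})),
            group_map=raw.get("group_map", dict(DEFAULT_GROUP_MAP)),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "simulate": dataclasses.asdict(self.simulate) if self.simulate else None,
            "inputs": {
                "protein": self.protein_path,
                "protein_design": self.protein_design_path,
                "asv_2h": self.asv_2h_path,
                "asv_2h_design": self.asv_2h_design_path,
                "asv_24h": self.asv_24h_path,
                "asv_24h_design": self.asv_24h_design_path,
                "annotation": self.annotation_path,
            },
            "thresholds": dataclasses.asdict(self.thresholds),
            "transform": dataclasses.asdict(self.transform),
            "group_map": self.group_map,
            "seed": self.seed,
        }


def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def _write_tsv(path: Path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def _write_lda_bundle(outdir: Path, stem: str, model: screen.DiscriminantModel) -> list[str]:
    files = []
    _write_json(outdir / f"{stem}.json", model.to_dict())
    files.append(f"{stem}.json")
    bp = screen.biplot_coordinates(model)
    for part, frame in (("case_scores", bp.case_scores),
                        ("centroids", bp.centroids),
                        ("feature_vectors", bp.feature_vectors)):
        name = f"{stem}_{part}.tsv"
        _write_tsv(outdir / name, frame)
        files.append(name)
    return files


def _screen_and_lda(outdir: Path, stem: str, data: pd.DataFrame, groups,
                    threshold: float, shrinkage, manifest: dict) -> list[str]:
    """KW screen a feature matrix, write the KW table, fit LDA on the
    retained features (skipped, with a note, if none survive)."""
    retained, kw = screen.screen_features(data, groups, threshold=threshold)
    _write_tsv(outdir / f"kw_{stem}.tsv", kw)
    files = [f"kw_{stem}.tsv"]
    manifest["stages"].append(
        f"screen:{stem} features_in={data.shape[0]} retained={len(retained)} "
        f"threshold={threshold}")
    if retained and len(set(groups)) >= 2:
        model = screen.fit_lda(data.loc[retained], groups, shrinkage=shrinkage)
        files += _write_lda_bundle(outdir, f"lda_{stem}", model)
        manifest["stages"].append(
            f"lda:{stem} features={len(retained)} axes={model.n_axes} "
            f"shrinkage={model.shrinkage}")
        manifest.setdefault("retained", {})[stem] = retained
    else:
        manifest["stages"].append(f"lda:{stem} skipped (no retained features)")
        manifest.setdefault("retained", {})[stem] = []
    return files


def _association_bundle(outdir: Path, stem: str, x_table, y_table,
                        th: Thresholds, manifest: dict) -> list[str]:
    results = association.pairwise_associations(
        x_table, y_table, compute_mi=True,
        high_threshold=th.corr_high, strong_threshold=th.corr_strong)
    frame = association.associations_frame(results)
    _write_tsv(outdir / f"associations_{stem}.tsv", frame, index=False)
    edges = association.threshold_associations(results, tau=th.corr_high,
                                               strong_tau=th.corr_strong)
    _write_tsv(outdir / f"chord_edges_{stem}.tsv", edges, index=False)
    _write_json(outdir / f"chord_edges_{stem}.json",
                edges.to_dict(orient="records"))
    neg, pos = association.top_k_signed(results, k=th.top_k)
    top = pd.DataFrame({
        "rank": list(range(1, len(neg) + 1)) + list(range(1, len(pos) + 1)),
        "direction": ["negative"] * len(neg) + ["positive"] * len(pos),
        "protein": [r.x_id for r in neg + pos],
        "microbe": [r.y_id for r in neg + pos],
        "r": [r.r for r in neg + pos],
    })
    _write_tsv(outdir / f"top{th.top_k}_{stem}.tsv", top, index=False)
    manifest["stages"].append(
        f"associate:{stem} pairs={len(results)} edges={len(edges)}")
    return [f"associations_{stem}.tsv", f"chord_edges_{stem}.tsv",
            f"chord_edges_{stem}.json", f"top{th.top_k}_{stem}.tsv"]


def _cca_bundle(outdir: Path, stem: str, x_table, y_table,
                x_feats: list[str], y_feats: list[str],
                cca_lambda, manifest: dict) -> list[str]:
    if not x_feats or not y_feats:
        manifest["stages"].append(f"cca:{stem} skipped (empty feature set)")
        return []
    Xb, Yb, _ = association.paired_blocks(x_table, y_table, x_feats, y_feats)
    model = association.fit_cca(Xb, Yb, lambda_x=cca_lambda, lambda_y=cca_lambda)
    sc = association.structure_correlations(model, Xb, Yb)
    files = [f"cca_{stem}.json"]
    _write_json(outdir / f"cca_{stem}.json", model.to_dict())
    for part, frame in (("x_intraset", sc.x_intraset), ("x_interset", sc.x_interset),
                        ("y_intraset", sc.y_intraset), ("y_interset", sc.y_interset)):
        name = f"cca_{stem}_{part}.tsv"
        _write_tsv(outdir / name, frame.iloc[:, : min(2, frame.shape[1])])
        files.append(name)
    manifest["stages"].append(
        f"cca:{stem} dims={model.n_dims} rho1={model.correlations[0]:.4f} "
        f"lambda=({model.lambda_x},{model.lambda_y})")
    return files


def _diversity_bundle(outdir: Path, tp: str, table: AsvAbundanceTable,
                      manifest: dict) -> list[str]:
    files = []
    sh = pd.DataFrame({
        "experiment_id": table.experiment_ids,
        "substrate": [e.substrate for e in table.design],
        "shannon": [diversity.shannon(table.data[c].values) for c in table.experiment_ids],
    })
    _write_tsv(outdir / f"shannon_{tp}.tsv", sh, index=False)
    files.append(f"shannon_{tp}.tsv")
    D = diversity.bray_curtis_matrix(table)
    _write_tsv(outdir / f"bray_curtis_{tp}.tsv", D)
    files.append(f"bray_curtis_{tp}.tsv")
    ord_res = diversity.pcoa(D)
    _write_tsv(outdir / f"pcoa_{tp}.tsv", ord_res.coordinates)
    eig = pd.DataFrame({
        "eigenvalue": ord_res.eigenvalues,
        "proportion": list(ord_res.proportions) + [np.nan] * (
            len(ord_res.eigenvalues) - len(ord_res.proportions)),
    })
    _write_tsv(outdir / f"pcoa_{tp}_eigenvalues.tsv", eig, index=False)
    files += [f"pcoa_{tp}.tsv", f"pcoa_{tp}_eigenvalues.tsv"]
    props = preprocess.total_sum_scale(table)
    subs = sorted(set(table.substrates))
    diff_cols = {}
    for i, a in enumerate(subs):
        for b in subs[i + 1:]:
            diff_cols[f"{a}_vs_{b}"] = diversity.log2_median_proportion(
                props.data, table.experiments_for(a), table.experiments_for(b))
    diff = pd.DataFrame(diff_cols)
    diff.insert(0, "taxonomy", [table.taxonomy.get(f, "") for f in diff.index])
    _write_tsv(outdir / f"log2_median_{tp}.tsv", diff)
    files.append(f"log2_median_{tp}.tsv")
    manifest["stages"].append(f"diversity:{tp} experiments={len(table.design)}")
    return files


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        proteome, mic_2h, mic_24h, amap, _truth = simulate_all(sim)
        return proteome, mic_2h, mic_24h, amap
    proteome = read_feature_table(config.protein_path, "protein",
                                  config.protein_design_path)
    mic_2h = read_feature_table(config.asv_2h_path, "asv", config.asv_2h_design_path)
    mic_24h = read_feature_table(config.asv_24h_path, "asv", config.asv_24h_design_path)
    amap = read_annotation_map(config.annotation_path) if config.annotation_path else None
    return proteome, mic_2h, mic_24h, amap


def _grouped(labels: np.ndarray, group_map: dict[str, str]) -> Optional[list[str]]:
    try:
        mapped = [group_map[s] for s in labels]
    except KeyError:
        return None
    return mapped if len(set(mapped)) >= 2 else None


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "duomics",
        "version": __version__,
        "lib_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "files": [],
    }
    files: list[str] = manifest["files"]
    stage = "load"
    try:
        proteome, mic_2h, mic_24h, amap = _load_inputs(config)
        manifest["stages"].append(
            f"load proteins={len(proteome.feature_ids)} asvs={len(mic_2h.feature_ids)}")

        stage = "detection"
        summary = summarize_detection(proteome)
        (outdir / "detection_summary.json").write_text(summary.to_json() + "\n")
        _write_tsv(outdir / "detection_summary.tsv", summary.to_frame(), index=False)
        files += ["detection_summary.json", "detection_summary.tsv"]
        manifest["stages"].append(f"detection union={summary.union_count}")

        stage = "imputation"
        imp = preprocess.fit_imputation_constant(
            proteome, scale=config.transform.skewness_scale)
        _write_json(outdir / "imputation.json", imp.to_dict())
        files.append("imputation.json")
        prot = preprocess.apply_imputation(proteome, imp.constant) \
            if imp.applicable else proteome
        write_feature_table(prot, outdir / "protein_imputed.tsv")
        files.append("protein_imputed.tsv")
        manifest["stages"].append(
            f"imputation n_imputed={imp.n_imputed} constant={imp.constant}")

        stage = "offset_log"
        combined = pd.concat([mic_2h.data, mic_24h.data], axis=1)
        spec = preprocess.offset_alpha_from_values(
            combined.values, bracket=config.transform.alpha_bracket)
        _write_json(outdir / "offset_spec.json", spec.to_dict())
        files.append("offset_spec.json")
        log_2h = preprocess.offset_log(mic_2h, spec)
        log_24h = preprocess.offset_log(mic_24h, spec)
        manifest["stages"].append(f"offset_log alpha={spec.alpha}")

        th = config.thresholds
        shrink = config.transform.lda_shrinkage

        stage = "screen_proteins"
        files += _screen_and_lda(outdir, "proteins", prot.data, prot.substrates,
                                 th.kw_protein, shrink, manifest)
        grouped = _grouped(prot.substrates, config.group_map)
        if grouped:
            files += _screen_and_lda(outdir, "proteins_2group", prot.data, grouped,
                                     th.kw_protein, shrink, manifest)

        stage = "screen_microbes"
        for tp, logged in (("2h", log_2h), ("24h", log_24h)):
            files += _screen_and_lda(outdir, f"microbes_{tp}", logged.data,
                                     logged.substrates, th.kw_microbe, shrink, manifest)
            grouped = _grouped(logged.substrates, config.group_map)
            if grouped:
                files += _screen_and_lda(outdir, f"microbes_{tp}_2group", logged.data,
                                         grouped, th.kw_microbe, shrink, manifest)

        stage = "annotation_aggregation"
        if amap is not None:
            for cat, stem in ((MOLECULAR_FUNCTION, "functions"),
                              (BIOLOGICAL_PROCESS, "processes")):
                agg = preprocess.aggregate_by_annotation(prot, amap, cat)
                if not agg.empty:
                    files += _screen_and_lda(outdir, stem, agg, prot.substrates,
                                             th.kw_protein, shrink, manifest)

        stage = "heatmap_order"
        for stem, frame in (("proteins", prot.data),
                            ("microbes_2h", log_2h.data),
                            ("microbes_24h", log_24h.data)):
            if frame.shape[0] >= 2:
                order = screen.hclust_complete_order(frame)
                out = pd.DataFrame({
                    "axis": ["row"] * len(order.row_order) + ["col"] * len(order.col_order),
                    "position": list(range(len(order.row_order))) +
                                list(range(len(order.col_order))),
                    "label": [frame.index[i] for i in order.row_order] +
                             [frame.columns[i] for i in order.col_order],
                })
                _write_tsv(outdir / f"heatmap_order_{stem}.tsv", out, index=False)
                files.append(f"heatmap_order_{stem}.tsv")

        stage = "association"
        if config.transform.association_protein_scale == "log10":
            from .data_model import TransformedTable
            prot_assoc = TransformedTable(np.log10(prot.data), prot.design)
        else:
            prot_assoc = prot
        files += _association_bundle(outdir, "protein_2h", prot_assoc, log_2h, th, manifest)
        files += _association_bundle(outdir, "protein_24h", prot_assoc, log_24h, th, manifest)
        cross_all, cross_edges = association.cross_timepoint_association(
            log_2h, log_24h, tau=th.corr_cross_time)
        _write_tsv(outdir / "associations_2h_24h_edges.tsv", cross_edges, index=False)
        files.append("associations_2h_24h_edges.tsv")
        _write_tsv(outdir / "associations_2h_24h.tsv",
                   association.associations_frame(cross_all), index=False)
        files.append("associations_2h_24h.tsv")
        manifest["stages"].append(f"cross_timepoint edges={len(cross_edges)}")

        stage = "cca"
        retained = manifest.get("retained", {})
        files += _cca_bundle(outdir, "protein_2h", prot_assoc, log_2h,
                             retained.get("proteins", []),
                             retained.get("microbes_2h", []),
                             config.transform.cca_lambda, manifest)
        files += _cca_bundle(outdir, "protein_24h", prot_assoc, log_24h,
                             retained.get("proteins", []),
                             retained.get("microbes_24h", []),
                             config.transform.cca_lambda, manifest)

        stage = "diversity"
        files += _diversity_bundle(outdir, "2h", mic_2h, manifest)
        files += _diversity_bundle(outdir, "24h", mic_24h, manifest)

        stage = "manifest"
        files.append("manifest.json")
        manifest["files"] = sorted(set(files))
        _write_json(outdir / "manifest.json", manifest)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc
    return manifest
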