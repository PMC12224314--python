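"""Synthetic proteome/microbiome generator with full ground truth.

Protein intensities are lognormal (base-10) with per-substrate shifts for a
planted set of discriminant proteins and left-censoring below a detection
limit (censored cells become the missing marker).  Microbial counts are
zero-inflated negative-binomial with planted substrate effects and signed
couplings to the substrate-mean levels of planted proteins.  Everything is
a deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AsvAbundanceTable,
    Experiment,
    ProteinIntensityTable,
    write_annotation_map,
    write_feature_table,
    AnnotationMap,
    MOLECULAR_FUNCTION,
    BIOLOGICAL_PROCESS,
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 200
    n_asvs: int = 100
    substrates: tuple[str, ...] = ("dentine", "enamel", "titanium")
    readings_per_substrate: int = 3
    replicates_per_substrate: int = 3
    # proteome
    base_log10_intensity_mean: float = 6.0
    base_log10_intensity_sd: float = 0.8
    reading_noise_sd: float = 0.25
    substrate_effect_sd: float = 0.6
    n_discriminant_proteins: int = 20
    detection_limit: float = 1e5
    # microbiome
    asv_log_mean: float = 3.0
    asv_log_sd: float = 1.0
    asv_substrate_effect_sd: float = 1.2
    n_discriminant_asvs: int = 15
    count_dispersion: float = 8.0
    zero_inflation: float = 0.03
    n_couplings: int = 10
    coupling_strength: float = 2.5
    persistence: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_proteins": self.n_proteins,
            "n_asvs": self.n_asvs,
            "readings_per_substrate": self.readings_per_substrate,
            "replicates_per_substrate": self.replicates_per_substrate,
        }
        for name, v in counts.items():
            if v < 1:
                raise SyntheticError(f"{name} must be >= 1, got {v}")
        if len(self.substrates) < 1:
            raise SyntheticError("at least one substrate required")
        if not 0 <= self.zero_inflation < 1:
            raise SyntheticError("zero_inflation must be in [0, 1)")
        if self.count_dispersion <= 0:
            raise SyntheticError("count_dispersion must be > 0")
        if self.detection_limit < 0:
            raise SyntheticError("detection_limit must be >= 0")
        if self.n_discriminant_proteins > self.n_proteins:
            raise SyntheticError("n_discriminant_proteins exceeds n_proteins")
        if self.n_discriminant_asvs + self.n_couplings > self.n_asvs:
            raise SyntheticError("n_discriminant_asvs + n_couplings exceeds n_asvs")
        if not 0 <= self.persistence <= 1:
            raise SyntheticError("persistence must be in [0, 1]")


@dataclass
class Coupling:
    protein_id: str
    asv_id: str
    sign: int
    strength: float


@dataclass
class GroundTruth:
    """Planted structure plus latent (pre-censoring) quantities."""

    discriminant_proteins: dict[str, dict[str, float]] = field(default_factory=dict)
    discriminant_asvs: dict[str, dict[str, float]] = field(default_factory=dict)
    couplings: list[Coupling] = field(default_factory=list)
    latent_intensity: Optional[pd.DataFrame] = None  # pre-censoring intensities
    protein_substrate_mean_log10: Optional[pd.DataFrame] = None
    dropped_proteins: list[str] = field(default_factory=list)
    asv_log_mean_2h: Optional[pd.DataFrame] = None
    asv_log_mean_24h: Optional[pd.DataFrame] = None

    def to_json(self) -> str:
        payload = {
            "discriminant_proteins": self.discriminant_proteins,
            "discriminant_asvs": self.discriminant_asvs,
            "couplings": [dataclasses.asdict(c) for c in self.couplings],
            "dropped_proteins": self.dropped_proteins,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def default_fixture_config(seed: int = 0) -> SyntheticConfig:
    """Config for the packaged end-to-end fixture.

    Uses 5 microbiome replicates per substrate: with only 3, the smallest
    reachable Kruskal-Wallis p-value for 3 groups is ~0.027, so the
    strict p < 0.01 microbe screen could never retain anything.
    """
    return SyntheticConfig(
        n_proteins=80,
        n_asvs=50,
        replicates_per_substrate=5,
        n_discriminant_proteins=15,
        n_discriminant_asvs=10,
        n_couplings=8,
        seed=seed,
    )


def _protein_design(config: SyntheticConfig) -> list[Experiment]:
    design = []
    for s in config.substrates:
        for r in range(1, config.readings_per_substrate + 1):
            design.append(Experiment(f"prot_{s}_{r}", s, None, r))
    return design


def _microbe_design(config: SyntheticConfig, timepoint: str) -> list[Experiment]:
    design = []
    for s in config.substrates:
        for r in range(1, config.replicates_per_substrate + 1):
            design.append(Experiment(f"mic_{timepoint}_{s}_{r}", s, timepoint, r))
    return design


def simulate_proteome(config: SyntheticConfig) -> tuple[ProteinIntensityTable, GroundTruth]:
    """Simulate a censored LFQ-like intensity table.

    log10 intensity per reading ~ Normal(mu_p + delta_{p,s}, reading sd);
    intensities below the detection limit become missing.  Proteins left
    with no present value at all are dropped (and recorded in the truth);
    an entirely censored table raises.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    protein_ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    design = _protein_design(config)
    subs = list(config.substrates)

    mu = rng.normal(config.base_log10_intensity_mean, config.base_log10_intensity_sd,
                    size=config.n_proteins)
    disc_idx = rng.choice(config.n_proteins, size=config.n_discriminant_proteins,
                          replace=False)
    delta = np.zeros((config.n_proteins, len(subs)))
    delta[disc_idx, :] = rng.normal(0.0, config.substrate_effect_sd,
                                    size=(len(disc_idx), len(subs)))

    cols = []
    for e in design:
        s_idx = subs.index(e.substrate)
        log10 = mu + delta[:, s_idx] + rng.normal(0.0, config.reading_noise_sd,
                                                  size=config.n_proteins)
        cols.append(10.0 ** log10)
    latent = pd.DataFrame(
        np.column_stack(cols),
        index=pd.Index(protein_ids, name="feature_id"),
        columns=[e.experiment_id for e in design],
    )

    censored = latent.where(latent.values >= config.detection_limit)
    present = censored.notna().values
    if not present.any():
        raise SyntheticError("detection limit censors every value: empty table")
    keep = present.any(axis=1)
    dropped = [p for p, k in zip(protein_ids, keep) if not k]

    truth = GroundTruth(
        discriminant_proteins={
            protein_ids[i]: {s: float(delta[i, j]) for j, s in enumerate(subs)}
            for i in sorted(disc_idx)
        },
        latent_intensity=latent,
        protein_substrate_mean_log10=pd.DataFrame(
            {
                s: np.log10(latent[[e.experiment_id for e in design
                                    if e.substrate == s]]).mean(axis=1)
                for s in subs
            }
        ),
        dropped_proteins=dropped,
    )
    table = ProteinIntensityTable(censored.loc[keep], design)
    return table, truth


def _standardized_substrate_profile(truth: GroundTruth, protein_id: str,
                                    substrates: Sequence[str]) -> np.ndarray:
    means = truth.protein_substrate_mean_log10
    if means is None or protein_id not in means.index:
        raise SyntheticError(f"coupling references unknown protein {protein_id!r}")
    prof = means.loc[protein_id, list(substrates)].to_numpy(dtype=float)
    sd = prof.std()
    if sd == 0:
        return np.zeros_like(prof)
    return (prof - prof.mean()) / sd


def _zinb_counts(rng: np.random.Generator, log_mu: np.ndarray, kappa: float,
                 pi: float, n_rep: int) -> np.ndarray:
    """Gamma-Poisson mixture (NB with mean exp(log_mu), dispersion kappa)
    with Bernoulli(pi) excess zeros; shape (n_asvs, n_substrates * n_rep)."""
    mu = np.exp(log_mu)  # (q, s)
    q, s = mu.shape
    mu_rep = np.repeat(mu, n_rep, axis=1)  # columns grouped by substrate
    lam = rng.gamma(shape=kappa, scale=mu_rep / kappa)
    counts = rng.poisson(lam).astype(float)
    if pi > 0:
        counts[rng.random(counts.shape) < pi] = 0.0
    return counts


def simulate_microbiome(
    config: SyntheticConfig,
    proteome_truth: GroundTruth,
    couplings: Optional[list[tuple[str, str, int]]] = None,
) -> tuple[AsvAbundanceTable, AsvAbundanceTable, GroundTruth]:
    """Simulate 2h and 24h zero-inflated count tables coupled to the proteome.

    Per-substrate log-mean = baseline + substrate effect (discriminant ASVs)
    + sum of signed couplings times the standardized substrate-mean log10
    level of the coupled protein.  24h log-means blend toward the 2h
    substrate profile with weight ``persistence``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    subs = list(config.substrates)
    asv_ids = [f"ASV{i:04d}" for i in range(config.n_asvs)]
    taxonomy = {a: f"Taxon species-{i:04d} HMT-{i % 900 + 100:03d}"
                for i, a in enumerate(asv_ids)}

    baseline = rng.normal(config.asv_log_mean, config.asv_log_sd, size=config.n_asvs)
    # planted discriminant ASVs and coupled ASVs are disjoint pools
    perm = rng.permutation(config.n_asvs)
    disc_idx = perm[: config.n_discriminant_asvs]
    coupled_pool = perm[config.n_discriminant_asvs:
                        config.n_discriminant_asvs + config.n_couplings]

    effect = np.zeros((config.n_asvs, len(subs)))
    effect[disc_idx, :] = rng.normal(0.0, config.asv_substrate_effect_sd,
                                     size=(len(disc_idx), len(subs)))

    if couplings is None:
        dropped = set(proteome_truth.dropped_proteins)
        disc_proteins = sorted(set(proteome_truth.discriminant_proteins) - dropped)
        if not disc_proteins and config.n_couplings > 0:
            raise SyntheticError("no discriminant proteins available to couple to")
        # plant couplings on proteins that are (i) well separated across
        # substrates — otherwise standardizing the profile amplifies noise
        # into an undetectable coupling — and (ii) fully observed, so the
        # planted signal is not erased by detection-limit censoring
        means = proteome_truth.protein_substrate_mean_log10
        latent = proteome_truth.latent_intensity
        spread = {p: float(means.loc[p].max() - means.loc[p].min())
                  for p in disc_proteins}
        n_censored = {p: int((latent.loc[p] < config.detection_limit).sum())
                      for p in disc_proteins}
        eligible = [p for p in disc_proteins
                    if spread[p] >= 3.5 * config.reading_noise_sd
                    and n_censored[p] == 0]
        if not eligible:
            eligible = [p for p in disc_proteins
                        if spread[p] >= 2.0 * config.reading_noise_sd]
        if not eligible:
            eligible = sorted(disc_proteins, key=lambda p: -spread[p])[
                : max(1, len(disc_proteins) // 2)]
        planted: list[Coupling] = []
        for k in range(config.n_couplings):
            pid = eligible[int(rng.integers(len(eligible)))]
            sign = 1 if rng.random() < 0.5 else -1
            planted.append(Coupling(pid, asv_ids[coupled_pool[k]], sign,
                                    config.coupling_strength))
    else:
        planted = [Coupling(p, a, s, config.coupling_strength) for p, a, s in couplings]

    log_mu_2h = baseline[:, None] + effect
    asv_index = {a: i for i, a in enumerate(asv_ids)}
    for c in planted:
        if c.asv_id not in asv_index:
            raise SyntheticError(f"coupling references unknown ASV {c.asv_id!r}")
        z = _standardized_substrate_profile(proteome_truth, c.protein_id, subs)
        log_mu_2h[asv_index[c.asv_id], :] += c.sign * c.strength * z

    # 24h profile: persistence toward the 2h substrate profile
    effect_alt = np.zeros_like(effect)
    effect_alt[disc_idx, :] = rng.normal(0.0, config.asv_substrate_effect_sd,
                                         size=(len(disc_idx), len(subs)))
    log_mu_24h = (config.persistence * log_mu_2h
                  + (1.0 - config.persistence) * (baseline[:, None] + effect_alt))

    n_rep = config.replicates_per_substrate
    counts_2h = _zinb_counts(rng, log_mu_2h, config.count_dispersion,
                             config.zero_inflation, n_rep)
    counts_24h = _zinb_counts(rng, log_mu_24h, config.count_dispersion,
                              config.zero_inflation, n_rep)

    idx = pd.Index(asv_ids, name="feature_id")
    design_2h = _microbe_design(config, "2h")
    design_24h = _microbe_design(config, "24h")
    table_2h = AsvAbundanceTable(
        pd.DataFrame(counts_2h, index=idx, columns=[e.experiment_id for e in design_2h]),
        design_2h, taxonomy=taxonomy)
    table_24h = AsvAbundanceTable(
        pd.DataFrame(counts_24h, index=idx, columns=[e.experiment_id for e in design_24h]),
        design_24h, taxonomy=taxonomy)

    truth = GroundTruth(
        discriminant_proteins=proteome_truth.discriminant_proteins,
        discriminant_asvs={
            asv_ids[i]: {s: float(effect[i, j]) for j, s in enumerate(subs)}
            for i in sorted(disc_idx)
        },
        couplings=planted,
        latent_intensity=proteome_truth.latent_intensity,
        protein_substrate_mean_log10=proteome_truth.protein_substrate_mean_log10,
        dropped_proteins=proteome_truth.dropped_proteins,
        asv_log_mean_2h=pd.DataFrame(log_mu_2h, index=idx, columns=subs),
        asv_log_mean_24h=pd.DataFrame(log_mu_24h, index=idx, columns=subs),
    )
    return table_2h, table_24h, truth


def _random_annotation_map(rng: np.random.Generator,
                           protein_ids: Sequence[str]) -> AnnotationMap:
    mf_pool = [f"MF_{i:02d}" for i in range(15)]
    bp_pool = [f"BP_{i:02d}" for i in range(10)]
    amap = AnnotationMap()
    for pid in protein_ids:
        for label in rng.choice(mf_pool, size=int(rng.integers(1, 4)), replace=False):
            amap.add(pid, MOLECULAR_FUNCTION, str(label))
        n_bp = int(rng.integers(0, 3))
        if n_bp:
            for label in rng.choice(bp_pool, size=n_bp, replace=False):
                amap.add(pid, BIOLOGICAL_PROCESS, str(label))
    return amap


def simulate_all(config: SyntheticConfig):
    """Full simulation: proteome, both microbiome timepoints, annotation, truth."""
    proteome, ptruth = simulate_proteome(config)
    mic_2h, mic_24h, truth = simulate_microbiome(config, ptruth)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    amap = _random_annotation_map(rng, proteome.feature_ids)
    return proteome, mic_2h, mic_24h, amap, truth


def write_fixture(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated tables, designs, annotation, and truth to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteome, mic_2h, mic_24h, amap, truth = simulate_all(config)
    paths = {
        "protein": outdir / "protein.tsv",
        "protein_design": outdir / "protein_design.tsv",
        "asv_2h": outdir / "asv_2h.tsv",
        "asv_2h_design": outdir / "asv_2h_design.tsv",
        "asv_24h": outdir / "asv_24h.tsv",
        "asv_24h_design": outdir / "asv_24h_design.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    write_feature_table(proteome, paths["protein"], paths["protein_design"])
    write_feature_table(mic_2h, paths["asv_2h"], paths["asv_2h_design"])
    write_feature_table(mic_24h, paths["asv_24h"], paths["asv_24h_design"])
    write_annotation_map(amap, paths["annotation"])
    paths["truth"].write_text(truth.to_json())
    return paths
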