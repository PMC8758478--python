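"""End-to-end orchestration of the transcriptomic and biophysical arms.

Validated configuration (pydantic schema, unknown keys rejected), shared
logging, and two run functions:

* transcriptomic arm: simulate -> filter -> TMM -> logCPM -> ComBat ->
  (a) NB differential expression on counts, (b) Boruta on the corrected
  matrix, (c) ranking comparison with the sentinel divergence summary;
* biophysics arm: per-titration-point sedimentation-velocity scan
  simulation -> c(S) deconvolution -> s_w integration -> one-site and
  two-site binding fits -> model comparison -> mass/stoichiometry
  report; plus the fluorescence branch.

Every report embeds the seed and a hash of the configuration so that
identical (config, seed) pairs are verifiably identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import binding, feature_select, hydrodynamics, synthetic_data, transcriptomics
from .binding import (FluorParams, TwoSiteParams, compare_models, fit_binding,
                      stoichiometry_select)
from .hydrodynamics import (CellGeometry, HydroSpecies, SolutionConditions,
                            fit_cs, implied_vbar, integrate_sw, mass_from_hydro)
from .synthetic_data import (SentinelConfig, SimCountConfig, SimTitrationDesign,
                             simulate_counts, simulate_fluor_titration,
                             simulate_pathology, simulate_sw_titration)
from .transcriptomics import (combat_adjust, filter_zero_counts, log_cpm,
                              nb_dea, tmm_factors)

__all__ = [
    "PipelineConfig",
    "TranscriptomicsConfig",
    "BiophysicsConfig",
    "load_config",
    "run_transcriptomic_arm",
    "run_biophysics_arm",
    "ConfigError",
]

logger = logging.getLogger("lfapp")


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails schema validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SentinelSchema(_StrictModel):
    case_log2fc: float = 0.5338
    n_outlier_controls: int = 4
    control_share: float = 0.55
    case_mean: float = 150.0
    case_dispersion: float = 0.25
    control_background: float = 2.5
    background_dispersion: float = 1.5


class CountSimSchema(_StrictModel):
    n_genes: int = 2000
    n_case: int = 60
    n_control: int = 60
    de_fraction: float = 0.17
    de_log2fc_sd: float = 0.8
    n_batches: int = 3
    batch_log_fc_sd: float = 0.25
    sentinel: SentinelSchema | None = Field(default_factory=SentinelSchema)


class BorutaSchema(_StrictModel):
    max_runs: int = 100
    n_trees: int = 300
    alpha: float = 0.05


class TranscriptomicsConfig(_StrictModel):
    simulate: CountSimSchema = Field(default_factory=CountSimSchema)
    boruta: BorutaSchema = Field(default_factory=BorutaSchema)
    combat_preserve_group: bool = True
    run_dea: bool = True
    run_boruta: bool = True
    fdr_cutoff: float = 0.05


class TitrationSchema(_StrictModel):
    a_tot: float = 2.5e-6
    l_max: float = 5e-6
    n_points: int = 8
    noise_cv: float = 0.01


class BiophysicsConfig(_StrictModel):
    kd1: float = 620e-9
    kd2: float = 8.2e-6
    fluor_kd1: float = 690e-9
    fluor_kd2: float = 9.4e-6
    sw_titration: TitrationSchema = Field(default_factory=TitrationSchema)
    fluor_titration: TitrationSchema = Field(
        default_factory=lambda: TitrationSchema(l_max=25e-6, n_points=12))
    scan_mode: Literal["direct-sw", "simulate-scans"] = "direct-sw"
    n_scans: int = 6
    n_radial: int = 200
    scan_noise_sd: float = 0.005
    n_starts: int = 16
    vbar: float = 0.73


class PipelineConfig(_StrictModel):
    """Top-level validated pipeline configuration."""

    seed: int = 0
    output_dir: str = "lfapp_out"
    log_level: str = "INFO"
    transcriptomics: TranscriptomicsConfig = Field(default_factory=TranscriptomicsConfig)
    biophysics: BiophysicsConfig = Field(default_factory=BiophysicsConfig)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown keys anywhere in the document are rejected. `overrides` is a
    shallow dict merged over the file contents (used by the CLI for
    --seed etc.).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping: {path}")
    if overrides:
        data = {**data, **overrides}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _write_report(outdir: Path, name: str, payload: dict, markdown: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    (outdir / f"{name}.md").write_text(markdown)


def run_transcriptomic_arm(cfg: PipelineConfig) -> dict:
    """Simulate counts, run DEA and Boruta, and contrast the rankings."""
    tc = cfg.transcriptomics
    outdir = Path(cfg.output_dir)
    logger.info("transcriptomic arm: seed=%d config=%s", cfg.seed, cfg.config_hash)

    sim = tc.simulate
    sent_cfg = None
    if sim.sentinel is not None:
        sent_cfg = SentinelConfig(**sim.sentinel.model_dump())
    sim_cfg = SimCountConfig(
        n_genes=sim.n_genes, n_case=sim.n_case, n_control=sim.n_control,
        de_fraction=sim.de_fraction, de_log2fc=(0.0, sim.de_log2fc_sd),
        n_batches=sim.n_batches, batch_log_fc_sd=sim.batch_log_fc_sd,
        sentinel=sent_cfg, seed=cfg.seed)
    counts, meta, truth = simulate_counts(sim_cfg)
    counts = filter_zero_counts(counts)
    logger.info("simulated %d genes x %d samples", *counts.counts.shape)

    factors = tmm_factors(counts)
    lcpm = log_cpm(counts, factors)
    group_ind = (meta.table["group"] == "case").to_numpy(dtype=float)[:, None]
    adjusted = combat_adjust(lcpm, meta.table["batch"],
                             preserve=group_ind if tc.combat_preserve_group else None)

    outdir.mkdir(parents=True, exist_ok=True)
    # report-only sample QC (PCA + clustering); nothing is dropped
    transcriptomics.qc_outlier_report(lcpm).to_csv(
        outdir / "qc_outliers.tsv", sep="\t")

    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash,
                    "n_genes": counts.counts.shape[0],
                    "n_samples": counts.counts.shape[1],
                    "sentinel_gene": truth.sentinel_gene_id}
    md = [f"# Transcriptomic arm\n\nseed {cfg.seed}, config {cfg.config_hash}\n"]

    dea = bor = None
    if tc.run_dea:
        logger.info("negative-binomial differential expression")
        dea = nb_dea(counts, meta, factors)
        dea.table.to_csv(outdir / "dea.tsv", sep="\t", index=False)
        n_deg = int((dea.table["fdr"] < tc.fdr_cutoff).sum())
        report["n_degs"] = n_deg
        md.append(f"- DEGs at FDR<{tc.fdr_cutoff}: {n_deg}\n")

    if tc.run_boruta:
        logger.info("Boruta feature selection (max_runs=%d)", tc.boruta.max_runs)
        bor = feature_select.boruta_select(
            adjusted.to_numpy().T, meta.table["group"].to_numpy(), task="classify",
            max_runs=tc.boruta.max_runs, alpha=tc.boruta.alpha,
            n_trees=tc.boruta.n_trees, seed=cfg.seed,
            feature_names=list(adjusted.index))
        bor.table.to_csv(outdir / "boruta.tsv", sep="\t", index=False)
        report["n_confirmed"] = len(bor.confirmed)
        md.append(f"- Boruta confirmed features: {len(bor.confirmed)}\n")

    if dea is not None and bor is not None:
        comp = feature_select.compare_rankings(
            bor, dea, fdr_cutoff=tc.fdr_cutoff, counts=counts.counts,
            groups=meta.table.set_index("sample_id")["group"])
        comp.table.to_csv(outdir / "rank_comparison.tsv", sep="\t", index=False)
        if comp.outlier_sensitivity is not None:
            comp.outlier_sensitivity.to_csv(outdir / "outlier_sensitivity.tsv",
                                            sep="\t", index=False)
        report["overlap"] = comp.overlap
        if truth.sentinel_gene_id is not None:
            row = comp.table.set_index("feature").loc[truth.sentinel_gene_id]
            report["sentinel"] = {
                "boruta_rank": int(row["boruta_rank"]),
                "dea_rank": int(row["dea_rank"]),
                "divergence": int(row["divergence"]),
            }
            md.append(f"- sentinel {truth.sentinel_gene_id}: Boruta rank "
                      f"{int(row['boruta_rank'])}, DEA rank {int(row['dea_rank'])}\n")

    _write_report(outdir, "transcriptomics_report", report, "".join(md))
    logger.info("transcriptomic arm complete")
    return report


def _sw_from_scans(params: TwoSiteParams, bio: BiophysicsConfig, seed: int,
                   geom: CellGeometry, cond: SolutionConditions) -> pd.DataFrame:
    """Scan-level titration: simulate scans per point, deconvolve, integrate."""
    l_grid = np.linspace(0.0, bio.sw_titration.l_max, bio.sw_titration.n_points)
    times = [420.0 * (k + 1) for k in range(bio.n_scans)]
    specs = [
        ("A", params.s_A, 1.40), ("L", params.s_L, 1.38),
        ("AL", params.s_AL, 1.39), ("AL2", params.s_AL2, 1.36),
    ]
    weights = np.array([params.signal_weight_A, params.signal_weight_L,
                        params.signal_weight_AL, params.signal_weight_AL2])
    rows = []
    for i, l_tot in enumerate(l_grid):
        st = binding.solve_equilibrium(bio.sw_titration.a_tot, float(l_tot),
                                       params.kd1, params.kd2)
        conc = st.as_array()
        signals = weights * conc * 1e6  # AU-scale loading signals
        species = [HydroSpecies(label=lab, s=s, frictional_ratio=ff,
                                loading_signal=float(sig), conditions=cond)
                   for (lab, s, ff), sig in zip(specs, signals) if sig > 1e-6]
        scans = synthetic_data.simulate_auc_scans(
            species, geom, times, cond, noise_sd=bio.scan_noise_sd,
            seed=seed + 1000 + i, n_radial=bio.n_radial)
        cs = fit_cs(scans, geom, cond, ff0=1.38, lam="auto",
                    noise_sd=bio.scan_noise_sd, n_radial=max(120, bio.n_radial // 2))
        sw = integrate_sw(cs)
        rows.append({"a_tot_molar": bio.sw_titration.a_tot, "l_tot_molar": l_tot,
                     "observable": sw,
                     "sigma": max(bio.sw_titration.noise_cv * sw, 1e-9)})
    return pd.DataFrame(rows)


def run_biophysics_arm(cfg: PipelineConfig) -> dict:
    """Sedimentation and fluorescence titrations: simulate, fit, compare."""
    bio = cfg.biophysics
    outdir = Path(cfg.output_dir)
    cond = SolutionConditions(partial_specific_volume=bio.vbar)
    geom = CellGeometry()
    logger.info("biophysics arm: seed=%d mode=%s", cfg.seed, bio.scan_mode)

    truth = TwoSiteParams(kd1=bio.kd1, kd2=bio.kd2)

    if bio.scan_mode == "simulate-scans":
        sw_frame = _sw_from_scans(truth, bio, cfg.seed, geom, cond)
        # measurement noise enters through the scans themselves
        sw_data = binding.SwTitration(sw_frame)
    else:
        design = SimTitrationDesign(
            a_tot=bio.sw_titration.a_tot,
            l_tot_grid=tuple(np.linspace(0.0, bio.sw_titration.l_max,
                                         bio.sw_titration.n_points)),
            noise_cv=bio.sw_titration.noise_cv, seed=cfg.seed)
        sw_data = simulate_sw_titration(truth, design)

    fit_two = fit_binding(sw_data, "two-site", n_starts=bio.n_starts, seed=cfg.seed)
    fit_one = fit_binding(sw_data, "one-site", n_starts=bio.n_starts, seed=cfg.seed)
    comp = compare_models(fit_one, fit_two)

    fluor_truth = FluorParams(f0=1.0, df1=0.10, df2=0.05,
                              kd1=bio.fluor_kd1, kd2=bio.fluor_kd2)
    fdesign = SimTitrationDesign(
        a_tot=bio.fluor_titration.a_tot,
        l_tot_grid=synthetic_data.FLUOR_L_GRID,
        noise_cv=bio.fluor_titration.noise_cv, n_replicates=3,
        seed=cfg.seed + 1)
    fl_data = simulate_fluor_titration(fluor_truth, fdesign)
    fl_two = fit_binding(fl_data, "two-site", n_starts=bio.n_starts, seed=cfg.seed)
    fl_one = fit_binding(fl_data, "one-site", n_starts=bio.n_starts, seed=cfg.seed)
    fl_comp = compare_models(fl_one, fl_two)

    # hydrodynamic mass / stoichiometry report at the observed peaks
    peaks = {"free_A": (3.9, 1.40, 61e3), "free_L": (5.1, 1.38, 79e3),
             "complex_1to1": (6.9, 1.39, 142e3), "complex_1to2": (9.8, 1.36, 223e3)}
    masses = {}
    for name, (s, ff0, printed) in peaks.items():
        m = mass_from_hydro(s, ff0, cond)
        masses[name] = {"s": s, "ff0": ff0, "mass_kda": m / 1e3,
                        "printed_kda": printed / 1e3,
                        "implied_vbar": implied_vbar(s, ff0, printed, cond)}
    n_a, n_l, err = stoichiometry_select(61e3, 79e3, 223e3, 4)

    report = {
        "seed": cfg.seed, "config_hash": cfg.config_hash,
        "scan_mode": bio.scan_mode,
        "sw_fit_two_site": fit_two.to_dict(),
        "sw_fit_one_site": fit_one.to_dict(),
        "sw_comparison": comp.__dict__,
        "fluor_fit_two_site": fl_two.to_dict(),
        "fluor_fit_one_site": fl_one.to_dict(),
        "fluor_comparison": fl_comp.__dict__,
        "masses": masses,
        "stoichiometry": {"n_app": n_a, "n_lf": n_l, "relative_error": err},
    }
    md = [
        f"# Biophysics arm\n\nseed {cfg.seed}, config {cfg.config_hash}\n",
        f"- s_w two-site: Kd1 = {fit_two.estimates.get('kd1', float('nan')):.3g} M, "
        f"Kd2 = {fit_two.estimates.get('kd2', float('nan')):.3g} M, "
        f"R^2 = {fit_two.r_squared:.4f}\n",
        f"- s_w one-site R^2 = {fit_one.r_squared:.4f}; preferred: {comp.preferred}\n",
        f"- fluorescence two-site: Kd1 = {fl_two.estimates.get('kd1', float('nan')):.3g} M, "
        f"R^2 = {fl_two.r_squared:.4f}\n",
        f"- stoichiometry: {n_a} APP : {n_l} Lf (mass mismatch {100 * err:.1f}%)\n",
    ]
    _write_report(outdir, "biophysics_report", report, "".join(md))
    logger.info("biophysics arm complete")
    return report
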