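"""Synthetic-data generators for both pipeline arms.

Every generator is a pure function of its configuration and seed. The
count generator emulates the statistical structure of a post-mortem
brain bulk RNA-seq case/control cohort: negative-binomial counts with
log-normal baselines, gene-wise gamma dispersions, multiplicative batch
effects, technical/demographic covariates, and a "sentinel" gene whose
case elevation is consistent but whose control-group expression is
concentrated in a handful of outlier control samples — the structure
under which tree-ensemble feature selection and parametric NB testing
rank the same gene very differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import (FluorParams, FluorTitration, SwTitration, TwoSiteParams,
                      fluor_model, sw_model)
from .hydrodynamics import (CellGeometry, HydroSpecies, RadialScan,
                            SolutionConditions, WATER_20C, lamm_simulate)
from .transcriptomics import CountMatrix, SampleMetadata

__all__ = [
    "SentinelConfig",
    "SimCountConfig",
    "SimTruth",
    "SimTitrationDesign",
    "simulate_counts",
    "simulate_pathology",
    "simulate_sw_titration",
    "simulate_fluor_titration",
    "simulate_auc_scans",
]


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SentinelConfig:
    """Sentinel-gene construction.

    The sentinel's case samples are drawn at a moderate mean with low
    dispersion (a consistent elevation); its control samples are drawn
    near zero, then the `n_outlier_controls` largest are deterministically
    rescaled so that they carry exactly `control_share` of the total
    control-group signal, and the whole control group is rescaled so the
    realised case/control mean ratio is 2**case_log2fc.
    """

    case_log2fc: float = 0.5338
    n_outlier_controls: int = 4
    control_share: float = 0.55
    case_mean: float = 150.0
    case_dispersion: float = 0.25     # consistent case elevation
    control_background: float = 2.5   # negligible counts in most controls
    background_dispersion: float = 1.5  # heavy-tailed near-zero controls

    def __post_init__(self) -> None:
        if not (0 < self.control_share < 1):
            raise ValueError("control_share must be in (0, 1)")
        if self.n_outlier_controls < 1:
            raise ValueError("need at least one outlier control")


@dataclass(frozen=True)
class SimCountConfig:
    """Configuration of the NB count generator.

    Defaults give the desk-scale fixture: 2,000 genes, 60 cases and 60
    controls in 3 batches, ~17% DE genes (the DEG prevalence reported for
    the cohort the generator emulates), moderate batch effects, and one
    sentinel gene.
    """

    n_genes: int = 2000
    n_case: int = 60
    n_control: int = 60
    baseline_log_mean: tuple[float, float] = (5.0, 2.0)   # natural-log mean counts
    dispersion_gamma: tuple[float, float] = (2.0, 0.05)   # shape, scale -> mean 0.1
    de_fraction: float = 0.17
    de_log2fc: tuple[float, float] = (0.0, 0.8)           # mean, sd of DE effects
    n_batches: int = 3
    batch_log_fc_sd: float = 0.25
    depth_log_sd: float = 0.15
    sentinel: SentinelConfig | None = field(default_factory=SentinelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must be in [0, 1]")
        if min(self.n_genes, self.n_case, self.n_control, self.n_batches) < 1:
            raise ValueError("counts must be >= 1")
        if self.sentinel is not None and self.sentinel.n_outlier_controls >= self.n_control:
            raise ValueError("more outlier controls than controls")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a simulated count matrix."""

    is_de: pd.Series          # per gene
    true_log2fc: pd.Series    # per gene (case vs control)
    sentinel_gene_id: str | None
    batch: pd.Series          # per sample
    group: pd.Series          # per sample


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB draws parameterised by mean and dispersion (var = mu + disp*mu^2)."""
    r = 1.0 / np.maximum(disp, 1e-12)
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: SimCountConfig) -> tuple[CountMatrix, SampleMetadata, SimTruth]:
    """Simulate an NB count matrix with group, batch and sentinel structure.

    Counts are NB with mean = baseline * group-effect * batch-effect *
    sample-depth and gamma-distributed gene dispersions. Covariates (age,
    sex, RIN, study) are drawn with mild case/control imbalance. Fully
    deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    g, n_case, n_ctrl = cfg.n_genes, cfg.n_case, cfg.n_control
    n = n_case + n_ctrl
    gene_ids = [f"gene{i:05d}" for i in range(g)]
    sample_ids = [f"sample{j:03d}" for j in range(n)]
    group = np.array(["case"] * n_case + ["control"] * n_ctrl)

    base = np.exp(rng.normal(*cfg.baseline_log_mean, size=g))
    disp = rng.gamma(cfg.dispersion_gamma[0], cfg.dispersion_gamma[1], size=g)

    is_de = rng.random(g) < cfg.de_fraction
    lfc = np.where(is_de, rng.normal(*cfg.de_log2fc, size=g), 0.0)

    batch = rng.integers(0, cfg.n_batches, size=n)
    batch_fc = rng.normal(0.0, cfg.batch_log_fc_sd, size=(g, cfg.n_batches))
    depth = np.exp(rng.normal(0.0, cfg.depth_log_sd, size=n))

    is_case = (group == "case").astype(float)
    log_mu = (np.log(base)[:, None]
              + np.log(2.0) * lfc[:, None] * is_case[None, :]
              + batch_fc[:, batch]
              + np.log(depth)[None, :])
    counts = _nb_draw(rng, np.exp(log_mu), np.tile(disp[:, None], (1, n))).astype(np.int64)

    sentinel_id = None
    if cfg.sentinel is not None:
        s = cfg.sentinel
        sentinel_id = gene_ids[0]
        is_de[0], lfc[0] = True, s.case_log2fc
        case_counts = _nb_draw(rng, np.full(n_case, s.case_mean) * depth[:n_case],
                               np.full(n_case, s.case_dispersion))
        # controls: near-zero background, then exact-share outlier scaling
        ctrl = _nb_draw(rng, np.full(n_ctrl, s.control_background) * depth[n_case:],
                        np.full(n_ctrl, s.background_dispersion)).astype(float)
        k = s.n_outlier_controls
        order = np.argsort(ctrl)[::-1]
        rest = np.delete(ctrl, order[:k])
        rest_sum = max(rest.sum(), 1.0)
        target_out_total = s.control_share / (1.0 - s.control_share) * rest_sum
        out_vals = ctrl[order[:k]]
        out_vals = np.maximum(out_vals, 1.0)
        ctrl[order[:k]] = out_vals * target_out_total / out_vals.sum()
        # rescale whole control group to realise the configured log2 fold change
        target_ctrl_mean = case_counts.mean() / 2.0 ** s.case_log2fc
        if ctrl.mean() > 0:
            ctrl *= target_ctrl_mean / ctrl.mean()
        sent = np.concatenate([case_counts.astype(float), ctrl])
        counts[0] = np.rint(sent).astype(np.int64)
        top_share = (np.sort(counts[0, n_case:])[::-1][:k].sum()
                     / max(counts[0, n_case:].sum(), 1))
        if top_share < s.control_share - 0.05:
            raise ValueError("infeasible sentinel share under rounding")

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "group": group,
        "batch": [f"b{b}" for b in batch],
        # mild case/control imbalance in demographics
        "age": rng.normal(85.0, 6.0, n) + 1.5 * is_case,
        "sex": rng.choice(["f", "m"], size=n, p=[0.55, 0.45]),
        "rin": np.clip(rng.normal(7.0, 1.0, n) - 0.2 * is_case, 2.0, 10.0),
        "study": rng.choice(["ROS", "MAP"], size=n),
    })

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    truth = SimTruth(
        is_de=pd.Series(is_de, index=gene_ids),
        true_log2fc=pd.Series(lfc, index=gene_ids),
        sentinel_gene_id=sentinel_id,
        batch=pd.Series([f"b{b}" for b in batch], index=sample_ids),
        group=pd.Series(group, index=sample_ids),
    )
    return cm, SampleMetadata(meta), truth


def simulate_pathology(meta: SampleMetadata, sentinel_expr, effect: float = 1.0,
                       group_offset: float = 1.0, noise_sd: float = 0.5,
                       seed: int = 0) -> pd.Series:
    """Continuous pathology burden driven by the sentinel gene.

    burden = softplus(effect * z(sentinel) + group_offset * is_case + noise);
    non-negative, like an areal-fraction immunoreactivity measure.
    """
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    rng = np.random.default_rng(seed)
    expr = np.asarray(sentinel_expr, dtype=float)
    sd = expr.std()
    z = (expr - expr.mean()) / sd if sd > 0 else np.zeros_like(expr)
    is_case = (meta.table["group"].to_numpy() == "case").astype(float)
    lin = effect * z + group_offset * is_case + rng.normal(0.0, noise_sd, expr.size)
    burden = np.log1p(np.exp(lin))
    return pd.Series(burden, index=meta.table["sample_id"].to_numpy(), name="burden")


# ---------------------------------------------------------------------------
# Titration and scan simulation
# ---------------------------------------------------------------------------

# Canonical fluorescence titration design: log-ish ligand spacing covering
# both dissociation constants, acquired in triplicate.
FLUOR_L_GRID = tuple(1e-6 * np.array(
    [0.0, 0.25, 0.5, 1.0, 1.5, 2.5, 3.5, 5.0, 7.5, 10.0, 15.0, 20.0, 25.0]))


@dataclass(frozen=True)
class SimTitrationDesign:
    """Titration design: fixed acceptor, ligand grid, relative noise."""

    a_tot: float = 2.5e-6
    l_tot_grid: tuple = tuple(np.linspace(0.0, 5e-6, 8))
    noise_cv: float = 0.01
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.l_tot_grid, dtype=float)
        if (grid < 0).any() or np.any(np.diff(grid) < 0):
            raise ValueError("l_tot grid must be non-negative ascending")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_sw_titration(params: TwoSiteParams, design: SimTitrationDesign) -> SwTitration:
    """Noisy s_w titration from the two-site forward model.

    sw_obs = sw_model * (1 + eps), eps ~ N(0, noise_cv); the sigma column
    is noise_cv * model value (floored at a tiny positive value so
    noise-free designs stay weightable).
    """
    rng = np.random.default_rng(design.seed)
    l_grid = np.tile(np.asarray(design.l_tot_grid, dtype=float), design.n_replicates)
    model = sw_model(params, design.a_tot, l_grid)
    eps = rng.normal(0.0, design.noise_cv, l_grid.size) if design.noise_cv > 0 else 0.0
    obs = model * (1.0 + eps)
    sigma = np.maximum(design.noise_cv * model, 1e-9)
    return SwTitration(pd.DataFrame({
        "a_tot_molar": design.a_tot, "l_tot_molar": l_grid,
        "observable": obs, "sigma": sigma}))


def simulate_fluor_titration(params: FluorParams, design: SimTitrationDesign) -> FluorTitration:
    """Noisy fluorescence titration from the independent-two-site model.

    Noise is Gaussian with SD = noise_cv * (dynamic range of the model
    curve): fluorescence titrations ride on a large unliganded baseline,
    so relative noise is meaningful only against the binding-induced
    intensity change, not the raw intensity.
    """
    rng = np.random.default_rng(design.seed)
    l_grid = np.tile(np.asarray(design.l_tot_grid, dtype=float), design.n_replicates)
    model = fluor_model(params, design.a_tot, l_grid)
    span = float(model.max() - model.min())
    sigma_val = max(design.noise_cv * span, 1e-12)
    obs = model + (rng.normal(0.0, sigma_val, l_grid.size)
                   if design.noise_cv > 0 else 0.0)
    return FluorTitration(pd.DataFrame({
        "a_tot_molar": design.a_tot, "l_tot_molar": l_grid,
        "observable": obs, "sigma": np.full(l_grid.size, sigma_val)}))


def simulate_auc_scans(species: list[HydroSpecies], geom: CellGeometry,
                       times, cond: SolutionConditions = WATER_20C,
                       noise_sd: float = 0.005, seed: int = 0,
                       n_radial: int = 300) -> list[RadialScan]:
    """Lamm-equation scans plus i.i.d. Gaussian absorbance noise."""
    rng = np.random.default_rng(seed)
    scans = lamm_simulate(species, geom, times, cond, n_radial=n_radial)
    if noise_sd == 0:
        return scans
    return [RadialScan(sc.time, sc.radius,
                       sc.signal + rng.normal(0.0, noise_sd, sc.signal.size))
            for sc in scans]
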