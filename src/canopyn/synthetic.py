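"""Synthetic field-trial generator.

Emulates everything the pipeline consumes: variety nitrogen trajectories over
the six growth stages, plot canopy reflectance consistent with the quadratic
NDRE->N% model (Model I), multiband digital-number scenes with the six ground
calibration panels, leaf-level ground measurements (chemical N%, SPAD, N-pen
with its 2% saturation floor, LAI), and the two-variety nitrogen dosage
trial.  Every generator is a pure function of (config, seed).

The canopy spectral shape is a fixed smooth template scaled so that the
800/720 nm pair reproduces the NDRE implied by inverting Model I at the
trajectory's true N%.  At tillering the sparse canopy is mixed with a
water-background spectrum (convex mixture), so tillering points deviate
systematically from the Model-I curve, which is why that stage is excluded
when Model I is fitted.

What it deliberately does not emulate: radiative-transfer canopy physics,
illumination/BRDF effects, spatially correlated pixel noise, or clouds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    BAND_CENTERS,
    DN,
    PANEL_REFLECTANCES,
    STAGE_INDEX,
    STAGES,
    BandStack,
    LayoutItem,
    Rect,
    validate_stage,
)
from .models import DEFAULT_PLANT_DENSITY

# ---------------------------------------------------------------------------
# trajectory templates

@dataclass
class TrajectoryTemplate:
    """A variety archetype: true leaf/canopy N% and LAI per stage, plus GD.

    Numeric defaults below are qualitative archetypes of rice nitrogen
    dilution curves (declining N% as biomass accumulates), not measurements.
    """

    name: str
    n_pct_by_stage: tuple[float, ...]
    lai_by_stage: tuple[float, ...]
    gd_days: float

    def __post_init__(self) -> None:
        self.n_pct_by_stage = tuple(float(v) for v in self.n_pct_by_stage)
        self.lai_by_stage = tuple(float(v) for v in self.lai_by_stage)
        if len(self.n_pct_by_stage) != len(STAGES) or len(self.lai_by_stage) != len(STAGES):
            raise ValueError("templates need one N% and one LAI value per stage")
        if any(v <= 0 for v in self.n_pct_by_stage):
            raise ValueError("N% values must be positive")
        if any(v <= 0 for v in self.lai_by_stage):
            raise ValueError("LAI values must be positive")
        if not self.gd_days > 0:
            raise ValueError("growth duration must be positive")


def default_baseline_templates() -> tuple[TrajectoryTemplate, ...]:
    return (
        TrajectoryTemplate(
            name="baseline",
            n_pct_by_stage=(3.2, 3.0, 2.8, 2.5, 1.8, 1.2),
            lai_by_stage=(1.5, 2.5, 3.5, 4.5, 4.2, 3.5),
            gd_days=95.0,
        ),
        TrajectoryTemplate(
            # early-peaking, nitrogen-lush variety: maximal in the vegetative
            # stages but declining fast (the classifier must reject it)
            name="lush",
            n_pct_by_stage=(3.8, 3.6, 3.3, 3.0, 2.0, 1.3),
            lai_by_stage=(2.0, 3.2, 4.2, 5.0, 4.6, 3.8),
            gd_days=105.0,
        ),
        TrajectoryTemplate(
            name="sparse",
            n_pct_by_stage=(2.8, 2.6, 2.4, 2.1, 1.5, 1.0),
            lai_by_stage=(1.2, 2.0, 3.0, 3.8, 3.6, 3.0),
            gd_days=88.0,
        ),
    )


def default_high_nue_template() -> TrajectoryTemplate:
    return TrajectoryTemplate(
        name="high_nue",
        n_pct_by_stage=(3.4, 3.3, 3.1, 2.9, 2.6, 2.2),
        lai_by_stage=(1.8, 2.8, 3.8, 4.6, 4.4, 3.8),
        gd_days=112.0,
    )


#: smooth green-canopy reflectance template over the 12 nominal bands
CANOPY_TEMPLATE: dict[int, float] = {
    490: 0.045, 520: 0.07, 550: 0.10, 570: 0.09,
    670: 0.05, 680: 0.05, 700: 0.13, 720: 0.25,
    800: 0.45, 850: 0.46, 900: 0.44, 950: 0.40,
}

#: water background: strong NIR absorption, low red edge
WATER_TEMPLATE: dict[int, float] = {
    490: 0.06, 520: 0.055, 550: 0.05, 570: 0.045,
    670: 0.03, 680: 0.028, 700: 0.022, 720: 0.01,
    800: 0.02, 850: 0.015, 900: 0.012, 950: 0.01,
}

#: flat dry-soil background used between plots in rendered scenes
SOIL_REFLECTANCE = 0.15


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with the study-design defaults.

    The default collection is 51 varieties x 6 stages with one planted
    high-NUE variety; the sensor is linear per band; the tillering stage
    carries a 30% water-background fraction; the N-pen floor sits at 2% N.
    """

    n_varieties: int = 51
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    high_nue_indices: tuple[int, ...] = (0,)
    band_centers: tuple[int, ...] = BAND_CENTERS
    # linear sensor model, per band: DN = (rho - offset) / gain
    true_gain: tuple[float, ...] = tuple(0.004 + 0.0002 * i for i in range(12))
    true_offset: tuple[float, ...] = (0.01,) * 12
    dn_noise_sd: float = 0.5            # DN units
    reflectance_noise_sd: float = 0.005  # plot-level reflectance jitter
    pixel_noise_sd: float = 0.005        # per-pixel reflectance jitter in scenes
    traj_noise_sd: float = 0.08          # per-stage N% jitter across varieties
    eqa_noise_sd: float = 0.05           # chemical measurement error (N%)
    spad_slope: float = 12.0             # SPAD = slope * N% + intercept + noise
    spad_intercept: float = 8.0
    spad_noise_sd: float = 1.5
    npen_noise_sd: float = 0.15
    npen_floor: float = 2.0              # N-pen saturates below 2% N
    water_fraction_ts: float = 0.3
    water_reflectance: tuple[float, ...] = tuple(WATER_TEMPLATE[c] for c in BAND_CENTERS)
    plot_grid: tuple[int, int] = (6, 9)  # rows x cols of plots in a scene
    plot_size_px: int = 8
    gap_px: int = 2
    quantize_10bit: bool = False
    plant_density: float = DEFAULT_PLANT_DENSITY
    model_i_coeffs: tuple[float, float, float] = (5.75, 8.17, 0.58)
    model_ii_coeffs: tuple[float, float] = (1.06, 4.57)
    baseline_templates: tuple[TrajectoryTemplate, ...] = field(
        default_factory=default_baseline_templates
    )
    high_nue_template: TrajectoryTemplate = field(default_factory=default_high_nue_template)
    dosage_replicates: int = 30
    dosage_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.band_centers = tuple(int(c) for c in self.band_centers)
        self.high_nue_indices = tuple(int(i) for i in self.high_nue_indices)
        if len(self.stages) != 6 or tuple(self.stages) != STAGES:
            raise ValueError(f"stages must be the 6 ordered codes {STAGES}")
        if set(self.band_centers) != set(BAND_CENTERS) or len(self.band_centers) != 12:
            raise ValueError(f"band_centers must be exactly {BAND_CENTERS}")
        if self.n_varieties < 2:
            raise ValueError("cannot form a collection with fewer than 2 varieties")
        if any(i < 0 or i >= self.n_varieties for i in self.high_nue_indices):
            raise ValueError("high_nue_indices must lie in [0, n_varieties)")
        if self.n_varieties - len(self.high_nue_indices) < 2:
            raise ValueError("need at least 2 baseline varieties for ranking")
        for name in ("dn_noise_sd", "reflectance_noise_sd", "pixel_noise_sd",
                     "traj_noise_sd", "eqa_noise_sd", "spad_noise_sd",
                     "npen_noise_sd", "dosage_noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.water_fraction_ts <= 1.0):
            raise ValueError("water_fraction_ts must be in [0, 1]")
        if len(self.true_gain) != 12 or len(self.true_offset) != 12:
            raise ValueError("true_gain/true_offset need one value per band")
        if any(g <= 0 for g in self.true_gain):
            raise ValueError("gains must be positive")
        if len(self.water_reflectance) != 12:
            raise ValueError("water_reflectance needs one value per band")

    def variety_id(self, i: int) -> str:
        return f"V{i:02d}"


def config_to_dict(config: SynthConfig) -> dict:
    """Plain JSON/YAML-safe dict (tuples become lists)."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    return _clean(asdict(config))


def config_from_dict(data: dict) -> SynthConfig:
    data = dict(data)
    if "baseline_templates" in data:
        data["baseline_templates"] = tuple(
            TrajectoryTemplate(**t) for t in data["baseline_templates"]
        )
    if "high_nue_template" in data and isinstance(data["high_nue_template"], dict):
        data["high_nue_template"] = TrajectoryTemplate(**data["high_nue_template"])
    for key in ("stages", "band_centers", "true_gain", "true_offset",
                "water_reflectance", "high_nue_indices", "plot_grid",
                "model_i_coeffs", "model_ii_coeffs"):
        if key in data:
            data[key] = tuple(data[key])
    return SynthConfig(**data)


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class VarietyTrajectory:
    """A realized (jittered) trajectory for one variety, plus its true label."""

    variety: str
    template: TrajectoryTemplate
    is_high_nue: bool


def generate_trajectories(config: SynthConfig) -> list[VarietyTrajectory]:
    """Draw the collection's nitrogen trajectories; plant the high-NUE curves.

    Baseline varieties cycle through the configured archetype templates with
    Gaussian per-stage jitter.  Planted high-NUE varieties are then enforced,
    by construction, to satisfy the screening phenotype on true values:
    vegetative N% inside the interior percentile band of the collection,
    maximal N% at FHS and MRS, and a below-median BS->MRS decline rate.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_varieties
    high = set(config.high_nue_indices)
    n_stages = len(STAGES)

    # one jitter block per variety, drawn in a fixed order for determinism
    n_jitter = rng.normal(0.0, config.traj_noise_sd, size=(n, n_stages))
    lai_jitter = rng.normal(0.0, config.traj_noise_sd * 0.5, size=(n, n_stages))
    gd_jitter = rng.normal(0.0, 4.0, size=n)

    n_mat = np.empty((n, n_stages))
    lai_mat = np.empty((n, n_stages))
    gd = np.empty(n)
    names = []
    baseline_cursor = 0
    for i in range(n):
        if i in high:
            tpl = config.high_nue_template
        else:
            tpl = config.baseline_templates[baseline_cursor % len(config.baseline_templates)]
            baseline_cursor += 1
        names.append(tpl.name)
        n_mat[i] = np.maximum(np.asarray(tpl.n_pct_by_stage) + n_jitter[i], 0.62)
        lai_mat[i] = np.maximum(np.asarray(tpl.lai_by_stage) + lai_jitter[i], 0.1)
        gd[i] = max(tpl.gd_days + gd_jitter[i], 60.0)

    others = np.array([i for i in range(n) if i not in high])
    other_rates = (n_mat[others, STAGE_INDEX["BS"]] - n_mat[others, STAGE_INDEX["MRS"]]) / 2.0
    median_rate = float(np.median(other_rates))
    for i in high:
        # clause (i): vegetative stages inside an interior band of the others
        for j in (STAGE_INDEX[s] for s in ("TS", "JS", "PIS", "BS")):
            lo = np.percentile(n_mat[others, j], 45.0)
            hi = np.percentile(n_mat[others, j], 90.0)
            n_mat[i, j] = float(np.clip(n_mat[i, j], lo, hi))
        # clause (iii): decline rate strictly below the collection median
        bs_j, mrs_j = STAGE_INDEX["BS"], STAGE_INDEX["MRS"]
        rate = (n_mat[i, bs_j] - n_mat[i, mrs_j]) / 2.0
        if median_rate > 0 and rate >= median_rate:
            n_mat[i, mrs_j] = n_mat[i, bs_j] - 2.0 * 0.8 * median_rate
        # clause (ii): strictly maximal at FHS and MRS
        for j in (STAGE_INDEX["FHS"], STAGE_INDEX["MRS"]):
            n_mat[i, j] = max(n_mat[i, j], float(n_mat[others, j].max()) + 0.1)
        # keep the curve declining through the reproductive stages
        n_mat[i, STAGE_INDEX["FHS"]] = max(n_mat[i, STAGE_INDEX["FHS"]],
                                           n_mat[i, STAGE_INDEX["MRS"]])

    out = []
    for i in range(n):
        tpl = TrajectoryTemplate(
            name=names[i],
            n_pct_by_stage=tuple(n_mat[i]),
            lai_by_stage=tuple(lai_mat[i]),
            gd_days=float(gd[i]),
        )
        out.append(VarietyTrajectory(variety=config.variety_id(i), template=tpl,
                                     is_high_nue=i in high))
    return out


def trajectories_frame(trajectories: Sequence[VarietyTrajectory]) -> pd.DataFrame:
    """Long-format true-trajectory table (one row per variety x stage)."""
    rows = []
    for traj in trajectories:
        for j, stage in enumerate(STAGES):
            rows.append(
                {
                    "variety": traj.variety,
                    "stage": stage,
                    "n_pct_true": traj.template.n_pct_by_stage[j],
                    "lai_true": traj.template.lai_by_stage[j],
                    "gd_days": traj.template.gd_days,
                    "is_high_nue": traj.is_high_nue,
                    "template": traj.template.name,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reflectance

def invert_model_i(n_pct: float, coeffs: tuple[float, float, float]) -> float:
    """Larger root of a*x^2 + b*x + c = N%, the NDRE implied by Model I.

    Requires N% in [c, a + b + c), which maps to NDRE in [0, 1).
    """
    a, b, c = coeffs
    lo, hi = c, a + b + c
    if not (lo <= n_pct < hi):
        raise ValueError(
            f"N% = {n_pct:.4g} outside the invertible range [{lo:.4g}, {hi:.4g}) "
            f"of the quadratic model"
        )
    disc = b * b - 4.0 * a * (c - n_pct)
    return (-b + math.sqrt(disc)) / (2.0 * a)


def _canopy_spectrum(ndre: float, band_centers: Sequence[int]) -> np.ndarray:
    """Smooth canopy spectrum whose 800/720 pair realizes the given NDRE.

    The NIR plateau is held at the template level and the 720 nm red edge is
    solved from the NDRE definition; bands at or below 720 nm are scaled with
    the red edge, bands at or above 800 nm keep the template plateau.
    """
    rho800 = CANOPY_TEMPLATE[800]
    rho720 = rho800 * (1.0 - ndre) / (1.0 + ndre)
    scale_low = rho720 / CANOPY_TEMPLATE[720]
    out = np.empty(len(band_centers))
    for j, c in enumerate(band_centers):
        base = CANOPY_TEMPLATE[c]
        out[j] = base * scale_low if c <= 720 else base
    return out


def generate_plot_reflectance(
    trajectory: TrajectoryTemplate,
    stage: str,
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Per-band plot reflectance for one variety at one stage.

    The 800/720 pair encodes the Model-I inverse of the stage's true N%
    (plus reflectance noise).  At tillering the canopy is convexly mixed with
    the water-background spectrum, pulling the point off the Model-I curve.
    """
    validate_stage(stage)
    j = STAGE_INDEX[stage]
    ndre = invert_model_i(trajectory.n_pct_by_stage[j], config.model_i_coeffs)
    rho = _canopy_spectrum(ndre, config.band_centers)
    if stage == "TS" and config.water_fraction_ts > 0:
        f = config.water_fraction_ts
        rho = f * np.asarray(config.water_reflectance) + (1.0 - f) * rho
    if config.reflectance_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng([config.seed, 1, j])
        rho = rho + rng.normal(0.0, config.reflectance_noise_sd, size=rho.shape)
    return np.clip(rho, 1e-4, None)


# ---------------------------------------------------------------------------
# scene rendering

def generate_scene(
    config: SynthConfig,
    stage: str,
    trajectories: Optional[Sequence[VarietyTrajectory]] = None,
) -> tuple[BandStack, list[LayoutItem]]:
    """Render one stage's digital-number raster plus its layout.

    The scene holds a top row of six calibration panels at the known
    reflectances, then the plot grid (row-major variety order).  Per band,
    DN = (rho - offset) / gain plus Gaussian DN noise; with
    ``quantize_10bit`` DNs are rounded and clipped to [0, 1023].
    """
    validate_stage(stage)
    if trajectories is None:
        trajectories = generate_trajectories(config)
    if len(trajectories) != config.n_varieties:
        raise ValueError("trajectory count does not match config.n_varieties")

    rows_g, cols_g = config.plot_grid
    if config.n_varieties > rows_g * cols_g:
        raise ValueError(
            f"plot grid {config.plot_grid} cannot hold {config.n_varieties} plots"
        )
    size, gap = config.plot_size_px, config.gap_px
    # wide enough for both the plot grid and the 6-panel calibration row
    width = gap + max(cols_g, len(PANEL_REFLECTANCES)) * (size + gap)
    height = gap + (size + gap) + rows_g * (size + gap)

    rng = np.random.default_rng([config.seed, 100 + STAGE_INDEX[stage]])
    n_bands = len(config.band_centers)
    rho = np.full((n_bands, height, width), SOIL_REFLECTANCE)

    layout: list[LayoutItem] = []
    # calibration panels along the top row
    for k, panel_rho in enumerate(PANEL_REFLECTANCES):
        r0 = gap
        c0 = gap + k * (size + gap)
        rect = Rect(r0, r0 + size, c0, c0 + size)
        rho[:, rect.row0:rect.row1, rect.col0:rect.col1] = panel_rho
        layout.append(LayoutItem(role="panel", item_id=f"P{k + 1}",
                                 rect=rect, stage=stage, reflectance=panel_rho))
    # research plots
    for i, traj in enumerate(trajectories):
        gr, gc = divmod(i, cols_g)
        r0 = gap + (size + gap) + gr * (size + gap)
        c0 = gap + gc * (size + gap)
        rect = Rect(r0, r0 + size, c0, c0 + size)
        plot_rho = generate_plot_reflectance(traj.template, stage, config, rng=rng)
        block = np.broadcast_to(
            plot_rho[:, None, None], (n_bands, size, size)
        ).copy()
        if config.pixel_noise_sd > 0:
            block += rng.normal(0.0, config.pixel_noise_sd, size=block.shape)
        rho[:, rect.row0:rect.row1, rect.col0:rect.col1] = block
        layout.append(LayoutItem(role="plot", item_id=traj.variety, rect=rect,
                                 variety=traj.variety, stage=stage))

    gain = np.asarray(config.true_gain)[:, None, None]
    offset = np.asarray(config.true_offset)[:, None, None]
    dn = (rho - offset) / gain
    if config.dn_noise_sd > 0:
        dn = dn + rng.normal(0.0, config.dn_noise_sd, size=dn.shape)
    if config.quantize_10bit:
        dn = np.clip(np.round(dn), 0, 1023)
    return BandStack(values=dn, band_centers=config.band_centers, value_kind=DN), layout


# ---------------------------------------------------------------------------
# ground measurements and the dosage trial

def generate_ground_measurements(
    trajectories: Sequence[VarietyTrajectory], config: SynthConfig
) -> pd.DataFrame:
    """Leaf-level ground truth per variety x stage.

    N%_EQA is the true N% plus small Gaussian error; SPAD is affine in N%;
    the N-pen reading saturates at the configured floor (values cluster at
    the floor wherever true N% sits below it); LAI comes straight from the
    trajectory, with single-plant leaf area back-computed from the plant
    density.
    """
    rng = np.random.default_rng([config.seed, 200])
    rows = []
    for traj in trajectories:
        for j, stage in enumerate(STAGES):
            true_n = traj.template.n_pct_by_stage[j]
            lai = traj.template.lai_by_stage[j]
            eqa = true_n + rng.normal(0.0, config.eqa_noise_sd)
            spad = (config.spad_slope * true_n + config.spad_intercept
                    + rng.normal(0.0, config.spad_noise_sd))
            npen = max(true_n + rng.normal(0.0, config.npen_noise_sd), config.npen_floor)
            rows.append(
                {
                    "variety": traj.variety,
                    "stage": stage,
                    "n_pct_true": true_n,
                    "n_pct_eqa": eqa,
                    "spad": spad,
                    "n_pct_npen": npen,
                    "la_s_m2": lai / config.plant_density,
                    "lai": lai,
                    "gd_days": traj.template.gd_days,
                    "is_high_nue": traj.is_high_nue,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DosageGroupSpec:
    """Per-plant trait means and SDs for one variety x N-treatment cell."""

    variety: str
    treatment_kg_ha: float
    pl_cm: float
    epn: float
    gnp: float
    ssr_pct: float
    weight_200_g: float
    gyp_g: float
    pl_sd: float = 0.6
    epn_sd: float = 1.0
    gnp_sd: float = 10.0
    ssr_sd: float = 4.0
    weight_200_sd: float = 0.12
    gyp_sd: float = 3.0


def default_dosage_groups() -> tuple[DosageGroupSpec, ...]:
    """Defaults for the two-variety dosage trial.

    The high-NUE variety carries higher grain yield per plant at every
    nitrogen treatment; the check variety gains more from added nitrogen.
    Trait levels echo a typical hybrid-vs-check contrast (seed setting near
    92% vs 56%, thousand-grain weight near 28.9 vs 31.2 g).
    """
    ly = {
        0: dict(pl_cm=20.83, epn=10.33, gnp=140.6, ssr_pct=92.1, weight_200_g=5.788, gyp_g=38.5),
        120: dict(pl_cm=20.70, epn=10.37, gnp=138.0, ssr_pct=91.5, weight_200_g=5.650, gyp_g=39.2),
        180: dict(pl_cm=20.67, epn=10.90, gnp=142.0, ssr_pct=92.0, weight_200_g=5.708, gyp_g=41.0),
        240: dict(pl_cm=20.24, epn=11.33, gnp=139.0, ssr_pct=90.8, weight_200_g=5.680, gyp_g=38.8),
    }
    check = {
        0: dict(pl_cm=20.16, epn=9.22, gnp=120.0, ssr_pct=56.3, weight_200_g=6.248, gyp_g=20.6),
        120: dict(pl_cm=19.65, epn=10.50, gnp=124.0, ssr_pct=60.0, weight_200_g=6.016, gyp_g=24.0),
        180: dict(pl_cm=19.90, epn=9.90, gnp=126.0, ssr_pct=62.0, weight_200_g=6.090, gyp_g=26.5),
        240: dict(pl_cm=19.91, epn=10.09, gnp=128.0, ssr_pct=63.0, weight_200_g=6.082, gyp_g=28.5),
    }
    specs = []
    for treatment in (0, 120, 180, 240):
        specs.append(DosageGroupSpec(variety="HIGH_NUE", treatment_kg_ha=treatment, **ly[treatment]))
        specs.append(DosageGroupSpec(variety="CHECK", treatment_kg_ha=treatment, **check[treatment]))
    return tuple(specs)


def generate_dosage_trial(
    config: SynthConfig,
    groups: Optional[Sequence[DosageGroupSpec]] = None,
) -> pd.DataFrame:
    """Per-plant trait table for the 2-variety x 4-treatment dosage trial.

    Counts are kept as continuous draws (no integer rounding), so group means
    reproduce the configured means exactly when ``dosage_noise_scale`` is 0.
    """
    if config.dosage_replicates < 2:
        raise ValueError("need at least 2 replicates per group for a t-test")
    if groups is None:
        groups = default_dosage_groups()
    rng = np.random.default_rng([config.seed, 300])
    scale = config.dosage_noise_scale
    n = config.dosage_replicates
    rows = []
    for g in groups:
        pl = g.pl_cm + rng.normal(0.0, g.pl_sd * scale, n)
        epn = np.maximum(g.epn + rng.normal(0.0, g.epn_sd * scale, n), 1.0)
        gnp = np.maximum(g.gnp + rng.normal(0.0, g.gnp_sd * scale, n), 1.0)
        ssr = np.clip(g.ssr_pct + rng.normal(0.0, g.ssr_sd * scale, n), 1.0, 100.0)
        w200 = np.maximum(g.weight_200_g + rng.normal(0.0, g.weight_200_sd * scale, n), 0.1)
        gyp = np.maximum(g.gyp_g + rng.normal(0.0, g.gyp_sd * scale, n), 0.1)
        full = gnp * epn
        total = full / (ssr / 100.0)
        for k in range(n):
            rows.append(
                {
                    "variety": g.variety,
                    "treatment_kg_ha": g.treatment_kg_ha,
                    "plant": k,
                    "pl_cm": pl[k],
                    "epn": epn[k],
                    "full_grains": full[k],
                    "total_grains": total[k],
                    "weight_200_g": w200[k],
                    "gyp_g": gyp[k],
                }
            )
    return pd.DataFrame(rows)
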