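"""Synthetic study generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access to any slide archive:

* per-tumor mean morphotype profiles drawn from a Dirichlet distribution,
  with per-section profiles drawn from a Dirichlet centred on the tumor
  mean (the concentration parameter controls section-to-section
  dispersion);
* spatially contiguous label maps realizing each section profile: the
  tumor is an elliptical mask partitioned into Voronoi patches, the
  patches are swept by angle and pixels are allocated to morphotypes at
  exact cumulative counts, so realized proportions match the target to
  within one pixel per class;
* planted clinical associations in the directions reported for colorectal
  adenocarcinoma — desmoplastic (DE) proportion pushes stage upward and
  shortens survival, mucinous (MU) and solid/trabecular (TB) proportions
  raise microsatellite-instability odds, MU favours right-sided tumors,
  papillary (PP) proportion is protective for survival;
* right-censored exponential survival times for overall and relapse-free
  survival.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` child streams (profiles, clinical, render).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import clinical_frame, write_label_map, _write_csv
from .types import ClinicalRecord, LabelMap, Morphotype, SECTION_ROLES, ValidationError

_SITES_OTHER = ("transverse", "left", "rectosigmoid", "rectum")
#: luminal-to-deep allocation order for the layer-preference render mode
_LAYER_ORDER = (Morphotype.PP, Morphotype.SE, Morphotype.CT,
                Morphotype.MU, Morphotype.TB, Morphotype.DE)


@dataclass
class SimConfig:
    """Study-generator settings; defaults mirror the cohort shape of a
    161-tumor, four-sections-per-tumor colorectal series."""

    n_tumors: int = 161
    sections_per_tumor: int = 4
    raster_shape: tuple[int, int] = (160, 160)
    n_seed_patches: int = 24
    # Dirichlet mean profile ~ (0.50, 0.10, 0.10, 0.10, 0.12, 0.08):
    # complex tubular dominant, desmoplastic second, serrated rarest
    tumor_alpha: tuple[float, ...] = (5.0, 1.0, 1.0, 1.0, 1.2, 0.8)
    section_concentration: float = 50.0
    # planted covariate effects (logit / cumulative-logit scales, per unit
    # proportion); zero everywhere gives a null cohort
    beta_de_stage: float = 4.0
    beta_mu_msi: float = 10.0
    beta_tb_msi: float = 5.0
    beta_mu_site: float = 4.0
    beta_tb_grade: float = 5.0
    msi_intercept: float = -3.0
    site_right_intercept: float = -1.5
    # survival: exponential hazards per month, log-hazard per unit proportion
    baseline_hazard: float = 0.012
    beta_de_hazard: float = 5.0
    beta_pp_hazard: float = -4.0
    rfs_hazard_ratio: float = 1.3
    censoring_rate: float = 0.3
    followup_horizon: float = 120.0  # administrative censoring, months
    layer_preference: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tumor_alpha) != 6 or any(a <= 0 for a in self.tumor_alpha):
            raise ValidationError("tumor_alpha must be 6 positive values")
        if self.section_concentration <= 0:
            raise ValidationError("section_concentration must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        if self.n_seed_patches < 1:
            raise ValidationError("n_seed_patches must be >= 1")
        if min(self.raster_shape) < 8:
            raise ValidationError("raster_shape too small")

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """A cohort with every planted effect zeroed (for calibration studies)."""
        zeros = dict(beta_de_stage=0.0, beta_mu_msi=0.0, beta_tb_msi=0.0,
                     beta_mu_site=0.0, beta_tb_grade=0.0,
                     beta_de_hazard=0.0, beta_pp_hazard=0.0)
        zeros.update(overrides)
        return cls(**zeros)


@dataclass
class SimTruth:
    """Ground truth stored alongside generated data for recovery tests."""

    tumor_means: pd.DataFrame  # tumor_id + true mean profile columns
    section_profiles: pd.DataFrame  # section_id + target profile columns
    coefficients: dict = field(default_factory=dict)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("profiles", "clinical", "render")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def draw_profiles(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Tumor mean and per-section morphotype profiles.

    Returns ``(tumor_means, section_profiles)`` with shapes
    (n_tumors, 6) and (n_tumors, sections_per_tumor, 6):
    tumor mean ~ Dirichlet(alpha), section ~ Dirichlet(concentration * mean).
    """
    rng = rng or _streams(config.seed)["profiles"]
    means = rng.dirichlet(config.tumor_alpha, size=config.n_tumors)
    sections = np.empty((config.n_tumors, config.sections_per_tumor, 6))
    for i in range(config.n_tumors):
        # clip tiny alphas: numpy's Dirichlet degenerates numerically below ~1e-3
        alpha = np.maximum(config.section_concentration * means[i], 1e-3)
        sections[i] = rng.dirichlet(alpha, size=config.sections_per_tumor)
    return means, sections


def _ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    return (((rr - (h - 1) / 2) / (0.45 * h)) ** 2
            + ((cc - (w - 1) / 2) / (0.45 * w)) ** 2) <= 1.0


def _allocate_counts(profile: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` pixels to 6 classes."""
    ideal = profile * total
    counts = np.floor(ideal).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def render_section(
    profile,
    config: SimConfig,
    rng: np.random.Generator,
    section_id: str = "S",
    tumor_id: str = "T",
    role: str = "central",
) -> LabelMap:
    """Realize a proportion profile as a contiguous-patch label raster.

    The elliptical tumor mask is split into Voronoi patches around random
    seeds; patches are swept by angle (or by depth when layer preference
    is on) and the sweep is cut at exact cumulative pixel counts, so the
    realized proportions equal the target up to one pixel per morphotype.
    Background outside the ellipse is 0.
    """
    profile = np.asarray(profile, dtype=float)
    if abs(profile.sum() - 1.0) > 1e-6 or (profile < 0).any():
        raise ValidationError("profile must be a non-negative vector summing to 1")
    mask = _ellipse_mask(config.raster_shape)
    coords = np.argwhere(mask)
    if coords.shape[0] < config.n_seed_patches:
        raise ValidationError("raster too small for requested patch count")
    seeds = coords[rng.choice(coords.shape[0], config.n_seed_patches, replace=False)]
    cell = cKDTree(seeds).query(coords)[1]

    center = coords.mean(axis=0)
    if config.layer_preference:
        cell_key = seeds[:, 0].astype(float)  # sweep luminal (top) -> deep (bottom)
        morph_order = _LAYER_ORDER
    else:
        offset = rng.uniform(0, 2 * np.pi)
        ang = np.arctan2(seeds[:, 0] - center[0], seeds[:, 1] - center[1])
        cell_key = np.mod(ang + offset, 2 * np.pi)
        morph_order = tuple(Morphotype)

    # order pixels: cells in sweep order, raster order within each cell
    cell_rank = np.argsort(np.argsort(cell_key, kind="stable"), kind="stable")
    order = np.lexsort((coords[:, 1], coords[:, 0], cell_rank[cell]))
    counts = _allocate_counts(profile, coords.shape[0])

    pixels = np.zeros(config.raster_shape, dtype=np.uint8)
    start = 0
    for morph in morph_order:
        c = counts[morph.value - 1]
        chunk = coords[order[start:start + c]]
        pixels[chunk[:, 0], chunk[:, 1]] = morph.value
        start += c
    return LabelMap(pixels=pixels, section_id=section_id, tumor_id=tumor_id, role=role)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _survival_times(
    rng: np.random.Generator, hazard: np.ndarray, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    t = rng.exponential(1.0 / hazard)
    event = (rng.uniform(size=t.size) >= config.censoring_rate).astype(int)
    censored = event == 0
    # censoring uniform on (0, T): independent of the event process given T
    t = np.where(censored, rng.uniform(size=t.size) * t, t)
    over = t > config.followup_horizon
    t = np.where(over, config.followup_horizon, t)
    event = np.where(over, 0, event)
    return t, event


def draw_clinical(
    tumor_means: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ClinicalRecord], dict]:
    """Clinical covariates and survival outcomes with planted effects.

    MSI odds rise with MU and TB proportions; AJCC stage follows a
    cumulative-logit model shifted by the DE proportion; right-sided
    location odds rise with MU; overall/relapse-free survival are
    exponential with log-hazard increasing in DE and decreasing in PP.
    Returns the records and the coefficient dictionary used (ground truth).
    """
    rng = rng or _streams(config.seed)["clinical"]
    n = tumor_means.shape[0]
    p = {m.name: tumor_means[:, m.value - 1] for m in Morphotype}

    age = np.clip(rng.normal(68, 10, size=n), 30, 95)
    gender = np.where(rng.uniform(size=n) < 0.55, "M", "F")

    msi_prob = _sigmoid(config.msi_intercept
                        + config.beta_mu_msi * p["MU"] + config.beta_tb_msi * p["TB"])
    msi = np.where(rng.uniform(size=n) < msi_prob, "MSI", "MSS")

    right_prob = _sigmoid(config.site_right_intercept + config.beta_mu_site * p["MU"])
    site = np.where(rng.uniform(size=n) < right_prob,
                    "right", rng.choice(_SITES_OTHER, size=n))

    # ordinal stage: latent logistic shifted by DE; thresholds give roughly
    # 25/30/30/15% stage I-IV at the null
    latent = config.beta_de_stage * p["DE"] + rng.logistic(size=n)
    thresholds = np.array([-0.5, 0.9, 2.3]) + config.beta_de_stage * float(np.mean(p["DE"]))
    stage_idx = np.searchsorted(thresholds, latent)  # 0..3 -> I..IV
    ajcc = np.array(["I", "II", "III", "IV"])[stage_idx]

    t_stage = np.empty(n, dtype=object)
    n_stage = np.empty(n, dtype=object)
    m_stage = np.where(ajcc == "IV", "M1", "M0")
    for i, s in enumerate(stage_idx):
        if s == 0:
            t_stage[i] = rng.choice(["T1", "T2"])
            n_stage[i] = "N0"
        elif s == 1:
            t_stage[i] = rng.choice(["T3", "T4"])
            n_stage[i] = "N0"
        else:
            t_stage[i] = rng.choice(["T2", "T3", "T4"])
            n_stage[i] = rng.choice(["N1", "N2"])

    grade3_prob = _sigmoid(-2.0 + config.beta_tb_grade * p["TB"])
    grade = np.where(rng.uniform(size=n) < grade3_prob, 3,
                     np.where(rng.uniform(size=n) < 0.3, 1, 2))

    log_hr = config.beta_de_hazard * p["DE"] + config.beta_pp_hazard * p["PP"]
    os_hazard = config.baseline_hazard * np.exp(log_hr)
    os_time, os_event = _survival_times(rng, os_hazard, config)
    rfs_time, rfs_event = _survival_times(rng, os_hazard * config.rfs_hazard_ratio, config)
    # relapse precedes or coincides with death
    rfs_time = np.minimum(rfs_time, os_time)

    records = [
        ClinicalRecord(
            tumor_id=f"T{i + 1:03d}", age=float(age[i]), gender=str(gender[i]),
            t_stage=str(t_stage[i]), n_stage=str(n_stage[i]), m_stage=str(m_stage[i]),
            ajcc_stage=str(ajcc[i]), grade=int(grade[i]), site=str(site[i]),
            msi=str(msi[i]),
            os_time=float(os_time[i]), os_event=int(os_event[i]),
            rfs_time=float(rfs_time[i]), rfs_event=int(rfs_event[i]),
        )
        for i in range(n)
    ]
    coeffs = {k: getattr(config, k) for k in
              ("beta_de_stage", "beta_mu_msi", "beta_tb_msi", "beta_mu_site",
               "baseline_hazard", "beta_de_hazard", "beta_pp_hazard",
               "censoring_rate")}
    return records, coeffs


def simulate_cohort_frame(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Tumor-level analysis frame (proportions + clinical), no rasters.

    The morphotype proportions are the per-tumor means of the section
    profiles — what the raster pipeline would recover, without the cost of
    rendering.  Used for statistical calibration and power studies.
    """
    streams = _streams(config.seed)
    means, sections = draw_profiles(config, streams["profiles"])
    records, coeffs = draw_clinical(means, config, streams["clinical"])
    from .heterogeneity import nsi

    analysis_means = sections.mean(axis=1)
    df = clinical_frame(records)
    for m in Morphotype:
        df[f"p_{m.name}"] = analysis_means[:, m.value - 1]
    df["tumor_nsi"] = [nsi(v) for v in analysis_means]
    truth = SimTruth(
        tumor_means=pd.DataFrame(means, columns=[f"p_{m.name}" for m in Morphotype])
        .assign(tumor_id=df["tumor_id"].to_numpy()),
        section_profiles=pd.DataFrame(
            sections.reshape(-1, 6), columns=[f"p_{m.name}" for m in Morphotype]
        ),
        coefficients=coeffs,
    )
    return df, truth


def emit_study(config: SimConfig, out_dir: str | Path) -> Path:
    """Write a complete on-disk study bundle.

    Produces ``sections.csv``, ``clinical.csv``, ``sim_truth.csv`` and one
    PNG label raster per section under ``rasters/`` — the layout the
    pipeline's ``run-all`` consumes.  Byte-identical for identical config
    (including seed).
    """
    out = Path(out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    streams = _streams(config.seed)
    means, sections = draw_profiles(config, streams["profiles"])
    records, coeffs = draw_clinical(means, config, streams["clinical"])
    render_rng = streams["render"]

    roles = [SECTION_ROLES[j % 4] for j in range(config.sections_per_tumor)]
    rows = []
    truth_rows = []
    for i in range(config.n_tumors):
        tumor_id = f"T{i + 1:03d}"
        for j in range(config.sections_per_tumor):
            section_id = f"{tumor_id}_S{j + 1}"
            rel = f"rasters/{section_id}.png"
            lm = render_section(sections[i, j], config, render_rng,
                                section_id=section_id, tumor_id=tumor_id,
                                role=roles[j])
            write_label_map(lm, out / rel)
            rows.append({"tumor_id": tumor_id, "section_id": section_id,
                         "role": roles[j], "path": rel})
            truth_rows.append(
                {"tumor_id": tumor_id, "section_id": section_id,
                 **{f"target_p_{m.name}": sections[i, j, m.value - 1]
                    for m in Morphotype}}
            )
    _write_csv(pd.DataFrame(rows), out / "sections.csv")
    _write_csv(clinical_frame(records), out / "clinical.csv")
    truth = pd.DataFrame(truth_rows)
    for m in Morphotype:
        truth[f"tumor_mean_p_{m.name}"] = np.repeat(
            means[:, m.value - 1], config.sections_per_tumor)
    _write_csv(truth, out / "sim_truth.csv")
    return out
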