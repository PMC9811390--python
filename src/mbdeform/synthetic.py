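"""Synthetic phantom cohorts with known deformation and survival ground truth.

Real Gd-T1w medulloblastoma cohorts are not public, so validation runs on
phantoms: ellipsoidal "brains" with concentric tissue shells, deformed by a
tumor-centered radial displacement field with a controllable decay length
and angular heterogeneity, and survival times drawn from a proportional-
hazards model on the subject's own ground-truth band features.

The displacement-magnitude model, for a voxel at distance d from the tumor
surface and azimuthal angle theta about the z-axis through the tumor
center, is

    m(d, theta) = A0 * (1 + h * cos(k * theta)) * exp(-d / tau)

with amplitude A0 (mm), heterogeneity h in [0, 1], angular harmonic k and
decay length tau (mm). The displacement at the voxel is m * r_hat with
r_hat the radial unit vector from the tumor center, and zero inside the
tumor. Subject volumes are defined by pulling the atlas back through the
field, I_subj(x) = I_atlas(x - u(x)), so the returned field is *exactly*
the tissue displacement a perfect registration should recover on the
subject grid.

All randomness flows from one integer seed through named streams
(:mod:`mbdeform._rng`), so each stage is independently reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import bands as _bands
from ._rng import stream
from .grid import DisplacementField, ImageVolume

__all__ = [
    "PhantomConfig",
    "DeformationSimConfig",
    "CohortSimConfig",
    "SubjectRecord",
    "Cohort",
    "generate_atlas",
    "generate_subject",
    "generate_cohort",
    "displacement_magnitude_model",
    "analytic_displacement_field",
    "analytic_band_features",
    "simulate_survival",
    "default_phantom_config",
    "registration_phantom_config",
]


# ---------------------------------------------------------------------------
# configs


@dataclass
class PhantomConfig:
    """Geometry and appearance of a phantom brain/atlas.

    The brain is an axis-aligned ellipsoid centered on the grid (the world
    origin is placed at the grid center). Tissue intensity levels are
    assigned to concentric ellipsoidal shells from the center outwards; an
    optional smooth random texture (Gaussian-filtered noise, correlation
    length ``texture_scale_mm``) gives deformable registration intensity
    gradients everywhere, and ``noise_sd`` adds iid voxel noise on top.
    """

    grid_shape: tuple[int, int, int] = (52, 60, 52)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    brain_semi_axes_mm: tuple[float, float, float] = (60.0, 70.0, 58.0)
    tissue_intensity_levels: tuple[float, ...] = (70.0, 110.0, 85.0, 45.0)
    noise_sd: float = 0.0
    bias_field_order: int = 0
    texture_amplitude: float = 0.0
    texture_scale_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) < 4 for n in self.grid_shape):
            raise ValueError("grid too small")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bias_field_order < 0:
            raise ValueError("bias_field_order must be >= 0")
        if not self.tissue_intensity_levels:
            raise ValueError("need at least one tissue intensity level")
        extents = [n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)]
        if any(a >= e for a, e in zip(self.brain_semi_axes_mm, extents)):
            raise ValueError(
                f"brain semi-axes {self.brain_semi_axes_mm} do not fit inside the "
                f"grid half-extents {tuple(round(e, 1) for e in extents)}"
            )

    @property
    def origin_mm(self) -> tuple[float, float, float]:
        # world origin at the grid center
        return tuple(
            -(n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)
        )


@dataclass
class DeformationSimConfig:
    """Parameters of the tumor-centered radial displacement model."""

    tumor_center_mm: tuple[float, float, float] = (0.0, 8.0, -12.0)
    tumor_radius_mm: float = 10.0
    amplitude_A0_mm: float = 3.0
    decay_tau_mm: float = 15.0
    heterogeneity_h: float = 0.4
    angular_harmonic: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be > 0")
        if self.amplitude_A0_mm < 0:
            raise ValueError("amplitude_A0_mm must be >= 0")
        if self.decay_tau_mm <= 0:
            raise ValueError("decay_tau_mm must be > 0")
        if not 0.0 <= self.heterogeneity_h <= 1.0:
            raise ValueError("heterogeneity_h must be in [0, 1]")
        if self.angular_harmonic < 1:
            raise ValueError("angular_harmonic must be >= 1")


#: Per-subgroup mean displacement amplitude A0 (mm) and heterogeneity h.
#: Ordering follows the clinical aggressiveness gradient (WNT least
#: aggressive; Group 3 most): more aggressive tumors push harder and less
#: uniformly on the surrounding parenchyma.
DEFAULT_SUBGROUP_EFFECTS: dict[str, tuple[float, float]] = {
    "WNT": (2.0, 0.20),
    "SHH": (2.8, 0.35),
    "G3": (4.5, 0.65),
    "G4": (3.5, 0.50),
}

#: Subgroup mix of the simulated cohorts (WNT, SHH, G3, G4) — the WNT-poor,
#: Group-4-heavy composition typical of consecutive pediatric MB series.
DEFAULT_SUBGROUP_PROPORTIONS: dict[str, float] = {
    "WNT": 0.10,
    "SHH": 0.30,
    "G3": 0.15,
    "G4": 0.45,
}


@dataclass
class CohortSimConfig:
    """Cohort composition, per-subgroup effect sizes and survival model.

    ``survival_beta`` maps band-feature names to true Cox log-hazard-ratio
    coefficients; the linear predictor is beta . z(x_true) with x_true the
    subject's ground-truth band features z-scored across the cohort, so a
    coefficient of 1 doubles the hazard roughly every standard deviation
    (e-fold per SD). Event times are exponential given the linear
    predictor; censoring is uniform on (0, censor_max_days).
    """

    n_subjects: int = 88
    subgroup_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_PROPORTIONS)
    )
    subgroup_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_EFFECTS)
    )
    amplitude_sd_mm: float = 0.6
    heterogeneity_sd: float = 0.08
    tumor_radius_mm: float = 10.0
    tumor_radius_sd_mm: float = 1.5
    survival_beta: dict[str, float] = field(default_factory=lambda: {"K_10": 1.0})
    baseline_rate: float = 1.0 / 1500.0
    censor_max_days: float = 3000.0
    covariate_probs: dict[str, float] = field(
        default_factory=lambda: {"chang_high": 0.5, "eor_gtr": 0.5, "metastasis": 0.5}
    )
    age_log_mean: float = np.log(5.0)
    age_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        total = sum(self.subgroup_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subgroup proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.subgroup_proportions.values()):
            raise ValueError("subgroup proportions must be nonnegative")
        missing = set(self.subgroup_proportions) - set(self.subgroup_effects)
        if missing:
            raise ValueError(f"no effect sizes for subgroups {sorted(missing)}")
        if self.baseline_rate <= 0 or self.censor_max_days <= 0:
            raise ValueError("baseline_rate and censor_max_days must be > 0")


def default_phantom_config(seed: int = 0) -> PhantomConfig:
    """The standard cohort phantom: 2.5 mm grid, modest texture and noise."""
    return PhantomConfig(texture_amplitude=6.0, noise_sd=2.0, seed=seed)


def registration_phantom_config(seed: int = 0) -> PhantomConfig:
    """Finer 64-cube phantom used for registration-recovery experiments."""
    return PhantomConfig(
        grid_shape=(64, 64, 64),
        spacing_mm=(2.0, 2.0, 2.0),
        brain_semi_axes_mm=(55.0, 58.0, 52.0),
        texture_amplitude=10.0,
        texture_scale_mm=10.0,
        noise_sd=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# atlas


def _ellipsoid_rho(cfg: PhantomConfig) -> np.ndarray:
    """Normalized ellipsoidal radius (1.0 on the brain surface)."""
    vol = ImageVolume(np.zeros(cfg.grid_shape), cfg.spacing_mm, cfg.origin_mm)
    x, y, z = vol.axis_coords_mm()
    a, b, c = cfg.brain_semi_axes_mm
    return np.sqrt(
        (x[:, None, None] / a) ** 2 + (y[None, :, None] / b) ** 2 + (z[None, None, :] / c) ** 2
    )


def generate_atlas(config: PhantomConfig) -> tuple[ImageVolume, np.ndarray]:
    """Phantom atlas volume plus its brain mask (the ellipsoid interior).

    Deterministic for a fixed seed. Intensities are piecewise-constant
    concentric tissue shells, plus the configured smooth texture, iid
    Gaussian noise, and (if ``bias_field_order`` > 0) a multiplicative
    polynomial bias field — all confined to the brain mask.
    """
    rho = _ellipsoid_rho(config)
    mask = rho <= 1.0
    levels = np.asarray(config.tissue_intensity_levels, dtype=float)
    idx = np.clip((rho * len(levels)).astype(int), 0, len(levels) - 1)
    data = np.where(mask, levels[idx], 0.0)

    if config.texture_amplitude > 0:
        rng = stream(config.seed, "atlas-texture")
        raw = rng.standard_normal(config.grid_shape)
        sigma_vox = [config.texture_scale_mm / s for s in config.spacing_mm]
        smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox)
        sd = smooth.std()
        if sd > 0:
            data = data + np.where(mask, config.texture_amplitude * smooth / sd, 0.0)

    if config.bias_field_order > 0:
        rng = stream(config.seed, "atlas-bias")
        coords = [np.linspace(-1, 1, n) for n in config.grid_shape]
        log_bias = np.zeros(config.grid_shape)
        for px in range(config.bias_field_order + 1):
            for py in range(config.bias_field_order + 1 - px):
                for pz in range(config.bias_field_order + 1 - px - py):
                    if px == py == pz == 0:
                        continue
                    coef = 0.3 * rng.standard_normal() / (px + py + pz)
                    log_bias += coef * np.multiply.outer(
                        np.multiply.outer(coords[0] ** px, coords[1] ** py), coords[2] ** pz
                    )
        log_bias -= log_bias[mask].mean()
        data = np.where(mask, data * np.exp(log_bias), data)

    if config.noise_sd > 0:
        rng = stream(config.seed, "atlas-noise")
        data = data + np.where(mask, rng.normal(0.0, config.noise_sd, config.grid_shape), 0.0)

    return ImageVolume(data, config.spacing_mm, config.origin_mm), mask


# ---------------------------------------------------------------------------
# deformation model


def displacement_magnitude_model(
    d: np.ndarray, theta: np.ndarray, dcfg: DeformationSimConfig
) -> np.ndarray:
    """m(d, theta) = A0 (1 + h cos(k theta)) exp(-d/tau), zero for d < 0."""
    d = np.asarray(d, dtype=float)
    m = (
        dcfg.amplitude_A0_mm
        * (1.0 + dcfg.heterogeneity_h * np.cos(dcfg.angular_harmonic * np.asarray(theta)))
        * np.exp(-np.maximum(d, 0.0) / dcfg.decay_tau_mm)
    )
    return np.where(d > 0, m, 0.0)


def analytic_displacement_field(
    dcfg: DeformationSimConfig, pcfg: PhantomConfig
) -> DisplacementField:
    """Rasterize the radial displacement model onto the phantom grid."""
    vol = ImageVolume(np.zeros(pcfg.grid_shape), pcfg.spacing_mm, pcfg.origin_mm)
    x, y, z = vol.axis_coords_mm()
    cx, cy, cz = dcfg.tumor_center_mm
    rx = (x - cx)[:, None, None]
    ry = (y - cy)[None, :, None]
    rz = (z - cz)[None, None, :]
    r = np.sqrt(rx**2 + ry**2 + rz**2)
    d = r - dcfg.tumor_radius_mm
    theta = np.arctan2(np.broadcast_to(ry, r.shape), np.broadcast_to(rx, r.shape))
    m = displacement_magnitude_model(d, theta, dcfg)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, m / np.where(r > 0, r, 1.0), 0.0)
    vectors = np.stack(
        [scale * np.broadcast_to(rx, r.shape), scale * np.broadcast_to(ry, r.shape), scale * rz],
        axis=-1,
    )
    return DisplacementField(vectors, pcfg.spacing_mm, pcfg.origin_mm)


def _tumor_mask(dcfg: DeformationSimConfig, pcfg: PhantomConfig) -> np.ndarray:
    vol = ImageVolume(np.zeros(pcfg.grid_shape), pcfg.spacing_mm, pcfg.origin_mm)
    x, y, z = vol.axis_coords_mm()
    cx, cy, cz = dcfg.tumor_center_mm
    r2 = (
        (x - cx)[:, None, None] ** 2
        + (y - cy)[None, :, None] ** 2
        + (z - cz)[None, None, :] ** 2
    )
    return r2 <= dcfg.tumor_radius_mm**2


def _check_tumor_inside_brain(dcfg: DeformationSimConfig, pcfg: PhantomConfig) -> None:
    shrunk = [a - dcfg.tumor_radius_mm for a in pcfg.brain_semi_axes_mm]
    if any(s <= 0 for s in shrunk):
        raise ValueError("tumor radius exceeds a brain semi-axis")
    c = dcfg.tumor_center_mm
    if sum((ci / si) ** 2 for ci, si in zip(c, shrunk)) > 1.0:
        raise ValueError(
            f"tumor sphere (center {c}, radius {dcfg.tumor_radius_mm} mm) "
            "is not contained in the brain ellipsoid"
        )


def generate_subject(
    atlas: ImageVolume,
    brain_mask: np.ndarray,
    dcfg: DeformationSimConfig,
    pcfg: PhantomConfig,
    tumor_intensity: float | None = None,
) -> tuple[ImageVolume, np.ndarray, DisplacementField]:
    """Deform the atlas by the radial model and paint in a bright tumor.

    Returns (subject volume, tumor mask, ground-truth displacement field).
    The subject is the pull-back I_subj(x) = I_atlas(x - u(x)) (linear
    interpolation), so u is exactly the outward tissue displacement on the
    subject grid; u = 0 inside the tumor and decays to 0 far away.
    """
    _check_tumor_inside_brain(dcfg, pcfg)
    fld = analytic_displacement_field(dcfg, pcfg)
    vol = ImageVolume(atlas.data, pcfg.spacing_mm, pcfg.origin_mm)
    x, y, z = vol.axis_coords_mm()
    pts = np.stack(
        np.meshgrid(x, y, z, indexing="ij"), axis=-1
    ) - fld.vectors  # x - u(x), world mm
    vox = vol.world_to_voxel(pts)
    data = ndimage.map_coordinates(
        np.asarray(atlas.data, dtype=float),
        [vox[..., 0], vox[..., 1], vox[..., 2]],
        order=1,
        mode="nearest",
    )
    tumor = _tumor_mask(dcfg, pcfg)
    if tumor_intensity is None:
        tumor_intensity = 1.6 * max(pcfg.tissue_intensity_levels)
    data[tumor] = tumor_intensity
    return ImageVolume(data, pcfg.spacing_mm, pcfg.origin_mm), tumor, fld


# ---------------------------------------------------------------------------
# analytic band features (quadrature oracle)


def _weighted_stats(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, float, float, float]:
    w = weights / weights.sum()
    mean = float(np.sum(w * values))
    order = np.argsort(values)
    cw = np.cumsum(w[order])
    med = float(np.interp(0.5, cw, values[order]))
    c = values - mean
    m2 = float(np.sum(w * c**2))
    if m2 <= 0:
        return mean, med, 0.0, 0.0, 0.0
    m3 = float(np.sum(w * c**3))
    m4 = float(np.sum(w * c**4))
    return mean, med, float(np.sqrt(m2)), m3 / m2**1.5, m4 / m2**2 - 3.0


def analytic_band_features(
    dcfg: DeformationSimConfig,
    width_mm: float = _bands.BAND_WIDTH_MM,
    n_bands: int = _bands.N_BANDS,
    n_d: int = 240,
    n_theta: int = 96,
) -> pd.Series:
    """Ground-truth band statistics by dense quadrature of the radial model.

    The magnitude depends only on (d, theta); over a spherical shell around
    the tumor the voxel measure is (R + d)^2 dd dtheta (the polar-angle
    integral is a constant). Band statistics are therefore weighted moments
    of m(d, theta) on a dense (d, theta) grid with weight (R + d)^2. The
    brain boundary is ignored (phantom brains are large relative to the
    tumor), which is what makes this an *independent* oracle for the
    rasterized path rather than a re-implementation of it.
    """
    names = _bands.canonical_feature_names(width_mm, n_bands)
    theta = (np.arange(n_theta) + 0.5) / n_theta * 2.0 * np.pi
    out: dict[str, float] = {}
    per_band = max(8, n_d // n_bands)
    for k in range(1, n_bands + 1):
        outer = k * width_mm
        n_pts = per_band * k  # constant density in d across bands
        d = (np.arange(n_pts) + 0.5) * outer / n_pts
        dd, tt = np.meshgrid(d, theta, indexing="ij")
        m = displacement_magnitude_model(dd, tt, dcfg)
        w = (dcfg.tumor_radius_mm + dd) ** 2
        stats = _weighted_stats(m.ravel(), w.ravel())
        for stat_name, value in zip(_bands.STAT_NAMES, stats):
            out[f"{stat_name}_{int(round(outer))}"] = value
    return pd.Series([out[n] for n in names], index=names, dtype=float)


# ---------------------------------------------------------------------------
# survival + cohort


def simulate_survival(
    linear_predictor: np.ndarray,
    baseline_rate: float,
    censor_max_days: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards event times with uniform censoring.

    T = -log(U) / (baseline_rate * exp(lp)); C ~ Uniform(0, censor_max_days);
    returns (observed time, event indicator). ``censor_max_days=inf`` means
    no censoring.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    u = rng.uniform(size=lp.shape)
    t_event = -np.log(u) / (baseline_rate * np.exp(lp))
    if np.isinf(censor_max_days):
        return t_event, np.ones(lp.shape, dtype=int)
    t_cens = rng.uniform(0.0, censor_max_days, size=lp.shape)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return observed, event


@dataclass
class SubjectRecord:
    subject_id: str
    subgroup: str
    age_years: float
    dcfg: DeformationSimConfig
    volume: ImageVolume | None = None
    tumor_mask: np.ndarray | None = None
    field: DisplacementField | None = None


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    features: pd.DataFrame  # subjects x 60 ground-truth band features
    clinical: pd.DataFrame  # subject_id, age_years, subgroup, chang, eor, metastasis, os_days, event
    brain_mask: np.ndarray
    pcfg: PhantomConfig


def _subject_features_rasterized(
    dcfg: DeformationSimConfig, pcfg: PhantomConfig, brain_mask: np.ndarray
) -> pd.Series:
    fld = analytic_displacement_field(dcfg, pcfg)
    tumor = _tumor_mask(dcfg, pcfg)
    mag = fld.magnitude()
    mag[~brain_mask] = 0.0
    return _bands.extract_features(mag, tumor, brain_mask, pcfg.spacing_mm)


def generate_cohort(
    ccfg: CohortSimConfig,
    pcfg: PhantomConfig | None = None,
    feature_mode: str = "analytic",
    render_volumes: bool = False,
    quadrature: tuple[int, int] = (96, 32),
) -> Cohort:
    """Simulate a cohort with known subgroup effects and survival model.

    Per subject: subgroup drawn from the configured proportions; amplitude
    and heterogeneity drawn around the subgroup means; tumor radius
    jittered; ground-truth band features computed either by quadrature of
    the analytic model (``feature_mode='analytic'``, fast) or from the
    rasterized field through the band-features module
    (``feature_mode='rasterized'``). Event times follow the exponential
    proportional-hazards model on the z-scored true features.

    With ``render_volumes=True`` each record also carries the deformed
    subject volume, tumor mask and ground-truth field.
    """
    if feature_mode not in ("analytic", "rasterized"):
        raise ValueError("feature_mode must be 'analytic' or 'rasterized'")
    if pcfg is None:
        pcfg = default_phantom_config(seed=ccfg.seed)

    atlas = brain_mask = None
    if feature_mode == "rasterized" or render_volumes:
        atlas, brain_mask = generate_atlas(pcfg)
    else:
        brain_mask = _ellipsoid_rho(pcfg) <= 1.0

    groups = list(ccfg.subgroup_proportions)
    probs = np.asarray([ccfg.subgroup_proportions[g] for g in groups])
    rng_lab = stream(ccfg.seed, "cohort-labels")
    rng_eff = stream(ccfg.seed, "cohort-effects")
    rng_cov = stream(ccfg.seed, "cohort-covariates")
    rng_surv = stream(ccfg.seed, "cohort-survival")

    labels = rng_lab.choice(groups, size=ccfg.n_subjects, p=probs)
    present = set(labels)
    absent = [g for g in groups if ccfg.subgroup_proportions[g] > 0 and g not in present]
    if absent:
        warnings.warn(f"subgroup(s) {absent} empty after sampling", stacklevel=2)

    subjects: list[SubjectRecord] = []
    feats: list[pd.Series] = []
    for i, grp in enumerate(labels):
        a0_mean, h_mean = ccfg.subgroup_effects[grp]
        a0 = max(0.0, rng_eff.normal(a0_mean, ccfg.amplitude_sd_mm))
        h = float(np.clip(rng_eff.normal(h_mean, ccfg.heterogeneity_sd), 0.0, 1.0))
        radius = max(3.0, rng_eff.normal(ccfg.tumor_radius_mm, ccfg.tumor_radius_sd_mm))
        age = float(np.clip(rng_eff.lognormal(ccfg.age_log_mean, ccfg.age_log_sd), 0.3, 17.5))
        dcfg = DeformationSimConfig(
            tumor_radius_mm=radius,
            amplitude_A0_mm=a0,
            heterogeneity_h=h,
            seed=ccfg.seed + i,
        )
        rec = SubjectRecord(subject_id=f"S{i:03d}", subgroup=grp, age_years=age, dcfg=dcfg)
        if feature_mode == "analytic":
            feats.append(analytic_band_features(dcfg, n_d=quadrature[0], n_theta=quadrature[1]))
        else:
            feats.append(_subject_features_rasterized(dcfg, pcfg, brain_mask))
        if render_volumes:
            rec.volume, rec.tumor_mask, rec.field = generate_subject(
                atlas, brain_mask, dcfg, pcfg
            )
        subjects.append(rec)

    features = pd.DataFrame(feats, index=[s.subject_id for s in subjects])

    lp = np.zeros(ccfg.n_subjects)
    for name, beta in ccfg.survival_beta.items():
        if name not in features.columns:
            raise ValueError(f"survival_beta names unknown feature {name!r}")
        col = features[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        lp = lp + beta * z
    os_days, event = simulate_survival(lp, ccfg.baseline_rate, ccfg.censor_max_days, rng_surv)

    p = ccfg.covariate_probs
    clinical = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "age_years": [s.age_years for s in subjects],
            "subgroup": labels,
            "chang": np.where(
                rng_cov.uniform(size=ccfg.n_subjects) < p.get("chang_high", 0.5),
                "high",
                "standard",
            ),
            "eor": np.where(
                rng_cov.uniform(size=ccfg.n_subjects) < p.get("eor_gtr", 0.5), "GTR", "STR"
            ),
            "metastasis": (
                rng_cov.uniform(size=ccfg.n_subjects) < p.get("metastasis", 0.5)
            ).astype(int),
            "os_days": os_days,
            "event": event,
        }
    )
    return Cohort(
        subjects=subjects, features=features, clinical=clinical, brain_mask=brain_mask, pcfg=pcfg
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write subject NIfTIs (if rendered) and the clinical/feature CSVs."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.features.rename_axis("subject_id").to_csv(out / "features_true.csv")
    pcfg = cohort.pcfg
    brain = ImageVolume(
        cohort.brain_mask.astype(float), pcfg.spacing_mm, pcfg.origin_mm
    )
    brain.save(out / "brain_mask.nii.gz")
    for rec in cohort.subjects:
        if rec.volume is None:
            continue
        rec.volume.save(out / f"{rec.subject_id}_t1gd.nii.gz")
        ImageVolume(
            rec.tumor_mask.astype(float), pcfg.spacing_mm, pcfg.origin_mm
        ).save(out / f"{rec.subject_id}_tumor.nii.gz")
        rec.field.save(out / f"{rec.subject_id}_field.nii.gz")
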