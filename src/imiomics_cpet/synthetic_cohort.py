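"""Synthetic cohort generation.

Produces simulated 50-year-old participants of both sexes:

* anthropometrics and true CPET endpoints drawn from a Gaussian copula
  whose marginals default to the published cohort characteristics and
  whose pairwise correlations (the "planted effects") are configurable;
* whole-body phantom volumes — nested analytic shapes (elliptic
  cylinders and ellipsoids) for trunk, thighs, gluteal region, arms,
  visceral depot, liver, lungs, heart and bone — emitting quantitative
  water/fat channels so each compartment carries a configured fat
  fraction; compartment sizes scale monotonically with the subject's
  latent morphology factors;
* breath-by-breath ramp-test traces (10 W/min from a sex-specific
  starting load) constructed so that the noise-free trace, passed back
  through the index pipeline, returns the subject's true endpoints
  exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import (
    ALL_VARIABLES,
    CLIP_RANGES,
    FAT_FRACTION_FACTORS,
    LATENT_FACTORS,
    MARGINAL_VARIABLES,
    CohortConfig,
    GridSpec,
    build_correlation_matrix,
)
from .cpet_indices import BreathSeries

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Anthropometrics:
    sex: str
    age: float
    height: float       # cm
    weight: float       # kg
    lean_mass: float    # kg (NaN if the DXA scan is "missing")
    bmi: float          # kg/m^2, always weight / (height in m)^2
    waist: float        # cm
    smoker: bool


@dataclass
class LatentProfile:
    z_muscle: float
    z_subq_trunk: float
    z_subq_gluteal: float
    z_visceral: float
    z_liver: float
    z_lung: float
    z_heart: float
    ff_subq: float
    ff_visceral: float
    ff_muscle: float
    ff_liver: float


@dataclass
class SubjectRecord:
    id: str
    index: int
    anthropometrics: Anthropometrics
    latents: LatentProfile
    true_endpoints: dict[str, float]
    image_paths: dict[str, str] = field(default_factory=dict)


@dataclass
class PhantomVolume:
    """Water/fat/label volumes on one grid.  ``labels`` is nonzero exactly
    where tissue emits signal (water + fat > 0), including the low-signal
    lungs."""

    water: np.ndarray
    fat: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels > 0


LABEL_IDS = {
    "background": 0,
    "subq_trunk": 1,
    "subq_gluteal": 2,
    "visceral": 3,
    "muscle": 4,
    "liver": 5,
    "lung": 6,
    "heart": 7,
    "bone": 8,
}
LABEL_NAMES = {v: k for k, v in LABEL_IDS.items()}

#: which latent factor scales which compartment
COMPARTMENT_LATENTS = {
    "subq_trunk": "z_subq_trunk",
    "subq_gluteal": "z_subq_gluteal",
    "visceral": "z_visceral",
    "muscle": "z_muscle",
    "liver": "z_liver",
    "lung": "z_lung",
    "heart": "z_heart",
}

#: fractional volume change per SD of the latent factor
VOLUME_GAIN_PER_SD = 0.12

#: total (water + fat) signal per label, arbitrary units
TOTAL_SIGNAL = {
    "subq_trunk": 100.0,
    "subq_gluteal": 100.0,
    "visceral": 100.0,
    "muscle": 100.0,
    "liver": 100.0,
    "lung": 12.0,   # mostly air
    "heart": 100.0,
    "bone": 60.0,
}

#: fixed fat fractions for compartments without a drawn ff
FIXED_FF = {"lung": 0.15, "heart": 0.05, "bone": 0.40}


class CompartmentOverflowError(ValueError):
    """A scaled compartment no longer fits inside the phantom grid."""


# ---------------------------------------------------------------------------
# Cohort sampling (Gaussian copula)
# ---------------------------------------------------------------------------

def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L L^T = corr, tolerating semi-definite matrices."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def _draw_sex(
    config: CohortConfig, sex: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    corr = build_correlation_matrix(
        config.correlation_entries(sex), config.marginals(sex)
    )
    L = _psd_factor(corr)
    z = rng.standard_normal((n, len(ALL_VARIABLES))) @ L.T
    cols: dict[str, np.ndarray] = {}
    marg = config.marginals(sex)
    for j, name in enumerate(ALL_VARIABLES):
        if name in LATENT_FACTORS:
            cols[name] = z[:, j]
        elif name in FAT_FRACTION_FACTORS:
            m = config.fat_fractions[name]
            cols[name] = m.mean + m.sd * z[:, j]
        else:
            m = marg[name]
            cols[name] = m.mean + m.sd * z[:, j]
    for name, (lo, hi) in CLIP_RANGES.items():
        cols[name] = np.clip(cols[name], lo, hi)
    # physiological guards, several SDs from the configured means
    cols["height"] = np.clip(cols["height"], 140.0, 215.0)
    cols["weight"] = np.clip(cols["weight"], 35.0, None)
    cols["waist"] = np.clip(cols["waist"], 50.0, None)
    cols["vo2peak"] = np.clip(cols["vo2peak"], 500.0, None)
    cols["dvo2_dwr"] = np.clip(cols["dvo2_dwr"], 4.0, None)
    cols["rerpeak"] = np.clip(cols["rerpeak"], 0.6, None)
    df = pd.DataFrame(cols)
    df["sex"] = sex
    df["smoker"] = rng.random(n) < config.smoker_prevalence
    df["lean_missing"] = rng.random(n) < config.missing_lean_rate
    return df


def sample_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw the full cohort.  Deterministic given ``config.seed``; males
    are drawn first, then females, from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    frames = []
    if config.n_male:
        frames.append(_draw_sex(config, "male", config.n_male, rng))
    if config.n_female:
        frames.append(_draw_sex(config, "female", config.n_female, rng))
    if not frames:
        return []
    df = pd.concat(frames, ignore_index=True)

    records: list[SubjectRecord] = []
    counters = {"male": 0, "female": 0}
    proto = config.protocol
    for i, row in df.iterrows():
        sex = row["sex"]
        counters[sex] += 1
        sid = f"{'M' if sex == 'male' else 'F'}{counters[sex]:04d}"
        height, weight = float(row["height"]), float(row["weight"])
        lean = math.nan if row["lean_missing"] else float(row["lean_frac"] * weight)
        if not math.isnan(lean):
            lean = min(lean, 0.95 * weight)
        anthro = Anthropometrics(
            sex=sex,
            age=config.age_years,
            height=height,
            weight=weight,
            lean_mass=lean,
            bmi=weight / (height / 100.0) ** 2,
            waist=float(row["waist"]),
            smoker=bool(row["smoker"]),
        )
        latents = LatentProfile(**{k: float(row[k]) for k in LATENT_FACTORS + FAT_FRACTION_FACTORS})
        peak_hr = float(row["hr_frac"] * (220.0 - config.age_years))
        start = config.start_load(sex)
        peak_wr = (float(row["vo2peak"]) - proto.vo2_intercept_ml_min) / float(row["dvo2_dwr"])
        peak_wr = max(peak_wr, start + 20.0)
        endpoints = {
            "vo2peak": float(row["vo2peak"]),
            "vevco2_slope": float(row["vevco2_slope"]),
            "dvo2_dwr": float(row["dvo2_dwr"]),
            "rerpeak": float(row["rerpeak"]),
            "hr_frac": float(row["hr_frac"]),
            "peak_hr": peak_hr,
            "peak_wr": peak_wr,
        }
        records.append(
            SubjectRecord(
                id=sid,
                index=int(i),
                anthropometrics=anthro,
                latents=latents,
                true_endpoints=endpoints,
            )
        )
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten the cohort to one row per subject (cohort.csv layout)."""
    rows = []
    for r in records:
        a, l = r.anthropometrics, r.latents
        row = {
            "id": r.id,
            "sex": a.sex,
            "age": a.age,
            "height_cm": a.height,
            "weight_kg": a.weight,
            "lean_mass_kg": a.lean_mass,
            "bmi": a.bmi,
            "waist_cm": a.waist,
            "smoker": a.smoker,
        }
        row.update({k: getattr(l, k) for k in LATENT_FACTORS + FAT_FRACTION_FACTORS})
        row.update({f"true_{k}": v for k, v in r.true_endpoints.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _grids(grid: GridSpec):
    """Voxel-centre coordinates in mm: x, y centred on the grid midline,
    z measured from the feet."""
    nx, ny, nz = grid.shape
    sx, sy, sz = grid.spacing
    x = (np.arange(nx) + 0.5) * sx - nx * sx / 2.0
    y = (np.arange(ny) + 0.5) * sy - ny * sy / 2.0
    z = (np.arange(nz) + 0.5) * sz
    return np.meshgrid(x, y, z, indexing="ij")


def _check_bounds(name: str, grid: GridSpec, x0, x1, y0, y1, z0, z1) -> None:
    ex, ey, ez = grid.extent_mm
    if x0 < -ex / 2 or x1 > ex / 2 or y0 < -ey / 2 or y1 > ey / 2 or z0 < 0 or z1 > ez:
        raise CompartmentOverflowError(
            f"compartment {name!r} exceeds the phantom grid "
            f"(x [{x0:.0f},{x1:.0f}] y [{y0:.0f},{y1:.0f}] z [{z0:.0f},{z1:.0f}] mm "
            f"vs extents {ex:.0f} x {ey:.0f} x {ez:.0f} mm)"
        )


def _ellipsoid(X, Y, Z, grid, name, center, semi):
    cx, cy, cz = center
    ax, ay, az = semi
    _check_bounds(name, grid, cx - ax, cx + ax, cy - ay, cy + ay, cz - az, cz + az)
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _cylinder(X, Y, Z, grid, name, cx, cy, radius, z0, z1):
    _check_bounds(name, grid, cx - radius, cx + radius, cy - radius, cy + radius, z0, z1)
    return (((X - cx) / radius) ** 2 + ((Y - cy) / radius) ** 2 <= 1.0) & (Z >= z0) & (Z < z1)


def _elliptic_cylinder(X, Y, Z, grid, name, cx, cy, ax, ay, z0, z1):
    _check_bounds(name, grid, cx - ax, cx + ax, cy - ay, cy + ay, z0, z1)
    return (((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0) & (Z >= z0) & (Z < z1)


def _vol_factor(z: float) -> float:
    return max(1.0 + VOLUME_GAIN_PER_SD * z, 0.3)


def build_phantom(subject: SubjectRecord, config: CohortConfig) -> PhantomVolume:
    """Paint the phantom for one subject.

    Compartment volumes scale linearly with their latent factor
    (ellipsoid semi-axes by the cube root, cylinder radii by the square
    root, shell thicknesses linearly), so compartment volume is a
    strictly increasing function of each factor.  Geometry is bilaterally
    symmetric up to voxelization.
    """
    l = subject.latents
    ax3 = lambda z: _vol_factor(z) ** (1.0 / 3.0)   # ellipsoid axes
    rad2 = lambda z: _vol_factor(z) ** 0.5          # cylinder radii
    lin = _vol_factor                               # shell thicknesses
    ff = {
        "subq_trunk": l.ff_subq,
        "subq_gluteal": l.ff_subq,
        "visceral": l.ff_visceral,
        "muscle": l.ff_muscle,
        "liver": l.ff_liver,
        **FIXED_FF,
    }
    return _paint_phantom(
        config.grid,
        muscle_scale=rad2(l.z_muscle),
        wall_scale=lin(l.z_muscle),
        subq_scale=lin(l.z_subq_trunk),
        gluteal_scale=ax3(l.z_subq_gluteal),
        visceral_scale=ax3(l.z_visceral),
        liver_scale=ax3(l.z_liver),
        lung_scale=ax3(l.z_lung),
        heart_scale=ax3(l.z_heart),
        fat_fractions=ff,
    )


def reference_phantom(config: CohortConfig, sex: str = "pooled") -> PhantomVolume:
    """Common reference geometry: the all-zero-latent phantom with mean
    fat fractions.  The geometry depends only on the latent factors, so
    the per-sex templates coincide; ``sex`` is kept for provenance."""
    ffm = config.fat_fractions
    ff = {
        "subq_trunk": ffm["ff_subq"].mean,
        "subq_gluteal": ffm["ff_subq"].mean,
        "visceral": ffm["ff_visceral"].mean,
        "muscle": ffm["ff_muscle"].mean,
        "liver": ffm["ff_liver"].mean,
        **FIXED_FF,
    }
    return _paint_phantom(config.grid, fat_fractions=ff)


def _paint_phantom(
    grid: GridSpec,
    muscle_scale: float = 1.0,
    wall_scale: float = 1.0,
    subq_scale: float = 1.0,
    gluteal_scale: float = 1.0,
    visceral_scale: float = 1.0,
    liver_scale: float = 1.0,
    lung_scale: float = 1.0,
    heart_scale: float = 1.0,
    fat_fractions: dict[str, float] | None = None,
) -> PhantomVolume:
    X, Y, Z = _grids(grid)
    labels = np.zeros(grid.shape, dtype=np.int16)

    def paint(mask, name):
        labels[mask] = LABEL_IDS[name]

    # --- thighs/legs: muscle cylinders with a subcutaneous sheath -------
    thigh_r_muscle = 36.0 * muscle_scale
    thigh_subq_t = 14.0 * subq_scale
    for sx in (-1, 1):
        paint(
            _cylinder(X, Y, Z, grid, "thigh_subq", sx * 48, 0, thigh_r_muscle + thigh_subq_t, 60, 420),
            "subq_trunk",
        )
    for sx in (-1, 1):
        paint(_cylinder(X, Y, Z, grid, "thigh_muscle", sx * 48, 0, thigh_r_muscle, 60, 420), "muscle")

    # --- trunk: subq shell, muscular body wall, lean interior -----------
    trunk_subq_t = 16.0 * subq_scale
    trunk_wall_t = 10.0 * wall_scale
    wall_ax, wall_ay = 72.0, 46.0
    paint(
        _elliptic_cylinder(X, Y, Z, grid, "trunk_subq", 0, 0, wall_ax + trunk_subq_t, wall_ay + trunk_subq_t, 420, 880),
        "subq_trunk",
    )
    paint(_elliptic_cylinder(X, Y, Z, grid, "trunk_wall", 0, 0, wall_ax, wall_ay, 420, 880), "muscle")
    cav_ax, cav_ay = wall_ax - trunk_wall_t, wall_ay - trunk_wall_t
    paint(_elliptic_cylinder(X, Y, Z, grid, "trunk_cavity", 0, 0, cav_ax, cav_ay, 420, 880), "muscle")

    # --- gluteal subcutaneous depot (posterior, overrides trunk/thigh) --
    gsemi = tuple(s * gluteal_scale for s in (40.0, 34.0, 60.0))
    for sx in (-1, 1):
        paint(_ellipsoid(X, Y, Z, grid, "gluteal", (sx * 42, 46, 440), gsemi), "subq_gluteal")

    # --- internal organs (override the lean interior) -------------------
    paint(
        _ellipsoid(X, Y, Z, grid, "visceral", (0, 2, 560), tuple(s * visceral_scale for s in (52.0, 30.0, 115.0))),
        "visceral",
    )
    paint(
        _ellipsoid(X, Y, Z, grid, "liver", (26, -2, 700), tuple(s * liver_scale for s in (34.0, 27.0, 48.0))),
        "liver",
    )
    for sx in (-1, 1):
        paint(
            _ellipsoid(X, Y, Z, grid, "lung", (sx * 30, -4, 800), tuple(s * lung_scale for s in (26.0, 28.0, 78.0))),
            "lung",
        )
    paint(
        _ellipsoid(X, Y, Z, grid, "heart", (-4, 10, 755), tuple(s * heart_scale for s in (22.0, 21.0, 30.0))),
        "heart",
    )

    # --- arms: subq sheath over muscle ----------------------------------
    arm_r_muscle = 12.0 * muscle_scale
    arm_subq_t = 5.0 * subq_scale
    for sx in (-1, 1):
        paint(_cylinder(X, Y, Z, grid, "arm_subq", sx * 106, 0, arm_r_muscle + arm_subq_t, 540, 860), "subq_trunk")
    for sx in (-1, 1):
        paint(_cylinder(X, Y, Z, grid, "arm_muscle", sx * 106, 0, arm_r_muscle, 540, 860), "muscle")

    # --- head (lean tissue blob) ----------------------------------------
    paint(_ellipsoid(X, Y, Z, grid, "head", (0, 0, 935), (52.0, 52.0, 52.0)), "muscle")

    # --- bone: femora, humeri, spine (painted last) ----------------------
    for sx in (-1, 1):
        paint(_cylinder(X, Y, Z, grid, "femur", sx * 48, 0, 9.0, 60, 420), "bone")
    for sx in (-1, 1):
        paint(_cylinder(X, Y, Z, grid, "humerus", sx * 106, 0, 5.0, 540, 860), "bone")
    paint(_cylinder(X, Y, Z, grid, "spine", 0, -40, 10.0, 420, 880), "bone")

    # --- emit water/fat channels ----------------------------------------
    ff = fat_fractions or {}
    water = np.zeros(grid.shape, dtype=np.float32)
    fat = np.zeros(grid.shape, dtype=np.float32)
    for name, lid in LABEL_IDS.items():
        if name == "background":
            continue
        m = labels == lid
        f = float(np.clip(ff.get(name, 0.1), 0.0, 1.0))
        s = TOTAL_SIGNAL[name]
        water[m] = s * (1.0 - f)
        fat[m] = s * f
    return PhantomVolume(water=water, fat=fat, labels=labels, spacing=grid.spacing)


def compartment_volumes(phantom: PhantomVolume) -> dict[str, float]:
    """Per-label volume in mm^3."""
    voxvol = float(np.prod(phantom.spacing))
    return {
        name: float((phantom.labels == lid).sum()) * voxvol
        for name, lid in LABEL_IDS.items()
        if name != "background"
    }


# ---------------------------------------------------------------------------
# Breath-trace synthesis
# ---------------------------------------------------------------------------

def synthesize_breaths(
    subject: SubjectRecord,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> BreathSeries:
    """Synthesize one ramp test from the subject's true endpoints.

    Construction: WR ramps continuously at 10 W/min from the sex-specific
    starting load and is then held at the peak load for one plateau
    window; V̇O2 is linear in WR (so ΔV̇O2/ΔWR is recovered exactly); RER
    rises linearly to RERpeak at the plateau; V̇CO2 = RER * V̇O2; V̇E is
    piecewise-linear in V̇CO2 with slope equal to the true
    V̇E/V̇CO2-slope below the respiratory compensation point and a
    steeper slope beyond it; HR ramps linearly to the true peak HR.
    Additive Gaussian noise per channel comes from ``config.noise``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 7919, subject.index])
    p = config.protocol
    ep = subject.true_endpoints
    sex = subject.anthropometrics.sex
    start = config.start_load(sex)
    peak_wr = ep["peak_wr"]
    if peak_wr <= start:
        raise ValueError(f"peak WR {peak_wr:.0f} W not above starting load {start:.0f} W")
    if not all(math.isfinite(v) for v in ep.values()):
        raise ValueError("non-finite true endpoints")

    dt = p.sample_dt_s
    ramp_s = 60.0 * (peak_wr - start) / p.ramp_w_per_min
    total_s = p.rest_duration_s + ramp_s + p.plateau_duration_s
    if total_s <= 0:
        raise ValueError("non-positive test duration")
    time = np.arange(0.0, total_s + dt / 2, dt)
    t_ex = time - p.rest_duration_s  # exercise clock
    in_ex = t_ex >= 0

    wr = np.zeros_like(time)
    wr[in_ex] = np.minimum(start + p.ramp_w_per_min * t_ex[in_ex] / 60.0, peak_wr)

    s = ep["dvo2_dwr"]
    vo2 = np.full_like(time, p.vo2_intercept_ml_min)
    vo2[in_ex] = p.vo2_intercept_ml_min + s * wr[in_ex]

    frac = np.clip(t_ex / ramp_s, 0.0, 1.0)
    rer = p.rer_start + (ep["rerpeak"] - p.rer_start) * np.where(in_ex, frac, 0.0)
    vco2 = rer * vo2

    s1 = ep["vevco2_slope"]
    v = vco2 / 1000.0  # L/min
    v_peak = ep["rerpeak"] * (p.vo2_intercept_ml_min + s * peak_wr) / 1000.0
    ve_intercept = 3.0
    if p.rcp_vco2_fraction < 1.0:
        v_rcp = p.rcp_vco2_fraction * v_peak
        s2 = p.rcp_slope_factor * s1
        ve = np.where(
            v <= v_rcp,
            ve_intercept + s1 * v,
            ve_intercept + s1 * v_rcp + s2 * (v - v_rcp),
        )
        true_rcp = v_rcp
    else:
        ve = ve_intercept + s1 * v
        true_rcp = math.nan

    hr = np.full_like(time, p.hr_rest_bpm)
    hr[in_ex] = p.hr_rest_bpm + (ep["peak_hr"] - p.hr_rest_bpm) * frac[in_ex]

    nz = config.noise
    vo2 = np.maximum(vo2 + rng.normal(0, nz.vo2_ml_min, time.size) if nz.vo2_ml_min else vo2, 0)
    vco2 = np.maximum(vco2 + rng.normal(0, nz.vco2_ml_min, time.size) if nz.vco2_ml_min else vco2, 0)
    ve = np.maximum(ve + rng.normal(0, nz.ve_l_min, time.size) if nz.ve_l_min else ve, 0)
    hr = np.maximum(hr + rng.normal(0, nz.hr_bpm, time.size) if nz.hr_bpm else hr, 0)

    ex_idx = np.flatnonzero(in_ex)
    return BreathSeries(
        time=time,
        wr=wr,
        vo2=vo2,
        vco2=vco2,
        ve=ve,
        hr=hr,
        exercise_start=int(ex_idx[0]),
        exercise_end=int(ex_idx[-1]),
        subject_id=subject.id,
        meta={"true_rcp_vco2_l_min": true_rcp, "start_load_w": start},
    )


# ---------------------------------------------------------------------------
# File output (NIfTI-1, RAS; CSV tables)
# ---------------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_phantom(phantom: PhantomVolume, outdir, subject_id: str) -> dict[str, str]:
    """Write water/fat/labels as NIfTI-1 (RAS, spacing in the affine)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.spacing)
    paths = {}
    for name, arr, dtype in (
        ("water", phantom.water, np.float32),
        ("fat", phantom.fat, np.float32),
        ("labels", phantom.labels, np.int16),
    ):
        p = outdir / f"{subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), str(p))
        paths[name] = str(p)
    return paths


def read_phantom(paths: dict[str, str]) -> PhantomVolume:
    imgs = {k: nib.load(paths[k]) for k in ("water", "fat", "labels")}
    spacing = tuple(float(s) for s in imgs["water"].header.get_zooms()[:3])
    return PhantomVolume(
        water=np.asarray(imgs["water"].dataobj, dtype=np.float32),
        fat=np.asarray(imgs["fat"].dataobj, dtype=np.float32),
        labels=np.asarray(imgs["labels"].dataobj, dtype=np.int16),
        spacing=spacing,
    )


def write_cohort(records: list[SubjectRecord], outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "cohort.csv"
    cohort_to_frame(records).to_csv(path, index=False)
    return path
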