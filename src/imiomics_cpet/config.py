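"""Configuration objects for the whole pipeline.

Everything tunable lives here: per-sex marginal distributions of
anthropometrics and CPET endpoints, the planted latent correlation
structure, the phantom voxel grid, the ramp-protocol constants, breath
noise, registration settings and statistical-mapping settings.  All
defaults are embedded so ``default_config()`` is a complete, runnable
configuration; every object round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Variable registry
# ---------------------------------------------------------------------------

#: Standard-normal latent morphology factors (dimensionless).
LATENT_FACTORS = (
    "z_muscle",
    "z_subq_trunk",
    "z_subq_gluteal",
    "z_visceral",
    "z_liver",
    "z_lung",
    "z_heart",
)

#: Tissue fat fractions, drawn with Gaussian marginals then clipped.
FAT_FRACTION_FACTORS = ("ff_subq", "ff_visceral", "ff_muscle", "ff_liver")

#: Variables with per-sex Gaussian marginals (units in comments below).
MARGINAL_VARIABLES = (
    "height",         # cm
    "weight",         # kg
    "waist",          # cm
    "vo2peak",        # mL/min
    "vevco2_slope",   # dimensionless (L/min per L/min)
    "dvo2_dwr",       # mL/min/W
    "rerpeak",        # dimensionless
    "hr_frac",        # peak HR as fraction of predicted (220 - age)
    "lean_frac",      # lean mass as fraction of body weight
)

#: Full joint-draw ordering used by the Gaussian copula.
ALL_VARIABLES = LATENT_FACTORS + FAT_FRACTION_FACTORS + MARGINAL_VARIABLES

#: Hard clip ranges applied after the Gaussian draw (physiological guards).
CLIP_RANGES = {
    "ff_subq": (0.55, 0.95),
    "ff_visceral": (0.50, 0.95),
    "ff_muscle": (0.01, 0.35),
    "ff_liver": (0.01, 0.45),
    "hr_frac": (0.70, 1.08),
    "lean_frac": (0.30, 0.90),
}


@dataclass
class Marginal:
    """Gaussian marginal, mean and standard deviation in natural units."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"marginal SD must be >= 0, got {self.sd}")


def _marginals(**kw: tuple[float, float]) -> dict[str, Marginal]:
    return {k: Marginal(*v) for k, v in kw.items()}


# Published cohort characteristics of the 50-year-old participants
# (mean, SD), one set per sex.  lean_frac and hr_frac are not published:
# lean_frac is chosen so VO2peak / (lean_frac * weight) reproduces the
# published VO2lean means (48.1 / 45.9 mL/kg/min); hr_frac is an assumed
# near-maximal-effort distribution.
MALE_MARGINALS = _marginals(
    height=(179.5, 6.5),
    weight=(85.0, 11.3),
    waist=(93.5, 9.5),
    vo2peak=(2878.1, 516.5),
    vevco2_slope=(27.1, 3.4),
    dvo2_dwr=(11.2, 1.2),
    rerpeak=(1.1, 0.1),
    hr_frac=(0.97, 0.05),
    lean_frac=(0.704, 0.03),
)

FEMALE_MARGINALS = _marginals(
    height=(166.8, 6.4),
    weight=(70.7, 12.4),
    waist=(88.5, 11.3),
    vo2peak=(1911.9, 359.4),
    vevco2_slope=(25.5, 4.0),
    dvo2_dwr=(10.2, 1.1),
    rerpeak=(1.1, 0.1),
    hr_frac=(0.97, 0.05),
    lean_frac=(0.589, 0.03),
)

FF_MARGINALS = _marginals(
    ff_subq=(0.85, 0.04),
    ff_visceral=(0.80, 0.05),
    ff_muscle=(0.08, 0.03),
    ff_liver=(0.06, 0.03),
)


@dataclass
class GridSpec:
    """Phantom voxel grid: shape (x=LR, y=AP, z=FH) and spacing in mm.

    The default desk-scale grid is 64x48x128 voxels at 4x4x8 mm, an
    anisotropic grid whose coarse foot-head axis mimics thick-slice
    whole-body water-fat MRI (2.07 x 2.07 x 8.0 mm at full resolution).
    """

    shape: tuple[int, int, int] = (64, 48, 128)
    spacing: tuple[float, float, float] = (4.0, 4.0, 8.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be > 0")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BreathNoise:
    """Additive zero-mean Gaussian noise SDs per breath channel."""

    vo2_ml_min: float = 20.0
    vco2_ml_min: float = 20.0
    ve_l_min: float = 0.5
    hr_bpm: float = 2.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"noise SD {f.name} must be >= 0")


@dataclass
class RampProtocol:
    """Ramp-test constants: 10 W/min increments starting at 50 W (males)
    or 30 W (females), sampled every 2 s as a breath-by-breath surrogate."""

    start_load_male_w: float = 50.0
    start_load_female_w: float = 30.0
    ramp_w_per_min: float = 10.0
    sample_dt_s: float = 2.0
    rest_duration_s: float = 60.0
    plateau_duration_s: float = 30.0   # hold peak load for one averaging window
    vo2_intercept_ml_min: float = 300.0  # V(.)O2 at zero external load
    rer_start: float = 0.80
    hr_rest_bpm: float = 80.0
    rcp_vco2_fraction: float = 0.85    # RCP position as fraction of peak VCO2
    rcp_slope_factor: float = 1.4      # VE-VCO2 slope multiplier beyond RCP


@dataclass
class CohortConfig:
    """Full description of one synthetic cohort."""

    n_male: int = 40
    n_female: int = 40
    seed: int = 0
    age_years: float = 50.0
    smoker_prevalence: float = 0.10
    missing_lean_rate: float = 0.0
    male: dict[str, Marginal] = field(default_factory=lambda: dict(MALE_MARGINALS))
    female: dict[str, Marginal] = field(default_factory=lambda: dict(FEMALE_MARGINALS))
    fat_fractions: dict[str, Marginal] = field(default_factory=lambda: dict(FF_MARGINALS))
    #: planted pairwise correlations, entries (var_a, var_b, rho) over
    #: ALL_VARIABLES names; the pseudo-target "vo2kg" is resolved into an
    #: equivalent vo2peak correlation (see resolve_correlations).
    correlations: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("weight", "vo2peak", 0.5)]
    )
    #: extra entries applied to one sex only (sex-specific planted effects)
    correlations_male: list[tuple[str, str, float]] = field(default_factory=list)
    correlations_female: list[tuple[str, str, float]] = field(default_factory=list)
    grid: GridSpec = field(default_factory=GridSpec)
    noise: BreathNoise = field(default_factory=BreathNoise)
    protocol: RampProtocol = field(default_factory=RampProtocol)

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not 0 <= self.smoker_prevalence <= 1:
            raise ValueError("smoker prevalence must be in [0, 1]")

    def start_load(self, sex: str) -> float:
        return (
            self.protocol.start_load_male_w
            if sex == "male"
            else self.protocol.start_load_female_w
        )

    def marginals(self, sex: str) -> dict[str, Marginal]:
        if sex == "male":
            return self.male
        if sex == "female":
            return self.female
        raise ValueError(f"unknown sex {sex!r}")

    def correlation_entries(self, sex: str) -> list[tuple[str, str, float]]:
        extra = self.correlations_male if sex == "male" else self.correlations_female
        return list(self.correlations) + list(extra)


@dataclass
class RegistrationConfig:
    """Multi-resolution symmetric-forces demons settings.

    Smoothing SDs are in mm; ``step_mm`` caps the per-iteration update
    magnitude.  The optimisation is fully deterministic.
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (60, 30, 10)
    sigma_field_mm: float = 12.0
    sigma_update_mm: float = 6.0
    step_mm: float = 2.0
    intensity_scale: float = 1.0  # weight of fat-fraction channel vs mask
    presmooth_sigma_vox: float = 0.75  # finest-level image smoothing

    def __post_init__(self) -> None:
        if len(self.shrink_factors) != len(self.iterations):
            raise ValueError("shrink_factors and iterations must align")
        if len(self.shrink_factors) < 1:
            raise ValueError("at least one pyramid level required")
        if any(i < 1 for i in self.iterations):
            raise ValueError("iterations per level must be >= 1")


@dataclass
class StatConfig:
    """Voxel-wise statistics settings: raw p < alpha thresholding (no
    multiple-testing correction by default, mirroring the mass-univariate
    procedure), cluster-extent filtering within anatomical structures."""

    alpha: float = 0.05
    min_cluster_voxels: int = 27
    connectivity: int = 26
    two_sided: bool = True
    fdr: bool = False
    use_log_jacobian: bool = False
    smooth_fwhm_mm: float = 0.0
    peak_window_s: float = 30.0
    rcp_slope_ratio: float = 1.15
    covariates: tuple[str, ...] = (
        "vo2peak",
        "vo2kg",
        "vo2lean",
        "vo2hr",
        "vevco2_slope",
        "dvo2_dwr",
        "rerpeak",
    )
    sexes: tuple[str, ...] = ("male", "female")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    stats: StatConfig = field(default_factory=StatConfig)
    write_images: bool = True


# ---------------------------------------------------------------------------
# Correlation-matrix machinery
# ---------------------------------------------------------------------------

def resolve_correlations(
    entries: Sequence[tuple[str, str, float]],
    marginals: dict[str, Marginal],
) -> list[tuple[str, str, float]]:
    """Resolve pseudo-target ``vo2kg`` entries into vo2peak correlations.

    vo2kg is derived as vo2peak/weight and never drawn; to plant
    rho(x, vo2kg) we linearize the ratio around its mean:
    vo2kg ~ const * (1 + dV/muV - dW/muW), whose latent representation is
    u = (aV zV - aW zW)/s with aV, aW the coefficients of variation and
    s^2 = aV^2 + aW^2 - 2 aV aW rho(V, W).  Keeping rho(x, weight) at its
    configured value (0 unless set), rho(x, vo2peak) is solved so that
    corr(x, u) equals the requested value.
    """
    plain = [(a, b, r) for a, b, r in entries if "vo2kg" not in (a, b)]
    derived = [(a, b, r) for a, b, r in entries if "vo2kg" in (a, b)]
    if not derived:
        return list(plain)

    lookup = {}
    for a, b, r in plain:
        lookup[frozenset((a, b))] = r
    c_vw = lookup.get(frozenset(("vo2peak", "weight")), 0.0)
    a_v = marginals["vo2peak"].sd / marginals["vo2peak"].mean
    a_w = marginals["weight"].sd / marginals["weight"].mean
    s = np.sqrt(a_v**2 + a_w**2 - 2 * a_v * a_w * c_vw)

    out = list(plain)
    for a, b, rho in derived:
        other = b if a == "vo2kg" else a
        if other == "vo2kg":
            raise ValueError("cannot correlate vo2kg with itself")
        r_xw = lookup.get(frozenset((other, "weight")), 0.0)
        # corr(x, u) = (aV r_xV - aW r_xW) / s  =>  solve for r_xV
        r_xv = (rho * s + a_w * r_xw) / a_v
        if abs(r_xv) > 1:
            raise ValueError(
                f"planted rho({other}, vo2kg)={rho} requires "
                f"rho({other}, vo2peak)={r_xv:.3f} outside [-1, 1]"
            )
        out.append((other, "vo2peak", r_xv))
    return out


def build_correlation_matrix(
    entries: Sequence[tuple[str, str, float]],
    marginals: dict[str, Marginal],
) -> np.ndarray:
    """Assemble the full latent correlation matrix over ALL_VARIABLES.

    Raises ``ValueError`` if an entry names an unknown variable, a pair is
    specified twice with conflicting values, or the resulting matrix is
    not positive semi-definite.
    """
    resolved = resolve_correlations(entries, marginals)
    idx = {name: i for i, name in enumerate(ALL_VARIABLES)}
    n = len(ALL_VARIABLES)
    mat = np.eye(n)
    seen: dict[frozenset, float] = {}
    for a, b, rho in resolved:
        if a not in idx or b not in idx:
            raise ValueError(f"unknown correlation variable in ({a}, {b})")
        if a == b:
            raise ValueError(f"self-correlation entry for {a}")
        if not -1 <= rho <= 1:
            raise ValueError(f"correlation rho({a},{b})={rho} outside [-1, 1]")
        key = frozenset((a, b))
        if key in seen and not np.isclose(seen[key], rho):
            raise ValueError(f"conflicting correlation entries for ({a}, {b})")
        seen[key] = rho
        mat[idx[a], idx[b]] = rho
        mat[idx[b], idx[a]] = rho
    eigmin = float(np.linalg.eigvalsh(mat).min())
    if eigmin < -1e-8:
        raise ValueError(
            f"latent correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3e}); reduce the planted correlations"
        )
    return mat


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(config: PipelineConfig) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=False)


def _marg_dict(d: dict) -> dict[str, Marginal]:
    return {k: Marginal(**v) if isinstance(v, dict) else v for k, v in d.items()}


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    co = dict(data.get("cohort", {}))
    for sex_key in ("male", "female", "fat_fractions"):
        if sex_key in co:
            co[sex_key] = _marg_dict(co[sex_key])
    for key in ("correlations", "correlations_male", "correlations_female"):
        if key in co:
            co[key] = [tuple(e) for e in co[key]]
    if "grid" in co and isinstance(co["grid"], dict):
        co["grid"] = GridSpec(**co["grid"])
    if "noise" in co and isinstance(co["noise"], dict):
        co["noise"] = BreathNoise(**co["noise"])
    if "protocol" in co and isinstance(co["protocol"], dict):
        co["protocol"] = RampProtocol(**co["protocol"])
    cohort = CohortConfig(**co)
    reg_d = dict(data.get("registration", {}))
    for k in ("shrink_factors", "iterations"):
        if k in reg_d:
            reg_d[k] = tuple(reg_d[k])
    reg = RegistrationConfig(**reg_d)
    st_d = dict(data.get("stats", {}))
    for k in ("covariates", "sexes"):
        if k in st_d:
            st_d[k] = tuple(st_d[k])
    stats = StatConfig(**st_d)
    return PipelineConfig(
        cohort=cohort,
        registration=reg,
        stats=stats,
        write_images=data.get("write_images", True),
    )


def config_from_yaml(text: str) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(text) or {})


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_yaml(fh.read())


def default_config() -> PipelineConfig:
    return PipelineConfig()
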