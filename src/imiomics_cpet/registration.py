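"""Deformable registration of subject phantoms to the common reference.

A multi-resolution symmetric-forces demons algorithm with Gaussian field
regularization, driven by two equally weighted similarity channels: the
fat-fraction image and the binary body mask (sum-of-squared-differences).
The optimisation contains no randomness, so registration is fully
deterministic given its configuration.

The resulting displacement field u(x), in mm on the reference grid, maps
reference coordinates to subject coordinates (x -> x + u(x)).  The local
volume change of that mapping is its Jacobian determinant, computed with
spacing-aware central differences: J > 1 means the subject is locally
larger than the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import RegistrationConfig
from .synthetic_cohort import PhantomVolume


@dataclass
class DeformationField:
    """Displacement in mm, shape (3, nx, ny, nz), on the reference grid."""

    displacement: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValueError("displacement must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[1:]


# ---------------------------------------------------------------------------
# Similarity channels
# ---------------------------------------------------------------------------

def registration_channels(phantom: PhantomVolume, intensity_scale: float = 1.0):
    """Fat-fraction image (0 outside the body) and body mask, both O(1)."""
    total = phantom.water + phantom.fat
    ff = np.zeros(total.shape, dtype=np.float64)
    np.divide(phantom.fat, total, out=ff, where=total > 0)
    mask = (phantom.labels > 0).astype(np.float64)
    return [intensity_scale * ff, mask]


# ---------------------------------------------------------------------------
# Demons optimisation
# ---------------------------------------------------------------------------

def _downsample(img: np.ndarray, shrink: int, presmooth: float = 0.0) -> np.ndarray:
    if shrink == 1:
        img = img.astype(np.float64)
        return ndimage.gaussian_filter(img, presmooth) if presmooth > 0 else img
    sm = ndimage.gaussian_filter(img.astype(np.float64), sigma=shrink / 2.0)
    out_shape = tuple(max(1, round(s / shrink)) for s in img.shape)
    return ndimage.zoom(sm, [o / s for o, s in zip(out_shape, img.shape)], order=1)


def _resize_field(u: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    if u.shape[1:] == shape:
        return u
    out = np.empty((3,) + shape)
    for a in range(3):
        out[a] = ndimage.zoom(u[a], [t / s for t, s in zip(shape, u.shape[1:])], order=1)
    return out


def _warp_channel(img: np.ndarray, u: np.ndarray, spacing) -> np.ndarray:
    idx = np.indices(img.shape, dtype=np.float64)
    coords = [idx[a] + u[a] / spacing[a] for a in range(3)]
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def _ssd(fixed_chs, moving_chs) -> float:
    return float(sum(np.mean((f - m) ** 2) for f, m in zip(fixed_chs, moving_chs)))


def _demons_level(
    fixed_chs, moving_chs, spacing, u0, iterations, sigma_update_vox, sigma_field_vox, step_cap
):
    u = u0.copy()
    grads_f = [np.stack(np.gradient(f, *spacing)) for f in fixed_chs]
    sigma_x2 = float(np.mean(spacing)) ** 2
    best_u = u.copy()
    best_sim = _ssd(fixed_chs, [_warp_channel(m, u, spacing) for m in moving_chs])
    for _ in range(iterations):
        update = np.zeros_like(u)
        for f, m, gf in zip(fixed_chs, moving_chs, grads_f):
            mw = _warp_channel(m, u, spacing)
            diff = f - mw
            gm = np.stack(np.gradient(mw, *spacing))
            g = 0.5 * (gf + gm)
            g2 = (g**2).sum(axis=0)
            denom = g2 + diff**2 / sigma_x2
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(denom > 1e-9, diff / denom, 0.0)
            update += w * g
        update /= len(fixed_chs)
        # fluid-like smoothing of the update, then cap its magnitude
        for a in range(3):
            update[a] = ndimage.gaussian_filter(update[a], sigma_update_vox)
        mag = np.sqrt((update**2).sum(axis=0))
        over = mag > step_cap
        if np.any(over):
            scale = np.where(over, step_cap / np.maximum(mag, 1e-12), 1.0)
            update *= scale
        u += update
        # diffusion-like regularization of the accumulated field
        for a in range(3):
            u[a] = ndimage.gaussian_filter(u[a], sigma_field_vox)
        sim = _ssd(fixed_chs, [_warp_channel(m, u, spacing) for m in moving_chs])
        if sim < best_sim:
            best_sim = sim
            best_u = u.copy()
    return best_u, best_sim


def register(
    fixed: PhantomVolume,
    moving: PhantomVolume,
    config: RegistrationConfig | None = None,
    fixed_id: str = "reference",
    moving_id: str = "subject",
) -> DeformationField:
    """Register ``moving`` onto ``fixed`` (both on the same grid).

    Returns the displacement field on the fixed (reference) grid.  Raises
    if either body mask is empty or if the optimised field folds
    (non-positive Jacobian) anywhere on the fixed body mask.
    """
    if config is None:
        config = RegistrationConfig()
    if fixed.water.shape != moving.water.shape:
        raise ValueError("fixed and moving phantoms must share one grid")
    if not np.any(fixed.labels > 0) or not np.any(moving.labels > 0):
        raise ValueError("empty body mask")

    fixed_chs_full = registration_channels(fixed, config.intensity_scale)
    moving_chs_full = registration_channels(moving, config.intensity_scale)
    spacing = np.asarray(fixed.spacing, dtype=float)

    u = None
    for shrink, iters in zip(config.shrink_factors, config.iterations):
        f_chs = [_downsample(c, shrink, config.presmooth_sigma_vox) for c in fixed_chs_full]
        m_chs = [_downsample(c, shrink, config.presmooth_sigma_vox) for c in moving_chs_full]
        sp = spacing * np.array(fixed.water.shape) / np.array(f_chs[0].shape)
        if u is None:
            u = np.zeros((3,) + f_chs[0].shape)
        else:
            u = _resize_field(u, f_chs[0].shape)
        sig_up = [config.sigma_update_mm / s for s in sp]
        sig_fl = [config.sigma_field_mm / s for s in sp]
        step_cap = config.step_mm * shrink
        u, _ = _demons_level(f_chs, m_chs, sp, u, iters, sig_up, sig_fl, step_cap)
    u = _resize_field(u, fixed.water.shape)

    out = DeformationField(
        displacement=u,
        spacing=fixed.spacing,
        provenance={
            "fixed": fixed_id,
            "moving": moving_id,
            "shrink_factors": list(config.shrink_factors),
            "iterations": list(config.iterations),
            "sigma_field_mm": config.sigma_field_mm,
            "sigma_update_mm": config.sigma_update_mm,
            "step_mm": config.step_mm,
            "presmooth_sigma_vox": config.presmooth_sigma_vox,
        },
    )
    jac = jacobian_determinant(out)
    body = fixed.labels > 0
    jmin = float(jac[body].min())
    if jmin <= 0:
        raise RuntimeError(
            f"registration produced a folding deformation (min Jacobian "
            f"{jmin:.3f} on the body mask); increase sigma_field_mm or "
            f"reduce step_mm"
        )
    return out


# ---------------------------------------------------------------------------
# Deformation application and Jacobian
# ---------------------------------------------------------------------------

def apply_deformation(
    field: DeformationField,
    image: np.ndarray,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> np.ndarray:
    """Resample a subject-grid image into reference space.

    Trilinear interpolation for intensities, nearest-neighbour for label
    maps; samples falling outside the subject grid take ``fill``.
    """
    image = np.asarray(image)
    if image.shape != field.grid_shape:
        raise ValueError(
            f"grid mismatch: image {image.shape} vs field {field.grid_shape}"
        )
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    idx = np.indices(image.shape, dtype=np.float64)
    coords = [idx[a] + field.displacement[a] / field.spacing[a] for a in range(3)]
    return ndimage.map_coordinates(
        image.astype(np.float64), coords, order=order, mode="constant", cval=fill
    )


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """Jacobian determinant of x -> x + u(x).

    Spatial derivatives of u are taken with spacing-aware central
    differences (one-sided at grid boundaries); the determinant of
    I + du/dx is evaluated voxel-wise.
    """
    u = field.displacement
    sp = field.spacing
    # g[a][b] = d u_a / d x_b
    g = [[np.gradient(u[a], sp[b], axis=b) for b in range(3)] for a in range(3)]
    a00 = 1.0 + g[0][0]
    a01, a02 = g[0][1], g[0][2]
    a10, a11, a12 = g[1][0], 1.0 + g[1][1], g[1][2]
    a20, a21, a22 = g[2][0], g[2][1], 1.0 + g[2][2]
    return (
        a00 * (a11 * a22 - a12 * a21)
        - a01 * (a10 * a22 - a12 * a20)
        + a02 * (a10 * a21 - a11 * a20)
    )


def make_gaussian_warp(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_vox: tuple[float, float, float] | None = None,
    sigma_mm: float = 60.0,
    peak_mm: tuple[float, float, float] = (4.0, 0.0, 0.0),
) -> DeformationField:
    """Smooth synthetic Gaussian-bump displacement (testing utility)."""
    idx = np.indices(shape, dtype=np.float64)
    if center_vox is None:
        center_vox = tuple((s - 1) / 2.0 for s in shape)
    r2 = sum(
        ((idx[a] - center_vox[a]) * spacing[a]) ** 2 for a in range(3)
    )
    bump = np.exp(-r2 / (2.0 * sigma_mm**2))
    disp = np.stack([peak_mm[a] * bump for a in range(3)])
    return DeformationField(displacement=disp, spacing=spacing, provenance={"synthetic": True})
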