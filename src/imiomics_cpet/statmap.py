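"""Voxel-wise mass-univariate statistics.

At every voxel of the analysis mask a Pearson correlation is computed
between the per-subject map value (tissue volume or fat content) and a
CPET index across subjects; two-sided p-values come from the exact
t-transform with n-2 degrees of freedom.  Voxels are thresholded at raw
p < alpha (no multiple-testing correction by default, matching the
mass-univariate procedure; Benjamini-Hochberg FDR is available behind a
flag).  The reporting rule "significant correlations in many adjacent
voxels within one anatomical structure" is quantified by
connected-component filtering: components of the significance mask
smaller than a voxel-count threshold are discarded, and components are
split by anatomical label so a cluster never spans structures.  Males
and females are analysed separately; a pooled analysis is optional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthetic_cohort import LABEL_NAMES
from .voxel_maps import VoxelMapStack

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMap:
    r: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray
    clusters: np.ndarray
    n: int
    covariate: str
    map_family: str
    sex: str
    alpha: float


@dataclass
class RegionSummary:
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# Voxel-wise Pearson
# ---------------------------------------------------------------------------

def voxelwise_pearson(
    stack: VoxelMapStack,
    covariate: np.ndarray,
    family: str,
    covariate_name: str = "",
    sex: str = "pooled",
    alpha: float = 0.05,
    fdr: bool = False,
    subject_subset: np.ndarray | None = None,
) -> CorrelationMap:
    """Pearson r and two-sided p at every analysed voxel.

    ``covariate`` holds one finite value per subject (after optional
    ``subject_subset`` boolean selection).  Voxels whose map values have
    zero variance across subjects get undefined r and never enter the
    significance mask.
    """
    maps = stack.family(family)
    if subject_subset is not None:
        maps = maps[subject_subset]
        covariate = np.asarray(covariate, dtype=float)[subject_subset]
    else:
        covariate = np.asarray(covariate, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if covariate.size != n:
        raise ValueError("covariate length does not match stack depth")
    if not np.all(np.isfinite(covariate)):
        raise ValueError("covariate contains non-finite values")
    if covariate.std() == 0:
        raise ValueError("constant covariate")

    x = maps.astype(np.float64)
    xc = x - x.mean(axis=0)
    yc = covariate - covariate.mean()
    sxx = (xc**2).sum(axis=0)
    syy = float((yc**2).sum())
    sxy = np.tensordot(yc, xc, axes=(0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    r = np.where(sxx > 0, r, np.nan)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.full(r.shape, np.nan)
    defined = np.isfinite(r)
    exact_one = defined & (np.abs(r) >= 1.0)
    finite_t = defined & ~exact_one
    p[finite_t] = 2.0 * stats.t.sf(np.abs(t[finite_t]), n - 2)
    p[exact_one] = 0.0

    analysed = stack.mask & defined
    if fdr:
        q = np.full(p.shape, np.nan)
        q[analysed] = stats.false_discovery_control(p[analysed], method="bh")
        sig = analysed & (q < alpha)
    else:
        sig = analysed & (p < alpha)
    return CorrelationMap(
        r=r,
        p=p,
        sig_mask=sig,
        clusters=np.zeros(r.shape, dtype=np.int32),
        n=n,
        covariate=covariate_name,
        map_family=family,
        sex=sex,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Cluster (adjacency) filtering
# ---------------------------------------------------------------------------

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def cluster_filter(
    cmap: CorrelationMap,
    labels: np.ndarray,
    min_voxels: int = 27,
    connectivity: int = 26,
) -> CorrelationMap:
    """Remove significant components smaller than ``min_voxels``.

    Components are found at the requested 3D connectivity within each
    anatomical label separately, so a cluster never spans two
    structures.  Returns a new map with the filtered significance mask
    and consecutive nonzero cluster labels.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    sig = np.asarray(cmap.sig_mask, dtype=bool)
    clusters = np.zeros(sig.shape, dtype=np.int32)
    kept = np.zeros_like(sig)
    next_id = 1
    for lid in np.unique(labels[sig]):
        comp, ncomp = ndimage.label(sig & (labels == lid), structure=structure)
        if ncomp == 0:
            continue
        sizes = np.bincount(comp.ravel())
        for cid in range(1, ncomp + 1):
            if sizes[cid] >= min_voxels:
                m = comp == cid
                kept |= m
                clusters[m] = next_id
                next_id += 1
    return replace(cmap, sig_mask=kept, clusters=clusters)


# ---------------------------------------------------------------------------
# Sex-stratified analysis
# ---------------------------------------------------------------------------

def stratified_maps(
    stack: VoxelMapStack,
    covariates: pd.DataFrame,
    covariate_names: list[str],
    families: tuple[str, ...] = ("volume", "fat"),
    sexes: tuple[str, ...] = ("male", "female"),
    alpha: float = 0.05,
    min_cluster_voxels: int = 27,
    connectivity: int = 26,
    fdr: bool = False,
) -> dict[tuple[str, str, str], CorrelationMap]:
    """One cluster-filtered CorrelationMap per (sex, covariate, family).

    ``covariates`` must carry an ``id`` column (or index) and a ``sex``
    column; rows are aligned to the stack by identifier, never by
    position.  Strata with fewer than 3 subjects are skipped with a
    warning.  ``sexes`` may include ``"pooled"``.
    """
    cov = covariates.copy()
    if "id" in cov.columns:
        cov = cov.set_index("id")
    try:
        cov = cov.loc[stack.subjects]
    except KeyError as exc:
        raise ValueError(f"covariate table is missing stack subjects: {exc}") from exc

    out: dict[tuple[str, str, str], CorrelationMap] = {}
    for sex in sexes:
        subset = (
            np.ones(stack.n, dtype=bool)
            if sex == "pooled"
            else (cov["sex"].to_numpy() == sex)
        )
        if subset.sum() < 3:
            logger.warning("stratum %s has %d subjects (<3); skipped", sex, subset.sum())
            continue
        for name in covariate_names:
            values = cov[name].to_numpy(dtype=float)
            ok = subset & np.isfinite(values)
            if ok.sum() < 3:
                logger.warning(
                    "stratum %s / %s has %d finite values (<3); skipped", sex, name, ok.sum()
                )
                continue
            for fam in families:
                cmap = voxelwise_pearson(
                    stack,
                    values,
                    fam,
                    covariate_name=name,
                    sex=sex,
                    alpha=alpha,
                    fdr=fdr,
                    subject_subset=ok,
                )
                out[(sex, name, fam)] = cluster_filter(
                    cmap, stack.labels, min_voxels=min_cluster_voxels, connectivity=connectivity
                )
    return out


# ---------------------------------------------------------------------------
# Region summaries (quantified substitute for visual map reading)
# ---------------------------------------------------------------------------

def region_summary(
    cmap: CorrelationMap,
    labels: np.ndarray,
    mask: np.ndarray,
) -> pd.DataFrame:
    """Per-anatomical-label mean r, significant-voxel share and largest
    intra-label cluster size.  Voxels with undefined r are excluded from
    both the numerator and denominator of the share."""
    rows = []
    defined = mask & np.isfinite(cmap.r)
    for lid, lname in LABEL_NAMES.items():
        if lid == 0:
            continue
        in_label = defined & (labels == lid)
        n_vox = int(in_label.sum())
        if n_vox == 0:
            rows.append(
                dict(
                    label_id=lid, label=lname, covariate=cmap.covariate,
                    family=cmap.map_family, sex=cmap.sex, n_voxels=0,
                    mean_r=np.nan, sig_share=0.0, largest_cluster=0, covered=False,
                )
            )
            continue
        sig_in = cmap.sig_mask & in_label
        largest = 0
        ids = cmap.clusters[in_label]
        ids = ids[ids > 0]
        if ids.size:
            largest = int(np.bincount(ids).max())
        rows.append(
            dict(
                label_id=lid, label=lname, covariate=cmap.covariate,
                family=cmap.map_family, sex=cmap.sex, n_voxels=n_vox,
                mean_r=float(cmap.r[in_label].mean()),
                sig_share=float(sig_in.sum() / n_vox),
                largest_cluster=largest, covered=True,
            )
        )
    return pd.DataFrame(rows)


def significant_fraction(cmap: CorrelationMap, mask: np.ndarray) -> float:
    """Share of analysed (defined-r) voxels that are significant."""
    defined = mask & np.isfinite(cmap.r)
    n = int(defined.sum())
    if n == 0:
        return 0.0
    return float((cmap.sig_mask & defined).sum() / n)
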