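"""Infusion-shape and model-comparison metrics.

An infusion region is the set of voxels whose drug concentration exceeds
2.5% of the infused concentration c0. Two simulations are compared through
the concentration RMSD over the union of their regions, the angle between
their PCA principal directions, the linear penetration length along those
directions, and the Jaccard overlap of the regions; per-orientation
differences are assessed with t statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .imaging_io import ScalarVolume, _check_same_grid

__all__ = [
    "InfusionRegion",
    "infusion_region",
    "rmsd",
    "principal_direction",
    "angle_between",
    "penetration_length",
    "overlap_fraction",
    "orientation_stats",
]

C_MIN_FRACTION = 0.025


@dataclasses.dataclass
class InfusionRegion:
    """Voxels reached by the drug above the c_min threshold."""

    voxels: np.ndarray            # boolean grid
    coordinates_mm: np.ndarray    # (n, 3) voxel-centre world coordinates
    voxel_volume_mm3: float

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


def infusion_region(c: ScalarVolume, c0: float,
                    c_min_fraction: float = C_MIN_FRACTION) -> InfusionRegion:
    """Region where the concentration is strictly above c_min = f * c0."""
    sel = c.data > c_min_fraction * c0
    return InfusionRegion(sel, c.voxel_centers_mm(sel), c.voxel_volume_mm3)


def rmsd(cA: ScalarVolume, cB: ScalarVolume, c0: float,
         c_min_fraction: float = C_MIN_FRACTION) -> float:
    """Concentration-normalized RMS difference over the union of regions.

    RMSD = (1/c0) sqrt( sum_i V_i (cA_i - cB_i)^2 / (V_A u V_B) ), with the
    sum over the union of the two infusion regions and V_i the per-voxel
    volume (kept explicit although it cancels on a uniform grid). Two empty
    regions give 0 by convention.
    """
    _check_same_grid(cA, cB, "concentration fields")
    union = (cA.data > c_min_fraction * c0) | (cB.data > c_min_fraction * c0)
    if not union.any():
        return 0.0
    vi = cA.voxel_volume_mm3
    v_union = union.sum() * vi
    diff2 = (cA.data[union] - cB.data[union]) ** 2
    return float(np.sqrt((vi * diff2).sum() / v_union) / c0)


def principal_direction(region: InfusionRegion,
                        weights: np.ndarray | None = None) -> np.ndarray:
    """First principal axis of the region's voxel-centre coordinates.

    Unweighted PCA of the coordinates by default (pass per-voxel
    ``weights``, e.g. concentrations, for the weighted variant). The sign is
    normalized so the first non-negligible component is positive; a
    degenerate (spherical) spectrum still returns the leading axis.
    """
    pts = np.asarray(region.coordinates_mm, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("direction undefined: region has fewer than 2 voxels")
    if weights is None:
        mean = pts.mean(axis=0)
        cov = np.cov((pts - mean).T)
    else:
        w = np.asarray(weights, dtype=float)
        mean = (pts * w[:, None]).sum(0) / w.sum()
        d = pts - mean
        cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(0) / w.sum()
    vals, vecs = np.linalg.eigh(cov)
    d = vecs[:, -1]
    for comp in d:
        if abs(comp) > 1.0e-12:
            d = d * np.sign(comp)
            break
    return d


def angle_between(d1, d2) -> float:
    """Angle in degrees between two axes (sign-insensitive), in [0, 90]."""
    d1 = np.asarray(d1, float); d2 = np.asarray(d2, float)
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    return float(np.degrees(np.arccos(np.clip(abs(d1 @ d2), 0.0, 1.0))))


def penetration_length(region: InfusionRegion, direction,
                       extra_voxel: bool = True) -> float:
    """Linear extent (mm) of the region along ``direction``.

    Max minus min of the voxel-centre projections, plus one voxel edge so a
    single voxel has nonzero support (documented convention; pass
    ``extra_voxel=False`` for the bare centre-to-centre extent).
    """
    if region.n_voxels == 0:
        return 0.0
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    proj = region.coordinates_mm @ d
    extent = float(proj.max() - proj.min())
    if extra_voxel:
        extent += region.voxel_volume_mm3 ** (1.0 / 3.0)
    return extent


def overlap_fraction(regionA: InfusionRegion, regionB: InfusionRegion,
                     denominator: str = "union") -> float:
    """Overlap of two infusion regions in percent.

    ``denominator='union'`` is the Jaccard index |A n B| / |A u B| (default);
    'min' divides by the smaller region instead. Identical regions give 100.
    """
    A, B = regionA.voxels, regionB.voxels
    inter = np.logical_and(A, B).sum()
    if denominator == "union":
        den = np.logical_or(A, B).sum()
    elif denominator == "min":
        den = min(A.sum(), B.sum())
    else:
        raise ValueError("denominator must be 'union' or 'min'")
    if den == 0:
        return 0.0
    return 100.0 * float(inter) / float(den)


def orientation_stats(values, test: str = "one_sample_one_sided",
                      paired_with=None):
    """t statistics across the per-orientation metric values.

    ``one_sample_one_sided`` tests mean(values) > 0; ``paired_two_sided``
    tests mean difference against ``paired_with``. Returns (statistic, p).
    """
    v = np.asarray(values, dtype=float)
    if test == "one_sample_one_sided":
        if np.allclose(v, v[0]):
            raise ValueError("zero variance: t statistic undefined")
        res = stats.ttest_1samp(v, 0.0, alternative="greater")
    elif test == "paired_two_sided":
        if paired_with is None:
            raise ValueError("paired test needs paired_with")
        w = np.asarray(paired_with, dtype=float)
        if np.allclose(v - w, (v - w)[0]) and not np.allclose(v, w):
            raise ValueError("zero variance: t statistic undefined")
        if np.allclose(v, w):
            return 0.0, 1.0
        res = stats.ttest_rel(v, w)
    else:
        raise ValueError(f"unknown test '{test}'")
    return float(res.statistic), float(res.pvalue)
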