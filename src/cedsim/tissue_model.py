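"""Tissue segmentation and voxel-wise diffusivity / permeability tensors.

The brain is treated as a rigid porous medium. FA thresholds split parenchyma
into grey and white matter; a free-water threshold flags CSF. Grey matter is
isotropic in both transport tensors. In white matter the diffusion tensor is
rescaled so its trace matches the drug's molecular diffusivity, and the
hydraulic permeability tensor is transversely isotropic about the principal
fibre direction, with eigenvalues (k_par, k_perp) either fixed (the classic
constant-permeability DTI model) or given per-voxel by closed-form laws in
the NODDI extracellular volume fraction (the DTI-NODDI model).
"""

from __future__ import annotations

import dataclasses
import enum
import logging

import numpy as np

from . import units
from .imaging_io import (EigenField, NoddiMaps, ScalarVolume, TensorVolume,
                         _check_same_grid)

__all__ = [
    "TissueLabel",
    "TissueConstants",
    "PermeabilityLaw",
    "segment_tissue",
    "k_parallel",
    "k_perpendicular",
    "build_diffusivity",
    "build_permeability",
    "csf_properties",
]

log = logging.getLogger(__name__)


class TissueLabel(enum.IntEnum):
    BACKGROUND = 0
    GM = 1
    WM = 2
    CSF = 3


@dataclasses.dataclass
class TissueConstants:
    """Physical constants of the transport model, in SI units.

    d0
        Gadolinium apparent molecular diffusivity, 1.54e-6 cm^2/s.
    k0_gm
        Isotropic grey-matter permeability (m^2).
    k_par_dti, k_perp_dti
        Fixed white-matter permeability eigenvalues of the constant
        (DTI-baseline) model (m^2).
    axon_radius
        Fibre radius of the microstructural model, 0.34 um.
    fa_gm_wm
        FA threshold separating grey from white matter.
    vf_water_csf
        Free-water fraction above which a voxel is CSF.
    d_csf, k_csf
        Isotropic CSF transport properties. The infusion protocol confines
        the drug to white matter, so these only matter if the plume touches
        CSF; defaults are d0 and a high permeability standing in for free
        fluid. Both are configurable.
    """

    d0: float = units.cm2_per_s(1.54e-6)
    k0_gm: float = 4.22e-18
    k_par_dti: float = 6.75e-15
    k_perp_dti: float = 4.22e-16
    axon_radius: float = 0.34e-6
    fa_gm_wm: float = 0.23
    vf_water_csf: float = 0.99
    d_csf: float | None = None
    k_csf: float = 1.0e-13

    def __post_init__(self):
        if self.d_csf is None:
            self.d_csf = self.d0
        for name in ("d0", "k0_gm", "k_par_dti", "k_perp_dti",
                     "axon_radius", "d_csf", "k_csf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("fa_gm_wm", "vf_water_csf"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


# Closed-form permeability laws for aligned fibre bundles, as functions of
# the solid fraction phi = 1 - vf_ecs. Axial flow follows the
# Tamayol–Bahrami functional form, transverse flow the Kuwabara form; the
# default coefficients are the refit values for triangular axon packings.
TAMAYOL_BAHRAMI_COEFFS = (2.97, -1.47, 0.94, 2.0, -0.5, -0.039)
KUWABARA_COEFFS = (7.77, -1.56, 1.04, 2.05, -0.5)

#: Original literature coefficients of the two functional forms (dilute-array
#: theory), useful as independent cross-checks of the microscale solvers.
TAMAYOL_BAHRAMI_ORIGINAL = (4.0, -1.479, 1.0, 2.0, -0.5, -0.0186)
KUWABARA_ORIGINAL = (8.0, -1.5, 1.0, 2.0, -0.5)


def _tb_bracket(phi, c):
    _, b0, blog, b1, b2, b4 = c
    return b0 + blog * (-np.log(phi)) + b1 * phi + b2 * phi ** 2 + b4 * phi ** 4


def _kuwabara_bracket(phi, c):
    _, b0, blog, b1, b2 = c
    return b0 + blog * (-np.log(phi)) + b1 * phi + b2 * phi ** 2


def k_parallel(vf_ecs, r: float = 0.34e-6,
               coeffs=TAMAYOL_BAHRAMI_COEFFS):
    """Permeability along the fibres (m^2) at extracellular fraction vf_ecs.

    Evaluates k_par = r^2 / (A * phi) * (B + C(-ln phi) + D phi + E phi^2 +
    F phi^4) with phi = 1 - vf_ecs. No clamping is applied here; the law was
    fitted on vf_ecs in [0.15, 0.80] and callers are expected to clamp.
    """
    if r <= 0:
        raise ValueError("fibre radius must be positive")
    phi = 1.0 - np.asarray(vf_ecs, dtype=float)
    return r ** 2 / (coeffs[0] * phi) * _tb_bracket(phi, coeffs)


def k_perpendicular(vf_ecs, r: float = 0.34e-6,
                    coeffs=KUWABARA_COEFFS):
    """Permeability across the fibres (m^2) at extracellular fraction vf_ecs.

    Evaluates k_perp = r^2 / (A * phi) * (B + C(-ln phi) + D phi + E phi^2)
    with phi = 1 - vf_ecs. Note that with the default refit coefficients the
    bracket changes sign near vf_ecs ~ 0.29: the printed coefficients are
    rounded to two decimals and the bracket is a small difference of O(1)
    terms, so the law is meaningful only where it evaluates positive.
    """
    if r <= 0:
        raise ValueError("fibre radius must be positive")
    phi = 1.0 - np.asarray(vf_ecs, dtype=float)
    return r ** 2 / (coeffs[0] * phi) * _kuwabara_bracket(phi, coeffs)


@dataclasses.dataclass
class PermeabilityLaw:
    """White-matter permeability eigenvalues as a function of VF_ECS.

    mode="noddi" evaluates the closed-form laws per voxel; mode="constant"
    returns the fixed DTI-baseline values regardless of VF_ECS. VF_ECS is
    clamped to ``vf_clamp_range`` (the range the laws were fitted on) and the
    number of clamped voxels is logged per run.
    """

    r: float = 0.34e-6
    mode: str = "noddi"
    coeffs_parallel: tuple = TAMAYOL_BAHRAMI_COEFFS
    coeffs_perpendicular: tuple = KUWABARA_COEFFS
    vf_clamp_range: tuple = (0.15, 0.80)
    k_par_constant: float = 6.75e-15
    k_perp_constant: float = 4.22e-16

    def __post_init__(self):
        if self.mode not in ("noddi", "constant"):
            raise ValueError("mode must be 'noddi' or 'constant'")
        lo, hi = self.vf_clamp_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("vf_clamp_range must satisfy 0 < lo < hi < 1")

    def clamp(self, vf_ecs):
        """Clamp VF_ECS to the fitted range; returns (clamped, n_clamped)."""
        v = np.asarray(vf_ecs, dtype=float)
        lo, hi = self.vf_clamp_range
        clamped = np.clip(v, lo, hi)
        n = int(np.count_nonzero(clamped != v))
        return clamped, n

    def evaluate(self, vf_ecs):
        """(k_par, k_perp) in m^2 for scalar or array VF_ECS."""
        if self.mode == "constant":
            v = np.asarray(vf_ecs, dtype=float)
            return (np.full_like(v, self.k_par_constant),
                    np.full_like(v, self.k_perp_constant))
        v, n = self.clamp(vf_ecs)
        if n:
            log.info("permeability law: clamped VF_ECS in %d voxel(s) to %s",
                     n, self.vf_clamp_range)
        return (k_parallel(v, self.r, self.coeffs_parallel),
                k_perpendicular(v, self.r, self.coeffs_perpendicular))


def segment_tissue(fa: ScalarVolume, vf_water: ScalarVolume,
                   constants: TissueConstants | None = None) -> np.ndarray:
    """Label every in-mask voxel as GM, WM or CSF.

    CSF (vf_water > 0.99) takes precedence over the FA thresholds: a
    free-water voxel can have arbitrarily low FA, and the FA split is only
    meaningful for parenchyma. Then FA > 0.23 -> WM, else GM (the boundary
    value 0.23 itself goes to GM: the lower interval is closed at the top).
    """
    constants = constants or TissueConstants()
    _check_same_grid(fa, vf_water, "FA and VF_Water")
    labels = np.full(fa.shape, TissueLabel.BACKGROUND, dtype=np.int8)
    mask = fa.brain_mask & vf_water.brain_mask
    labels[mask] = TissueLabel.GM
    labels[mask & (fa.data > constants.fa_gm_wm)] = TissueLabel.WM
    labels[mask & (vf_water.data > constants.vf_water_csf)] = TissueLabel.CSF
    return labels


def _transversely_isotropic(e: np.ndarray, k_par, k_perp) -> np.ndarray:
    """E diag(k_par, k_perp, k_perp) E^T, vectorized over voxels."""
    lam = np.stack([np.broadcast_to(k_par, e.shape[:-2]),
                    np.broadcast_to(k_perp, e.shape[:-2]),
                    np.broadcast_to(k_perp, e.shape[:-2])], axis=-1)
    return np.einsum("...ik,...k,...jk->...ij", e, lam, e)


def build_diffusivity(labels: np.ndarray, eig: EigenField,
                      constants: TissueConstants | None = None) -> TensorVolume:
    """Voxel-wise drug diffusivity tensor.

    GM and CSF voxels get the isotropic molecular diffusivity D0 * I. WM
    voxels keep the shape and orientation of the water diffusion tensor but
    are rescaled by D0 / mean(lambda), so that trace(D_WM) = 3 * D0 exactly:
    the DTI tensor supplies anisotropy, the drug's molecular diffusivity
    supplies magnitude.
    """
    constants = constants or TissueConstants()
    labels = np.asarray(labels)
    shape = labels.shape
    out = np.zeros(shape + (3, 3))
    eye = np.eye(3)
    out[labels == TissueLabel.GM] = constants.d0 * eye
    out[labels == TissueLabel.CSF] = constants.d_csf * eye

    wm = labels == TissueLabel.WM
    if wm.any():
        lam = eig.eigenvalues[wm]
        mean = lam.mean(axis=-1)
        if np.any(mean <= 0):
            bad = np.argwhere(wm)[mean <= 0]
            raise ValueError(
                f"non-positive mean diffusivity in WM voxel(s) {bad[:5].tolist()}"
            )
        scale = constants.d0 / mean
        e = eig.eigenvectors[wm]
        lam_scaled = lam * scale[:, None]
        out[wm] = np.einsum("vik,vk,vjk->vij", e, lam_scaled, e)

    mask = labels != TissueLabel.BACKGROUND
    return TensorVolume.from_matrices(out, eig.affine.copy(), mask)


def build_permeability(labels: np.ndarray, eig: EigenField,
                       noddi: NoddiMaps | None = None,
                       law: PermeabilityLaw | None = None,
                       constants: TissueConstants | None = None) -> TensorVolume:
    """Voxel-wise hydraulic permeability tensor.

    GM voxels get K0 * I; CSF voxels get the configured isotropic k_csf. WM
    voxels get the transversely isotropic E diag(k_par, k_perp, k_perp) E^T
    with the main axis along the principal diffusion eigenvector, and
    (k_par, k_perp) either from the VF_ECS laws (law.mode="noddi", requires
    NODDI maps) or the fixed baseline constants (law.mode="constant").
    """
    constants = constants or TissueConstants()
    law = law or PermeabilityLaw(r=constants.axon_radius,
                                 k_par_constant=constants.k_par_dti,
                                 k_perp_constant=constants.k_perp_dti)
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (3, 3))
    eye = np.eye(3)
    out[labels == TissueLabel.GM] = constants.k0_gm * eye
    out[labels == TissueLabel.CSF] = constants.k_csf * eye

    wm = labels == TissueLabel.WM
    if wm.any():
        e = eig.eigenvectors[wm]
        if law.mode == "noddi":
            if noddi is None:
                raise ValueError("mode='noddi' requires NoddiMaps")
            vf = noddi.vf_ecs.data
            if not np.isfinite(vf[wm]).all():
                raise ValueError("VF_ECS missing (non-finite) on WM voxel(s)")
            k_par, k_perp = law.evaluate(vf[wm])
        else:
            k_par, k_perp = law.evaluate(np.zeros(int(wm.sum())))
        out[wm] = _transversely_isotropic(e, k_par, k_perp)

    mask = labels != TissueLabel.BACKGROUND
    return TensorVolume.from_matrices(out, eig.affine.copy(), mask)


def csf_properties(constants: TissueConstants | None = None):
    """Isotropic CSF transport properties (D_csf, K_csf), configurable.

    The source study confined the infusion to white matter and states no CSF
    transport constants; the simulator warns if the plume touches CSF.
    """
    constants = constants or TissueConstants()
    log.info("CSF properties: D_csf=%.4g m^2/s, K_csf=%.4g m^2",
             constants.d_csf, constants.k_csf)
    return constants.d_csf, constants.k_csf
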