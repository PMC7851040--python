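"""NIfTI-backed volume containers and diffusion-tensor utilities.

The containers mirror what a diffusion-MRI preprocessing pipeline hands over:
scalar maps (FA, NODDI compartment fractions, later pressure/concentration),
per-voxel symmetric 3x3 tensors, and the eigensystem of the diffusion tensor.
Voxel indices are 0-based; world coordinates come from the NIfTI affine (mm).

Tensor volumes are stored on disk as 4-D NIfTI with the six unique components
in lower-triangular order ``(xx, xy, yy, xz, yz, zz)`` along the last axis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "TensorVolume",
    "NoddiMaps",
    "EigenField",
    "load_scalar_volume",
    "save_scalar_volume",
    "load_tensor_volume",
    "save_tensor_volume",
    "reparameterize_noddi",
    "eigendecompose",
    "compute_fa",
]

#: Component order of the tensor storage dialect (lower-triangular).
TENSOR_COMPONENTS = ("xx", "xy", "yy", "xz", "yz", "zz")

#: Eigenvalue floor guaranteeing positive definiteness in noisy voxels (SI).
EIGENVALUE_FLOOR = 1.0e-12


def _voxel_size(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclasses.dataclass
class ScalarVolume:
    """A 3-D scalar field on a regular voxel grid.

    Parameters
    ----------
    data : (nx, ny, nz) array
        Voxel values. NaN is tolerated outside ``brain_mask``.
    affine : (4, 4) array
        Voxel-to-world transform (NIfTI convention, mm).
    brain_mask : (nx, ny, nz) bool array, optional
        Voxels that belong to the head/brain; defaults to finite voxels.
    """

    data: np.ndarray
    affine: np.ndarray = None
    brain_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3-D volume, got {self.data.ndim}-D shape {self.data.shape}"
            )
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.brain_mask is None:
            self.brain_mask = np.isfinite(self.data)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape:
            raise ValueError("brain_mask shape does not match data shape")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be strictly positive on all axes")
        bad = ~np.isfinite(self.data) & self.brain_mask
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} non-finite voxel(s) inside the brain mask"
            )

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return _voxel_size(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def voxel_centers_mm(self, where: np.ndarray | None = None) -> np.ndarray:
        """World (mm) coordinates of voxel centres; optionally only ``where``."""
        if where is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(where)
        return nib.affines.apply_affine(self.affine, idx)

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """New volume with the same grid metadata and mask."""
        return ScalarVolume(np.asarray(data), self.affine.copy(),
                            self.brain_mask.copy())


def _check_same_grid(a, b, what="volumes"):
    if a.shape != b.shape or not np.allclose(a.affine, b.affine):
        raise ValueError(f"{what} are not on the same grid")


@dataclasses.dataclass
class TensorVolume:
    """Per-voxel symmetric 3x3 tensor field.

    ``data`` holds the six unique components in the order
    ``(xx, xy, yy, xz, yz, zz)`` along the last axis.
    """

    data: np.ndarray
    affine: np.ndarray = None
    brain_mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError("tensor volume must have shape (nx, ny, nz, 6)")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.brain_mask is None:
            self.brain_mask = np.isfinite(self.data).all(axis=-1)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("brain_mask shape does not match tensor grid")

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return _voxel_size(self.affine)

    def to_matrices(self) -> np.ndarray:
        """(nx, ny, nz, 3, 3) symmetric matrices."""
        xx, xy, yy, xz, yz, zz = np.moveaxis(self.data, -1, 0)
        m = np.empty(self.shape + (3, 3), dtype=self.data.dtype)
        m[..., 0, 0] = xx
        m[..., 1, 1] = yy
        m[..., 2, 2] = zz
        m[..., 0, 1] = m[..., 1, 0] = xy
        m[..., 0, 2] = m[..., 2, 0] = xz
        m[..., 1, 2] = m[..., 2, 1] = yz
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, affine=None, brain_mask=None,
                      sym_tol: float = 1.0e-8) -> "TensorVolume":
        m = np.asarray(m)
        asym = np.abs(m - np.swapaxes(m, -1, -2)).max()
        scale = max(np.abs(m).max(), 1.0)
        if asym > sym_tol * scale:
            raise ValueError(
                f"tensor field is not symmetric (max asymmetry {asym:.3e})"
            )
        data = np.stack(
            [m[..., 0, 0], m[..., 0, 1], m[..., 1, 1],
             m[..., 0, 2], m[..., 1, 2], m[..., 2, 2]], axis=-1)
        return cls(data, affine, brain_mask)


@dataclasses.dataclass
class NoddiMaps:
    """NODDI compartment fractions per voxel.

    ``vf_inc`` (intraneurite), ``vf_enc`` (extraneurite) and ``vf_water``
    (free water / CSF) sum to 1 in every voxel; the extracellular-space
    fraction ``vf_ecs = vf_enc + vf_water`` is the space a drug can flow in.
    """

    vf_inc: ScalarVolume
    vf_enc: ScalarVolume
    vf_water: ScalarVolume

    def __post_init__(self):
        _check_same_grid(self.vf_inc, self.vf_enc, "NODDI maps")
        _check_same_grid(self.vf_inc, self.vf_water, "NODDI maps")
        mask = self.vf_inc.brain_mask
        total = (self.vf_inc.data + self.vf_enc.data + self.vf_water.data)[mask]
        if total.size and np.abs(total - 1.0).max() > 1.0e-6:
            raise ValueError("compartment fractions do not sum to 1 per voxel")

    @property
    def vf_ecs(self) -> ScalarVolume:
        return self.vf_inc.like(self.vf_enc.data + self.vf_water.data)


@dataclasses.dataclass
class EigenField:
    """Eigensystem of a symmetric tensor field.

    ``eigenvalues`` sorted descending (l1 >= l2 >= l3); ``eigenvectors`` holds
    the orthonormal columns E = [e1, e2, e3] per voxel.
    """

    eigenvalues: np.ndarray   # (..., 3), descending
    eigenvectors: np.ndarray  # (..., 3, 3), columns
    affine: np.ndarray = None
    brain_mask: np.ndarray = None

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.eye(4)
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.eigenvalues.shape[:-1], dtype=bool)

    def principal_direction(self) -> np.ndarray:
        """Unit vector e1 per voxel, shape (..., 3)."""
        return self.eigenvectors[..., :, 0]

    def reconstruct(self) -> np.ndarray:
        """E diag(l) E^T per voxel, shape (..., 3, 3)."""
        lam = self.eigenvalues
        e = self.eigenvectors
        return np.einsum("...ik,...k,...jk->...ij", e, lam, e)


# ---------------------------------------------------------------------------
# I/O

def load_scalar_volume(path, brain_mask=None) -> ScalarVolume:
    """Read a NIfTI-1/2 scalar volume.

    NaN voxels outside the mask are tolerated; non-finite values inside the
    mask raise with the offending voxel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got shape {data.shape}")
    return ScalarVolume(data, img.affine, brain_mask)


def save_scalar_volume(vol: ScalarVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_data_dtype(vol.data.dtype)
    nib.save(img, str(path))
    return path


def load_tensor_volume(path, brain_mask=None) -> TensorVolume:
    """Read a 4-D NIfTI tensor volume (six components, lower-triangular)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(
            f"expected a 4-D volume with 6 tensor components, got {data.shape}"
        )
    return TensorVolume(data, img.affine, brain_mask)


def save_tensor_volume(vol: TensorVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_data_dtype(vol.data.dtype)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# NODDI reparameterization

def reparameterize_noddi(vf_inc_raw: ScalarVolume,
                         vf_water: ScalarVolume,
                         tol: float = 1.0e-6) -> NoddiMaps:
    """Derive absolute compartment fractions from raw NODDI outputs.

    The NODDI toolbox reports the intraneurite fraction ``vf_inc_raw``
    relative to the tissue (non-free-water) compartment. Rescaling by the
    tissue fraction gives absolute fractions that sum to 1 per voxel::

        vf_inc = vf_inc_raw * (1 - vf_water)
        vf_enc = (1 - vf_inc_raw) * (1 - vf_water)

    and the extracellular space fraction is ``vf_ecs = vf_enc + vf_water``.
    """
    _check_same_grid(vf_inc_raw, vf_water, "NODDI inputs")
    mask = vf_inc_raw.brain_mask & vf_water.brain_mask
    for name, vol in (("vf_inc_raw", vf_inc_raw), ("vf_water", vf_water)):
        vals = vol.data[mask]
        if vals.size and (vals.min() < -tol or vals.max() > 1 + tol):
            raise ValueError(f"{name} has values outside [0, 1]")
    ficvf = np.clip(vf_inc_raw.data, 0.0, 1.0)
    fiso = np.clip(vf_water.data, 0.0, 1.0)
    vf_inc = ficvf * (1.0 - fiso)
    vf_enc = (1.0 - ficvf) * (1.0 - fiso)
    make = lambda d: ScalarVolume(d, vf_inc_raw.affine.copy(), mask.copy())
    return NoddiMaps(make(vf_inc), make(vf_enc), make(fiso.copy()))


# ---------------------------------------------------------------------------
# Eigendecomposition and FA

def _fix_sign(vectors: np.ndarray, tol: float = 1.0e-12) -> np.ndarray:
    """Make the first non-negligible component of each eigenvector positive."""
    # vectors: (..., 3, 3) columns; decide sign per column
    comp = vectors  # component axis is -2, column axis is -1
    sign = np.ones(comp.shape[:-2] + (comp.shape[-1],))
    decided = np.zeros_like(sign, dtype=bool)
    for i in range(comp.shape[-2]):
        c = comp[..., i, :]
        pick = (~decided) & (np.abs(c) > tol)
        sign = np.where(pick, np.sign(c), sign)
        decided |= pick
    return vectors * sign[..., None, :]


def eigendecompose(tensor: TensorVolume,
                   floor: float = EIGENVALUE_FLOOR) -> EigenField:
    """Per-voxel eigendecomposition D E = E Lambda of a symmetric tensor field.

    Eigenvalues are sorted descending and floored at ``floor`` to keep the
    reconstructed tensor positive definite in noisy voxels. Eigenvector signs
    follow the first-nonzero-component-positive convention so that repeated
    runs produce identical fields.
    """
    m = tensor.to_matrices().astype(float)
    vals, vecs = np.linalg.eigh(m)          # ascending
    vals = vals[..., ::-1]                  # descending
    vecs = vecs[..., ::-1]
    if floor is not None:
        vals = np.maximum(vals, floor)
    vecs = _fix_sign(vecs)
    return EigenField(vals, vecs, tensor.affine.copy(),
                      tensor.brain_mask.copy())


def compute_fa(eig: EigenField) -> ScalarVolume:
    """Fractional anisotropy sqrt(3/2) * ||l - lbar|| / ||l|| per voxel.

    A zero tensor (all eigenvalues ~0) gets FA = 0: such voxels are
    background or CSF, where anisotropy is meaningless.
    """
    lam = np.asarray(eig.eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)
    return ScalarVolume(fa, eig.affine.copy(), eig.brain_mask.copy())
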