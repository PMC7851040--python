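"""Synthetic DTI/NODDI phantoms with known ground truth.

Every pipeline stage is testable without subject data: the phantoms emit
exactly the products a diffusion-MRI pipeline would (a diffusion tensor
volume, an FA map, NODDI compartment fractions summing to 1, a brain mask)
on a 2 mm isotropic grid, plus a ground-truth record of the fields used to
build them.

Scenarios
---------
uniform_wm_slab
    Homogeneous white matter, a single fibre direction, constant FA and
    VF_ECS. The workhorse for solver oracles and direction-following tests.
curved_bundle
    White matter whose fibre directions follow a circular arc, for testing
    that the infusion tracks curving tracts.
three_tissue
    Stacked CSF / grey-matter / white-matter slabs exercising segmentation
    and tissue-dependent tensor assembly.

The FA <-> eigenvalue parametrization is closed-form: for an axially
symmetric tensor with eigenvalue ratio t = l_perp / l_par,
FA = (1 - t) / sqrt(1 + 2 t^2), inverted as
t = (1 - FA sqrt(3 - 2 FA^2)) / (1 - 2 FA^2)  (t = 1/4 at FA^2 = 1/2).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .imaging_io import (NoddiMaps, ScalarVolume, TensorVolume,
                         save_scalar_volume, save_tensor_volume)

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "curved_bundle_field",
    "write_phantom",
    "eigenvalue_ratio_for_fa",
]

SCENARIOS = ("uniform_wm_slab", "curved_bundle", "three_tissue")

#: Typical parenchymal water diffusivity scale (m^2/s) for the synthetic
#: tensors; the transport model rescales WM tensors to the drug diffusivity,
#: so only ratios matter downstream.
LAMBDA_PARALLEL = 1.7e-9


@dataclasses.dataclass
class PhantomSpec:
    """Recipe for a synthetic dataset.

    Defaults follow the imaging protocol the model consumes: 2 mm isotropic
    voxels; WM anisotropy FA = 0.7; VF_ECS = 0.30, the middle of the
    physiological range, split between extraneurite tissue and a small free
    water fraction; optional multiplicative noise on FA and VF maps.
    """

    shape: tuple = (32, 32, 32)
    voxel_size: float = 2.0               # mm, isotropic
    scenario: str = "uniform_wm_slab"
    fibre_direction: tuple = (1.0, 0.0, 0.0)
    fa_wm: float = 0.7
    fa_gm: float = 0.1
    vf_ecs: float = 0.30
    vf_water_wm: float = 0.05
    vf_ecs_gradient_axis: int | None = None
    vf_ecs_range: tuple = (0.15, 0.80)
    bundle_curvature: float = 0.0         # 1/mm, for curved_bundle
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 < self.fa_wm < 1.0:
            raise ValueError("fa_wm must lie in (0, 1)")
        if self.fa_wm <= 0.23:
            raise ValueError("fa_wm below the WM threshold is not white matter")
        if self.fa_gm >= 0.23:
            raise ValueError("fa_gm above the WM threshold is not grey matter")
        if not self.vf_water_wm < self.vf_ecs < 1.0:
            raise ValueError("need vf_water_wm < vf_ecs < 1")


@dataclasses.dataclass
class PhantomBundle:
    """Generated phantom plus its ground truth."""

    tensor: TensorVolume
    fa: ScalarVolume
    noddi: NoddiMaps
    mask: np.ndarray
    labels: np.ndarray
    ground_truth: dict
    spec: PhantomSpec


def eigenvalue_ratio_for_fa(fa: float) -> float:
    """l_perp / l_par of an axially symmetric tensor with the given FA."""
    if not 0.0 <= fa < 1.0:
        raise ValueError("FA must lie in [0, 1)")
    if fa == 0.0:
        return 1.0
    fa2 = fa * fa
    if abs(1.0 - 2.0 * fa2) < 1.0e-12:
        return 0.25
    return (1.0 - fa * np.sqrt(3.0 - 2.0 * fa2)) / (1.0 - 2.0 * fa2)


def _affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.diag([spec.voxel_size] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(spec.shape) - 1) / 2.0 * spec.voxel_size
    return aff


def _tensor_from_directions(dirs: np.ndarray, fa: np.ndarray) -> np.ndarray:
    """Axially symmetric tensors with principal axis ``dirs`` and given FA."""
    t = np.vectorize(eigenvalue_ratio_for_fa)(fa)
    l_par = np.full(fa.shape, LAMBDA_PARALLEL)
    l_perp = l_par * t
    d = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
    outer = d[..., :, None] * d[..., None, :]
    eye = np.eye(3)
    return (l_perp[..., None, None] * eye
            + (l_par - l_perp)[..., None, None] * outer)


def curved_bundle_field(shape, voxel_size: float, curvature: float,
                        base_direction=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Unit fibre directions along a circular arc in the x-y plane.

    ``curvature`` (1/mm) bends the bundle around a z-aligned axis placed a
    radius 1/curvature below the grid centre; zero curvature degenerates to
    the constant ``base_direction``. Directions vary smoothly: neighbouring
    voxels differ by about voxel_size * curvature radians.
    """
    shape = tuple(shape)
    if curvature == 0.0:
        d = np.asarray(base_direction, float)
        d = d / np.linalg.norm(d)
        return np.broadcast_to(d, shape + (3,)).copy()
    ii = np.indices(shape).astype(float)
    x = (ii[0] - (shape[0] - 1) / 2.0) * voxel_size
    y = (ii[1] - (shape[1] - 1) / 2.0) * voxel_size
    radius = 1.0 / curvature
    cy = -radius                       # arc centre below the grid centre
    dx, dy = x - 0.0, y - cy
    norm = np.hypot(dx, dy)
    norm = np.where(norm == 0, 1.0, norm)
    # tangent of the circle through each voxel
    dirs = np.stack([dy / norm, -dx / norm, np.zeros(shape)], axis=-1)
    return dirs


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the synthetic dataset described by ``spec``.

    Deterministic for a given seed. Raises if the requested FA values are
    inconsistent with the tissue classes they must produce.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    aff = _affine(spec)
    mask = np.ones(shape, dtype=bool)

    # per-voxel tissue plan
    labels = np.full(shape, 2, dtype=np.int8)  # WM
    if spec.scenario == "three_tissue":
        nz = shape[2]
        labels[:, :, : nz // 4] = 3                     # CSF slab
        labels[:, :, nz // 4: nz // 2] = 1              # GM slab

    # fibre directions
    if spec.scenario == "curved_bundle":
        dirs = curved_bundle_field(shape, spec.voxel_size,
                                   spec.bundle_curvature,
                                   spec.fibre_direction)
    else:
        d0 = np.asarray(spec.fibre_direction, float)
        d0 = d0 / np.linalg.norm(d0)
        dirs = np.broadcast_to(d0, shape + (3,)).copy()

    # FA field
    fa = np.full(shape, spec.fa_wm)
    fa[labels == 1] = spec.fa_gm
    fa[labels == 3] = 0.0
    if spec.noise > 0:
        fa = fa * (1.0 + spec.noise * rng.standard_normal(shape))
        fa = np.clip(fa, 0.0, 0.95)
        # keep noisy voxels on the right side of the GM/WM threshold
        fa[labels == 2] = np.maximum(fa[labels == 2], 0.24)
        fa[labels == 1] = np.minimum(fa[labels == 1], 0.22)
        fa[labels == 3] = 0.0

    # NODDI fractions
    vf_ecs = np.full(shape, float(spec.vf_ecs))
    if spec.vf_ecs_gradient_axis is not None:
        lo, hi = spec.vf_ecs_range
        ramp = np.linspace(lo, hi, shape[spec.vf_ecs_gradient_axis])
        vf_ecs = np.ones(shape) * ramp.reshape(
            [-1 if a == spec.vf_ecs_gradient_axis else 1 for a in range(3)])
    if spec.noise > 0:
        lo, hi = spec.vf_ecs_range
        vf_ecs = np.clip(vf_ecs * (1.0 + spec.noise * rng.standard_normal(shape)),
                         max(lo, spec.vf_water_wm + 0.01), hi)
    vf_water = np.full(shape, float(spec.vf_water_wm))
    vf_water[labels == 3] = 0.995
    vf_ecs[labels == 3] = 1.0 - 1.0e-4  # nearly free fluid
    vf_enc = vf_ecs - vf_water
    vf_inc = 1.0 - vf_ecs

    # diffusion tensors
    tens = _tensor_from_directions(dirs, fa)
    tens[labels == 3] = 3.0e-9 * np.eye(3)  # free-water diffusivity

    make = lambda d: ScalarVolume(d.astype(float), aff.copy(), mask.copy())
    noddi = NoddiMaps(make(vf_inc), make(vf_enc), make(vf_water))
    bundle = PhantomBundle(
        tensor=TensorVolume.from_matrices(tens, aff.copy(), mask.copy()),
        fa=make(fa),
        noddi=noddi,
        mask=mask,
        labels=labels,
        ground_truth={
            "directions": dirs,
            "fa": fa.copy(),
            "vf_ecs": vf_ecs.copy(),
            "labels": labels.copy(),
            "seed": spec.seed,
        },
        spec=spec,
    )
    return bundle


def write_phantom(bundle: PhantomBundle, directory) -> dict:
    """Write the phantom as NIfTI files plus a JSON manifest."""
    directory = Path(directory)
    if not directory.exists():
        raise FileNotFoundError(f"output directory {directory} does not exist")
    paths = {
        "tensor": save_tensor_volume(bundle.tensor, directory / "tensor.nii"),
        "fa": save_scalar_volume(bundle.fa, directory / "fa.nii"),
        "vf_inc": save_scalar_volume(bundle.noddi.vf_inc, directory / "vf_inc.nii"),
        "vf_enc": save_scalar_volume(bundle.noddi.vf_enc, directory / "vf_enc.nii"),
        "vf_water": save_scalar_volume(bundle.noddi.vf_water,
                                       directory / "vf_water.nii"),
    }
    manifest = {
        "files": {k: p.name for k, p in paths.items()},
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in dataclasses.asdict(bundle.spec).items()},
        "seed": bundle.spec.seed,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["directory"] = str(directory)
    return manifest
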