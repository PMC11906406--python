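"""Synthetic DWI phantoms with class-dependent anisotropy.

The phantom stands in for a brain scan at desk scale: four concentric tissue
classes on a cubic grid — a CSF core (isotropic, fast diffusion), a
subcortical ring (a 50/50 two-tensor mixture), a white-matter interior whose
principal diffusion direction rotates smoothly with position (spatially
coherent anisotropy, so spatial layers have structure to exploit) and a
gray-matter shell (near-isotropic, slow).  Per-voxel signals follow the
mono-exponential tensor model ``S(v) = S0 exp(-b v^T D v)``, which is
antipodally symmetric by construction — the same symmetry the Watson
interpolation kernel assumes.

Default acquisition mirrors a typical single-shell protocol: 90 gradient
directions at b = 1000 s/mm^2 plus b0 volumes; optional Rician noise
(|S + e1 + i e2|, e ~ N(0, sigma S0)).

Default diffusivities (mm^2/s) are literature-typical package defaults:
CSF (3.0, 3.0, 3.0)e-3, WM (1.7, 0.3, 0.3)e-3, GM (0.9, 0.7, 0.7)e-3,
subcortical = 50/50 WM/GM mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spherical_signal import (
    SamplingScheme,
    SphericalVolume,
    normalize_b0,
    read_bvals_bvecs,
    read_nifti,
    write_bvals_bvecs,
    write_nifti,
)

__all__ = [
    "TissueModel",
    "PhantomConfig",
    "DEFAULT_TISSUES",
    "CLASS_NAMES",
    "generate_directions",
    "tensor_signal",
    "generate_phantom",
    "generate_raw_phantom",
    "write_phantom",
    "read_phantom",
]

CLASS_NAMES = ("CSF", "subcortical", "WM", "GM")


@dataclass(frozen=True)
class TissueModel:
    """Diffusion-tensor description of one tissue class.

    ``eigenvalues`` (mm^2/s) must satisfy l1 >= l2 >= l3 > 0;
    ``orientation`` names the rule assigning the principal direction per
    voxel: ``"constant"`` (x-axis), ``"tangential"`` (rotates smoothly with
    the azimuth of the voxel position — coherent, fiber-like) or
    ``"radial"``.  ``mix_with`` points at another class id for a 50/50
    two-tensor mixture (the subcortical model).
    """

    class_id: int
    eigenvalues: tuple[float, float, float]
    orientation: str = "constant"
    s0: float = 1.0
    mix_with: int | None = None

    def __post_init__(self):
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if self.orientation not in ("constant", "tangential", "radial"):
            raise ValueError(f"unknown orientation rule {self.orientation!r}")


DEFAULT_TISSUES: dict[int, TissueModel] = {
    0: TissueModel(0, (3.0e-3, 3.0e-3, 3.0e-3)),                       # CSF
    1: TissueModel(1, (1.7e-3, 0.3e-3, 0.3e-3), "tangential",
                   mix_with=3),                                        # subcortical
    2: TissueModel(2, (1.7e-3, 0.3e-3, 0.3e-3), "tangential"),         # WM
    3: TissueModel(3, (0.9e-3, 0.7e-3, 0.7e-3)),                       # GM
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, acquisition and noise settings for one phantom."""

    grid_size: int = 32
    bvalue: float = 1000.0
    n_directions: int = 90
    n_b0: int = 3
    noise: str = "rician"  # none | gaussian | rician
    sigma: float = 0.02  # relative to S0
    seed: int = 0
    # the acquisition protocol (gradient table) is shared across scans of a
    # study, so it has its own seed, independent of the per-scan noise seed
    direction_seed: int = 2025
    tissues: dict[int, TissueModel] = field(default_factory=lambda: DEFAULT_TISSUES)
    # class shells as fractions of the outer mask radius
    radii: tuple[float, float, float, float] = (0.32, 0.46, 0.78, 1.0)
    mask_radius_fraction: float = 0.44  # outer radius / grid size

    def __post_init__(self):
        if self.grid_size < 9:
            raise ValueError("grid must be at least 9^3 so 7^3 patches exist")
        if self.n_directions < 6:
            raise ValueError("need at least 6 gradient directions")
        if self.noise not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if list(self.radii) != sorted(self.radii):
            raise ValueError("class radii must be increasing")


def generate_directions(n: int, seed: int = 0, n_b0: int = 0,
                        bvalue: float = 1000.0,
                        iterations: int = 500) -> SamplingScheme:
    """Approximately uniform unit directions via electrostatic repulsion.

    Seeded gradient descent on the Coulomb energy of n point charges on the
    sphere (500 iterations by default); deterministic per seed.  ``n_b0``
    zero-direction b0 entries are prepended.
    """
    if n < 6:
        raise ValueError("need at least 6 directions")
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    step = 1e-3
    for _ in range(iterations):
        diff = p[:, None, :] - p[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        force = (diff / dist[..., None] ** 3).sum(axis=1)
        force -= (force * p).sum(axis=1, keepdims=True) * p  # tangent part
        p += step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    directions = np.concatenate([np.zeros((n_b0, 3)), p])
    bvalues = np.concatenate([np.zeros(n_b0), np.full(n, bvalue)])
    return SamplingScheme(directions=directions, bvalues=bvalues)


def tensor_signal(D: np.ndarray, b: float, directions: np.ndarray,
                  s0: float = 1.0) -> np.ndarray:
    """Mono-exponential tensor signal ``S(v) = S0 exp(-b v^T D v)``.

    ``D`` must be symmetric positive-definite; the output is antipodally
    symmetric because the exponent is a quadratic form.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3) or np.abs(D - D.T).max() > 1e-12:
        raise ValueError("D must be a symmetric 3x3 tensor")
    if np.linalg.eigvalsh(D).min() <= 0:
        raise ValueError("D must be positive-definite")
    v = np.atleast_2d(directions)
    quad = np.einsum("ni,ij,nj->n", v, D, v)
    return s0 * np.exp(-b * quad)


def _principal_directions(coords: np.ndarray, rule: str) -> np.ndarray:
    """Per-voxel principal diffusion direction (unit vectors)."""
    if rule == "constant":
        e = np.zeros_like(coords)
        e[:, 0] = 1.0
        return e
    r = np.linalg.norm(coords, axis=1, keepdims=True)
    if rule == "radial":
        e = np.where(r > 1e-9, coords / np.maximum(r, 1e-9), [1.0, 0.0, 0.0])
        return e
    # tangential: azimuthal unit vector e_phi = (-sin phi, cos phi, 0),
    # rotating smoothly with the polar angle of the voxel position
    rho = np.linalg.norm(coords[:, :2], axis=1)
    e = np.zeros_like(coords)
    ok = rho > 1e-9
    e[ok, 0] = -coords[ok, 1] / rho[ok]
    e[ok, 1] = coords[ok, 0] / rho[ok]
    e[~ok, 0] = 1.0
    return e


def _tensor_for(model: TissueModel, e1: np.ndarray) -> np.ndarray:
    """Diffusion tensors (M, 3, 3) with principal axis e1 per voxel."""
    l1, l2, l3 = model.eigenvalues
    # complete an orthonormal frame around e1
    ref = np.where(np.abs(e1[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    return (l1 * e1[:, :, None] * e1[:, None, :]
            + l2 * e2[:, :, None] * e2[:, None, :]
            + l3 * e3[:, :, None] * e3[:, None, :])


def _class_geometry(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the concentric class shells; returns (labels, mask).

    Labels: 0 = CSF core, 1 = subcortical ring, 2 = WM interior,
    3 = GM shell; 255 outside the mask.
    """
    S = config.grid_size
    c = (S - 1) / 2.0
    idx = np.indices((S, S, S)).reshape(3, -1).T - c
    r = np.linalg.norm(idx, axis=1)
    R = config.mask_radius_fraction * S
    mask = r < R
    labels = np.full(S**3, 255, dtype=np.uint8)
    bounds = np.array(config.radii) * R
    labels[mask & (r < bounds[0])] = 0
    labels[mask & (r >= bounds[0]) & (r < bounds[1])] = 1
    labels[mask & (r >= bounds[1]) & (r < bounds[2])] = 2
    labels[mask & (r >= bounds[2])] = 3
    return labels.reshape(S, S, S), mask.reshape(S, S, S)


def generate_raw_phantom(config: PhantomConfig) -> tuple[
        np.ndarray, SamplingScheme, np.ndarray, np.ndarray]:
    """Raw (un-normalized) phantom: values incl. b0 volumes, scheme, labels, mask."""
    scheme = generate_directions(config.n_directions, seed=config.direction_seed,
                                 n_b0=config.n_b0, bvalue=config.bvalue)
    labels, mask = _class_geometry(config)
    S = config.grid_size
    for cid in range(4):
        if not (labels == cid).any():
            raise ValueError(f"degenerate geometry: class {cid} is empty")

    c = (S - 1) / 2.0
    coords = np.indices((S, S, S)).reshape(3, -1).T - c
    flat_labels = labels.reshape(-1)
    values = np.zeros((S**3, scheme.n))
    dirs = scheme.directions
    b = scheme.bvalues

    for cid, model in config.tissues.items():
        sel = np.flatnonzero(flat_labels == cid)
        if sel.size == 0:
            continue
        e1 = _principal_directions(coords[sel], model.orientation)
        tensors = _tensor_for(model, e1)
        quad = np.einsum("mij,ni,nj->mn", tensors, dirs, dirs)
        sig = model.s0 * np.exp(-b[None, :] * quad)
        if model.mix_with is not None:
            other = config.tissues[model.mix_with]
            e1o = _principal_directions(coords[sel], other.orientation)
            to = _tensor_for(other, e1o)
            quado = np.einsum("mij,ni,nj->mn", to, dirs, dirs)
            sig = 0.5 * sig + 0.5 * other.s0 * np.exp(-b[None, :] * quado)
        values[sel] = sig

    if config.noise != "none":
        rng = np.random.default_rng(config.seed + 1)
        sigma = config.sigma  # relative to S0 = 1
        e1 = rng.normal(scale=sigma, size=values.shape)
        if config.noise == "gaussian":
            values = values + e1
        else:
            e2 = rng.normal(scale=sigma, size=values.shape)
            values = np.sqrt((values + e1) ** 2 + e2**2)
    values = values.reshape(S, S, S, scheme.n)
    return values, scheme, labels, mask


def generate_phantom(config: PhantomConfig) -> tuple[
        SphericalVolume, np.ndarray, np.ndarray]:
    """b0-normalized phantom: (SphericalVolume, labels, mask).

    Two calls with equal configs (same seed) produce identical volumes.
    """
    raw, scheme, labels, mask = generate_raw_phantom(config)
    volume = normalize_b0(raw, scheme, mask=mask)
    return volume, labels, volume.mask


def write_phantom(raw_values: np.ndarray, scheme: SamplingScheme,
                  labels: np.ndarray, mask: np.ndarray,
                  prefix: str | Path) -> dict[str, Path]:
    """Write NIfTI image/labels/mask plus FSL bval/bvec next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": prefix.with_suffix(".nii.gz"),
        "labels": Path(f"{prefix}_labels.nii.gz"),
        "mask": Path(f"{prefix}_mask.nii.gz"),
        "bval": prefix.with_suffix(".bval"),
        "bvec": prefix.with_suffix(".bvec"),
    }
    write_nifti(raw_values, paths["dwi"], dtype=np.float32)
    write_nifti(labels, paths["labels"], dtype=np.uint8)
    write_nifti(mask.astype(np.uint8), paths["mask"], dtype=np.uint8)
    write_bvals_bvecs(scheme, paths["bval"], paths["bvec"])
    return paths


def read_phantom(prefix: str | Path) -> tuple[
        np.ndarray, SamplingScheme, np.ndarray, np.ndarray]:
    """Round-trip reader for :func:`write_phantom` outputs."""
    prefix = Path(prefix)
    raw = read_nifti(prefix.with_suffix(".nii.gz"))
    scheme = read_bvals_bvecs(prefix.with_suffix(".bval"),
                              prefix.with_suffix(".bvec"))
    labels = read_nifti(f"{prefix}_labels.nii.gz").astype(np.uint8)
    mask = read_nifti(f"{prefix}_mask.nii.gz").astype(bool)
    return raw, scheme, labels, mask
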