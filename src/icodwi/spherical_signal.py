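"""DWI-like volumes as per-voxel spherical signals.

A diffusion-weighted scan measures, in every voxel, the signal attenuation
along N gradient directions (b-vectors) on the sphere.  Two discretizations
are used downstream:

* *Type 1* — the raw measurement vector, an image ``R^3 -> R^N`` (the
  classical CNN's view of the data);
* *Type 2* — a proper spherical function obtained by Watson-kernel
  interpolation of the N samples, an image ``R^3 x S^2 -> R`` (the view the
  group-convolutional networks use).

The Watson kernel ``exp(kappa * (mu . v)^2)`` is antipodally symmetric, which
matches the physics: diffusion attenuation cannot distinguish a direction
from its negation.  Weights are row-normalized (Nadaraya-Watson smoothing),
so interpolated values are convex combinations of the measured ones and the
``kappa = 0`` limit is the uniform average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SamplingScheme",
    "SphericalVolume",
    "InterpolationMatrix",
    "watson_weights",
    "normalize_b0",
    "resample",
    "rotate_scheme",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_nifti",
    "write_nifti",
]

B0_THRESHOLD = 50.0  # s/mm^2; b-values below this count as unweighted
B0_EPSILON = 1e-6  # voxels with mean b0 at or below this are masked out


@dataclass(frozen=True)
class SamplingScheme:
    """Gradient table: N directions with their b-values (s/mm^2).

    b0 entries (``bvalue < 50``) may carry a zero direction, FSL-style; all
    diffusion-weighted directions must be unit vectors.
    """

    directions: np.ndarray  # (N, 3)
    bvalues: np.ndarray  # (N,)

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if len(d) != len(b) or len(d) < 1:
            raise ValueError("directions and bvalues must have equal length >= 1")
        norms = np.linalg.norm(d[b >= B0_THRESHOLD], axis=1)
        if norms.size and np.abs(norms - 1.0).max() > 1e-6:
            raise ValueError("non-b0 directions must be unit norm")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvalues < B0_THRESHOLD)

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvalues >= B0_THRESHOLD)

    @property
    def n(self) -> int:
        return len(self.bvalues)


@dataclass(frozen=True)
class SphericalVolume:
    """A 3D grid of per-voxel spherical samples (b0-normalized attenuations).

    ``values`` has shape ``(X, Y, Z, N)`` with N the number of (non-b0)
    directions in ``scheme``; voxel indices are 0-based in (x, y, z) order and
    gradient directions live in the same world frame as the rotation group.
    """

    values: np.ndarray  # (X, Y, Z, N)
    scheme: SamplingScheme
    mask: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 4:
            raise ValueError("values must be (X, Y, Z, N)")
        if v.shape[-1] != self.scheme.n:
            raise ValueError("last axis must match the sampling scheme size")
        if not np.isfinite(v[np.asarray(self.mask)]).all():
            raise ValueError("masked-in values must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass(frozen=True)
class InterpolationMatrix:
    """Row-stochastic Q x N matrix mapping measured to query directions."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("interpolation weights must be non-negative")
        if np.abs(w.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("interpolation rows must sum to 1")
        object.__setattr__(self, "weights", w)


def watson_weights(query_dirs: np.ndarray, sample_dirs: np.ndarray,
                   kappa: float) -> InterpolationMatrix:
    """Watson-kernel interpolation weights ``exp(kappa (q.v)^2)``, row-normalized.

    Antipodally symmetric by construction: ``q`` and ``-q`` get identical
    rows.  ``kappa = 0`` gives the uniform average 1/N.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    q = np.atleast_2d(np.asarray(query_dirs, dtype=float))
    v = np.atleast_2d(np.asarray(sample_dirs, dtype=float))
    cos2 = (q @ v.T) ** 2
    w = np.exp(kappa * (cos2 - cos2.max(axis=1, keepdims=True)))
    rowsum = w.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("zero row sum in Watson weights")
    return InterpolationMatrix(weights=w / rowsum)


def normalize_b0(raw_values: np.ndarray, scheme: SamplingScheme,
                 mask: np.ndarray | None = None,
                 epsilon: float = B0_EPSILON) -> SphericalVolume:
    """Divide diffusion-weighted signals by the voxel-wise mean b0.

    Returns a :class:`SphericalVolume` holding only the non-b0 volumes; voxels
    whose mean b0 is ``<= epsilon`` are removed from the mask (their values
    are set to zero rather than left non-finite).
    """
    raw_values = np.asarray(raw_values, dtype=float)
    b0_idx = scheme.b0_indices
    if b0_idx.size == 0:
        raise ValueError("scheme has no b0 volumes")
    if mask is None:
        mask = np.ones(raw_values.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    b0_mean = raw_values[..., b0_idx].mean(axis=-1)
    good = b0_mean > epsilon
    new_mask = mask & good
    denom = np.where(good, b0_mean, 1.0)
    dwi = raw_values[..., scheme.dwi_indices] / denom[..., None]
    dwi[~good] = 0.0
    sub = SamplingScheme(directions=scheme.directions[scheme.dwi_indices],
                         bvalues=scheme.bvalues[scheme.dwi_indices])
    return SphericalVolume(values=dwi, scheme=sub, mask=new_mask)


def resample(volume: SphericalVolume, query_dirs: np.ndarray,
             kappa: float = 10.0) -> np.ndarray:
    """Evaluate each voxel's Watson-interpolated spherical function at query directions.

    Returns an ``(X, Y, Z, Q)`` array; one interpolation matrix is built per
    (scheme, query set) pair and applied as a single matrix product.
    """
    W = watson_weights(query_dirs, volume.scheme.directions, kappa)
    return volume.values @ W.weights.T


def rotate_scheme(scheme: SamplingScheme, R: np.ndarray) -> SamplingScheme:
    """Rotate all gradient directions by a proper rotation; b-values unchanged."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.linalg.norm(R @ R.T - np.eye(3)) > 1e-6 \
            or abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise ValueError("R must be a proper rotation matrix")
    return replace(scheme, directions=scheme.directions @ R.T)


# ---------------------------------------------------------------------------
# file formats: FSL bval/bvec and NIfTI-1


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> SamplingScheme:
    """Read an FSL gradient table (one row of b-values; three rows x/y/z)."""
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise ValueError("bvec file must have exactly 3 rows")
    return SamplingScheme(directions=bvecs.T, bvalues=bvals)


def write_bvals_bvecs(scheme: SamplingScheme, bval_path: str | Path,
                      bvec_path: str | Path) -> None:
    np.savetxt(bval_path, scheme.bvalues[None], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.9f")


def read_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


def write_nifti(data: np.ndarray, path: str | Path,
                dtype: np.dtype | type = np.float32) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine=np.eye(4))
    nib.save(img, str(path))
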