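"""Direct (regular-representation) group-convolution operators.

Three operators make up the separable equivariant layers, plus an invariant
projection:

* :func:`lift_s2` — lifting convolution: a star-shaped kernel with 11 sample
  points (the reference vertex, the 5 arc-midpoints of its incident edges and
  its 5 one-ring neighbours) is transported to every vertex and spun through
  the 5 stabilizer rotations, producing one response per group element —
  a function on the 60-element icosahedral rotation group.
* :func:`gconv_so3` — group convolution with a kernel supported on exactly
  one fiber (the 5 stabilizer spins): a cyclic correlation inside each left
  coset, computed through the Cayley table.
* :func:`spatial_conv` — a 3x3x3 valid spatial correlation applied per group
  slot; the kernel is unrotated (``T^3 x SO(3)`` action), rotated by the
  fiber's coset representative (partial ``SE(3)``) or by the slot's own
  rotation (full ``SE(3)``), using trilinear interpolation with zero outside
  the cube.
* :func:`project_max` — channel-wise max over spins (back to the sphere) or
  over all 60 elements (back to the voxel grid), conferring invariance.

All operators act on arrays whose trailing axes are ``(..., G, C)`` — or
``(..., X, Y, Z, G, C)`` for the spatial convolution — with G = 60 group
slots.  Because the star-kernel orbit is closed under the group, lifting,
group convolution and projection are *exactly* equivariant (pure index
permutations); spatial rotation of kernels is exact for the 180-degree
coordinate-axis group elements and trilinear elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .icosa_group import Icosahedron, RotationGroup, stabilizer_cycle

__all__ = [
    "StarKernelLayout",
    "StarKernel",
    "FiberKernel",
    "SpatialKernel",
    "GroupFeatureMap",
    "star_layout",
    "build_orbit",
    "Orbit",
    "lift_s2",
    "gconv_so3",
    "rotate_spatial_kernel",
    "rotation_operator",
    "spatial_conv",
    "project_max",
    "gconv_index_table",
]

N_STAR = 11  # center + 5 edge arc-midpoints + 5 one-ring vertices


@dataclass(frozen=True)
class StarKernelLayout:
    """The 11 sample points of the star kernel on S^2.

    Point 0 is the reference vertex; points ``1 + i`` are the arc-midpoints
    of the edges to the one-ring, points ``6 + i`` the one-ring vertices,
    with arm ordering following ``Icosahedron.neighbors``.  The 5 stabilizer
    rotations permute the layout onto itself cyclically by arm.
    """

    sample_points: np.ndarray  # (11, 3)


@dataclass
class StarKernel:
    """Learnable S^2 lifting kernel: (C_in, C_out, 11) weights + C_out biases."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.shape[-1] != N_STAR or self.weights.ndim != 3:
            raise ValueError("star kernel weights must be (C_in, C_out, 11)")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias).all()):
            raise ValueError("kernel weights must be finite")


@dataclass
class FiberKernel:
    """Learnable SO(3) kernel supported on one fiber: (C_in, C_out, 5) weights."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.shape[-1] != 5 or self.weights.ndim != 3:
            raise ValueError("fiber kernel weights must be (C_in, C_out, 5)")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias).all()):
            raise ValueError("kernel weights must be finite")


@dataclass
class SpatialKernel:
    """Learnable R^3 kernel: (C_in, C_out, 3, 3, 3) weights + C_out biases."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.shape[-3:] != (3, 3, 3) or self.weights.ndim != 5:
            raise ValueError("spatial kernel weights must be (C_in, C_out, 3, 3, 3)")
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias).all()):
            raise ValueError("kernel weights must be finite")


@dataclass(frozen=True)
class GroupFeatureMap:
    """Feature values indexed by (voxel, group element, channel).

    ``values`` has trailing axes (..., 60, C); all 60 slots are always
    present.  Thin wrapper used at module boundaries — the operator functions
    below accept plain arrays too.
    """

    values: np.ndarray
    group: RotationGroup

    def __post_init__(self):
        if self.values.shape[-2] != self.group.order:
            raise ValueError("second-to-last axis must index the 60 group elements")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")


def star_layout(ico: Icosahedron) -> StarKernelLayout:
    v0 = ico.v0
    ring = ico.vertices[ico.neighbors[ico.reference_vertex]]
    mid = v0[None, :] + ring
    mid /= np.linalg.norm(mid, axis=1, keepdims=True)
    return StarKernelLayout(sample_points=np.concatenate([v0[None], mid, ring]))


@dataclass(frozen=True)
class Orbit:
    """Deduplicated orbit of the star layout under the group.

    ``points`` are the unique sample directions (42 in the standard
    embedding: 12 vertices + 30 edge arc-midpoints); ``index[g, j]`` locates
    ``elements[g] @ sample_points[j]`` in ``points``.
    """

    points: np.ndarray  # (P, 3)
    index: np.ndarray  # (60, 11) int


def build_orbit(group: RotationGroup, layout: StarKernelLayout | None = None,
                tol: float = 1e-9) -> Orbit:
    """All rotated star sample points, deduplicated at ``tol``."""
    if layout is None:
        layout = star_layout(group.ico)
    pts: list[np.ndarray] = []
    index = np.empty((group.order, N_STAR), dtype=np.intp)
    for g, E in enumerate(group.elements):
        rotated = layout.sample_points @ E.T
        for j, p in enumerate(rotated):
            for k, q in enumerate(pts):
                if np.linalg.norm(p - q) < tol:
                    index[g, j] = k
                    break
            else:
                pts.append(p)
                index[g, j] = len(pts) - 1
    return Orbit(points=np.array(pts), index=index)


def _values_weights(kernel) -> tuple[np.ndarray, np.ndarray]:
    return kernel.weights, kernel.bias


def lift_s2(values: np.ndarray, kernel: StarKernel, group: RotationGroup,
            orbit: Orbit | None = None) -> np.ndarray:
    """Lifting convolution from orbit-sampled spherical signals to the group.

    ``values`` holds, per voxel, the signal at every orbit point:
    shape ``(..., C_in, P)`` with P = number of orbit points.  Output is
    ``(..., 60, C_out)`` with
    ``out[..., g, o] = bias[o] + sum_{c,j} values[..., c, index[g, j]] * w[c, o, j]``
    — the discretization of the lifting integral with counting measure on the
    11 star samples.
    """
    if orbit is None:
        orbit = build_orbit(group)
    values = np.asarray(values)
    if values.shape[-1] != len(orbit.points):
        raise ValueError(
            f"expected {len(orbit.points)} orbit samples, got {values.shape[-1]}"
        )
    w, b = _values_weights(kernel)
    gathered = values[..., orbit.index]  # (..., C_in, 60, 11)
    out = np.einsum("...cgj,coj->...go", gathered, w, optimize=True)
    return out + b


def gconv_index_table(group: RotationGroup) -> np.ndarray:
    """``idx[g, k]`` = index of ``g . sigma_k^-1`` (sigma_k the spin-k stabilizer)."""
    cyc = stabilizer_cycle(group).rotations
    inv = group.inverse[cyc]
    return group.cayley[:, inv]  # (60, 5)


def gconv_so3(F: np.ndarray, kernel: FiberKernel, group: RotationGroup,
              index_table: np.ndarray | None = None) -> np.ndarray:
    """Group convolution with a fiber-supported kernel: cyclic correlation per coset.

    ``F`` has trailing axes ``(..., 60, C_in)``; output
    ``out[..., g, o] = bias[o] + sum_{c,k} F[..., g sigma_k^-1, c] * w[c, o, k]``.
    Exactly left-equivariant: a pure Cayley-table lookup.
    """
    F = np.asarray(F)
    if F.shape[-2] != group.order:
        raise ValueError("F must have 60 group slots on its second-to-last axis")
    w, b = _values_weights(kernel)
    if F.shape[-1] != w.shape[0]:
        raise ValueError("channel mismatch between F and kernel")
    if index_table is None:
        index_table = gconv_index_table(group)
    out = None
    for k in range(5):
        term = F[..., index_table[:, k], :] @ w[:, :, k]
        out = term if out is None else out + term
    return out + b


def rotation_operator(R: np.ndarray) -> np.ndarray:
    """Linear operator on flattened 3x3x3 kernels realizing ``w'(y) = w(R^-1 y)``.

    Trilinear interpolation on the integer offset grid centered at 0, zero
    outside the cube.  Returns a (27, 27) matrix ``M`` with
    ``w_rot.ravel() = M @ w.ravel()``.
    """
    R = np.asarray(R, dtype=float)
    offs = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                indexing="ij")).reshape(3, -1).T  # (27, 3)
    M = np.zeros((27, 27))
    for a, y in enumerate(offs):
        src = R.T @ y
        base = np.floor(src).astype(int)
        frac = src - base
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    corner = base + (dx, dy, dz)
                    wgt = ((frac[0] if dx else 1 - frac[0])
                           * (frac[1] if dy else 1 - frac[1])
                           * (frac[2] if dz else 1 - frac[2]))
                    if wgt == 0.0 or np.abs(corner).max() > 1:
                        continue
                    bidx = int((corner[0] + 1) * 9 + (corner[1] + 1) * 3
                               + (corner[2] + 1))
                    M[a, bidx] += wgt
    return M


def rotate_spatial_kernel(kernel: SpatialKernel, R: np.ndarray) -> SpatialKernel:
    """Rotate a 3x3x3 kernel: ``w'(y) = w(R^-1 y)`` by trilinear interpolation.

    Grid-exact for rotations with entries in {-1, 0, 1}; the central weight
    is always invariant.  Bias unchanged.
    """
    M = rotation_operator(R)
    ci, co = kernel.weights.shape[:2]
    flat = kernel.weights.reshape(ci, co, 27)
    rotated = flat @ M.T
    return SpatialKernel(weights=rotated.reshape(ci, co, 3, 3, 3),
                         bias=kernel.bias.copy())


def _slot_rotation_indices(group: RotationGroup, mode: str) -> np.ndarray | None:
    """Group-element index whose rotation matrix rotates the kernel for each slot."""
    if mode == "none":
        return None
    if mode == "full":
        return np.arange(group.order)
    if mode == "partial":
        return group.fiber_of[:, 0] * 5  # spin-0 coset representative of g's fiber
    raise ValueError(f"unknown orientation mode {mode!r}")


def slot_kernels(kernel: SpatialKernel, group: RotationGroup,
                 mode: str) -> np.ndarray:
    """Per-slot rotated kernel stack ``(G, C_in, C_out, 27)`` (or (1, ...) for none)."""
    ci, co = kernel.weights.shape[:2]
    flat = kernel.weights.reshape(ci, co, 27)
    slots = _slot_rotation_indices(group, mode)
    if slots is None:
        return flat[None]
    ops = np.stack([rotation_operator(group.elements[s]) for s in slots])
    return np.einsum("gab,cob->gcoa", ops, flat, optimize=True)


def spatial_conv(F: np.ndarray, kernel: SpatialKernel, group: RotationGroup,
                 orientation_mode: str = "none") -> np.ndarray:
    """Valid (no padding) 3x3x3 correlation, stride 1, per group slot.

    ``F`` has trailing axes ``(..., X, Y, Z, G, C_in)``; the output spatial
    extent shrinks by 2 per axis.  ``orientation_mode``:

    * ``"none"`` — the unrotated kernel for every slot (T^3 x SO(3));
    * ``"partial"`` — the kernel rotated by the spin-0 coset representative
      of the slot's fiber (SE(3)*);
    * ``"full"`` — the kernel rotated by the slot's own rotation (SE(3)).
    """
    F = np.asarray(F)
    X, Y, Z, G, Ci = F.shape[-5:]
    if min(X, Y, Z) < 3:
        raise ValueError("spatial extent must be >= 3 in each axis")
    Kg = slot_kernels(kernel, group, orientation_mode)  # (G or 1, Ci, Co, 27)
    Co = Kg.shape[2]
    out = np.zeros(F.shape[:-5] + (X - 2, Y - 2, Z - 2, G, Co), dtype=F.dtype)
    d = 0
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                sl = F[..., dx:dx + X - 2, dy:dy + Y - 2, dz:dz + Z - 2, :, :]
                if Kg.shape[0] == 1:
                    out += sl @ Kg[0, :, :, d]
                else:
                    out += np.einsum("...gc,gco->...go", sl, Kg[:, :, :, d],
                                     optimize=True)
                d += 1
    return out + kernel.bias


def project_max(F: np.ndarray, group: RotationGroup,
                target: str = "space") -> np.ndarray:
    """Channel-wise max-projection over group coordinates.

    ``target="sphere"`` takes the max over the 5 spins inside each of the 12
    fibers, yielding ``(..., 12, C)`` (the SO(3)-only network's head);
    ``target="space"`` takes the max over all 60 slots, yielding ``(..., C)``.
    No learned weights.
    """
    F = np.asarray(F)
    if F.shape[-2] != group.order:
        raise ValueError("F must have 60 group slots on its second-to-last axis")
    if target == "space":
        return F.max(axis=-2)
    if target == "sphere":
        # element ordering is (vertex, spin) lexicographic: slot 5*v + s
        shaped = F.reshape(F.shape[:-2] + (12, 5, F.shape[-1]))
        return shaped.max(axis=-2)
    raise ValueError(f"unknown projection target {target!r}")
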