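"""Icosahedron geometry and the 60-element icosahedral rotation group.

The sphere :math:`S^2` is discretized by the 12 vertices of a regular
icosahedron, and the rotation group :math:`SO(3)` by the 60 proper rotational
symmetries of that solid.  Every group element maps the distinguished "north"
vertex ``v0`` to some vertex ``v`` and can be written uniquely as a coset
representative for ``v`` composed with one of the five stabilizer rotations of
``v0`` (rotations by ``2*k*pi/5`` about the ``v0`` axis).  This 12 x 5
factorization — 12 fibers of 5 spins — is the index structure every
group-convolution layer in this package relies on.

The embedding places vertices at the normalized cyclic coordinate
permutations of ``(0, +-1, +-phi)``, which has the convenient property that
the three 180-degree rotations about the coordinate axes are exact group
members; those rotations are also exact permutations of any cubic voxel grid,
which is what makes interpolation-free end-to-end equivariance checks
possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Icosahedron",
    "RotationGroup",
    "StabilizerCycle",
    "build_icosahedron",
    "build_rotation_group",
    "stabilizer_cycle",
    "left_translate",
    "coordinate_axis_twofold_rotations",
    "rotation_about_axis",
    "group_to_json",
    "group_from_json",
]

GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

#: angular distance between neighbouring vertices: arccos(1/sqrt(5))
NEIGHBOR_ANGLE = float(np.arccos(1.0 / np.sqrt(5.0)))


@dataclass(frozen=True)
class Icosahedron:
    """Regular icosahedron with ordered one-ring neighbourhoods.

    ``vertices`` are unit vectors; ``neighbors[i]`` lists the five one-ring
    vertex indices of vertex ``i`` ordered counter-clockwise as seen from
    outside the solid.  ``reference_vertex`` is the distinguished north vertex
    ``v0`` (the lexicographically largest coordinate triple, index 0 by
    construction).
    """

    vertices: np.ndarray  # (12, 3)
    neighbors: np.ndarray  # (12, 5) int
    reference_vertex: int = 0

    @property
    def v0(self) -> np.ndarray:
        return self.vertices[self.reference_vertex]


@dataclass(frozen=True)
class RotationGroup:
    """The 60 icosahedral rotations with their index tables.

    ``cayley[i, j]`` is the index of ``elements[i] @ elements[j]``;
    ``inverse[i]`` the index of the inverse; ``fiber_of[i]`` the
    ``(vertex, spin)`` pair of element ``i``; ``vertex_perm[i]`` the induced
    permutation of the 12 vertices.  Elements are ordered lexicographically by
    ``(vertex, spin)``, so element ``5*v + s`` has fiber ``(v, s)`` and the
    identity is element 0.
    """

    elements: np.ndarray  # (60, 3, 3)
    cayley: np.ndarray  # (60, 60) int
    inverse: np.ndarray  # (60,) int
    fiber_of: np.ndarray  # (60, 2) int
    vertex_perm: np.ndarray  # (60, 12) int
    ico: Icosahedron = field(repr=False)
    identity_index: int = 0

    @property
    def order(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class StabilizerCycle:
    """The cyclic order-5 stabilizer of the reference vertex.

    ``rotations[k]`` is the group-element index of the rotation by
    ``2*k*pi/5`` about the ``v0`` axis; ``rotations[0]`` is the identity.
    """

    rotations: np.ndarray  # (5,) int


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (unit-normalized) axis."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def build_icosahedron() -> Icosahedron:
    """Standard embedding: normalized cyclic permutations of (0, +-1, +-phi).

    Vertices are sorted lexicographically descending so the reference vertex
    (the lexicographically largest triple) gets index 0.
    """
    raw = []
    for a in (-1.0, 1.0):
        for b in (-GOLDEN, GOLDEN):
            raw.append((0.0, a, b))
            raw.append((a, b, 0.0))
            raw.append((b, 0.0, a))
    verts = np.array(raw) / np.sqrt(1.0 + GOLDEN**2)
    order = sorted(range(12), key=lambda i: tuple(np.round(verts[i], 12)), reverse=True)
    verts = verts[order]

    dots = verts @ verts.T
    neighbors = np.zeros((12, 5), dtype=np.intp)
    for i in range(12):
        ring = np.flatnonzero(np.abs(dots[i] - 1.0 / np.sqrt(5.0)) < 1e-9)
        # order counter-clockwise seen from outside: increasing angle in the
        # right-handed tangent frame (e1, e2, v) with e2 = v x e1
        v = verts[i]
        e1 = verts[ring[0]] - dots[i, ring[0]] * v
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)
        proj = verts[ring] - np.outer(dots[i, ring], v)
        ang = np.arctan2(proj @ e2, proj @ e1)
        neighbors[i] = ring[np.argsort(ang)]
    return Icosahedron(vertices=verts, neighbors=neighbors, reference_vertex=0)


def _face_axis(ico: Icosahedron) -> np.ndarray:
    """Center of a face incident to v0 (v0 plus two adjacent neighbours)."""
    v0 = ico.v0
    n0, n1 = ico.neighbors[0][:2]
    center = v0 + ico.vertices[n0] + ico.vertices[n1]
    return center / np.linalg.norm(center)


def _close_generators(generators: list[np.ndarray], tol: float = 1e-6,
                      max_order: int = 200) -> np.ndarray:
    """Close a generator set under composition, deduplicating at ``tol``."""
    elements: list[np.ndarray] = [np.eye(3)]

    def find(M: np.ndarray) -> int:
        for k, E in enumerate(elements):
            if np.linalg.norm(M - E) < tol:
                return k
        return -1

    frontier = [np.eye(3)]
    while frontier:
        new_frontier = []
        for E in frontier:
            for G in generators:
                P = G @ E
                if find(P) < 0:
                    elements.append(P)
                    new_frontier.append(P)
                    if len(elements) > max_order:
                        raise RuntimeError(
                            "group closure exceeded expected order; broken geometry"
                        )
        frontier = new_frontier
    return np.array(elements)


def build_rotation_group(ico: Icosahedron) -> RotationGroup:
    """Generate the 60 icosahedral rotations and all index tables.

    The group is generated by a 2*pi/5 rotation about ``v0`` and a 2*pi/3
    rotation about an adjacent face center, closed under composition with
    1e-6 Frobenius deduplication; the final tables are verified at 1e-9.

    Raises
    ------
    RuntimeError
        If the closure does not produce exactly 60 elements.
    """
    g5 = rotation_about_axis(ico.v0, 2.0 * np.pi / 5.0)
    g3 = rotation_about_axis(_face_axis(ico), 2.0 * np.pi / 3.0)
    elements = _close_generators([g5, g3])
    if len(elements) != 60:
        raise RuntimeError(f"closure produced {len(elements)} elements, expected 60")

    verts = ico.vertices
    n = len(elements)

    # fiber decomposition: vertex reached from v0, then spin inside the coset
    v_of = np.empty(n, dtype=np.intp)
    for i, E in enumerate(elements):
        d = np.linalg.norm(verts - (E @ ico.v0), axis=1)
        j = int(np.argmin(d))
        if d[j] > 1e-9:
            raise RuntimeError("element does not map v0 onto a vertex")
        v_of[i] = j

    # deterministic coset representative: maximal (trace, matrix entries);
    # the identity has the unique maximal trace 3, so the v0 coset
    # representative is the identity and gets spin 0.
    def rep_key(i: int):
        E = elements[i]
        return (round(float(np.trace(E)), 9),) + tuple(np.round(E.ravel(), 9))

    sigma1 = g5  # stabilizer generator, angle 2*pi/5
    spin_of = np.empty(n, dtype=np.intp)
    for v in range(12):
        coset = np.flatnonzero(v_of == v)
        rep = max(coset, key=rep_key)
        Rinv = elements[rep].T
        for i in coset:
            S = Rinv @ elements[i]  # stabilizer element sigma_1^k
            P = np.eye(3)
            for k in range(5):
                if np.linalg.norm(S - P) < 1e-6:
                    spin_of[i] = k
                    break
                P = sigma1 @ P
            else:
                raise RuntimeError("coset element not reached by stabilizer powers")

    order = sorted(range(n), key=lambda i: (v_of[i], spin_of[i]))
    elements = elements[order]
    fiber_of = np.stack([v_of[order], spin_of[order]], axis=1)

    def index_of(M: np.ndarray) -> int:
        d = np.linalg.norm(elements.reshape(n, 9) - M.ravel(), axis=1)
        j = int(np.argmin(d))
        if d[j] > 1e-9:
            raise RuntimeError("product left the element set; closure broken")
        return j

    cayley = np.empty((n, n), dtype=np.intp)
    for i in range(n):
        for j in range(n):
            cayley[i, j] = index_of(elements[i] @ elements[j])
    inverse = np.array([index_of(E.T) for E in elements], dtype=np.intp)

    vertex_perm = np.empty((n, 12), dtype=np.intp)
    for i, E in enumerate(elements):
        rotated = verts @ E.T
        d = np.linalg.norm(rotated[:, None, :] - verts[None, :, :], axis=2)
        vertex_perm[i] = np.argmin(d, axis=1)
        if d[np.arange(12), vertex_perm[i]].max() > 1e-9:
            raise RuntimeError("element does not permute the vertex set")

    return RotationGroup(
        elements=elements,
        cayley=cayley,
        inverse=inverse,
        fiber_of=fiber_of,
        vertex_perm=vertex_perm,
        ico=ico,
    )


def stabilizer_cycle(group: RotationGroup) -> StabilizerCycle:
    """Indices of the five rotations fixing v0, ordered by angle 2*k*pi/5."""
    v = group.fiber_of[:, 0] == group.ico.reference_vertex
    idx = np.flatnonzero(v)
    rotations = idx[np.argsort(group.fiber_of[idx, 1])]
    return StabilizerCycle(rotations=rotations)


def left_translate(group: RotationGroup, g_index: int, values: np.ndarray,
                   axis: int = 0) -> np.ndarray:
    """Regular representation: ``out[h] = values[g^-1 h]``, a pure index permutation.

    ``values`` must have one entry per group element along ``axis``.
    """
    values = np.asarray(values)
    if values.shape[axis] != group.order:
        raise IndexError(
            f"axis {axis} has length {values.shape[axis]}, expected {group.order}"
        )
    perm = group.cayley[group.inverse[g_index]]
    return np.take(values, perm, axis=axis)


def coordinate_axis_twofold_rotations(group: RotationGroup) -> list[int]:
    """Group elements equal to 180-degree rotations about x, y, z.

    In the standard (0, +-1, +-phi) embedding all three exist; an empty list
    signals a non-standard embedding (exact grid-based tests must then be
    skipped).
    """
    targets = [np.diag(d) for d in ([1, -1, -1], [-1, 1, -1], [-1, -1, 1])]
    found = []
    for T in targets:
        d = np.linalg.norm(group.elements - T[None], axis=(1, 2))
        j = int(np.argmin(d))
        if d[j] < 1e-9:
            found.append(j)
    return found


def group_to_json(group: RotationGroup) -> str:
    """Serialize element matrices (row-major) and index tables to JSON."""
    return json.dumps({
        "elements": group.elements.reshape(60, 9).tolist(),
        "cayley": group.cayley.tolist(),
        "inverse": group.inverse.tolist(),
        "fiber_of": group.fiber_of.tolist(),
        "vertex_perm": group.vertex_perm.tolist(),
    })


def group_from_json(text: str, ico: Icosahedron | None = None) -> RotationGroup:
    """Inverse of :func:`group_to_json` (fixture caching)."""
    d = json.loads(text)
    if ico is None:
        ico = build_icosahedron()
    return RotationGroup(
        elements=np.array(d["elements"]).reshape(60, 3, 3),
        cayley=np.array(d["cayley"], dtype=np.intp),
        inverse=np.array(d["inverse"], dtype=np.intp),
        fiber_of=np.array(d["fiber_of"], dtype=np.intp),
        vertex_perm=np.array(d["vertex_perm"], dtype=np.intp),
        ico=ico,
    )
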