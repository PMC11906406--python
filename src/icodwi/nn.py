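"""Minimal trainable-layer framework for the group-convolutional networks.

Layers operate on activations with canonical layout ``(G, B, X, Y, Z, C)`` —
group slot first (so batched BLAS matmuls broadcast over it), then batch,
three spatial axes and channels.  Networks without a group axis (the
classical CNN) simply use ``G = 1``.

Every layer implements ``forward`` (caching what backward needs) and
``backward`` which *accumulates* into ``Parameter.grad`` — call
:meth:`Adam.zero_grad` before each step.  The first layer of a network can
set ``needs_input_grad = False`` to skip the (relatively expensive) gradient
with respect to the input data.

The layers wrap the functional operators of
:mod:`icodwi.equivariant_layers`; forward results agree with those functions
(asserted in the test suite), the classes only add gradients and an
activation layout optimized for CPU training.
"""

from __future__ import annotations

import numpy as np

from .equivariant_layers import (
    N_STAR,
    Orbit,
    gconv_index_table,
    rotation_operator,
)
from .icosa_group import RotationGroup

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "LiftLayer",
    "GConvLayer",
    "SpatialConvLayer",
    "ReLULayer",
    "ProjectMaxLayer",
    "FlattenLayer",
    "DenseLayer",
    "RotationAveragedStack",
    "Adam",
    "he_uniform",
]


class Parameter:
    """A learnable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...],
               fan_in: int, dtype=np.float64) -> np.ndarray:
    """He-style uniform init scaled by fan-in (channels x kernel support)."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Module:
    needs_input_grad: bool = True

    def parameters(self) -> list[tuple[str, Parameter]]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray | None:  # pragma: no cover
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = layers

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", p) for n, p in layer.parameters())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class LiftLayer(Module):
    """S^2 lifting convolution (star kernel) as the network entry point.

    Input ``(B, X, Y, Z, C_in, P)`` — per-voxel signals at the P orbit
    points — output ``(G, B, X, Y, Z, C_out)``.
    """

    def __init__(self, group: RotationGroup, orbit: Orbit, c_in: int, c_out: int,
                 rng: np.random.Generator, dtype=np.float64):
        self.orbit = orbit
        self.G = group.order
        self.c_in, self.c_out = c_in, c_out
        self.weight = Parameter(he_uniform(rng, (c_in, c_out, N_STAR),
                                           c_in * N_STAR, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        # 0/1 scatter matrix (Ci*P, Ci*G*J): combined with the star weights it
        # turns the whole lift into a single (B*XYZ, Ci*P) GEMM
        P = len(orbit.points)
        S = np.zeros((P, self.G * N_STAR), dtype=dtype)
        S[orbit.index.ravel(), np.arange(self.G * N_STAR)] = 1.0
        self._scatter = S
        self._P = P

    def parameters(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def _combined(self):
        """M[(c, p), (g, o)] = sum_j S[p, (g, j)] W[c, o, j]."""
        S = self._scatter.reshape(self._P, self.G, N_STAR)
        M = np.einsum("pgj,coj->cpgo", S, self.weight.value, optimize=True)
        return M.reshape(self.c_in * self._P, self.G * self.c_out)

    def forward(self, x):
        B, X, Y, Z, Ci, P = x.shape
        flat = x.reshape(B * X * Y * Z, Ci * P)
        out = flat @ self._combined().astype(x.dtype)
        out = out.reshape(B, X, Y, Z, self.G, self.c_out)
        out = np.ascontiguousarray(np.moveaxis(out, -2, 0))
        self._cache = (flat, x.shape)
        return out + self.bias.value

    def backward(self, gy):
        flat, xshape = self._cache
        B, X, Y, Z, Ci, P = xshape
        # gy is (G, B, X, Y, Z, Co) -> (B*XYZ, G*Co)
        g = np.moveaxis(gy, 0, -2).reshape(B * X * Y * Z, self.G * self.c_out)
        gM = (flat.T @ g).reshape(Ci, P, self.G, self.c_out)
        S = self._scatter.reshape(P, self.G, N_STAR)
        self.weight.grad += np.einsum("cpgo,pgj->coj", gM.astype(S.dtype), S,
                                      optimize=True)
        self.bias.grad += g.reshape(-1, self.c_out).sum(axis=0)
        if not self.needs_input_grad:
            return None
        gx = g @ self._combined().astype(g.dtype).T
        return gx.reshape(B, X, Y, Z, Ci, P)


class GConvLayer(Module):
    """SO(3) fiber group convolution: input/output ``(G, B, X, Y, Z, C)``."""

    def __init__(self, group: RotationGroup, c_in: int, c_out: int,
                 rng: np.random.Generator, dtype=np.float64):
        self.index = gconv_index_table(group)  # (G, 5)
        self.c_in, self.c_out = c_in, c_out
        self.weight = Parameter(he_uniform(rng, (c_in, c_out, 5), c_in * 5, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        # g . sigma_k^-1 stays inside g's fiber: with the (vertex, spin)
        # element ordering the whole layer is a cyclic correlation over the 5
        # spins of each fiber, i.e. one GEMM with a block-circulant matrix
        # BC[(s', c), (s, o)] = W[c, o, (s - s') mod 5]
        shift = (np.arange(5)[None, :] - np.arange(5)[:, None]) % 5  # (s', s)
        self._shift = shift

    def parameters(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def _circulant(self, dtype):
        W = self.weight.value  # (Ci, Co, 5)
        BC = W[:, :, self._shift]  # (Ci, Co, s', s)
        return np.ascontiguousarray(BC.transpose(2, 0, 3, 1)).reshape(
            5 * self.c_in, 5 * self.c_out).astype(dtype)

    @staticmethod
    def _to_fiber_rows(x, Ci):
        """(60, B, X, Y, Z, C) -> (12*B*XYZ, 5*C) with spin adjacent to channels."""
        G = x.shape[0]
        rest = x.shape[1:-1]
        v = x.reshape(12, 5, -1, Ci)  # (v, s, N, C)
        v = np.ascontiguousarray(v.transpose(0, 2, 1, 3))
        return v.reshape(-1, 5 * Ci), rest

    @staticmethod
    def _from_fiber_rows(rows, rest, Co):
        v = rows.reshape(12, -1, 5, Co).transpose(0, 2, 1, 3)
        return np.ascontiguousarray(v).reshape((60,) + rest + (Co,))

    def forward(self, x):
        rows, rest = self._to_fiber_rows(x, self.c_in)
        self._cache = (rows, rest)
        out = rows @ self._circulant(x.dtype)
        return self._from_fiber_rows(out, rest, self.c_out) + self.bias.value

    def backward(self, gy):
        rows, rest = self._cache
        grows, _ = self._to_fiber_rows(gy, self.c_out)
        self.bias.grad += grows.reshape(-1, self.c_out).sum(axis=0)
        gBC = (rows.T @ grows).reshape(5, self.c_in, 5, self.c_out)
        # collapse the circulant structure back onto the 5 kernel taps
        sp = np.arange(5)
        for k in range(5):
            self.weight.grad[:, :, k] += \
                gBC[sp, :, (sp + k) % 5, :].sum(axis=0).astype(
                    self.weight.grad.dtype)
        if not self.needs_input_grad:
            return None
        grows_x = grows @ self._circulant(gy.dtype).T
        return self._from_fiber_rows(grows_x, rest, self.c_in)


class SpatialConvLayer(Module):
    """Valid 3x3x3 spatial correlation per group slot, optionally slot-rotated.

    ``mode``: ``"none"`` shares one kernel across slots; ``"partial"``/
    ``"full"`` rotate the base kernel per slot with precomputed trilinear
    rotation operators.  ``rotation_op`` (27x27), when set, additionally
    pre-rotates the base kernel — used by the rotation-averaged classical CNN
    whose branches share weights.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 group: RotationGroup | None = None, mode: str = "none",
                 dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        self.mode = mode
        self.weight = Parameter(he_uniform(rng, (c_in, c_out, 27), c_in * 27, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self.rotation_op: np.ndarray | None = None
        if mode == "none":
            self._ops = None
        elif mode in ("partial", "full"):
            if group is None:
                raise ValueError(f"mode {mode!r} requires a rotation group")
            slots = (np.arange(group.order) if mode == "full"
                     else group.fiber_of[:, 0] * 5)
            self._ops = np.stack(
                [rotation_operator(group.elements[s]) for s in slots]
            ).astype(dtype)  # (G, 27, 27)
        else:
            raise ValueError(f"unknown orientation mode {mode!r}")

    def parameters(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def _base_kernel(self) -> np.ndarray:
        W = self.weight.value
        if self.rotation_op is not None:
            W = W @ self.rotation_op.T.astype(W.dtype)
        return W

    def _slot_kernels(self) -> np.ndarray:
        """(G, C_in, C_out, 27) rotated stack, or (1, ...) when shared."""
        W = self._base_kernel()
        if self._ops is None:
            return W[None]
        return np.einsum("gab,cob->gcoa", self._ops, W, optimize=True)

    @staticmethod
    def _im2col(x):
        """(G, B*Ox*Oy*Oz, 27*Ci) patch matrix (one big GEMM operand)."""
        from numpy.lib.stride_tricks import sliding_window_view

        G, B, X, Y, Z, Ci = x.shape
        Ox, Oy, Oz = X - 2, Y - 2, Z - 2
        w = sliding_window_view(x, (3, 3, 3), axis=(2, 3, 4))
        # (G,B,Ox,Oy,Oz,Ci,3,3,3) -> (G, N, (dx,dy,dz,Ci)) in one gather
        wt = np.ascontiguousarray(w.transpose(0, 1, 2, 3, 4, 6, 7, 8, 5))
        return wt.reshape(G, B * Ox * Oy * Oz, 27 * Ci)

    def _kernel_matrix(self, Kg, dtype):
        """Per-slot kernels as (G or 1, 27*Ci, Co) GEMM operands."""
        # Kg is (G or 1, Ci, Co, 27) -> (g, d*Ci + c, o)
        return np.ascontiguousarray(
            Kg.transpose(0, 3, 1, 2).reshape(Kg.shape[0], 27 * Kg.shape[1],
                                             Kg.shape[2])).astype(dtype)

    def forward(self, x):
        G, B, X, Y, Z, Ci = x.shape
        Ox, Oy, Oz = X - 2, Y - 2, Z - 2
        if min(Ox, Oy, Oz) < 1:
            raise ValueError("input smaller than the 3x3x3 kernel")
        Kg = self._slot_kernels()
        Km = self._kernel_matrix(Kg, x.dtype)
        cols = self._im2col(x)
        N = B * Ox * Oy * Oz
        if Km.shape[0] == 1:
            out = cols.reshape(G * N, -1) @ Km[0]
        else:
            out = np.matmul(cols, Km)
        self._cache = (x, Kg, cols)
        out = out.reshape(G, B, Ox, Oy, Oz, self.c_out)
        return out + self.bias.value

    def backward(self, gy):
        x, Kg, cols = self._cache
        self._cache = None  # free the column buffer as soon as backward ran
        G, B, X, Y, Z, Ci = x.shape
        Ox, Oy, Oz = X - 2, Y - 2, Z - 2
        N = B * Ox * Oy * Oz
        gflat = np.ascontiguousarray(gy).reshape(G, N, self.c_out)
        self.bias.grad += gflat.sum(axis=(0, 1))
        Km = self._kernel_matrix(Kg, x.dtype)
        # kernel gradient: (g, 27*Ci, Co) then back to (g, Ci, Co, 27)
        if Km.shape[0] == 1:
            gKm = (cols.reshape(G * N, -1).T
                   @ gflat.reshape(G * N, self.c_out))[None]
        else:
            gKm = np.matmul(cols.transpose(0, 2, 1), gflat)
        gKg = gKm.reshape(Km.shape[0], 27, Ci, self.c_out).transpose(0, 2, 3, 1)
        gx = None
        if self.needs_input_grad:
            # input gradient = full correlation of gy with the offset-reversed,
            # channel-transposed kernel: pad gy by 2 and reuse the im2col GEMM.
            # Chunked over group slots to bound the padded im2col buffer.
            KT = Kg[:, :, :, ::-1].transpose(0, 3, 2, 1).reshape(
                Kg.shape[0], 27 * self.c_out, Ci).astype(x.dtype)
            gx = np.empty_like(x)
            gyr = gflat.reshape(G, B, Ox, Oy, Oz, self.c_out)
            chunk = max(1, int(6e7 / max(1, B * (X + 2) * (Y + 2) * (Z + 2)
                                         * self.c_out * 28)))
            for lo in range(0, G, chunk):
                hi = min(G, lo + chunk)
                gpad = np.zeros((hi - lo, B, X + 2, Y + 2, Z + 2, self.c_out),
                                dtype=x.dtype)
                gpad[:, :, 2:-2, 2:-2, 2:-2, :] = gyr[lo:hi]
                gcol = self._im2col(gpad)  # (chunk, B*X*Y*Z, 27*Co)
                if Km.shape[0] == 1:
                    out = gcol.reshape(-1, 27 * self.c_out) @ KT[0]
                else:
                    out = np.matmul(gcol, KT[lo:hi])
                gx[lo:hi] = out.reshape(hi - lo, B, X, Y, Z, Ci)
        # pull the per-slot kernel gradient back to the base weights
        if self._ops is None:
            gW = gKg[0]
        else:
            gW = np.einsum("gab,gcoa->cob", self._ops, gKg.astype(self._ops.dtype),
                           optimize=True)
        if self.rotation_op is not None:
            gW = gW @ self.rotation_op.astype(gW.dtype)
        self.weight.grad += gW.astype(self.weight.grad.dtype)
        return gx


class ReLULayer(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class ProjectMaxLayer(Module):
    """Max-projection over group coordinates; output flattened to ``(B, F)``.

    ``target="space"``: max over all G slots -> (B, X*Y*Z*C);
    ``target="sphere"``: max over the 5 spins per fiber -> (B, X*Y*Z*12*C).
    """

    def __init__(self, target: str = "space"):
        if target not in ("space", "sphere"):
            raise ValueError(f"unknown projection target {target!r}")
        self.target = target

    def forward(self, x):
        G, B = x.shape[:2]
        if self.target == "space":
            arg = x.argmax(axis=0)  # (B,X,Y,Z,C)
            out = np.take_along_axis(x, arg[None], axis=0)[0]
            self._cache = (arg, x.shape)
            return out.reshape(B, -1)
        shaped = x.reshape(12, 5, *x.shape[1:])
        arg = shaped.argmax(axis=1)  # (12,B,X,Y,Z,C)
        out = np.take_along_axis(shaped, arg[:, None], axis=1)[:, 0]
        self._cache = (arg, x.shape)
        # vertex axis moves next-to-channels: (B, X, Y, Z, 12, C)
        out = np.moveaxis(out, 0, -2)
        return out.reshape(B, -1)

    def backward(self, gy):
        arg, xshape = self._cache
        G, B = xshape[:2]
        gx = np.zeros(xshape, dtype=gy.dtype)
        if self.target == "space":
            g = gy.reshape(xshape[1:])
            np.put_along_axis(gx, arg[None], g[None], axis=0)
            return gx
        g = gy.reshape(B, *xshape[2:5], 12, xshape[5])
        g = np.moveaxis(g, -2, 0)  # (12,B,X,Y,Z,C)
        gshaped = gx.reshape(12, 5, *xshape[1:])
        np.put_along_axis(gshaped, arg[:, None], g[:, None], axis=1)
        return gshaped.reshape(xshape)


class FlattenLayer(Module):
    """(G, B, X, Y, Z, C) -> (B, G*X*Y*Z*C); used by the classical head (G=1)."""

    def forward(self, x):
        self._shape = x.shape
        B = x.shape[1]
        return np.moveaxis(x, 0, 1).reshape(B, -1)

    def backward(self, gy):
        G, B = self._shape[0], self._shape[1]
        gx = gy.reshape(B, G, *self._shape[2:])
        return np.ascontiguousarray(np.moveaxis(gx, 1, 0))


class DenseLayer(Module):
    """Fully connected head: (B, F_in) -> (B, F_out)."""

    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.weight = Parameter(he_uniform(rng, (f_in, f_out), f_in, dtype))
        self.bias = Parameter(np.zeros(f_out, dtype=dtype))

    def parameters(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, gy):
        self.weight.grad += self._x.T @ gy
        self.bias.grad += gy.sum(axis=0)
        if not self.needs_input_grad:
            return None
        return gy @ self.weight.value.T


class RotationAveragedStack(Module):
    """Weight-shared rotated copies of a classical CNN stack, responses averaged.

    Each branch runs the same layer stack with every spatial kernel
    pre-rotated by one branch rotation; branch logits are averaged.  Shared
    parameters are counted (and updated) once.  Backward re-runs each
    branch's forward to restore its caches before backpropagating.
    """

    def __init__(self, stack: Sequential, rotations: np.ndarray):
        self.stack = stack
        self.rotations = np.asarray(rotations)
        self._ops = [rotation_operator(R) for R in self.rotations]
        self._convs = [l for l in stack.layers if isinstance(l, SpatialConvLayer)]

    def parameters(self):
        return self.stack.parameters()

    def _set_branch(self, i: int | None):
        op = None if i is None else self._ops[i]
        for conv in self._convs:
            conv.rotation_op = op

    def forward(self, x):
        self._x = x
        total = None
        for i in range(len(self.rotations)):
            self._set_branch(i)
            out = self.stack.forward(x)
            total = out if total is None else total + out
        self._set_branch(None)
        return total / len(self.rotations)

    def backward(self, gy):
        gshare = gy / len(self.rotations)
        gx = None
        for i in range(len(self.rotations)):
            self._set_branch(i)
            self.stack.forward(self._x)  # restore this branch's caches
            g = self.stack.backward(gshare)
            if g is not None:
                gx = g if gx is None else gx + g
        self._set_branch(None)
        return gx


class Adam:
    """Standard Adam; fully deterministic given the update order."""

    def __init__(self, params: list[tuple[str, Parameter]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for _, p in params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype)
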