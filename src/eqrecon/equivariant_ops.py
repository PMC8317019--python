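"""Steerable kernel bases, equivariant convolutions and nonlinearities.

A linear translation-equivariant map between feature fields is an ordinary
convolution.  Requiring equivariance under the rotations of ``Z_m`` as well
constrains the kernel: the kernel ``k`` (an array of shape
``[d_out, d_in, s, s]``) must satisfy

    k(R x) = pi_out(R) k(x) pi_in(R^{-1})

for the group generator ``R`` (for a cyclic group the generator constraint
implies the constraint for every element).  This module solves the
discretised constraint directly by computing an orthonormal null-space basis
with an SVD, expands basis coefficients into ordinary convolution kernels,
and provides the convolution itself plus the nonlinearities that preserve
equivariance: pointwise ones for permutation representations and norm
nonlinearities for unitary representations.

It also houses the plain 2-D convolution primitive (forward and the
gradients needed for training), shared with the unrolled networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .groups import (
    CyclicGroup,
    FeatureField,
    Representation,
    rotate_array,
)

CONSTRAINT_TOL = 1e-10


# ---------------------------------------------------------------------------
# Plain 2-D convolution primitive (cross-correlation, 'same' output)
# ---------------------------------------------------------------------------


def conv2d(x: np.ndarray, kernel: np.ndarray, padding: str = "zeros") -> np.ndarray:
    """Cross-correlate ``x`` [C_in, H, W] with ``kernel`` [C_out, C_in, s, s].

    'same' output size; ``padding`` is "zeros" or "circular".
    """
    s = kernel.shape[-1]
    p = s // 2
    mode = "wrap" if padding == "circular" else "constant"
    xp = np.pad(x, ((0, 0), (p, p), (p, p)), mode=mode)
    win = sliding_window_view(xp, (s, s), axis=(1, 2))
    return np.einsum("ihwkl,oikl->ohw", win, kernel, optimize=True)


def _fold_wrap(arr: np.ndarray, p: int) -> np.ndarray:
    """Adjoint of periodic padding by p on the last two axes: crop + wrap-add."""
    if p == 0:
        return arr
    out = arr
    for ax in (-2, -1):
        n = out.shape[ax] - 2 * p
        core = np.take(out, range(p, p + n), axis=ax).copy()
        head = np.take(out, range(0, p), axis=ax)
        tail = np.take(out, range(p + n, p + n + p), axis=ax)
        idx_head = [slice(None)] * core.ndim
        idx_head[ax] = slice(n - p, n)
        core[tuple(idx_head)] += head
        idx_tail = [slice(None)] * core.ndim
        idx_tail[ax] = slice(0, p)
        core[tuple(idx_tail)] += tail
        out = core
    return out


def conv2d_backward(
    x: np.ndarray, kernel: np.ndarray, dy: np.ndarray, padding: str = "zeros"
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of ``sum(dy * conv2d(x, kernel))`` w.r.t. ``x`` and ``kernel``."""
    s = kernel.shape[-1]
    p = s // 2
    mode = "wrap" if padding == "circular" else "constant"
    xp = np.pad(x, ((0, 0), (p, p), (p, p)), mode=mode)
    win = sliding_window_view(xp, (s, s), axis=(1, 2))
    dk = np.einsum("ihwkl,ohw->oikl", win, dy, optimize=True)

    dyp = np.pad(dy, ((0, 0), (s - 1, s - 1), (s - 1, s - 1)))
    winy = sliding_window_view(dyp, (s, s), axis=(1, 2))
    kflip = kernel[:, :, ::-1, ::-1]
    dxp = np.einsum("ohwkl,oikl->ihw", winy, kflip, optimize=True)
    if padding == "circular":
        dx = _fold_wrap(dxp, p)
    else:
        h, w = x.shape[-2:]
        dx = dxp[:, p : p + h, p : p + w]
    return dx, dk


def leaky_relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    """phi(x) = x for x > 0, slope*x otherwise."""
    return np.where(x > 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


# ---------------------------------------------------------------------------
# Steerable kernel basis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteerableKernelBasis:
    """Orthonormal basis of kernels satisfying the rotation constraint.

    ``basis`` has shape [n_basis, d_out, d_in, s, s]; elements are orthonormal
    under the Frobenius inner product.
    """

    rep_in: Representation
    rep_out: Representation
    size: int
    basis: np.ndarray

    def __len__(self) -> int:
        return self.basis.shape[0]


def _constraint_apply(
    k: np.ndarray, rep_in: Representation, rep_out: Representation, g: int
) -> np.ndarray:
    """k(R_g .) - pi_out(g) k(.) pi_in(g^{-1}) on the sampled grid."""
    group = rep_in.group
    # value at rotated position R_g x == array rotated by the inverse element
    spatial = rotate_array(k, group, group.inverse(g))
    pin_inv = rep_in.matrix(group.inverse(g))
    pout = rep_out.matrix(g)
    chan = np.einsum("oa,aikl,ib->obkl", pout, k, pin_inv, optimize=True)
    return spatial - chan


def constraint_residual(
    k: np.ndarray, rep_in: Representation, rep_out: Representation
) -> float:
    """Max Frobenius norm of the constraint defect over all group elements."""
    group = rep_in.group
    return max(
        float(np.linalg.norm(_constraint_apply(k, rep_in, rep_out, g)))
        for g in group.elements
    )


def solve_kernel_basis(
    rep_in: Representation,
    rep_out: Representation,
    size: int,
    group: CyclicGroup | None = None,
) -> SteerableKernelBasis:
    """Null-space basis of the generator kernel constraint on an s x s grid.

    The constraint is a linear map on kernels; its matrix is assembled by
    applying it to unit kernels and the null space extracted with an SVD
    (singular values below 1e-10 relative kept).  For cyclic groups the
    generator constraint implies the constraint for all elements.
    """
    if group is None:
        group = rep_in.group
    if rep_in.group != group or rep_out.group != group:
        raise ValueError("representations must share the group")
    if size % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {size}")
    do, di = rep_out.dim, rep_in.dim
    n = do * di * size * size
    if group.order == 1:
        basis = np.eye(n).reshape(n, do, di, size, size)
        return SteerableKernelBasis(rep_in, rep_out, size, basis)
    mat = np.empty((n, n))
    unit = np.zeros((do, di, size, size))
    for idx in range(n):
        unit.flat[idx] = 1.0
        mat[:, idx] = _constraint_apply(unit, rep_in, rep_out, 1).ravel()
        unit.flat[idx] = 0.0
    _, svals, vt = np.linalg.svd(mat)
    smax = svals[0] if svals.size else 0.0
    null_mask = svals <= max(CONSTRAINT_TOL, CONSTRAINT_TOL * smax)
    n_null = int(np.sum(null_mask)) + (n - svals.size)
    basis = vt[n - n_null :].reshape(n_null, do, di, size, size)
    return SteerableKernelBasis(rep_in, rep_out, size, basis)


# ---------------------------------------------------------------------------
# Equivariant convolution layer
# ---------------------------------------------------------------------------


@dataclass
class EquivariantConvLayer:
    """A convolution whose kernel lives in the steerable basis, blockwise.

    One coefficient vector per (output field, input field) pair, and one bias
    per output field, replicated across that field's channels (required for
    exact equivariance under the channel-permuting regular representations).
    """

    in_types: list[Representation]
    out_types: list[Representation]
    size: int
    padding: str = "zeros"
    basis_table: dict = field(default_factory=dict, repr=False)
    coefficients: dict = field(default_factory=dict, repr=False)
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        group = self.in_types[0].group
        cache: dict[tuple[str, str], SteerableKernelBasis] = {}
        for io, rout in enumerate(self.out_types):
            for ii, rin in enumerate(self.in_types):
                key = (rout.kind, rin.kind)
                if key not in cache:
                    cache[key] = solve_kernel_basis(rin, rout, self.size, group)
                self.basis_table[(io, ii)] = cache[key]
                if (io, ii) not in self.coefficients:
                    self.coefficients[(io, ii)] = np.zeros(len(cache[key]))
        if self.bias is None:
            self.bias = np.zeros(len(self.out_types))

    # -- channel bookkeeping ------------------------------------------------
    @property
    def c_in(self) -> int:
        return sum(r.dim for r in self.in_types)

    @property
    def c_out(self) -> int:
        return sum(r.dim for r in self.out_types)

    def _slices(self, types: Sequence[Representation]) -> list[slice]:
        out, start = [], 0
        for rep in types:
            out.append(slice(start, start + rep.dim))
            start += rep.dim
        return out

    def bias_vector(self) -> np.ndarray:
        """Per-channel bias: each field's scalar bias replicated over its block."""
        vec = np.empty(self.c_out)
        for b, sl in zip(self.bias, self._slices(self.out_types)):
            vec[sl] = b
        return vec

    # -- parameter initialisation -------------------------------------------
    def he_init(self, rng: np.random.Generator, gain: float = 1.0) -> None:
        """He-style init generalised to the steerable basis, gain-calibrated.

        Coefficients are first drawn i.i.d. with the fan-in variance suggested
        by orthonormality of the basis.  Because expanded steerable kernels
        are correlated across the channels of a field (rows are rotated copies
        of one another), the naive draw can badly misestimate the layer gain,
        so the draw is then rescaled empirically: a white-noise probe is
        pushed through the expanded convolution and all coefficients are
        scaled so the output/input standard-deviation ratio equals ``gain``.
        Deterministic given the generator state.
        """
        fan_in = self.c_in * self.size * self.size
        for (io, ii), c in self.coefficients.items():
            nb = len(c)
            if nb == 0:
                continue
            basis = self.basis_table[(io, ii)]
            block_elems = basis.basis.shape[1] * basis.basis.shape[2] * self.size**2
            sigma = np.sqrt(2.0 * block_elems / (fan_in * nb))
            self.coefficients[(io, ii)] = rng.normal(0.0, sigma, size=nb)
        self.bias = np.zeros(len(self.out_types))
        probe = rng.normal(size=(self.c_in, 24, 24))
        out = conv2d(probe, expand_kernel(self), padding="circular")
        ratio = float(out.std() / probe.std())
        if ratio > 0:
            scale = gain / ratio
            for key in self.coefficients:
                self.coefficients[key] = self.coefficients[key] * scale

    def zero_init(self) -> None:
        for key, c in self.coefficients.items():
            self.coefficients[key] = np.zeros_like(c)
        self.bias = np.zeros(len(self.out_types))


def _homogeneous_basis(layer: EquivariantConvLayer) -> SteerableKernelBasis | None:
    first = layer.basis_table[(0, 0)]
    if all(b is first for b in layer.basis_table.values()):
        return first
    return None


def expand_kernel(layer: EquivariantConvLayer) -> np.ndarray:
    """Assemble the full [C_out, C_in, s, s] kernel from basis coefficients."""
    s = layer.size
    for (io, ii), c in layer.coefficients.items():
        if len(c) != len(layer.basis_table[(io, ii)]):
            raise ValueError(
                f"coefficient count {len(c)} does not match basis size "
                f"{len(layer.basis_table[(io, ii)])}"
            )
    shared = _homogeneous_basis(layer)
    if shared is not None and len(shared):
        p, q = len(layer.out_types), len(layer.in_types)
        coeff = np.stack(
            [
                np.stack([layer.coefficients[(io, ii)] for ii in range(q)])
                for io in range(p)
            ]
        )  # [p, q, nb]
        kern = np.einsum("pqn,nabkl->paqbkl", coeff, shared.basis, optimize=True)
        return np.ascontiguousarray(kern.reshape(layer.c_out, layer.c_in, s, s))
    kernel = np.zeros((layer.c_out, layer.c_in, s, s))
    out_sl = layer._slices(layer.out_types)
    in_sl = layer._slices(layer.in_types)
    for (io, ii), c in layer.coefficients.items():
        if len(c):
            kernel[out_sl[io], in_sl[ii]] = np.tensordot(
                c, layer.basis_table[(io, ii)].basis, axes=1
            )
    return kernel


def kernel_coefficient_grad(
    layer: EquivariantConvLayer, dkernel: np.ndarray
) -> dict:
    """Back-propagate a kernel gradient through the basis expansion."""
    shared = _homogeneous_basis(layer)
    if shared is not None and len(shared):
        p, q = len(layer.out_types), len(layer.in_types)
        do, di = shared.basis.shape[1], shared.basis.shape[2]
        s = layer.size
        dk = dkernel.reshape(p, do, q, di, s, s)
        dc = np.einsum("paqbkl,nabkl->pqn", dk, shared.basis, optimize=True)
        return {(io, ii): dc[io, ii] for io in range(p) for ii in range(q)}
    out_sl = layer._slices(layer.out_types)
    in_sl = layer._slices(layer.in_types)
    grads = {}
    for (io, ii), c in layer.coefficients.items():
        basis = layer.basis_table[(io, ii)]
        block = dkernel[out_sl[io], in_sl[ii]]
        grads[(io, ii)] = (
            np.tensordot(basis.basis, block, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
            if len(c)
            else np.zeros(0)
        )
    return grads


def bias_field_grad(layer: EquivariantConvLayer, dy: np.ndarray) -> np.ndarray:
    """Gradient of the per-field (tied) biases from a per-channel output grad."""
    per_channel = dy.sum(axis=(-2, -1))
    return np.array(
        [per_channel[sl].sum() for sl in layer._slices(layer.out_types)]
    )


def equivariant_conv(layer: EquivariantConvLayer, fld: FeatureField) -> FeatureField:
    """Ordinary convolution with the expanded kernel plus tied per-field bias."""
    if [r.kind for r in fld.field_types] != [r.kind for r in layer.in_types] or (
        fld.values.shape[0] != layer.c_in
    ):
        raise ValueError("input field types do not match the layer's input types")
    kernel = expand_kernel(layer)
    y = conv2d(fld.values, kernel, padding=layer.padding)
    y += layer.bias_vector()[:, None, None]
    return FeatureField(values=y, field_types=list(layer.out_types))


# ---------------------------------------------------------------------------
# Equivariant nonlinearities
# ---------------------------------------------------------------------------


def pointwise_nonlinearity(
    fld: FeatureField, phi: Callable[[np.ndarray], np.ndarray] = leaky_relu
) -> FeatureField:
    """Apply phi elementwise; equivariant when all field types are permutation
    representations (trivial or regular)."""
    for rep in fld.field_types:
        if not rep.is_permutation:
            raise ValueError(
                "pointwise nonlinearities require permutation representations "
                f"(got kind {rep.kind!r})"
            )
    return FeatureField(values=phi(fld.values), field_types=list(fld.field_types))


def norm_nonlinearity(
    fld: FeatureField, phi: Callable[[np.ndarray], np.ndarray]
) -> FeatureField:
    """Per pixel and per field block, f -> f * phi(||f||); needs unitary types."""
    for rep in fld.field_types:
        if not rep.is_unitary:
            raise ValueError("norm nonlinearities require unitary representations")
    out = np.empty_like(fld.values)
    for sl in fld.block_slices():
        block = fld.values[sl]
        norms = np.sqrt(np.sum(block * block, axis=0, keepdims=True))
        out[sl] = block * phi(norms)
    return FeatureField(values=out, field_types=list(fld.field_types))


# ---------------------------------------------------------------------------
# Equivariance test harness
# ---------------------------------------------------------------------------


def equivariance_residual(
    map_fn: Callable[[FeatureField], FeatureField],
    fld: FeatureField,
    k: int,
    t: tuple[int, int] = (0, 0),
    wrap: bool = True,
) -> float:
    """Relative defect ||f(g.x) - g.f(x)|| / (||f(g.x)|| + eps) of a field map."""
    from .groups import act_on_field

    lhs = map_fn(act_on_field(fld, k, t, wrap=wrap)).values
    rhs = act_on_field(map_fn(fld), k, t, wrap=wrap).values
    eps = np.finfo(float).eps
    return float(np.linalg.norm(lhs - rhs) / (np.linalg.norm(lhs) + eps))
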