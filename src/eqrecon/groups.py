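"""Finite cyclic rotation groups, their representations, and actions on feature fields.

The symmetry groups used throughout the package are the cyclic groups
``Z_m`` of planar rotations by multiples of ``2*pi/m``, viewed as subgroups
of SO(2).  Group elements are stored as integers ``k`` in ``{0, ..., m-1}``
so that group arithmetic is exact.  A :class:`Representation` attaches a
matrix to every group element (trivial: the 1x1 identity; regular: the
``m x m`` permutation matrices of the group acting on itself), and a
:class:`FeatureField` is a channel-stacked planar image together with the
list of representations its channel blocks carry.

Coordinate convention: the image centre is the pixel-grid centre
``((H-1)/2, (W-1)/2)``; rotations are counter-clockwise in standard
``(x right, y up)`` coordinates.  With this convention a rotation by
``2*pi*k/4`` is exactly ``numpy.rot90(values, k)``, so for ``m`` in
``{1, 2, 4}`` the spatial action is an exact re-indexing of the array.
For other ``m`` the spatial rotation uses bilinear interpolation with zero
fill and is approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

ON_GRID_ORDERS = (1, 2, 4)


@dataclass(frozen=True)
class CyclicGroup:
    """The cyclic group Z_m of rotations by multiples of 2*pi/m."""

    order: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"group order must be a positive integer, got {self.order}")

    @property
    def elements(self) -> range:
        return range(self.order)

    def multiply(self, a: int, b: int) -> int:
        return (a + b) % self.order

    def inverse(self, a: int) -> int:
        return (self.order - a) % self.order

    @property
    def identity(self) -> int:
        return 0

    def angle(self, k: int) -> float:
        return 2.0 * np.pi * k / self.order

    def is_on_grid(self) -> bool:
        """Whether rotations by the generator map the pixel grid onto itself."""
        return self.order in ON_GRID_ORDERS


def rotation_matrix(group: CyclicGroup, k: int) -> np.ndarray:
    """The 2x2 rotation matrix of element ``k``, counter-clockwise by 2*pi*k/m."""
    if not (0 <= k < group.order):
        raise ValueError(f"element {k} out of range for Z_{group.order}")
    theta = group.angle(k)
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class Representation:
    """A matrix representation of a cyclic group (trivial or regular)."""

    group: CyclicGroup
    dim: int
    kind: str  # "trivial" | "regular"
    _matrices: tuple = field(repr=False, default=())

    def matrix(self, k: int) -> np.ndarray:
        if not (0 <= k < self.group.order):
            raise ValueError(f"element {k} out of range for Z_{self.group.order}")
        return np.asarray(self._matrices[k])

    @property
    def is_permutation(self) -> bool:
        """True when every representation matrix is a permutation matrix."""
        return self.kind in ("trivial", "regular")

    @property
    def is_unitary(self) -> bool:
        return self.kind in ("trivial", "regular")


def trivial_representation(group: CyclicGroup) -> Representation:
    mats = tuple(np.eye(1) for _ in group.elements)
    return Representation(group=group, dim=1, kind="trivial", _matrices=mats)


def regular_representation(group: CyclicGroup) -> Representation:
    """Permutation action of Z_m on itself: matrix(i) maps e_j to e_{(i+j) mod m}."""
    m = group.order
    mats = []
    for i in group.elements:
        mat = np.zeros((m, m))
        for j in range(m):
            mat[(i + j) % m, j] = 1.0
        mats.append(mat)
    return Representation(group=group, dim=m, kind="regular", _matrices=tuple(mats))


# ---------------------------------------------------------------------------
# Spatial action on planar arrays
# ---------------------------------------------------------------------------


def rotate_array(values: np.ndarray, group: CyclicGroup, k: int) -> np.ndarray:
    """Rotate the last two axes counter-clockwise by 2*pi*k/m about the centre.

    Exact (a pure re-indexing) when 4*k is a multiple of m; bilinear with zero
    fill otherwise.
    """
    if not (0 <= k < group.order):
        raise ValueError(f"element {k} out of range for Z_{group.order}")
    if k == 0:
        return values.copy()
    if (4 * k) % group.order == 0:
        return np.rot90(values, (4 * k) // group.order, axes=(-2, -1)).copy()
    theta = group.angle(k)
    h, w = values.shape[-2:]
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    x = jj - cc
    y = cr - ii
    # output(x) = input(R^{-1} x); R^{-1} rotates clockwise by theta
    xs = np.cos(theta) * x + np.sin(theta) * y
    ys = -np.sin(theta) * x + np.cos(theta) * y
    src_r = cr - ys
    src_c = xs + cc
    flat = values.reshape(-1, h, w)
    out = np.stack(
        [map_coordinates(ch, [src_r, src_c], order=1, cval=0.0) for ch in flat]
    )
    return out.reshape(values.shape)


def translate_array(
    values: np.ndarray, t: tuple[int, int], wrap: bool = False
) -> tuple[np.ndarray, bool]:
    """Shift content by ``t = (t_row, t_col)`` pixels on the last two axes.

    Returns the shifted array and a flag that is True when nonzero content was
    pushed off-grid (always False in wrap mode, which shifts circularly).
    """
    tr, tc = int(t[0]), int(t[1])
    if wrap:
        return np.roll(values, (tr, tc), axis=(-2, -1)), False
    h, w = values.shape[-2:]
    out = np.zeros_like(values)
    src_r = slice(max(0, -tr), min(h, h - tr))
    src_c = slice(max(0, -tc), min(w, w - tc))
    dst_r = slice(max(0, tr), min(h, h + tr))
    dst_c = slice(max(0, tc), min(w, w + tc))
    clipped = False
    if src_r.start < src_r.stop and src_c.start < src_c.stop:
        out[..., dst_r, dst_c] = values[..., src_r, src_c]
        kept = np.abs(values[..., src_r, src_c]).sum()
        clipped = not np.isclose(kept, np.abs(values).sum())
    else:
        clipped = bool(np.any(values))
    return out, clipped


@dataclass
class FeatureField:
    """A [C, H, W] image whose channel blocks carry declared representations."""

    values: np.ndarray
    field_types: list[Representation]
    clipped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("FeatureField values must have shape [C, H, W]")
        total = sum(rep.dim for rep in self.field_types)
        if total != self.values.shape[0]:
            raise ValueError(
                f"field_types dims sum to {total}, values have {self.values.shape[0]} channels"
            )

    @property
    def group(self) -> CyclicGroup:
        return self.field_types[0].group

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for rep in self.field_types:
            out.append(slice(start, start + rep.dim))
            start += rep.dim
        return out


def act_on_field(
    fld: FeatureField, k: int, t: tuple[int, int] = (0, 0), wrap: bool = False
) -> FeatureField:
    """Apply the induced action of the roto-translation (t, R_k) to a field.

    The output at position x is ``pi(R) f(R^{-1}(x - t))``: the grid is rotated
    about the image centre and shifted, and every channel block is multiplied
    by its representation matrix.  ``wrap=True`` makes the translation circular
    (useful together with circular convolution padding, where equivariance is
    then exact).
    """
    group = fld.group
    rotated = rotate_array(fld.values, group, k)
    moved, clipped = translate_array(rotated, t, wrap=wrap)
    out = np.empty_like(moved)
    for rep, sl in zip(fld.field_types, fld.block_slices()):
        mat = rep.matrix(k)
        out[sl] = np.einsum("ab,bhw->ahw", mat, moved[sl])
    return FeatureField(values=out, field_types=list(fld.field_types), clipped=clipped)


def compose_elements(
    group: CyclicGroup,
    k1: int,
    t1: tuple[int, int],
    k2: int,
    t2: tuple[int, int],
) -> tuple[int, tuple[int, int]]:
    """Product (t1, R1)(t2, R2) = (t1 + R1 t2, R1 R2) in array-index translations.

    Exact for on-grid rotations; rounds the rotated translation otherwise.
    """
    k = group.multiply(k1, k2)
    # index displacement (dr, dc) corresponds to (x, y) = (dc, -dr)
    x, y = t2[1], -t2[0]
    mat = rotation_matrix(group, k1)
    xr, yr = mat @ np.array([x, y])
    t = (int(round(t1[0] - yr)), int(round(t1[1] + xr)))
    return k, t
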