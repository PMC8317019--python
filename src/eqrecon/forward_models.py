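"""Forward operators, noise simulation and data-discrepancy gradients.

Two linear measurement operators are provided, each with its exact adjoint:

* a parallel-beam ray transform (Radon transform) for low-dose CT, built as
  an explicit sparse matrix of ray-driven line integrals with bilinear
  sampling, so the adjoint is the algebraic transpose and the dot-product
  identity holds by construction;
* a subsampled Fourier transform for Cartesian MRI, a unitary 2-D DFT with
  whole k-space columns masked (so the nonzero singular values are all 1 and
  the adjoint is the zero-filling reconstruction).

CT measurements follow the low-dose post-log model

    y = -(1/mu) log(max(n / N_in, eta)),   n ~ Pois(N_in exp(-mu R(u))),

with ``N_in`` the mean photon count per detector pixel, ``mu`` a base
attenuation coefficient and ``eta`` a small clip constant.  MRI measurements
are ``y = S F u + eps`` with complex white Gaussian noise ``eps``.  In both
problems the data-discrepancy functional is E_y(u) = ||A u - y||^2 / 2, whose
gradient A^T(A u - y) drives both the classical and the learned proximal
gradient methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse


# ---------------------------------------------------------------------------
# Parallel-beam ray transform (CT)
# ---------------------------------------------------------------------------


@dataclass
class RadonGeometry:
    """Parallel-beam geometry: uniform view angles in [0, pi)."""

    image_size: int
    n_angles: int = 50
    n_detectors: int | None = None
    detector_spacing: float = 1.0
    step: float = 0.5  # integration step along rays, in pixels

    def __post_init__(self) -> None:
        if self.n_detectors is None:
            # cover the full image diagonal at every angle
            self.n_detectors = int(np.ceil(np.sqrt(2.0) * self.image_size)) + 1
        self._matrix: sparse.csr_matrix | None = None

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_angles, self.n_detectors)

    def matrix(self) -> sparse.csr_matrix:
        """The discretised transform as a sparse matrix (cached)."""
        if self._matrix is None:
            self._matrix = _build_radon_matrix(self)
        return self._matrix


def _build_radon_matrix(geom: RadonGeometry) -> sparse.csr_matrix:
    n = geom.image_size
    c = (n - 1) / 2.0
    offsets = (np.arange(geom.n_detectors) - (geom.n_detectors - 1) / 2.0) * (
        geom.detector_spacing
    )
    half_len = np.sqrt(2.0) * n / 2.0 + 1.0
    ts = np.arange(-half_len, half_len + geom.step / 2, geom.step)
    rows_all, cols_all, vals_all = [], [], []
    for ia, theta in enumerate(geom.angles):
        d = np.array([np.cos(theta), np.sin(theta)])
        nrm = np.array([-np.sin(theta), np.cos(theta)])
        # sample points: [n_det, n_samples, 2] in centred (x, y) coordinates
        x = offsets[:, None] * nrm[0] + ts[None, :] * d[0]
        y = offsets[:, None] * nrm[1] + ts[None, :] * d[1]
        rr = c - y
        cc = c + x
        r0 = np.floor(rr).astype(int)
        c0 = np.floor(cc).astype(int)
        fr = rr - r0
        fc = cc - c0
        ray_idx = np.broadcast_to(
            (ia * geom.n_detectors + np.arange(geom.n_detectors))[:, None], rr.shape
        )
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            pr = r0 + dr
            pc = c0 + dc
            ok = (pr >= 0) & (pr < n) & (pc >= 0) & (pc < n) & (w > 0)
            rows_all.append(ray_idx[ok])
            cols_all.append((pr * n + pc)[ok])
            vals_all.append((w * geom.step)[ok])
    mat = sparse.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(geom.n_angles * geom.n_detectors, n * n),
    )
    return mat.tocsr()


def radon_apply(image: np.ndarray, geom: RadonGeometry) -> np.ndarray:
    """Line integrals of a square image: sinogram of shape [n_angles, n_detectors]."""
    if image.shape != (geom.image_size, geom.image_size):
        raise ValueError("image shape does not match geometry")
    return (geom.matrix() @ image.ravel()).reshape(geom.sinogram_shape)


def radon_adjoint(sinogram: np.ndarray, geom: RadonGeometry) -> np.ndarray:
    """Exact transpose of the discretised forward map (weighted backprojection)."""
    if sinogram.shape != geom.sinogram_shape:
        raise ValueError("sinogram shape does not match geometry")
    n = geom.image_size
    return (geom.matrix().T @ sinogram.ravel()).reshape(n, n)


def fbp(sinogram: np.ndarray, geom: RadonGeometry) -> np.ndarray:
    """Filtered backprojection: Ram-Lak filtering per angle, then backprojection.

    The ramp filter is applied in the frequency domain along the detector
    axis (zero-padded); the filtered sinogram is backprojected with the
    transpose operator and scaled by pi / (2 * n_angles) so that dense
    angular sampling recovers the image.
    """
    nd = geom.n_detectors
    npad = max(64, int(2 ** np.ceil(np.log2(2 * nd))))
    # discrete-space ramp kernel (avoids the DC bias of a naive |f| ramp)
    n = np.concatenate([np.arange(0, npad // 2 + 1), np.arange(npad // 2 - 1, 0, -1)])
    h = np.zeros(npad)
    h[0] = 0.25
    odd = n % 2 == 1
    h[odd] = -1.0 / (np.pi * n[odd]) ** 2
    ramp = 2.0 * np.real(np.fft.fft(h)) / geom.detector_spacing**2
    padded = np.zeros((geom.n_angles, npad))
    padded[:, :nd] = sinogram
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * ramp, axis=1))[:, :nd]
    back = radon_adjoint(filtered, geom)
    return back * np.pi / (2.0 * geom.n_angles)


@dataclass
class CTNoiseModel:
    """Low-dose photon statistics for the post-log CT measurement model.

    ``mu=None`` calibrates the attenuation coefficient per image so that the
    maximum of mu * R(u) is ``target_attenuation``, i.e. the strongest ray is
    attenuated to exp(-target): a genuinely low-dose regime regardless of the
    phantom's intensity scale.
    """

    n_photons: float = 10_000.0
    mu: float | None = None
    eta: float = 1e-8
    seed: int = 0
    target_attenuation: float = 5.0

    def __post_init__(self) -> None:
        if self.n_photons <= 0 or self.eta <= 0:
            raise ValueError("n_photons and eta must be positive")


def calibrate_mu(u: np.ndarray, geom: RadonGeometry, target: float = 5.0) -> float:
    """Attenuation coefficient making the strongest ray attenuate to exp(-target)."""
    smax = float(radon_apply(u, geom).max())
    if smax <= 0:
        raise ValueError("cannot calibrate mu on a non-positive image")
    return target / smax


def simulate_ct(
    u: np.ndarray,
    geom: RadonGeometry,
    noise: CTNoiseModel,
    noiseless: bool = False,
) -> np.ndarray:
    """Post-log low-dose sinogram; ``noiseless=True`` replaces the Poisson draw
    by its expectation (in which case y = R(u) exactly when the clip is inactive)."""
    mu = noise.mu if noise.mu is not None else calibrate_mu(u, geom, noise.target_attenuation)
    sino = radon_apply(u, geom)
    expected = noise.n_photons * np.exp(-mu * sino)
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(noise.seed)
        counts = rng.poisson(expected).astype(float)
    return -np.log(np.maximum(counts / noise.n_photons, noise.eta)) / mu


# ---------------------------------------------------------------------------
# Subsampled Fourier transform (MRI)
# ---------------------------------------------------------------------------


@dataclass
class MRISampling:
    """Cartesian line sampling: a boolean mask constant along the readout axis."""

    mask: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D boolean array")
        cols = self.mask.any(axis=0)
        if not np.array_equal(self.mask, np.broadcast_to(cols, self.mask.shape)):
            raise ValueError("mask must be a union of full k-space columns")

    @property
    def sampled_fraction(self) -> float:
        return float(self.mask.mean())


def generate_cartesian_mask(
    shape: tuple[int, int],
    target_fraction: float = 0.203,
    center_fraction: float = 0.08,
    seed: int = 0,
) -> MRISampling:
    """Variable-density Cartesian line mask (fftshifted convention: the centre
    of k-space is the middle column).

    The central ``center_fraction`` of columns is always fully sampled;
    remaining columns are drawn without replacement with Gaussian-decaying
    probability in the distance from the centre until ``target_fraction`` of
    k-space is covered.  Deterministic given the seed.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must be in (0, 1]")
    if target_fraction < center_fraction:
        raise ValueError("target_fraction must be at least center_fraction")
    h, w = shape
    n_target = int(round(target_fraction * w))
    n_center = max(1, int(round(center_fraction * w)))
    n_center = min(n_center, n_target)
    centre = w // 2
    cols = np.zeros(w, dtype=bool)
    lo = centre - n_center // 2
    cols[lo : lo + n_center] = True
    n_extra = n_target - int(cols.sum())
    if n_extra > 0:
        rng = np.random.default_rng(seed)
        candidates = np.flatnonzero(~cols)
        dist = np.abs(candidates - centre)
        weights = np.exp(-0.5 * (dist / (w / 4.0)) ** 2)
        weights /= weights.sum()
        chosen = rng.choice(candidates, size=n_extra, replace=False, p=weights)
        cols[chosen] = True
    mask = np.broadcast_to(cols, (h, w)).copy()
    return MRISampling(mask=mask)


def _to_complex(u: np.ndarray) -> np.ndarray:
    if u.ndim == 3 and u.shape[0] == 2:
        return u[0] + 1j * u[1]
    return u.astype(complex)


def _to_channels(z: np.ndarray) -> np.ndarray:
    return np.stack([z.real, z.imag])


def mri_apply(u: np.ndarray, sampling: MRISampling) -> np.ndarray:
    """Masked unitary 2-D DFT; complex images are passed as 2 real channels.

    Returns k-space as 2 real channels with unsampled entries zero.  The DFT
    is fftshifted so the mask's central columns select low frequencies.
    """
    z = _to_complex(u)
    k = np.fft.fftshift(np.fft.fft2(z, norm="ortho"))
    return _to_channels(k * sampling.mask)


def mri_adjoint(y: np.ndarray, sampling: MRISampling) -> np.ndarray:
    """Zero-filling reconstruction: exact adjoint of the masked unitary DFT."""
    k = _to_complex(y) * sampling.mask
    z = np.fft.ifft2(np.fft.ifftshift(k), norm="ortho")
    return _to_channels(z)


def simulate_mri(u: np.ndarray, sampling: MRISampling) -> np.ndarray:
    """y = S F u + eps with complex white Gaussian noise on the sampled lines."""
    y = mri_apply(u, sampling)
    if sampling.noise_sd > 0:
        rng = np.random.default_rng(sampling.seed)
        eps = rng.normal(0.0, sampling.noise_sd, size=y.shape)
        y = y + eps * sampling.mask
    return y


# ---------------------------------------------------------------------------
# Operator pairs and the data-discrepancy gradient
# ---------------------------------------------------------------------------


@dataclass
class LinearOperatorPair:
    """A forward operator with its exact adjoint, as array-to-array callables."""

    apply: Callable[[np.ndarray], np.ndarray]
    adjoint: Callable[[np.ndarray], np.ndarray]
    name: str
    in_shape: tuple
    out_shape: tuple

    def normal(self, u: np.ndarray) -> np.ndarray:
        return self.adjoint(self.apply(u))


def radon_operator(geom: RadonGeometry) -> LinearOperatorPair:
    n = geom.image_size
    return LinearOperatorPair(
        apply=lambda u: radon_apply(u, geom),
        adjoint=lambda y: radon_adjoint(y, geom),
        name="radon",
        in_shape=(n, n),
        out_shape=geom.sinogram_shape,
    )


def mri_operator(sampling: MRISampling) -> LinearOperatorPair:
    h, w = sampling.mask.shape
    return LinearOperatorPair(
        apply=lambda u: mri_apply(u, sampling),
        adjoint=lambda y: mri_adjoint(y, sampling),
        name="masked_fourier",
        in_shape=(2, h, w),
        out_shape=(2, h, w),
    )


def discrepancy_gradient(
    u: np.ndarray, y: np.ndarray, op: LinearOperatorPair
) -> np.ndarray:
    """Gradient of E_y(u) = ||A u - y||^2 / 2, namely A^T(A u - y)."""
    return op.adjoint(op.apply(u) - y)


def operator_norm(op: LinearOperatorPair, n_iter: int = 30, seed: int = 0) -> float:
    """Estimate ||A|| by power iteration on A^T A."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=op.in_shape)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = op.normal(v)
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 0.0
        v = w / lam
    return float(np.sqrt(lam))


def adjoint_residual(
    op: LinearOperatorPair, seed: int = 0
) -> float:
    """|<Ax, y> - <x, A^T y>| / (||Ax|| ||y||) on a random draw."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=op.in_shape)
    y = rng.normal(size=op.out_shape)
    ax = op.apply(x)
    aty = op.adjoint(y)
    num = abs(float(np.vdot(ax, y)) - float(np.vdot(x, aty)))
    den = float(np.linalg.norm(ax) * np.linalg.norm(y)) + np.finfo(float).eps
    return num / den
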