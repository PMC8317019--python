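"""Seeded synthetic phantoms and measurement datasets.

These generators stand in for clinical CT/MRI image collections at desk
scale: random ellipse phantoms with deliberately oriented, anisotropic
structures (elongated ellipses at random angles), so that generalisation to
rotated test images is non-trivial — isotropic blobs would mask the gap
between rotation-equivariant and ordinary reconstruction networks.

Every generator is a pure function of its seed and parameters.  Rotations
by multiples of 90 degrees are exact array permutations; other angles use
bilinear interpolation, which removes some high-frequency content (rotated
test sets built with off-grid angles are therefore slightly easier, and the
fixtures flag which regime they are in).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .forward_models import (
    CTNoiseModel,
    MRISampling,
    RadonGeometry,
    calibrate_mu,
    generate_cartesian_mask,
    simulate_ct,
    simulate_mri,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the random ellipse phantom generator."""

    size: int = 64
    n_ellipses: int = 8
    intensity_range: tuple[float, float] = (0.2, 0.6)
    semi_major_range: tuple[float, float] = (0.15, 0.4)  # fraction of image size
    eccentricity_range: tuple[float, float] = (0.6, 0.95)
    # range of ellipse orientations (radians).  The full default makes an
    # isotropic ensemble; a narrow range emulates globally oriented anatomy
    # (as in clinical images), which is what makes testing on rotated images
    # an out-of-distribution probe.
    orientation_range: tuple[float, float] = (0.0, np.pi)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise ValueError("phantom size must be at least 16")


def ellipse_phantom(spec: PhantomSpec) -> np.ndarray:
    """Overlay of randomly placed, oriented ellipses with anti-aliased edges.

    Intensities add where ellipses overlap and the result is clipped to
    [0, max intensity], so the declared range bounds the pixel values.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    img = np.zeros((n, n))
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = (n - 1) / 2.0
    x = jj - c
    y = c - ii
    for _ in range(spec.n_ellipses):
        cx, cy = rng.uniform(-0.3 * n, 0.3 * n, size=2)
        a = rng.uniform(*spec.semi_major_range) * n
        ecc = rng.uniform(*spec.eccentricity_range)
        b = a * np.sqrt(1.0 - ecc**2)
        theta = rng.uniform(*spec.orientation_range)
        amp = rng.uniform(*spec.intensity_range)
        xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
        yr = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
        q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        # ~1-pixel anti-aliased edge in the ellipse's own scale
        edge = 1.0 / min(a, b)
        img += amp * np.clip((1.0 - q) / edge + 0.5, 0.0, 1.0)
    return np.clip(img, 0.0, spec.intensity_range[1] * 2.0)


def rotate_image(image: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate counter-clockwise about the centre; exact permutation for
    multiples of 90 degrees, spline interpolation (zero fill) otherwise."""
    k = angle_deg / 90.0
    if np.isclose(k, round(k)):
        return np.rot90(image, int(round(k)) % 4, axes=(-2, -1)).copy()
    return ndimage.rotate(
        image, angle_deg, axes=(-2, -1), reshape=False, order=order, cval=0.0
    )


# ---------------------------------------------------------------------------
# Measurement datasets
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Paired ground-truth images and simulated measurements."""

    images: list
    measurements: list
    modality: Literal["ct", "mri"]
    geometry: RadonGeometry | None = None
    sampling: MRISampling | None = None
    mu: float | None = None

    def __len__(self) -> int:
        return len(self.images)

    def pairs(self):
        return list(zip(self.images, self.measurements))


def make_dataset(
    n: int,
    modality: Literal["ct", "mri"],
    spec: PhantomSpec | None = None,
    seed: int = 0,
    geometry: RadonGeometry | None = None,
    sampling: MRISampling | None = None,
    noise: CTNoiseModel | None = None,
    mri_noise_sd: float = 0.01,
    noiseless: bool = False,
) -> Dataset:
    """Generate n phantom/measurement pairs with per-pair derived seeds.

    CT: post-log low-dose sinograms; the attenuation coefficient mu is
    calibrated once on the first phantom of the dataset (strongest ray
    attenuated to exp(-5)) and shared by all pairs.  MRI: masked unitary DFT
    of the phantom (real part; imaginary part zero) plus complex Gaussian
    noise, returned as 2-channel images and 2-channel k-space.
    """
    if n < 1:
        raise ValueError("need at least one pair")
    spec = spec or PhantomSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n)
    images, measurements = [], []
    if modality == "ct":
        geometry = geometry or RadonGeometry(spec.size)
        noise = noise or CTNoiseModel()
        mu = noise.mu
        for i in range(n):
            u = ellipse_phantom(replace(spec, seed=int(child_seeds[2 * i])))
            if mu is None:
                mu = calibrate_mu(u, geometry, noise.target_attenuation)
            nm = CTNoiseModel(
                n_photons=noise.n_photons,
                mu=mu,
                eta=noise.eta,
                seed=int(child_seeds[2 * i + 1]),
            )
            y = simulate_ct(u, geometry, nm, noiseless=noiseless)
            images.append(u)
            measurements.append(y)
        return Dataset(images, measurements, "ct", geometry=geometry, mu=mu)
    elif modality == "mri":
        sampling = sampling or generate_cartesian_mask(
            (spec.size, spec.size), seed=seed
        )
        for i in range(n):
            u = ellipse_phantom(replace(spec, seed=int(child_seeds[2 * i])))
            u2 = np.stack([u, np.zeros_like(u)])
            samp_i = MRISampling(
                mask=sampling.mask,
                noise_sd=0.0 if noiseless else mri_noise_sd,
                seed=int(child_seeds[2 * i + 1]),
            )
            y = simulate_mri(u2, samp_i)
            images.append(u2)
            measurements.append(y)
        return Dataset(images, measurements, "mri", sampling=sampling)
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# Single-pair denoising fixture (toy rotation-generalisation experiment)
# ---------------------------------------------------------------------------


def save_datasets(path, splits: dict, config: dict | None = None) -> None:
    """Write named splits (e.g. {"train": ds, "test": ds}) to one HDF5 file,
    with geometry / sampling / noise parameters stored as attributes."""
    import h5py

    with h5py.File(path, "w") as f:
        for key, val in (config or {}).items():
            f.attrs[f"config_{key}"] = val
        for name, ds in splits.items():
            grp = f.create_group(name)
            grp.attrs["modality"] = ds.modality
            if ds.modality == "ct":
                g = ds.geometry
                grp.attrs.update(
                    image_size=g.image_size,
                    n_angles=g.n_angles,
                    n_detectors=g.n_detectors,
                    detector_spacing=g.detector_spacing,
                    step=g.step,
                    mu=ds.mu,
                )
            else:
                grp.create_dataset("mask", data=ds.sampling.mask)
            for i, (u, y) in enumerate(ds.pairs()):
                grp.create_dataset(f"image_{i:04d}", data=u)
                grp.create_dataset(f"measurement_{i:04d}", data=y)


def load_datasets(path) -> dict:
    """Inverse of :func:`save_datasets`."""
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            grp = f[name]
            modality = str(grp.attrs["modality"])
            n = sum(1 for k in grp if k.startswith("image_"))
            images = [grp[f"image_{i:04d}"][()] for i in range(n)]
            meas = [grp[f"measurement_{i:04d}"][()] for i in range(n)]
            if modality == "ct":
                geom = RadonGeometry(
                    image_size=int(grp.attrs["image_size"]),
                    n_angles=int(grp.attrs["n_angles"]),
                    n_detectors=int(grp.attrs["n_detectors"]),
                    detector_spacing=float(grp.attrs["detector_spacing"]),
                    step=float(grp.attrs["step"]),
                )
                out[name] = Dataset(
                    images, meas, "ct", geometry=geom, mu=float(grp.attrs["mu"])
                )
            else:
                out[name] = Dataset(
                    images,
                    meas,
                    "mri",
                    sampling=MRISampling(mask=grp["mask"][()]),
                )
    return out


@dataclass(frozen=True)
class Figure1Fixture:
    clean: np.ndarray
    noisy: np.ndarray
    rotated_clean: np.ndarray
    rotated_noisy: np.ndarray
    angle_deg: float
    noise_sd: float
    exact_rotation: bool


def figure1_fixture(
    seed: int = 0,
    size: int = 64,
    angle_deg: float = 90.0,
    noise_sd: float = 0.3,
) -> Figure1Fixture:
    """A single strongly oriented phantom, its noisy copy, and rotated test copies.

    The phantom stacks elongated parallel ellipses in one common direction, so
    a denoiser that exploits the training orientation fails on the rotated
    test image.  The default 90-degree rotation is an exact permutation; an
    off-grid angle (e.g. 20 degrees) exposes the interpolation-smoothing
    caveat instead.
    """
    rng = np.random.default_rng(seed)
    n = size
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = (n - 1) / 2.0
    x = jj - c
    y = c - ii
    clean = np.zeros((n, n))
    theta = np.pi / 6.0  # common orientation of all structures
    for _ in range(6):
        cx, cy = rng.uniform(-0.35 * n, 0.35 * n, size=2)
        a = rng.uniform(0.3, 0.45) * n
        b = rng.uniform(0.02, 0.04) * n
        amp = rng.uniform(0.5, 1.0)
        xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
        yr = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
        q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        clean += amp * np.clip((1.0 - q) * min(a, b) + 0.5, 0.0, 1.0)
    clean = np.clip(clean, 0.0, 1.0)
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    exact = bool(np.isclose(angle_deg / 90.0, round(angle_deg / 90.0)))
    return Figure1Fixture(
        clean=clean,
        noisy=noisy,
        rotated_clean=rotate_image(clean, angle_deg),
        rotated_noisy=rotate_image(noisy, angle_deg),
        angle_deg=angle_deg,
        noise_sd=noise_sd,
        exact_rotation=exact,
    )
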