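"""Image quality metrics: PSNR, windowed SSIM, and masked SSIM-map averages.

PSNR for a ground truth u and reconstruction u_hat (both with n entries):

    PSNR(u_hat, u) = 10 log10( n * max_i |u_i|^2 / ||u - u_hat||^2 )  [dB]

with the peak taken over the ground-truth image (not a fixed bit-depth
range).  Identical images give the +inf sentinel.

SSIM is the classical windowed statistic with a uniform (not Gaussian)
window of 7x7 and stabilisers c1 = (0.01 L)^2, c2 = (0.03 L)^2 where L is
the data range; covariances use the sample normalisation, matching the
defaults of the standard scikit-image implementation, and the global score
averages the per-window statistic over all fully contained windows.

For region-restricted evaluation the images are reflection-padded by
floor(w/2), the per-pixel SSIM map (aligned with the original grid) is
computed, and the map is averaged over the mask.  Complex (two-channel)
images are evaluated on their pixelwise magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter


@dataclass
class MetricConfig:
    """Window size and stabiliser constants for SSIM."""

    window: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float | None = None  # default: max(u) - min(u) of the ground truth

    def __post_init__(self) -> None:
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("stabilisers must be nonnegative")


PSNR_PERFECT = np.inf  # sentinel for identical images


def psnr(u_hat: np.ndarray, u: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf sentinel when u_hat == u."""
    u = np.asarray(u, dtype=float)
    u_hat = np.asarray(u_hat, dtype=float)
    if u.shape != u_hat.shape:
        raise ValueError("shapes must match")
    peak2 = float(np.max(np.abs(u)) ** 2)
    if peak2 == 0.0:
        raise ValueError("PSNR is undefined for an identically zero ground truth")
    err = float(np.sum((u - u_hat) ** 2))
    if err == 0.0:
        return PSNR_PERFECT
    return 10.0 * np.log10(u.size * peak2 / err)


def _ssim_map(u_hat: np.ndarray, u: np.ndarray, cfg: MetricConfig) -> np.ndarray:
    """Per-window SSIM values on the common grid (no padding applied here)."""
    w = cfg.window
    L = cfg.data_range if cfg.data_range is not None else float(u.max() - u.min())
    c1 = (cfg.k1 * L) ** 2
    c2 = (cfg.k2 * L) ** 2
    np_ = w * w
    cov_norm = np_ / (np_ - 1.0)  # sample covariance, reference-implementation default

    mean = lambda x: uniform_filter(x, size=w, mode="constant")
    mx = mean(u_hat)
    my = mean(u)
    mxx = mean(u_hat * u_hat)
    myy = mean(u * u)
    mxy = mean(u_hat * u)
    vx = cov_norm * (mxx - mx * mx)
    vy = cov_norm * (myy - my * my)
    cxy = cov_norm * (mxy - mx * my)
    num = (2 * mx * my + c1) * (2 * cxy + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    return num / den


def ssim(u_hat: np.ndarray, u: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """Mean SSIM over all fully contained w x w windows."""
    cfg = cfg or MetricConfig()
    u = np.asarray(u, dtype=float)
    u_hat = np.asarray(u_hat, dtype=float)
    if u.shape != u_hat.shape:
        raise ValueError("shapes must match")
    if min(u.shape) < cfg.window:
        raise ValueError(f"images must be at least {cfg.window}x{cfg.window}")
    pad = cfg.window // 2
    smap = _ssim_map(u_hat, u, cfg)
    return float(smap[pad:-pad, pad:-pad].mean())


def ssim_map(
    u_hat: np.ndarray, u: np.ndarray, cfg: MetricConfig | None = None
) -> np.ndarray:
    """SSIM map aligned with the input grid, via reflection padding."""
    cfg = cfg or MetricConfig()
    pad = cfg.window // 2
    if cfg.data_range is None:
        cfg = MetricConfig(cfg.window, cfg.k1, cfg.k2, float(u.max() - u.min()))
    up = np.pad(u, pad, mode="reflect")
    vp = np.pad(u_hat, pad, mode="reflect")
    return _ssim_map(vp, up, cfg)[pad:-pad, pad:-pad]


def masked_ssim(
    u_hat: np.ndarray,
    u: np.ndarray,
    mask: np.ndarray,
    cfg: MetricConfig | None = None,
) -> float:
    """Average of the (reflection-padded) SSIM map over the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(u).shape:
        raise ValueError("mask shape must match the images")
    if not mask.any():
        raise ValueError("mask must select at least one pixel")
    smap = ssim_map(u_hat, u, cfg)
    return float(smap[mask].mean())


def _magnitude(u: np.ndarray) -> np.ndarray:
    if u.ndim == 3 and u.shape[0] == 2:
        return np.sqrt(u[0] ** 2 + u[1] ** 2)
    return np.abs(np.asarray(u, dtype=float))


def complex_metrics(
    u_hat: np.ndarray, u: np.ndarray, cfg: MetricConfig | None = None
) -> tuple[float, float]:
    """(PSNR, SSIM) of two-channel complex images, computed on magnitudes."""
    return (
        psnr(_magnitude(u_hat), _magnitude(u)),
        ssim(_magnitude(u_hat), _magnitude(u), cfg),
    )
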