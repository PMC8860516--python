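"""Speckle suppression: Frost filter and a Lee-style adaptive mean filter.

The Frost filter replaces each pixel by a weighted average of its
``(2N+1) x (2N+1)`` window. Weights decay exponentially with distance from
the center, scaled by the local squared coefficient of variation:

    h(k, l) = exp(-K * (sigma^2 / mu^2) * d)
    s(i, j) = sum h * I / sum h,      d = sqrt((i-k)^2 + (j-l)^2)

so in homogeneous areas (sigma^2 ~ 0) the filter tends to the plain window
mean, while near edges and point targets (large coefficient of variation)
the center pixel dominates and detail is preserved. ``K`` is the damping
constant; large ``K`` approaches the identity, ``K = 0`` is the box mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["FrostParams", "FilterResult", "frost_filter", "adaptive_mean_filter",
           "filter_cube"]

# Edge-repeating reflection: scipy.ndimage calls it "reflect", np.pad
# calls it "symmetric" — both entries must stay in sync.
_PAD_MODES = {"reflect": "reflect", "constant-zero": "constant"}
_NP_PAD_MODES = {"reflect": "symmetric", "constant-zero": "constant"}


@dataclass
class FrostParams:
    """Frost filter parameters: window half-size N, damping K, border mode."""

    window_half: int = 2
    damping: float = 2.0
    border_mode: str = "reflect"

    def validate(self) -> None:
        if self.window_half < 1:
            raise ValueError(f"window_half must be >= 1; got {self.window_half}")
        if not self.damping > 0:
            raise ValueError(f"damping must be > 0; got {self.damping}")
        if self.border_mode not in _PAD_MODES:
            raise ValueError(
                f"border_mode must be one of {tuple(_PAD_MODES)}; "
                f"got {self.border_mode!r}"
            )


@dataclass
class FilterResult:
    """Filtered image plus the per-pixel unnormalized kernel weight sums."""

    filtered: np.ndarray
    weights_checksum: np.ndarray
    params: object


def _local_stats(img: np.ndarray, half: int, mode: str
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Window mean and (population) variance via box filters."""
    size = 2 * half + 1
    mu = uniform_filter(img, size=size, mode=mode)
    mu2 = uniform_filter(img * img, size=size, mode=mode)
    var = np.maximum(mu2 - mu * mu, 0.0)
    return mu, var


def frost_filter(img: np.ndarray, params: FrostParams | None = None
                 ) -> FilterResult:
    """Apply the Frost filter to a 2-D image.

    Pixels whose window mean is zero are set to zero. Raises on non-finite
    input or invalid parameters.
    """
    params = params or FrostParams()
    params.validate()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"frost_filter expects a 2-D image; got {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("input image contains non-finite values")

    half = params.window_half
    pad_mode = _PAD_MODES[params.border_mode]
    mu, var = _local_stats(img, half, pad_mode)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / (mu * mu), 0.0)

    padded = np.pad(img, half, mode=_NP_PAD_MODES[params.border_mode])
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    H, W = img.shape
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            d = np.hypot(dy, dx)
            w = np.exp(-params.damping * cv2 * d)
            shifted = padded[half + dy:half + dy + H, half + dx:half + dx + W]
            num += w * shifted
            den += w
    out = np.where(mu > 0, num / den, 0.0)
    return FilterResult(filtered=out, weights_checksum=den, params=params)


def adaptive_mean_filter(img: np.ndarray, window_half: int = 2,
                         noise_cv: float = 0.5,
                         border_mode: str = "reflect") -> FilterResult:
    """Lee-style local-statistics filter: ``s = mu + W (I - mu)``.

    ``W = max(0, 1 - C_n^2 / C_I^2)`` with ``C_n`` the assumed noise
    coefficient of variation and ``C_I`` the observed local one. With
    ``noise_cv = 0`` the filter is the identity; in flat areas
    (``C_I <= C_n``) it returns the window mean.
    """
    if window_half < 1:
        raise ValueError(f"window_half must be >= 1; got {window_half}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0; got {noise_cv}")
    if border_mode not in _PAD_MODES:
        raise ValueError(f"border_mode must be one of {tuple(_PAD_MODES)}")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"adaptive_mean_filter expects a 2-D image; got {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("input image contains non-finite values")

    mu, var = _local_stats(img, window_half, _PAD_MODES[border_mode])
    with np.errstate(divide="ignore", invalid="ignore"):
        ci2 = np.where(mu > 0, var / (mu * mu), 0.0)
        w = np.where(ci2 > 0, np.maximum(0.0, 1.0 - noise_cv**2 / np.where(ci2 > 0, ci2, 1.0)), 0.0)
    if noise_cv == 0:
        w = np.ones_like(img)
    out = mu + w * (img - mu)
    size = 2 * window_half + 1
    checksum = np.full_like(img, float(size * size))
    return FilterResult(filtered=out, weights_checksum=checksum,
                        params={"window_half": window_half, "noise_cv": noise_cv,
                                "border_mode": border_mode})


def filter_cube(cube_data: np.ndarray, params: FrostParams | None = None,
                mode: str = "frost", **kwargs) -> np.ndarray:
    """Apply a speckle filter band-by-band to an H x W x B cube."""
    cube_data = np.asarray(cube_data, dtype=float)
    if cube_data.ndim != 3:
        raise ValueError(f"filter_cube expects (H, W, B); got {cube_data.shape}")
    out = np.empty_like(cube_data)
    for b in range(cube_data.shape[2]):
        band = cube_data[:, :, b]
        if mode == "frost":
            out[:, :, b] = frost_filter(band, params).filtered
        elif mode == "adaptive":
            out[:, :, b] = adaptive_mean_filter(band, **kwargs).filtered
        else:
            raise ValueError(f"unknown filter mode {mode!r}")
    return out
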