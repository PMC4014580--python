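"""Frame-level imagery metrics: microbial cover and luminosity.

Two per-frame quality/cover indices support the image time series:

* ``coverage_percent`` — percent of a binary mask that is white.
  Microbial mats are segmented (elsewhere) into a white-on-black
  mask; the metric is simply 100 · white / total pixels.
* ``hsl_index`` — a 0–255 luminosity index of an RGB frame used to
  track the gradual darkening of long camera deployments. The default
  mode averages the per-pixel HSL lightness L = (max + min)/2 scaled
  to 0–255, so an all-black frame scores 0 and an all-white frame
  255. ``mode="hsl-mean"`` instead averages all three HSL channels
  (each scaled 0–255); both modes are monotone in uniform lightness
  changes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["coverage_percent", "hsl_index", "rgb_to_hsl"]


def _as_array(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    return arr


def coverage_percent(mask) -> float:
    """Percent of white pixels in a binary cover mask.

    Accepts boolean arrays, 0/1 or 0/255 integer masks, and grayscale
    images, which are binarized at the midpoint of their value range
    (above 0.5 for unit-scaled, above 127.5 for 8-bit input).
    """
    arr = _as_array(mask)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.dtype == bool:
        white = arr
    elif np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) > 1:
        white = arr > 127.5
    else:
        white = arr > 0.5 if arr.max(initial=0.0) <= 1.0 else arr > 127.5
    return float(100.0 * white.mean())


def rgb_to_hsl(rgb: np.ndarray) -> np.ndarray:
    """Convert an (..., 3) RGB array in [0, 1] to HSL in [0, 1].

    Standard hexcone HSL: L = (max + min)/2, S relative to the
    lightness band, H on the colour wheel (0 for achromatic pixels).
    """
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cmax = rgb.max(axis=-1)
    cmin = rgb.min(axis=-1)
    L = (cmax + cmin) / 2.0
    delta = cmax - cmin
    chromatic = delta > 0
    S = np.zeros_like(L)
    denom = 1.0 - np.abs(2.0 * L - 1.0)
    good = chromatic & (denom > 0)
    S[good] = delta[good] / denom[good]
    H = np.zeros_like(L)
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = np.mod((g - b) / delta, 6.0)
        hg = (b - r) / delta + 2.0
        hb = (r - g) / delta + 4.0
    H = np.where(cmax == r, hr, np.where(cmax == g, hg, hb)) / 6.0
    H = np.where(chromatic, H, 0.0)
    return np.stack([H, S, L], axis=-1)


def hsl_index(frame, mode: str = "lightness-only") -> float:
    """Luminosity index of an RGB frame on a 0–255 scale.

    ``mode="lightness-only"`` (default): mean HSL lightness, 0 for
    black, 255 for white. ``mode="hsl-mean"``: mean over pixels of the
    per-pixel mean of the H, S and L channels, each scaled 0–255.
    """
    arr = _as_array(frame).astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    if arr.max(initial=0.0) > 1.0:
        arr = arr / 255.0
    hsl = rgb_to_hsl(arr)
    if mode == "lightness-only":
        return float(255.0 * hsl[..., 2].mean())
    if mode == "hsl-mean":
        return float(255.0 * hsl.mean(axis=-1).mean())
    raise ValueError(f"unknown mode {mode!r}")
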