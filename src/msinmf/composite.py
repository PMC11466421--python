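"""Color-coded composite "H&E-like" images from spatial component maps.

Each spatial intensity map is thresholded into foreground/background,
scaled by a color vector (fractions of red, green, blue), and the colored
layers are added together into one 8-bit RGB composite. Pixels exceeding
255 in a channel are clamped (never wrapped), with a warning when too
many pixels saturate.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np

log = logging.getLogger(__name__)


class ColorVector(NamedTuple):
    """Per-channel fractions in [0, 1]; (0.1, 0.8, 0.3) is 10% red, 80% green, 30% blue."""

    r: float
    g: float
    b: float

    def validate(self) -> "ColorVector":
        for v in self:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"color vector entries must be in [0, 1], got {tuple(self)}")
        return self


# 20 visually distinct colors (paired qualitative palette).
DEFAULT_PALETTE: tuple[ColorVector, ...] = tuple(
    ColorVector(*c)
    for c in [
        (0.121, 0.466, 0.705), (0.682, 0.780, 0.909), (1.000, 0.498, 0.054),
        (1.000, 0.733, 0.470), (0.172, 0.627, 0.172), (0.596, 0.874, 0.541),
        (0.839, 0.152, 0.156), (1.000, 0.596, 0.588), (0.580, 0.403, 0.741),
        (0.772, 0.690, 0.835), (0.549, 0.337, 0.294), (0.768, 0.611, 0.580),
        (0.890, 0.466, 0.760), (0.968, 0.713, 0.823), (0.498, 0.498, 0.498),
        (0.780, 0.780, 0.780), (0.737, 0.741, 0.133), (0.858, 0.858, 0.553),
        (0.090, 0.745, 0.811), (0.619, 0.854, 0.898),
    ]
)


def threshold_masks(cmap: np.ndarray, thr: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Foreground (``map >= thr``) and background masks partitioning the map.

    ``thr=None`` picks Otsu's threshold on the map (0 for a constant
    map); low-intensity background pixels are what the background mask
    zeroes out before colorization.
    """
    cmap = np.asarray(cmap)
    if np.any(cmap < 0):
        raise ValueError("component maps must be nonnegative")
    if thr is None:
        from skimage.filters import threshold_otsu

        thr = 0.0 if np.ptp(cmap) == 0 else float(threshold_otsu(cmap))
    if thr < 0:
        raise ValueError("threshold must be nonnegative")
    fg = cmap >= thr
    return fg, ~fg


def colorize(
    cmap: np.ndarray,
    fg_mask: np.ndarray,
    cv: ColorVector | Sequence[float],
    scale: float = 255.0,
    normalize: bool = True,
) -> np.ndarray:
    """Scale foreground map intensities by a color vector into an RGB layer.

    With ``normalize`` the map is first divided by its own maximum so
    layer intensities land in [0, scale]; background pixels are zero in
    every channel.
    """
    cv = ColorVector(*cv).validate()
    cmap = np.asarray(cmap, dtype=np.float64)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    if fg_mask.shape != cmap.shape:
        raise ValueError("mask/map shape mismatch")
    vals = cmap * fg_mask
    if normalize:
        vmax = vals.max()
        if vmax > 0:
            vals = vals / vmax
    out = np.zeros(cmap.shape + (3,), dtype=np.float64)
    for c in range(3):
        out[..., c] = scale * vals * cv[c]
    return out


def compose(layers: Sequence[np.ndarray], clamp_warn_frac: float = 0.01) -> np.ndarray:
    """Add RGB float layers, clamp at 255 and cast to 8-bit.

    Addition commutes, so the composite is order-invariant. A warning is
    emitted when more than ``clamp_warn_frac`` of pixels clamp in some
    channel (a saturated composite loses contrast).
    """
    if not len(layers):
        raise ValueError("no layers")
    shape = np.asarray(layers[0]).shape
    total = np.zeros(shape, dtype=np.float64)
    for layer in layers:
        arr = np.asarray(layer, dtype=np.float64)
        if arr.shape != shape:
            raise ValueError("layer shape mismatch")
        total += arr
    clipped_pixels = np.any(total > 255.0, axis=-1) if total.ndim == 3 else total > 255.0
    frac = float(clipped_pixels.mean())
    if frac > clamp_warn_frac:
        log.warning("compose: %.1f%% of pixels clamped at 255; composite may be saturated", 100 * frac)
    return np.clip(total, 0.0, 255.0).astype(np.uint8)


def composite_image(
    maps: np.ndarray,
    components: Sequence[int],
    palette: Sequence[ColorVector | Sequence[float]] | None = None,
    thr: float | None = None,
    scale: float = 255.0,
) -> np.ndarray:
    """Convenience wrapper: threshold, colorize and compose chosen components.

    ``maps`` is an (H, W, m) cube; each selected component gets the
    corresponding palette entry (default palette cycles if needed).
    """
    maps = np.asarray(maps)
    if palette is None:
        palette = DEFAULT_PALETTE
    layers = []
    for i, j in enumerate(components):
        cmap = maps[:, :, j]
        fg, _bg = threshold_masks(cmap, thr)
        layers.append(colorize(cmap, fg, palette[i % len(palette)], scale=scale))
    return compose(layers)
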