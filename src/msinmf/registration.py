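"""H&E-to-component-map registration via color segmentation and ECC.

Histology images and MSI component maps come from different instruments
and differ in scale and perspective. The alignment pipeline is:

1. down-sample the RGB histology image to the component-map size,
2. segment an anatomical structure by color: per-channel mean/sd over a
   small ROI (after outlier removal), thresholded at mean ± 2 sd,
3. Canny edge maps of both the segment mask and the component map,
4. iteratively optimize a 3×3 homography maximizing the enhanced
   correlation coefficient (ECC) between the edge maps, keeping the
   best-scoring (map, segment) pair.

The ECC objective is the zero-mean normalized correlation between the
fixed image and the warped moving image, so it is invariant to affine
intensity rescaling of either input. The optimizer is the standard
forward-additive Gauss-Newton ECC iteration run coarse-to-fine over a
Gaussian scale-space schedule; edge maps are smoothed so the objective
is differentiable.

Convention: ``WarpResult.warp`` maps *moving-image* coordinates (x, y,
homogeneous) to *fixed-image* coordinates; :func:`apply_warp` resamples a
moving image onto the fixed frame accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage


@dataclass
class ColorStats:
    """Per-channel ROI color statistics (after outlier removal)."""

    mean: np.ndarray  # (3,) R, G, B
    sd: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.sd = np.asarray(self.sd, dtype=float).reshape(3)
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be nonnegative")


@dataclass
class WarpResult:
    """A homography (moving → fixed) with its attained ECC score."""

    warp: np.ndarray  # 3x3, bottom-right element 1
    ecc: float
    converged: bool = True
    fixed_id: object = None
    moving_id: object = None

    def __post_init__(self) -> None:
        self.warp = np.asarray(self.warp, dtype=float).reshape(3, 3)


def downsample_to(img: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Area-interpolated resize to exactly ``target_shape`` (rows, cols).

    Integer decimation factors use an exact block mean; other ratios fall
    back to anti-aliased resampling. Upsampling requests are an error.
    """
    th, tw = target_shape
    h, w = img.shape[:2]
    if th > h or tw > w:
        raise ValueError("downsample_to cannot upsample")
    if th <= 0 or tw <= 0:
        raise ValueError("target shape must be positive")
    arr = np.asarray(img)
    orig_dtype = arr.dtype
    if h % th == 0 and w % tw == 0:
        fy, fx = h // th, w // tw
        if arr.ndim == 2:
            out = arr.reshape(th, fy, tw, fx).astype(np.float64).mean(axis=(1, 3))
        else:
            out = arr.reshape(th, fy, tw, fx, arr.shape[2]).astype(np.float64).mean(axis=(1, 3))
    else:
        from skimage.transform import resize

        out_shape = (th, tw) if arr.ndim == 2 else (th, tw, arr.shape[2])
        out = resize(arr.astype(np.float64), out_shape, anti_aliasing=True, preserve_range=True)
    if np.issubdtype(orig_dtype, np.integer):
        return np.clip(np.rint(out), np.iinfo(orig_dtype).min, np.iinfo(orig_dtype).max).astype(orig_dtype)
    return out.astype(orig_dtype)


def roi_color_stats(img: np.ndarray, center: tuple[int, int], roi_size: int = 8) -> ColorStats:
    """Mean/sd per color channel over an ROI centered at ``center=(x, y)``.

    Outliers are removed per channel before computing the statistics:
    pixels farther than 3 scaled MADs (median absolute deviation,
    consistency factor 1.4826) from the channel median are dropped. For a
    degenerate ROI (MAD 0) only pixels equal to the median survive, which
    discards lone extreme pixels while keeping a uniform ROI intact.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    x, y = int(center[0]), int(center[1])
    half = roi_size // 2
    x0, y0 = x - half, y - half
    if x0 < 0 or y0 < 0 or x0 + roi_size > img.shape[1] or y0 + roi_size > img.shape[0]:
        raise ValueError("ROI extends outside the image")
    roi = img[y0 : y0 + roi_size, x0 : x0 + roi_size].reshape(-1, 3).astype(np.float64)
    mean = np.empty(3)
    sd = np.empty(3)
    for c in range(3):
        vals = roi[:, c]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        keep = np.abs(vals - med) <= 3.0 * 1.4826 * mad
        kept = vals[keep]
        mean[c] = kept.mean()
        sd[c] = kept.std()
    return ColorStats(mean=mean, sd=sd)


def segment_by_color(img: np.ndarray, stats: ColorStats) -> np.ndarray:
    """Mask of pixels within mean ± 2 sd in all three color channels."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    lo = stats.mean - 2.0 * stats.sd
    hi = stats.mean + 2.0 * stats.sd
    return np.all((img >= lo) & (img <= hi), axis=2)


def detect_edges(
    img: np.ndarray, low_thr: float = 50.0, high_thr: float = 150.0, sigma: float = 1.0
) -> np.ndarray:
    """Canny edge map with hysteresis thresholds on the 8-bit scale.

    Grayscale inputs only: component maps are used directly (rescaled to
    0–255 by their max), boolean masks as 0/255. Returns a boolean map.
    """
    from skimage.feature import canny

    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError("detect_edges expects a 2D grayscale image or mask")
    if arr.dtype == bool:
        arr = arr.astype(np.float64) * 255.0
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64)
    else:  # float component map: rescale to the 8-bit range by its max
        arr = arr.astype(np.float64)
        amax = arr.max()
        if amax > 0:
            arr = arr * (255.0 / amax)
    return canny(arr, sigma=sigma, low_threshold=low_thr, high_threshold=high_thr)


def _as_float_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.dtype == bool:
        return arr.astype(np.float64)
    arr = arr.astype(np.float64)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr


_H_IDX = [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2), (2, 0), (2, 1)]


def _ecc_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    W: np.ndarray,
    max_iters: int,
    eps: float,
    motion: str,
) -> tuple[np.ndarray, float, bool]:
    """One pyramid level of forward-additive ECC maximization.

    ``W`` maps fixed-image coordinates into the moving image; the eight
    homography entries (six for affine) are updated additively from the
    Gauss-Newton system of the ECC objective.
    """
    B, A = fixed.shape
    ys, xs = np.mgrid[0:B, 0:A]
    x = xs.ravel().astype(np.float64)
    y = ys.ravel().astype(np.float64)
    t_full = fixed.ravel()
    gy_m, gx_m = np.gradient(moving)
    param_idx = _H_IDX[:6] if motion == "affine" else _H_IDX
    n_par = len(param_idx)
    ecc_prev = -np.inf
    ecc = -1.0
    converged = False
    W = W.copy()
    for _ in range(max_iters):
        den = W[2, 0] * x + W[2, 1] * y + W[2, 2]
        ok = np.abs(den) > 1e-9
        xw = np.where(ok, (W[0, 0] * x + W[0, 1] * y + W[0, 2]) / np.where(ok, den, 1.0), -1.0)
        yw = np.where(ok, (W[1, 0] * x + W[1, 1] * y + W[1, 2]) / np.where(ok, den, 1.0), -1.0)
        valid = ok & (xw >= 0) & (xw <= A - 1) & (yw >= 0) & (yw <= B - 1)
        if valid.sum() < max(32, 2 * n_par):
            return W, -1.0, False
        coords = [yw[valid], xw[valid]]
        iw = ndimage.map_coordinates(moving, coords, order=1, mode="constant")
        gx = ndimage.map_coordinates(gx_m, coords, order=1, mode="constant")
        gy = ndimage.map_coordinates(gy_m, coords, order=1, mode="constant")
        xv, yv, dv = x[valid], y[valid], den[valid]
        xwv, ywv = xw[valid], yw[valid]
        t = t_full[valid] - t_full[valid].mean()
        i0 = iw - iw.mean()
        nt, ni = np.linalg.norm(t), np.linalg.norm(i0)
        if nt < 1e-12 or ni < 1e-12:
            return W, 0.0, False
        ecc = float(t @ i0 / (nt * ni))
        if abs(ecc - ecc_prev) < eps:
            converged = True
            break
        ecc_prev = ecc
        gxd, gyd = gx / dv, gy / dv
        cols = {
            (0, 0): gxd * xv,
            (0, 1): gxd * yv,
            (0, 2): gxd,
            (1, 0): gyd * xv,
            (1, 1): gyd * yv,
            (1, 2): gyd,
            (2, 0): -(gx * xwv + gy * ywv) / dv * xv,
            (2, 1): -(gx * xwv + gy * ywv) / dv * yv,
        }
        G = np.column_stack([cols[idx] for idx in param_idx])
        H = G.T @ G
        H += np.eye(n_par) * (1e-12 * max(np.trace(H), 1e-12))
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return W, ecc, False
        Gi = G.T @ i0
        Gt = G.T @ t
        HGi = Hinv @ Gi
        lam_num = ni**2 - Gi @ HGi
        lam_den = float(t @ i0) - Gt @ HGi
        if lam_den <= 0:
            # images insufficiently correlated for the ECC update
            return W, ecc, False
        lam = lam_num / lam_den
        err = lam * t - i0
        dp = Hinv @ (G.T @ err)
        for k, (r, c) in enumerate(param_idx):
            W[r, c] += dp[k]
    return W, ecc, converged


def align_ecc(
    fixed: np.ndarray,
    moving: np.ndarray,
    motion: str = "homography",
    max_iters: int = 500,
    eps: float = 1e-6,
    levels: int = 3,
    smooth_sigma: float = 1.0,
    init: np.ndarray | None = None,
    fixed_id=None,
    moving_id=None,
) -> WarpResult:
    """Homography maximizing the ECC between ``fixed`` and warped ``moving``.

    Runs a coarse-to-fine scale-space schedule: ``levels`` stages of
    Gauss-Newton iterations (up to ``max_iters`` each) on progressively
    less-smoothed images, ending at ``smooth_sigma`` (some smoothing is
    essential for binary edge maps). Full resolution is kept at every
    stage — on the small rasters involved that is cheaper and more
    robust than decimation. Non-convergence returns the last iterate
    flagged ``converged=False`` with its ECC, so callers can still
    compare scores.
    """
    if motion not in ("homography", "affine"):
        raise ValueError("motion must be 'homography' or 'affine'")
    f0 = _as_float_image(fixed)
    m0 = _as_float_image(moving)
    if f0.shape != m0.shape:
        raise ValueError("fixed and moving must share a shape")
    # internal warp maps fixed coords -> moving coords
    Wm = np.eye(3) if init is None else np.linalg.inv(np.asarray(init, dtype=float))
    Wm = Wm / Wm[2, 2]
    converged = False
    ecc = -1.0
    for lvl in range(levels - 1, -1, -1):
        sigma = smooth_sigma * (2.0**lvl)
        fs = ndimage.gaussian_filter(f0, sigma)
        ms = ndimage.gaussian_filter(m0, sigma)
        Wm, ecc, converged = _ecc_level(fs, ms, Wm, max_iters, eps, motion)
    Wm = Wm / Wm[2, 2]
    warp = np.linalg.inv(Wm)
    warp = warp / warp[2, 2]
    return WarpResult(warp=warp, ecc=ecc, converged=converged, fixed_id=fixed_id, moving_id=moving_id)


def best_alignment(
    nmf_maps: Sequence[np.ndarray],
    segments: Sequence[np.ndarray],
    low_thr: float = 50.0,
    high_thr: float = 150.0,
    canny_sigma: float = 1.0,
    **ecc_kwargs,
) -> WarpResult:
    """Highest-ECC alignment over all (component map, segment) pairs.

    Both inputs are reduced to Canny edge maps before alignment. Flagged
    (non-converged) results still compete on their recorded score; ties
    break toward the lexicographically lower (map index, segment index).
    """
    if not len(nmf_maps) or not len(segments):
        raise ValueError("need at least one map and one segment")
    best: WarpResult | None = None
    for i, cmap in enumerate(nmf_maps):
        fe = detect_edges(np.asarray(cmap), low_thr, high_thr, sigma=canny_sigma)
        for k, seg in enumerate(segments):
            me = detect_edges(np.asarray(seg), low_thr, high_thr, sigma=canny_sigma)
            res = align_ecc(fe, me, fixed_id=i, moving_id=k, **ecc_kwargs)
            if not np.isfinite(res.ecc):
                continue
            if best is None or res.ecc > best.ecc:
                best = res
    if best is None:
        raise RuntimeError("all alignment pairs failed")
    return best


def apply_warp(
    img: np.ndarray, warp: np.ndarray, output_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Resample ``img`` onto the fixed frame under a moving→fixed warp.

    Bilinear interpolation; out-of-frame pixels are zero-filled. A
    (near-)singular warp is an error.
    """
    from skimage.transform import ProjectiveTransform, warp as sk_warp

    warp = np.asarray(warp, dtype=float).reshape(3, 3)
    det = np.linalg.det(warp)
    if not np.isfinite(det) or abs(det) < 1e-12:
        raise ValueError("singular warp matrix")
    arr = np.asarray(img)
    orig_dtype = arr.dtype
    tform = ProjectiveTransform(matrix=np.linalg.inv(warp))
    out = sk_warp(
        arr.astype(np.float64),
        inverse_map=tform,
        output_shape=output_shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    if np.issubdtype(orig_dtype, np.integer):
        return np.clip(np.rint(out), np.iinfo(orig_dtype).min, np.iinfo(orig_dtype).max).astype(orig_dtype)
    return out.astype(orig_dtype)
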