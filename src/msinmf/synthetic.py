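"""Synthetic MSI phantom cohorts with full ground truth.

The phantom emulates the study design the pipeline targets: a cohort of
D = 8 datasets in two classes (4 "CPH", 4 "naive") of intentionally
unequal raster sizes, each pixel carrying a sparse centroided lipid-range
spectrum composed from planted nonnegative spectral components on
"swiss-roll"-like spatial templates:

* concentric annuli (rolled-tissue rings),
* Gaussian blobs at fixed polar positions (focal structures),
* one diffuse component spread across the whole tissue disk,
* one off-tissue/matrix component occupying the area outside the tissue
  disk.

The two classes differ ONLY through designated discriminative
component(s), whose abundance is multiplied by ``effect`` in the CPH
class. The default discriminative component is the diffuse one: TIC
normalization keeps only compositional information, so a class effect is
detectable exactly where the shifted component shares pixels with others
— a diffuse marker changes the composition of every tissue pixel,
matching the working assumption that class-separating compounds are
distributed throughout the tissue. Template geometry is identical across datasets up to a small
per-dataset amplitude jitter, so under a null effect no component carries
class information. Noise: Poisson counts on the planted peak intensities,
sparse uniform background peaks across the full acquisition range, and a
multiplicative per-pixel TIC jitter (which TIC normalization must undo).

Matched H&E-like RGB images are rendered at higher resolution from the
same templates (one distinct color per dominant component) and distorted
by a known small homography, supporting end-to-end registration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .composite import DEFAULT_PALETTE
from .msi_io import BinGrid, MSIDataset

GOLDEN_ANGLE = 2.399963229728653


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for the phantom cohort.

    Defaults give 8 datasets (4 CPH / 4 naive) of 36-48 px per side,
    20 planted components (6 annuli + 12 blobs + 1 diffuse + 1 matrix),
    ~8000 counts per pixel, and a x1.8 abundance shift of the diffuse
    component (index 18) in the CPH class.
    """

    n_datasets: int = 8
    n_cph: int = 4
    shapes: tuple[tuple[int, int], ...] = (
        (48, 48), (48, 40), (40, 48), (40, 40), (44, 36), (36, 44), (40, 36), (36, 40),
    )  # (width A, height B) per dataset
    m_true: int = 20
    n_rings: int = 6
    mz_min: float = 600.0
    mz_max: float = 2000.0
    signal_mz_max: float = 1100.0
    peaks_per_component: int = 8
    n_shared_peaks: int = 2
    shared_pool_size: int = 12
    amp_jitter: float = 0.05
    effect: float = 1.8
    discriminative: tuple[int, ...] | None = None  # default: the diffuse component
    counts_per_pixel: float = 8000.0
    background_peaks: int = 12
    background_mean: float = 1.0
    tic_jitter: float = 0.2
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets != len(self.shapes):
            raise ValueError("need one shape per dataset")
        if not 0 < self.n_cph < self.n_datasets:
            raise ValueError("n_cph must leave both classes non-empty")
        if self.m_true < self.n_rings + 3:
            raise ValueError("m_true too small for the template layout")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if self.discriminative is None:
            object.__setattr__(self, "discriminative", (self.diffuse_component,))
        if any(j < 0 or j >= self.m_true for j in self.discriminative):
            raise ValueError("discriminative component index out of range")

    @property
    def diffuse_component(self) -> int:
        return self.m_true - 2

    @property
    def matrix_component(self) -> int:
        return self.m_true - 1

    @property
    def dataset_ids(self) -> tuple[str, ...]:
        return tuple(f"ds{i}" for i in range(self.n_datasets))

    @property
    def class_of(self) -> dict[str, str]:
        return {
            did: ("CPH" if i < self.n_cph else "naive")
            for i, did in enumerate(self.dataset_ids)
        }


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    peak_mzs: list[np.ndarray]  # per component, sorted m/z positions
    peak_heights: list[np.ndarray]  # matching heights, L1-normalized
    z: dict[str, np.ndarray]  # dataset_id -> (H, W, m_true) spatial loadings
    class_labels: dict[str, str]
    disk_masks: dict[str, np.ndarray]  # biological tissue disk (excl. matrix area)
    region_labels: dict[str, np.ndarray]  # dominant component per pixel, -1 = none
    discriminative: tuple[int, ...]
    palette: np.ndarray  # (m_true, 3) colors used for the H&E-like render
    hne_warps: dict[str, np.ndarray] = field(default_factory=dict)  # moving->fixed, map scale

    @property
    def m_true(self) -> int:
        return len(self.peak_mzs)

    def binned_psi(self, grid: BinGrid) -> np.ndarray:
        """Planted spectral templates rasterized onto a bin grid (max rule)."""
        psi = np.zeros((self.m_true, grid.M))
        edges = grid.edges
        for j in range(self.m_true):
            idx = np.searchsorted(edges, self.peak_mzs[j], side="right") - 1
            ok = (idx >= 0) & (idx < grid.M) & (self.peak_mzs[j] >= edges[0])
            np.maximum.at(psi[j], idx[ok], self.peak_heights[j][ok])
        return psi

    def tissue_masks(self) -> dict[str, np.ndarray]:
        """Acquisition tissue masks: every pixel records signal (matrix incl.)."""
        return {did: np.ones(z.shape[:2], dtype=bool) for did, z in self.z.items()}

    def normalized_z(self) -> dict[str, np.ndarray]:
        """Compositional loadings: each pixel's loadings divided by their sum.

        This is the noise-free analogue of the spatial maps the pipeline
        estimates from TIC-normalized spectra (spectral templates are
        L1-normalized, so a pixel's total intensity equals its loading
        sum). Abundance effects appear here only as compositional shifts,
        exactly as they do downstream of TIC normalization.
        """
        out: dict[str, np.ndarray] = {}
        for did, zd in self.z.items():
            tot = zd.sum(axis=2, keepdims=True)
            out[did] = np.divide(zd, tot, out=np.zeros_like(zd), where=tot > 0)
        return out


def _spectral_templates(cfg: PhantomConfig, rng: np.random.Generator) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Sparse peak sets per component: mostly unique peaks plus a shared pool."""
    n_unique = cfg.peaks_per_component - cfg.n_shared_peaks
    n_positions = cfg.m_true * n_unique + cfg.shared_pool_size
    lo, hi = cfg.mz_min + 1.0, cfg.signal_mz_max - 1.0
    grid_positions = np.arange(lo, hi, 0.35)
    if len(grid_positions) < n_positions:
        raise ValueError("signal m/z range too narrow for the requested peak count")
    chosen = rng.choice(len(grid_positions), size=n_positions, replace=False)
    positions = grid_positions[chosen] + rng.uniform(0.0, 0.04, size=n_positions)
    shared = positions[:cfg.shared_pool_size]
    unique = positions[cfg.shared_pool_size:].reshape(cfg.m_true, n_unique)
    mzs, heights = [], []
    for j in range(cfg.m_true):
        pool_pick = rng.choice(cfg.shared_pool_size, size=cfg.n_shared_peaks, replace=False)
        mz = np.concatenate([unique[j], shared[pool_pick]])
        h = rng.uniform(0.3, 1.0, size=len(mz))
        h[n_unique:] *= 0.2  # shared peaks are minor so templates stay distinct
        order = np.argsort(mz)
        mz, h = mz[order], h[order]
        h = h / h.sum()  # L1-normalized so loadings carry the abundance scale
        mzs.append(mz)
        heights.append(h)
    return mzs, heights


def _spatial_templates(cfg: PhantomConfig, width: int, height: int, supersample: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude spatial templates on a (height*s, width*s) raster.

    Returns (templates (H, W, m_true), disk mask). Geometry is expressed
    in map-scale units so supersampled rasters stay aligned with the
    base raster.
    """
    s = supersample
    H, W = height * s, width * s
    yy, xx = np.mgrid[0:H, 0:W]
    # pixel centers in map units
    x = (xx + 0.5) / s - 0.5
    y = (yy + 0.5) / s - 0.5
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    R = 0.46 * min(width, height)
    r = np.hypot(x - cx, y - cy)
    disk = r <= R
    m = cfg.m_true
    z = np.zeros((H, W, m))
    # annuli kept away from the center (the rolled tissue leaves a core);
    # sigma chosen so neighboring rings stay well separated
    ring_sigma = 0.40 * R / cfg.n_rings
    for j in range(cfg.n_rings):
        rho = (0.15 + 0.75 * j / max(cfg.n_rings - 1, 1)) * R
        z[:, :, j] = np.exp(-0.5 * ((r - rho) / ring_sigma) ** 2) * disk
    n_blobs = m - cfg.n_rings - 2
    blob_sigma = 0.14 * R
    for k in range(n_blobs):
        j = cfg.n_rings + k
        # sunflower packing in the 0.25R-0.9R annulus keeps blobs apart
        rad = R * np.sqrt(0.25**2 + (0.9**2 - 0.25**2) * (k + 0.5) / n_blobs)
        ang = k * GOLDEN_ANGLE
        bx, by = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
        z[:, :, j] = np.exp(-0.5 * (((x - bx) ** 2 + (y - by) ** 2) / blob_sigma**2)) * disk
    # diffuse tissue-wide component (the default class marker)
    z[:, :, m - 2] = 0.35 * np.exp(-0.5 * (r / (0.9 * R)) ** 2) * disk
    z[:, :, m - 1] = 0.6 * (~disk)  # off-tissue / matrix component
    return z, disk


def make_ground_truth(cfg: PhantomConfig) -> GroundTruth:
    """Build the planted components and per-dataset loadings (no spectra).

    Cheap relative to :func:`make_cohort`; useful when only the ground
    truth maps are needed (e.g. ranking studies across many seeds).
    """
    master = np.random.SeedSequence(cfg.seed)
    rng_spec, rng_amp = [np.random.default_rng(s) for s in master.spawn(2)]
    mzs, heights = _spectral_templates(cfg, rng_spec)
    z: dict[str, np.ndarray] = {}
    disks: dict[str, np.ndarray] = {}
    regions: dict[str, np.ndarray] = {}
    class_of = cfg.class_of
    for i, did in enumerate(cfg.dataset_ids):
        wd, ht = cfg.shapes[i]
        templates, disk = _spatial_templates(cfg, wd, ht)
        if not disk.any():
            raise ValueError("zero-area tissue disk")
        amps = rng_amp.uniform(1.0 - cfg.amp_jitter, 1.0 + cfg.amp_jitter, size=cfg.m_true)
        if class_of[did] == "CPH":
            for j in cfg.discriminative:
                amps[j] *= cfg.effect
        zd = templates * amps
        z[did] = zd
        disks[did] = disk
        regions[did] = _region_labels(zd)
    palette = np.array([tuple(DEFAULT_PALETTE[j % len(DEFAULT_PALETTE)]) for j in range(cfg.m_true)])
    return GroundTruth(
        peak_mzs=mzs,
        peak_heights=heights,
        z=z,
        class_labels=dict(class_of),
        disk_masks=disks,
        region_labels=regions,
        discriminative=tuple(cfg.discriminative),
        palette=palette,
    )


def _region_labels(z: np.ndarray, min_intensity: float = 0.05) -> np.ndarray:
    lab = np.argmax(z, axis=2).astype(int)
    lab[z.max(axis=2) < min_intensity] = -1
    return lab


def make_cohort(cfg: PhantomConfig) -> tuple[list[MSIDataset], GroundTruth]:
    """Generate the phantom cohort as sparse centroided spectra.

    Per pixel: planted peak intensities ``z @ psi`` scaled to
    ``counts_per_pixel`` mean TIC, Poisson-sampled, plus sparse
    exponential background peaks across the full m/z range, all modulated
    by the per-pixel TIC jitter. Bit-reproducible under ``cfg.seed``.
    """
    gt = make_ground_truth(cfg)
    master = np.random.SeedSequence([cfg.seed, 1])
    streams = master.spawn(cfg.n_datasets)
    all_mz = np.concatenate(gt.peak_mzs)
    comp_of_peak = np.concatenate([np.full(len(m), j) for j, m in enumerate(gt.peak_mzs)])
    height_of_peak = np.concatenate(gt.peak_heights)
    order = np.argsort(all_mz)
    all_mz, comp_of_peak, height_of_peak = all_mz[order], comp_of_peak[order], height_of_peak[order]
    # (m_true, n_peaks) dense peak-height matrix
    Hmat = np.zeros((cfg.m_true, len(all_mz)))
    Hmat[comp_of_peak, np.arange(len(all_mz))] = height_of_peak

    datasets: list[MSIDataset] = []
    for i, did in enumerate(cfg.dataset_ids):
        rng = np.random.default_rng(streams[i])
        zd = gt.z[did]
        ht, wd = zd.shape[:2]
        zflat = zd.reshape(-1, cfg.m_true)
        sig = zflat @ Hmat  # (n_px, n_peaks) expected intensities
        tot = sig.sum(axis=1)
        mean_tot = tot[tot > 0].mean()
        sig *= cfg.counts_per_pixel / mean_tot
        if cfg.poisson:
            sig = rng.poisson(sig).astype(np.float64)
        n_px = zflat.shape[0]
        bg_mz = rng.uniform(cfg.mz_min, cfg.mz_max, size=(n_px, cfg.background_peaks))
        bg_int = rng.exponential(cfg.background_mean, size=(n_px, cfg.background_peaks))
        jitter = rng.uniform(1.0 - cfg.tic_jitter, 1.0 + cfg.tic_jitter, size=n_px)
        coords = []
        mzs_out: list[np.ndarray] = []
        ints_out: list[np.ndarray] = []
        for p in range(n_px):
            y, x = divmod(p, wd)
            mz = np.concatenate([all_mz, bg_mz[p]])
            inten = np.concatenate([sig[p], bg_int[p]]) * jitter[p]
            keep = inten > 0
            mz, inten = mz[keep], inten[keep]
            o = np.argsort(mz)
            coords.append((x, y))
            mzs_out.append(mz[o])
            ints_out.append(inten[o])
        datasets.append(
            MSIDataset(
                dataset_id=did,
                class_label=gt.class_labels[did],
                coords=np.asarray(coords, dtype=np.int64),
                mzs=mzs_out,
                intensities=ints_out,
                width=wd,
                height=ht,
            )
        )
    return datasets, gt


def make_hne_like(
    cfg: PhantomConfig,
    gt: GroundTruth,
    scale: int = 4,
    max_corner_frac: float = 0.05,
    noise_sd: float = 4.0,
    seed: int | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Render per-dataset H&E-like RGB images with a planted homography.

    Regions (dominant component per pixel) are painted in distinct palette
    colors at ``scale``× the map resolution, lightly noised, then warped
    by a random homography whose corner displacements stay within
    ``max_corner_frac`` of the map width. Returns
    ``{dataset_id: (image uint8, warp)}`` where ``warp`` maps the
    distorted image's coordinates to map coordinates (at map scale); the
    warps are also recorded on ``gt.hne_warps``.
    """
    from skimage.transform import ProjectiveTransform, warp as sk_warp

    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    background = np.array([245.0, 240.0, 245.0])
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i, did in enumerate(cfg.dataset_ids):
        wd, ht = cfg.shapes[i]
        templates, _disk = _spatial_templates(cfg, wd, ht, supersample=scale)
        regions = _region_labels(templates)
        img = np.empty(regions.shape + (3,), dtype=np.float64)
        img[:] = background
        for j in range(cfg.m_true):
            img[regions == j] = 255.0 * gt.palette[j]
        # bounded texture noise: stays within the mean +- 2 sd color gate
        img += rng.uniform(-noise_sd, noise_sd, size=img.shape)
        img = np.clip(img, 0, 255)

        corners = np.array([[0, 0], [wd - 1.0, 0], [wd - 1.0, ht - 1.0], [0, ht - 1.0]])
        if max_corner_frac > 0:
            perturbed = corners + rng.uniform(-max_corner_frac, max_corner_frac, size=(4, 2)) * wd
        else:
            perturbed = corners.copy()
        if hasattr(ProjectiveTransform, "from_estimate"):
            tform = ProjectiveTransform.from_estimate(src=perturbed, dst=corners)
            if not tform:
                raise RuntimeError("homography estimation failed")
        else:  # older scikit-image
            tform = ProjectiveTransform()
            if not tform.estimate(src=perturbed, dst=corners):
                raise RuntimeError("homography estimation failed")
        T = tform.params / tform.params[2, 2]  # moving -> fixed, map scale
        S = np.diag([float(scale), float(scale), 1.0])
        T_hi = S @ T @ np.linalg.inv(S)
        warped = np.stack(
            [
                sk_warp(
                    img[:, :, c],
                    inverse_map=ProjectiveTransform(matrix=T_hi),
                    order=1,
                    mode="constant",
                    cval=background[c],
                    preserve_range=True,
                )
                for c in range(3)
            ],
            axis=2,
        )
        image = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
        gt.hne_warps[did] = T
        out[did] = (image, T)
    return out
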