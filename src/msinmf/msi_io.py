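"""imzML input/output and spectral preprocessing for MSI cohorts.

An MSI dataset is a raster of pixels, each carrying a centroided mass
spectrum (lists of (m/z, intensity) pairs). Preprocessing turns the ragged
per-pixel peak lists into a dense, uniformly binned cube:

1. binning onto a fixed m/z grid (max peak intensity per bin),
2. truncation of the sparse high-mass tail,
3. per-pixel total-ion-current (TIC) normalization so every on-tissue
   spectrum sums to 1.

Pixel coordinates are 0-based with x = column and y = row; rasterized
arrays are row-major ``(y, x)``, so a binned cube has shape
``(height, width, M)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

log = logging.getLogger(__name__)

CLASS_LABELS = ("CPH", "naive", "unlabeled")

_COHORT_FORMAT_VERSION = "1"


@dataclass
class MSIDataset:
    """One tissue sample's pixel-indexed centroided spectra.

    ``coords`` is an ``(n, 2)`` integer array of (x, y) pixel locations;
    ``mzs[i]`` / ``intensities[i]`` hold the peaks recorded at
    ``coords[i]``. ``width`` and ``height`` are the raster extents
    (A^d and B^d).
    """

    dataset_id: str
    class_label: str
    coords: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}")
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        n = len(self.coords)
        if len(self.mzs) != n or len(self.intensities) != n:
            raise ValueError("coords, mzs and intensities must have equal length")
        if n and len(np.unique(self.coords, axis=0)) != n:
            raise ValueError("duplicate pixel coordinates")
        for i in range(n):
            if len(self.mzs[i]) != len(self.intensities[i]):
                raise ValueError(f"spectrum {i}: mz/intensity length mismatch")
            if len(self.intensities[i]) and np.min(self.intensities[i]) < 0:
                raise ValueError(f"spectrum {i}: negative intensity")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class BinGrid:
    """Uniform m/z binning grid over ``[mz_min, mz_max)``.

    Bin ``s`` spans the half-open interval
    ``[mz_min + s*bin_width, mz_min + (s+1)*bin_width)``.
    """

    mz_min: float
    mz_max: float
    bin_width: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.mz_max <= self.mz_min:
            raise ValueError("mz_max must exceed mz_min")

    @property
    def M(self) -> int:
        return int(round((self.mz_max - self.mz_min) / self.bin_width))

    @property
    def edges(self) -> np.ndarray:
        """The ``M + 1`` bin edges, ``edges[s] = mz_min + s*bin_width``."""
        return self.mz_min + np.arange(self.M + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return self.mz_min + (np.arange(self.M) + 0.5) * self.bin_width


@dataclass
class BinnedDataset:
    """Dense binned intensity cube for one dataset.

    ``cube`` has shape ``(height, width, M)`` (row-major y, x, bin) and is
    nonnegative everywhere. ``tissue_mask`` is True exactly where a pixel's
    total intensity is positive.
    """

    dataset_id: str
    class_label: str
    grid: BinGrid
    cube: np.ndarray
    tissue_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.cube.ndim != 3:
            raise ValueError("cube must be (height, width, M)")
        if self.cube.shape[2] != self.grid.M:
            raise ValueError("cube depth does not match grid.M")
        if self.tissue_mask.shape != self.cube.shape[:2]:
            raise ValueError("tissue_mask shape mismatch")

    @property
    def width(self) -> int:
        return self.cube.shape[1]

    @property
    def height(self) -> int:
        return self.cube.shape[0]


def load_imzml(path: str | Path) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    imzML stores 1-based coordinates; they are shifted to 0-based here.
    The raster extents are the coordinate bounding box. A non-monotone
    m/z axis within any spectrum is rejected.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if b"<spectrum " not in path.read_bytes():  # zero-spectra file; parser can't cope
        return MSIDataset(path.stem, "unlabeled", np.zeros((0, 2), np.int64), [], [], 0, 0)
    parser = ImzMLParser(str(path))
    coords = []
    mzs: list[np.ndarray] = []
    intensities: list[np.ndarray] = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        if len(mz) > 1 and np.any(np.diff(mz) < 0):
            raise ValueError(f"{path.name}: non-monotone m/z axis in spectrum {i}")
        coords.append((x - 1, y - 1))
        mzs.append(mz)
        intensities.append(inten)
    if hasattr(parser, "m"):  # release the mmap'd ibd handle
        try:
            parser.m.close()
        except Exception:  # pragma: no cover
            pass
    coords_arr = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
    if len(coords_arr):
        width = int(coords_arr[:, 0].max()) + 1
        height = int(coords_arr[:, 1].max()) + 1
    else:
        width = height = 0
    return MSIDataset(
        dataset_id=path.stem,
        class_label="unlabeled",
        coords=coords_arr,
        mzs=mzs,
        intensities=intensities,
        width=width,
        height=height,
    )


def write_imzml(ds: MSIDataset, path: str | Path) -> Path:
    """Write a dataset as a processed-mode imzML/ibd pair.

    Round-trips through :func:`load_imzml` up to float precision
    (m/z float64, intensities float32).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    empty = ds.n_pixels == 0
    with ImzMLWriter(str(path), mode="processed") as writer:
        if empty:
            # the writer cannot render a file with no spectra; emit a
            # placeholder and strip it from the XML below
            writer.addSpectrum(np.array([0.0]), np.array([0.0]), (1, 1, 1))
        for (x, y), mz, inten in zip(ds.coords, ds.mzs, ds.intensities):
            writer.addSpectrum(np.asarray(mz, float), np.asarray(inten, float), (int(x) + 1, int(y) + 1, 1))
    if empty:
        from lxml import etree

        tree = etree.parse(str(path))
        ns = {"m": tree.getroot().nsmap.get(None, "")}
        for run in tree.findall(".//m:spectrumList", ns):
            run.attrib["count"] = "0"
            for spec in run.findall("m:spectrum", ns):
                run.remove(spec)
        tree.write(str(path), xml_declaration=True, encoding="ISO-8859-1")
    return path


def bin_spectra(ds: MSIDataset, grid: BinGrid) -> BinnedDataset:
    """Bin centroided peaks onto ``grid`` using the max-in-bin rule.

    Each bin's intensity is the maximum peak intensity falling inside its
    half-open interval; empty bins are 0. Peaks outside
    ``[mz_min, mz_max)`` are dropped and counted in the log, never an
    error. The result is permutation-invariant in peak order.
    """
    M = grid.M
    edges = grid.edges
    cube = np.zeros((ds.height, ds.width, M), dtype=np.float32)
    dropped = 0
    for (x, y), mz, inten in zip(ds.coords, ds.mzs, ds.intensities):
        if len(mz) == 0:
            continue
        idx = np.searchsorted(edges, mz, side="right") - 1
        inside = (idx >= 0) & (idx < M) & (mz >= edges[0])
        dropped += int(len(mz) - inside.sum())
        np.maximum.at(cube[y, x], idx[inside], inten[inside].astype(np.float32))
    if dropped:
        log.info("bin_spectra(%s): dropped %d peaks outside [%g, %g)", ds.dataset_id, dropped, grid.mz_min, grid.mz_max)
    tissue = cube.sum(axis=2, dtype=np.float64) > 0
    return BinnedDataset(ds.dataset_id, ds.class_label, grid, cube, tissue)


def truncate(bd: BinnedDataset, mz_cut: float) -> BinnedDataset:
    """Drop all bins whose left edge is at or above ``mz_cut``.

    Typical use is cutting the sparse high-mass tail (e.g. at 1100 Da for
    the phospholipid range). ``mz_cut`` must lie in
    ``(mz_min, mz_max]``.
    """
    g = bd.grid
    if mz_cut <= g.mz_min:
        raise ValueError("mz_cut must exceed mz_min (result would be empty)")
    if mz_cut > g.mz_max:
        raise ValueError("mz_cut beyond grid mz_max")
    left_edges = g.edges[:-1]
    M_new = int(np.searchsorted(left_edges, mz_cut, side="left"))
    if M_new == g.M:
        return bd
    new_grid = BinGrid(g.mz_min, g.mz_min + M_new * g.bin_width, g.bin_width)
    cube = np.ascontiguousarray(bd.cube[:, :, :M_new])
    tissue = cube.sum(axis=2, dtype=np.float64) > 0
    return BinnedDataset(bd.dataset_id, bd.class_label, new_grid, cube, tissue)


def tic_normalize(bd: BinnedDataset, dtype=np.float64) -> BinnedDataset:
    """Divide each pixel's spectrum by its total ion current.

    After normalization every tissue pixel's spectrum sums to 1. Pixels
    with zero total intensity are left all-zero and marked off-tissue in
    ``tissue_mask`` rather than raising. ``dtype`` defaults to float64 so
    the per-pixel sums hold to ~1e-15.
    """
    totals = bd.cube.sum(axis=2, dtype=np.float64)
    tissue = totals > 0
    cube = bd.cube.astype(dtype, copy=True)
    safe = np.where(tissue, totals, 1.0)
    cube /= safe[:, :, None].astype(dtype)
    cube[~tissue] = 0
    return BinnedDataset(bd.dataset_id, bd.class_label, bd.grid, cube, tissue)


def save_cohort(cohort: Sequence[BinnedDataset], path: str | Path) -> Path:
    """Persist binned cubes to a versioned HDF5 container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "msinmf-cohort"
        f.attrs["version"] = _COHORT_FORMAT_VERSION
        for i, bd in enumerate(cohort):
            grp = f.create_group(f"{i:03d}")
            grp.attrs["dataset_id"] = bd.dataset_id
            grp.attrs["class_label"] = bd.class_label
            grp.attrs["mz_min"] = bd.grid.mz_min
            grp.attrs["mz_max"] = bd.grid.mz_max
            grp.attrs["bin_width"] = bd.grid.bin_width
            grp.create_dataset("cube", data=bd.cube, compression="gzip", compression_opts=1)
            grp.create_dataset("tissue_mask", data=bd.tissue_mask)
    return path


def load_cohort(path: str | Path) -> list[BinnedDataset]:
    path = Path(path)
    out: list[BinnedDataset] = []
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "msinmf-cohort":
            raise ValueError(f"{path} is not an msinmf cohort container")
        if str(f.attrs.get("version")) != _COHORT_FORMAT_VERSION:
            raise ValueError(f"unsupported cohort container version {f.attrs.get('version')!r}")
        for key in sorted(f.keys()):
            grp = f[key]
            grid = BinGrid(float(grp.attrs["mz_min"]), float(grp.attrs["mz_max"]), float(grp.attrs["bin_width"]))
            out.append(
                BinnedDataset(
                    str(grp.attrs["dataset_id"]),
                    str(grp.attrs["class_label"]),
                    grid,
                    grp["cube"][...],
                    grp["tissue_mask"][...].astype(bool),
                )
            )
    return out


def preprocess(
    ds: MSIDataset,
    grid: BinGrid,
    mz_cut: float | None = None,
    dtype=np.float64,
) -> BinnedDataset:
    """Bin, optionally truncate, and TIC-normalize one dataset."""
    bd = bin_spectra(ds, grid)
    if mz_cut is not None:
        bd = truncate(bd, mz_cut)
    return tic_normalize(bd, dtype=dtype)
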