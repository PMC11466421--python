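"""Cohort stacking, joint NMF (with a PCA baseline) and component ranking.

All tissue pixels of a cohort are stacked row-wise into one nonnegative
matrix ``I`` of shape ``(N, M)`` so that a single factorization
``I ≈ Z Ψ`` learns spectral components Ψ shared across every sample while
the spatial loadings Z remain sample-specific. Components are ranked for
reconstruction by backward elimination: at each step, remove the component
whose absence hurts the reconstruction most.

The normalized reconstruction error used throughout is

    err(keep) = Σ (I − Z_keep Ψ_keep)² / Σ I²

i.e. the residual sum of squares over the data sum of squares, a fraction
in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .msi_io import BinGrid, BinnedDataset

_MODEL_FORMAT_VERSION = "1"


@dataclass
class StackedMatrix:
    """Tissue pixels of a cohort stacked into an ``(N, M)`` matrix.

    ``row_index`` is a DataFrame with columns (dataset_id, x, y) mapping
    every row back to exactly one pixel; ``shapes`` and ``class_labels``
    carry per-dataset raster extents and labels for unstacking.
    """

    matrix: np.ndarray
    row_index: pd.DataFrame
    grid: BinGrid
    shapes: dict[str, tuple[int, int]]  # dataset_id -> (height, width)
    class_labels: dict[str, str]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def D(self) -> int:
        return len(self.shapes)


@dataclass
class NMFFactorization:
    """Joint NMF model: nonnegative Ψ (m, M) and Z (N, m).

    ``order`` is a permutation of components by reconstruction importance
    (identity until :func:`rank_by_reconstruction` is applied);
    ``residual_norm`` is the normalized reconstruction error with all
    components kept.
    """

    m: int
    psi: np.ndarray
    z: np.ndarray
    order: np.ndarray
    residual_norm: float
    n_iter: int = 0
    converged: bool = True


@dataclass
class PCAFactorization:
    m: int
    components: np.ndarray  # (m, M), orthonormal rows
    scores: np.ndarray  # (N, m)
    mean_spectrum: np.ndarray  # (M,)
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.zeros(0))


def stack_cohort(cohort: Sequence[BinnedDataset]) -> StackedMatrix:
    """Flatten each dataset's tissue pixels and stack them in cohort order.

    Only tissue pixels (``tissue_mask`` True) become rows; off-tissue
    pixels are excluded from the factorization entirely. All datasets
    must share one bin grid.
    """
    if not cohort:
        raise ValueError("empty cohort")
    grid = cohort[0].grid
    ids = [bd.dataset_id for bd in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_id in cohort")
    blocks = []
    index_parts = []
    shapes: dict[str, tuple[int, int]] = {}
    labels: dict[str, str] = {}
    for bd in cohort:
        if bd.grid != grid:
            raise ValueError(f"bin grid mismatch for dataset {bd.dataset_id}")
        ys, xs = np.nonzero(bd.tissue_mask)
        blocks.append(bd.cube[ys, xs])
        index_parts.append(pd.DataFrame({"dataset_id": bd.dataset_id, "x": xs, "y": ys}))
        shapes[bd.dataset_id] = (bd.height, bd.width)
        labels[bd.dataset_id] = bd.class_label
    matrix = np.concatenate(blocks, axis=0)
    row_index = pd.concat(index_parts, ignore_index=True)
    return StackedMatrix(matrix, row_index, grid, shapes, labels)


def unstack_maps(S: StackedMatrix, Z: np.ndarray) -> dict[str, np.ndarray]:
    """Scatter stacked per-row loadings back to per-dataset (H, W, m) maps.

    Off-tissue pixels are zero. Exact inverse of the stacking row order.
    """
    Z = np.asarray(Z)
    if Z.shape[0] != S.n_rows:
        raise ValueError("Z row count does not match stacked matrix")
    m = Z.shape[1]
    maps: dict[str, np.ndarray] = {}
    for did, (h, w) in S.shapes.items():
        maps[did] = np.zeros((h, w, m), dtype=Z.dtype)
    dids = S.row_index["dataset_id"].to_numpy()
    xs = S.row_index["x"].to_numpy()
    ys = S.row_index["y"].to_numpy()
    for did in S.shapes:
        sel = dids == did
        maps[did][ys[sel], xs[sel]] = Z[sel]
    return maps


def tissue_masks_from_stack(S: StackedMatrix) -> dict[str, np.ndarray]:
    """Per-dataset boolean masks of the rows present in the stack."""
    masks = {did: np.zeros(shape, dtype=bool) for did, shape in S.shapes.items()}
    dids = S.row_index["dataset_id"].to_numpy()
    xs = S.row_index["x"].to_numpy()
    ys = S.row_index["y"].to_numpy()
    for did in S.shapes:
        sel = dids == did
        masks[did][ys[sel], xs[sel]] = True
    return masks


def fit_nmf(
    S: StackedMatrix,
    m: int,
    max_iter: int = 6000,
    seed: int | None = None,
    tol: float = 1e-4,
    solver_dtype=np.float32,
    init: str = "nndsvda",
) -> NMFFactorization:
    """Fit ``I ≈ Z Ψ`` with nonnegative Z, Ψ minimizing squared error.

    Coordinate-descent (HALS-style) updates on the Frobenius loss.
    Initialization defaults to the deterministic nonnegative-double-SVD
    variant (the library default, and empirically a better optimum than
    random starts on cohort data); ``init="random"`` with a ``seed``
    gives seeded random-uniform starts. Either way the fit is
    deterministic for a given ``(init, seed)``. Non-convergence at
    ``max_iter`` warns and returns the best iterate.

    ``solver_dtype`` controls the working precision inside the solver
    (single by default — standard for factorizations at this scale);
    the reported ``residual_norm`` is always accumulated in float64.
    """
    from sklearn.decomposition import NMF
    from sklearn.exceptions import ConvergenceWarning

    if m <= 0:
        raise ValueError("m must be positive")
    if m > min(S.matrix.shape):
        raise ValueError("m exceeds min(N, M)")
    if np.min(S.matrix) < 0:
        raise ValueError("stacked matrix must be nonnegative")
    model = NMF(
        n_components=m,
        init=init,
        solver="cd",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    X = S.matrix if S.matrix.dtype == solver_dtype else S.matrix.astype(solver_dtype)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        Z = model.fit_transform(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                f"NMF did not converge within {max_iter} iterations; returning best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
    psi = model.components_
    fact = NMFFactorization(
        m=m,
        psi=psi,
        z=Z,
        order=np.arange(m),
        residual_norm=0.0,
        n_iter=int(model.n_iter_),
        converged=converged,
    )
    fact.residual_norm = reconstruction_error(S, fact)
    return fact


def fit_pca(S: StackedMatrix, m: int, seed: int | None = 0) -> PCAFactorization:
    """Mean-centered truncated PCA baseline (components may be negative)."""
    from sklearn.decomposition import PCA

    if m <= 0 or m > min(S.matrix.shape):
        raise ValueError("m out of range")
    model = PCA(n_components=m, svd_solver="auto", random_state=seed)
    scores = model.fit_transform(S.matrix)
    return PCAFactorization(
        m=m,
        components=model.components_,
        scores=scores,
        mean_spectrum=model.mean_,
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def pca_reconstruction_error(S: StackedMatrix, P: PCAFactorization, m_use: int | None = None) -> float:
    """Normalized squared error of the rank-``m_use`` PCA reconstruction."""
    k = P.m if m_use is None else int(m_use)
    if not 0 <= k <= P.m:
        raise ValueError("m_use out of range")
    X = S.matrix
    denom = float(np.einsum("ij,ij->", X, X, dtype=np.float64))
    if denom == 0:
        return 0.0
    err = 0.0
    comps = P.components[:k]
    scores = P.scores[:, :k]
    block = max(1, int(2**24 // max(X.shape[1], 1)))
    for lo in range(0, X.shape[0], block):
        hi = min(lo + block, X.shape[0])
        recon = scores[lo:hi] @ comps + P.mean_spectrum
        diff = X[lo:hi] - recon
        err += float(np.einsum("ij,ij->", diff, diff, dtype=np.float64))
    return err / denom


def reconstruction_error(
    S: StackedMatrix,
    F: NMFFactorization,
    keep: Iterable[int] | None = None,
) -> float:
    """Σ(I − Σ_{j∈keep} ZΨ)² / ΣI², a fraction in [0, 1+].

    ``keep=None`` keeps all components; an empty ``keep`` yields exactly
    1.0 (zero reconstruction). Computed blockwise in float64.
    """
    X = S.matrix
    denom = float(np.einsum("ij,ij->", X, X, dtype=np.float64))
    if denom == 0:
        return 0.0
    keep_idx = np.arange(F.m) if keep is None else np.asarray(sorted(set(int(k) for k in keep)), dtype=int)
    if keep_idx.size and (keep_idx.min() < 0 or keep_idx.max() >= F.m):
        raise ValueError("keep indices out of range")
    if keep_idx.size == 0:
        return 1.0
    psi = F.psi[keep_idx].astype(np.float64)
    z = F.z[:, keep_idx].astype(np.float64)
    err = 0.0
    block = max(1, int(2**24 // max(X.shape[1], 1)))
    for lo in range(0, X.shape[0], block):
        hi = min(lo + block, X.shape[0])
        diff = X[lo:hi] - z[lo:hi] @ psi
        err += float(np.einsum("ij,ij->", diff, diff, dtype=np.float64))
    return err / denom


class _GramErrors:
    """Closed-form subset reconstruction errors from cached Gram matrices.

    For a fixed factorization, err(keep) expands into terms depending only
    on Z'Z, ΨΨ', diag(Z'X Ψ') and ΣX², so backward elimination can score
    every candidate subset in O(m²) instead of re-reading the data.
    """

    def __init__(self, S: StackedMatrix, F: NMFFactorization) -> None:
        X = S.matrix
        Z = F.z.astype(np.float64)
        psi = F.psi.astype(np.float64)
        C = Z.T @ X  # (m, M)
        self.cross = np.einsum("jm,jm->j", C, psi)  # tr(X'ZΨ) restricted per component
        self.Q = (Z.T @ Z) * (psi @ psi.T)  # pairwise quadratic terms
        self.sx2 = float(np.einsum("ij,ij->", X, X, dtype=np.float64))

    def error(self, keep: np.ndarray) -> float:
        if self.sx2 == 0:
            return 0.0
        if len(keep) == 0:
            return 1.0
        quad = float(self.Q[np.ix_(keep, keep)].sum())
        err = self.sx2 - 2.0 * float(self.cross[keep].sum()) + quad
        return max(err, 0.0) / self.sx2


def rank_by_reconstruction(S: StackedMatrix, F: NMFFactorization) -> np.ndarray:
    """Backward-elimination ranking of components by reconstruction impact.

    Starting from the full set, each step removes every retained
    component in turn and evaluates the residual error of the remainder;
    the component whose removal yields the highest error is the
    next-most-important (rank 0 first). Ties break toward the lower
    original index. Returns the permutation ``order`` (rank position ->
    component index) and stores it on ``F.order``.
    """
    grams = _GramErrors(S, F)
    retained = list(range(F.m))
    ranking: list[int] = []
    while len(retained) > 1:
        best_j = None
        best_err = -np.inf
        for j in retained:
            rest = np.array([k for k in retained if k != j], dtype=int)
            e = grams.error(rest)
            if e > best_err + 1e-15 or (best_j is None):
                best_err, best_j = e, j
            # ties (within 1e-15) keep the earlier (lower) index
        ranking.append(best_j)
        retained.remove(best_j)
    ranking.extend(retained)
    order = np.asarray(ranking, dtype=int)
    F.order = order
    return order


def save_model(
    path: str | Path,
    S: StackedMatrix,
    F: NMFFactorization,
) -> Path:
    """Persist a fitted factorization plus row provenance to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "msinmf-model"
        f.attrs["version"] = _MODEL_FORMAT_VERSION
        f.attrs["m"] = F.m
        f.attrs["residual_norm"] = F.residual_norm
        f.attrs["n_iter"] = F.n_iter
        f.attrs["converged"] = F.converged
        f.attrs["mz_min"] = S.grid.mz_min
        f.attrs["mz_max"] = S.grid.mz_max
        f.attrs["bin_width"] = S.grid.bin_width
        f.create_dataset("psi", data=F.psi)
        f.create_dataset("z", data=F.z, compression="gzip", compression_opts=1)
        f.create_dataset("order", data=F.order)
        enc = f.create_group("rows")
        dids = S.row_index["dataset_id"].to_numpy().astype("S")
        enc.create_dataset("dataset_id", data=dids)
        enc.create_dataset("x", data=S.row_index["x"].to_numpy())
        enc.create_dataset("y", data=S.row_index["y"].to_numpy())
        meta = f.create_group("datasets")
        for i, (did, (h, w)) in enumerate(S.shapes.items()):
            g = meta.create_group(f"{i:03d}")
            g.attrs["dataset_id"] = did
            g.attrs["height"] = h
            g.attrs["width"] = w
            g.attrs["class_label"] = S.class_labels[did]
    return path


def load_model(path: str | Path) -> tuple[NMFFactorization, pd.DataFrame, dict[str, tuple[int, int]], dict[str, str], BinGrid]:
    """Load a model saved by :func:`save_model`.

    Returns (factorization, row_index, shapes, class_labels, grid); the
    stacked data matrix itself is not stored.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "msinmf-model":
            raise ValueError(f"{path} is not an msinmf model container")
        F = NMFFactorization(
            m=int(f.attrs["m"]),
            psi=f["psi"][...],
            z=f["z"][...],
            order=f["order"][...],
            residual_norm=float(f.attrs["residual_norm"]),
            n_iter=int(f.attrs["n_iter"]),
            converged=bool(f.attrs["converged"]),
        )
        row_index = pd.DataFrame(
            {
                "dataset_id": [s.decode() for s in f["rows/dataset_id"][...]],
                "x": f["rows/x"][...],
                "y": f["rows/y"][...],
            }
        )
        shapes: dict[str, tuple[int, int]] = {}
        labels: dict[str, str] = {}
        for key in sorted(f["datasets"].keys()):
            g = f["datasets"][key]
            did = str(g.attrs["dataset_id"])
            shapes[did] = (int(g.attrs["height"]), int(g.attrs["width"]))
            labels[did] = str(g.attrs["class_label"])
        grid = BinGrid(float(f.attrs["mz_min"]), float(f.attrs["mz_max"]), float(f.attrs["bin_width"]))
    return F, row_index, shapes, labels, grid
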