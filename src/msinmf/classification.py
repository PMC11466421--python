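"""Patch-augmented SVM classification of experimental groups.

Each dataset's spatial component maps (an ``(H, W, m)`` cube of NMF
loadings) are divided into a grid of non-overlapping ``w × w`` patches
anchored at the image origin; partial border patches are dropped and
patches with insufficient tissue coverage are discarded. Every surviving
patch becomes one labeled sample: the cube crop flattened in fixed
``(y, x, component)`` order into a vector of length ``w·w·m``.

Train/test splitting balances the two classes exactly by random
down-sampling of the majority class. Classifiers are support vector
machines (linear or RBF kernel) tuned by stratified K-fold grid search;
the reported score is the F1 of the positive (CPH) class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVE_CLASS = "CPH"

log = logging.getLogger(__name__)

DEFAULT_PARAM_GRID_LINEAR = {"C": [0.1, 1.0, 10.0, 100.0]}
DEFAULT_PARAM_GRID_RBF = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 1e-3, 1e-2]}


@dataclass
class PatchSet:
    """Labeled, flattened, spatially disjoint patches of component maps."""

    vectors: np.ndarray  # (n, w*w*m)
    labels: np.ndarray  # (n,) class label strings
    dataset_ids: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 2) patch-grid (row, col) within the dataset
    w: int
    m: int

    def __post_init__(self) -> None:
        n = len(self.vectors)
        if not (len(self.labels) == len(self.dataset_ids) == len(self.positions) == n):
            raise ValueError("inconsistent PatchSet field lengths")
        if n and self.vectors.shape[1] != self.w * self.w * self.m:
            raise ValueError("vector length != w*w*m")

    @property
    def n(self) -> int:
        return len(self.vectors)

    def subset(self, idx: np.ndarray) -> "PatchSet":
        idx = np.asarray(idx)
        return PatchSet(
            self.vectors[idx], self.labels[idx], self.dataset_ids[idx], self.positions[idx], self.w, self.m
        )

    def restrict_components(self, components: Sequence[int]) -> "PatchSet":
        """Keep only the given components in every patch vector."""
        comps = np.asarray(sorted(components), dtype=int)
        if comps.size and (comps.min() < 0 or comps.max() >= self.m):
            raise ValueError("component index out of range")
        cube = self.vectors.reshape(self.n, self.w, self.w, self.m)
        vec = cube[:, :, :, comps].reshape(self.n, self.w * self.w * len(comps))
        return PatchSet(vec, self.labels, self.dataset_ids, self.positions, self.w, len(comps))

    def counts_per_dataset(self) -> dict[str, int]:
        ids, counts = np.unique(self.dataset_ids, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class ClassifierReport:
    """Fitted SVM with its tuned hyperparameters and F1 scores."""

    kernel: str
    best_params: dict
    train_f1: float
    test_f1: float | None
    cv_folds: int
    weight_vector: np.ndarray | None
    model: object = field(repr=False, default=None)


def extract_patches(
    maps: Mapping[str, np.ndarray],
    tissue_masks: Mapping[str, np.ndarray],
    class_labels: Mapping[str, str],
    w: int = 20,
    min_tissue_frac: float = 0.8,
) -> PatchSet:
    """Cut every dataset's component maps into disjoint ``w × w`` patches.

    The patch grid is anchored at (0, 0); partial border patches are
    dropped. A patch is kept only if at least ``min_tissue_frac`` of its
    pixels are on tissue. Vectors are flattened in (y, x, component)
    order.
    """
    if w <= 0:
        raise ValueError("patch width must be positive")
    vectors, labels, ids, positions = [], [], [], []
    m = None
    for did in maps:
        cube = np.asarray(maps[did])
        mask = np.asarray(tissue_masks[did], dtype=bool)
        if cube.ndim != 3 or mask.shape != cube.shape[:2]:
            raise ValueError(f"dataset {did}: maps must be (H, W, m) with matching tissue mask")
        if m is None:
            m = cube.shape[2]
        elif cube.shape[2] != m:
            raise ValueError("inconsistent component count across datasets")
        H, W = mask.shape
        for gy in range(H // w):
            for gx in range(W // w):
                sl = np.s_[gy * w : (gy + 1) * w, gx * w : (gx + 1) * w]
                if mask[sl].mean() < min_tissue_frac:
                    continue
                vectors.append(cube[sl].reshape(-1))
                labels.append(class_labels[did])
                ids.append(did)
                positions.append((gy, gx))
    m = 0 if m is None else m
    if vectors:
        vec = np.asarray(vectors)
    else:
        vec = np.zeros((0, w * w * m))
    return PatchSet(
        vec,
        np.asarray(labels, dtype=object),
        np.asarray(ids, dtype=object),
        np.asarray(positions, dtype=int).reshape(-1, 2),
        w,
        m,
    )


def split_balanced(
    ps: PatchSet, train_frac: float = 0.8, seed: int | None = None
) -> tuple[PatchSet, PatchSet]:
    """Class-balanced train/test split.

    The majority class is randomly down-sampled so both classes carry the
    minority count ``n``; ``round(train_frac * n)`` per class go to train,
    the rest to test. Every retained patch lands in exactly one side.
    """
    classes = np.unique(ps.labels.astype(str))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    rng = np.random.default_rng(seed)
    per_class = [np.flatnonzero(ps.labels.astype(str) == c) for c in classes]
    n = min(len(idx) for idx in per_class)
    if n == 0:
        raise ValueError("a class has zero patches")
    n_train = int(round(train_frac * n))
    train_idx, test_idx = [], []
    for idx in per_class:
        chosen = rng.permutation(idx)[:n]
        train_idx.append(chosen[:n_train])
        test_idx.append(chosen[n_train:])
    return ps.subset(np.concatenate(train_idx)), ps.subset(np.concatenate(test_idx))


def _encode(labels: np.ndarray) -> np.ndarray:
    return (labels.astype(str) == POSITIVE_CLASS).astype(int)


def train_svm(
    train: PatchSet,
    kernel: str = "rbf",
    param_grid: dict | None = None,
    cv_folds: int = 5,
    seed: int | None = None,
) -> ClassifierReport:
    """Grid-search an SVM on the training patches by stratified K-fold CV.

    The best hyperparameters are refit on the full training set; the
    report carries the training F1 (positive class = CPH) and, for the
    linear kernel, the primal weight vector.
    """
    from sklearn.metrics import f1_score
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.svm import SVC

    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    y = _encode(train.labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv_folds:
        raise ValueError(
            f"need at least cv_folds={cv_folds} samples per class, got {counts.tolist()}"
        )
    if param_grid is None:
        param_grid = DEFAULT_PARAM_GRID_LINEAR if kernel == "linear" else DEFAULT_PARAM_GRID_RBF
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(SVC(kernel=kernel), param_grid, scoring="f1", cv=cv, refit=True)
    search.fit(train.vectors, y)
    model = search.best_estimator_
    train_f1 = float(f1_score(y, model.predict(train.vectors), zero_division=0))
    weights = model.coef_.ravel().copy() if kernel == "linear" else None
    return ClassifierReport(
        kernel=kernel,
        best_params=dict(search.best_params_),
        train_f1=train_f1,
        test_f1=None,
        cv_folds=cv_folds,
        weight_vector=weights,
        model=model,
    )


def evaluate_f1(model, test: PatchSet) -> float:
    """F1 of the positive (CPH) class on a held-out patch set."""
    from sklearn.metrics import f1_score

    if isinstance(model, ClassifierReport):
        model = model.model
    if test.n == 0:
        raise ValueError("empty test set")
    y = _encode(test.labels)
    return float(f1_score(y, model.predict(test.vectors), zero_division=0))


def patch_size_sweep(
    maps: Mapping[str, np.ndarray],
    tissue_masks: Mapping[str, np.ndarray],
    class_labels: Mapping[str, str],
    widths: Sequence[int],
    fixed_patch_count: int,
    seed: int | None = None,
    kernel: str = "rbf",
    min_tissue_frac: float = 0.8,
    train_frac: float = 0.8,
    cv_folds: int = 5,
) -> pd.DataFrame:
    """Test accuracy as a function of patch width at a fixed sample count.

    For each width the patch pool is balanced-subsampled to
    ``fixed_patch_count`` patches (half per class) before the standard
    split/train/evaluate pipeline runs. Widths that cannot supply the
    requested count are omitted with a warning.
    """
    from sklearn.metrics import accuracy_score

    rows = []
    per_class_target = fixed_patch_count // 2
    rng = np.random.default_rng(seed)
    for w in widths:
        ps = extract_patches(maps, tissue_masks, class_labels, w=w, min_tissue_frac=min_tissue_frac)
        if ps.n == 0:
            log.warning("patch_size_sweep: width %d yields no patches; omitted", w)
            continue
        classes = np.unique(ps.labels.astype(str))
        if len(classes) != 2 or min(
            (ps.labels.astype(str) == c).sum() for c in classes
        ) < per_class_target:
            log.warning("patch_size_sweep: width %d cannot supply %d balanced patches; omitted", w, fixed_patch_count)
            continue
        keep = []
        for c in classes:
            idx = np.flatnonzero(ps.labels.astype(str) == c)
            keep.append(rng.permutation(idx)[:per_class_target])
        sub = ps.subset(np.concatenate(keep))
        split_seed = int(rng.integers(2**31))
        train, test = split_balanced(sub, train_frac=train_frac, seed=split_seed)
        report = train_svm(train, kernel=kernel, cv_folds=cv_folds, seed=split_seed)
        acc = float(accuracy_score(_encode(test.labels), report.model.predict(test.vectors)))
        rows.append({"width": w, "accuracy": acc, "n_patches_available": ps.n})
    return pd.DataFrame(rows, columns=["width", "accuracy", "n_patches_available"])
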