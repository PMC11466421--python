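"""Ranking NMF components by their contribution to classification accuracy.

Datasets of different spatial size produce different numbers of patches,
which would bias a patch classifier toward the larger samples. The
procedure therefore equalizes representation: with ``P`` the smallest
per-dataset patch count, every evaluation draws exactly ``P`` patches per
dataset, trains an SVM by K-fold cross-validation on patch vectors
restricted to a candidate component set, and repeats the draw to build a
distribution of mean CV accuracies per candidate.

Per iteration, each not-yet-selected component is appended singly to the
current candidate list and scored; the component with the highest mean
accuracy is selected together with every component whose distribution is
statistically indistinguishable from it (Welch two-sample t-test,
p ≥ alpha). Iterations stop once the candidate list alone reaches the
target accuracy (default 75%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classification import PatchSet, _encode, extract_patches


@dataclass
class AccuracyDistribution:
    """Resampled mean-CV-accuracy distribution for one component set."""

    component_set: tuple[int, ...]
    extra: int | None
    samples: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0


@dataclass
class IterationLog:
    tested: dict[int, AccuracyDistribution]
    p_values: dict[int, float]
    selected: list[int]
    candidate_accuracy: float


@dataclass
class RankingResult:
    """Ordered candidate list with the full per-iteration evidence."""

    candidate_list: list[int]
    K: int
    P: int
    iterations: list[IterationLog] = field(default_factory=list)
    stop_accuracy: float = float("nan")
    converged: bool = False


def min_patch_count(ps: PatchSet) -> int:
    """Smallest per-dataset patch count ``P`` (the equalization quota)."""
    counts = ps.counts_per_dataset()
    if not counts:
        raise ValueError("no patches")
    if min(counts.values()) == 0:
        raise ValueError("a dataset has zero patches")
    return min(counts.values())


def sample_equalized(ps: PatchSet, P: int, rng: np.random.Generator | int | None = None) -> PatchSet:
    """Draw exactly ``P`` patches per dataset, uniformly without replacement."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = ps.counts_per_dataset()
    if min(counts.values()) < P:
        raise ValueError(f"a dataset has fewer than P={P} patches")
    take = []
    ids = ps.dataset_ids.astype(str)
    for did in sorted(counts):
        idx = np.flatnonzero(ids == did)
        take.append(rng.choice(idx, size=P, replace=False))
    return ps.subset(np.sort(np.concatenate(take)))


def _derived_rng(master_seed: int, iteration: int, component_key: int, repeat: int) -> np.random.Generator:
    # Independent stream per (iteration, component, repeat) so the 50 x N
    # fits can run in any order (or concurrently) with identical results.
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, iteration, component_key, repeat])
    return np.random.default_rng(ss)


def accuracy_distribution(
    ps: PatchSet,
    base_set: Sequence[int],
    extra: int | None = None,
    repeats: int = 50,
    cv_folds: int = 5,
    master_seed: int = 0,
    iteration: int = 0,
    C: float = 1.0,
) -> AccuracyDistribution:
    """Resampled CV-accuracy distribution for ``base_set ∪ {extra}``.

    Per repeat: redraw ``P`` patches per dataset, restrict the patch
    vectors to the component set, and record the mean stratified
    ``cv_folds``-fold CV accuracy of a linear SVM (fixed ``C``).
    Deterministic given ``master_seed`` via per-(iteration, component,
    repeat) derived seeds.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.svm import SVC

    if repeats < 2:
        raise ValueError("repeats must be >= 2 (t-test undefined otherwise)")
    base = tuple(sorted(int(b) for b in base_set))
    if extra is not None and int(extra) in base:
        raise ValueError("extra component already in base set")
    comps = base if extra is None else tuple(sorted(base + (int(extra),)))
    if not comps:
        raise ValueError("empty component set")
    sub = ps.restrict_components(comps)
    P = min_patch_count(ps)
    comp_key = 0 if extra is None else int(extra) + 1
    samples = np.empty(repeats)
    for r in range(repeats):
        rng = _derived_rng(master_seed, iteration, comp_key, r)
        draw = sample_equalized(sub, P, rng)
        y = _encode(draw.labels)
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        scores = cross_val_score(SVC(kernel="linear", C=C), draw.vectors, y, cv=skf, scoring="accuracy")
        samples[r] = scores.mean()
    return AccuracyDistribution(component_set=comps, extra=extra, samples=samples)


def select_statistically_best(
    dists: Sequence[AccuracyDistribution], alpha: float = 0.05
) -> tuple[list[int], dict[int, float]]:
    """Pick the highest-mean component plus all statistically similar ones.

    Each distribution is compared to the best by a Welch (unequal
    variance) two-sample t-test; components with p ≥ alpha join the
    selection. Identical zero-variance distributions count as p = 1.
    Returns (selected component indices, p-values keyed by component).
    """
    if len(dists) < 1:
        raise ValueError("need at least one distribution")
    keyed = {d.extra if d.extra is not None else -1: d for d in dists}
    means = {k: d.mean for k, d in keyed.items()}
    best_key = min(means, key=lambda k: (-means[k], k))
    best = keyed[best_key]
    p_values: dict[int, float] = {best_key: 1.0}
    selected = [best_key]
    for k, d in keyed.items():
        if k == best_key:
            continue
        if np.std(best.samples) == 0 and np.std(d.samples) == 0:
            p = 1.0 if best.mean == d.mean else 0.0
        else:
            p = float(stats.ttest_ind(best.samples, d.samples, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        p_values[k] = p
        if p >= alpha:
            selected.append(k)
    # order the selection by descending mean, ties toward lower index
    selected.sort(key=lambda k: (-means[k], k))
    return selected, p_values


def rank_components(
    maps: Mapping[str, np.ndarray],
    tissue_masks: Mapping[str, np.ndarray],
    class_labels: Mapping[str, str],
    patch_width: int = 20,
    threshold: float = 0.75,
    alpha: float = 0.05,
    repeats: int = 50,
    cv_folds: int = 5,
    seed: int = 0,
    min_tissue_frac: float = 0.8,
    C: float = 1.0,
) -> RankingResult:
    """Grow the candidate list until it alone classifies at ``threshold``.

    Each iteration scores every remaining component appended singly to the
    current candidate list, appends the statistically-best set, then
    checks the candidate list's own accuracy distribution against the
    stopping threshold. Exhausting all components without reaching it is
    flagged (``converged=False``), not an error.
    """
    ps = extract_patches(maps, tissue_masks, class_labels, w=patch_width, min_tissue_frac=min_tissue_frac)
    m = ps.m
    P = min_patch_count(ps)
    result = RankingResult(candidate_list=[], K=0, P=P)
    iteration = 0
    while len(result.candidate_list) < m:
        remaining = [j for j in range(m) if j not in result.candidate_list]
        dists = {
            j: accuracy_distribution(
                ps, result.candidate_list, extra=j, repeats=repeats, cv_folds=cv_folds,
                master_seed=seed, iteration=iteration, C=C,
            )
            for j in remaining
        }
        if len(remaining) == 1:
            selected, p_values = [remaining[0]], {remaining[0]: 1.0}
        else:
            selected, p_values = select_statistically_best(list(dists.values()), alpha=alpha)
        result.candidate_list.extend(selected)
        cand_dist = accuracy_distribution(
            ps, result.candidate_list, extra=None, repeats=repeats, cv_folds=cv_folds,
            master_seed=seed, iteration=iteration, C=C,
        )
        result.iterations.append(
            IterationLog(tested=dists, p_values=p_values, selected=selected, candidate_accuracy=cand_dist.mean)
        )
        result.stop_accuracy = cand_dist.mean
        if cand_dist.mean >= threshold:
            result.converged = True
            break
        iteration += 1
    result.K = len(result.candidate_list)
    return result
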