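"""Stacking, NMF/PCA fits, reconstruction error and backward elimination."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from msinmf import (
    BinGrid,
    BinnedDataset,
    fit_nmf,
    fit_pca,
    rank_by_reconstruction,
    reconstruction_error,
    stack_cohort,
    unstack_maps,
)
from msinmf.decomposition import StackedMatrix, load_model, pca_reconstruction_error, save_model
from msinmf.synthetic import make_cohort
from msinmf import preprocess

from conftest import tiny_config


def _stack_from_matrix(X):
    n = X.shape[0]
    return StackedMatrix(
        matrix=np.asarray(X, float),
        row_index=pd.DataFrame({"dataset_id": ["d0"] * n, "x": np.arange(n), "y": 0}),
        grid=BinGrid(600.0, 600.0 + 0.05 * X.shape[1], 0.05),
        shapes={"d0": (1, n)},
        class_labels={"d0": "unlabeled"},
    )


def _rank3_matrix(rng, n=60, M=40):
    W = rng.uniform(0.0, 1.0, (n, 3))
    H = rng.uniform(0.0, 1.0, (3, M))
    return W @ H


def _grid_for(cohort):
    return cohort[0].grid


class TestStacking:
    def test_row_count_additivity(self):
        grid = BinGrid(600.0, 601.0, 0.5)
        cubes = []
        for did, n_tissue, shape in (("a", 3, (2, 2)), ("b", 5, (3, 2))):
            cube = np.zeros(shape + (grid.M,))
            flat = cube.reshape(-1, grid.M)
            flat[:n_tissue, 0] = 1.0
            mask = flat.sum(axis=1).reshape(shape) > 0
            cubes.append(BinnedDataset(did, "CPH", grid, cube, mask))
        S = stack_cohort(cubes)
        assert S.n_rows == 8
        assert S.D == 2

    def test_unstack_inverts_stack(self, tiny_stack):
        m = 4
        rng = np.random.default_rng(0)
        Z = rng.uniform(size=(tiny_stack.n_rows, m))
        maps = unstack_maps(tiny_stack, Z)
        # re-gather rows in stack order and compare
        gathered = np.concatenate(
            [
                maps[did][
                    tiny_stack.row_index.loc[tiny_stack.row_index.dataset_id == did, "y"],
                    tiny_stack.row_index.loc[tiny_stack.row_index.dataset_id == did, "x"],
                ]
                for did in tiny_stack.shapes
            ]
        )
        assert np.allclose(gathered, Z)

    def test_grid_mismatch_rejected(self):
        g1, g2 = BinGrid(600.0, 601.0, 0.5), BinGrid(600.0, 601.0, 0.25)
        mk = lambda did, g: BinnedDataset(
            did, "CPH", g, np.ones((1, 1, g.M)), np.ones((1, 1), bool)
        )
        with pytest.raises(ValueError):
            stack_cohort([mk("a", g1), mk("b", g2)])

    def test_phantom_full_tissue_row_count(self, tiny_stack):
        # every phantom pixel records signal (matrix region included)
        assert tiny_stack.n_rows == 24 * 24 + 24 * 20 + 20 * 24 + 20 * 20


class TestFitNMF:
    def test_exact_rank_recovery(self):
        X = _rank3_matrix(np.random.default_rng(1))
        F = fit_nmf(_stack_from_matrix(X), 3, max_iter=2000, tol=1e-8, solver_dtype=np.float64)
        assert F.residual_norm < 1e-3

    def test_nonnegativity(self, nmf20):
        assert nmf20.psi.min() >= 0
        assert nmf20.z.min() >= 0

    def test_determinism_given_seed(self):
        X = _rank3_matrix(np.random.default_rng(2))
        S = _stack_from_matrix(X)
        F1 = fit_nmf(S, 3, max_iter=50, seed=7, init="random")
        F2 = fit_nmf(S, 3, max_iter=50, seed=7, init="random")
        assert np.array_equal(F1.psi, F2.psi)
        assert np.array_equal(F1.z, F2.z)

    def test_objective_non_increasing_over_iterations(self):
        X = _rank3_matrix(np.random.default_rng(3), n=80, M=50) + 0.05
        S = _stack_from_matrix(X)
        errs = [
            fit_nmf(S, 3, max_iter=k, seed=4, init="random", tol=0).residual_norm
            for k in (5, 20, 80, 320)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_invalid_m_rejected(self, tiny_stack):
        with pytest.raises(ValueError):
            fit_nmf(tiny_stack, 0)

    def test_planted_templates_recovered(self, nmf20, default_gt):
        """Hungarian-matched cosine similarity against generator truth."""
        from scipy.optimize import linear_sum_assignment

        psi_true = default_gt.binned_psi(BinGrid(600.0, 1100.0, 0.05))
        a = nmf20.psi / np.linalg.norm(nmf20.psi, axis=1, keepdims=True)
        b = psi_true / np.linalg.norm(psi_true, axis=1, keepdims=True)
        cos = a @ b.T
        r, c = linear_sum_assignment(-cos)
        assert cos[r, c].min() > 0.9


class TestFitPCA:
    def test_full_rank_reconstruction_and_nesting(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(30, 8))
        S = _stack_from_matrix(X)
        P = fit_pca(S, 8)
        errs = [pca_reconstruction_error(S, P, k) for k in range(1, 9)]
        assert errs[-1] < 1e-10
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_components_orthonormal(self, tiny_stack):
        P = fit_pca(tiny_stack, 4)
        G = P.components @ P.components.T
        assert np.allclose(G, np.eye(4), atol=1e-6)

    def test_phantom_components_mixed_sign(self, tiny_stack):
        P = fit_pca(tiny_stack, 4)
        assert (P.components < 0).any()

    def test_m_too_large_rejected(self):
        S = _stack_from_matrix(np.ones((4, 3)))
        with pytest.raises(ValueError):
            fit_pca(S, 5)


class TestReconstructionError:
    def test_empty_keep_is_exactly_one(self, tiny_stack):
        F = fit_nmf(tiny_stack, 3, max_iter=30, seed=0)
        assert reconstruction_error(tiny_stack, F, keep=[]) == 1.0

    def test_all_components_on_exact_rank_fit(self):
        X = _rank3_matrix(np.random.default_rng(6))
        S = _stack_from_matrix(X)
        F = fit_nmf(S, 3, max_iter=2000, tol=1e-8, solver_dtype=np.float64)
        assert reconstruction_error(S, F) < 1e-3

    def test_gram_shortcut_matches_direct(self, tiny_stack):
        from msinmf.decomposition import _GramErrors

        F = fit_nmf(tiny_stack, 4, max_iter=40, seed=1)
        grams = _GramErrors(tiny_stack, F)
        for keep in ([0], [1, 3], [0, 1, 2, 3]):
            direct = reconstruction_error(tiny_stack, F, keep=keep)
            assert grams.error(np.asarray(keep)) == pytest.approx(direct, rel=1e-6, abs=1e-9)


def brute_force_backward_elimination(S, F):
    """Independent greedy oracle computing residuals directly per subset."""
    retained = list(range(F.m))
    ranking = []
    while len(retained) > 1:
        errs = []
        for j in retained:
            rest = [k for k in retained if k != j]
            recon = F.z[:, rest].astype(float) @ F.psi[rest].astype(float)
            diff = S.matrix - recon
            errs.append((float((diff**2).sum() / (S.matrix**2).sum()), j))
        # highest residual wins; ties toward the lower index
        errs.sort(key=lambda t: (-t[0], t[1]))
        ranking.append(errs[0][1])
        retained.remove(errs[0][1])
    return ranking + retained


class TestBackwardElimination:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(50, 3)) @ rng.uniform(size=(3, 30)) + 0.01 * rng.uniform(size=(50, 30))
        S = _stack_from_matrix(X)
        F = fit_nmf(S, 3, max_iter=500, seed=3, solver_dtype=np.float64)
        assert rank_by_reconstruction(S, F).tolist() == brute_force_backward_elimination(S, F)

    def test_dominant_component_ranked_first(self):
        rng = np.random.default_rng(8)
        z = np.zeros((60, 3))
        z[:, 0] = 10.0 * rng.uniform(0.5, 1.0, 60)  # carries ~99% of the energy
        z[:, 1] = 0.3 * rng.uniform(size=60)
        z[:, 2] = 0.2 * rng.uniform(size=60)
        psi = np.eye(3, 24) + 0.01
        X = z @ psi
        S = _stack_from_matrix(X)
        F = fit_nmf(S, 3, max_iter=2000, tol=1e-10, solver_dtype=np.float64)
        order = rank_by_reconstruction(S, F)
        dominant_fit = int(np.argmax(F.z.sum(axis=0)))
        assert order[0] == dominant_fit

    def test_tie_between_identical_components_breaks_low(self):
        from msinmf.decomposition import NMFFactorization

        rng = np.random.default_rng(9)
        psi_row = rng.uniform(size=12)
        F = NMFFactorization(
            m=3,
            psi=np.vstack([psi_row, psi_row, rng.uniform(size=12)]),
            z=np.column_stack([np.ones(20), np.ones(20), 5.0 * np.ones(20)]),
            order=np.arange(3),
            residual_norm=0.0,
        )
        X = F.z @ F.psi
        S = _stack_from_matrix(X)
        order = rank_by_reconstruction(S, F)
        assert sorted(order.tolist()) == [0, 1, 2]
        # components 0 and 1 are byte-identical; the earlier index precedes
        assert order.tolist().index(0) < order.tolist().index(1)

    def test_elimination_step_removes_argmax_residual(self, tiny_stack):
        """Defining property: each removed component maximizes the residual."""
        from msinmf.decomposition import _GramErrors

        F = fit_nmf(tiny_stack, 4, max_iter=40, seed=2)
        order = rank_by_reconstruction(tiny_stack, F)
        grams = _GramErrors(tiny_stack, F)
        retained = list(range(4))
        for step in range(3):
            j_star = order[step]
            errs = {
                j: grams.error(np.asarray([k for k in retained if k != j]))
                for j in retained
            }
            assert errs[j_star] == max(errs.values())
            retained.remove(j_star)


class TestModelContainer:
    def test_round_trip(self, tmp_path, tiny_stack):
        F = fit_nmf(tiny_stack, 3, max_iter=30, seed=0)
        rank_by_reconstruction(tiny_stack, F)
        path = save_model(tmp_path / "m.h5", tiny_stack, F)
        F2, row_index, shapes, labels, grid = load_model(path)
        assert np.allclose(F2.psi, F.psi)
        assert np.allclose(F2.z, F.z)
        assert np.array_equal(F2.order, F.order)
        assert shapes == tiny_stack.shapes
        assert labels == tiny_stack.class_labels
        assert grid == tiny_stack.grid
        assert len(row_index) == tiny_stack.n_rows
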