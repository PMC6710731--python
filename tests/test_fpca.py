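"""Pseudo-time grids, spline smoothing, FPCA and the functional F-statistic."""

import numpy as np
import pandas as pd
import pytest

from methylpath.fpca import (
    build_pseudotime,
    compute_f_table,
    f_statistic,
    fit_fpca,
    rank_genes,
    smooth_curves,
    _bspline_design,
)


def _matrix(values, samples):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        values, index=[f"G{i}" for i in range(values.shape[0])], columns=samples
    )


class TestPseudotime:
    def test_equispaced_positions(self):
        samples = ["c1", "c2", "k1", "k2"]
        matrix = _matrix([[0.2, 0.4, 0.3, 0.1]], samples)
        groups = pd.Series(["case", "case", "control", "control"], index=samples)
        grid = build_pseudotime(matrix, groups)
        assert np.allclose(grid.positions, [0, 1 / 3, 2 / 3, 1])

    def test_controls_first_ordered_by_mean(self):
        samples = ["c1", "c2", "k1", "k2"]
        matrix = _matrix([[0.9, 0.1, 0.8, 0.2]], samples)
        groups = pd.Series(["case", "case", "control", "control"], index=samples)
        grid = build_pseudotime(matrix, groups)
        assert grid.sample_ids == ("k2", "k1", "c2", "c1")

    def test_invariant_to_column_permutation(self):
        samples = ["a", "b", "c", "d", "e", "f"]
        rng = np.random.default_rng(3)
        matrix = _matrix(rng.uniform(0.2, 0.8, (5, 6)), samples)
        groups = pd.Series(["case", "control"] * 3, index=samples)
        grid = build_pseudotime(matrix, groups)
        shuffled = build_pseudotime(matrix[["f", "b", "a", "e", "c", "d"]], groups)
        assert grid.sample_ids == shuffled.sample_ids

    def test_given_rule_preserves_order(self):
        samples = ["a", "b", "c", "d"]
        matrix = _matrix([[0.5, 0.4, 0.3, 0.2]], samples)
        groups = pd.Series(["case"] * 2 + ["control"] * 2, index=samples)
        grid = build_pseudotime(matrix, groups, rule="given", order=["d", "b", "a", "c"])
        assert grid.sample_ids == ("d", "b", "a", "c")

    def test_unknown_rule_rejected(self):
        samples = ["a", "b", "c", "d"]
        matrix = _matrix([[0.5, 0.4, 0.3, 0.2]], samples)
        groups = pd.Series(["case"] * 2 + ["control"] * 2, index=samples)
        with pytest.raises(ValueError):
            build_pseudotime(matrix, groups, rule="random")

    def test_too_few_samples(self):
        samples = ["a", "b", "c"]
        matrix = _matrix([[0.5, 0.4, 0.3]], samples)
        groups = pd.Series(["case", "case", "control"], index=samples)
        with pytest.raises(ValueError):
            build_pseudotime(matrix, groups)


def _grid_and_matrix(n_samples=12, n_genes=6, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    matrix = _matrix(rng.uniform(0.2, 0.8, (n_genes, n_samples)), samples)
    groups = pd.Series(
        ["control"] * (n_samples // 2) + ["case"] * (n_samples - n_samples // 2),
        index=samples,
    )
    return build_pseudotime(matrix, groups), matrix


class TestSmoothCurves:
    def test_constant_gene_stays_constant(self):
        grid, matrix = _grid_and_matrix()
        matrix.iloc[0] = 0.42
        smoothed = smooth_curves(matrix, grid)
        assert np.allclose(smoothed.iloc[0], 0.42, atol=1e-10)

    def test_curve_in_spline_space_reproduced(self):
        grid, matrix = _grid_and_matrix()
        design = _bspline_design(np.asarray(grid.positions), basis_size=6)
        coefs = np.linspace(-1, 1, 6)
        target = design @ coefs
        # assign in pseudo-time order so the curve lies in the spline space
        matrix.loc[matrix.index[1], list(grid.sample_ids)] = target
        smoothed = smooth_curves(matrix, grid, basis_size=6)
        assert np.allclose(smoothed.iloc[1].to_numpy(), target, atol=1e-8)

    def test_mean_preserved(self):
        grid, matrix = _grid_and_matrix(seed=5)
        smoothed = smooth_curves(matrix, grid)
        assert np.allclose(
            smoothed.mean(axis=1).to_numpy(), matrix[list(grid.sample_ids)].mean(axis=1).to_numpy(),
            atol=1e-8,
        )

    @pytest.mark.parametrize("basis_size", [3, 13])
    def test_basis_size_bounds(self, basis_size):
        grid, matrix = _grid_and_matrix()
        with pytest.raises(ValueError):
            smooth_curves(matrix, grid, basis_size=basis_size)


class TestFitFpca:
    def test_rank_one_structure(self):
        t = np.linspace(0, 1, 10)
        shape = np.sin(2 * np.pi * t)
        curves = pd.DataFrame(
            np.outer([1.0, 2.0, -1.5, 0.5], shape), index=list("abcd")
        )
        decomp = fit_fpca(curves)
        assert decomp.L == 1
        assert decomp.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_eigenfunctions_orthonormal(self):
        rng = np.random.default_rng(1)
        curves = pd.DataFrame(rng.normal(size=(8, 10)))
        curves = curves.sub(curves.mean(axis=1), axis=0)
        decomp = fit_fpca(curves)
        gram = decomp.eigenfunctions @ decomp.eigenfunctions.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        curves = pd.DataFrame(rng.normal(size=(7, 9)))
        curves = curves.sub(curves.mean(axis=1), axis=0)
        decomp = fit_fpca(curves)
        recon = decomp.reconstruct(n_components=decomp.n_components)
        assert np.allclose(recon.to_numpy(), curves.to_numpy(), atol=1e-6)

    def test_repeated_fits_identical(self):
        rng = np.random.default_rng(3)
        curves = pd.DataFrame(rng.normal(size=(6, 8)))
        a = fit_fpca(curves)
        b = fit_fpca(curves)
        assert np.array_equal(a.eigenfunctions, b.eigenfunctions)
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())

    def test_sign_convention_nonnegative_sum(self):
        rng = np.random.default_rng(4)
        curves = pd.DataFrame(rng.normal(size=(6, 8)))
        decomp = fit_fpca(curves)
        sums = decomp.eigenfunctions.sum(axis=1)
        nonzero = np.abs(sums) > 1e-10
        assert (sums[nonzero] >= 0).all()

    def test_degenerate_input_gives_zero_components(self):
        curves = pd.DataFrame(np.zeros((5, 6)))
        decomp = fit_fpca(curves)
        assert decomp.L == 0
        assert decomp.reconstruct().shape == (5, 6)

    def test_variance_target_controls_l(self):
        rng = np.random.default_rng(5)
        curves = pd.DataFrame(rng.normal(size=(20, 10)))
        curves = curves.sub(curves.mean(axis=1), axis=0)
        low = fit_fpca(curves, variance_target=0.5)
        high = fit_fpca(curves, variance_target=0.99)
        assert low.L <= high.L
        cum = np.cumsum(high.variance_explained)
        assert cum[high.L - 1] >= 0.99 - 1e-9


class TestFStatistic:
    def test_constant_gene_scores_zero(self):
        entry = f_statistic([0.3, 0.3, 0.3], [0.3, 0.3, 0.3], delta=1.0)
        assert entry.rss0 == entry.rss1 == 0.0
        assert entry.f_value == 0.0

    def test_perfect_reconstruction_limit(self):
        curve = [0.1, 0.5, 0.9, 0.5]
        entry = f_statistic(curve, curve, delta=0.5)
        assert entry.rss1 == 0.0
        assert entry.f_value == pytest.approx(entry.rss0 / 0.5)

    def test_hand_computed_toy(self):
        # grid {0, 0.5, 1}, values {0, 1, 0}: mean 1/3, RSS0 = 2/3, RSS1 = 0
        entry = f_statistic([0.0, 1.0, 0.0], [0.0, 1.0, 0.0], delta=1.0)
        assert entry.f_value == pytest.approx(2 / 3, rel=1e-12)

    def test_shift_invariance(self):
        curve = np.array([0.1, 0.6, 0.2, 0.4])
        recon = np.array([0.15, 0.55, 0.25, 0.35])
        base = f_statistic(curve, recon, delta=0.3)
        shifted = f_statistic(curve + 0.2, recon + 0.2, delta=0.3)
        assert shifted.f_value == pytest.approx(base.f_value, rel=1e-12)

    def test_scale_covariance_with_rescaled_delta(self):
        # scaling curve and reconstruction by c and delta by c^2 leaves F fixed
        curve = np.array([0.1, 0.6, 0.2, 0.4])
        recon = np.array([0.15, 0.55, 0.25, 0.35])
        base = f_statistic(curve, recon, delta=0.3)
        for c in (2.0, 10.0):
            scaled = f_statistic(c * curve, c * recon, delta=c**2 * 0.3)
            assert scaled.f_value == pytest.approx(base.f_value, rel=1e-12)

    @pytest.mark.parametrize("delta", [0.0, -1.0])
    def test_delta_must_be_positive(self, delta):
        with pytest.raises(ValueError):
            f_statistic([0.1, 0.2], [0.1, 0.2], delta=delta)

    def test_table_uses_median_rss1_delta(self):
        rng = np.random.default_rng(6)
        smoothed = pd.DataFrame(rng.uniform(0.2, 0.8, (9, 8)))
        centered = smoothed.sub(smoothed.mean(axis=1), axis=0)
        decomp = fit_fpca(centered, variance_target=0.5)
        table = compute_f_table(smoothed, decomp)
        assert (table["delta"] == max(float(np.median(table["rss1"])), 1e-12)).all()
        assert (table["f_value"] >= 0).all()
        assert (table["rss0"] + 1e-12 >= table["rss1"]).all()


class TestRankGenes:
    def _table(self, mapping):
        return pd.DataFrame(
            {"f_value": list(mapping.values())}, index=list(mapping.keys())
        )

    def test_descending_order(self):
        out = rank_genes(self._table({"A": 3.0, "B": 1.0, "C": 2.0}), ["A", "B", "C"])
        assert list(out["gene"]) == ["A", "C", "B"]
        assert list(out["rank"]) == [1, 2, 3]

    def test_top_one(self):
        out = rank_genes(self._table({"A": 3.0, "B": 1.0}), ["A", "B"], top_k=1)
        assert list(out["gene"]) == ["A"]

    def test_tie_broken_lexicographically(self):
        out = rank_genes(self._table({"B": 2.0, "A": 2.0}), ["A", "B"], top_k=1)
        assert list(out["gene"]) == ["A"]

    def test_missing_members_skipped(self):
        out = rank_genes(self._table({"A": 1.0}), ["A", "ZZ"], top_k=3)
        assert list(out["gene"]) == ["A"]

    def test_top_k_positive(self):
        with pytest.raises(ValueError):
            rank_genes(self._table({"A": 1.0}), ["A"], top_k=0)
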