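"""Solver policy, pair enumeration, binary-constrained selection, confidence."""

import itertools

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st

from specmix.unmixing import (
    binary_constrained_unmix,
    classify_image,
    confidence_pearson,
    enumerate_pairs,
    fit_binary_pair,
    unmix_nonnegative,
    unmix_unconstrained,
    unmix_with_fallback,
)


class TestUnconstrained:
    def test_identity_matrix(self):
        res = unmix_unconstrained(np.array([3.0, 5.0]), np.eye(2))
        np.testing.assert_allclose(res.abundances, [3.0, 5.0])
        assert res.residual_ss == pytest.approx(0.0, abs=1e-18)
        assert res.method_used == "unconstrained"

    def test_forward_model_recovery(self, toy_reference, rng):
        x_true = rng.uniform(0.5, 2.0, 4)
        y = toy_reference.matrix @ x_true
        res = unmix_unconstrained(y, toy_reference)
        np.testing.assert_allclose(res.abundances, x_true, atol=1e-9)

    def test_rank_deficient_warns(self):
        F = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.warns(UserWarning, match="rank"):
            unmix_unconstrained(np.ones(4), F)


def _negative_ols_case():
    """Geometry engineered so OLS gives a negative coefficient.

    With highly correlated columns and y slightly 'outside' the cone of
    non-negative combinations, the projection needs a negative weight.
    """
    F = np.column_stack([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0]])
    y = np.array([1.0, 0.5, 0.0])
    return F, y


class TestNonnegativeAndFallback:
    def test_constraint_inactive_matches_unconstrained(self, toy_reference, rng):
        x_true = rng.uniform(0.5, 2.0, 4)
        y = toy_reference.matrix @ x_true
        a = unmix_unconstrained(y, toy_reference)
        b = unmix_nonnegative(y, toy_reference)
        np.testing.assert_allclose(a.abundances, b.abundances, atol=1e-9)

    def test_negative_case_clamps_and_matches_grid_oracle(self):
        F, y = _negative_ols_case()
        ols = unmix_unconstrained(y, F)
        assert (ols.abundances < 0).any()
        nn = unmix_nonnegative(y, F)
        assert np.all(nn.abundances >= 0)
        assert nn.abundances[1] == pytest.approx(0.0, abs=1e-12)
        # 1-D grid oracle over the surviving coefficient
        grid = np.linspace(0, 2, 20001)
        ss = ((y[:, None] - F[:, [0]] * grid[None, :]) ** 2).sum(axis=0)
        assert nn.abundances[0] == pytest.approx(grid[ss.argmin()], abs=1e-3)
        assert nn.residual_ss >= ols.residual_ss  # constraint can only cost

    def test_zero_observation(self, toy_reference):
        res = unmix_nonnegative(np.zeros(6), toy_reference)
        np.testing.assert_allclose(res.abundances, 0.0)
        assert res.residual_ss == pytest.approx(0.0, abs=1e-18)

    def test_fallback_branch_bookkeeping(self, toy_reference, rng):
        x_true = rng.uniform(0.5, 2.0, 4)
        clean = unmix_with_fallback(toy_reference.matrix @ x_true, toy_reference)
        assert clean.method_used == "unconstrained"
        F, y = _negative_ols_case()
        assert unmix_with_fallback(y, F).method_used == "nonnegative"

    def test_batch_branch_decisions_match_elementwise(self, toy_reference, rng):
        ys = rng.uniform(-0.2, 1.0, size=(20, 6))
        for y in ys:
            res = unmix_with_fallback(y, toy_reference)
            ols = unmix_unconstrained(y, toy_reference)
            expected = "unconstrained" if np.all(ols.abundances >= 0) else "nonnegative"
            assert res.method_used == expected


class TestEnumeratePairs:
    def test_sixteen_fluorophores_give_120_label_types(self):
        pairs = enumerate_pairs(16)
        assert len(pairs) == 120

    def test_two_fluorophores(self):
        assert enumerate_pairs(2) == [(0, 1)]

    def test_rejects_fewer_than_two(self):
        with pytest.raises(ValueError):
            enumerate_pairs(1)

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(2, 24))
    def test_matches_double_loop_oracle(self, n):
        pairs = enumerate_pairs(n)
        oracle = [(i, j) for i in range(n) for j in range(i + 1, n)]
        assert pairs == oracle
        assert len(pairs) == n * (n - 1) // 2
        assert all(i < j for i, j in pairs)
        assert len(set(pairs)) == len(pairs)


class TestFitBinaryPair:
    def test_noise_free_recovery_with_background(self, toy_reference):
        F = toy_reference.matrix
        b = np.full(6, 0.3)
        y = 2.0 * F[:, 1] + 3.0 * F[:, 2] + b
        xi, xj, rss = fit_binary_pair(y, toy_reference, (1, 2), b)
        assert xi == pytest.approx(2.0, abs=1e-9)
        assert xj == pytest.approx(3.0, abs=1e-9)
        assert rss == pytest.approx(0.0, abs=1e-16)

    def test_residual_equals_orthogonal_complement(self, toy_reference):
        """Fitting a foreign spectrum leaves exactly its out-of-span component."""
        F = toy_reference.matrix
        y = F[:, 3]
        xi, xj, rss = fit_binary_pair(y, toy_reference, (0, 1))
        # projection oracle: unconstrained projection onto span(f0, f1)
        A = F[:, [0, 1]]
        proj = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        expected = float((y - proj) @ (y - proj))
        # NNLS residual >= projection residual; equal when coefficients >= 0
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        if np.all(coef >= 0):
            assert rss == pytest.approx(expected, rel=1e-9)
        else:
            assert rss >= expected - 1e-12
        assert rss > 0

    def test_matches_scipy_nnls(self, toy_reference, rng):
        """Closed-form 2-variable solver equals scipy's active-set NNLS."""
        F = toy_reference.matrix
        b = np.zeros(6)
        for _ in range(50):
            y = rng.uniform(-0.5, 2.0, 6)
            for pair in enumerate_pairs(4):
                xi, xj, rss = fit_binary_pair(y, toy_reference, pair, b)
                x_ref, rnorm = scipy.optimize.nnls(F[:, list(pair)], y)
                np.testing.assert_allclose([xi, xj], x_ref, atol=1e-9)
                assert rss == pytest.approx(rnorm**2, abs=1e-9)

    def test_estimates_within_three_standard_errors(self, fig5_reference, rng):
        """Over seeded Poisson replicates the pair fit is unbiased within 3 SE."""
        F = fig5_reference.matrix
        pair = (0, 1)
        scale = 900.0  # peak photons
        mix = 1.0 * F[:, 0] + 1.0 * F[:, 1]
        mu = mix * (scale / mix.max())
        amp = scale / mix.max()
        n_rep = 200
        est = np.empty((n_rep, 2))
        for k in range(n_rep):
            y = rng.poisson(mu).astype(float)
            xi, xj, _ = fit_binary_pair(y, fig5_reference, pair)
            est[k] = (xi, xj)
        se = est.std(axis=0) / np.sqrt(n_rep)
        bias = est.mean(axis=0) - amp
        assert np.all(np.abs(bias) < 3 * se + 0.02 * amp)

    def test_degenerate_pair_warns(self, small_layout):
        from specmix.spectra import FluorophoreSpectrum, build_reference_matrix

        v = np.array([1.0, 0.5, 0.2, 0.1, 0.05, 0.01])
        ref = build_reference_matrix(
            [
                FluorophoreSpectrum("a", v),
                FluorophoreSpectrum("b", v * 0.999999999),
                FluorophoreSpectrum("c", v[::-1].copy()),
            ],
            small_layout,
        )
        with pytest.warns(UserWarning, match="parallel"):
            fit_binary_pair(np.ones(6), ref, (0, 1))


class TestBinaryConstrainedUnmix:
    def test_noise_free_identifiability_all_pairs(self, toy_reference, rng):
        F = toy_reference.matrix
        b = np.full(6, 0.1)
        for pair in enumerate_pairs(4):
            y = 1.3 * F[:, pair[0]] + 0.8 * F[:, pair[1]] + b
            a = binary_constrained_unmix(y, toy_reference, b)
            assert a.pair == pair
            assert a.residual_ss < 1e-12 * float(y @ y)

    def test_all_candidates_evaluated(self, full_reference, rng):
        y = rng.uniform(0, 1, 120)
        a = binary_constrained_unmix(y, full_reference, keep_all_residuals=True)
        assert a.all_pair_residuals.shape == (120,)
        assert a.residual_ss == a.all_pair_residuals.min()
        assert np.all(a.residual_ss <= a.all_pair_residuals)

    def test_matches_brute_force_reenumeration(self, fig5_reference, rng):
        """Winning pair and residual equal an independent per-pair NNLS loop."""
        F = fig5_reference.matrix
        b = np.full(F.shape[0], 1.0)
        for _ in range(25):
            pair = tuple(sorted(rng.choice(4, 2, replace=False)))
            mix = rng.uniform(0.5, 2.0) * F[:, pair[0]] + rng.uniform(0.5, 2.0) * F[:, pair[1]]
            mu = mix * (400.0 / mix.max()) + 1.0
            y = rng.poisson(mu).astype(float)
            a = binary_constrained_unmix(y, fig5_reference, b)
            best = min(
                (
                    (scipy.optimize.nnls(F[:, list(p)], y - b)[1] ** 2, p)
                    for p in enumerate_pairs(4)
                ),
                key=lambda t: t[0],
            )
            assert a.pair == best[1]
            assert a.residual_ss == pytest.approx(best[0], rel=1e-9, abs=1e-9)

    def test_lexicographic_tie_break(self):
        """Two exactly tied pairs resolve to the lexicographically first."""
        F = np.eye(4)
        y = np.array([0.0, 0.0, 0.0, 1.0])  # pairs (0,3),(1,3),(2,3) all tie
        a = binary_constrained_unmix(y, F)
        assert a.pair == (0, 3)


class TestConfidencePearson:
    def test_perfect_and_anti_correlation(self, rng):
        y = rng.uniform(0, 1, 10)
        assert confidence_pearson(y, y) == pytest.approx(1.0)
        assert confidence_pearson(y, -y + 2.0) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        got = confidence_pearson(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 4.0, 5.0, 4.0])
        )
        assert got == pytest.approx(0.7181848464596079, abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert np.isnan(confidence_pearson(np.ones(4), np.array([1.0, 2, 3, 4])))


class TestClassifyImage:
    def test_empty_mask_gives_empty_table(self, toy_reference):
        from specmix.segmentation import SegmentationMask

        mask = SegmentationMask(np.zeros((8, 8), dtype=np.int32), 1.0, (0,))
        table = classify_image(np.zeros((6, 8, 8)), mask, toy_reference)
        assert len(table) == 0
        assert "confidence" in table.columns

    def test_assignments_on_synthetic_field(self, rng):
        """Every high-SNR particle gets its generating pair."""
        from specmix import simulation as sim
        from specmix.segmentation import compute_threshold, segment_particles
        from specmix.spectra import concatenate_stacks

        layout = sim.default_layout()
        spec = sim.SimulationSpec(sim.DEFAULT_FLUOROPHORES, layout, snr=30.0, seed=9)
        pairs = [(0, 1), (4, 5), (10, 15)]
        stacks, records = sim.generate_synthetic_image(
            spec, pairs, shape=(160, 160), n_cells=40
        )
        img = concatenate_stacks(stacks, layout)
        mask = segment_particles(img, compute_threshold(img))
        ref = sim.reference_matrix_from_models(sim.DEFAULT_FLUOROPHORES, layout)
        b = np.full(layout.m, spec.background_level)
        table = classify_image(img, mask, ref, b)
        score = sim.score_assignments(table, records)
        assert score["percent_correct"] == 100.0
        assert (table["confidence"] > 0.98).all()
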