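"""Unit and property tests for the orthogonalization screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trioscreen import (
    InputError,
    NamedMatrix,
    ScreenConfig,
    bonferroni_threshold,
    build_pair_basis,
    center_columns,
    p_from_t,
    partial_correlations,
    screen_triples,
    t_from_r,
)
from trioscreen.core import ScreenRecord

from conftest import random_named


class TestCenterColumns:
    def test_simple_column(self):
        c, means, ssq = center_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(c[:, 0], [-1, 0, 1])
        assert means[0] == 2.0 and ssq[0] == 2.0

    def test_constant_column_has_zero_sumsq(self):
        c, means, ssq = center_columns(np.full((3, 1), 5.0))
        np.testing.assert_array_equal(c, 0.0)
        assert ssq[0] == 0.0

    def test_random_matrix_centered_to_machine_precision(self, rng):
        M = rng.standard_normal((100, 10)) * 50 + 7
        c, _, _ = center_columns(M)
        assert np.abs(c.mean(axis=0)).max() < 1e-12


class TestPairBasis:
    def test_identical_binary_columns_are_degenerate(self):
        x = np.array([0.0, 1, 0, 1, 1, 0, 1, 0])
        xc = x - x.mean()
        # x == z and x binary: xz == x lies in span{1, x, z}
        basis = build_pair_basis(xc, xc, x * x, 1e-12)
        assert basis.degenerate

    def test_orthogonal_inputs_pass_through(self):
        n = 8
        x = np.zeros(n)
        x[:4] = 1.0
        z = np.tile([1.0, 0, 0, 1], 2)
        xc, zc = x - x.mean(), z - z.mean()
        basis = build_pair_basis(xc, zc, x * z, 1e-12)
        assert not basis.degenerate
        np.testing.assert_allclose(basis.q2, xc / np.linalg.norm(xc), atol=1e-12)
        assert abs(basis.q2 @ basis.q3) < 1e-10
        assert abs(basis.q2 @ basis.q4) < 1e-10
        assert abs(basis.q3 @ basis.q4) < 1e-10

    def test_random_basis_orthonormal_and_spans_checked(self, rng):
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        basis = build_pair_basis(x - x.mean(), z - z.mean(), x * z, 1e-12)
        assert not basis.degenerate
        ones = np.ones(50) / np.sqrt(50)
        for q in (basis.q2, basis.q3, basis.q4):
            assert abs(np.linalg.norm(q) - 1) < 1e-10
            assert abs(q @ ones) < 1e-8
        # q4 has no component left along 1, x or z
        for v in (np.ones(50), x, z):
            coef = (basis.q4 @ v) / np.linalg.norm(v)
            assert abs(coef) < 1e-8


class TestPartialCorrelations:
    def test_outcome_equal_to_q4_gives_r_one(self, rng):
        x, z = rng.standard_normal(30), rng.standard_normal(30)
        basis = build_pair_basis(x - x.mean(), z - z.mean(), x * z, 1e-12)
        Y = basis.q4[:, None]
        Yc, _, ssy = center_columns(Y)
        r = partial_correlations(Yc, ssy, basis)
        assert r[0] == pytest.approx(1.0, abs=1e-12)

    def test_outcome_in_design_span_is_skipped(self, rng):
        x, z = rng.standard_normal(30), rng.standard_normal(30)
        basis = build_pair_basis(x - x.mean(), z - z.mean(), x * z, 1e-12)
        y = 2.0 + 3.0 * x - z
        Yc, _, ssy = center_columns(y[:, None])
        r = partial_correlations(Yc, ssy, basis)
        assert np.isnan(r[0])

    def test_matches_brute_force_residualization(self, rng):
        """r must equal the correlation of the residuals of y and x*z on {1,x,z}."""
        n = 100
        x, z = rng.standard_normal(n), rng.standard_normal(n)
        y = rng.standard_normal(n)
        basis = build_pair_basis(x - x.mean(), z - z.mean(), x * z, 1e-12)
        Yc, _, ssy = center_columns(y[:, None])
        r = partial_correlations(Yc, ssy, basis)[0]

        D = np.column_stack([np.ones(n), x, z])
        res_y = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
        res_xz = x * z - D @ np.linalg.lstsq(D, x * z, rcond=None)[0]
        expected = (res_y @ res_xz) / np.sqrt((res_y @ res_y) * (res_xz @ res_xz))
        assert r == pytest.approx(expected, abs=1e-10)


class TestTandP:
    @pytest.mark.parametrize(
        "r, df, expected",
        [
            (0.0, 10, 0.0),
            (0.5, 16, 2.309401076758503),
            (-0.6, 21, -3.4369317712168796),
        ],
    )
    def test_t_from_r_values(self, r, df, expected):
        assert t_from_r(r, df) == pytest.approx(expected, rel=1e-12)

    def test_t_is_signed_infinity_at_perfect_correlation(self):
        assert t_from_r(1.0, 5) == np.inf
        assert t_from_r(-1.0, 5) == -np.inf

    @pytest.mark.parametrize(
        "t, df, expected",
        [
            (0.0, 7, 1.0),
            (2.0, 10, 0.07338803477074037),  # via the incomplete-beta identity
            (np.inf, 10, 0.0),
        ],
    )
    def test_p_from_t_values(self, t, df, expected):
        assert p_from_t(t, df) == pytest.approx(expected, rel=1e-9, abs=1e-300)

    def test_p_is_symmetric_in_t(self):
        assert p_from_t(2.5, 12) == p_from_t(-2.5, 12)

    def test_df_must_be_positive(self):
        with pytest.raises(InputError):
            t_from_r(0.5, 0)
        with pytest.raises(InputError):
            p_from_t(1.0, 0)

    @settings(derandomize=True, max_examples=50)
    @given(
        r1=st.floats(0.0, 0.999),
        r2=st.floats(0.0, 0.999),
        df=st.integers(1, 200),
    )
    def test_p_monotone_decreasing_in_abs_t(self, r1, r2, df):
        t1, t2 = t_from_r(r1, df), t_from_r(r2, df)
        p1, p2 = p_from_t(t1, df), p_from_t(t2, df)
        if abs(t1) < abs(t2):
            assert p1 >= p2
        elif abs(t1) > abs(t2):
            assert p1 <= p2

    def test_p_strictly_decreasing_away_from_saturation(self):
        ps = [p_from_t(t, 30) for t in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestBonferroni:
    def test_single_design(self):
        assert bonferroni_threshold(0.05, [(10, 10, 10)]) == pytest.approx(5e-5)

    def test_identity_design(self):
        assert bonferroni_threshold(0.05, [(1, 1, 1)]) == 0.05

    def test_two_platform_genome_scale_design(self):
        thr = bonferroni_threshold(0.05, [(345372, 16, 117), (345372, 376, 6406)])
        assert thr == pytest.approx(6.01e-14, rel=5e-3)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InputError):
            bonferroni_threshold(0.05, [])
        with pytest.raises(InputError):
            bonferroni_threshold(0.05, [(0, 5, 5)])
        with pytest.raises(InputError):
            bonferroni_threshold(1.5, [(2, 2, 2)])


class TestScreenTriples:
    def test_emits_full_cross_product_at_threshold_one(self, rng):
        X = random_named(rng, 50, 2, "x")
        Y = random_named(rng, 50, 3, "y")
        Z = random_named(rng, 50, 2, "z")
        res = screen_triples(X, Y, Z, ScreenConfig(p_threshold=1.0))
        assert len(res.records) == 12
        assert res.n_candidates == 12
        assert all(rec.df == 46 for rec in res.records)

    def test_constant_outcome_column_is_skipped_and_counted(self, rng):
        X = random_named(rng, 30, 2, "x")
        Z = random_named(rng, 30, 2, "z")
        Yv = rng.standard_normal((30, 2))
        Yv[:, 1] = 3.14
        Y = NamedMatrix(Yv, X.row_ids, ["y0", "yconst"])
        res = screen_triples(X, Y, Z, ScreenConfig())
        assert all(rec.y_name == "y0" for rec in res.records)
        assert res.skipped_outcomes == 4  # constant y for each of 4 (x,z) pairs

    def test_degenerate_pair_skipped_not_fatal(self, rng):
        xv = rng.standard_normal((30, 2))
        X = NamedMatrix(xv, [f"o{i}" for i in range(30)], ["x0", "x1"])
        Z = NamedMatrix(xv.copy(), X.row_ids, ["z0", "z1"])  # z == x columns
        Y = random_named(rng, 30, 2, "y")
        Y = NamedMatrix(Y.values, X.row_ids, Y.col_names)
        res = screen_triples(X, Y, Z, ScreenConfig())
        assert res.degenerate_pairs == 2  # (x0,z0) and (x1,z1) collinear
        assert len(res.records) == 2 * 2 * 2 - 2 * 2

    def test_row_mismatch_errors_name_matrices(self, rng):
        X = random_named(rng, 30, 2, "x")
        Y = random_named(rng, 29, 2, "y")
        Z = random_named(rng, 30, 2, "z")
        with pytest.raises(InputError, match="row count mismatch"):
            screen_triples(X, Y, Z)
        Y2 = random_named(rng, 30, 2, "y")
        Y2 = NamedMatrix(Y2.values, list(reversed(X.row_ids)), Y2.col_names)
        with pytest.raises(InputError, match="row ID"):
            screen_triples(X, Y2, Z)

    def test_too_few_observations_rejected(self, rng):
        X = random_named(rng, 4, 1, "x")
        Y = random_named(rng, 4, 1, "y")
        Z = random_named(rng, 4, 1, "z")
        with pytest.raises(InputError, match="at least 5"):
            screen_triples(X, Y, Z)

    def test_threshold_monotonicity(self, small_triple):
        X, Y, Z = small_triple
        loose = screen_triples(X, Y, Z, ScreenConfig(p_threshold=1.0))
        tight = screen_triples(X, Y, Z, ScreenConfig(p_threshold=0.3))
        loose_keys = {(r.x_name, r.y_name, r.z_name): r.p for r in loose.records}
        assert all(r.p <= 0.3 for r in tight.records)
        for r in tight.records:
            assert loose_keys[(r.x_name, r.y_name, r.z_name)] == r.p
        assert {k for k, p in loose_keys.items() if p <= 0.3} == {
            (r.x_name, r.y_name, r.z_name) for r in tight.records
        }

    def test_canonical_output_order(self, small_triple):
        X, Y, Z = small_triple
        res = screen_triples(X, Y, Z, ScreenConfig())
        keys = [(r.x_index, r.z_index, r.y_index) for r in res.records]
        assert keys == sorted(keys)

    def test_worker_count_does_not_change_results(self, rng):
        X = random_named(rng, 60, 5, "x")
        Y = random_named(rng, 60, 4, "y")
        Z = random_named(rng, 60, 6, "z")
        base = screen_triples(X, Y, Z, ScreenConfig(n_workers=1))
        for w in (2, 4):
            other = screen_triples(X, Y, Z, ScreenConfig(n_workers=w))
            assert len(other.records) == len(base.records)
            for a, b in zip(base.records, other.records):
                assert (a.x_name, a.y_name, a.z_name) == (b.x_name, b.y_name, b.z_name)
                assert abs(a.p - b.p) <= 1e-12
                assert abs(a.r - b.r) <= 1e-12

    def test_xz_symmetry(self, rng):
        X = random_named(rng, 40, 3, "x")
        Y = random_named(rng, 40, 2, "y")
        Z = random_named(rng, 40, 4, "z")
        fwd = screen_triples(X, Y, Z, ScreenConfig())
        rev = screen_triples(Z, Y, X, ScreenConfig())
        fwd_map = {(r.x_name, r.y_name, r.z_name): r.p for r in fwd.records}
        rev_map = {(r.z_name, r.y_name, r.x_name): r.p for r in rev.records}
        assert fwd_map.keys() == rev_map.keys()
        for k in fwd_map:
            assert fwd_map[k] == pytest.approx(rev_map[k], abs=1e-12)

    def test_affine_invariance_of_p_values(self, rng):
        n = 60
        X = random_named(rng, n, 2, "x")
        Y = random_named(rng, n, 2, "y")
        Z = random_named(rng, n, 2, "z")
        base = screen_triples(X, Y, Z, ScreenConfig())
        X2 = NamedMatrix(-3.0 * X.values + 7.0, X.row_ids, X.col_names)
        Y2 = NamedMatrix(0.5 * Y.values - 2.0, Y.row_ids, Y.col_names)
        Z2 = NamedMatrix(10.0 * Z.values + 1.0, Z.row_ids, Z.col_names)
        other = screen_triples(X2, Y2, Z2, ScreenConfig())
        for a, b in zip(base.records, other.records):
            assert a.p == pytest.approx(b.p, rel=1e-10, abs=1e-12)

    def test_explicit_orientation_matches_auto(self, rng):
        X = random_named(rng, 40, 3, "x")
        Y = random_named(rng, 40, 2, "y")
        Z = random_named(rng, 40, 5, "z")
        auto = screen_triples(X, Y, Z, ScreenConfig())
        pinned = screen_triples(X, Y, Z, ScreenConfig(), outer_over="z")
        assert [r.p for r in auto.records] == [r.p for r in pinned.records]


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(InputError):
            ScreenConfig(p_threshold=0.0)
        with pytest.raises(InputError):
            ScreenConfig(p_threshold=1.5)
        with pytest.raises(InputError):
            ScreenConfig(degeneracy_tol=0.0)
        with pytest.raises(InputError):
            ScreenConfig(n_workers=0)

    def test_named_matrix_invariants(self):
        with pytest.raises(InputError):
            NamedMatrix(np.zeros((3, 2)), ["a", "a", "b"], ["c1", "c2"])
        with pytest.raises(InputError):
            NamedMatrix(np.zeros((3, 2)), ["a", "b", "c"], ["c1", ""])
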