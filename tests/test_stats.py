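"""Paired tests, FDR, partial correlations, and MDS oracles."""

import numpy as np
import pandas as pd
import pytest

from speechstate.stats import (bh_fdr, mds_embed, paired_feature_tests,
                               partial_correlations, wilcoxon_paired)


class TestWilcoxon:
    def test_five_positive_differences_exact(self):
        res = wilcoxon_paired(np.array([3., 1, 2, 5, 4]), np.zeros(5))
        assert res.statistic == pytest.approx(15.0)
        assert res.p_value == pytest.approx(0.0625, rel=1e-9)

    def test_sign_flip_symmetry(self):
        a = np.array([3., 1, 2, 5, 4, 0.5, 2.5])
        p1 = wilcoxon_paired(a, np.zeros(7)).p_value
        p2 = wilcoxon_paired(np.zeros(7), a).p_value
        assert p1 == pytest.approx(p2)

    def test_antisymmetric_differences_not_significant(self):
        d = np.array([1., -1, 2, -2, 3, -3])
        res = wilcoxon_paired(d, np.zeros(6))
        assert res.p_value > 0.9

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_paired(np.ones(6), np.ones(6))
        assert res.degenerate and res.p_value == 1.0

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(40) + 1.0
        res = wilcoxon_paired(d, np.zeros(40))
        assert res.p_value < 1e-4


class TestBH:
    def test_step_up_example(self):
        reject, q = bh_fdr(np.array([0.001, 0.01, 0.02, 0.04, 0.2]))
        assert list(reject) == [True, True, True, True, False]

    def test_all_ones_no_rejections(self):
        reject, _ = bh_fdr(np.ones(10))
        assert not reject.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    def test_bh_rejections_superset_of_bonferroni(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=50) ** 2
            bh_rej, _ = bh_fdr(p, q=0.05)
            bonf = p <= 0.05 / len(p)
            assert np.all(bh_rej[bonf])


class TestPairedFeatureTests:
    def test_tidy_output_with_fdr(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(12):
            for cond in ("A", "B"):
                shift = 3.0 if cond == "A" else 0.0
                rows.append([f"s{i}", cond, "T",
                             rng.standard_normal() + shift,
                             rng.standard_normal()])
        table = pd.DataFrame(rows, columns=["subject_id", "condition",
                                            "task", "A-big", "A-null"])
        res = paired_feature_tests(table, "A", "B", "T")
        assert set(res["feature"]) == {"A-big", "A-null"}
        big = res[res["feature"] == "A-big"].iloc[0]
        assert big["reject"] and big["q"] < 0.05


class TestPartialCorrelations:
    def test_full_shrinkage_gives_identity_off_diagonal(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 4))
        pc = partial_correlations(X, shrinkage=1.0).to_numpy()
        off = pc[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(pc), 1.0)

    def test_common_cause_matches_residual_oracle(self):
        rng = np.random.default_rng(4)
        n = 2000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x3 = x1 + x2 + 0.1 * rng.standard_normal(n)
        X = np.column_stack([x1, x2, x3])
        pc = partial_correlations(X, shrinkage=0.0)
        # oracle: correlation of the residuals of x1 and x2 regressed on x3
        def resid(v, c):
            beta = np.polyfit(c, v, 1)
            return v - np.polyval(beta, c)
        oracle = np.corrcoef(resid(x1, x3), resid(x2, x3))[0, 1]
        assert oracle < -0.5
        assert pc.iloc[0, 1] == pytest.approx(oracle, abs=0.05)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((2000, 6))
        pc = partial_correlations(X).to_numpy()
        off = pc[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.08

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 5))
        scale = np.array([3.0, 0.1, 7.0, 1.0, 0.01])
        shift = np.array([-2.0, 5.0, 0.0, 100.0, 1.0])
        p1 = partial_correlations(X).to_numpy()
        p2 = partial_correlations(X * scale + shift).to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_singular_unshrunk_case_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((4, 6))  # n <= p
        with pytest.raises(ValueError, match="shrinkage"):
            partial_correlations(X, shrinkage=0.0)


def _mat(values, names=("a", "b")):
    return pd.DataFrame(np.asarray(values, float), index=list(names),
                        columns=list(names))


class TestMDS:
    def test_identical_matrices_coincide(self):
        m = _mat([[1, 0.3], [0.3, 1]])
        m2 = _mat([[1, -0.5], [-0.5, 1]])
        emb = mds_embed([m, m.copy(), m2])
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1],
                                   atol=1e-9)

    def test_collinear_distances_recover_one_dimension(self):
        base = np.eye(2)
        E = np.array([[0.0, 1 / np.sqrt(2)], [1 / np.sqrt(2), 0.0]])
        mats = [_mat(base + t * E) for t in (0.0, 1.0, 3.0)]
        emb = mds_embed(mats)
        assert np.allclose(emb.coordinates[:, 1], 0.0, atol=1e-8)
        d01 = np.linalg.norm(emb.coordinates[0] - emb.coordinates[1])
        assert d01 == pytest.approx(1.0, abs=1e-8)

    def test_torgerson_exact_on_euclidean_configuration(self):
        # matrices spanning a plane: Frobenius distances are Euclidean
        rng = np.random.default_rng(8)
        E1 = np.array([[1.0, 0.0], [0.0, -1.0]]) / np.sqrt(2)
        E2 = np.array([[0.0, 1.0], [1.0, 0.0]]) / np.sqrt(2)
        pts = rng.standard_normal((5, 2))
        mats = [_mat(x * E1 + y * E2) for x, y in pts]
        emb = mds_embed(mats)
        D_in = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        D_out = np.linalg.norm(emb.coordinates[:, None]
                               - emb.coordinates[None], axis=2)
        np.testing.assert_allclose(D_out, D_in, atol=1e-8)
        assert emb.stress == pytest.approx(0.0, abs=1e-8)

    def test_order_invariance_of_geometry(self):
        rng = np.random.default_rng(9)
        E1 = np.array([[1.0, 0.0], [0.0, -1.0]]) / np.sqrt(2)
        E2 = np.array([[0.0, 1.0], [1.0, 0.0]]) / np.sqrt(2)
        pts = rng.standard_normal((4, 2))
        mats = [_mat(x * E1 + y * E2) for x, y in pts]
        emb1 = mds_embed(mats)
        perm = [2, 0, 3, 1]
        emb2 = mds_embed([mats[i] for i in perm])
        D1 = np.linalg.norm(emb1.coordinates[:, None]
                            - emb1.coordinates[None], axis=2)
        D2 = np.linalg.norm(emb2.coordinates[:, None]
                            - emb2.coordinates[None], axis=2)
        np.testing.assert_allclose(D2, D1[np.ix_(perm, perm)], atol=1e-8)

    def test_mismatched_feature_lists_rejected(self):
        with pytest.raises(ValueError):
            mds_embed([_mat(np.eye(2)), _mat(np.eye(2)),
                       _mat(np.eye(2), names=("x", "y"))])

    def test_centered_at_origin(self):
        mats = [_mat(np.eye(2) * s) for s in (1.0, 2.0, 4.0)]
        emb = mds_embed(mats)
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0.0,
                                   atol=1e-9)
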