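"""Preprocessing, cosine kernel, and KPCA feature extraction."""

import math

import numpy as np
import pytest

from fegfs.features import (ExpressionMatrix, build_feature_matrix,
                            cosine_kernel, filter_noise_genes, kpca_reduce,
                            log_transform, read_expression, retention_ratio,
                            write_expression)
from fegfs.repetition import FunctionalGeneSet


def expr_matrix(values, log_transformed=False):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_ids=[f"g{j}" for j in range(values.shape[1])],
        log_transformed=log_transformed,
    )


def kpca_oracle(X, ratio):
    """Brute-force KPCA: explicit centering matrix + full eigendecomposition."""
    n = X.shape[0]
    K = cosine_kernel(X)
    H = np.eye(n) - np.ones((n, n)) / n
    Kc = H @ K @ H
    lam, V = np.linalg.eigh(Kc)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    keep = lam > 1e-10 * max(lam[0], 0.0)
    lam, V = lam[keep], V[:, keep]
    cum = np.cumsum(lam)
    d = int(np.searchsorted(cum, ratio * cum[-1]) + 1)
    d = max(1, min(d, lam.size))
    return V[:, :d] * np.sqrt(lam[:d])


def assert_equal_up_to_sign(A, B, tol=1e-8):
    assert A.shape == B.shape
    for k in range(A.shape[1]):
        assert (np.allclose(A[:, k], B[:, k], atol=tol)
                or np.allclose(A[:, k], -B[:, k], atol=tol))


class TestNoiseFilter:
    def test_threshold_nine_at_301_cells(self):
        # 3 * floor(0.01 * 301) = 9: expressed in 8 cells -> removed, 9 -> kept
        values = np.zeros((301, 2))
        values[:8, 0] = 5.0
        values[:9, 1] = 5.0
        out = filter_noise_genes(expr_matrix(values))
        assert out.gene_ids == ["g1"]

    def test_small_dataset_floor_clamped_to_one(self):
        # 50 cells: floor(0.5) = 0 clamps to 1, threshold 3
        values = np.zeros((50, 2))
        values[:2, 0] = 1.0
        values[:3, 1] = 1.0
        out = filter_noise_genes(expr_matrix(values))
        assert out.gene_ids == ["g1"]

    def test_all_positive_matrix_unchanged(self, rng):
        e = expr_matrix(rng.lognormal(size=(30, 5)))
        out = filter_noise_genes(e)
        assert out.gene_ids == e.gene_ids
        np.testing.assert_array_equal(out.values, e.values)

    def test_everything_removed_raises(self):
        with pytest.raises(ValueError, match="every gene"):
            filter_noise_genes(expr_matrix(np.zeros((40, 3))))

    def test_refuses_log_transformed_input(self):
        e = expr_matrix(np.ones((10, 2)), log_transformed=True)
        with pytest.raises(ValueError):
            filter_noise_genes(e)


class TestLogTransform:
    def test_decade_values(self):
        e = log_transform(expr_matrix([[0.0, 9.0, 99.0]]))
        np.testing.assert_allclose(e.values, [[0.0, 1.0, 2.0]])
        assert e.log_transformed

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(expr_matrix([[-1.0]]))


class TestRetentionRatio:
    @pytest.mark.parametrize("n,expected", [
        (301, 0.40), (1000, 0.40), (1001, 0.60), (2717, 0.60),
        (3000, 0.60), (3001, 0.80), (3005, 0.80),
    ])
    def test_size_brackets(self, n, expected):
        assert retention_ratio(n) == expected

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            retention_ratio(1)


class TestCosineKernel:
    def test_identical_rows_give_one(self):
        K = cosine_kernel(np.array([[1.0, 2.0], [2.0, 4.0]]))
        assert K[0, 1] == pytest.approx(1.0)

    def test_orthogonal_rows_give_zero(self):
        K = cosine_kernel(np.array([[1.0, 0.0], [0.0, 3.0]]))
        assert K[0, 1] == pytest.approx(0.0)

    def test_hand_value(self):
        K = cosine_kernel(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert K[0, 1] == pytest.approx(1 / math.sqrt(2))

    def test_zero_row_zeroed_with_unit_diagonal(self):
        K = cosine_kernel(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert K[0, 1] == 0.0 and K[1, 0] == 0.0
        assert K[0, 0] == 1.0

    def test_invariant_to_positive_row_rescaling(self, rng):
        X = rng.normal(size=(6, 4))
        scales = rng.uniform(0.1, 10.0, size=6)
        np.testing.assert_allclose(cosine_kernel(X),
                                   cosine_kernel(X * scales[:, None]),
                                   atol=1e-12)

    def test_symmetric_bounded(self, rng):
        K = cosine_kernel(rng.normal(size=(8, 5)))
        np.testing.assert_allclose(K, K.T)
        assert np.all(np.abs(K) <= 1.0 + 1e-12)


class TestKpcaReduce:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            X = rng.lognormal(size=(rng.integers(4, 15),
                                    rng.integers(3, 10)))
            for ratio in (0.4, 0.8, 1.0):
                assert_equal_up_to_sign(kpca_reduce(X, ratio),
                                        kpca_oracle(X, ratio))

    def test_rank_one_kernel_gives_single_component(self, rng):
        # two distinct cell states -> centered cosine kernel has rank 1
        a, b = rng.lognormal(size=(2, 6))
        X = np.vstack([a, a, b, b])
        assert kpca_reduce(X, 0.99).shape[1] == 1

    def test_ratio_one_keeps_all_positive_eigenvalues(self, rng):
        X = rng.lognormal(size=(9, 7))
        K = cosine_kernel(X)
        H = np.eye(9) - np.ones((9, 9)) / 9
        lam = np.linalg.eigvalsh(H @ K @ H)
        n_pos = int((lam > 1e-10 * lam.max()).sum())
        assert kpca_reduce(X, 1.0).shape[1] == n_pos

    def test_projection_columns_uncorrelated(self, rng):
        P = kpca_reduce(rng.lognormal(size=(12, 8)), 1.0)
        gram = P.T @ P
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_deterministic_and_sign_fixed(self, rng):
        X = rng.lognormal(size=(10, 6))
        P1, P2 = kpca_reduce(X, 0.6), kpca_reduce(X, 0.6)
        np.testing.assert_array_equal(P1, P2)
        for k in range(P1.shape[1]):
            assert P1[np.argmax(np.abs(P1[:, k])), k] > 0

    def test_count_mode(self, rng):
        X = rng.lognormal(size=(10, 6))
        full = kpca_reduce(X, 1.0).shape[1]
        half = kpca_reduce(X, 0.5, mode="count").shape[1]
        assert half == math.ceil(0.5 * full)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            kpca_reduce(np.ones((1, 3)), 0.5)


class TestBuildFeatureMatrix:
    def make_expr(self, rng, n=12, g=9):
        return log_transform(expr_matrix(rng.lognormal(size=(n, g))))

    def set_of(self, name, gene_ids):
        return FunctionalGeneSet(id=name, genes=frozenset(gene_ids),
                                 source_terms=frozenset({name}))

    def test_single_full_set_equals_whole_matrix_kpca(self, rng):
        e = self.make_expr(rng)
        fm = build_feature_matrix(e, [self.set_of("all", e.gene_ids)], 0.7)
        np.testing.assert_allclose(fm.values, kpca_reduce(e.values, 0.7))

    def test_disjoint_sets_concatenate(self, rng):
        e = self.make_expr(rng)
        s1 = self.set_of("left", e.gene_ids[:4])
        s2 = self.set_of("right", e.gene_ids[4:])
        fm = build_feature_matrix(e, [s1, s2], 0.7)
        d1 = kpca_reduce(e.values[:, :4], 0.7).shape[1]
        d2 = kpca_reduce(e.values[:, 4:], 0.7).shape[1]
        assert fm.values.shape[1] == d1 + d2
        assert fm.block_index == {"left": (0, d1), "right": (d1, d1 + d2)}

    def test_blocks_match_per_set_oracle(self, rng):
        e = self.make_expr(rng)
        sets = [self.set_of(f"s{i}", e.gene_ids[3 * i:3 * i + 3])
                for i in range(3)]
        fm = build_feature_matrix(e, sets, 0.5)
        for i, s in enumerate(sets):
            lo, hi = fm.block_index[s.id]
            cols = [e.gene_ids.index(g) for g in sorted(s.genes)]
            assert_equal_up_to_sign(fm.values[:, lo:hi],
                                    kpca_oracle(e.values[:, cols], 0.5))

    def test_unknown_gene_set_skipped(self, rng):
        e = self.make_expr(rng)
        good = self.set_of("good", e.gene_ids[:5])
        alien = self.set_of("alien", ["zz1", "zz2"])
        fm = build_feature_matrix(e, [good, alien], 0.6)
        assert list(fm.block_index) == ["good"]

    def test_requires_log_transform(self, rng):
        e = expr_matrix(rng.lognormal(size=(6, 4)))
        with pytest.raises(ValueError, match="log"):
            build_feature_matrix(e, [self.set_of("all", e.gene_ids)], 0.5)

    def test_no_overlapping_set_raises(self, rng):
        e = self.make_expr(rng)
        with pytest.raises(ValueError):
            build_feature_matrix(e, [self.set_of("alien", ["zz"])], 0.5)


class TestExpressionIO:
    def test_csv_round_trip(self, tmp_path, rng):
        e = expr_matrix(rng.lognormal(size=(5, 4)))
        path = tmp_path / "expr.csv"
        write_expression(e, path)
        back = read_expression(path)
        np.testing.assert_allclose(back.values, e.values)
        assert back.cell_ids == e.cell_ids
        assert back.gene_ids == e.gene_ids

    def test_transpose_flag(self, tmp_path, rng):
        e = expr_matrix(rng.lognormal(size=(5, 4)))
        path = tmp_path / "expr.csv"
        write_expression(e, path)
        t = read_expression(path, transpose=True)
        assert t.cell_ids == e.gene_ids
        np.testing.assert_allclose(t.values, e.values.T)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(values=np.ones((2, 2)),
                             cell_ids=["a", "a"], gene_ids=["g1", "g2"])
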