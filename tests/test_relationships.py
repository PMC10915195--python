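"""A, G22, blending/scaling and H against closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_pedigree
from ssgwas.io import DataError, GenotypeMatrix, PedigreeTable
from ssgwas.relationships import (BlendParams, blend_and_scale, build_A,
                                  build_G22, build_H_inverse,
                                  build_relationships)


def recursive_A_oracle(ped):
    """Independent recursive definition of the numerator relationships:
    a_ij = 0.5 (a_{sire(i),j} + a_{dam(i),j}), a_ii = 1 + 0.5 a_{s,d}."""
    parents = ped.parent_indices()
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def a(i, j):
        if i < j:
            return a(j, i)
        s, d = parents[i]
        if i == j:
            return 1.0 + (0.5 * a(max(s, d), min(s, d)) if s >= 0 and d >= 0 else 0.0)
        out = 0.0
        if s >= 0:
            out += 0.5 * a(max(s, j) if s != j else j, min(s, j))
        if d >= 0:
            out += 0.5 * a(max(d, j) if d != j else j, min(d, j))
        return out

    n = len(ped)
    return np.array([[a(max(i, j), min(i, j)) for j in range(n)] for i in range(n)])


class TestBuildA:
    def test_unrelated_founders_identity(self):
        bf = pd.DataFrame(index=pd.Index(["a", "b", "c"], name="animal"))
        ped = PedigreeTable(["a", "b", "c"], ["0"] * 3, ["0"] * 3, bf)
        np.testing.assert_array_equal(build_A(ped), np.eye(3))

    def test_trio_closed_form(self, trio_pedigree):
        A = build_A(trio_pedigree)
        assert A[2, 0] == A[2, 1] == 0.5
        assert A[2, 2] == 1.0
        assert A[0, 1] == 0.0

    def test_full_sib_mating_inbreeding(self):
        # z is the offspring of full sibs o1 x o2: F_z = 0.25
        bf = pd.DataFrame(index=pd.Index(["s", "d", "o1", "o2", "z"], name="animal"))
        ped = PedigreeTable(["s", "d", "o1", "o2", "z"],
                           ["0", "0", "s", "s", "o1"],
                           ["0", "0", "d", "d", "o2"], bf)
        A = build_A(ped)
        assert A[4, 4] == pytest.approx(1.25)

    def test_matches_recursive_oracle_on_random_pedigrees(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            ped = random_pedigree(rng)
            np.testing.assert_allclose(build_A(ped), recursive_A_oracle(ped),
                                       atol=1e-12)


def make_geno(codes, chrom="1"):
    codes = np.asarray(codes, dtype=float)
    mm = pd.DataFrame({"marker": [f"m{j}" for j in range(codes.shape[1])],
                       "chrom": chrom, "pos": np.arange(1, codes.shape[1] + 1) * 10})
    return GenotypeMatrix([f"a{i}" for i in range(codes.shape[0])], codes, mm)


class TestG22:
    def test_hand_example(self):
        # codes [[0,2],[2,0]]: p = (.5,.5), Z = [[-1,1],[1,-1]], s = 1
        G, p = build_G22(make_geno([[0, 2], [2, 0]]))
        np.testing.assert_allclose(p, [0.5, 0.5])
        np.testing.assert_allclose(G, [[2, -2], [-2, 2]], atol=1e-12)

    def test_brute_force_product(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(6, 20)).astype(float)
        G, p = build_G22(make_geno(codes))
        Z = codes - 2 * p
        s = 2 * np.sum(p * (1 - p))
        np.testing.assert_allclose(G, Z @ Z.T / s, atol=1e-12)

    def test_heterozygous_column_centered_to_zero(self):
        codes = np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 1.0]])
        G, p = build_G22(make_geno(codes))
        Z = codes - 2 * p
        np.testing.assert_allclose(Z[:, 0], 0.0, atol=1e-12)

    def test_symmetry_and_order_invariance(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(5, 30)).astype(float)
        G, _ = build_G22(make_geno(codes))
        np.testing.assert_allclose(G, G.T)
        assert np.trace(G) >= 0
        perm = rng.permutation(5)
        G2, _ = build_G22(make_geno(codes[perm]))
        np.testing.assert_allclose(G2, G[np.ix_(perm, perm)], atol=1e-12)

    def test_monomorphic_fatal(self):
        with pytest.raises(DataError, match="monomorphic"):
            build_G22(make_geno([[2, 2], [2, 2]]))


class TestBlendScale:
    def test_fixed_point(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((4, 4))
        A22 = M @ M.T / 4 + np.eye(4)
        out = blend_and_scale(A22.copy(), A22)
        np.testing.assert_allclose(out, A22, atol=1e-10)

    def test_identity_when_already_matched(self):
        rng = np.random.default_rng(4)
        M = rng.standard_normal((5, 5))
        G = M @ M.T / 5
        out = blend_and_scale(G, G, BlendParams(alpha=1.0, beta=0.0))
        np.testing.assert_allclose(out, G, atol=1e-10)

    def test_means_matched_after_scaling(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((5, 8))
        G = M @ M.T / 8
        A22 = np.eye(5) + 0.1
        # independent solve of the 2x2 system
        off = ~np.eye(5, dtype=bool)
        a = (np.diag(A22).mean() - A22[off].mean()) / (np.diag(G).mean() - G[off].mean())
        b = np.diag(A22).mean() - a * np.diag(G).mean()
        G_scaled_oracle = a * G + b
        out = blend_and_scale(G, A22, BlendParams(alpha=1.0, beta=0.0))
        np.testing.assert_allclose(out, G_scaled_oracle, atol=1e-10)
        assert np.diag(out).mean() == pytest.approx(np.diag(A22).mean(), abs=1e-10)
        assert out[off].mean() == pytest.approx(A22[off].mean(), abs=1e-10)

    def test_blend_restores_positive_definiteness(self):
        # rank-deficient G becomes PD after beta * A22 is mixed in
        z = np.array([[1.0, -1.0, 0.0]]).T
        G = z @ z.T
        A22 = np.eye(3)
        out = blend_and_scale(G, A22)
        assert np.linalg.eigvalsh(out).min() > 0

    def test_constant_G_fatal(self):
        with pytest.raises(DataError, match="singular"):
            blend_and_scale(np.ones((3, 3)), np.eye(3))


class TestH:
    def test_no_genotypes_H_equals_A(self):
        rng = np.random.default_rng(6)
        ped = random_pedigree(rng, 15)
        A = build_A(ped)
        H, Hinv = build_H_inverse(A, np.empty(0, dtype=int), None)
        np.testing.assert_allclose(H, A)
        np.testing.assert_allclose(Hinv @ A, np.eye(len(A)), atol=1e-8)

    def test_gstar_equals_A22_degenerates_to_A(self):
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, 20)
        A = build_A(ped)
        gi = np.arange(len(A))  # all genotyped
        H, Hinv = build_H_inverse(A, gi, A[np.ix_(gi, gi)])
        np.testing.assert_allclose(H, A, atol=1e-10)
        np.testing.assert_allclose(Hinv, np.linalg.inv(A), atol=1e-8)

    def test_block_H_and_corrected_inverse_are_mutual(self):
        # 12-animal random pedigree, 5 genotyped: H from the 4-block dense
        # formula and H^-1 from the correction identity must invert each other
        rng = np.random.default_rng(8)
        for _ in range(5):
            ped = random_pedigree(rng, 12)
            n = len(ped)
            if n < 6:
                continue
            A = build_A(ped)
            gi = np.sort(rng.choice(n, size=5, replace=False))
            codes = rng.integers(0, 3, size=(5, 40)).astype(float)
            G, _ = build_G22(make_geno(codes))
            Gs = blend_and_scale(G, A[np.ix_(gi, gi)])
            H, Hinv = build_H_inverse(A, gi, Gs)
            np.testing.assert_allclose(H @ Hinv, np.eye(n), atol=1e-6)

    def test_build_relationships_bundle(self, small_sim):
        rel = build_relationships(small_sim.pedigree, small_sim.genotypes)
        assert rel.G22_star is not None
        assert rel.A.shape[0] == len(small_sim.pedigree)
        np.testing.assert_allclose(rel.H[np.ix_(rel.genotyped_idx, rel.genotyped_idx)],
                                   rel.G22_star, atol=1e-10)
        assert np.diag(rel.A).min() >= 1.0
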