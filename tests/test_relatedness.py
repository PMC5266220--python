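"""Relationship-matrix construction against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from sgekit import (
    GenotypeMatrix,
    Pedigree,
    RelationshipMatrix,
    blend_G,
    blend_constants,
    build_H,
    genomic_G,
    pedigree_A,
    sample_var,
    scale_components,
)
from sgekit.relatedness import DegenerateDesignError, PedigreeError
from sgekit.simulate import PopulationSpec, assign_cages, simulate_population


def recursive_A(ped: Pedigree) -> np.ndarray:
    """Independent oracle: Wright's coefficients by direct recursion."""
    from functools import lru_cache

    sire, dam = ped.sire, ped.dam

    @lru_cache(maxsize=None)
    def a(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        # recurse on the later individual in topological order
        oi = int(np.where(ped.order == i)[0][0])
        oj = int(np.where(ped.order == j)[0][0])
        if i == j:
            return 1.0 + 0.5 * a(*sorted((sire[i], dam[i])))
        if oi < oj:
            i, j = j, i
        return 0.5 * (a(j, sire[i]) + a(j, dam[i]))

    n = ped.n
    return np.array([[a(*sorted((i, j))) for j in range(n)] for i in range(n)])


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = Pedigree(ids=["a", "b"], sire=[-1, -1], dam=[-1, -1])
        assert np.array_equal(pedigree_A(ped).values, np.eye(2))

    def test_parent_offspring_half(self):
        ped = Pedigree(ids=["s", "d", "o"], sire=[-1, -1, 0], dam=[-1, -1, 1])
        A = pedigree_A(ped).values
        assert A[0, 2] == 0.5
        assert A[2, 2] == 1.0

    def test_full_sib_mating_inbreeding(self, textbook_pedigree):
        A = pedigree_A(textbook_pedigree).values
        assert A[2, 3] == 0.5  # full sibs
        assert A[4, 4] == 1.25  # F = 0.25 from the full-sib mating

    def test_matches_recursive_oracle_on_random_pedigrees(self, rng):
        for trial in range(5):
            n = int(rng.integers(5, 13))
            sire = np.full(n, -1)
            dam = np.full(n, -1)
            for i in range(2, n):
                if rng.random() < 0.8:
                    sire[i], dam[i] = rng.choice(i, size=2, replace=False)
            ped = Pedigree(ids=[f"i{k}" for k in range(n)], sire=sire, dam=dam)
            A = pedigree_A(ped).values
            np.testing.assert_allclose(A, recursive_A(ped), rtol=0, atol=1e-12)
            assert np.all(np.diag(A) >= 1.0)

    def test_cycle_rejected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(ids=["a", "b"], sire=[1, 0], dam=[-1, -1])

    def test_unknown_parent_id_rejected(self):
        df = pd.DataFrame({"id": ["a"], "sire": ["ghost"], "dam": ["0"]})
        with pytest.raises(PedigreeError, match="ghost"):
            Pedigree.from_frame(df)


class TestGenomicG:
    def test_single_locus_hand_case(self):
        geno = GenotypeMatrix(ids=["a", "b"], loci=["l1"],
                              dosages=np.array([[2.0], [0.0]]))
        G = genomic_G(geno).values
        np.testing.assert_allclose(G, [[2, -2], [-2, 2]])

    def test_all_monomorphic_rejected(self):
        geno = GenotypeMatrix(ids=["a", "b"], loci=["l1", "l2"],
                              dosages=np.array([[2.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="monomorphic"):
            genomic_G(geno)

    def test_missing_dosages_mean_imputed(self):
        geno = GenotypeMatrix(ids=["a", "b", "c"], loci=["l1"],
                              dosages=np.array([[2.0], [0.0], [np.nan]]))
        G = genomic_G(geno).values
        # the imputed individual is centered to zero: no self-relationship signal
        assert G[2, 2] == 0.0

    def test_plink_raw_dialect_autodetected(self, tmp_path):
        raw = tmp_path / "geno.raw"
        raw.write_text(
            "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_G\n"
            "f1 m1 0 0 1 -9 0 2\n"
            "f1 m2 0 0 2 -9 1 NA\n"
        )
        g = GenotypeMatrix.from_tsv(raw)
        assert g.ids == ["m1", "m2"]
        assert g.loci == ["snp1_A", "snp2_G"]
        assert g.dosages[0, 1] == 2.0 and np.isnan(g.dosages[1, 1])

    def test_hardy_weinberg_mean_diagonal_near_one(self):
        pop = simulate_population(
            PopulationSpec(n_families=100, family_size=1, n_loci=2000, generations=0),
            seed=5,
        )
        G = genomic_G(pop.genotypes).values
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.05


class TestBlend:
    def test_printed_constants_hand_arithmetic(self):
        one = RelationshipMatrix(ids=["a"], values=np.array([[1.0]]))
        out = blend_G(one, RelationshipMatrix(ids=["a"], values=np.array([[1.0]])))
        assert out.values[0, 0] == pytest.approx(0.99715, abs=1e-12)

    def test_identity_blend_recovers_G(self, rng):
        M = rng.standard_normal((4, 8))
        G = RelationshipMatrix(ids=list("abcd"), values=M @ M.T / 8)
        out = blend_G(G, G, a=0.0, b=1.0)
        np.testing.assert_allclose(out.values, G.values, atol=1e-12)

    def test_computed_constants_fixed_point(self, rng):
        M = rng.standard_normal((5, 30))
        G = RelationshipMatrix(ids=list("abcde"), values=M @ M.T / 30 + np.eye(5))
        a, b = blend_constants(G, G)
        assert a == pytest.approx(0.0, abs=1e-10)
        assert b == pytest.approx(1.0, abs=1e-10)


class TestBuildH:
    def test_no_genotypes_returns_A(self, textbook_pedigree):
        A = pedigree_A(textbook_pedigree)
        empty = RelationshipMatrix(ids=[], values=np.zeros((0, 0)))
        H = build_H(A, empty, [])
        np.testing.assert_allclose(H.values, A.values, atol=1e-8)

    def test_all_genotyped_returns_G_star(self, small_design):
        pop = small_design.population
        A = pedigree_A(pop.pedigree)
        G = genomic_G(pop.genotypes)
        G_star = blend_G(G, A, a=None, b=None)
        H = build_H(A, G_star, pop.pedigree.ids)
        np.testing.assert_allclose(H.values, G_star.values, atol=1e-6)

    def test_mixed_vs_partitioned_identity_oracle(self, small_design):
        """H agrees with the direct partitioned-matrix identity
        H_gg = G*, H_ng = A_ng A_gg^-1 G*, and the genotype correction
        propagated through the pedigree for non-genotyped pairs."""
        pop = small_design.population
        A = pedigree_A(pop.pedigree)
        genotyped = small_design.genotyped
        G_star = blend_G(genomic_G(pop.genotypes).subset(genotyped),
                         A.subset(genotyped), a=None, b=None)
        H = build_H(A, G_star, genotyped)
        ids = A.ids
        g = np.array([i in set(genotyped) for i in ids])
        order = np.concatenate([np.where(~g)[0], np.where(g)[0]])
        P = A.values[np.ix_(order, order)]
        n1 = int((~g).sum())
        A11, A12, A22 = P[:n1, :n1], P[:n1, n1:], P[n1:, n1:]
        # reorder G* rows to match A's genotyped order
        gs = G_star.subset([ids[i] for i in order[n1:]]).values
        A22i = np.linalg.inv(A22)
        B = A12 @ A22i
        Ho = np.block([
            [A11 + B @ (gs - A22) @ B.T, B @ gs],
            [gs @ B.T, gs],
        ])
        Hp = H.values[np.ix_(order, order)]
        np.testing.assert_allclose(Hp, Ho, atol=1e-6)


class TestSampleVar:
    def test_identity_is_one(self):
        for n in (2, 5, 10, 50):
            assert sample_var(np.eye(n)) == pytest.approx(1.0, abs=1e-12)

    def test_ones_matrix_is_zero(self):
        assert sample_var(np.ones((6, 6))) == pytest.approx(0.0, abs=1e-12)

    def test_tridiagonal_matches_brute_force(self):
        M = np.array([[2.0, 1, 0], [1, 2, 1], [0, 1, 2]])
        P = np.eye(3) - np.ones((3, 3)) / 3
        assert sample_var(M) == pytest.approx(np.trace(P @ M @ P) / 2, abs=1e-14)

    def test_constant_shift_invariance(self, rng):
        for _ in range(5):
            M = rng.standard_normal((7, 7))
            M = M @ M.T
            c = float(rng.normal(scale=10))
            assert sample_var(M + c) == pytest.approx(sample_var(M), abs=1e-9)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            sample_var(np.eye(1))


class TestScaleComponents:
    def test_defining_properties(self, small_design):
        s = small_design.scaled
        Z = small_design.cages.Z
        assert sample_var(s.H1) == pytest.approx(1.0, rel=1e-10)
        assert sample_var(Z @ s.H3 @ Z.T) == pytest.approx(1.0, rel=1e-10)
        assert sample_var(Z @ s.I3 @ Z.T) == pytest.approx(1.0, rel=1e-10)
        assert sample_var(small_design.cages.W @ s.I4 @ small_design.cages.W.T) \
            == pytest.approx(1.0, rel=1e-10)
        # H2 carries the geometric mean of the H1 and H3 scale factors
        np.testing.assert_allclose(
            s.H2, small_design.H.values / np.sqrt(s.var_H * s.var_ZHZ), atol=1e-12
        )

    def test_identity_design_all_scales_one(self):
        # two cages of two: sampleVar(ZZ') = sampleVar(I permuted) = 1
        from sgekit import CageDesign
        cages = CageDesign(ids=list("abcd"), cages=["c1", "c1", "c2", "c2"])
        s = scale_components(np.eye(4), cages.Z, cages.W)
        np.testing.assert_allclose(s.H1, np.eye(4))
        np.testing.assert_allclose(s.H3, np.eye(4))
        np.testing.assert_allclose(s.H2, np.eye(4))

    def test_singleton_cages_rejected(self):
        from sgekit import CageDesign
        cages = CageDesign(ids=list("abcd"), cages=["c1", "c2", "c3", "c4"])
        with pytest.raises(DegenerateDesignError):
            scale_components(np.eye(4), cages.Z, cages.W)

    def test_symmetry_of_outputs(self, small_design):
        for M in (small_design.H.values, small_design.scaled.H1,
                  small_design.scaled.H3):
            assert np.max(np.abs(M - M.T)) < 1e-10


class TestCageAssignment:
    def test_full_sib_packing_relatedness(self):
        pop = simulate_population(PopulationSpec(n_families=30, family_size=3,
                                                 n_loci=10), seed=3)
        A = pedigree_A(pop.pedigree).subset(pop.cohort).values
        packed = assign_cages(pop.cohort, pop.family, cage_sizes=3,
                              cohousing_weight=1.0, seed=4)
        Z = packed.Z
        within = A[Z > 0].mean()
        assert within == pytest.approx(0.5, abs=0.05)

    def test_random_assignment_matches_population_mean(self):
        pop = simulate_population(PopulationSpec(n_families=60, family_size=3,
                                                 n_loci=10), seed=3)
        A = pedigree_A(pop.pedigree).subset(pop.cohort).values
        rand = assign_cages(pop.cohort, pop.family, cage_sizes=3,
                            cohousing_weight=0.0, seed=4)
        Z = rand.Z
        off = ~np.eye(len(pop.cohort), dtype=bool)
        assert abs(A[Z > 0].mean() - A[off].mean()) < 0.05
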