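"""Relationship matrices and mixed-model equations against dense oracles."""

import numpy as np
import pandas as pd
import pytest

from breedsim import (
    Chip,
    Population,
    blup_solve,
    compute_A,
    compute_G,
    compute_H_inverse,
    evaluate,
    export_evaluation_data,
    import_ebvs,
    mass_selection_ebv,
    phenotype_population,
    sample_architecture,
)
from breedsim.prediction import G_DIAGONAL_INFLATION


class TestComputeG:
    # 3 individuals x 4 SNPs toy, dosages fixed in the test
    DOS = np.array(
        [[0, 1, 2, 1],
         [1, 1, 0, 2],
         [2, 0, 1, 0]], dtype=float)

    def _hand_G(self):
        x = self.DOS - self.DOS.mean(axis=0)
        p = self.DOS.mean(axis=0) / 2
        return x @ x.T / (2 * np.sum(p * (1 - p)))

    def test_matches_hand_computation(self):
        g = compute_G(self.DOS, inflate_diagonal=False)
        np.testing.assert_allclose(g, self._hand_G(), atol=1e-12)

    def test_diagonal_safeguard_ratio(self):
        g0 = compute_G(self.DOS, inflate_diagonal=False)
        g1 = compute_G(self.DOS)
        np.testing.assert_allclose(np.diag(g1) / np.diag(g0), G_DIAGONAL_INFLATION)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(g1[off], g0[off])

    def test_identical_genotypes_identical_rows(self):
        dos = np.vstack([self.DOS, self.DOS[0]])
        g = compute_G(dos)
        off = [1, 2]
        np.testing.assert_allclose(g[0, off], g[3, off])

    def test_monomorphic_chip_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_G(np.ones((3, 4)))

    def test_psd_and_conditioning_improved_by_safeguard(self, rng):
        dos = rng.integers(0, 3, (10, 30)).astype(float)
        g0 = compute_G(dos, inflate_diagonal=False)
        g1 = compute_G(dos)
        ev0 = np.linalg.eigvalsh(g0)
        ev1 = np.linalg.eigvalsh(g1)
        assert ev0.min() >= -1e-9  # PSD before safeguard
        assert ev1.min() >= ev0.min() - 1e-12

    def test_symmetric(self, rng):
        dos = rng.integers(0, 3, (8, 20)).astype(float)
        g = compute_G(dos)
        np.testing.assert_allclose(g, g.T)


class TestComputeA:
    def test_founders_only_identity(self):
        ped = pd.DataFrame({"id": [0, 1, 2], "sire": [-1] * 3, "dam": [-1] * 3})
        np.testing.assert_array_equal(compute_A(ped), np.eye(3))

    def test_full_sibs_half_related(self):
        ped = pd.DataFrame({"id": [0, 1, 2, 3],
                            "sire": [-1, -1, 1, 1],
                            "dam": [-1, -1, 0, 0]})
        a = compute_A(ped)
        assert a[2, 3] == pytest.approx(0.5)
        assert a[2, 0] == pytest.approx(0.5)  # parent-offspring
        assert a[2, 2] == pytest.approx(1.0)  # unrelated parents, not inbred

    def test_selfed_offspring_inbred(self):
        ped = pd.DataFrame({"id": [0, 1], "sire": [-1, 0], "dam": [-1, 0]})
        a = compute_A(ped)
        assert a[1, 1] == pytest.approx(1.5)

    def test_unsorted_pedigree_rejected(self):
        ped = pd.DataFrame({"id": [0, 1], "sire": [1, -1], "dam": [-1, -1]})
        with pytest.raises(ValueError):
            compute_A(ped)


class TestBlupSolve:
    def _toy(self):
        # 2-generation pedigree: 2 founders, 2 full sibs
        ped = pd.DataFrame({"id": [0, 1, 2, 3],
                            "sire": [-1, -1, 1, 1],
                            "dam": [-1, -1, 0, 0]})
        a = compute_A(ped)
        y = np.array([2.0, 4.0, 3.5, np.nan])
        return a, y

    def test_matches_direct_dense_mme_solve(self):
        a, y = self._toy()
        h2 = 0.4
        lam = (1 - h2) / h2
        res = blup_solve(y, h2, relationship=a)
        # independent assembly: observed individuals 0,1,2
        z = np.zeros((3, 4))
        z[0, 0] = z[1, 1] = z[2, 2] = 1
        yo = y[:3]
        ainv = np.linalg.inv(a)
        top = np.concatenate([[3.0], z.sum(axis=0)])
        bottom = np.hstack([z.sum(axis=0)[:, None], z.T @ z + ainv * lam])
        c = np.vstack([top, bottom])
        rhs = np.concatenate([[yo.sum()], z.T @ yo])
        sol = np.linalg.solve(c, rhs)
        np.testing.assert_allclose(res.ebv, sol[1:], atol=1e-8)
        # the unphenotyped sib still gets an EBV
        assert res.ids.size == 4
        assert list(res.phenotyped_ids) == [0, 1, 2]

    def test_equal_phenotypes_give_zero_ebv(self):
        a, _ = self._toy()
        res = blup_solve(np.full(4, 7.0), 0.5, relationship=a)
        np.testing.assert_allclose(res.ebv, 0.0, atol=1e-10)

    def test_strong_shrinkage_drives_ebv_to_zero(self):
        a, y = self._toy()
        res = blup_solve(y, 1e-6, relationship=a)
        np.testing.assert_allclose(res.ebv, 0.0, atol=1e-3)

    def test_permuting_individuals_permutes_ebvs(self):
        a, y = self._toy()
        res = blup_solve(y, 0.4, relationship=a)
        perm = np.array([2, 0, 3, 1])
        res_p = blup_solve(y[perm], 0.4, relationship=a[np.ix_(perm, perm)])
        np.testing.assert_allclose(res_p.ebv, res.ebv[perm], atol=1e-10)

    def test_invalid_h2_rejected(self):
        a, y = self._toy()
        with pytest.raises(ValueError):
            blup_solve(y, 1.0, relationship=a)


class TestSingleStep:
    def _pop(self, diploid_data, n_off=6):
        fh, _, genome = diploid_data
        rng = np.random.default_rng(21)
        pop = Population(genome, fh)
        arch = sample_architecture("random", fh, genome, rng, n_qtn=10, h2=0.5)
        for _ in range(n_off):
            pop.add_offspring(0, 1, rng)
        phenotype_population(pop, arch, rng)
        return pop, rng

    def test_all_genotyped_reduces_to_gblup(self, diploid_data):
        pop, _ = self._pop(diploid_data)
        chip = Chip("all", np.arange(pop.genome.n_snps))
        idx = list(range(pop.size))
        y = np.array([pop[i].y[0] for i in idx])
        g = compute_G(pop.decode(idx, chip.snp_indices))
        ped = pop.pedigree()
        a = compute_A(ped)
        h_inv = compute_H_inverse(a, g, np.arange(len(idx)))
        r_ss = blup_solve(y, 0.5, relationship_inv=h_inv)
        r_g = blup_solve(y, 0.5, relationship=g)
        np.testing.assert_allclose(r_ss.ebv, r_g.ebv, atol=1e-8)

    def test_none_genotyped_reduces_to_pedigree_blup(self, diploid_data):
        pop, _ = self._pop(diploid_data)
        y = np.array([pop[i].y[0] for i in range(pop.size)])
        a = compute_A(pop.pedigree())
        h_inv = compute_H_inverse(a, np.zeros((0, 0)), np.array([], dtype=int))
        r_ss = blup_solve(y, 0.5, relationship_inv=h_inv)
        r_a = blup_solve(y, 0.5, relationship=a)
        np.testing.assert_allclose(r_ss.ebv, r_a.ebv, atol=1e-8)

    def test_mixed_case_matches_dense_block_formula(self, diploid_data):
        pop, _ = self._pop(diploid_data, n_off=4)
        chip = Chip("all", np.arange(pop.genome.n_snps))
        idx = list(range(pop.size))
        geno = np.array([20, 21, 22, 23])  # the four offspring
        y = np.array([pop[i].y[0] for i in idx])
        a = compute_A(pop.pedigree())
        g = compute_G(pop.decode(geno.tolist(), chip.snp_indices))
        h_inv = compute_H_inverse(a, g, geno)
        # independent dense assembly of the same block formula
        expect = np.linalg.inv(a).copy()
        expect[np.ix_(geno, geno)] += np.linalg.inv(g) - np.linalg.inv(
            a[np.ix_(geno, geno)])
        np.testing.assert_allclose(h_inv, expect, atol=1e-8)
        r1 = blup_solve(y, 0.5, relationship_inv=h_inv)
        r2 = blup_solve(y, 0.5, relationship_inv=expect)
        np.testing.assert_allclose(r1.ebv, r2.ebv, atol=1e-8)


class TestMassSelection:
    def test_ranking_equals_phenotype_ranking(self):
        y = np.array([3.0, 1.0, np.nan, 5.0])
        res = mass_selection_ebv(y)
        assert list(res.ranking()) == [3, 0, 1]

    def test_unphenotyped_excluded(self):
        res = mass_selection_ebv(np.array([1.0, np.nan]))
        assert list(res.ids) == [0]

    def test_h2_one_ranking_equals_genotypic_ranking(self, diploid_data):
        fh, _, genome = diploid_data
        rng = np.random.default_rng(2)
        pop = Population(genome, fh)
        arch = sample_architecture("random", fh, genome, rng, n_qtn=10, h2=1.0)
        phenotype_population(pop, arch, rng)
        y = np.array([pop[i].y[0] for i in range(pop.size)])
        g = np.array([pop[i].g[0] for i in range(pop.size)])
        res = mass_selection_ebv(y)
        np.testing.assert_array_equal(res.ranking(), np.lexsort((np.arange(g.size), -g)))


class TestGBLUPBeatsPedigreeForSibs:
    def test_accuracy_comparison_unphenotyped_sibs(self, tmp_path):
        """GBLUP distinguishes full sibs; pedigree BLUP cannot (directional)."""
        from breedsim import build_genome, read_vcf
        from breedsim.fixtures import make_fixture
        paths = make_fixture(tmp_path, n_founders=60, n_chrom=2, n_snps=500,
                             ld_blocks=25, seed=17)
        fh, meta = read_vcf(paths["vcf"])
        genome = build_genome(meta)
        rng = np.random.default_rng(17)
        pop = Population(genome, fh)
        arch = sample_architecture("random", fh, genome, rng, n_qtn=50, h2=0.5)
        # families of full sibs, phenotyped parents, unphenotyped sibs
        sib_ids = []
        for fam in range(15):
            dam, sire = 2 * fam, 2 * fam + 1
            for _ in range(8):
                sib_ids.append(pop.add_offspring(dam, sire, rng).id)
        phenotype_population(pop, arch, rng, ids=list(range(60)))
        chip = Chip("seq", np.arange(genome.n_snps))
        r_g = evaluate(pop, "gblup", h2=0.5, chip=chip)
        r_a = evaluate(pop, "blup", h2=0.5)
        g_true = np.array([
            float(v) for v in
            (pop.decode(sib_ids, arch.qtn_indices) - 1) @ arch.a[:, 0]
        ])
        acc_g = np.corrcoef(g_true, r_g.ebv[sib_ids])[0, 1]
        acc_a = np.corrcoef(g_true, r_a.ebv[sib_ids])[0, 1]
        assert acc_g > acc_a


class TestExternalRoundTrip:
    def test_export_import_reproduces_decisions(self, diploid_data, tmp_path, rng):
        fh, _, genome = diploid_data
        pop = Population(genome, fh)
        arch = sample_architecture("random", fh, genome, rng, n_qtn=10, h2=0.5)
        phenotype_population(pop, arch, rng)
        chip = Chip("half", np.arange(0, genome.n_snps, 2))
        export_evaluation_data(pop, chip, tmp_path / "dos.tsv", tmp_path / "phe.tsv")
        # exported dosages equal decode on the chip
        dos = pd.read_csv(tmp_path / "dos.tsv", sep="\t", index_col=0)
        np.testing.assert_array_equal(dos.to_numpy(), pop.decode(None, chip.snp_indices))
        # run an internal GBLUP, write it out as if external, re-import
        res = evaluate(pop, "gblup", h2=0.5, chip=chip)
        ebv_file = tmp_path / "ebv.txt"
        with open(ebv_file, "w") as fh_out:
            for i, v in zip(res.ids, res.ebv):
                fh_out.write(f"{i} {v:.10f}\n")
        imp = import_ebvs(ebv_file, pop)
        np.testing.assert_array_equal(imp.ranking(), res.ranking())

    def test_unknown_id_rejected(self, diploid_pop, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("9999 1.0\n")
        with pytest.raises(ValueError):
            import_ebvs(f, diploid_pop)
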