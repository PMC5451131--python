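"""Relationship matrices against dense/tabular/Monte-Carlo oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from wssgwas.datatypes import GenotypePanel
from wssgwas.relationship import (a_inverse, genomic_relationship, h_inverse,
                                  inbreeding, numerator_relationship)
from wssgwas.simulate import SimConfig, simulate_pedigree
from conftest import make_pedigree


class TestNumeratorRelationship:
    def test_unrelated_founders(self):
        ped = make_pedigree([("A", "0", "0", 0), ("B", "0", "0", 0)])
        a, f = numerator_relationship(ped)
        np.testing.assert_allclose(a, np.eye(2))
        np.testing.assert_allclose(f, 0)

    def test_full_sibs_related_by_half(self):
        ped = make_pedigree([("S", "0", "0", 0, "M"), ("D", "0", "0", 0),
                             ("C1", "S", "D", 1), ("C2", "S", "D", 1)])
        a, _ = numerator_relationship(ped)
        assert a[2, 3] == pytest.approx(0.5)
        assert a[2, 2] == pytest.approx(1.0)

    def test_sire_daughter_mating_gives_inbreeding_quarter(self):
        ped = make_pedigree([("S", "0", "0", 0, "M"), ("D", "0", "0", 0),
                             ("G", "S", "D", 1), ("I", "S", "G", 2)])
        a, f = numerator_relationship(ped)
        assert f[3] == pytest.approx(0.25)
        assert a[3, 3] == pytest.approx(1.25)

    def test_meuwissen_luo_inbreeding_matches_tabular(self):
        ped = simulate_pedigree(SimConfig(seed=5, n_founders=30,
                                          n_generations=4,
                                          progeny_per_sire=8,
                                          natural_progeny_per_sire=3))
        _, f_tab = numerator_relationship(ped)
        np.testing.assert_allclose(inbreeding(ped), f_tab, atol=1e-12)


class TestAInverse:
    def test_single_founder(self):
        ped = make_pedigree([("A", "0", "0", 0)])
        np.testing.assert_allclose(a_inverse(ped).toarray(), [[1.0]])

    def test_trio_against_hand_values(self):
        ped = make_pedigree([("S", "0", "0", 0, "M"), ("D", "0", "0", 0),
                             ("O", "S", "D", 1)])
        expected = np.array([[1.5, 0.5, -1.0],
                             [0.5, 1.5, -1.0],
                             [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(a_inverse(ped).toarray(), expected)

    def test_inverts_tabular_a_on_random_pedigree(self):
        ped = simulate_pedigree(SimConfig(seed=6, n_founders=12,
                                          n_generations=3,
                                          progeny_per_sire=6,
                                          natural_progeny_per_sire=3))
        assert ped.n_animals <= 50
        a, _ = numerator_relationship(ped)
        prod = a_inverse(ped).toarray() @ a
        assert np.abs(prod - np.eye(len(a))).max() < 1e-8

    def test_sparsity_limited_to_parent_triples(self):
        ped = simulate_pedigree(SimConfig(seed=7, n_founders=20,
                                          n_generations=2,
                                          progeny_per_sire=5,
                                          natural_progeny_per_sire=3))
        sires, dams = ped.parent_indices()
        allowed = set()
        for i in range(ped.n_animals):
            fam = [i] + [p for p in (sires[i], dams[i]) if p >= 0]
            allowed.update((x, y) for x in fam for y in fam)
        coo = a_inverse(ped).tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if abs(v) > 1e-14:
                assert (i, j) in allowed

    def test_gene_drop_ibd_estimates_match_tabular_a(self, rng):
        """Monte-Carlo single-locus allele dropping reproduces A within
        sampling error on a 30-animal pedigree."""
        ped = simulate_pedigree(SimConfig(seed=8, n_founders=10,
                                          n_generations=2,
                                          progeny_per_sire=4,
                                          natural_progeny_per_sire=2))
        n = ped.n_animals
        assert n <= 40
        sires, dams = ped.parent_indices()
        a, _ = numerator_relationship(ped)
        reps = 3000
        alleles = np.zeros((n, 2, reps), dtype=np.int64)
        next_label = 0
        for i in range(n):
            for h, p in enumerate((sires[i], dams[i])):
                if p < 0:
                    alleles[i, h] = next_label
                    next_label += 1
                else:
                    pick = rng.integers(2, size=reps)
                    alleles[i, h] = alleles[p, pick, np.arange(reps)]
        pick_i = rng.integers(2, size=(n, reps))
        sampled = alleles[np.arange(n)[:, None], pick_i, np.arange(reps)]
        for i in range(0, n, 5):
            for j in range(i, n, 5):
                if i == j:
                    continue
                kin = (sampled[i] == sampled[j]).mean()
                se = max(np.sqrt(kin * (1 - kin) / reps), 1e-3)
                assert abs(2 * kin - a[i, j]) <= 6 * se + 0.02


class TestGenomicRelationship:
    def _panel(self, dosages):
        m, n = dosages.shape
        mmap = pd.DataFrame({"chrom": ["1"] * m,
                             "marker_id": [f"M{i}" for i in range(m)],
                             "bp": np.arange(1, m + 1) * 1000})
        return GenotypePanel(dosages.astype(float), np.ones_like(dosages,
                                                                 dtype=float),
                             mmap, [f"A{j}" for j in range(n)])

    # animal 0 heterozygous at every marker; columns chosen so p_i = 0.5
    HET_PANEL = np.tile([1.0, 0.0, 2.0, 1.0], (4, 1))  # markers x animals

    def test_all_heterozygous_animal_has_zero_raw_diagonal(self):
        panel = self._panel(self.HET_PANEL)
        g, p, used = genomic_relationship(panel, blend_weight=0.0)
        np.testing.assert_allclose(p[used], 0.5)
        assert g[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_blending_arithmetic(self):
        panel = self._panel(self.HET_PANEL)
        a22 = np.eye(4)
        g, _, _ = genomic_relationship(panel, blend_weight=0.05, a22=a22)
        assert g[0, 0] == pytest.approx(0.95 * 0.0 + 0.05 * 1.0)

    def test_hwe_founder_panel_centers_g_around_identity(self):
        from wssgwas.simulate import gene_drop, simulate_pedigree
        cfg = SimConfig(seed=13, n_founders=400, n_generations=0,
                        n_markers=1000, missing_rate=0.0,
                        low_quality_rate=0.0)
        ped = simulate_pedigree(cfg)
        dosages, mmap = gene_drop(ped, cfg, np.random.default_rng(13))
        panel = GenotypePanel(dosages, np.ones_like(dosages), mmap,
                              ped.animal_ids)
        g, _, _ = genomic_relationship(panel, blend_weight=0.0)
        off = ~np.eye(len(g), dtype=bool)
        assert abs(np.diag(g).mean() - 1.0) < 0.05
        assert abs(g[off].mean()) < 0.02

    def test_monomorphic_markers_excluded_with_warning(self):
        dosages = np.array([[1.0, 1.0, 0.0, 2.0], [2.0, 2.0, 2.0, 2.0]])
        panel = self._panel(dosages)
        with pytest.warns(UserWarning, match="monomorphic"):
            _, _, used = genomic_relationship(panel, blend_weight=0.0)
        assert used.tolist() == [0]

    def test_missing_dosages_imputed_at_mean(self):
        dosages = np.array([[0.0, 1.0, 2.0, np.nan],
                            [2.0, 1.0, 0.0, 1.0]])
        panel = self._panel(dosages)
        g, _, _ = genomic_relationship(panel, blend_weight=0.0)
        assert np.isfinite(g).all()


class TestHInverse:
    def test_no_genotyped_animals_reduces_to_a_inverse(self, trio):
        a_inv = a_inverse(trio)
        parts = h_inverse(a_inv, np.zeros((0, 0)), np.zeros((0, 0)),
                          np.array([], dtype=int))
        np.testing.assert_allclose(parts.to_sparse().toarray(),
                                   a_inv.toarray())

    def test_g_equal_a22_cancels_genomic_block(self):
        ped = simulate_pedigree(SimConfig(seed=9, n_founders=12,
                                          n_generations=2,
                                          progeny_per_sire=5,
                                          natural_progeny_per_sire=2))
        a, _ = numerator_relationship(ped)
        idx = np.arange(0, ped.n_animals, 3)
        a22 = a[np.ix_(idx, idx)]
        a_inv = a_inverse(ped)
        parts = h_inverse(a_inv, a22, a22.copy(), idx)
        np.testing.assert_allclose(parts.to_sparse().toarray(),
                                   a_inv.toarray(), atol=1e-10)

    def test_dense_inversion_matches_blockwise_h_definition(self):
        """inv(H^-1) equals the textbook blockwise H built from A and G."""
        ped = simulate_pedigree(SimConfig(seed=10, n_founders=8,
                                          n_generations=2,
                                          progeny_per_sire=4,
                                          natural_progeny_per_sire=2))
        n = ped.n_animals
        assert n >= 20
        rng = np.random.default_rng(0)
        idx = np.sort(rng.choice(n, size=5, replace=False))
        a, _ = numerator_relationship(ped)
        a22 = a[np.ix_(idx, idx)]
        g = a22 + 0.1 * np.eye(5)  # any SPD genomic block
        parts = h_inverse(a_inverse(ped), a22, g, idx)
        h = np.linalg.inv(parts.to_sparse().toarray())

        rest = np.setdiff1d(np.arange(n), idx)
        order = np.r_[rest, idx]
        a_ord = a[np.ix_(order, order)]
        k = len(rest)
        a11, a12, a21 = a_ord[:k, :k], a_ord[:k, k:], a_ord[k:, :k]
        a22i = np.linalg.inv(a22)
        h_oracle = np.zeros_like(a_ord)
        h_oracle[:k, :k] = a11 + a12 @ a22i @ (g - a22) @ a22i @ a21
        h_oracle[:k, k:] = a12 @ a22i @ g
        h_oracle[k:, :k] = g @ a22i @ a21
        h_oracle[k:, k:] = g
        assert np.abs(h[np.ix_(order, order)] - h_oracle).max() < 1e-8

    def test_singular_g_raises_actionable_error(self, trio):
        a, _ = numerator_relationship(trio)
        idx = np.array([0, 1])
        singular = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="blend_weight"):
            h_inverse(a_inverse(trio), a[np.ix_(idx, idx)], singular, idx)

    def test_matvec_agrees_with_materialized_matrix(self, rng):
        ped = simulate_pedigree(SimConfig(seed=11, n_founders=10,
                                          n_generations=2,
                                          progeny_per_sire=4,
                                          natural_progeny_per_sire=2))
        a, _ = numerator_relationship(ped)
        idx = np.arange(0, ped.n_animals, 4)
        a22 = a[np.ix_(idx, idx)]
        parts = h_inverse(a_inverse(ped), a22, a22 + 0.05 * np.eye(len(idx)),
                          idx)
        x = rng.standard_normal(ped.n_animals)
        np.testing.assert_allclose(parts.matvec(x),
                                   parts.to_sparse() @ x, atol=1e-10)
        assert parts.quadratic(x) == pytest.approx(x @ (parts.to_sparse() @ x))
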