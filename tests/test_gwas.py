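"""Back-solving, weight iteration and the 1-Mb window scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wssgwas.gwas import (SnpWeightState, WssGblup, backsolve_snp_effects,
                          update_weights, window_scan)
from wssgwas.qc import PhenotypeEditor, filter_markers, filter_samples
from wssgwas.simulate import SimConfig, simulate_dataset
from wssgwas.studies import derive_seed


def random_state(rng, n_animals=12, n_markers=30):
    p = rng.uniform(0.1, 0.5, n_markers)
    dos = rng.binomial(2, p, size=(n_animals, n_markers)).astype(float)
    z = dos - 2 * p
    return SnpWeightState(0, np.zeros(n_markers), np.ones(n_markers), p, z)


class TestBacksolve:
    def test_projection_identity_z_uhat_equals_a_hat(self, rng):
        state = random_state(rng)
        a_hat = rng.standard_normal(12)
        u = backsolve_snp_effects(a_hat, state.z, state.weights)
        assert np.abs(state.z @ u - a_hat).max() < 1e-8

    def test_zero_weight_marker_gets_zero_effect(self, rng):
        state = random_state(rng)
        w = state.weights.copy()
        w[5] = 0.0
        u = backsolve_snp_effects(rng.standard_normal(12), state.z, w)
        assert u[5] == 0.0

    def test_two_by_two_hand_computation(self):
        z = np.array([[1.0, -1.0], [0.0, 2.0]])
        d = np.array([1.0, 2.0])
        a_hat = np.array([1.0, -1.0])
        # ZDZ' = [[3, -4], [-4, 8]]; det = 8; inv = [[8,4],[4,3]]/8
        zdz_inv = np.array([[8.0, 4.0], [4.0, 3.0]]) / 8.0
        expected = (np.diag(d) @ z.T) @ (zdz_inv @ a_hat)
        u = backsolve_snp_effects(a_hat, z, d)
        np.testing.assert_allclose(u, expected, atol=1e-12)
        np.testing.assert_allclose(z @ u, a_hat, atol=1e-12)

    def test_singular_system_advises_blending(self):
        z = np.zeros((2, 3))
        with pytest.raises(np.linalg.LinAlgError, match="blend"):
            backsolve_snp_effects(np.ones(2), z, np.ones(3))


class TestWeightUpdate:
    def test_weight_formula_direct_substitution(self, rng):
        """d_i follows u^2 p (1-p): with u=0.2, p=0.5 the unnormalized
        weight is 0.04 * 0.25 = 0.01; ratios survive normalization."""
        state = random_state(rng, n_markers=2)
        state = SnpWeightState(0, np.array([0.2, 0.1]),
                               np.ones(2), np.array([0.5, 0.2]), state.z[:, :2])
        new = update_weights(state)
        raw = np.array([0.2**2 * 0.5 * 0.5, 0.1**2 * 0.2 * 0.8])
        assert raw[0] == pytest.approx(0.01)
        assert new.weights[1] / new.weights[0] == pytest.approx(
            raw[1] / raw[0], rel=1e-12)
        assert new.round_index == 1

    def test_zero_effect_marker_keeps_zero_weight(self, rng):
        state = random_state(rng)
        state = SnpWeightState(0, np.abs(rng.standard_normal(30)) + 0.1,
                               np.ones(30), state.p, state.z)
        state.u_hat[7] = 0.0
        new = update_weights(state)
        assert new.weights[7] == 0.0

    def test_variance_budget_conserved(self, rng):
        state = random_state(rng)
        state = SnpWeightState(0, rng.standard_normal(30), np.ones(30),
                               state.p, state.z)
        budget0 = state.variance_budget
        new = update_weights(state)
        assert new.variance_budget == pytest.approx(budget0, rel=1e-10)
        again = update_weights(
            SnpWeightState(new.round_index, rng.standard_normal(30),
                           new.weights, new.p, new.z))
        assert again.variance_budget == pytest.approx(budget0, rel=1e-10)

    def test_all_zero_effects_fall_back_to_uniform(self, rng):
        state = random_state(rng)
        with pytest.warns(UserWarning, match="uniform"):
            new = update_weights(state)  # u_hat all zero
        assert np.allclose(new.weights, new.weights[0])

    @given(st.integers(0, 2**31 - 1))
    def test_budget_invariant_under_any_effects(self, seed):
        rng = np.random.default_rng(seed)
        state = random_state(rng, n_markers=10)
        state = SnpWeightState(0, rng.standard_normal(10) * 10,
                               np.ones(10), state.p, state.z)
        new = update_weights(state)
        assert new.variance_budget == pytest.approx(state.variance_budget,
                                                    rel=1e-9)


class TestWindowScan:
    def _map(self, chrom, bp):
        return pd.DataFrame({"chrom": chrom,
                             "marker_id": [f"M{i}" for i in range(len(bp))],
                             "bp": bp})

    def test_single_window_holds_everything(self, rng):
        z = rng.standard_normal((20, 5))
        u = rng.standard_normal(5)
        win = window_scan(u, z, self._map(["1"] * 5,
                                          [10, 200, 5000, 99999, 1_000_000]))
        assert len(win) == 1
        assert win["pct_variance"].iloc[0] == pytest.approx(100.0)

    def test_boundary_markers_fall_in_adjacent_windows(self, rng):
        z = rng.standard_normal((10, 2))
        win = window_scan(np.ones(2), z,
                          self._map(["1", "1"], [1_000_000, 1_000_001]))
        assert win["n_snps"].tolist() == [1, 1]
        assert win["start_bp"].tolist() == [1, 1_000_001]
        assert win["end_bp"].tolist() == [1_000_000, 2_000_000]

    def test_tiling_counts_windows_per_chromosome(self, rng):
        bp = [500_000, 1_500_000, 2_500_000, 400_000, 1_200_000]
        chrom = ["1", "1", "1", "2", "2"]
        win = window_scan(np.ones(5), rng.standard_normal((8, 5)),
                          self._map(chrom, bp))
        assert len(win) == 3 + 2

    def test_empty_windows_reported_as_zero(self, rng):
        win = window_scan(np.ones(2), rng.standard_normal((8, 2)),
                          self._map(["1", "1"], [100, 2_500_000]))
        middle = win[(win["start_bp"] == 1_000_001)]
        assert middle["n_snps"].iloc[0] == 0
        assert middle["pct_variance"].iloc[0] == 0.0

    def test_ranking_descending_with_deterministic_ties(self, rng):
        z = rng.standard_normal((30, 4))
        u = np.array([2.0, 0.1, 0.1, 1.5])
        win = window_scan(u, z, self._map(["1", "1", "2", "2"],
                                          [5, 1_000_005, 5, 1_000_005]))
        ranked = win.sort_values("rank")
        assert ranked["pct_variance"].is_monotonic_decreasing
        assert set(win["rank"]) == {1, 2, 3, 4}

    def test_top_k_flagging(self, rng):
        z = rng.standard_normal((30, 6))
        bp = [1 + i * 1_000_000 for i in range(6)]
        win = window_scan(rng.standard_normal(6), z,
                          self._map(["1"] * 6, bp), top_k=2)
        assert win["top20"].sum() == 2
        assert set(win.loc[win["top20"], "rank"]) == {1, 2}


@pytest.fixture(scope="module")
def fitted():
    cfg = SimConfig(seed=31, n_founders=150, n_generations=3,
                    n_markers=600, n_qtl=30, genotyped_fraction=0.25,
                    progeny_per_sire=15, natural_progeny_per_sire=5,
                    major_qtl_share=0.2, h2_true=0.25)
    sim = simulate_dataset(cfg)
    panel, _ = filter_markers(sim.genotyped_panel)
    panel, _ = filter_samples(panel)
    phenotypes = PhenotypeEditor().fit(sim.phenotypes).grouped_
    est = WssGblup(n_rounds=2, n_iterations=2500, burn_in=500, thin=5,
                   seed=3)
    est.fit(phenotypes, sim.pedigree, panel, panel.animal_ids)
    return sim, est, panel


class TestWssGblupRounds:
    def test_two_rounds_recorded_in_order(self, fitted):
        _, est, _ = fitted
        assert [s.round_index for s in est.states_] == [0, 1]
        assert np.allclose(est.states_[0].weights, 1.0)
        assert not np.allclose(est.states_[1].weights, 1.0)

    def test_fitted_effects_reproduce_genomic_breeding_values(self, fitted):
        """The back-solve inverts through the blended genomic matrix, so
        Z u_hat tracks the genotyped animals' posterior-mean breeding
        values up to the 5% blend toward A22."""
        _, est, panel = fitted
        final = est.states_[-1]
        a_hat = est.model_.predict(panel.animal_ids)
        fit_vals = final.z @ final.u_hat
        assert np.corrcoef(fit_vals, a_hat)[0, 1] > 0.99
        scale = np.abs(a_hat).max()
        assert np.abs(fit_vals - a_hat).max() < 0.15 * scale

    def test_each_round_preserves_variance_budget(self, fitted):
        _, est, _ = fitted
        budgets = [s.variance_budget for s in est.states_]
        assert budgets[1] == pytest.approx(budgets[0], rel=1e-9)

    def test_windows_cover_all_markers(self, fitted):
        _, est, _ = fitted
        assert est.windows_["n_snps"].sum() == len(est.states_[-1].u_hat)

    def test_major_qtl_weight_increases(self):
        """Re-weighting should promote the window of a large-effect QTL."""
        wins = 0
        n_rep = 4
        for r in range(n_rep):
            cfg = SimConfig(seed=derive_seed(77, r), n_founders=100,
                            n_generations=3, n_markers=600, n_qtl=30,
                            genotyped_fraction=0.3, progeny_per_sire=15,
                            natural_progeny_per_sire=5,
                            major_qtl_share=0.3, h2_true=0.4)
            sim = simulate_dataset(cfg)
            panel, _ = filter_markers(sim.genotyped_panel)
            panel, _ = filter_samples(panel)
            phenotypes = PhenotypeEditor().fit(sim.phenotypes).grouped_
            est = WssGblup(n_rounds=2, n_iterations=2000, burn_in=400,
                           thin=5, seed=r + 1)
            est.fit(phenotypes, sim.pedigree, panel, panel.animal_ids)
            dos = sim.panel.dosages[sim.model.qtl_indices]
            p = np.nanmean(dos, axis=1) / 2
            v = 2 * p * (1 - p) * sim.model.qtl_effects**2
            big_marker = sim.model.qtl_indices[int(np.argmax(v))]
            big_id = sim.panel.marker_ids[big_marker]
            kept = est.marker_map_["marker_id"].tolist()
            if big_id not in kept:
                continue
            pos = kept.index(big_id)
            if est.states_[1].weights[pos] > est.states_[0].weights[pos]:
                wins += 1
        assert wins >= n_rep - 1
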