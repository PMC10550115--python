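"""Unit and property tests for the stochastic fate simulator."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

from hepaclone import fate_sim as fs
from hepaclone.fate_sim import FateModelParams, get_model_params

from conftest import SEED


class TestParams:
    def test_fate_table_must_normalise(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FateModelParams(0.5, 0.5, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_any_normalised_table_is_accepted(self, a, b):
        assume(a + b <= 1.0)
        p = FateModelParams(a, b, max(0.0, 1.0 - a - b))
        assert abs(p.p_hc + p.p_cc + p.p_hh - 1.0) < 1e-9

    def test_rates_and_counts_validated(self):
        with pytest.raises(ValueError, match="rates"):
            FateModelParams(1, 0, 0, rate_c=0.0)
        with pytest.raises(ValueError, match="n_init"):
            FateModelParams(1, 0, 0, n_init=300, n_diff_threshold=200)

    def test_config_file_presets_and_overrides(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text("model: 4\nrate_c: 0.0667\n")
        p = fs.load_fate_params(cfg)
        assert (p.p_hc, p.p_cc, p.p_hh) == (0.2, 0.05, 0.75)
        assert p.rate_c == pytest.approx(1 / 15, rel=1e-3)
        cfg.write_text("p_hc: 1.0\np_cc: 0.0\np_hh: 0.0\nn_final: 500\n")
        custom = fs.load_fate_params(cfg)
        assert custom.p_hc == 1.0 and custom.n_final == 500

    def test_presets_match_the_fate_and_rate_tables(self):
        # model identity: probabilities (H+C, C+C, H+H) and BEC rate
        expect = {
            1: (1.0, 0.0, 0.0, 0.1),
            2: (1.0, 0.0, 0.0, 1 / 15),
            3: (0.5, 0.0, 0.5, 0.1),
            4: (0.2, 0.05, 0.75, 0.1),
            5: (0.2, 0.05, 0.75, 1 / 15),
            6: (0.2, 0.0, 0.8, 0.1),
        }
        for m, (hc, cc, hh, rc) in expect.items():
            p = get_model_params(m)
            assert (p.p_hc, p.p_cc, p.p_hh) == (hc, cc, hh)
            assert p.rate_c == pytest.approx(rc)
            assert p.rate_p == p.rate_h == pytest.approx(0.1)
            assert (p.n_init, p.n_diff_threshold, p.n_final) == (100, 200, 3000)


class TestGillespieDraw:
    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            fs.sample_next_event(np.array([]), rng)

    def test_single_cell_mean_waiting_time(self, rng):
        waits = [fs.sample_next_event(np.array([0.1]), rng)[0] for _ in range(5000)]
        assert np.mean(waits) == pytest.approx(10.0, rel=0.05)

    def test_waiting_times_are_exponential(self, rng):
        """10,000 draws at rate 0.1 pass a KS test against Exp(0.1)."""
        waits = np.array([fs.sample_next_event(np.array([0.1]), rng)[0] for _ in range(10_000)])
        _, p = stats.kstest(waits, "expon", args=(0, 10.0))
        assert p > 0.01

    def test_equal_rates_give_equal_selection(self, rng):
        picks = np.array(
            [fs.sample_next_event(np.array([0.1, 0.1]), rng)[1] for _ in range(4000)]
        )
        # total event rate 0.2, each cell chosen w.p. 1/2 (3-sigma band)
        assert abs(picks.mean() - 0.5) < 3 * 0.5 / np.sqrt(4000)

    def test_selection_proportional_to_rate(self, rng):
        rates = np.array([0.3, 0.1])
        picks = np.array([fs.sample_next_event(rates, rng)[1] for _ in range(4000)])
        assert abs((picks == 0).mean() - 0.75) < 3 * np.sqrt(0.75 * 0.25 / 4000)


class TestDivision:
    def _diff_state(self, n=10_000):
        params = get_model_params(
            6, n_init=n, n_diff_threshold=n, n_final=3 * n
        )
        rng = np.random.default_rng(SEED)
        return fs._SimState(params, rng), rng

    def test_division_conserves_count_plus_one(self):
        state, rng = self._diff_state(100)
        before = state.n_cells
        fs.divide_cell(state, 0, rng)
        assert state.n_cells == before + 1

    def test_missing_cell_rejected(self):
        state, rng = self._diff_state(10)
        with pytest.raises(ValueError, match="does not exist"):
            fs.divide_cell(state, 99, rng)

    def test_differentiating_fate_pair_frequencies_model6(self):
        """10,000 differentiating divisions hit (0.2, 0, 0.8) within 3 sigma."""
        state, rng = self._diff_state()
        assert state.diff_active
        pairs = {"HC": 0, "CC": 0, "HH": 0}
        for cid in range(10_000):
            fa, fb, _ = fs.divide_cell(state, cid, rng)
            key = "".join(sorted(fs.TYPE_NAMES[[fa, fb]]))
            pairs["HC" if key == "CH" else key] += 1
        n = 10_000
        assert abs(pairs["HC"] / n - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)
        assert pairs["CC"] == 0
        assert abs(pairs["HH"] / n - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)

    def test_daughter_placed_within_placement_radius(self):
        params = get_model_params(1, n_init=50, n_diff_threshold=60, n_final=80,
                                  spatial_mode=fs.RELAXED_3D, placement_radius=2.0)
        rng = np.random.default_rng(SEED)
        state = fs._SimState(params, rng)
        for cid in range(50):
            mother_pos = np.array(state.positions[cid])
            _, _, daughter = fs.divide_cell(state, cid, rng)
            d = np.linalg.norm(state.positions[daughter] - mother_pos)
            assert d <= params.placement_radius + 1e-9


class TestRelaxation:
    def test_coincident_cells_are_separated(self):
        pos = np.zeros((2, 3))
        out, ok = fs.relax_positions(pos, min_separation=1.0)
        assert ok
        assert np.linalg.norm(out[0] - out[1]) >= 1.0 - 1e-3

    def test_separated_configuration_is_near_identity(self):
        pos = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0]])
        out, ok = fs.relax_positions(pos, min_separation=1.0)
        assert ok
        assert np.allclose(out, pos, atol=1e-9)

    def test_dense_cluster_reaches_minimum_separation(self, rng):
        """500 random points end at least 0.95x min separation apart."""
        pos = rng.normal(scale=3.0, size=(500, 3))
        out, _ = fs.relax_positions(pos, min_separation=1.0, max_iter=500)
        from scipy.spatial.distance import pdist

        assert pdist(out).min() >= 0.95


class TestRunModel:
    def test_reproducible_from_seed(self):
        a = fs.run_simulation(get_model_params(6, n_final=400), seed=SEED)
        b = fs.run_simulation(get_model_params(6, n_final=400), seed=SEED)
        assert a.events.equals(b.events)
        assert a.cells.equals(b.cells)

    def test_count_conservation(self):
        res = fs.run_simulation(get_model_params(4, n_final=500), seed=SEED)
        assert res.cells.shape[0] == res.params.n_init + len(res.events)
        assert res.cells.shape[0] >= res.params.n_final

    def test_differentiation_waits_for_threshold(self):
        res = fs.run_simulation(get_model_params(6, n_final=500), seed=SEED)
        traj = res.trajectory
        first_diff = traj.index[(traj.n_h > 0) | (traj.n_c > 0)][0]
        assert traj.n_p.iloc[first_diff - 1] >= res.params.n_diff_threshold

    def test_model1_ratio_near_one(self):
        ens = fs.run_model(1, n_reps=10, seed=SEED)
        assert ens.mean_ratio == pytest.approx(1.0, abs=max(0.2, 3 * ens.se_ratio))

    def test_model3_matches_mean_field(self):
        # closed form (p_hc + 2 p_hh)/(p_hc + 2 p_cc) = 3 for model 3
        ens = fs.run_model(3, n_reps=10, seed=SEED)
        assert abs(ens.mean_ratio - 3.0) < 3 * ens.se_ratio + 0.15

    def test_all_unipotent_hepatocyte_gives_no_becs(self):
        params = FateModelParams(0.0, 0.0, 1.0, n_init=50, n_diff_threshold=100, n_final=400)
        ens = fs.run_model(params, n_reps=3, seed=SEED)
        for rep in ens.replicates:
            assert rep.final_counts["C"] == 0
            assert not rep.ratio_defined
        assert np.isnan(ens.ratios).all()  # undefined, not an exception

    def test_h_c_swap_symmetry(self):
        """Swapping H and C roles inverts the expected final ratio."""
        params = get_model_params(6, n_init=50, n_diff_threshold=100, n_final=800)
        fwd = fs.run_model(params, n_reps=8, seed=SEED)
        swp = fs.run_model(params.swapped(), n_reps=8, seed=SEED)
        inv = 1.0 / swp.ratios
        se = np.std(np.concatenate([fwd.ratios, inv]), ddof=1) / np.sqrt(8)
        assert abs(fwd.mean_ratio - inv.mean()) < 3 * se + 0.3

    def test_spatial_mode_does_not_affect_fates(self):
        """Final H counts agree between well-mixed and relaxed-3D modes."""
        base = dict(n_init=50, n_diff_threshold=100, n_final=400)
        wm = fs.run_model(get_model_params(6, **base), n_reps=10, seed=SEED)
        rx = fs.run_model(
            get_model_params(6, spatial_mode=fs.RELAXED_3D, **base), n_reps=10, seed=SEED + 1
        )
        h_wm = [r.final_counts["H"] for r in wm.replicates]
        h_rx = [r.final_counts["H"] for r in rx.replicates]
        _, p = stats.mannwhitneyu(h_wm, h_rx, alternative="two-sided")
        assert p > 0.01


class TestTrajectory:
    def test_fractions_sum_to_one_and_start_pure(self):
        res = fs.run_simulation(get_model_params(6, n_final=400), seed=SEED)
        df = fs.ratio_trajectory(res)
        total = df[["frac_p", "frac_h", "frac_c"]].sum(axis=1)
        assert np.allclose(total, 1.0)
        assert (df.iloc[0][["frac_p", "frac_h", "frac_c"]] == [1.0, 0.0, 0.0]).all()

    def test_model6_final_bec_fraction_near_ten_percent(self):
        res = fs.run_simulation(get_model_params(6), seed=SEED)
        df = fs.ratio_trajectory(res)
        assert 0.05 < df.frac_c.iloc[-1] < 0.2
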