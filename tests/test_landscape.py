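import numpy as np
import pytest

from foldcv import (FOLDED, KB_KCAL_PER_MOL_K, TRANSIT, UNFOLDED, FESGrid,
                    Frame, StateSeries, TimeSeries, assign_states_dual_cutoff,
                    count_transitions, delta_F, delta_H, fes, replica_stats,
                    rmsd_ca, rmsd_ca_series, weights_from_bias)

from conftest import random_rotation


def labels_series(labels, dt_ps=1000.0):
    labels = np.asarray(labels)
    return StateSeries(labels=labels, times=np.arange(len(labels)) * dt_ps)


def rmsd_ts(values, dt_ps=100.0):
    v = np.asarray(values, dtype=float)
    return TimeSeries(names=["time", "rmsd_ca"],
                      data=np.column_stack([np.arange(len(v)) * dt_ps, v]))


class TestRmsd:
    def brute_force_rmsd(self, a, b, n_grid=30):
        """Oracle: dense rotation search refined by local optimisation."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)

        def cost(rv):
            R = Rotation.from_rotvec(rv)
            return np.sqrt(np.mean(np.sum((R.apply(a) - b) ** 2, axis=1)))

        best = np.inf
        rng = np.random.default_rng(0)
        for _ in range(n_grid):
            res = minimize(cost, rng.uniform(-np.pi, np.pi, 3), method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, res.fun)
        return best

    def test_self_rmsd_zero(self, system):
        top, folded, _ = system
        assert rmsd_ca(folded, folded, top) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, system):
        top, folded, _ = system
        rot = random_rotation(np.random.default_rng(4))
        moved = Frame(coords=rot.apply(folded.coords) + np.array([3.0, 4.0, 5.0]))
        assert rmsd_ca(moved, folded, top) == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_oracle(self, system):
        top, folded, misfolded = system
        rng = np.random.default_rng(9)
        ca = top.select({"CA"}, protein=True)
        for target in (misfolded.coords,
                       folded.coords + rng.normal(0, 1.0, folded.coords.shape)):
            frame = Frame(coords=target)
            got = rmsd_ca(frame, folded, top)
            oracle = self.brute_force_rmsd(frame.coords[ca], folded.coords[ca])
            assert got == pytest.approx(oracle, abs=1e-4)

    def test_matches_mdanalysis(self, system):
        """Independent cross-check against MDAnalysis' superposition RMSD."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd
        top, folded, misfolded = system
        ca = top.select({"CA"}, protein=True)
        got = rmsd_ca(misfolded, folded, top)
        ref = mda_rmsd(misfolded.coords[ca], folded.coords[ca],
                       center=True, superposition=True)
        assert got == pytest.approx(ref, abs=1e-6)

    def test_too_few_atoms(self):
        from foldcv import Topology
        t = Topology(names=np.array(["CA", "CA"]), elements=np.array(["C", "C"]),
                     resindices=np.array([0, 1]), resnames=np.array(["ALA", "ALA"]),
                     chain_ids=np.array(["A", "A"]), masses=np.full(2, 12.011),
                     is_protein=np.array([True, True]),
                     is_water=np.array([False, False]))
        fr = Frame(coords=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            rmsd_ca(fr, fr, t)


class TestDualCutoff:
    def test_constant_below_folded_cut(self):
        ts = rmsd_ts([1.0] * 50)
        s = assign_states_dual_cutoff(ts, 1.5, 2.5, window=1.0)  # 10 frames
        assert np.all(s.labels[:9] == TRANSIT)
        assert np.all(s.labels[9:] == FOLDED)

    def test_square_wave_counts(self):
        """Half-period 30 frames ≫ 10-frame window: one flip per half-period."""
        half = 30
        values = ([1.0] * half + [4.0] * half) * 4
        s = assign_states_dual_cutoff(rmsd_ts(values), 1.5, 2.5, window=1.0)
        stats = count_transitions(s)
        assert stats.n_folding == 3   # first folded segment starts from transit
        assert stats.n_unfolding == 4

    def test_oscillation_between_cutoffs_never_commits(self):
        values = [2.0, 2.2, 1.8, 2.4, 2.0] * 20  # strictly between 1.5 and 2.5
        s = assign_states_dual_cutoff(rmsd_ts(values), 1.5, 2.5, window=0.5)
        assert np.all(s.labels == TRANSIT)
        with pytest.raises(ValueError):
            count_transitions(s)

    def test_hysteresis_never_exceeds_naive_crossings(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            values = rng.uniform(0.5, 4.0, size=400)
            s = assign_states_dual_cutoff(rmsd_ts(values), 1.5, 2.5, window=0.3)
            stats = count_transitions(s) if np.any(s.labels != TRANSIT) else None
            mid = 2.0
            naive = int(np.sum(np.diff(values > mid) != 0))
            if stats is not None:
                assert stats.n_folding + stats.n_unfolding <= naive

    def test_window_shorter_than_stride(self):
        with pytest.raises(ValueError):
            assign_states_dual_cutoff(rmsd_ts([1.0] * 10, dt_ps=1000.0),
                                      1.5, 2.5, window=0.5)

    def test_cutoff_ordering(self):
        with pytest.raises(ValueError):
            assign_states_dual_cutoff(rmsd_ts([1.0] * 10), 2.5, 1.5, window=1.0)


class TestTransitions:
    def test_hand_counted_sequence(self):
        s = labels_series([UNFOLDED, UNFOLDED, FOLDED, FOLDED, UNFOLDED, FOLDED])
        stats = count_transitions(s)
        assert stats.n_folding == 2
        assert stats.n_unfolding == 1

    def test_all_folded_has_no_transitions(self):
        stats = count_transitions(labels_series([FOLDED] * 10))
        assert stats.n_folding == 0 and stats.n_unfolding == 0
        assert stats.mean_folding_time_us is None
        assert stats.mean_unfolding_time_us is None

    def test_telegraph_residence_times(self):
        """Exponential dwell oracle: mean residence ≈ 1/k within 20%."""
        k_fold, k_unfold = 10.0, 1.0      # events per µs
        dt_us = 0.01                      # 10 ns frames
        n = 100_000                       # 1 ms of signal
        rng = np.random.default_rng(42)
        p_uf = 1.0 - np.exp(-k_fold * dt_us)
        p_fu = 1.0 - np.exp(-k_unfold * dt_us)
        labels = np.empty(n, dtype=int)
        state = UNFOLDED
        u = rng.random(n)
        for i in range(n):
            labels[i] = state
            if state == UNFOLDED and u[i] < p_uf:
                state = FOLDED
            elif state == FOLDED and u[i] < p_fu:
                state = UNFOLDED
        stats = count_transitions(labels_series(labels, dt_ps=dt_us * 1e6))
        assert stats.mean_folding_time_us == pytest.approx(1 / k_fold, rel=0.2)
        assert stats.mean_unfolding_time_us == pytest.approx(1 / k_unfold, rel=0.2)


class TestDeltaF:
    def test_equal_populations_zero(self):
        s = labels_series([FOLDED, UNFOLDED] * 10)
        assert delta_F(s, 340.0) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_e_at_340K(self):
        # population ratio ≈ e via counts 2718:1000
        labels = [FOLDED] * 2718 + [UNFOLDED] * 1000
        s = labels_series(labels)
        expected = -KB_KCAL_PER_MOL_K * 340.0 * np.log(2.718)
        assert delta_F(s, 340.0) == pytest.approx(expected, abs=1e-4)
        assert delta_F(s, 340.0) == pytest.approx(-0.6757, abs=1e-3)

    def test_empty_basin_raises(self):
        with pytest.raises(ValueError):
            delta_F(labels_series([FOLDED] * 5), 300.0)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        labels = rng.choice([FOLDED, UNFOLDED], size=500, p=[0.7, 0.3])
        s = labels_series(labels)
        swapped = labels_series(np.where(labels == FOLDED, UNFOLDED, FOLDED))
        assert delta_F(s, 340.0) == pytest.approx(-delta_F(swapped, 340.0),
                                                  abs=1e-12)

    def test_recovers_known_stationary_population(self):
        """p_F = 0.7 at 340 K → ΔF = −kT ln(7/3) within Monte-Carlo error."""
        rng = np.random.default_rng(17)
        labels = rng.choice([FOLDED, UNFOLDED], size=200_000, p=[0.7, 0.3])
        s = labels_series(labels)
        expected = -KB_KCAL_PER_MOL_K * 340.0 * np.log(7.0 / 3.0)
        assert delta_F(s, 340.0) == pytest.approx(expected, abs=0.02)


class TestDeltaH:
    def energy_ts(self, values):
        v = np.asarray(values, dtype=float)
        return TimeSeries(names=["time", "energy"],
                          data=np.column_stack([np.arange(len(v)) * 1000.0, v]))

    def test_identical_distributions_zero(self):
        e = self.energy_ts([-5.0] * 10)
        s = labels_series([FOLDED, UNFOLDED] * 5)
        assert delta_H(e, s) == 0.0

    def test_arithmetic(self):
        s = labels_series([FOLDED] * 5 + [UNFOLDED] * 5)
        e = self.energy_ts([-10.0] * 5 + [-3.0] * 5)
        assert delta_H(e, s) == pytest.approx(7.0)

    def test_transit_frames_excluded(self):
        s = labels_series([TRANSIT, FOLDED, UNFOLDED, TRANSIT])
        e = self.energy_ts([1000.0, -10.0, -3.0, 1000.0])
        assert delta_H(e, s) == pytest.approx(7.0)

    def test_gaussian_sampling(self):
        rng = np.random.default_rng(8)
        n = 10_000
        ef = rng.normal(-20.0, 3.0, n)
        eu = rng.normal(-15.0, 3.0, n)
        s = labels_series([FOLDED] * n + [UNFOLDED] * n)
        e = self.energy_ts(np.concatenate([ef, eu]))
        se = 3.0 * np.sqrt(2.0 / n)
        assert delta_H(e, s) == pytest.approx(5.0, abs=3 * se)

    def test_misaligned_error(self):
        with pytest.raises(ValueError):
            delta_H(self.energy_ts([1.0, 2.0]), labels_series([FOLDED] * 5))


class TestFES:
    def cv_ts(self, values):
        v = np.asarray(values, dtype=float)
        return TimeSeries(names=["time", "s"],
                          data=np.column_stack([np.arange(len(v)), v]))

    def test_uniform_two_bins(self):
        g = fes(self.cv_ts([0.25, 0.75] * 50), "s", kT=1.0, bins=2,
                ranges=[(0.0, 1.0)])
        np.testing.assert_allclose(g.free_energy, [0.0, 0.0], atol=1e-12)

    def test_weight_ratio_e_gives_one_kT(self):
        ts = self.cv_ts([0.25, 0.75])
        w = np.array([np.e, 1.0])
        g = fes(ts, "s", kT=1.0, weights=w, bins=2, ranges=[(0.0, 1.0)])
        np.testing.assert_allclose(g.free_energy, [0.0, 1.0], atol=1e-12)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        ts = self.cv_ts(rng.normal(size=500))
        w = rng.uniform(0.1, 2.0, size=500)
        g1 = fes(ts, "s", kT=0.6, weights=w, bins=20)
        g2 = fes(ts, "s", kT=0.6, weights=1234.5 * w, bins=20)
        np.testing.assert_allclose(g1.free_energy, g2.free_energy, atol=1e-12)

    def test_min_is_zero_and_empty_bins_inf(self):
        g = fes(self.cv_ts([0.1, 0.1, 0.9]), "s", kT=1.0, bins=4,
                ranges=[(0.0, 1.0)])
        finite = g.free_energy[np.isfinite(g.free_energy)]
        assert finite.min() == 0.0
        assert np.isinf(g.free_energy).sum() == 2

    def test_2d_surface(self):
        rng = np.random.default_rng(0)
        n = 2000
        ts = TimeSeries(names=["time", "a", "b"],
                        data=np.column_stack([np.arange(n),
                                              rng.normal(size=n),
                                              rng.normal(size=n)]))
        g = fes(ts, ["a", "b"], kT=0.64, bins=10)
        assert g.free_energy.shape == (10, 10)
        assert np.nanmin(g.free_energy[np.isfinite(g.free_energy)]) == 0.0

    def test_bias_reweighting_recovers_unbiased_density(self):
        """Samples biased by +V(s) and reweighted by exp(V/kT) must reproduce
        the unbiased histogram."""
        rng = np.random.default_rng(21)
        kT = 1.0
        # two states with unbiased probabilities 0.8 / 0.2; bias flattens them
        p_biased = np.array([0.5, 0.5])
        v_bias = -kT * np.log(np.array([0.8, 0.2]) / p_biased)  # V = F_unb - F_b
        n = 200_000
        states = rng.choice([0, 1], size=n, p=p_biased)
        values = np.where(states == 0, 0.25, 0.75)
        ts = TimeSeries(names=["time", "s", "bias"],
                        data=np.column_stack([np.arange(n), values,
                                              -v_bias[states]]))
        w = weights_from_bias(ts, "bias", kT)
        g = fes(ts, "s", kT=kT, weights=w, bins=2, ranges=[(0.0, 1.0)])
        expected = -kT * np.log(np.array([0.8, 0.2]))
        expected -= expected.min()
        np.testing.assert_allclose(g.free_energy, expected, atol=0.02)

    def test_errors(self):
        ts = self.cv_ts([0.1, 0.2])
        with pytest.raises(ValueError):
            fes(ts, "s", kT=-1.0)
        with pytest.raises(ValueError):
            fes(ts, "s", kT=1.0, weights=np.zeros(2))
        with pytest.raises(ValueError):
            fes(ts, "s", kT=1.0, weights=np.ones(3))


class TestReplicaStats:
    def test_identical_replicas_zero_std(self):
        r = replica_stats([-1.5, -1.5, -1.5])
        assert r.mean == -1.5 and r.std == 0.0

    def test_scalar_arithmetic(self):
        r = replica_stats([-1.0, -2.0, -3.0])
        assert r.mean == pytest.approx(-2.0)
        assert r.std == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-6)  # 0.816

    def test_grid_aggregation_flags_incomplete_bins(self):
        edges = [np.linspace(0, 1, 4)]
        g1 = FESGrid(cv_names=["s"], edges=edges,
                     free_energy=np.array([0.0, 1.0, np.inf]), kT=1.0)
        g2 = FESGrid(cv_names=["s"], edges=edges,
                     free_energy=np.array([0.0, 2.0, 3.0]), kT=1.0)
        r = replica_stats([g1, g2])
        assert r.incomplete_bins.tolist() == [False, False, True]
        np.testing.assert_allclose(r.mean[:2], [0.0, 1.5])
        assert np.isinf(r.mean[2])

    def test_incompatible_binning(self):
        g1 = FESGrid(cv_names=["s"], edges=[np.linspace(0, 1, 4)],
                     free_energy=np.zeros(3), kT=1.0)
        g2 = FESGrid(cv_names=["s"], edges=[np.linspace(0, 2, 4)],
                     free_energy=np.zeros(3), kT=1.0)
        with pytest.raises(ValueError):
            replica_stats([g1, g2])

    def test_needs_two_replicas(self):
        with pytest.raises(ValueError):
            replica_stats([1.0])

    def test_std_shrinks_with_replicas(self):
        rng = np.random.default_rng(30)
        grids = []
        for _ in range(20):
            samples = rng.normal(size=3000)
            ts = TimeSeries(names=["time", "s"],
                            data=np.column_stack([np.arange(3000), samples]))
            grids.append(fes(ts, "s", kT=1.0, bins=8, ranges=[(-3, 3)]))
        r5 = replica_stats(grids[:5])
        r20 = replica_stats(grids)
        # per-bin standard *error of the mean* shrinks ~1/sqrt(n)
        sem5 = np.nanmean(r5.std[np.isfinite(r5.std)]) / np.sqrt(5)
        sem20 = np.nanmean(r20.std[np.isfinite(r20.std)]) / np.sqrt(20)
        assert sem20 < sem5
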