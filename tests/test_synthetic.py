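import numpy as np
import pytest

from placecode import maps, synthetic
from placecode.synthetic import DrugEffect, SessionConfig, SpeedProfile


class TestTrajectory:
    def test_trial_counts(self, bundle, small_config):
        s = bundle.session
        assert s.n_traversals("LR") == small_config.n_trials
        assert s.n_traversals("RL") == small_config.n_trials

    def test_positions_on_track(self, bundle):
        s = bundle.session
        assert s.x_cm.min() >= 0 and s.x_cm.max() <= s.track_length_cm

    def test_monotone_within_traversal(self, bundle):
        s = bundle.session
        for code, sign in ((1, 1), (-1, -1)):
            for t in range(3):
                sel = (s.direction == code) & (s.trial_index == t)
                assert (sign * np.diff(s.x_cm[sel]) > 0).all()

    def test_speed_mostly_in_filter_range(self, bundle, speed):
        trav = bundle.session.direction != 0
        frac = ((speed[trav] >= 8) & (speed[trav] <= 25)).mean()
        assert frac > 0.8

    def test_zero_dwell_opposite_ends(self):
        cfg = SessionConfig(
            n_trials=3, n_neurons=1,
            speed_profile=SpeedProfile(dwell_s=0.0),
        )
        s = synthetic.simulate_trajectory(cfg, np.random.default_rng(0))
        for code, start, end in ((1, 0.0, 160.0), (-1, 160.0, 0.0)):
            for t in range(3):
                sel = np.nonzero((s.direction == code) & (s.trial_index == t))[0]
                assert s.x_cm[sel[0]] == pytest.approx(start)
                assert s.x_cm[sel[-1]] == pytest.approx(end)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SessionConfig(n_trials=0)
        with pytest.raises(ValueError):
            SessionConfig(fps=-1)


class TestTuning:
    def test_no_place_cells(self):
        cfg = SessionConfig(n_neurons=30, place_cell_fraction=0.0)
        tun = synthetic.simulate_tuning(cfg, np.random.default_rng(0))
        assert not tun.is_place_cell.any()
        assert not tun.peak_rate_hz.any()

    def test_place_cell_count_rounding(self):
        cfg = SessionConfig(n_neurons=640, place_cell_fraction=0.55)
        tun = synthetic.simulate_tuning(cfg, np.random.default_rng(0))
        assert tun.is_place_cell.sum() == 352

    def test_population_mean_rate_near_target(self, bundle, small_config):
        rate = bundle.raster.mean_rate_hz()
        assert rate == pytest.approx(small_config.target_mean_rate_hz, rel=0.10)

    def test_selective_cells_silent_in_one_direction(self, bundle):
        tun = bundle.tuning
        pc = tun.is_place_cell
        selective = pc & ((tun.peak_rate_hz[:, 0] == 0) ^ (tun.peak_rate_hz[:, 1] == 0))
        assert selective.sum() == round(0.5 * pc.sum())


class TestEvents:
    def test_zero_rates_zero_raster(self):
        cfg = SessionConfig(
            n_neurons=5, n_trials=2, place_cell_fraction=0.0,
            baseline_rate_hz=0.0,
        )
        rng = np.random.default_rng(0)
        tun = synthetic.simulate_tuning(cfg, rng)
        sess = synthetic.simulate_trajectory(cfg, rng)
        assert not synthetic.simulate_events(sess, tun, rng).counts.any()

    def test_constant_rate_poisson_total(self):
        """1 Hz constant neuron, ~10 min: total within 3 SD of Poisson."""
        cfg = SessionConfig(
            n_neurons=1, n_trials=24, place_cell_fraction=0.0,
            baseline_rate_hz=1.0,
        )
        rng = np.random.default_rng(5)
        tun = synthetic.simulate_tuning(cfg, rng)
        sess = synthetic.simulate_trajectory(cfg, rng)
        total = synthetic.simulate_events(sess, tun, rng).counts.sum()
        expected = sess.duration_s
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_tuned_neuron_events_near_field(self):
        cfg = SessionConfig(
            n_neurons=20, n_trials=6, place_cell_fraction=1.0,
            baseline_rate_hz=0.0, direction_selective_fraction=0.0,
            peak_rate_hz=2.0,
        )
        rng = np.random.default_rng(2)
        tun = synthetic.simulate_tuning(cfg, rng)
        sess = synthetic.simulate_trajectory(cfg, rng)
        ras = synthetic.simulate_events(sess, tun, rng)
        for i in range(5):
            frames = np.nonzero(ras.counts[i])[0]
            if frames.size < 5:
                continue
            dist = np.abs(sess.x_cm[frames] - tun.field_centre_cm[i, 0])
            assert (dist <= 2 * cfg.field_width_cm).mean() > 0.9

    def test_geometry_mismatch(self, bundle):
        cfg = SessionConfig(n_neurons=5, track_length_cm=100.0)
        tun = synthetic.simulate_tuning(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            synthetic.simulate_events(bundle.session, tun)


class TestDrugEffect:
    def test_identity_preserves_tuning(self, bundle):
        out = synthetic.apply_drug_effect(
            bundle.tuning, DrugEffect.identity(), np.random.default_rng(0)
        )
        np.testing.assert_array_equal(out.field_centre_cm, bundle.tuning.field_centre_cm)
        np.testing.assert_array_equal(out.peak_rate_hz, bundle.tuning.peak_rate_hz)
        assert out.detected.all()
        assert out.field_jitter_cm == 0.0

    def test_rate_scaling(self, bundle):
        eff = DrugEffect(rate_scale=0.834, detect_scale=1.0)
        out = synthetic.apply_drug_effect(bundle.tuning, eff, np.random.default_rng(0))
        np.testing.assert_allclose(
            out.peak_rate_hz, 0.834 * bundle.tuning.peak_rate_hz
        )
        np.testing.assert_allclose(
            out.baseline_rate_hz, 0.834 * bundle.tuning.baseline_rate_hz
        )

    def test_retained_count(self):
        cfg = SessionConfig(n_neurons=640)
        tun = synthetic.simulate_tuning(cfg, np.random.default_rng(1))
        eff = DrugEffect(detect_scale=0.847)
        out = synthetic.apply_drug_effect(tun, eff, np.random.default_rng(2))
        assert abs(int(out.detected.sum()) - 542) <= 1

    def test_invalid_effect(self):
        with pytest.raises(ValueError):
            DrugEffect(detect_scale=1.5)
        with pytest.raises(ValueError):
            DrugEffect(rate_scale=-0.1)


class TestPairedExperiment:
    def test_same_seed_bit_identical(self, small_config):
        a = synthetic.generate_paired_experiment(
            small_config, DrugEffect.scopolamine(), seed=77
        )
        b = synthetic.generate_paired_experiment(
            small_config, DrugEffect.scopolamine(), seed=77
        )
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.session.x_cm, y.session.x_cm)
            np.testing.assert_array_equal(x.raster.counts, y.raster.counts)

    def test_shared_identity(self, small_config):
        base, post = synthetic.generate_paired_experiment(
            small_config, DrugEffect.scopolamine(), seed=78
        )
        assert base.raster.n_neurons == post.raster.n_neurons
        np.testing.assert_array_equal(
            base.tuning.is_place_cell, post.tuning.is_place_cell
        )
        # undetected cells keep their rows but emit nothing
        assert not post.raster.counts[~post.tuning.detected].any()

    def test_rate_scale_recovery(self, small_config):
        """Measured post/baseline mean-rate ratio recovers rate_scale."""
        eff = DrugEffect(rate_scale=0.834, detect_scale=1.0)
        ratios = []
        for seed in range(5):
            base, post = synthetic.generate_paired_experiment(
                small_config, eff, seed=200 + seed
            )
            ratios.append(post.raster.mean_rate_hz() / base.raster.mean_rate_hz())
        assert np.mean(ratios) == pytest.approx(0.834, rel=0.05)


def test_solve_baseline_rate_nonnegative():
    assert synthetic.solve_baseline_rate(SessionConfig()) >= 0.0
    rich = SessionConfig(peak_rate_hz=10.0)
    assert synthetic.solve_baseline_rate(rich) == 0.0
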