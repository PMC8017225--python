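import numpy as np
import pytest

from placecode import maps
from placecode.session import EventRaster, TrackSession


def _session(x, fps=30.0, L=160.0, direction=None, trial=None):
    n = len(x)
    return TrackSession(
        x_cm=np.asarray(x, float),
        fps=fps,
        track_length_cm=L,
        direction=np.ones(n, dtype=int) if direction is None else np.asarray(direction),
        trial_index=np.zeros(n, dtype=int) if trial is None else np.asarray(trial),
    )


class TestSpeed:
    def test_constant_position_zero_speed(self):
        s = _session([50.0] * 20)
        assert np.allclose(maps.compute_speed(s), 0.0)

    def test_linear_motion(self):
        s = _session(np.arange(30) * 0.5)  # 0.5 cm/frame at 30 fps
        sp = maps.compute_speed(s)
        assert np.allclose(sp[3:-3], 15.0)

    def test_turning_point_slower_than_run(self):
        # triangular trajectory: hand finite-difference oracle
        x = np.array([0, 2, 4, 6, 8, 10, 8, 6, 4, 2], float)
        sp = maps.compute_speed(_session(x))
        assert sp[5] < sp[2]

    def test_too_short(self):
        with pytest.raises(ValueError):
            maps.compute_speed(_session([0.0, 1.0]))


class TestBinIndex:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, maps.OUTSIDE), (1.99, maps.OUTSIDE), (2.0, 0), (3.99, 0),
         (4.0, 1), (159.99, maps.OUTSIDE), (160.0, maps.OUTSIDE), (157.9, 77)],
    )
    def test_kept_bins(self, binning, x, expected):
        assert maps.bin_index(x, binning, 160.0) == expected

    def test_out_of_track(self, binning):
        with pytest.raises(ValueError):
            maps.bin_index(-1.0, binning, 160.0)

    def test_n_kept_bins(self, binning):
        assert binning.n_kept_bins(160.0) == 78


class TestValidMask:
    def test_speed_filter(self, binning):
        s = _session(np.linspace(10, 100, 50))  # ~54 cm/s: too fast
        assert not maps.valid_frame_mask(s, binning, "LR").any()

    def test_direction_and_bins(self, binning):
        x = np.full(40, 80.0) + np.arange(40) * 0.5
        s = _session(x)
        m_lr = maps.valid_frame_mask(s, binning, "LR")
        m_rl = maps.valid_frame_mask(s, binning, "RL")
        assert m_lr[5:-5].all() and not m_rl.any()

    def test_end_bin_discarded(self, binning):
        x = np.concatenate([np.full(10, 1.0), np.linspace(10, 20, 30)])
        s = _session(x)
        m = maps.valid_frame_mask(s, binning, "LR")
        assert not m[:10].any()


class TestOccupancyCounts:
    def test_conservation(self, bundle, binning, speed):
        occ, counts = maps.occupancy_and_counts(
            bundle.session, bundle.raster, binning, "LR", speed=speed
        )
        mask = maps.valid_frame_mask(bundle.session, binning, "LR", speed=speed)
        assert occ.sum() * bundle.session.fps == pytest.approx(mask.sum())
        assert counts.sum() == bundle.raster.counts[:, mask].sum()

    def test_single_bin_occupancy(self, binning):
        s = _session(np.full(30, 11.0))
        s.direction[:] = 1
        sp = np.full(30, 15.0)
        occ, counts = maps.occupancy_and_counts(
            s, EventRaster(np.zeros((2, 30), dtype=int), 30.0), binning, "LR", speed=sp
        )
        assert occ[maps.bin_index(11.0, binning, 160.0)] == pytest.approx(1.0)
        assert occ.sum() == pytest.approx(1.0)
        assert not counts.any()

    def test_empty_mask_errors(self, binning):
        s = _session(np.full(20, 80.0))  # zero speed
        with pytest.raises(ValueError):
            maps.occupancy_and_counts(
                s, EventRaster(np.zeros((1, 20), dtype=int), 30.0), binning, "LR"
            )


class TestSmoothing:
    def test_constant_unchanged(self, binning):
        v = np.full(20, 3.3)
        assert np.allclose(maps.gaussian_smooth(v, binning), 3.3)

    def test_impulse_gives_kernel(self, binning):
        # oracle: exp(-k^2/(2*1.5^2)), k=-2..2, normalised
        k = np.arange(-2, 3)
        expected = np.exp(-(k**2) / (2 * 1.5**2))
        expected /= expected.sum()
        v = np.zeros(11)
        v[5] = 1.0
        sm = maps.gaussian_smooth(v, binning)
        np.testing.assert_allclose(sm[3:8], expected, atol=1e-12)

    def test_zero_vector(self, binning):
        assert not maps.gaussian_smooth(np.zeros(9), binning).any()

    def test_interior_sum_preserved(self, binning):
        v = np.zeros(30)
        v[10:20] = np.arange(10)
        assert maps.gaussian_smooth(v, binning).sum() == pytest.approx(v.sum())

    def test_kernel_larger_than_vector(self, binning):
        with pytest.raises(ValueError):
            maps.gaussian_smooth(np.ones(3), binning)

    def test_no_negative_output(self, binning):
        rng = np.random.default_rng(0)
        v = rng.poisson(0.5, size=50).astype(float)
        assert (maps.gaussian_smooth(v, binning) >= 0).all()


class TestPlaceFieldMap:
    def test_argmax_at_firing_bin(self, binning):
        rng = np.random.default_rng(1)
        x = np.tile(np.linspace(0, 160, 320, endpoint=False), 3)
        s = _session(x, trial=np.repeat([0, 1, 2], 320))
        sp = np.full(x.size, 15.0)
        counts = np.zeros((1, x.size), dtype=int)
        target = maps.bin_index(x, binning, 160.0) == 7
        counts[0, target] = 1
        pfm = maps.place_field_map(s, EventRaster(counts, 30.0), binning, "LR", speed=sp)
        assert pfm.field_bin[0] == 7

    def test_zero_neuron_flat(self, lr_map):
        silent = lr_map.counts.sum(axis=1) == 0
        if silent.any():
            i = np.nonzero(silent)[0][0]
            assert not lr_map.rate[i].any()
            assert not lr_map.display_map()[i].any()

    def test_rates_without_smoothing(self):
        # 2 bins of 1 s occupancy, counts [4, 0] -> rates [4, 0]
        spec = maps.BinningSpec(
            bin_width_cm=2.0, smooth_sigma_bins=0.0, smooth_size_bins=1
        )
        x = np.concatenate([np.full(30, 3.0), np.full(30, 5.0)])
        s = _session(x)
        sp = np.full(60, 15.0)
        counts = np.zeros((1, 60), dtype=int)
        counts[0, :4] = 1
        pfm = maps.place_field_map(s, EventRaster(counts, 30.0), spec, "LR", speed=sp)
        assert pfm.rate[0, 0] == pytest.approx(4.0)
        assert pfm.rate[0, 1] == pytest.approx(0.0)

    def test_track_reversal_equivariance(self, bundle, binning, speed):
        s = bundle.session
        flipped = TrackSession(
            x_cm=s.track_length_cm - s.x_cm,
            fps=s.fps,
            track_length_cm=s.track_length_cm,
            direction=-s.direction,
            trial_index=s.trial_index,
        )
        a = maps.place_field_map(s, bundle.raster, binning, "LR", speed=speed)
        b = maps.place_field_map(flipped, bundle.raster, binning, "RL", speed=speed)
        np.testing.assert_allclose(a.rate, b.rate[:, ::-1], atol=1e-9)

    def test_field_recovery_within_one_bin(self, binning):
        """Dense sampling + pure Gaussian tuning: argmax within a bin of the
        true field centre."""
        from placecode import synthetic

        cfg = synthetic.SessionConfig(
            n_neurons=40, n_trials=12, place_cell_fraction=1.0,
            peak_rate_hz=8.0, baseline_rate_hz=0.0,
            direction_selective_fraction=0.0, tuning_irregularity_sd=0.0,
        )
        rng = np.random.default_rng(9)
        tun = synthetic.simulate_tuning(cfg, rng=rng)
        sess = synthetic.simulate_trajectory(cfg, rng=rng)
        ras = synthetic.simulate_events(sess, tun, rng=rng)
        sp = maps.compute_speed(sess)
        pfm = maps.place_field_map(sess, ras, binning, "LR", speed=sp)
        interior = (tun.field_centre_cm[:, 0] > 20) & (tun.field_centre_cm[:, 0] < 140)
        idx = np.nonzero(interior)[0]
        centres = pfm.bin_centres_cm()[pfm.field_bin[idx]]
        err_bins = np.abs(centres - tun.field_centre_cm[idx, 0]) / binning.bin_width_cm
        assert np.median(err_bins) <= 1.0
        assert (err_bins <= 2.0).mean() > 0.9

    def test_map_io(self, lr_map, tmp_path):
        maps.write_map(lr_map, tmp_path / "m.tsv")
        lines = (tmp_path / "m.tsv").read_text().splitlines()
        assert len(lines) == 2 + lr_map.n_neurons
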