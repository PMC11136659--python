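"""Task timeline, binning and normalization against hand-computed oracles."""

import numpy as np
import pytest

from wmcrys import (TaskConfig, Trial, bin_activity, build_epoch_windows,
                    epoch_mean, zscore_response_map)
from wmcrys.task_model import InvalidConfigError

from conftest import make_session


class TestEpochWindows:
    def test_default_late_delay_covers_delay_seconds_4_to_5(self, task):
        win = build_epoch_windows(task)
        assert win["late_delay"] == (4.0, 6.0)
        assert win["baseline"] == (-5.0, 0.0)
        assert win["first_odour"] == (0.0, 1.0)
        assert win["early_delay"] == (1.0, 3.0)
        assert win["second_odour"] == (6.0, 7.0)
        assert win["choice"] == (7.0, 10.0)

    def test_half_spans_tile_delay_exactly(self, task):
        win = build_epoch_windows(task, early_span=2.5, late_span=2.5)
        assert win["early_delay"][1] == win["late_delay"][0]
        assert win["early_delay"] == (1.0, 3.5)
        assert win["late_delay"] == (3.5, 6.0)

    def test_overlong_spans_rejected(self, task):
        with pytest.raises(InvalidConfigError):
            build_epoch_windows(task, early_span=3.0, late_span=3.0)

    def test_unknown_epoch_raises(self, windows):
        with pytest.raises(KeyError, match="unknown epoch"):
            windows["reward"]

    @pytest.mark.parametrize("field", ["delay_dur", "frame_rate", "bin_width"])
    def test_nonpositive_durations_rejected(self, field):
        with pytest.raises(InvalidConfigError, match=field):
            TaskConfig(**{field: 0.0})


class TestBinActivity:
    def test_shape_10hz_500ms_15s_trial(self, task, random_session):
        tensor = bin_activity(random_session, task)
        assert tensor.values.shape == (20, 6, 30)
        assert tensor.bin_edges[0] == -5.0 and tensor.bin_edges[-1] == 10.0

    def test_all_zero_activity_gives_zero_tensor(self, task):
        s = make_session(np.zeros((4, 2, task.n_frames)))
        assert not bin_activity(s, task).values.any()

    def test_hand_summed_frame_pattern(self, task):
        # one neuron, 1s of unit frames then silence: first two bins 5 and 5
        act = np.zeros((1, 1, task.n_frames))
        act[0, 0, :10] = 1.0
        tensor = bin_activity(make_session(act), task)
        assert tensor.values[0, 0, 0] == 5.0
        assert tensor.values[0, 0, 1] == 5.0
        assert tensor.values[0, 0, 2:].sum() == 0.0

    def test_mass_conserved_when_extent_divides_evenly(self, task):
        rng = np.random.default_rng(3)
        act = rng.exponential(size=(5, 3, task.n_frames))
        tensor = bin_activity(make_session(act), task)
        assert np.isclose(tensor.values.sum(), act.sum())

    def test_trailing_partial_bin_dropped(self, task):
        # 153 frames at 10 Hz: 15.3 s -> 30 bins, last 3 frames dropped
        act = np.ones((2, 1, 153))
        tensor = bin_activity(make_session(act), task)
        assert tensor.values.shape[2] == 30
        assert tensor.values.sum() < act.sum()

    def test_nan_error_names_neuron_and_frame(self, task):
        act = np.zeros((2, 3, task.n_frames))
        act[1, 2, 7] = np.nan
        with pytest.raises(ValueError, match="neuron 2.*frame 7"):
            bin_activity(make_session(act), task)

    def test_empty_session_rejected(self, task):
        s = make_session(np.zeros((1, 1, task.n_frames)))
        s.activity = s.activity[:0]
        s.trials = []
        with pytest.raises(ValueError, match="empty"):
            bin_activity(s, task)


class TestEpochMean:
    def test_constant_tensor_gives_constant(self, task, windows):
        s = make_session(np.full((4, 2, task.n_frames), 0.4))
        tensor = bin_activity(s, task)
        for ep in windows.names():
            assert np.allclose(epoch_mean(tensor, windows, ep), 2.0)

    def test_matches_bruteforce_loop(self, task, windows, random_session):
        tensor = bin_activity(random_session, task)
        got = epoch_mean(tensor, windows, "late_delay")
        start, end = windows["late_delay"]
        bins = [b for b in range(tensor.n_bins)
                if start <= tensor.bin_starts[b] < end]
        for t in range(tensor.values.shape[0]):
            for n in range(tensor.values.shape[1]):
                expect = np.mean([tensor.values[t, n, b] for b in bins])
                assert abs(got[t, n] - expect) < 1e-12

    def test_linear_in_activity(self, task, windows, random_session):
        tensor = bin_activity(random_session, task)
        scaled = bin_activity(
            make_session(random_session.activity * 3.5), task)
        assert np.allclose(epoch_mean(scaled, windows, "choice"),
                           3.5 * epoch_mean(tensor, windows, "choice"))

    def test_unknown_epoch_raises(self, task, windows, random_session):
        tensor = bin_activity(random_session, task)
        with pytest.raises(KeyError):
            epoch_mean(tensor, windows, "nope")


class TestZscoreResponseMap:
    def test_arithmetic_example(self, task, windows):
        # baseline bins alternate 0.2/0.6 per frame -> binned 1 and 3:
        # mean 2, sd 1; a later bin of 4 maps to z = 2
        act = np.zeros((1, 1, task.n_frames))
        act[0, 0, :50] = np.tile(np.repeat([0.2, 0.6], 5), 5)
        act[0, 0, 50:55] = 0.8   # first_odour bin sums to 4
        tensor = bin_activity(make_session(act), task)
        zmap, flagged = zscore_response_map(tensor, windows)
        assert not flagged[0]
        assert np.isclose(zmap[0, 10], 2.0)

    def test_constant_trace_flagged_zero(self, task, windows):
        s = make_session(np.full((3, 2, task.n_frames), 0.1))
        zmap, flagged = zscore_response_map(bin_activity(s, task), windows)
        assert flagged.all()
        assert not zmap.any()

    def test_baseline_window_standardized(self, task, windows,
                                          random_session):
        tensor = bin_activity(random_session, task)
        zmap, flagged = zscore_response_map(tensor, windows)
        base = tensor.epoch_bin_mask(windows, "baseline")
        ok = ~flagged
        assert np.allclose(zmap[ok][:, base].mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(zmap[ok][:, base].std(axis=1), 1.0, atol=1e-9)


class TestTrial:
    @pytest.mark.parametrize("tt,licked,outcome", [
        ("AC", True, "hit"), ("BD", False, "miss"),
        ("AD", True, "false_alarm"), ("BC", False, "correct_rejection")])
    def test_outcome_is_deterministic(self, tt, licked, outcome):
        t = Trial(trial_type=tt, licked=licked)
        assert t.outcome == outcome
        assert t.rewarded == (tt in ("AC", "BD"))
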