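"""Generator correctness: planted counts, drift schedule, event statistics."""

import dataclasses

import numpy as np
import pytest

from wmcrys import (GeneratorConfig, generate_cohort, ground_truth_summary,
                    performance, simulate_behaviour)
from wmcrys.task_model import InvalidConfigError


def small_config(**kw):
    base = dict(n_animals=1, n_days=2, n_neurons=50, trials_per_day=40,
                crystallization_day=2, seed=1)
    base.update(kw)
    return GeneratorConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_neurons", 0), ("mixed_prob", 1.5), ("retention", -0.1),
        ("error_rate", 1.0), ("effect_rate_hi", -1.0),
        ("detection_dropout", 1.0)])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(InvalidConfigError, match=field):
            small_config(**{field: value})

    def test_crystallization_day_bound(self):
        with pytest.raises(InvalidConfigError, match="crystallization_day"):
            small_config(n_days=3, crystallization_day=5)

    def test_unknown_epoch_rejected(self):
        with pytest.raises(InvalidConfigError, match="frac_selective"):
            small_config(frac_selective={"reward": 0.1})


class TestPlantedTuning:
    def test_exact_selective_count_by_construction(self):
        cfg = small_config(n_neurons=200, frac_selective={"first_odour": 0.1},
                           pair_cell_frac=0.0)
        _, gt = generate_cohort(cfg)
        assert len(gt.selective_ids("m01", 1, "first_odour")) == 20

    def test_quotas_exact_for_all_epochs_every_day(self):
        cfg = small_config(n_neurons=100, n_days=3, crystallization_day=3,
                           retention=0.5)
        _, gt = generate_cohort(cfg)
        for d in range(1, 4):
            for ep, frac in cfg.frac_selective.items():
                assert len(gt.selective_ids("m01", d, ep)) \
                    == int(np.floor(frac * 100))

    def test_full_retention_freezes_tuning(self):
        cfg = small_config(n_days=4, retention=1.0, crystallization_day=5)
        _, gt = generate_cohort(cfg)
        day1 = gt.tuning[gt.tuning.day == 1].drop(columns="day")
        for d in range(2, 5):
            dd = gt.tuning[gt.tuning.day == d].drop(columns="day")
            assert day1.reset_index(drop=True).equals(
                dd.reset_index(drop=True))

    def test_overlap_equals_retention_in_binomial_band(self):
        cfg = small_config(n_neurons=300, n_days=6, crystallization_day=7,
                           retention=0.6, trials_per_day=10, seed=3)
        _, gt = generate_cohort(cfg)
        summ = ground_truth_summary(gt)
        ov = summ.dropna(subset=["overlap_next_day"])
        # pooled kept fraction over all epochs/transitions; expectation is
        # rho plus the small chance a dropped neuron is redrawn
        n_tuned = sum(len(gt.selective_ids("m01", d, ep))
                      for d in range(1, 6) for ep in cfg.frac_selective)
        pooled = np.average(ov.overlap_next_day,
                            weights=[len(gt.selective_ids("m01", r.day,
                                                          r.epoch))
                                     for r in ov.itertuples()])
        k = 0.15 * 300   # typical per-epoch quota scale for the chance term
        p_exp = 0.6 + 0.4 * (k * 0.4) / 300
        half = 1.96 * np.sqrt(p_exp * (1 - p_exp) / n_tuned)
        assert abs(pooled - p_exp) < half + 0.02

    def test_zero_retention_overlap_is_chance_redraw_rate(self):
        cfg = small_config(n_neurons=250, n_days=8, crystallization_day=9,
                           retention=0.0, trials_per_day=10,
                           frac_selective={"first_odour": 0.2},
                           pair_cell_frac=0.0, seed=4)
        _, gt = generate_cohort(cfg)
        ov = ground_truth_summary(gt)
        ov = ov[ov.epoch == "first_odour"].dropna(subset=["overlap_next_day"])
        k = 50
        p_chance = k / 250          # refill draws k slots from all n neurons
        pooled = ov.overlap_next_day.mean()
        half = 1.96 * np.sqrt(p_chance * (1 - p_chance) / (k * len(ov)))
        assert abs(pooled - p_chance) < half

    def test_crystallization_freezes_late_days_only(self):
        cfg = small_config(n_days=6, retention=0.2, crystallization_day=4,
                           trials_per_day=10, seed=5)
        _, gt = generate_cohort(cfg)
        summ = ground_truth_summary(gt).dropna(subset=["overlap_next_day"])
        late = summ[summ.day >= 4]
        early = summ[summ.day < 4]
        assert (late.overlap_next_day == 1.0).all()
        assert early.overlap_next_day.mean() < 0.6


class TestActivityStatistics:
    def test_nonnegative_everywhere(self, tiny_cohort):
        cohort, _ = tiny_cohort
        for s in cohort.sessions:
            assert (s.activity >= 0).all()

    def test_same_seed_bit_identical_different_seed_differs(self):
        cfg = small_config()
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        c, _ = generate_cohort(dataclasses.replace(cfg, seed=2))
        assert all(np.array_equal(x.activity, y.activity)
                   for x, y in zip(a.sessions, b.sessions))
        assert not np.array_equal(a.sessions[0].activity,
                                  c.sessions[0].activity)

    def test_nonselective_mean_event_mass_converges_to_noise_rate(self):
        # >= 1e5 bin samples of pure-noise neurons: relative error < 5%
        cfg = small_config(n_days=1, n_neurons=120, trials_per_day=40,
                           crystallization_day=1,
                           frac_selective={}, noise_rate=0.2, seed=6)
        cohort, _ = generate_cohort(cfg)
        act = cohort.sessions[0].activity
        fpb = cfg.task.frame_rate * cfg.task.bin_width
        per_bin = act.mean() * fpb
        n_bins = act.size / fpb
        assert n_bins >= 1e5
        assert abs(per_bin - 0.2) / 0.2 < 0.05

    def test_detection_dropout_shrinks_sessions(self):
        cfg = small_config(detection_dropout=0.3, n_neurons=200)
        cohort, gt = generate_cohort(cfg)
        n = cohort.sessions[0].n_neurons
        assert 200 * 0.55 < n < 200 * 0.85
        assert set(cohort.sessions[0].neuron_ids) == set(
            gt.detected[gt.detected.day == 1].neuron_id)


class TestSimulateBehaviour:
    def test_error_free_is_perfect_with_no_abort(self):
        cfg = small_config(error_rate=0.0)
        trials = simulate_behaviour(cfg, 100)
        assert len(trials) == 100
        assert performance(trials).performance == 1.0

    def test_law_of_large_numbers_performance(self):
        cfg = small_config(error_rate=0.2, apply_abort=False)
        trials = simulate_behaviour(cfg, 10_000,
                                    rng=np.random.default_rng(9))
        p = performance(trials, apply_abort=False).performance
        assert abs(p - 0.8) < 1.96 * np.sqrt(0.8 * 0.2 / 10_000) + 0.005

    def test_abort_truncates_after_miss_run(self):
        cfg = small_config(error_rate=0.9, seed=13)
        trials = simulate_behaviour(cfg, 200)
        assert len(trials) < 200
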