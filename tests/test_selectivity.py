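"""Selectivity statistics against enumeration and degenerate-case oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wmcrys import (EpochWindows, TrialTensor, activity_field_test,
                    associated_pair_cells, classify_profile,
                    movement_correlation_test, selectivity_test,
                    sequence_correlation)
from wmcrys.task_model import Trial

from conftest import make_session

ONE_BIN_WIN = EpochWindows({"e": (0.0, 0.5)})


def one_bin_tensor(values):
    """[n_trials] of scalars as a 1-neuron, 1-bin TrialTensor."""
    v = np.asarray(values, dtype=float)[:, None, None]
    return TrialTensor(values=v, bin_edges=np.array([0.0, 0.5]))


def exhaustive_ranksum_p(g1, g2):
    """Symmetric-tail permutation p of the rank-sum U over all label splits."""
    pooled = np.concatenate([g1, g2])
    n1 = len(g1)
    mu = n1 * len(g2) / 2

    def ustat(a, b):
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    u_obs = ustat(g1, g2)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        rest = [i for i in range(len(pooled)) if i not in combo]
        us.append(ustat(pooled[list(combo)], pooled[rest]))
    us = np.array(us)
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))


class TestSelectivityTest:
    def test_disjoint_small_groups_exact_p(self):
        tensor = one_bin_tensor([1, 2, 3, 4, 5, 6])
        labels = ["A", "A", "A", "B", "B", "B"]
        res = selectivity_test(tensor, ONE_BIN_WIN, "e", labels, "first_odour")
        assert res.p[0] == pytest.approx(0.1, abs=1e-12)
        assert not res.selective[0]
        assert res.preferred[0] == "B"
        assert res.auc[0] == 0.0   # every A value below every B value

    def test_identical_distributions_not_selective(self):
        tensor = one_bin_tensor([2.0] * 8)
        res = selectivity_test(tensor, ONE_BIN_WIN, "e",
                               ["A", "B"] * 4, "first_odour")
        assert res.p[0] == 1.0
        assert not res.selective[0]
        assert res.ambiguous[0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration_4v4(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=8)
        labels = np.array(["A"] * 4 + ["B"] * 4)
        res = selectivity_test(one_bin_tensor(vals), ONE_BIN_WIN, "e",
                               labels, "first_odour")
        assert res.p[0] == pytest.approx(
            exhaustive_ranksum_p(vals[:4], vals[4:]), abs=1e-12)

    def test_auc_flips_under_label_exchange(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=10)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        a = selectivity_test(one_bin_tensor(vals), ONE_BIN_WIN, "e",
                             labels, "c")
        flipped = np.where(labels == "A", "B", "A")
        # group order is alphabetical, so relabelling mirrors the AUC
        b = selectivity_test(one_bin_tensor(vals), ONE_BIN_WIN, "e",
                             flipped, "c")
        assert a.auc[0] == pytest.approx(1.0 - b.auc[0], abs=1e-12)
        assert a.p[0] == pytest.approx(b.p[0], abs=1e-12)

    def test_too_few_trials_per_label_rejected(self):
        tensor = one_bin_tensor([1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match=">= 3 trials"):
            selectivity_test(tensor, ONE_BIN_WIN, "e",
                             ["A", "A", "A", "A", "B"], "c")

    def test_single_label_rejected(self):
        tensor = one_bin_tensor([1, 2, 3, 4])
        with pytest.raises(ValueError, match="exactly 2 labels"):
            selectivity_test(tensor, ONE_BIN_WIN, "e", ["A"] * 4, "c")


class TestClassifyProfile:
    def _results(self, flags):
        return pd.DataFrame({
            "neuron_index": [0] * len(flags),
            "epoch": [f"ep{i}" for i in range(len(flags))],
            "comparison": "first_odour",
            "selective": flags})

    @pytest.mark.parametrize("flags,category", [
        ([True, False, False], "pure"),
        ([True, True, False], "mixed"),
        ([False, False, False], "none")])
    def test_taxonomy_forced_by_definition(self, flags, category):
        prof = classify_profile(self._results(flags))
        assert prof.category[0] == category


class TestAssociatedPairCells:
    def _grid(self, rows):
        return pd.DataFrame(rows, columns=[
            "neuron_index", "comparison", "epoch", "selective", "preferred",
            "ambiguous"])

    def test_a_and_c_pairing_included(self):
        rows = [(1, "first_odour", "first_odour", True, "A", False),
                (1, "second_odour", "second_odour", True, "C", False),
                (2, "first_odour", "first_odour", True, "B", False),
                (2, "second_odour", "second_odour", True, "D", False)]
        assert list(associated_pair_cells(self._grid(rows))) == [1, 2]

    def test_wrong_pairing_excluded(self):
        rows = [(1, "first_odour", "first_odour", True, "A", False),
                (1, "second_odour", "second_odour", True, "D", False)]
        assert associated_pair_cells(self._grid(rows)).size == 0

    def test_no_overlap_empty(self):
        rows = [(1, "first_odour", "first_odour", True, "A", False),
                (2, "second_odour", "second_odour", True, "C", False)]
        assert associated_pair_cells(self._grid(rows)).size == 0

    def test_planted_pair_cells_recovered(self, task, windows):
        import wmcrys
        cfg = wmcrys.GeneratorConfig(
            n_animals=1, n_days=1, n_neurons=150, trials_per_day=120,
            crystallization_day=1, pair_cell_frac=0.04, error_rate=0.0,
            detection_dropout=0.0, seed=8)
        cohort, gt = wmcrys.generate_cohort(cfg)
        s = cohort.sessions[0]
        tensor = wmcrys.bin_activity(s, cfg.task)
        grid = wmcrys.selectivity_grid(tensor, windows, s.trials)
        found = set(associated_pair_cells(grid))
        fo = gt.preferred("m01", 1, "first_odour")
        so = gt.preferred("m01", 1, "second_odour")
        planted = {n for n in set(fo.index) & set(so.index)
                   if (fo[n], so[n]) in (("A", "C"), ("B", "D"))}
        assert len(planted) >= 6
        # most planted pair cells recovered, few spurious extras
        assert len(found & planted) >= 0.8 * len(planted)
        assert len(found - planted) <= max(3, 0.02 * 150)


class TestActivityFieldTest:
    def test_all_zero_neuron_never_significant(self, task, windows):
        s = make_session(np.zeros((5, 2, task.n_frames)))
        res = activity_field_test(s, task, windows, "late_delay",
                                  n_shuffles=100, seed=0)
        assert (res.p == 1.0).all()
        assert not res.significant.any()

    def test_permutation_floor_when_all_mass_in_epoch(self, task, windows):
        # single trial, constant mass exactly filling the first-odour epoch:
        # every nonzero circular shift strictly lowers the epoch mean
        act = np.zeros((1, 1, task.n_frames))
        act[0, 0, 50:60] = 1.0
        s = make_session(act)
        res = activity_field_test(s, task, windows, "first_odour",
                                  n_shuffles=1000, seed=0)
        assert res.p[0] == pytest.approx(1 / 1001)
        assert res.significant[0]

    def test_p_has_permutation_floor(self, task, windows, random_session):
        res = activity_field_test(random_session, task, windows, "choice",
                                  n_shuffles=50, seed=1)
        assert (res.p >= 1 / 51 - 1e-12).all()
        assert (res.p <= 1.0).all()


class TestMovementCorrelation:
    def test_trace_equal_to_locomotion_significant(self):
        rng = np.random.default_rng(0)
        loco = np.convolve(rng.standard_normal(2000), np.ones(30) / 30,
                           mode="same")
        res = movement_correlation_test(loco.copy(), loco, n_shuffles=500,
                                        seed=1)
        assert res.r[0] == pytest.approx(1.0)
        assert res.significant[0]

    def test_constant_neuron_degenerate_not_significant(self):
        loco = np.random.default_rng(1).random(500)
        res = movement_correlation_test(np.full(500, 2.0), loco,
                                        n_shuffles=200, seed=2)
        assert res.degenerate[0]
        assert not res.significant[0]
        assert np.isnan(res.r[0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            movement_correlation_test(np.ones(100), np.ones(99))


class TestSequenceCorrelation:
    def _tensor_and_trials(self, a_trace, b_trace, n_trials=4):
        n_bins = a_trace.shape[1]
        vals = np.concatenate([
            np.tile(a_trace, (n_trials, 1, 1)),
            np.tile(b_trace, (n_trials, 1, 1))])
        trials = [Trial("AC", True)] * n_trials + \
                 [Trial("BD", True)] * n_trials
        edges = 0.5 * np.arange(n_bins + 1)
        return TrialTensor(values=vals, bin_edges=edges), trials

    def test_identical_coding_r_one(self):
        rng = np.random.default_rng(3)
        trace = rng.random((3, 12))
        tensor, trials = self._tensor_and_trials(trace, trace)
        res = sequence_correlation(tensor, trials)
        assert np.allclose(res.per_neuron_r, 1.0)

    def test_type_specific_sequences_anticorrelated(self):
        trace_a = np.eye(4, 12, k=2)         # peaks at bins 2..5
        trace_b = np.eye(4, 12, k=6)         # peaks at bins 6..9
        tensor, trials = self._tensor_and_trials(trace_a, trace_b)
        res = sequence_correlation(tensor, trials)
        assert (res.per_neuron_r < 0.2).all()
        assert list(res.peak_bin["AC"]) == [2, 3, 4, 5]
        assert list(res.peak_bin["BD"]) == [6, 7, 8, 9]

    def test_per_neuron_r_invariant_to_neuron_order(self):
        rng = np.random.default_rng(4)
        ta, tb = rng.random((5, 10)), rng.random((5, 10))
        tensor, trials = self._tensor_and_trials(ta, tb)
        r1 = sequence_correlation(tensor, trials).per_neuron_r
        perm = rng.permutation(5)
        tensor2, _ = self._tensor_and_trials(ta[perm], tb[perm])
        r2 = sequence_correlation(tensor2, trials).per_neuron_r
        assert np.allclose(r1[perm], r2)

    def test_flat_neuron_recorded_missing(self):
        ta = np.vstack([np.ones((1, 10)), np.random.default_rng(5).random((1, 10))])
        tensor, trials = self._tensor_and_trials(ta, ta)
        res = sequence_correlation(tensor, trials)
        assert np.isnan(res.per_neuron_r[0])
        assert np.isfinite(res.per_neuron_r[1])
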