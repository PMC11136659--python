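"""Cross-day decoder generalization and crystallization estimation.

A decoder trained on all trials of day i (restricted to neurons matched
between the two days) is tested on all trials of day j; the diagonal holds
the same-day cross-validated accuracy so the matrix is comparable on and off
the diagonal.  Stability contrasts mean off-diagonal accuracy between an
early and a late block of days, tested across animals (one-sided, late >
early, since the hypothesis is directional) and by a day-identity
permutation test.  The crystallization day is estimated as the block change
point maximizing the post-minus-pre off-diagonal accuracy difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import registration
from .decoding import DecodingConfig, decode_bin, fit_and_score, same_day_decoding
from .synthetic import Cohort
from .task_model import (EpochWindows, Session, TaskConfig, bin_activity,
                         labels_for)

logger = logging.getLogger("wmcrys.stability")


@dataclass
class CrossDayMatrix:
    """Day x day decoder-generalization accuracies for one animal and epoch."""

    acc: np.ndarray                     # [n_days, n_days], NaN = missing
    n_matched: np.ndarray               # neurons used per (train, test) pair
    days: np.ndarray                    # 1-based day indices (row/col order)
    epoch: str
    label_kind: str
    animal_id: str

    def day_pos(self, day: int) -> int:
        pos = np.flatnonzero(self.days == day)
        if pos.size == 0:
            raise KeyError(f"day {day} not in matrix")
        return int(pos[0])


def _block_offdiag_mean(acc: np.ndarray, positions: np.ndarray) -> float:
    """Mean over off-diagonal (train, test) pairs within one block of days."""
    if len(positions) < 2:
        raise ValueError("a block needs >= 2 days to have off-diagonal pairs")
    vals = [acc[i, j] for i in positions for j in positions if i != j]
    return float(np.nanmean(vals))


def cross_day_decoding(sessions: Sequence[Session], task: TaskConfig,
                       windows: EpochWindows, epoch: str,
                       label_kind: str = "first_odour",
                       config: DecodingConfig = DecodingConfig(),
                       seed: Optional[int] = None,
                       max_dist: float = registration.DEFAULT_MAX_DIST_UM,
                       min_matched: int = 10,
                       matching: Optional[dict] = None) -> CrossDayMatrix:
    """Train-on-day-i / test-on-day-j accuracy matrix for one animal.

    Matched-neuron scope is the pairwise intersection per (i, j) — found by
    centroid registration unless an explicit ``matching`` of
    ``(day_i, day_j) -> (index_i, index_j)`` arrays is supplied — which
    maximizes the neurons available to each pair.  Off-diagonal entries use
    one decoder per time bin trained on all day-i trials; diagonal entries
    are the same-day cross-validated accuracy on all of that day's neurons.
    Pairs with fewer than ``min_matched`` common neurons stay NaN.
    """
    sessions = sorted(sessions, key=lambda s: s.day_index)
    animals = {s.animal_id for s in sessions}
    if len(animals) != 1:
        raise ValueError(f"sessions span several animals: {sorted(animals)}")
    days = np.array([s.day_index for s in sessions])
    n_days = len(days)
    tensors = [bin_activity(s, task) for s in sessions]
    labels = [labels_for(s.trials, label_kind) for s in sessions]
    bin_mask = tensors[0].epoch_bin_mask(windows, epoch)
    bins = np.flatnonzero(bin_mask)

    acc = np.full((n_days, n_days), np.nan)
    n_matched = np.zeros((n_days, n_days), dtype=int)
    ss = np.random.SeedSequence(seed).spawn(n_days * n_days)

    for i in range(n_days):
        # diagonal: held-out cross-validated accuracy, all day-i neurons
        res = same_day_decoding(tensors[i], labels[i], windows, config,
                                seed=int(np.random.default_rng(
                                    ss[i * n_days + i]).integers(2 ** 31)),
                                epochs=[epoch])
        acc[i, i] = res.epoch_acc[epoch]
        n_matched[i, i] = sessions[i].n_neurons
        for j in range(n_days):
            if j == i:
                continue
            if matching is not None:
                idx_i, idx_j = matching[(days[i], days[j])]
            else:
                table = registration.match_sessions(sessions[i], sessions[j],
                                                    max_dist=max_dist)
                idx_i, idx_j = table.index_arrays()
            n_matched[i, j] = len(idx_i)
            if len(idx_i) < min_matched:
                logger.warning("day pair (%d, %d): only %d matched neurons; "
                               "entry left missing", days[i], days[j],
                               len(idx_i))
                continue
            bin_accs = [fit_and_score(tensors[i].values[:, idx_i, b],
                                      labels[i],
                                      tensors[j].values[:, idx_j, b],
                                      labels[j], config.C)
                        for b in bins]
            acc[i, j] = float(np.mean(bin_accs))

    return CrossDayMatrix(acc=acc, n_matched=n_matched, days=days,
                          epoch=epoch, label_kind=label_kind,
                          animal_id=sessions[0].animal_id)


def cohort_cross_day(cohort: Cohort, windows: EpochWindows, epoch: str,
                     label_kind: str = "first_odour",
                     config: DecodingConfig = DecodingConfig(),
                     seed: Optional[int] = None,
                     **kwargs) -> list[CrossDayMatrix]:
    """Cross-day matrix per animal of a cohort (one child seed per animal)."""
    animals = cohort.animals()
    ss = np.random.SeedSequence(seed).spawn(len(animals))
    out = []
    for a, animal in enumerate(animals):
        sess = [s for s in cohort.sessions if s.animal_id == animal]
        out.append(cross_day_decoding(
            sess, cohort.task, windows, epoch, label_kind, config,
            seed=int(np.random.default_rng(ss[a]).integers(2 ** 31)),
            **kwargs))
    return out


@dataclass
class StabilityStats:
    """Early/late block contrast of off-diagonal cross-day accuracy."""

    early_days: tuple
    late_days: tuple
    early_means: np.ndarray             # per animal
    late_means: np.ndarray
    difference: float                   # mean(late) - mean(early)
    t_stat: float
    p_value: float                      # one-sided, late > early
    shuffle_p: Optional[float] = None


def block_stability_stat(matrices: Sequence[CrossDayMatrix],
                         early_days: Sequence[int],
                         late_days: Sequence[int]) -> StabilityStats:
    """Across-animal contrast of mean off-diagonal accuracy, late vs early.

    Per animal, the mean is over off-diagonal (train, test) pairs whose days
    both lie in the block; blocks must be disjoint and contain at least two
    days each.  The across-animal test is an unpaired one-sided t-test.
    """
    early_days, late_days = tuple(early_days), tuple(late_days)
    if set(early_days) & set(late_days):
        raise ValueError("early and late blocks must be disjoint")
    early, late = [], []
    for m in matrices:
        e_pos = np.array([m.day_pos(d) for d in early_days])
        l_pos = np.array([m.day_pos(d) for d in late_days])
        early.append(_block_offdiag_mean(m.acc, e_pos))
        late.append(_block_offdiag_mean(m.acc, l_pos))
    early = np.asarray(early)
    late = np.asarray(late)
    diff = float(late.mean() - early.mean())
    if len(matrices) >= 2:
        t, p = stats.ttest_ind(late, early, alternative="greater")
        t, p = float(t), float(p)
        if np.isnan(p):        # zero variance in both groups
            p = 1.0 if diff <= 0 else 0.0
            t = np.inf if diff > 0 else 0.0
    else:
        t, p = np.nan, np.nan
    return StabilityStats(early_days=early_days, late_days=late_days,
                          early_means=early, late_means=late,
                          difference=diff, t_stat=t, p_value=p)


def day_shuffle_test(matrices: Sequence[CrossDayMatrix],
                     early_days: Sequence[int], late_days: Sequence[int],
                     n_perm: int = 1000,
                     seed: Optional[int] = None) -> float:
    """Permutation p for the late-minus-early block difference.

    Each permutation relabels the days — the same permutation applied jointly
    to rows and columns of every animal's matrix — and recomputes the block
    difference; p = (1 + #{perm diff >= observed}) / (n_perm + 1), one-sided.
    """
    days = matrices[0].days
    for m in matrices:
        if not np.array_equal(m.days, days):
            raise ValueError("matrices must share the same day set")
    e_pos = np.array([matrices[0].day_pos(d) for d in early_days])
    l_pos = np.array([matrices[0].day_pos(d) for d in late_days])

    def block_diff(accs: Sequence[np.ndarray]) -> float:
        e = np.mean([_block_offdiag_mean(a, e_pos) for a in accs])
        l = np.mean([_block_offdiag_mean(a, l_pos) for a in accs])
        return l - e

    observed = block_diff([m.acc for m in matrices])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(days))
        permuted = [m.acc[np.ix_(perm, perm)] for m in matrices]
        if block_diff(permuted) >= observed - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)


@dataclass
class CrystallizationEstimate:
    """Block change point of the day x day accuracy matrix."""

    day: Optional[int]                  # estimated first stable day, or None
    objective: np.ndarray               # post-minus-pre difference per candidate
    candidates: np.ndarray              # candidate days evaluated
    margin: float
    band: Optional[tuple] = None        # bootstrap percentile interval on day


def estimate_crystallization_day(matrix: CrossDayMatrix | np.ndarray,
                                 days: Optional[np.ndarray] = None,
                                 margin: float = 0.05,
                                 n_boot: int = 200,
                                 seed: Optional[int] = None
                                 ) -> CrystallizationEstimate:
    """Estimate the day from which the cross-day code is stable.

    For each candidate day c the objective is the mean off-diagonal accuracy
    among days >= c minus the mean among days < c (each side needs at least
    one off-diagonal pair, so candidates run from the third day to the
    second-to-last).  The estimate is the argmax, or None when the best
    difference is below ``margin``.  The confidence band resamples
    off-diagonal cells within each side (bootstrap percentile interval of the
    re-estimated day).
    """
    if isinstance(matrix, CrossDayMatrix):
        acc, days = matrix.acc, matrix.days
    else:
        acc = np.asarray(matrix, dtype=float)
        days = np.arange(1, acc.shape[0] + 1) if days is None else days
    n = len(days)
    if n < 4:
        raise ValueError("need >= 4 days to estimate a change point")
    candidates = days[2:n - 1]

    def side_vals(pos: np.ndarray) -> np.ndarray:
        return np.array([acc[i, j] for i in pos for j in pos if i != j])

    def objective_at(c: int, pre_v: np.ndarray, post_v: np.ndarray,
                     rng: Optional[np.random.Generator] = None) -> float:
        if rng is not None:
            pre_v = rng.choice(pre_v, size=len(pre_v), replace=True)
            post_v = rng.choice(post_v, size=len(post_v), replace=True)
        return float(np.nanmean(post_v) - np.nanmean(pre_v))

    sides = {}
    for c in candidates:
        pre = np.flatnonzero(days < c)
        post = np.flatnonzero(days >= c)
        sides[c] = (side_vals(pre), side_vals(post))
    objective = np.array([objective_at(c, *sides[c]) for c in candidates])
    best = int(np.argmax(objective))
    day = int(candidates[best]) if objective[best] >= margin else None

    band = None
    if day is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        boot_days = []
        for _ in range(n_boot):
            obj = np.array([objective_at(c, *sides[c], rng=rng)
                            for c in candidates])
            boot_days.append(candidates[int(np.argmax(obj))])
        band = tuple(np.percentile(boot_days, [2.5, 97.5]))
    return CrystallizationEstimate(day=day, objective=objective,
                                   candidates=np.asarray(candidates),
                                   margin=margin, band=band)


def mean_matrix(matrices: Sequence[CrossDayMatrix]) -> CrossDayMatrix:
    """Element-wise mean of several animals' matrices (shared day set)."""
    days = matrices[0].days
    for m in matrices:
        if not np.array_equal(m.days, days):
            raise ValueError("matrices must share the same day set")
    acc = np.nanmean([m.acc for m in matrices], axis=0)
    return CrossDayMatrix(acc=acc,
                          n_matched=np.min([m.n_matched for m in matrices],
                                           axis=0),
                          days=days, epoch=matrices[0].epoch,
                          label_kind=matrices[0].label_kind,
                          animal_id="mean")
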