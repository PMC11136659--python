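"""Neuron-level statistics: activity fields, odour/choice selectivity,
pure/mixed taxonomy, associated-pair cells, movement and sequence correlation.

Conventions
-----------
* The activity-field null circularly shifts each neuron's whole-session
  concatenated trace (trials laid back-to-back) by a uniform nonzero offset,
  preserving autocorrelation; one independent offset per neuron per shuffle.
  The test is one-sided (activation) with a permutation p floor of
  ``1/(n_shuffles + 1)``.
* Selectivity uses the two-sided Wilcoxon rank-sum test at alpha = 0.01 on
  per-trial epoch means: exact distribution when the smaller group has at
  most 10 trials and no ties are present, normal approximation with tie and
  continuity correction otherwise.
* No multiple-testing correction across neurons: reported per-neuron
  fractions are raw, as is standard for these population prevalence figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .task_model import (EpochWindows, Session, TaskConfig, Trial, TrialTensor,
                         epoch_mean, labels_for)

logger = logging.getLogger("wmcrys.selectivity")

ALPHA_SELECTIVITY = 0.01   # 99% confidence rank-sum threshold
ALPHA_FIELD = 0.05         # activity-field flag threshold (configurable)

#: default selectivity grid: which trial parameter is compared in which epoch
DEFAULT_GRID: Mapping[str, tuple[str, ...]] = {
    "first_odour": ("first_odour", "early_delay", "late_delay"),
    "choice": ("choice",),
    "second_odour": ("second_odour",),
}


# ---------------------------------------------------------------------------
# significant activity fields (circular-shuffle permutation null)
# ---------------------------------------------------------------------------

def activity_field_test(session: Session, config: TaskConfig,
                        windows: EpochWindows, epoch: str,
                        n_shuffles: int = 1000,
                        alpha_field: float = ALPHA_FIELD,
                        seed: Optional[int] = None,
                        chunk: int = 200) -> pd.DataFrame:
    """Per-neuron one-sided permutation test for epoch-locked activation.

    The observed statistic is the across-trial mean activity in the epoch;
    the null rebuilds it after circularly shifting the concatenated session
    trace.  All-zero neurons get p = 1 (never significant).
    """
    if session.n_trials < 1:
        raise ValueError("session has no trials")
    start, end = windows[epoch]
    frame_rate = session.frame_rate or config.frame_rate
    times = config.trial_start + np.arange(session.n_frames) / frame_rate
    in_ep = np.flatnonzero((times >= start - 1e-9) & (times < end - 1e-9))
    if in_ep.size == 0:
        raise ValueError(f"epoch {epoch!r} covers no frames")
    m = in_ep.size
    T, N, F = session.activity.shape
    L = T * F
    trace = session.activity.transpose(1, 0, 2).reshape(N, L)
    seg_starts = np.arange(T) * F + in_ep[0]          # epoch is contiguous
    denom = T * m
    # A whole-trace shift by any multiple of the trial length permutes which
    # trial contributes which segment and leaves the across-trial mean
    # unchanged; only the offset modulo the trial length matters.  Offsets
    # are therefore drawn over the F-1 effective within-trial shifts (no-op
    # shifts would only add conservative ties).
    max_off = F

    observed = trace[:, (seg_starts[:, None] + np.arange(m)).ravel()]\
        .sum(axis=1) / denom

    csum = np.concatenate(
        [np.zeros((N, 1)), np.cumsum(np.concatenate([trace, trace], axis=1),
                                     axis=1)], axis=1)
    rng = np.random.default_rng(seed)
    n_ge = np.zeros(N, dtype=int)
    null_all = np.empty((N, n_shuffles))
    done = 0
    rows_idx = np.arange(N)[:, None, None]
    while done < n_shuffles:
        k = min(chunk, n_shuffles - done)
        offsets = rng.integers(1, max_off, size=(N, k))
        src = (seg_starts[None, None, :] - offsets[:, :, None]) % L
        sums = (csum[rows_idx, src + m] - csum[rows_idx, src]).sum(axis=2)
        null = sums / denom
        null_all[:, done:done + k] = null
        n_ge += (null >= observed[:, None] - 1e-12).sum(axis=1)
        done += k

    p = (1 + n_ge) / (n_shuffles + 1)
    q = np.quantile(null_all, [0.5, 0.95, 0.99], axis=1)
    return pd.DataFrame({
        "neuron_id": np.asarray(session.neuron_ids),
        "epoch": epoch,
        "observed": observed,
        "p": p,
        "significant": p < alpha_field,
        "null_q50": q[0], "null_q95": q[1], "null_q99": q[2],
        "n_shuffles": n_shuffles,
    })


# ---------------------------------------------------------------------------
# rank-sum selectivity
# ---------------------------------------------------------------------------

def _ranksum_pvalues(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum p and AUC per column of [trials, neurons] groups.

    Exact null distribution when min(n1, n2) <= 10 and the neuron's data are
    tie-free; otherwise the normal approximation with continuity and tie
    correction.
    """
    n1, n2 = x.shape[0], y.shape[0]
    n_neurons = x.shape[1]
    if min(n1, n2) <= 10:
        p = np.empty(n_neurons)
        u = np.empty(n_neurons)
        for j in range(n_neurons):
            both = np.concatenate([x[:, j], y[:, j]])
            method = "exact" if np.unique(both).size == both.size \
                else "asymptotic"
            res = mannwhitneyu(x[:, j], y[:, j], alternative="two-sided",
                               method=method, use_continuity=True)
            p[j], u[j] = res.pvalue, res.statistic
    else:
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True, axis=0)
        p, u = np.asarray(res.pvalue), np.asarray(res.statistic)
    return p, u / (n1 * n2)


def selectivity_test(tensor: TrialTensor, windows: EpochWindows, epoch: str,
                     labels: Sequence[str], comparison: str,
                     alpha: float = ALPHA_SELECTIVITY) -> pd.DataFrame:
    """Rank-sum comparison of per-trial epoch means between the two labels.

    ``labels`` must take exactly two values with at least three trials each.
    AUC is P(value from the first label, sorted alphabetically, exceeds one
    from the second).  The preferred label has the larger mean; exact mean
    ties fall to the first label with ``ambiguous`` flagged.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(
            f"selectivity_test needs exactly 2 labels, got {list(uniq)}")
    means = epoch_mean(tensor, windows, epoch)
    g1, g2 = means[labels == uniq[0]], means[labels == uniq[1]]
    if min(len(g1), len(g2)) < 3:
        raise ValueError(
            f"need >= 3 trials per label, got {len(g1)} vs {len(g2)}")
    p, auc = _ranksum_pvalues(g1, g2)
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    preferred = np.where(m1 >= m2, uniq[0], uniq[1])
    return pd.DataFrame({
        "neuron_index": np.arange(means.shape[1]),
        "epoch": epoch,
        "comparison": comparison,
        "p": p,
        "auc": auc,
        "preferred": preferred,
        "selective": p < alpha,
        "ambiguous": m1 == m2,
    })


def selectivity_grid(tensor: TrialTensor, windows: EpochWindows,
                     trials: Sequence[Trial],
                     grid: Mapping[str, tuple[str, ...]] = DEFAULT_GRID,
                     alpha: float = ALPHA_SELECTIVITY) -> pd.DataFrame:
    """Run the selectivity grid (trial parameter x epoch) over all neurons."""
    frames = []
    for comparison, epochs in grid.items():
        labels = labels_for(trials, comparison)
        for epoch in epochs:
            frames.append(selectivity_test(tensor, windows, epoch, labels,
                                           comparison, alpha=alpha))
    return pd.concat(frames, ignore_index=True)


def classify_profile(results: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron taxonomy: pure (exactly one selective epoch/parameter),
    mixed (two or more), none."""
    counts = results.groupby("neuron_index")["selective"].sum()
    category = np.where(counts == 0, "none",
                        np.where(counts == 1, "pure", "mixed"))
    return pd.DataFrame({"neuron_index": counts.index.to_numpy(),
                         "n_selective": counts.to_numpy().astype(int),
                         "category": category})


def associated_pair_cells(results: pd.DataFrame) -> np.ndarray:
    """Neurons selective for both rewarded-pair odours (A with C, B with D).

    Requires grid rows for the first-odour comparison in the first-odour
    epoch and the second-odour comparison in the second-odour epoch.
    """
    def _set(comparison: str, epoch: str, label: str) -> set:
        m = ((results.comparison == comparison) & (results.epoch == epoch)
             & results.selective & (results.preferred == label)
             & ~results.ambiguous)
        return set(results.loc[m, "neuron_index"])

    a = _set("first_odour", "first_odour", "A")
    b = _set("first_odour", "first_odour", "B")
    c = _set("second_odour", "second_odour", "C")
    d = _set("second_odour", "second_odour", "D")
    return np.array(sorted((a & c) | (b & d)), dtype=int)


# ---------------------------------------------------------------------------
# movement correlation
# ---------------------------------------------------------------------------

def movement_correlation_test(traces: np.ndarray, locomotion: np.ndarray,
                              n_shuffles: int = 1000,
                              seed: Optional[int] = None) -> pd.DataFrame:
    """Pearson correlation of each neuron with locomotion against a
    circular-shift null; significant if the observed r is at least 2 null
    s.d. away from the null mean.

    All circular lags are obtained at once via FFT cross-correlation; the
    null samples ``n_shuffles`` nonzero lags.  Zero-variance traces are
    flagged degenerate and never significant.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    loco = np.asarray(locomotion, dtype=float)
    if traces.shape[1] != loco.shape[0]:
        raise ValueError("traces and locomotion must have equal length")
    L = loco.shape[0]
    if L < 10:
        raise ValueError("traces must have length >= 10")
    sd_t = traces.std(axis=1)
    sd_l = loco.std()
    degenerate = (sd_t == 0) | (sd_l == 0)
    zt = (traces - traces.mean(axis=1, keepdims=True)) \
        / np.where(sd_t == 0, 1.0, sd_t)[:, None]
    zl = (loco - loco.mean()) / (sd_l if sd_l else 1.0)

    # r at every circular lag k: corr(trace, roll(loco, k))
    r_all = np.fft.irfft(np.fft.rfft(zt, axis=1)
                         * np.conj(np.fft.rfft(zl)), n=L, axis=1) / L
    r_obs = r_all[:, 0].copy()
    rng = np.random.default_rng(seed)
    lags = rng.integers(1, L, size=n_shuffles)
    null = r_all[:, lags]
    null_mean, null_sd = null.mean(axis=1), null.std(axis=1)
    sig = np.abs(r_obs - null_mean) >= 2 * null_sd
    sig &= ~degenerate
    r_obs[degenerate] = np.nan
    return pd.DataFrame({
        "neuron_index": np.arange(traces.shape[0]),
        "r": r_obs, "null_mean": null_mean, "null_sd": null_sd,
        "significant": sig, "degenerate": degenerate,
    })


# ---------------------------------------------------------------------------
# trial-type sequence correlation
# ---------------------------------------------------------------------------

@dataclass
class SequenceCorrelation:
    """Cross-trial-type similarity of trial-averaged activity sequences."""

    per_neuron_r: np.ndarray          # Pearson r between mean traces, NaN if flat
    peak_bin: dict                    # type -> per-neuron argmax bin
    order: dict                       # type -> neuron order by peak time
    per_bin_r: np.ndarray             # across-neuron r at each time bin
    bin_starts: np.ndarray
    types: tuple


def sequence_correlation(tensor: TrialTensor, trials: Sequence[Trial],
                         types: tuple[str, str] = ("AC", "BD")
                         ) -> SequenceCorrelation:
    """Compare trial-type-averaged activity sequences between two types.

    Weak per-bin correlation inside the delay marks the point where the two
    types' delay-period sequences diverge.
    """
    tt = np.array([t.trial_type for t in trials])
    means = {}
    for ty in types:
        sel = tt == ty
        if sel.sum() < 3:
            raise ValueError(f"need >= 3 trials of type {ty!r}, "
                             f"got {int(sel.sum())}")
        means[ty] = tensor.values[sel].mean(axis=0)   # [neurons, bins]
    a, b = means[types[0]], means[types[1]]

    sd_a, sd_b = a.std(axis=1), b.std(axis=1)
    flat = (sd_a == 0) | (sd_b == 0)
    za = (a - a.mean(axis=1, keepdims=True)) / np.where(sd_a == 0, 1, sd_a)[:, None]
    zb = (b - b.mean(axis=1, keepdims=True)) / np.where(sd_b == 0, 1, sd_b)[:, None]
    r = (za * zb).mean(axis=1)
    r[flat] = np.nan

    per_bin = np.full(a.shape[1], np.nan)
    for k in range(a.shape[1]):
        xa, xb = a[:, k], b[:, k]
        if xa.std() > 0 and xb.std() > 0:
            per_bin[k] = np.corrcoef(xa, xb)[0, 1]

    peaks = {ty: means[ty].argmax(axis=1) for ty in types}
    order = {ty: np.argsort(peaks[ty], kind="stable") for ty in types}
    return SequenceCorrelation(per_neuron_r=r, peak_bin=peaks, order=order,
                               per_bin_r=per_bin,
                               bin_starts=tensor.bin_starts, types=types)
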