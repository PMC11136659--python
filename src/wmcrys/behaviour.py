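"""Behavioural performance metrics and learning-stage labels.

Performance is the fraction of hits plus correct rejections over completed
trials; a session is aborted once the animal accumulates more than three
misses within the most recent ten trials (lack of motivation), and trials
after the abort point are excluded from all rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .task_model import Trial

#: stage thresholds on performance p
NAIVE_BELOW = 0.65
EXPERT_AT = 0.80


def apply_abort_rule(outcomes: Sequence[str]) -> int:
    """Number of completed trials before the motivation abort rule fires.

    Scanning in order, the session ends at the first trial whose trailing
    window of at most ten trials contains four or more misses; that trial
    counts as completed.
    """
    misses = np.asarray([o == "miss" for o in outcomes], dtype=int)
    run = 0
    for i in range(len(misses)):
        run += misses[i]
        if i >= 10:
            run -= misses[i - 10]
        if run >= 4:
            return i + 1
    return len(misses)


def classify_stage(p: float, day_index: int = 1) -> str:
    """naive (p < 0.65), training (0.65 <= p < 0.80) or expert (p >= 0.80)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"performance must be in [0, 1], got {p}")
    if p < NAIVE_BELOW:
        return "naive"
    if p < EXPERT_AT:
        return "training"
    return "expert"


def dprime(hit_rate: float, fa_rate: float,
           n_signal: Optional[int] = None,
           n_noise: Optional[int] = None) -> float:
    """Signal-detection discriminability D' = z(H) - z(F).

    Extreme rates (0 or 1) are replaced by 1/(2N) and 1 - 1/(2N) when the
    trial counts are supplied, keeping D' finite.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")

    def _clip(rate: float, n: Optional[int]) -> float:
        if n is not None and n > 0:
            lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
            return min(max(rate, lo), hi)
        return rate

    h = _clip(hit_rate, n_signal)
    f = _clip(fa_rate, n_noise)
    return float(norm.ppf(h) - norm.ppf(f))


@dataclass(frozen=True)
class BehaviourSummary:
    """Outcome counts, performance, hit/false-alarm rates, D' and stage."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    performance: float
    hit_rate: float
    fa_rate: float
    dprime: float
    stage: str
    novice: bool
    completed_trials: int


def performance(trials: Sequence[Trial], day_index: int = 1,
                apply_abort: bool = True) -> BehaviourSummary:
    """Summarize a session's behaviour from its ordered trial list."""
    if len(trials) == 0:
        raise ValueError("cannot summarize an empty trial list")
    outcomes = [t.outcome for t in trials]
    n_done = apply_abort_rule(outcomes) if apply_abort else len(outcomes)
    done = outcomes[:n_done]
    hits = done.count("hit")
    misses = done.count("miss")
    fas = done.count("false_alarm")
    crs = done.count("correct_rejection")
    p = (hits + crs) / n_done
    n_sig = hits + misses
    n_noise = fas + crs
    h = hits / n_sig if n_sig else 0.0
    f = fas / n_noise if n_noise else 0.0
    d = dprime(h, f, n_signal=n_sig or None, n_noise=n_noise or None)
    return BehaviourSummary(
        hits=hits, misses=misses, false_alarms=fas, correct_rejections=crs,
        performance=p, hit_rate=h, fa_rate=f, dprime=d,
        stage=classify_stage(p, day_index), novice=(day_index == 1),
        completed_trials=n_done)
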