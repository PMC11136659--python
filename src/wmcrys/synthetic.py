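"""Synthetic multi-animal, multi-day cohorts with planted tuning and drift.

The generator emulates the statistical structure of trial-aligned deconvolved
calcium recordings in a delayed-association task:

* epoch-locked nonnegative event activity (Poisson event counts per frame
  with exponential amplitudes, i.e. compound-Poisson event mass);
* odour and choice tuning with pure and mixed selectivity, planted per epoch
  at configured fractions;
* session-to-session tuning drift — each selective neuron keeps its tuning
  across a day transition with probability ``retention`` and is otherwise
  replaced by a freshly drawn neuron — with tuning frozen from the
  crystallization day onward;
* a depth gradient in where late-delay information sits (deeper neurons are
  more likely to carry the late-delay code);
* degraded late-delay coding on error trials;
* behavioural outcome sequences with the motivation abort rule.

Every planted quantity is recorded in :class:`GroundTruth`, so each analysis
stage can be validated by parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import behaviour as _behaviour
from .task_model import (EpochWindows, InvalidConfigError, Session, TaskConfig,
                         Trial, TRIAL_TYPES, build_epoch_windows)

logger = logging.getLogger("wmcrys.synthetic")

#: epochs that can carry planted tuning, with the trial parameter they encode
TUNED_EPOCHS: Mapping[str, str] = {
    "first_odour": "first_odour",
    "early_delay": "first_odour",
    "late_delay": "first_odour",
    "second_odour": "second_odour",
    "choice": "choice",
}

_LABELS = {"first_odour": ("A", "B"), "second_odour": ("C", "D"),
           "choice": ("lick", "nolick")}

#: default selective fractions per epoch (roughly the expert-stage prevalence
#: of first-odour/choice tuning reported for M2 populations)
DEFAULT_FRAC_SELECTIVE: Mapping[str, float] = {
    "first_odour": 0.18,
    "early_delay": 0.11,
    "late_delay": 0.07,
    "second_odour": 0.10,
    "choice": 0.28,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Rates are expected event mass per 500 ms bin (``effect_rate_hi`` on
    preferred trials in a neuron's informative epoch, ``effect_rate_lo`` on
    non-preferred trials, ``noise_rate`` everywhere else).  ``retention`` is
    the per-day-transition probability that a selective neuron keeps its
    tuning; from ``crystallization_day`` onward tuning is frozen.
    """

    n_animals: int = 4
    n_days: int = 10
    n_neurons: int = 200
    trials_per_day: int = 200
    frac_selective: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAC_SELECTIVE))
    mixed_prob: float = 0.6
    effect_rate_hi: float = 3.0
    effect_rate_lo: float = 1.0
    noise_rate: float = 0.2
    retention: float = 0.2
    crystallization_day: int = 6
    depth_range: tuple[float, float] = (30.0, 450.0)
    depth_gradient: float = 1.0
    error_rate: float = 0.06
    error_degrade: float = 1.0
    detection_dropout: float = 0.05
    pair_cell_frac: float = 0.015
    apply_abort: bool = True
    centroid_jitter_um: float = 0.5
    fov_um: float = 1000.0
    min_spacing_um: float = 12.0
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(name: str, why: str) -> InvalidConfigError:
            return InvalidConfigError(f"GeneratorConfig.{name}: {why}")

        for name in ("n_animals", "n_days", "n_neurons", "trials_per_day"):
            if getattr(self, name) < 1:
                raise bad(name, "must be >= 1")
        for name in ("effect_rate_hi", "effect_rate_lo", "noise_rate",
                     "centroid_jitter_um"):
            if getattr(self, name) < 0:
                raise bad(name, "must be >= 0")
        for name in ("mixed_prob", "retention", "error_degrade",
                     "pair_cell_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise bad(name, "must be in [0, 1]")
        for name in ("error_rate", "detection_dropout"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise bad(name, "must be in [0, 1)")
        for ep, frac in self.frac_selective.items():
            if ep not in TUNED_EPOCHS:
                raise bad("frac_selective", f"unknown epoch {ep!r}")
            if not 0.0 <= frac <= 1.0:
                raise bad("frac_selective", f"{ep} fraction must be in [0, 1]")
        if self.crystallization_day > self.n_days + 1:
            raise bad("crystallization_day", "must be <= n_days + 1")
        if self.depth_range[0] >= self.depth_range[1]:
            raise bad("depth_range", "must be an increasing (lo, hi) pair")


@dataclass
class GroundTruth:
    """Planted parameters: the target of parameter recovery.

    ``tuning`` has one row per (animal, day, neuron, epoch) with the
    preferred label; ``neurons`` carries depths; ``detected`` lists the
    neurons present in each day's session; ``trials`` records per-trial error
    flags.
    """

    tuning: pd.DataFrame
    neurons: pd.DataFrame
    detected: pd.DataFrame
    trials: pd.DataFrame
    config: GeneratorConfig

    def selective_ids(self, animal_id: str, day: int, epoch: str) -> np.ndarray:
        t = self.tuning
        m = ((t.animal_id == animal_id) & (t.day == day) & (t.epoch == epoch))
        return t.loc[m, "neuron_id"].to_numpy()

    def preferred(self, animal_id: str, day: int, epoch: str) -> pd.Series:
        t = self.tuning
        m = ((t.animal_id == animal_id) & (t.day == day) & (t.epoch == epoch))
        return t.loc[m].set_index("neuron_id")["preferred_label"]


@dataclass
class Cohort:
    """All sessions of all animals plus the shared task configuration."""

    sessions: list[Session]
    task: TaskConfig

    def animals(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            seen.setdefault(s.animal_id, None)
        return list(seen)

    def days(self, animal_id: str) -> list[int]:
        return sorted(s.day_index for s in self.sessions
                      if s.animal_id == animal_id)

    def session(self, animal_id: str, day: int) -> Session:
        for s in self.sessions:
            if s.animal_id == animal_id and s.day_index == day:
                return s
        raise KeyError(f"no session for animal {animal_id!r} day {day}")


# ---------------------------------------------------------------------------
# behaviour simulation
# ---------------------------------------------------------------------------

def simulate_behaviour(config: GeneratorConfig, n_trials: int,
                       rng: Optional[np.random.Generator] = None,
                       apply_abort: Optional[bool] = None) -> list[Trial]:
    """Draw an ordered trial list: uniform random trial types, correct
    responses except on error trials (rate ``error_rate``), then the
    motivation abort rule."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if apply_abort is None:
        apply_abort = config.apply_abort
    types = rng.choice(TRIAL_TYPES, size=n_trials)
    errors = rng.random(n_trials) < config.error_rate
    trials = []
    for tt, err in zip(types, errors):
        rewarded = tt in ("AC", "BD")
        licked = rewarded != err  # correct response flipped on error trials
        trials.append(Trial(trial_type=str(tt), licked=bool(licked)))
    if apply_abort:
        n_done = _behaviour.apply_abort_rule([t.outcome for t in trials])
        trials = trials[:n_done]
    return trials


# ---------------------------------------------------------------------------
# tuning tables
# ---------------------------------------------------------------------------

def _depth_weights(depths: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Logistic weight of a neuron being chosen as late-delay selective."""
    lo, hi = config.depth_range
    mid = 0.5 * (lo + hi)
    return 1.0 / (1.0 + np.exp(-config.depth_gradient * (depths - mid) / 100.0))


def _epoch_quotas(config: GeneratorConfig) -> dict[str, int]:
    """Exact planted counts: floor(frac x n) per epoch."""
    return {ep: int(np.floor(frac * config.n_neurons))
            for ep, frac in config.frac_selective.items() if frac > 0}


def _draw_label(rng: np.random.Generator, epoch: str) -> str:
    return str(rng.choice(_LABELS[TUNED_EPOCHS[epoch]]))


#: epoch planting order; late delay first so its depth profile is drawn from
#: the full pool before mixed reuse dilutes it
_PLANT_ORDER = ("late_delay", "first_odour", "early_delay", "second_odour",
                "choice")


def _systematic_pps(rng: np.random.Generator, eligible: np.ndarray,
                    count: int, weights: np.ndarray,
                    sort_key: np.ndarray) -> np.ndarray:
    """Systematic probability-proportional-to-size sample without replacement.

    Units are laid out along ``sort_key`` (depth) and picked with evenly
    spaced pointers over cumulative weight: marginal inclusion probability is
    proportional to weight while per-stratum counts are near-deterministic —
    the planted depth gradient realizes its expectation closely.
    """
    if count >= len(eligible):
        return eligible.copy()
    order = np.argsort(sort_key, kind="stable")
    elig = eligible[order]
    w = np.maximum(weights[order], 1e-12)
    cum = np.cumsum(w)
    step = cum[-1] / count
    points = (rng.random() + np.arange(count)) * step
    idx = np.searchsorted(cum, points, side="right")
    idx = np.unique(np.minimum(idx, len(elig) - 1))
    picked = list(elig[idx])
    if len(picked) < count:    # pointer collisions: top up uniformly
        rest = np.setdiff1d(elig, picked)
        extra = rng.choice(rest, size=count - len(picked), replace=False)
        picked.extend(extra.tolist())
    return np.asarray(picked[:count], dtype=int)


def _draw_fresh(rng: np.random.Generator, eligible: np.ndarray, count: int,
                epoch: str, depths: np.ndarray,
                config: GeneratorConfig) -> np.ndarray:
    """Draw ``count`` neurons for an epoch; late-delay draws follow the
    logistic depth gradient."""
    if count <= 0:
        return np.empty(0, dtype=int)
    if epoch == "late_delay" and config.depth_gradient != 0:
        w = _depth_weights(depths[eligible], config)
        return _systematic_pps(rng, eligible, count, w, depths[eligible])
    return rng.choice(eligible, size=min(count, len(eligible)),
                      replace=False)


def _coherent_label(rng: np.random.Generator,
                    tuning: dict[int, dict[str, str]], nid: int,
                    epoch: str) -> str:
    """First-odour preference is consistent across a neuron's odour epochs."""
    if TUNED_EPOCHS[epoch] == "first_odour":
        for ep, lab in tuning.get(nid, {}).items():
            if TUNED_EPOCHS[ep] == "first_odour":
                return lab
    return _draw_label(rng, epoch)


def _fill_epoch(rng: np.random.Generator, tuning: dict[int, dict[str, str]],
                epoch: str, quota: int, depths: np.ndarray,
                config: GeneratorConfig, mix: bool) -> None:
    """Fill an epoch's quota: with probability ``mixed_prob`` a slot reuses a
    neuron already selective elsewhere (mixed selectivity, at most three
    epochs per neuron); remaining slots take fresh non-selective neurons."""
    have = sum(1 for eps in tuning.values() if epoch in eps)
    need = quota - have
    if need <= 0:
        return
    mixable = np.array([nid for nid, eps in tuning.items()
                        if epoch not in eps and len(eps) < 3], dtype=int)
    n_mixed = 0
    if mix and mixable.size:
        n_mixed = min(int(rng.binomial(need, config.mixed_prob)),
                      mixable.size)
    picked = list(rng.choice(mixable, size=n_mixed, replace=False)) \
        if n_mixed else []
    fresh_pool = np.array([i for i in range(config.n_neurons)
                           if i not in tuning], dtype=int)
    n_fresh = need - n_mixed
    if n_fresh > len(fresh_pool):   # saturated: reuse anyone not in epoch
        overflow = n_fresh - len(fresh_pool)
        pool = np.array([nid for nid in range(config.n_neurons)
                         if epoch not in tuning.get(nid, {})
                         and nid not in picked
                         and nid not in fresh_pool], dtype=int)
        picked.extend(rng.choice(pool, size=overflow, replace=False).tolist())
        n_fresh = len(fresh_pool)
    picked.extend(_draw_fresh(rng, fresh_pool, n_fresh, epoch, depths,
                              config).tolist())
    for nid in picked:
        nid = int(nid)
        tuning.setdefault(nid, {})[epoch] = _coherent_label(rng, tuning, nid,
                                                            epoch)


def _plant_day1(rng: np.random.Generator, depths: np.ndarray,
                config: GeneratorConfig) -> dict[int, dict[str, str]]:
    """Day-1 tuning: mapping neuron -> {epoch: preferred label}.

    Pair cells (first-odour A with second-odour C, or B with D) are planted
    first and consume both quotas; each remaining quota is then filled with a
    mix of already-selective (mixed) and fresh neurons.
    """
    n = config.n_neurons
    quotas = _epoch_quotas(config)
    tuning: dict[int, dict[str, str]] = {}

    n_pair = int(np.floor(config.pair_cell_frac * n))
    if n_pair and quotas.get("first_odour", 0) and quotas.get("second_odour", 0):
        n_pair = min(n_pair, quotas["first_odour"], quotas["second_odour"])
        picks = rng.choice(n, size=n_pair, replace=False)
        for k, nid in enumerate(picks):
            fo, so = ("A", "C") if k % 2 == 0 else ("B", "D")
            tuning[int(nid)] = {"first_odour": fo, "second_odour": so}

    for epoch in _PLANT_ORDER:
        if epoch in quotas:
            _fill_epoch(rng, tuning, epoch, quotas[epoch], depths, config,
                        mix=True)
    return tuning


def _drift_day(rng: np.random.Generator, prev: dict[int, dict[str, str]],
               rho: float, depths: np.ndarray,
               config: GeneratorConfig) -> dict[int, dict[str, str]]:
    """Advance a tuning table by one day transition with retention rho.

    Each selective neuron keeps its entire profile with probability rho;
    dropped slots are refilled per epoch with fresh draws from the currently
    non-selective pool (depth-weighted for late delay)."""
    if rho >= 1.0:
        return {nid: dict(eps) for nid, eps in prev.items()}
    kept = {nid: dict(eps) for nid, eps in prev.items() if rng.random() < rho}
    quotas = _epoch_quotas(config)
    for epoch in _PLANT_ORDER:
        if epoch in quotas:
            _fill_epoch(rng, kept, epoch, quotas[epoch], depths, config,
                        mix=False)
    return kept


# ---------------------------------------------------------------------------
# activity synthesis
# ---------------------------------------------------------------------------

def _epoch_frame_masks(task: TaskConfig,
                       windows: EpochWindows) -> dict[str, np.ndarray]:
    times = task.frame_times()
    masks = {}
    for ep in windows.names():
        s, e = windows[ep]
        masks[ep] = (times >= s - 1e-9) & (times < e - 1e-9)
    return masks


def _session_rates(trials: Sequence[Trial], tuning: dict[int, dict[str, str]],
                   detected: np.ndarray, masks: dict[str, np.ndarray],
                   config: GeneratorConfig) -> np.ndarray:
    """Per-frame event-mass rate tensor [n_trials, n_detected, n_frames]."""
    fpb = config.task.frame_rate * config.task.bin_width
    noise = config.noise_rate / fpb
    hi = config.effect_rate_hi / fpb
    lo = config.effect_rate_lo / fpb
    n_frames = config.task.n_frames
    rates = np.full((len(trials), len(detected), n_frames), noise)
    col = {nid: j for j, nid in enumerate(detected)}

    trial_param = {
        "first_odour": np.array([t.first_odour for t in trials]),
        "second_odour": np.array([t.second_odour for t in trials]),
        "choice": np.array(["lick" if t.licked else "nolick" for t in trials]),
    }
    errors = np.array([not t.correct for t in trials])

    for nid, eps in tuning.items():
        j = col.get(nid)
        if j is None:
            continue
        for epoch, label in eps.items():
            pref = trial_param[TUNED_EPOCHS[epoch]] == label
            r = np.where(pref, hi, lo)
            if epoch == "late_delay" and config.error_degrade > 0:
                degraded = lo + (r - lo) * (1.0 - config.error_degrade)
                r = np.where(errors, degraded, r)
            rates[:, j, masks[epoch]] = r[:, None]
    return rates


def _draw_activity(rng: np.random.Generator, rates: np.ndarray) -> np.ndarray:
    """Compound-Poisson event mass: Poisson counts x exponential amplitudes."""
    counts = rng.poisson(rates)
    return rng.standard_gamma(counts)


def _place_centroids(rng: np.random.Generator,
                     config: GeneratorConfig) -> np.ndarray:
    """(x, y, depth) with a minimum lateral spacing (cells have bodies)."""
    n = config.n_neurons
    pts = np.empty((n, 2))
    k = 0
    min_sq = config.min_spacing_um ** 2
    attempts = 0
    while k < n:
        cand = rng.uniform(0, config.fov_um, size=2)
        if k == 0 or np.min(((pts[:k] - cand) ** 2).sum(axis=1)) >= min_sq:
            pts[k] = cand
            k += 1
        attempts += 1
        if attempts > 200 * n:
            raise InvalidConfigError(
                "cannot place n_neurons with min_spacing_um in fov_um; "
                "reduce density")
    depths = rng.uniform(*config.depth_range, size=n)
    return np.column_stack([pts, depths])


def _smooth_locomotion(rng: np.random.Generator, n: int) -> np.ndarray:
    """Nonnegative, autocorrelated speed trace (arbitrary units)."""
    x = rng.standard_normal(n + 40)
    kernel = np.ones(40) / 40.0
    sm = np.convolve(x, kernel, mode="valid")[:n]
    return np.maximum(sm + 0.5, 0.0)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Generate all sessions of all animals plus the planted ground truth.

    Deterministic under ``config.seed``: all randomness flows from one seed
    sequence, spawned per animal and per day.
    """
    windows = build_epoch_windows(config.task)
    masks = _epoch_frame_masks(config.task, windows)
    ss = np.random.SeedSequence(config.seed)
    animal_seeds = ss.spawn(config.n_animals)

    sessions: list[Session] = []
    tuning_rows, neuron_rows, detected_rows, trial_rows = [], [], [], []

    for a in range(config.n_animals):
        animal_id = f"m{a + 1:02d}"
        a_ss = animal_seeds[a]
        rng_anat = np.random.default_rng(a_ss.spawn(1)[0])
        centroids = _place_centroids(rng_anat, config)
        depths = centroids[:, 2]
        for nid in range(config.n_neurons):
            neuron_rows.append((animal_id, nid, depths[nid]))

        day_seeds = a_ss.spawn(config.n_days)
        tuning: dict[int, dict[str, str]] = {}
        for d in range(1, config.n_days + 1):
            rng = np.random.default_rng(day_seeds[d - 1])
            if d == 1:
                tuning = _plant_day1(rng, depths, config)
            else:
                rho = 1.0 if (d - 1) >= config.crystallization_day \
                    else config.retention
                tuning = _drift_day(rng, tuning, rho, depths, config)

            trials = simulate_behaviour(config, config.trials_per_day, rng)
            det_mask = rng.random(config.n_neurons) >= config.detection_dropout
            detected = np.flatnonzero(det_mask)
            rates = _session_rates(trials, tuning, detected, masks, config)
            activity = _draw_activity(rng, rates)
            jitter = rng.normal(0.0, config.centroid_jitter_um,
                                size=(len(detected), 2))
            cents = centroids[detected].copy()
            cents[:, :2] += jitter
            n_sess_frames = len(trials) * config.task.n_frames
            loco = _smooth_locomotion(rng, n_sess_frames)
            sessions.append(Session(
                animal_id=animal_id, day_index=d, trials=trials,
                activity=activity, neuron_ids=detected, centroids=cents,
                locomotion=loco, frame_rate=config.task.frame_rate))

            for nid, eps in sorted(tuning.items()):
                for epoch, label in sorted(eps.items()):
                    tuning_rows.append((animal_id, d, nid, epoch, label))
            for nid in detected:
                detected_rows.append((animal_id, d, int(nid)))
            for i, t in enumerate(trials):
                trial_rows.append((animal_id, d, i, t.trial_type, t.licked,
                                   not t.correct))

    gt = GroundTruth(
        tuning=pd.DataFrame(tuning_rows, columns=[
            "animal_id", "day", "neuron_id", "epoch", "preferred_label"]),
        neurons=pd.DataFrame(neuron_rows, columns=[
            "animal_id", "neuron_id", "depth"]),
        detected=pd.DataFrame(detected_rows, columns=[
            "animal_id", "day", "neuron_id"]),
        trials=pd.DataFrame(trial_rows, columns=[
            "animal_id", "day", "trial_index", "trial_type", "licked",
            "error"]),
        config=config)
    return Cohort(sessions=sessions, task=config.task), gt


def ground_truth_summary(gt: GroundTruth) -> pd.DataFrame:
    """Per (animal, day, epoch): selective fraction, overlap with the next
    day's selective set, and error-trial count.

    ``overlap(d, d+1) = |tuned_d intersect tuned_{d+1}| / |tuned_d|`` equals
    the retention probability in expectation (plus the small chance that a
    dropped neuron is redrawn)."""
    cfg = gt.config
    rows = []
    for animal_id in gt.neurons.animal_id.unique():
        errs = gt.trials[gt.trials.animal_id == animal_id]
        for d in range(1, cfg.n_days + 1):
            n_err = int(errs[(errs.day == d)].error.sum())
            for epoch in TUNED_EPOCHS:
                cur = set(gt.selective_ids(animal_id, d, epoch))
                frac = len(cur) / cfg.n_neurons
                if d < cfg.n_days and cur:
                    nxt = set(gt.selective_ids(animal_id, d + 1, epoch))
                    overlap = len(cur & nxt) / len(cur)
                else:
                    overlap = np.nan
                rows.append((animal_id, d, epoch, frac, overlap, n_err))
    return pd.DataFrame(rows, columns=[
        "animal_id", "day", "epoch", "selective_fraction", "overlap_next_day",
        "n_error_trials"])
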