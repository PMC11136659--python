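"""Task timeline, trial/session data model, binning and response-map normalization.

The delayed-association task presents a first odour (A or B), a delay, a
second odour (C or D) and a choice window.  Licking after the rewarded
combinations (AC, BD) yields a hit; all analyses are aligned to first-odour
onset (trial time 0) and operate on nonnegative deconvolved event amplitudes.

Time conventions
----------------
* trial time 0 = first-odour onset; the baseline epoch precedes it.
* all windows are half-open ``[start, end)`` seconds.
* frames are assigned to bins by their *start* time; trailing partial bins
  are dropped so all trials share one binned shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger("wmcrys.task_model")

#: epoch names in temporal order
EPOCH_NAMES = ("baseline", "first_odour", "early_delay", "late_delay",
               "second_odour", "choice")

#: trial types and their components
TRIAL_TYPES = ("AC", "AD", "BC", "BD")
REWARDED_TYPES = frozenset({"AC", "BD"})


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Durations (seconds) of the task phases plus acquisition parameters.

    Defaults follow the standard protocol: 5 s baseline, 1 s first odour,
    5 s delay, 1 s second odour, 3 s choice window, imaged at 10 Hz and
    analysed in 500 ms bins.
    """

    baseline_dur: float = 5.0
    odour1_dur: float = 1.0
    delay_dur: float = 5.0
    odour2_dur: float = 1.0
    choice_dur: float = 3.0
    frame_rate: float = 10.0
    bin_width: float = 0.5

    def __post_init__(self) -> None:
        for name in ("baseline_dur", "odour1_dur", "delay_dur", "odour2_dur",
                     "choice_dur", "frame_rate", "bin_width"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")

    @property
    def trial_extent(self) -> float:
        """Total trial duration in seconds (baseline through choice)."""
        return (self.baseline_dur + self.odour1_dur + self.delay_dur
                + self.odour2_dur + self.choice_dur)

    @property
    def trial_start(self) -> float:
        """Trial start time relative to first-odour onset."""
        return -self.baseline_dur

    @property
    def n_frames(self) -> int:
        """Frames per trial at the configured frame rate."""
        return int(round(self.trial_extent * self.frame_rate))

    def frame_times(self, n_frames: Optional[int] = None) -> np.ndarray:
        """Frame *start* times in seconds relative to first-odour onset."""
        n = self.n_frames if n_frames is None else n_frames
        return self.trial_start + np.arange(n) / self.frame_rate


@dataclass(frozen=True)
class EpochWindows:
    """Named task epochs as ``[start, end)`` intervals relative to odour onset."""

    windows: Mapping[str, tuple[float, float]]

    def __getitem__(self, epoch: str) -> tuple[float, float]:
        try:
            return self.windows[epoch]
        except KeyError:
            raise KeyError(
                f"unknown epoch {epoch!r}; available: {sorted(self.windows)}"
            ) from None

    def __contains__(self, epoch: str) -> bool:
        return epoch in self.windows

    def names(self) -> tuple[str, ...]:
        return tuple(self.windows)


def build_epoch_windows(config: TaskConfig, early_span: float = 2.0,
                        late_span: float = 2.0) -> EpochWindows:
    """Map epoch names to time windows.

    ``early_delay`` is the first ``early_span`` seconds of the delay and
    ``late_delay`` the last ``late_span`` seconds; with the 5 s delay and the
    2 s defaults the late-delay window covers delay seconds 4-5 (the
    behaviourally critical interval), leaving the middle second unassigned.
    """
    if early_span <= 0 or late_span <= 0:
        raise InvalidConfigError("early_span and late_span must be > 0")
    if early_span + late_span > config.delay_dur + 1e-12:
        raise InvalidConfigError(
            f"early_span + late_span = {early_span + late_span} exceeds "
            f"delay_dur = {config.delay_dur}")
    o1 = config.odour1_dur
    delay_end = o1 + config.delay_dur
    o2_end = delay_end + config.odour2_dur
    return EpochWindows({
        "baseline": (-config.baseline_dur, 0.0),
        "first_odour": (0.0, o1),
        "early_delay": (o1, o1 + early_span),
        "late_delay": (delay_end - late_span, delay_end),
        "second_odour": (delay_end, o2_end),
        "choice": (o2_end, o2_end + config.choice_dur),
    })


def _outcome(rewarded: bool, licked: bool) -> str:
    if rewarded:
        return "hit" if licked else "miss"
    return "false_alarm" if licked else "correct_rejection"


@dataclass(frozen=True)
class Trial:
    """One trial: the ordered odour pair, the animal's response and outcome."""

    trial_type: str
    licked: bool
    lick_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")

    @property
    def first_odour(self) -> str:
        return self.trial_type[0]

    @property
    def second_odour(self) -> str:
        return self.trial_type[1]

    @property
    def rewarded(self) -> bool:
        return self.trial_type in REWARDED_TYPES

    @property
    def outcome(self) -> str:
        return _outcome(self.rewarded, self.licked)

    @property
    def correct(self) -> bool:
        """True for hits and correct rejections."""
        return self.licked == self.rewarded


@dataclass
class Session:
    """One day's recording: trial-aligned activity plus trial metadata.

    ``activity`` is a ``[n_trials, n_neurons, n_frames]`` tensor of
    nonnegative deconvolved event amplitudes.  ``neuron_ids`` are stable
    identifiers (consistent across days for the same physical neuron when
    known, e.g. from the synthetic generator); ``centroids`` are (x, y, depth)
    in micrometres.  ``frame_rate`` may differ between days.
    """

    animal_id: str
    day_index: int
    trials: list[Trial]
    activity: np.ndarray
    neuron_ids: np.ndarray
    centroids: np.ndarray
    locomotion: Optional[np.ndarray] = None
    frame_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 3:
            raise ValueError("activity must be [n_trials, n_neurons, n_frames]")
        nt, nn, _ = self.activity.shape
        if nt != len(self.trials):
            raise ValueError(
                f"activity has {nt} trials but {len(self.trials)} Trial records")
        self.neuron_ids = np.asarray(self.neuron_ids)
        if len(self.neuron_ids) != nn:
            raise ValueError("neuron_ids length does not match activity")
        if len(np.unique(self.neuron_ids)) != nn:
            raise ValueError("neuron_ids must be unique within a session")
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != nn:
            raise ValueError("centroids length does not match activity")
        if self.day_index < 1:
            raise ValueError("day_index is 1-based and must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.activity.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[2]

    @property
    def depths(self) -> np.ndarray:
        """Neuron depths (μm); third centroid coordinate."""
        if self.centroids.shape[1] < 3:
            raise ValueError("session centroids carry no depth coordinate")
        return self.centroids[:, 2]


@dataclass(frozen=True)
class TrialTensor:
    """Binned activity ``[n_trials, n_neurons, n_bins]`` with its bin edges."""

    values: np.ndarray
    bin_edges: np.ndarray
    provenance: tuple = ()

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.bin_edges[:-1]

    def epoch_bin_mask(self, windows: EpochWindows, epoch: str) -> np.ndarray:
        """Boolean mask of bins whose start lies in the epoch window."""
        start, end = windows[epoch]
        s = self.bin_starts
        return (s >= start - 1e-9) & (s < end - 1e-9)


def bin_activity(session: Session, config: TaskConfig) -> TrialTensor:
    """Sum deconvolved event amplitudes into fixed-width time bins.

    Frames are assigned to bins by frame start time; bins aggregate by SUM
    (event mass).  A trailing partial bin is dropped so the binned shape is
    identical across trials and sessions.
    """
    if session.n_trials == 0:
        raise ValueError("cannot bin an empty session (0 trials)")
    act = session.activity
    if np.isnan(act).any():
        t, n, f = np.argwhere(np.isnan(act))[0]
        raise ValueError(
            f"NaN in activity: trial {t}, neuron {session.neuron_ids[n]}, "
            f"frame {f}")
    frame_rate = session.frame_rate or config.frame_rate
    n_frames = session.n_frames
    times = config.trial_start + np.arange(n_frames) / frame_rate
    n_bins = int(np.floor(n_frames / frame_rate / config.bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("trial too short for a single bin")
    edges = config.trial_start + config.bin_width * np.arange(n_bins + 1)
    idx = np.floor((times - config.trial_start) / config.bin_width + 1e-9)
    idx = idx.astype(int)
    keep = idx < n_bins
    fpb = frame_rate * config.bin_width
    if abs(fpb - round(fpb)) < 1e-9 and keep.sum() == n_bins * int(round(fpb)):
        # uniform case: plain reshape-sum
        k = int(round(fpb))
        values = act[:, :, :n_bins * k].reshape(
            session.n_trials, session.n_neurons, n_bins, k).sum(axis=3)
    else:
        values = np.zeros((session.n_trials, session.n_neurons, n_bins))
        for b in range(n_bins):
            values[:, :, b] = act[:, :, keep & (idx == b)].sum(axis=2)
    return TrialTensor(values=values, bin_edges=edges,
                       provenance=(session.animal_id, session.day_index,
                                   config.bin_width))


def epoch_mean(tensor: TrialTensor, windows: EpochWindows,
               epoch: str) -> np.ndarray:
    """Per-trial, per-neuron mean of the bins inside an epoch window."""
    mask = tensor.epoch_bin_mask(windows, epoch)
    if not mask.any():
        raise ValueError(f"epoch {epoch!r} covers no bins")
    return tensor.values[:, :, mask].mean(axis=2)


def zscore_response_map(tensor: TrialTensor,
                        windows: EpochWindows) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged trace per neuron, z-scored against its baseline epoch.

    Returns ``(zmap, flagged)`` where ``zmap`` is ``[n_neurons, n_bins]`` and
    ``flagged`` marks neurons with zero baseline s.d. (their map is all-zero
    rather than an error: silent neurons are expected under synthetic nulls).
    Visualization aid; statistics elsewhere run on raw event amplitudes.
    """
    base = tensor.epoch_bin_mask(windows, "baseline")
    if not base.any():
        raise ValueError("baseline window covers no bins")
    trace = tensor.values.mean(axis=0)  # [n_neurons, n_bins]
    mu = trace[:, base].mean(axis=1)
    sd = trace[:, base].std(axis=1)
    flagged = sd == 0
    safe = np.where(flagged, 1.0, sd)
    zmap = (trace - mu[:, None]) / safe[:, None]
    zmap[flagged] = 0.0
    return zmap, flagged


def first_odour_labels(trials: Sequence[Trial]) -> np.ndarray:
    """Label array for first-odour identity decoding/selectivity (A/B)."""
    return np.array([t.first_odour for t in trials])


def second_odour_labels(trials: Sequence[Trial]) -> np.ndarray:
    """Label array for second-odour identity (C/D)."""
    return np.array([t.second_odour for t in trials])


def choice_labels(trials: Sequence[Trial]) -> np.ndarray:
    """Label array for choice (lick / nolick)."""
    return np.array(["lick" if t.licked else "nolick" for t in trials])


def category_labels(trials: Sequence[Trial]) -> np.ndarray:
    """4-way trial-category labels (AC/AD/BC/BD)."""
    return np.array([t.trial_type for t in trials])


def labels_for(trials: Sequence[Trial], kind: str) -> np.ndarray:
    """Dispatch label extraction by kind name."""
    fns = {"first_odour": first_odour_labels, "second_odour": second_odour_labels,
           "choice": choice_labels, "category": category_labels}
    try:
        return fns[kind](trials)
    except KeyError:
        raise ValueError(f"unknown label kind {kind!r}; "
                         f"expected one of {sorted(fns)}") from None
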