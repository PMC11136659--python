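"""Linear population decoding protocols.

One linear max-margin classifier is trained per 500 ms time bin on a
stratified 90% split of trials and tested on the held-out 10%, repeated
``n_repeats`` (default 32) times with fresh random splits; epoch accuracy is
the mean over the epoch's member bins.  Chance comes from re-running the same
protocol on label-shuffled trials.  Features are standardized per neuron on
the training split only; the inverse regularization is fixed at C = 1.
Multiclass (4-way trial category) uses one-vs-one voting over binary linear
decoders, ties broken by aggregate decision-function margin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.multiclass import OneVsOneClassifier
from sklearn.svm import LinearSVC

from .task_model import EpochWindows, TrialTensor

logger = logging.getLogger("wmcrys.decoding")

DEFAULT_N_GRID = (1, 2, 4, 8, 16, 32, 64, 100)


@dataclass(frozen=True)
class DecodingConfig:
    """Decoding protocol parameters."""

    train_fraction: float = 0.9
    n_repeats: int = 32
    C: float = 1.0
    n_grid: tuple[int, ...] = DEFAULT_N_GRID
    max_resample: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class DecodingResult:
    """Per-bin and per-epoch accuracies with repeat-level detail."""

    bin_acc: np.ndarray                 # mean accuracy per bin (NaN = skipped)
    bin_sem: np.ndarray
    repeat_acc: np.ndarray              # [n_bins, n_repeats], NaN for skipped
    epoch_acc: dict
    epoch_sem: dict
    bin_starts: np.ndarray
    n_neurons: int
    n_repeats: int

    def epoch_repeat_acc(self, windows: EpochWindows, epoch: str) -> np.ndarray:
        """Per-repeat epoch accuracy (mean over the epoch's member bins)."""
        start, end = windows[epoch]
        mask = (self.bin_starts >= start - 1e-9) & (self.bin_starts < end - 1e-9)
        return np.nanmean(self.repeat_acc[mask], axis=0)


def _make_classifier(n_classes: int, C: float):
    base = LinearSVC(C=C, dual="auto", max_iter=5000)
    return OneVsOneClassifier(base) if n_classes > 2 else base


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def fit_and_score(x_train: np.ndarray, y_train: np.ndarray,
                  x_test: np.ndarray, y_test: np.ndarray,
                  C: float = 1.0) -> float:
    """Train one linear decoder (standardized on train) and score on test."""
    xtr, xte = _standardize(x_train, x_test)
    clf = _make_classifier(np.unique(y_train).size, C)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(xtr, y_train)
        return float(np.mean(clf.predict(xte) == y_test))


def _split_indices(y: np.ndarray, config: DecodingConfig,
                   rng: np.random.Generator):
    """Yield ``n_repeats`` stratified (train, test) index pairs.

    Stratification keeps every label in the training split; if a degenerate
    split slips through it is resampled (up to ``max_resample`` times).
    """
    classes = np.unique(y)
    produced = 0
    attempts = 0
    while produced < config.n_repeats:
        if attempts > config.max_resample + config.n_repeats:
            raise RuntimeError("could not produce label-complete splits; "
                               "too few trials per label")
        sss = StratifiedShuffleSplit(
            n_splits=1, train_size=config.train_fraction,
            random_state=int(rng.integers(2 ** 31)))
        tr, te = next(sss.split(np.zeros((len(y), 1)), y))
        attempts += 1
        if np.unique(y[tr]).size < classes.size:
            continue
        produced += 1
        yield tr, te


def decode_bin(X: np.ndarray, y: np.ndarray, config: DecodingConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Per-repeat held-out accuracies for one time bin's features."""
    return np.array([fit_and_score(X[tr], y[tr], X[te], y[te], config.C)
                     for tr, te in _split_indices(y, config, rng)])


def _bins_to_compute(tensor: TrialTensor, windows: Optional[EpochWindows],
                     epochs: Optional[Sequence[str]]) -> np.ndarray:
    if epochs is None:
        return np.arange(tensor.n_bins)
    mask = np.zeros(tensor.n_bins, dtype=bool)
    for ep in epochs:
        mask |= tensor.epoch_bin_mask(windows, ep)
    return np.flatnonzero(mask)


def same_day_decoding(tensor: TrialTensor, labels: Sequence[str],
                      windows: Optional[EpochWindows] = None,
                      config: DecodingConfig = DecodingConfig(),
                      seed: Optional[int] = None,
                      epochs: Optional[Sequence[str]] = None) -> DecodingResult:
    """Cross-validated decoding of ``labels`` from each time bin.

    ``epochs`` restricts computation to the bins of the named epochs (all
    bins otherwise); per-epoch aggregates for any computed epoch are in
    ``epoch_acc``.  Deterministic under ``seed`` (one child stream per bin).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise ValueError(f"need >= 5 trials per label, got {counts.min()}")
    bins = _bins_to_compute(tensor, windows, epochs)
    n_bins = tensor.n_bins
    repeat_acc = np.full((n_bins, config.n_repeats), np.nan)
    bin_seeds = np.random.SeedSequence(seed).spawn(n_bins)
    for b in bins:
        rng = np.random.default_rng(bin_seeds[b])
        repeat_acc[b] = decode_bin(tensor.values[:, :, b], y, config, rng)

    bin_acc = repeat_acc.mean(axis=1)
    bin_sem = repeat_acc.std(axis=1, ddof=1) / np.sqrt(config.n_repeats) \
        if config.n_repeats > 1 else np.zeros(n_bins)
    epoch_acc, epoch_sem = {}, {}
    if windows is not None:
        for ep in windows.names():
            mask = tensor.epoch_bin_mask(windows, ep)
            if mask.any() and not np.isnan(repeat_acc[mask]).all():
                per_rep = np.nanmean(repeat_acc[mask], axis=0)
                epoch_acc[ep] = float(per_rep.mean())
                epoch_sem[ep] = float(per_rep.std(ddof=1)
                                      / np.sqrt(len(per_rep))) \
                    if len(per_rep) > 1 else 0.0
    return DecodingResult(bin_acc=bin_acc, bin_sem=bin_sem,
                          repeat_acc=repeat_acc, epoch_acc=epoch_acc,
                          epoch_sem=epoch_sem, bin_starts=tensor.bin_starts,
                          n_neurons=tensor.values.shape[1],
                          n_repeats=config.n_repeats)


@dataclass
class ChanceBand:
    """Label-shuffle chance distribution summary for one epoch."""

    mean: float
    lo: float
    hi: float
    values: np.ndarray                  # per-shuffle epoch accuracies
    sem: float

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def shuffle_chance(tensor: TrialTensor, labels: Sequence[str],
                   windows: EpochWindows,
                   config: DecodingConfig = DecodingConfig(),
                   n_shuffles: int = 10, seed: Optional[int] = None,
                   epochs: Optional[Sequence[str]] = None
                   ) -> dict[str, ChanceBand]:
    """Chance accuracy by assigning random labels to each trial.

    Each shuffle permutes the label vector and reruns the full decoding
    protocol; the band is the 2.5-97.5% quantile range of per-shuffle epoch
    accuracies.
    """
    y = np.asarray(labels)
    ss = np.random.SeedSequence(seed).spawn(n_shuffles + 1)
    rng = np.random.default_rng(ss[0])
    per_epoch: dict[str, list] = {}
    for s in range(n_shuffles):
        perm = rng.permutation(len(y))
        res = same_day_decoding(tensor, y[perm], windows, config,
                                seed=int(np.random.default_rng(
                                    ss[s + 1]).integers(2 ** 31)),
                                epochs=epochs)
        for ep, acc in res.epoch_acc.items():
            per_epoch.setdefault(ep, []).append(acc)
    out = {}
    for ep, vals in per_epoch.items():
        v = np.asarray(vals)
        lo, hi = np.quantile(v, [0.025, 0.975])
        sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        out[ep] = ChanceBand(mean=float(v.mean()), lo=float(lo), hi=float(hi),
                             values=v, sem=float(sem))
    return out


def top_fraction_curve(tensor: TrialTensor, labels: Sequence[str],
                       scores: np.ndarray, windows: EpochWindows,
                       epoch: str, config: DecodingConfig = DecodingConfig(),
                       seed: Optional[int] = None) -> pd.DataFrame:
    """Decoding accuracy using the top N% most selective neurons.

    ``scores`` ranks all neurons (higher = more selective).  For each N in
    the grid the top ``ceil(N% x n_neurons)`` neurons are used; if N% rounds
    to zero neurons, one neuron is used and the row is flagged.
    """
    scores = np.asarray(scores, dtype=float)
    n = tensor.values.shape[1]
    if scores.shape[0] != n:
        raise ValueError("scores must cover all neurons")
    order = np.argsort(-scores, kind="stable")
    rows = []
    for N in config.n_grid:
        k = int(np.ceil(N / 100.0 * n))
        flagged = k < 1
        k = max(k, 1)
        sub = TrialTensor(values=tensor.values[:, order[:k], :],
                          bin_edges=tensor.bin_edges,
                          provenance=tensor.provenance)
        # one shared seed: identical trial splits across N (paired design)
        res = same_day_decoding(sub, labels, windows, config, seed=seed,
                                epochs=[epoch])
        rows.append((N, k, res.epoch_acc[epoch], res.epoch_sem[epoch],
                     flagged))
    return pd.DataFrame(rows, columns=["N_percent", "n_neurons", "accuracy",
                                       "sem", "flagged"])


@dataclass
class DepthDecodingResult:
    """Per-depth-interval decoding with equalized neuron counts."""

    edges: np.ndarray                   # interval boundaries, ascending depth
    counts: np.ndarray                  # neuron census per interval
    equalized_n: int
    accuracy: np.ndarray
    sem: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def depth_stratified_decoding(tensor: TrialTensor, depths: np.ndarray,
                              labels: Sequence[str], windows: EpochWindows,
                              epoch: str,
                              config: DecodingConfig = DecodingConfig(),
                              seed: Optional[int] = None,
                              n_intervals: int = 7,
                              interval_um: float = 60.0
                              ) -> DepthDecodingResult:
    """Decode per depth interval with neuron counts equalized to the minimum.

    The bottom ``n_intervals x interval_um`` (default 7 x 60 = 420 μm) of the
    imaged depth range is tiled into equal intervals; every interval is
    subsampled to the census of the sparsest interval before decoding.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.shape[0] != tensor.values.shape[1]:
        raise ValueError("depths must cover all neurons")
    top = depths.max() - n_intervals * interval_um
    edges = top + interval_um * np.arange(n_intervals + 1)
    members = []
    for i in range(n_intervals):
        lo, hi = edges[i], edges[i + 1]
        m = (depths >= lo) & ((depths < hi) | (i == n_intervals - 1)
                              & (depths <= hi))
        members.append(np.flatnonzero(m))
    counts = np.array([len(m) for m in members])
    if (counts == 0).any():
        empty = [f"[{edges[i]:.0f}, {edges[i+1]:.0f}) um"
                 for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"empty depth interval(s): {', '.join(empty)}")
    m_eq = int(counts.min())
    ss = np.random.SeedSequence(seed).spawn(n_intervals)
    acc = np.empty(n_intervals)
    sem = np.empty(n_intervals)
    for i in range(n_intervals):
        rng = np.random.default_rng(ss[i])
        pick = rng.choice(members[i], size=m_eq, replace=False)
        sub = TrialTensor(values=tensor.values[:, pick, :],
                          bin_edges=tensor.bin_edges,
                          provenance=tensor.provenance)
        res = same_day_decoding(sub, labels, windows, config,
                                seed=int(rng.integers(2 ** 31)),
                                epochs=[epoch])
        acc[i], sem[i] = res.epoch_acc[epoch], res.epoch_sem[epoch]
    return DepthDecodingResult(edges=edges, counts=counts, equalized_n=m_eq,
                               accuracy=acc, sem=sem)


def decode_trial_category(tensor: TrialTensor, labels: Sequence[str],
                          windows: EpochWindows,
                          config: DecodingConfig = DecodingConfig(),
                          seed: Optional[int] = None,
                          epochs: Optional[Sequence[str]] = None
                          ) -> DecodingResult:
    """4-way trial-category decoding (AC/AD/BC/BD) via one-vs-one voting."""
    if np.unique(np.asarray(labels)).size < 3:
        raise ValueError("decode_trial_category expects a multiclass label set")
    return same_day_decoding(tensor, labels, windows, config, seed=seed,
                             epochs=epochs)


def train_correct_test_error(tensor: TrialTensor, labels: Sequence[str],
                             correct: np.ndarray, windows: EpochWindows,
                             config: DecodingConfig = DecodingConfig(),
                             seed: Optional[int] = None,
                             epochs: Optional[Sequence[str]] = None,
                             shuffle_train_labels: bool = False
                             ) -> DecodingResult:
    """Train on (90% splits of) correct trials, test on all error trials.

    The correct-vs-error dissociation mode: a decoder that generalizes to
    error trials in one epoch but not another localizes where coding breaks
    down on errors.  ``shuffle_train_labels`` reruns the identical protocol
    with permuted training labels to obtain the matching chance level.
    """
    y = np.asarray(labels)
    correct = np.asarray(correct, dtype=bool)
    err_idx = np.flatnonzero(~correct)
    cor_idx = np.flatnonzero(correct)
    if err_idx.size == 0:
        raise ValueError("no error trials to test on")
    y_cor = y[cor_idx]
    if np.unique(y_cor, return_counts=True)[1].min() < 5:
        raise ValueError("need >= 5 correct trials per label")
    bins = _bins_to_compute(tensor, windows, epochs)
    n_bins = tensor.n_bins
    repeat_acc = np.full((n_bins, config.n_repeats), np.nan)
    bin_seeds = np.random.SeedSequence(seed).spawn(n_bins)
    for b in bins:
        rng = np.random.default_rng(bin_seeds[b])
        X = tensor.values[:, :, b]
        accs = []
        for tr, _ in _split_indices(y_cor, config, rng):
            y_tr = y_cor[tr]
            if shuffle_train_labels:
                y_tr = rng.permutation(y_tr)
            accs.append(fit_and_score(X[cor_idx[tr]], y_tr,
                                      X[err_idx], y[err_idx], config.C))
        repeat_acc[b] = accs

    bin_acc = repeat_acc.mean(axis=1)
    bin_sem = repeat_acc.std(axis=1, ddof=1) / np.sqrt(config.n_repeats) \
        if config.n_repeats > 1 else np.zeros(n_bins)
    epoch_acc, epoch_sem = {}, {}
    for ep in windows.names():
        mask = tensor.epoch_bin_mask(windows, ep)
        if mask.any() and not np.isnan(repeat_acc[mask]).all():
            per_rep = np.nanmean(repeat_acc[mask], axis=0)
            epoch_acc[ep] = float(per_rep.mean())
            epoch_sem[ep] = float(per_rep.std(ddof=1) / np.sqrt(len(per_rep))) \
                if len(per_rep) > 1 else 0.0
    return DecodingResult(bin_acc=bin_acc, bin_sem=bin_sem,
                          repeat_acc=repeat_acc, epoch_acc=epoch_acc,
                          epoch_sem=epoch_sem, bin_starts=tensor.bin_starts,
                          n_neurons=tensor.values.shape[1],
                          n_repeats=config.n_repeats)
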