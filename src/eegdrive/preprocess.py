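"""Signal conditioning and epoching.

Deterministic stages applied to a continuous multichannel recording before
any analysis: re-referencing (earlobe average or common average), zero-phase
FIR band-pass (2-36 Hz default), IIR notch (50/100 Hz), fixed-window
epoching around segment-onset events (-0.4 to 1.6 s) and baseline
correction (-0.2 to 0 s).  Channel-level z-scoring is split into a fit step
(training epochs only) and an apply step so that cross-validation folds can
enforce the no-leakage contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .defaults import BASELINE_WINDOW, CONDITIONS

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("onset_sample", "condition", "subject", "lap", "segment")


@dataclass
class Recording:
    """Continuous multichannel EEG: ``data`` is channels x samples in uV.

    ``events`` is a DataFrame with columns ``onset_sample, condition,
    subject, lap, segment`` sorted by onset.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples) matching channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")
        if len(self.events):
            onsets = np.asarray(self.events["onset_sample"])
            if (np.diff(onsets) < 0).any():
                raise ValueError("events must be sorted by onset")
            if onsets.min() < 0 or onsets.max() >= self.data.shape[1]:
                raise ValueError("event onsets must lie within the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


@dataclass
class EpochSet:
    """Epoched data: ``data`` is epochs x channels x time (uV)."""

    data: np.ndarray
    fs: float
    tmin: float
    tmax: float
    channel_names: tuple[str, ...]
    labels: np.ndarray           # condition per epoch
    groups: pd.DataFrame         # columns subject, lap, segment; one row per epoch
    baseline_window: tuple[float, float] = BASELINE_WINDOW

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        n_t = int(round((self.tmax - self.tmin) * self.fs)) + 1
        if self.data.ndim != 3 or self.data.shape[2] != n_t:
            raise ValueError(f"epoch time axis must have {n_t} samples")
        if len(self.labels) != self.data.shape[0] or len(self.groups) != self.data.shape[0]:
            raise ValueError("labels/groups must have one entry per epoch")
        unknown = set(self.labels) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        t = self.times
        return (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)

    def subset(self, idx: np.ndarray) -> "EpochSet":
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            groups=self.groups.iloc[np.atleast_1d(idx)].reset_index(drop=True),
        )


def rereference(recording: Recording, reference: str = "common-average",
                ref_channels: tuple[str, str] = ("A1", "A2")) -> Recording:
    """Re-reference to the earlobe average or the common average.

    Common-average referencing is idempotent; earlobe mode subtracts the
    mean of the two named reference channels from every channel.
    """
    if reference == "common-average":
        ref = recording.data.mean(axis=0, keepdims=True)
    elif reference == "earlobe-average":
        idx = [recording.channel_index(c) for c in ref_channels]
        ref = recording.data[idx].mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown reference scheme {reference!r}")
    return replace(recording, data=recording.data - ref)


def _fir_taps(fs: float, lo: float, hi: float) -> np.ndarray:
    # Hamming windowed-sinc; transition width tied to the low edge.
    trans = min(lo, 0.25 * lo + 2.0)
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs, window="hamming")


def bandpass_fir(recording: Recording, lo: float = 2.0, hi: float = 36.0) -> Recording:
    """Zero-phase FIR band-pass via forward-backward filtering."""
    if not 0 < lo < hi < recording.fs / 2:
        raise ValueError(f"band ({lo}, {hi}) Hz invalid for fs={recording.fs}")
    taps = _fir_taps(recording.fs, lo, hi)
    if recording.n_samples < 3 * len(taps):
        raise ValueError(
            f"recording too short for filtering: need >= {3 * len(taps)} samples, "
            f"have {recording.n_samples}")
    out = signal.filtfilt(taps, [1.0], recording.data, axis=1)
    return replace(recording, data=out)


def notch(recording: Recording, freqs: tuple[float, ...] = (50.0, 100.0),
          q: float = 35.0) -> Recording:
    """Zero-phase IIR notch at each frequency in ``freqs``."""
    out = recording.data
    for f0 in freqs:
        if not 0 < f0 < recording.fs / 2:
            raise ValueError(f"notch frequency {f0} Hz outside (0, fs/2)")
        b, a = signal.iirnotch(f0, q, fs=recording.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return replace(recording, data=out)


def epoch(recording: Recording, tmin: float = -0.4, tmax: float = 1.6) -> EpochSet:
    """Cut one epoch per event; events too close to the edges are dropped."""
    if tmax <= tmin:
        raise ValueError("tmax must exceed tmin")
    fs = recording.fs
    i0 = int(round(tmin * fs))
    i1 = int(round(tmax * fs))
    n_t = i1 - i0 + 1
    chunks, rows = [], []
    n_dropped = 0
    for _, ev in recording.events.iterrows():
        onset = int(ev["onset_sample"])
        a, b = onset + i0, onset + i1
        if a < 0 or b >= recording.n_samples:
            n_dropped += 1
            continue
        chunks.append(recording.data[:, a:b + 1])
        rows.append(ev)
    if n_dropped:
        logger.info("epoch: dropped %d events overlapping recording edges", n_dropped)
    if not chunks:
        raise ValueError("no usable events: all epochs overlap the recording edges")
    evd = pd.DataFrame(rows).reset_index(drop=True)
    return EpochSet(
        data=np.stack(chunks),
        fs=fs, tmin=tmin, tmax=tmax,
        channel_names=recording.channel_names,
        labels=np.asarray(evd["condition"]),
        groups=evd[["subject", "lap", "segment"]].reset_index(drop=True),
    )


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = BASELINE_WINDOW) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``window``."""
    if not (epochs.tmin - 1e-9 <= window[0] < window[1] <= 1e-9):
        raise ValueError("baseline window must lie within [tmin, 0]")
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base, baseline_window=window)


@dataclass
class Normalizer:
    """Per-channel mean/sd fitted on training epochs only."""

    mean: np.ndarray
    sd: np.ndarray
    eps: float = 1e-12
    degenerate_channels: tuple[int, ...] = field(default_factory=tuple)


def zscore_fit(epochs_train: EpochSet, eps: float = 1e-12) -> Normalizer:
    """Fit per-channel statistics across training epochs and time.

    Zero-variance channels get their sd floored at ``eps`` and are flagged.
    """
    x = epochs_train.data  # epochs x channels x time
    mean = x.mean(axis=(0, 2))
    sd = x.std(axis=(0, 2))
    degenerate = tuple(int(i) for i in np.flatnonzero(sd < eps))
    if degenerate:
        logger.warning("zscore_fit: %d zero-variance channels floored", len(degenerate))
    return Normalizer(mean=mean, sd=np.maximum(sd, eps), eps=eps,
                      degenerate_channels=degenerate)


def zscore_apply(normalizer: Normalizer, epochs: EpochSet) -> EpochSet:
    """Apply stored statistics; never re-fits."""
    out = (epochs.data - normalizer.mean[None, :, None]) / normalizer.sd[None, :, None]
    return replace(epochs, data=out)


def standard_pipeline(recording: Recording, *, reference: str = "common-average",
                      band: tuple[float, float] = (2.0, 36.0),
                      notch_freqs: tuple[float, ...] = (50.0, 100.0),
                      tmin: float = -0.4, tmax: float = 1.6,
                      baseline: tuple[float, float] = BASELINE_WINDOW) -> EpochSet:
    """reref -> band-pass -> notch -> epoch -> baseline, with defaults."""
    rec = rereference(recording, reference)
    rec = bandpass_fir(rec, *band)
    if notch_freqs:
        rec = notch(rec, notch_freqs)
    ep = epoch(rec, tmin, tmax)
    return baseline_correct(ep, baseline)
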