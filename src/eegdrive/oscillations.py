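"""Band power, ERD/ERS and connectivity metrics.

Band power is the mean squared amplitude of the zero-phase band-pass
filtered signal over an analysis window; ERD/ERS is its percent change in
an active window relative to a pre-onset baseline (negative values =
desynchronization).  Connectivity between region or channel time courses is
quantified two ways: broadband Pearson correlation (linear coupling) and
Welch magnitude-squared coherence ``|Pxy|^2 / (Pxx Pyy)`` (frequency-specific
synchronization; upward-biased by roughly 1/n_segments for independent
signals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .defaults import ANALYSIS_WINDOW, BASELINE_WINDOW, CANONICAL_BANDS

logger = logging.getLogger(__name__)

__all__ = [
    "BandDef", "ConnectivityMatrix", "band_power", "erd_ers", "pearson_corr",
    "msc", "band_coherence", "connectivity_matrix", "connectivity_contrast",
    "CANONICAL_BANDS",
]


@dataclass(frozen=True)
class BandDef:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi")

    @classmethod
    def named(cls, name: str) -> "BandDef":
        lo, hi = CANONICAL_BANDS[name]
        return cls(name, lo, hi)


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _window_mask(n: int, fs: float, tmin: float, window: tuple[float, float]) -> np.ndarray:
    t = tmin + np.arange(n) / fs
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return mask


def band_power(x: np.ndarray, fs: float, band: BandDef, *, tmin: float = 0.0,
               window: tuple[float, float] | None = None) -> float:
    """Mean squared amplitude of the band-passed signal over ``window``.

    ``tmin`` anchors the signal's time axis so epoch-relative windows
    (e.g. the 0.1-0.8 s analysis window) can be selected.
    """
    x = np.asarray(x, dtype=float)
    filtered = _bandpass(x, fs, band.lo, band.hi)
    if window is not None:
        mask = _window_mask(x.shape[-1], fs, tmin, window)
        if mask.sum() < 3 * fs / band.lo:
            logger.warning("band_power: window shorter than 3 cycles of %.3g Hz", band.lo)
        filtered = filtered[..., mask]
    return float(np.mean(filtered ** 2))


def erd_ers(x: np.ndarray, fs: float, band: BandDef, *, tmin: float,
            active: tuple[float, float] = ANALYSIS_WINDOW,
            baseline: tuple[float, float] = BASELINE_WINDOW) -> float:
    """Percent band-power change of the active window relative to baseline.

    ``(P_active - P_baseline) / P_baseline * 100``; scale-invariant in the
    input signal.  Raises on zero baseline power (degenerate input).
    """
    filtered = _bandpass(np.asarray(x, dtype=float), fs, band.lo, band.hi)
    n = filtered.shape[-1]
    p_act = float(np.mean(filtered[..., _window_mask(n, fs, tmin, active)] ** 2))
    p_base = float(np.mean(filtered[..., _window_mask(n, fs, tmin, baseline)] ** 2))
    return erd_ers_from_power(p_act, p_base)


def erd_ers_from_power(p_active: float, p_baseline: float) -> float:
    """ERD/ERS percentage from precomputed window powers."""
    if p_baseline <= 0:
        raise ValueError("degenerate input: baseline power is zero")
    return (p_active - p_baseline) / p_baseline * 100.0


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r between two equal-length time courses."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _welch_params(n: int, n_segments: int) -> int:
    """Segment length giving >= n_segments half-overlapping Welch windows."""
    nperseg = int(2 * n // (n_segments + 1))
    if nperseg < 8:
        need = 8 * (n_segments + 1) // 2
        raise ValueError(
            f"input too short for {n_segments} Welch segments: need >= {need} samples")
    return nperseg


def msc(x: np.ndarray, y: np.ndarray, fs: float, n_segments: int = 8,
        ) -> tuple[np.ndarray, np.ndarray]:
    """Welch magnitude-squared coherence (Hann window, 50% overlap).

    Returns ``(freqs, coherence)``.  A single-segment estimate is
    identically 1, hence the ``n_segments >= 8`` floor; for independent
    signals the estimator's bias level is about ``1/n_segments``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if n_segments < 8:
        raise ValueError("n_segments must be >= 8 (single-segment coherence is 1)")
    nperseg = _welch_params(len(x), n_segments)
    f, c = signal.coherence(x, y, fs=fs, window="hann", nperseg=nperseg,
                            noverlap=nperseg // 2, detrend=False)
    return f, c


def band_coherence(x: np.ndarray, y: np.ndarray, fs: float, band: BandDef,
                   n_segments: int = 8) -> float:
    """Mean coherence over the frequency bins inside ``band``."""
    f, c = msc(x, y, fs, n_segments)
    mask = (f >= band.lo) & (f <= band.hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name!r}")
    return float(c[mask].mean())


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI connectivity; ``metric`` is correlation or coherence."""

    values: np.ndarray
    rois: tuple[str, ...]
    metric: str
    condition: str = ""
    band: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.rois), len(self.rois)):
            raise ValueError("matrix shape must match roi list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v


def connectivity_matrix(timecourses: dict[str, np.ndarray], fs: float,
                        metric: str = "correlation", band: BandDef | None = None,
                        n_segments: int = 8, condition: str = "") -> ConnectivityMatrix:
    """Pairwise connectivity between named time courses.

    Correlation is computed on the broadband series; coherence is
    band-resolved and requires ``band``.
    """
    rois = tuple(timecourses)
    n = len(rois)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "correlation":
                v = pearson_corr(timecourses[rois[i]], timecourses[rois[j]])
            elif metric == "coherence":
                if band is None:
                    raise ValueError("coherence requires a band")
                v = band_coherence(timecourses[rois[i]], timecourses[rois[j]],
                                   fs, band, n_segments)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            vals[i, j] = vals[j, i] = v
    if metric == "coherence":
        # diagonal coherence of a signal with itself is 1 by definition
        np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(values=vals, rois=rois, metric=metric,
                              condition=condition,
                              band=band.name if band else None)


def connectivity_contrast(mat_a: ConnectivityMatrix,
                          mat_b: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise difference a - b; antisymmetric under argument swap."""
    if mat_a.metric != mat_b.metric or mat_a.band != mat_b.band:
        raise ValueError("connectivity matrices have mismatched metric/band")
    if mat_a.rois != mat_b.rois:
        raise ValueError("connectivity matrices have mismatched ROIs")
    return ConnectivityMatrix(values=mat_a.values - mat_b.values, rois=mat_a.rois,
                              metric=mat_a.metric,
                              condition=f"{mat_a.condition} - {mat_b.condition}",
                              band=mat_a.band)
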