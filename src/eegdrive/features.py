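"""Sensor-level wavelet features for cognitive-state classification.

Each channel of each epoch is decomposed with a 5-level Daubechies-4
discrete wavelet transform; the five retained sub-bands at 500 Hz map
approximately to A5 0-7.8, D5 7.8-15.6, D4 15.6-31.25, D3 31.25-62.5 and
D2 62.5-125 Hz (D1 is discarded: it lies entirely above the 2-36 Hz
filtered content).  Per sub-band, three statistics are computed - mean
absolute amplitude, energy and wavelet entropy (Shannon entropy of the
normalized squared coefficients, natural log) - plus, for 11 anatomically
informed electrode pairs, the Pearson correlation of the two channels'
coefficient vectors per sub-band ("wavelet coherence").  With 29 channels
this yields 29*5*3 + 11*5 = 490 named features per epoch.

Feature extraction is strictly per-epoch (no cross-epoch statistics), so it
is fold-safe by construction; normalization and selection carry fold state
elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .defaults import DEFAULT_PAIRS
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "WaveletPlan", "FeatureTable", "SUBBAND_STATS",
    "dwt_subbands", "subband_stats", "pair_coherence_features", "assemble",
]

SUBBAND_STATS = ("mean_amplitude", "energy", "entropy")


@dataclass(frozen=True)
class WaveletPlan:
    """db4 decomposition plan: 5 levels, keeping A5 and D5..D2.

    The default boundary mode is 'periodization', the orthogonal extension
    under which the decomposition conserves energy exactly; entropy values
    depend mildly on this choice.
    """

    wavelet: str = "db4"
    level: int = 5
    keep: tuple[str, ...] = ("A5", "D5", "D4", "D3", "D2")
    mode: str = "periodization"

    #: nominal band edges (Hz) per sub-band at fs = 500 Hz
    band_map: dict = field(default_factory=lambda: {
        "A5": (0.0, 7.8125), "D5": (7.8125, 15.625), "D4": (15.625, 31.25),
        "D3": (31.25, 62.5), "D2": (62.5, 125.0)})


def dwt_subbands(x: np.ndarray, plan: WaveletPlan = WaveletPlan()
                 ) -> dict[str, np.ndarray]:
    """Decompose a single-channel epoch into the plan's sub-band coefficients."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_subbands expects a 1-D signal")
    wavelet = pywt.Wavelet(plan.wavelet)
    min_len = 2 ** plan.level
    if len(x) < max(min_len, wavelet.dec_len):
        raise ValueError(
            f"epoch too short for a {plan.level}-level {plan.wavelet} transform: "
            f"need >= {max(min_len, wavelet.dec_len)} samples")
    if plan.mode == "periodization":
        # exact orthogonality (Parseval) needs a length divisible by 2^level;
        # crop the tail remainder (< 2^level samples)
        x = x[: (len(x) // min_len) * min_len]
    coeffs = pywt.wavedec(x, wavelet, mode=plan.mode, level=plan.level)
    names = [f"A{plan.level}"] + [f"D{lev}" for lev in range(plan.level, 0, -1)]
    by_name = dict(zip(names, coeffs))
    return {name: by_name[name] for name in plan.keep}


def subband_stats(coeffs: np.ndarray) -> tuple[float, float, float]:
    """(mean |c|, sum c^2, Shannon entropy of normalized squared coefficients).

    Entropy uses the natural log with 0*log(0) := 0; an all-zero vector has
    entropy 0 by convention (degenerate).
    """
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient vector")
    energy = float(np.sum(c ** 2))
    mean_amp = float(np.mean(np.abs(c)))
    if energy == 0.0:
        return 0.0, 0.0, 0.0
    p = c ** 2 / energy
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])))
    return mean_amp, energy, entropy


def pair_coherence_features(epoch: np.ndarray, channel_names: tuple[str, ...],
                            plan: WaveletPlan = WaveletPlan(),
                            pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
                            ) -> dict[str, float]:
    """Pearson r of the two channels' wavelet coefficients, per pair per sub-band.

    Zero-variance coefficient vectors yield 0 (flagged degenerate).
    """
    idx = {name: i for i, name in enumerate(channel_names)}
    bad = [p for p in pairs for c in p if c not in idx]
    if bad:
        raise KeyError(f"pair channels missing from montage: {bad}")
    sub = {name: dwt_subbands(epoch[idx[name]], plan)
           for name in sorted({c for p in pairs for c in p})}
    out = {}
    for a, b in pairs:
        for band in plan.keep:
            ca, cb = sub[a][band], sub[b][band]
            if ca.std() == 0 or cb.std() == 0:
                logger.warning("degenerate coefficients for pair %s-%s %s", a, b, band)
                r = 0.0
            else:
                r = float(np.corrcoef(ca, cb)[0, 1])
            out[f"coh|{a}-{b}|{band}"] = r
    return out


@dataclass
class FeatureTable:
    """Epochs x named-features matrix with labels and grouping ids."""

    features: pd.DataFrame
    labels: np.ndarray
    groups: pd.DataFrame     # subject, lap, segment per row

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise ValueError("feature table contains NaN")
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if not (len(self.features) == len(self.labels) == len(self.groups)):
            raise ValueError("features/labels/groups must align")

    @property
    def n_epochs(self) -> int:
        return len(self.features)

    def subset(self, idx) -> "FeatureTable":
        idx = np.atleast_1d(idx)
        return FeatureTable(self.features.iloc[idx].reset_index(drop=True),
                            self.labels[idx],
                            self.groups.iloc[idx].reset_index(drop=True))


def assemble(epochs: EpochSet, plan: WaveletPlan = WaveletPlan(),
             pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS) -> FeatureTable:
    """Concatenate sub-band statistics and pair coherences per epoch.

    Feature names encode provenance: ``pw|<channel>|<subband>|<stat>`` and
    ``coh|<chA>-<chB>|<subband>``.  Epochs producing any non-finite feature
    are dropped and logged.
    """
    columns = [f"pw|{ch}|{band}|{stat}"
               for ch in epochs.channel_names
               for band in plan.keep
               for stat in SUBBAND_STATS]
    columns += [f"coh|{a}-{b}|{band}" for a, b in pairs for band in plan.keep]

    rows, keep_idx = [], []
    for e in range(epochs.n_epochs):
        row = {}
        for c, ch in enumerate(epochs.channel_names):
            sub = dwt_subbands(epochs.data[e, c], plan)
            for band in plan.keep:
                stats = subband_stats(sub[band])
                for stat, v in zip(SUBBAND_STATS, stats):
                    row[f"pw|{ch}|{band}|{stat}"] = v
        row.update(pair_coherence_features(epochs.data[e], epochs.channel_names,
                                           plan, pairs))
        vals = np.array([row[c] for c in columns])
        if not np.all(np.isfinite(vals)):
            logger.warning("assemble: dropping epoch %d with non-finite features", e)
            continue
        rows.append(row)
        keep_idx.append(e)
    if not rows:
        raise ValueError("no epochs survived feature assembly")
    feats = pd.DataFrame(rows, columns=columns)
    keep_idx = np.array(keep_idx)
    return FeatureTable(features=feats, labels=epochs.labels[keep_idx],
                        groups=epochs.groups.iloc[keep_idx].reset_index(drop=True))
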