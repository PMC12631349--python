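"""Synthetic multichannel EEG with planted, parameterized condition effects.

The generator emulates the statistical structure of a driving-engagement
EEG study: each subject completes a block of manual-driving (MD) laps
followed by a block of passive automated-replay (AD) laps; each lap
alternates Easy and Hard road segments; a segment-onset event is written
for every segment.  The continuous signal per channel is

    1/f background (with low-rank spatial mixing)
    + condition-scaled narrow-band oscillations (PlantedEffect)
    + coherently coupled narrow-band pairs     (PlantedCoupling)
    + white sensor noise.

Planted oscillations are narrow-band *filtered noise*, not sinusoids, so
coherence and entropy features downstream are non-degenerate.  Condition
multipliers are band-POWER ratios relative to the pre-onset amplitude, so a
multiplier of 2.0 means twice the baseline band power in the active part of
the segment.  Within each segment, the first ``onset_delay`` seconds carry
the baseline amplitude, and the planted scaling is ramped in at the event
onset, giving every epoch a condition-neutral baseline window.

Coupling is produced with a common-source model: both channel groups
receive ``w*s + sqrt(1-w^2)*n_i`` with a shared band-limited source ``s``
and independent per-channel noise; the analytic magnitude-squared coherence
of the coupling component between any cross-group pair is then ``w^4``, so
``w = strength**0.25`` plants the requested coherence.  Note the 1/f
background dilutes coherence measured on raw channels; the ground-truth
record stores the component-level value.

Between-subject variability is planted two ways (both log-normal):
a global per-subject amplitude gain, and a per-subject, per-effect exponent
``gamma`` applied to the log multipliers (``m ** gamma``), so subjects
differ in how strongly they express each condition effect while no-effect
conditions stay at 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .defaults import CHANNELS, CONDITIONS
from .preprocess import Recording

__all__ = [
    "PlantedEffect", "PlantedCoupling", "SimConfig", "GroundTruth",
    "default_effects", "default_couplings", "default_config", "quick_config",
    "null_config", "generate_recording", "generate_study", "inject_artifacts",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A band-limited oscillation on a channel group with per-condition power."""

    name: str
    channels: tuple[str, ...]
    band: tuple[float, float]
    base_amplitude: float                      # uV RMS of the baseline oscillation
    condition_multipliers: dict[str, float]    # condition -> band-power ratio
    subject_sd: float = 0.0                    # log-normal sd of per-subject exponent

    def validate(self, channel_names: tuple[str, ...], fs: float) -> None:
        if not self.channels:
            raise ValueError(f"effect {self.name!r}: empty channel group")
        missing = set(self.channels) - set(channel_names)
        if missing:
            raise ValueError(f"effect {self.name!r}: unknown channels {sorted(missing)}")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"effect {self.name!r}: invalid band {self.band}")
        if hi >= fs / 2:
            raise ValueError(
                f"effect {self.name!r}: band edge {hi} Hz >= Nyquist ({fs / 2} Hz)")
        if set(self.condition_multipliers) != set(CONDITIONS):
            raise ValueError(f"effect {self.name!r}: multipliers must cover {CONDITIONS}")
        if any(m <= 0 for m in self.condition_multipliers.values()):
            raise ValueError(f"effect {self.name!r}: multipliers must be positive")


@dataclass(frozen=True)
class PlantedCoupling:
    """A shared band-limited source coupling two channel groups."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    band: tuple[float, float]
    amplitude: float                    # uV RMS of the coupling component
    strength: dict[str, float]          # condition -> target coherence in [0, 1]

    def validate(self, channel_names: tuple[str, ...], fs: float) -> None:
        for grp in (self.group_a, self.group_b):
            missing = set(grp) - set(channel_names)
            if missing:
                raise ValueError(
                    f"coupling {self.name!r}: unknown channels {sorted(missing)}")
        lo, hi = self.band
        if not 0 < lo < hi or hi >= fs / 2:
            raise ValueError(f"coupling {self.name!r}: invalid band {self.band}")
        if any(not 0 <= c <= 1 for c in self.strength.values()):
            raise ValueError(f"coupling {self.name!r}: strength must lie in [0, 1]")


def default_effects() -> tuple[PlantedEffect, ...]:
    """Planted condition effects mirroring the study's qualitative findings.

    Frontal-midline theta and occipito-parietal alpha are elevated during
    manual driving; motor beta rises with complexity only under manual
    control; motor mu desynchronizes during easy manual driving.  Mode
    effects carry large between-subject heterogeneity (sd 0.6), the
    documented obstacle to cross-subject generalization.
    """
    return (
        PlantedEffect(
            name="frontal_theta",
            channels=("AF3", "Fz", "AF4", "F3", "F4"),
            band=(4.0, 7.0), base_amplitude=5.0,
            condition_multipliers={
                "MD-Easy": 1.8, "MD-Hard": 2.4, "AD-Easy": 1.0, "AD-Hard": 1.0},
            subject_sd=0.6,
        ),
        PlantedEffect(
            name="posterior_alpha",
            channels=("O1", "O2", "PO3", "PO4", "P3", "Pz", "P4"),
            band=(8.0, 12.0), base_amplitude=5.0,
            condition_multipliers={
                "MD-Easy": 1.7, "MD-Hard": 1.4, "AD-Easy": 1.2, "AD-Hard": 0.8},
            subject_sd=0.6,
        ),
        PlantedEffect(
            name="motor_beta",
            channels=("C3", "Cz", "C4"),
            band=(13.0, 30.0), base_amplitude=4.0,
            condition_multipliers={
                "MD-Easy": 1.0, "MD-Hard": 2.0, "AD-Easy": 1.0, "AD-Hard": 1.0},
            subject_sd=0.35,
        ),
        PlantedEffect(
            name="motor_mu",
            channels=("C3", "C4"),
            band=(8.0, 13.0), base_amplitude=4.0,
            condition_multipliers={
                "MD-Easy": 0.5, "MD-Hard": 0.9, "AD-Easy": 1.0, "AD-Hard": 1.0},
            subject_sd=0.35,
        ),
    )


def default_couplings() -> tuple[PlantedCoupling, ...]:
    """Fronto-parietal theta/beta coupling, stronger under manual driving."""
    return (
        PlantedCoupling(
            name="frontoparietal_theta",
            group_a=("F3", "Fz", "F4"), group_b=("P3", "Pz", "P4"),
            band=(4.0, 7.0), amplitude=3.0,
            strength={"MD-Easy": 0.55, "MD-Hard": 0.65,
                      "AD-Easy": 0.2, "AD-Hard": 0.2},
        ),
        PlantedCoupling(
            name="frontoparietal_beta",
            group_a=("F3", "F4"), group_b=("P3", "P4"),
            band=(13.0, 30.0), amplitude=3.0,
            strength={"MD-Easy": 0.35, "MD-Hard": 0.5,
                      "AD-Easy": 0.15, "AD-Hard": 0.15},
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 11
    fs: float = 500.0
    channel_names: tuple[str, ...] = CHANNELS
    laps_per_mode: int = 5          # MD laps, then the same count of AD laps
    segments_per_lap: int = 20      # alternating Easy/Hard -> 10 vs 10 per lap
    segment_duration: float = 6.0   # s
    onset_delay: float = 0.5        # s of baseline-amplitude pre-roll per segment
    noise_exponent: float = 1.0     # 1/f^a background slope
    background_sd: float = 6.0      # uV, broadband background per channel
    sensor_noise_sd: float = 2.0    # uV white sensor noise
    spatial_mixing: float = 0.4     # variance share of low-rank shared background
    spatial_rank: int = 5
    subject_gain_sd: float = 0.35   # log-normal sd of global per-subject gain
    effects: tuple[PlantedEffect, ...] = field(default_factory=default_effects)
    couplings: tuple[PlantedCoupling, ...] = field(default_factory=default_couplings)
    randomize_lap_order: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        n_seg_samples = self.segment_duration * self.fs
        if abs(n_seg_samples - round(n_seg_samples)) > 1e-9:
            raise ValueError("segment_duration * fs must be an integer sample count")
        for eff in self.effects:
            eff.validate(self.channel_names, self.fs)
        for cpl in self.couplings:
            cpl.validate(self.channel_names, self.fs)

    @property
    def n_laps(self) -> int:
        return 2 * self.laps_per_mode

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_duration * self.fs))

    @property
    def samples_per_subject(self) -> int:
        return self.n_laps * self.segments_per_lap * self.segment_samples


def default_config(**overrides) -> SimConfig:
    return SimConfig(**overrides)


def quick_config(**overrides) -> SimConfig:
    """Desk-scale profile: 3 subjects, 3 laps per mode, 20 segments per lap.

    Scales the study down in subjects and laps only; the within-lap
    structure (10 Easy vs 10 Hard segments per lap) is preserved, and three
    laps per mode keeps lap-grouped cross-validation meaningful (with two,
    each fold would train on a single lap per mode).
    """
    params = dict(n_subjects=3, laps_per_mode=3, segments_per_lap=20)
    params.update(overrides)
    return SimConfig(**params)


def null_config(**overrides) -> SimConfig:
    """No planted effects or couplings: every condition is exchangeable."""
    params = dict(effects=(), couplings=(), subject_gain_sd=0.0)
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class GroundTruth:
    """What was actually planted for one subject, reproducible from (config, seed)."""

    subject: int
    segments: pd.DataFrame            # onset_sample, condition, subject, lap, segment
    subject_gain: float
    effect_multipliers: dict[str, dict[str, float]]   # effect -> condition -> realized power ratio
    coupling_coherence: dict[str, dict[str, float]]   # coupling -> condition -> analytic MSC
    seed: int

    def to_json(self) -> str:
        d = asdict(self)
        d["segments"] = self.segments.to_dict(orient="list")
        return json.dumps(d, indent=2, default=float)


# ---------------------------------------------------------------------------
# noise primitives

def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise (spectrum flattened below 1 Hz)."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = 1.0 / np.maximum(f, 1.0) ** (exponent / 2)
    shape[0] = 0.0
    y = np.fft.irfft(spec * shape, n)
    return y / y.std()


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance noise band-limited to [lo, hi] Hz with tapered edges."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1 / fs)
    taper = max(0.05 * (hi - lo), 0.25)
    gain = np.zeros_like(f)
    core = (f >= lo) & (f <= hi)
    gain[core] = 1.0
    rise = (f >= lo - taper) & (f < lo)
    gain[rise] = 0.5 * (1 + np.cos(np.pi * (lo - f[rise]) / taper))
    fall = (f > hi) & (f <= hi + taper)
    gain[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / taper))
    y = np.fft.irfft(spec * gain, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _smooth_envelope(env: np.ndarray, fs: float, ramp_s: float = 0.05) -> np.ndarray:
    """Soften step changes with a short Hann kernel to avoid spectral clicks."""
    k = int(round(ramp_s * fs))
    if k < 2:
        return env
    kernel = np.hanning(k)
    kernel /= kernel.sum()
    return np.convolve(env, kernel, mode="same")


# ---------------------------------------------------------------------------
# schedule

def _segment_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lap/segment schedule with condition labels and event onsets."""
    modes = ["MD"] * config.laps_per_mode + ["AD"] * config.laps_per_mode
    if config.randomize_lap_order:
        rng.shuffle(modes)
    rows = []
    seg_n = config.segment_samples
    onset_off = int(round(config.onset_delay * config.fs))
    idx = 0
    for lap, mode in enumerate(modes):
        for seg in range(config.segments_per_lap):
            difficulty = "Easy" if seg % 2 == 0 else "Hard"
            rows.append({
                "start_sample": idx * seg_n,
                "onset_sample": idx * seg_n + onset_off,
                "condition": f"{mode}-{difficulty}",
                "lap": lap,
                "segment": seg,
            })
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# main generator

def generate_recording(config: SimConfig, subject_id: int
                       ) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Generate one subject's continuous recording, events and ground truth."""
    if not 0 <= subject_id < config.n_subjects:
        raise ValueError(f"subject_id {subject_id} outside [0, {config.n_subjects})")
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.n_subjects)[subject_id]
    rng = np.random.default_rng(child)

    fs, n_ch = config.fs, len(config.channel_names)
    n = config.samples_per_subject
    gain = float(np.exp(rng.normal(0.0, config.subject_gain_sd)))

    schedule = _segment_table(config, rng)
    seg_n = config.segment_samples
    onset_off = int(round(config.onset_delay * fs))

    # 1/f background with low-rank spatial mixing
    data = np.empty((n_ch, n))
    latents = np.stack([_shaped_noise(rng, n, fs, config.noise_exponent)
                        for _ in range(config.spatial_rank)])
    mix_w = rng.standard_normal((n_ch, config.spatial_rank))
    mix_w /= np.linalg.norm(mix_w, axis=1, keepdims=True)
    rho = config.spatial_mixing
    for c in range(n_ch):
        indep = _shaped_noise(rng, n, fs, config.noise_exponent)
        bg = np.sqrt(1 - rho) * indep + np.sqrt(rho) * (mix_w[c] @ latents)
        data[c] = config.background_sd * gain * (bg / bg.std())

    ch_index = {name: i for i, name in enumerate(config.channel_names)}
    effect_mults: dict[str, dict[str, float]] = {}

    # planted condition-scaled oscillations
    for eff in config.effects:
        gamma = float(np.exp(rng.normal(0.0, eff.subject_sd)))
        realized = {c: float(m ** gamma)
                    for c, m in eff.condition_multipliers.items()}
        effect_mults[eff.name] = realized
        env = np.empty(n)
        for _, row in schedule.iterrows():
            s0 = int(row["start_sample"])
            amp_active = eff.base_amplitude * np.sqrt(realized[row["condition"]])
            env[s0:s0 + onset_off] = eff.base_amplitude
            env[s0 + onset_off:s0 + seg_n] = amp_active
        env = _smooth_envelope(env, fs)
        for name in eff.channels:
            osc = _band_noise(rng, n, fs, *eff.band)
            data[ch_index[name]] += gain * env * osc

    # planted coherent coupling (common-source model, w = strength**0.25)
    coupling_coh: dict[str, dict[str, float]] = {}
    for cpl in config.couplings:
        coupling_coh[cpl.name] = {c: float(v) for c, v in cpl.strength.items()}
        w_env = np.empty(n)
        for _, row in schedule.iterrows():
            s0 = int(row["start_sample"])
            w_env[s0:s0 + seg_n] = cpl.strength[row["condition"]] ** 0.25
        w_env = _smooth_envelope(w_env, fs)
        shared = _band_noise(rng, n, fs, *cpl.band)
        for name in tuple(cpl.group_a) + tuple(cpl.group_b):
            indep = _band_noise(rng, n, fs, *cpl.band)
            comp = w_env * shared + np.sqrt(np.maximum(0.0, 1 - w_env ** 2)) * indep
            data[ch_index[name]] += gain * cpl.amplitude * comp

    if config.sensor_noise_sd > 0:
        data += rng.normal(0.0, config.sensor_noise_sd, size=data.shape)

    events = schedule[["onset_sample", "condition", "lap", "segment"]].copy()
    events.insert(2, "subject", subject_id)
    recording = Recording(data=data, fs=fs,
                          channel_names=tuple(config.channel_names), events=events)
    gt = GroundTruth(
        subject=subject_id,
        segments=events.copy(),
        subject_gain=gain,
        effect_multipliers=effect_mults,
        coupling_coherence=coupling_coh,
        seed=config.seed,
    )
    return recording, events, gt


def generate_study(config: SimConfig):
    """Yield (recording, events, ground_truth) for every subject."""
    for sid in range(config.n_subjects):
        yield generate_recording(config, sid)


# ---------------------------------------------------------------------------
# artifact injector

def inject_artifacts(recording: Recording, *, blink_rate: float = 0.0,
                     blink_channels: tuple[str, ...] = ("Fp1", "Fp2", "AF3", "AF4"),
                     blink_amplitude: float = 80.0, blink_duration: float = 0.3,
                     emg_channels: tuple[str, ...] = (), emg_sd: float = 0.0,
                     emg_rate: float = 0.1, emg_duration: float = 0.5,
                     seed: int = 0) -> tuple[Recording, pd.DataFrame]:
    """Add stereotyped blinks and broadband EMG bursts; returns annotations.

    With ``blink_rate == 0`` and ``emg_sd == 0`` the recording is returned
    unchanged.  Blink transients are raised-cosine deflections (< 4 Hz
    energy) on frontal channels; EMG bursts are band-limited (>20 Hz) noise
    on the named channels.
    """
    if blink_rate < 0 or emg_sd < 0 or emg_rate < 0:
        raise ValueError("artifact rates/amplitudes must be >= 0")
    for name in tuple(blink_channels) + tuple(emg_channels):
        if name not in recording.channel_names:
            raise KeyError(f"channel {name!r} not in recording")

    rng = np.random.default_rng(seed)
    data = recording.data.copy()
    fs, n = recording.fs, recording.n_samples
    duration_s = n / fs
    annotations = []

    if blink_rate > 0:
        width = int(round(blink_duration * fs))
        waveform = blink_amplitude * np.hanning(width)
        n_blinks = rng.poisson(blink_rate * duration_s)
        starts = np.sort(rng.integers(0, max(1, n - width), size=n_blinks))
        for s0 in starts:
            for name in blink_channels:
                data[recording.channel_index(name), s0:s0 + width] += waveform
            annotations.append({"onset_sample": int(s0), "kind": "blink",
                                "duration": blink_duration})

    if emg_sd > 0 and emg_channels:
        width = int(round(emg_duration * fs))
        n_bursts = rng.poisson(emg_rate * duration_s)
        starts = np.sort(rng.integers(0, max(1, n - width), size=n_bursts))
        for s0 in starts:
            for name in emg_channels:
                burst = emg_sd * _band_noise(rng, width, fs, 20.0, min(0.45 * fs, 120.0))
                data[recording.channel_index(name), s0:s0 + width] += burst
            annotations.append({"onset_sample": int(s0), "kind": "emg",
                                "duration": emg_duration})

    ann = pd.DataFrame(annotations, columns=["onset_sample", "kind", "duration"])
    return replace(recording, data=data), ann
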