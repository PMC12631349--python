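"""Montage, condition and band constants shared across the pipeline.

The montage is the 29-channel extended 10-20 layout of a portable dry-EEG
headset; the four condition labels cross engagement mode (manual driving MD
vs. passive automated-driving replay AD) with road complexity (Easy/Hard).
"""

from __future__ import annotations

#: 29 scalp channels of the extended 10-20 montage.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8",
    "O1", "O2",
)

#: Condition labels: engagement mode x road complexity.
CONDITIONS: tuple[str, ...] = ("MD-Easy", "MD-Hard", "AD-Easy", "AD-Hard")

MD_CONDITIONS = ("MD-Easy", "MD-Hard")
AD_CONDITIONS = ("AD-Easy", "AD-Hard")
EASY_CONDITIONS = ("MD-Easy", "AD-Easy")
HARD_CONDITIONS = ("MD-Hard", "AD-Hard")

#: Canonical analysis bands (Hz).  Mu is motor-cortex specific.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "mu": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Coarser grouping used when interpreting classifier features.
CLASSIFIER_BANDS: dict[str, tuple[float, float]] = {
    "delta-theta": (2.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta-low": (13.0, 20.0),
    "beta-high": (20.0, 36.0),
}

#: ROI names used by the toy source model.
ROI_NAMES: tuple[str, ...] = ("Motor", "mPFC", "ACC", "Visual", "PPC", "DLPFC")

#: Channel groups whose mean direction seeds each toy-geometry ROI sector.
#: DLPFC is bilateral, hence two seed groups.
ROI_SEED_CHANNELS: dict[str, tuple[tuple[str, ...], ...]] = {
    "Motor": (("C3", "Cz", "C4"),),
    "mPFC": (("Fp1", "Fp2", "AF3", "AF4"),),
    "ACC": (("Fz", "F3", "F4"),),
    "Visual": (("O1", "O2", "PO7", "PO8"),),
    "PPC": (("P3", "Pz", "P4", "PO3", "PO4"),),
    "DLPFC": (("F7", "FC5"), ("F8", "FC6")),
}

#: Hypothesis-driven (ROI, band) pairs tested for condition effects.
#: "FrontalMidline" is the union of the mPFC and ACC sectors.
ROI_BAND_PLAN: tuple[tuple[str, str], ...] = (
    ("Motor", "beta"),
    ("Motor", "mu"),
    ("Visual", "alpha"),
    ("FrontalMidline", "theta"),
    ("PPC", "alpha"),
)

#: Default 11 anatomically informed electrode pairs for wavelet-coefficient
#: coherence features (fronto-parietal, fronto-central, centro-parietal and
#: interhemispheric).
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fz", "Pz"),
    ("F3", "P3"),
    ("F4", "P4"),
    ("F3", "C3"),
    ("F4", "C4"),
    ("C3", "P3"),
    ("C4", "P4"),
    ("F3", "F4"),
    ("C3", "C4"),
    ("P3", "P4"),
    ("O1", "O2"),
)

#: Post-onset analysis window (s) for ROI activation / band-power statistics.
ANALYSIS_WINDOW: tuple[float, float] = (0.1, 0.8)

#: Pre-onset baseline window (s).
BASELINE_WINDOW: tuple[float, float] = (-0.2, 0.0)
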