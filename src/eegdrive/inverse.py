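"""Toy-geometry distributed inverse with dSPM noise normalization.

A minimum-norm inverse operator is built from a quasi-dipolar spherical
leadfield: sensors sit on a unit shell at standard 10-20 positions, sources
on a Fibonacci lattice at radius 0.8 with radial normals.  The operator
uses a loose orientation constraint (transverse variance scaled by
``loose**2``), depth weighting (per-source gain-norm prior ``|G_i|^-2*depth``)
and Tikhonov regularization ``lambda2 = 1/SNR**2``; source covariance is
rescaled so the whitened gain has unit average sensor power, making
``lambda2`` an interpretable inverse squared SNR.  dSPM divides each source
by its projected noise standard deviation, yielding dimensionless z-like
values.  Only the cortical-normal component is retained (third orientation
of each local triplet).

No anatomical fidelity is claimed: ROI sectors are contiguous patches of
the sphere labelled by the functional region whose electrodes they sit
under ("putative" regions only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .defaults import ANALYSIS_WINDOW, CHANNELS, ROI_SEED_CHANNELS
from .preprocess import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "Leadfield", "InverseOperator", "SourceEstimate",
    "sensor_positions", "make_toy_leadfield", "noise_covariance",
    "make_inverse", "apply_inverse_dspm", "condition_average",
    "contrast", "roi_timecourse", "window_mean", "roi_masks_with_frontal_midline",
]


@dataclass
class Leadfield:
    """Forward model: ``gain`` is channels x (3 * n_sources).

    Gain columns come in per-source triplets expressed in the source's local
    orientation basis (tangent1, tangent2, normal), so the normal component
    of any source-space quantity is every third row.
    """

    gain: np.ndarray
    source_positions: np.ndarray      # n_sources x 3
    source_normals: np.ndarray        # n_sources x 3 (unit)
    channel_names: tuple[str, ...]
    roi_masks: dict[str, np.ndarray]  # roi -> source indices

    @property
    def n_sources(self) -> int:
        return self.source_positions.shape[0]


@dataclass
class InverseOperator:
    kernel: np.ndarray          # (3 * n_sources) x channels, local orientation basis
    dspm_scale: np.ndarray      # n_sources, 1/sqrt(projected noise variance)
    lambda2: float
    loose: float
    depth: float
    noise_cov: np.ndarray
    source_scale: float         # covariance rescaling factor mu
    channel_names: tuple[str, ...]


@dataclass
class SourceEstimate:
    """Noise-normalized (dSPM) normal-component source activity."""

    values: np.ndarray          # n_sources x n_times
    fs: float
    tmin: float
    condition: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.values.shape[1]) / self.fs


# ---------------------------------------------------------------------------
# geometry

def sensor_positions(channel_names: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Unit-shell sensor positions from the bundled standard 10-20 montage."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # montage rename pending
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [c for c in channel_names if c not in pos]
    if missing:
        raise KeyError(f"channels missing from standard_1020 montage: {missing}")
    xyz = np.array([pos[c] for c in channel_names])
    xyz = xyz - xyz.mean(axis=0) * np.array([1.0, 1.0, 0.0])  # center laterally
    return xyz / np.linalg.norm(xyz, axis=1, keepdims=True)


def _fibonacci_hemisphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n                      # uniform in z over (0, 1)
    phi = np.pi * (1 + 5 ** 0.5) * i
    r_xy = np.sqrt(1 - z ** 2)
    pts = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    return radius * pts


def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def make_toy_leadfield(n_channels: int = 29, n_sources: int = 96,
                       geometry_seed: int = 0,
                       channel_names: tuple[str, ...] = CHANNELS,
                       source_radius: float = 0.8,
                       roi_angle_cap_deg: float = 60.0) -> Leadfield:
    """Spherical quasi-dipolar leadfield with ROI sectors under electrode groups.

    The gain of source ``i`` with orientation ``e`` at sensor ``s`` follows
    the unbounded-medium dipole potential ``e . (s - p) / |s - p|^3``, then
    an average-reference projection is applied (the inverse stage always
    receives common-average data).
    """
    channel_names = tuple(channel_names[:n_channels])
    if len(channel_names) != n_channels:
        raise ValueError("n_channels exceeds available channel names")
    if n_sources < 2 * len(ROI_SEED_CHANNELS):
        raise ValueError("need at least two sources per ROI")
    rng = np.random.default_rng(geometry_seed)
    sensors = sensor_positions(channel_names)

    for attempt in range(5):
        src = _fibonacci_hemisphere(n_sources, source_radius)
        # random azimuthal rotation so distinct seeds give distinct lattices
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        src = src @ rot.T
        d = np.linalg.norm(src[:, None] - src[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 1e-6 * source_radius:
            break
        logger.warning("degenerate source geometry; regenerating with perturbation")
        src = src + rng.normal(0, 1e-3, src.shape)
    normals = src / np.linalg.norm(src, axis=1, keepdims=True)

    gain = np.empty((n_channels, 3 * n_sources))
    for i in range(n_sources):
        t1, t2 = _tangent_basis(normals[i])
        diff = sensors - src[i]
        dist3 = np.linalg.norm(diff, axis=1) ** 3
        for k, e in enumerate((t1, t2, normals[i])):
            gain[:, 3 * i + k] = (diff @ e) / dist3
    gain -= gain.mean(axis=0, keepdims=True)  # average-reference projection

    fixed = gain[:, 2::3]
    logger.info("toy leadfield: fixed-orientation condition number %.3g",
                np.linalg.cond(fixed))

    # ROI sectors: nearest seed direction within the angular cap
    seed_dirs, seed_roi = [], []
    ch_idx = {c: j for j, c in enumerate(channel_names)}
    for roi, groups in ROI_SEED_CHANNELS.items():
        for grp in groups:
            if all(c in ch_idx for c in grp):
                v = sensors[[ch_idx[c] for c in grp]].mean(axis=0)
                seed_dirs.append(v / np.linalg.norm(v))
                seed_roi.append(roi)
    seed_dirs = np.array(seed_dirs)
    cosines = normals @ seed_dirs.T
    best = np.argmax(cosines, axis=1)
    cap = np.cos(np.deg2rad(roi_angle_cap_deg))
    roi_masks: dict[str, np.ndarray] = {roi: [] for roi in ROI_SEED_CHANNELS}
    for i in range(n_sources):
        if cosines[i, best[i]] >= cap:
            roi_masks[seed_roi[best[i]]].append(i)
    roi_masks = {roi: np.array(ix, dtype=int) for roi, ix in roi_masks.items()}
    return Leadfield(gain=gain, source_positions=src, source_normals=normals,
                     channel_names=channel_names, roi_masks=roi_masks)


def roi_masks_with_frontal_midline(leadfield: Leadfield) -> dict[str, np.ndarray]:
    """ROI masks plus the FrontalMidline union (mPFC + ACC sectors)."""
    masks = dict(leadfield.roi_masks)
    masks["FrontalMidline"] = np.union1d(masks["mPFC"], masks["ACC"])
    return masks


# ---------------------------------------------------------------------------
# operator construction

def noise_covariance(epochs: EpochSet, window: tuple[float, float] = (-0.2, 0.0),
                     shrinkage: float = 0.1) -> np.ndarray:
    """Channel covariance of the baseline period, shrunk toward scaled identity."""
    if epochs.n_epochs < 2:
        raise ValueError("need >= 2 epochs for a noise covariance")
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError("window contains no samples")
    x = epochs.data[:, :, mask]                       # epochs x channels x t
    x = np.concatenate([e for e in x], axis=1)        # channels x (epochs * t)
    x = x - x.mean(axis=1, keepdims=True)
    c = x @ x.T / (x.shape[1] - 1)
    n = c.shape[0]
    if shrinkage == 0.0:
        eig = np.linalg.eigvalsh(c)
        if eig.min() < 1e-10 * np.trace(c) / n:
            logger.warning("noise covariance rank-deficient; enforcing shrinkage 0.1")
            shrinkage = 0.1
    c = (1 - shrinkage) * c + shrinkage * (np.trace(c) / n) * np.eye(n)
    return (c + c.T) / 2


def make_inverse(leadfield: Leadfield, noise_cov: np.ndarray, snr: float = 3.0,
                 loose: float = 0.2, depth: float = 0.8) -> InverseOperator:
    """Regularized minimum-norm kernel with loose orientation, depth weighting
    and dSPM normalization factors.

    ``K = R G^T (G R G^T + lambda2 C)^-1`` with diagonal source covariance
    ``R``: per source ``w_i = |G_i|_F^(-2*depth)`` on the orientation
    triplet, transverse components additionally scaled by ``loose**2``, and
    a global rescaling ``mu`` such that the whitened gain carries unit mean
    power per channel.  dSPM scale of source ``i`` is
    ``1/sqrt(sum_triplet diag(K C K^T))``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not (0 <= loose <= 1 and 0 <= depth <= 1):
        raise ValueError("loose and depth must lie in [0, 1]")
    g = leadfield.gain
    n_ch, n_cols = g.shape
    n_src = n_cols // 3
    lambda2 = 1.0 / snr ** 2

    w = np.empty(n_src)
    for i in range(n_src):
        norm = np.linalg.norm(g[:, 3 * i:3 * i + 3])
        w[i] = norm ** (-2.0 * depth) if depth > 0 else 1.0
    r_diag = np.repeat(w, 3) * np.tile([loose ** 2, loose ** 2, 1.0], n_src)

    # rescale R so trace(Gw R Gw^T) = n_ch in whitened sensor space
    try:
        chol = np.linalg.cholesky(noise_cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("noise covariance not positive definite") from err
    gw = np.linalg.solve(chol, g)
    denom = float(np.sum(r_diag * np.einsum("ij,ij->j", gw, gw)))
    mu = n_ch / denom
    r_diag = mu * r_diag

    grg = (g * r_diag) @ g.T
    m = grg + lambda2 * noise_cov
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e14:
        raise ValueError(f"(G R G^T + lambda2 C) is singular: condition number {cond:.3g}")
    kernel = r_diag[:, None] * g.T @ np.linalg.inv(m)

    kck_diag = np.einsum("ij,ij->i", kernel @ noise_cov, kernel)
    noise_var = kck_diag.reshape(n_src, 3).sum(axis=1)
    dspm_scale = 1.0 / np.sqrt(noise_var)
    return InverseOperator(kernel=kernel, dspm_scale=dspm_scale, lambda2=lambda2,
                           loose=loose, depth=depth, noise_cov=noise_cov,
                           source_scale=mu, channel_names=leadfield.channel_names)


# ---------------------------------------------------------------------------
# application

def _check_channels(inv: InverseOperator, epochs: EpochSet) -> None:
    if tuple(inv.channel_names) != tuple(epochs.channel_names):
        a = set(inv.channel_names) ^ set(epochs.channel_names)
        raise ValueError(f"channel mismatch between operator and epochs: {sorted(a) or 'order differs'}")


def apply_inverse_dspm(epochs: EpochSet, inv: InverseOperator) -> list[SourceEstimate]:
    """Per-epoch dSPM source estimates (normal component only)."""
    _check_channels(inv, epochs)
    n_src = inv.kernel.shape[0] // 3
    out = []
    for ep, label in zip(epochs.data, epochs.labels):
        sc = inv.kernel @ ep
        normal = sc[2::3]
        out.append(SourceEstimate(values=normal * inv.dspm_scale[:, None],
                                  fs=epochs.fs, tmin=epochs.tmin, condition=str(label)))
    assert all(stc.values.shape[0] == n_src for stc in out)
    return out


def condition_average(epochs: EpochSet, inv: InverseOperator) -> dict[str, SourceEstimate]:
    """Mean dSPM estimate per condition label."""
    stcs = apply_inverse_dspm(epochs, inv)
    by_label: dict[str, list[np.ndarray]] = {}
    for stc in stcs:
        by_label.setdefault(stc.condition, []).append(stc.values)
    return {
        lab: SourceEstimate(values=np.mean(vals, axis=0), fs=epochs.fs,
                            tmin=epochs.tmin, condition=lab)
        for lab, vals in by_label.items()
    }


def contrast(stc_a: SourceEstimate, stc_b: SourceEstimate) -> SourceEstimate:
    """Elementwise difference a - b, tagged with the contrast name."""
    if stc_a.values.shape != stc_b.values.shape:
        raise ValueError("source estimates have mismatched shapes")
    if abs(stc_a.tmin - stc_b.tmin) > 1e-9 or stc_a.fs != stc_b.fs:
        raise ValueError("source estimates have mismatched time axes")
    return SourceEstimate(values=stc_a.values - stc_b.values, fs=stc_a.fs,
                          tmin=stc_a.tmin,
                          condition=f"{stc_a.condition} - {stc_b.condition}")


def roi_timecourse(stc: SourceEstimate, roi_masks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Arithmetic mean across the sources of each ROI, per time point."""
    out = {}
    for roi, idx in roi_masks.items():
        if len(idx) == 0:
            raise ValueError(f"ROI {roi!r} has an empty mask")
        out[roi] = stc.values[idx].mean(axis=0)
    return out


def window_mean(timecourse: np.ndarray, fs: float, tmin: float,
                window: tuple[float, float] = ANALYSIS_WINDOW) -> float:
    """Mean of a time course over a time window (defaults to 0.1-0.8 s)."""
    t = tmin + np.arange(len(timecourse)) / fs
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError("window contains no samples")
    return float(timecourse[mask].mean())
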