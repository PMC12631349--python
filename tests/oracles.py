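"""Independent reference implementations used to cross-check the package."""

import numpy as np
from scipy import signal


def welch_csd_oracle(x, y, fs, nperseg):
    """Direct windowed-DFT re-implementation of the Welch cross-spectrum
    (Hann window, 50% overlap, one-sided density scaling)."""
    w = signal.get_window("hann", nperseg)
    step = nperseg // 2
    n_seg = (len(x) - nperseg) // step + 1
    scale = 1.0 / (fs * (w * w).sum())
    acc = np.zeros(nperseg // 2 + 1, dtype=complex)
    for k in range(n_seg):
        xs = x[k * step: k * step + nperseg] * w
        ys = y[k * step: k * step + nperseg] * w
        fx, fy = np.fft.rfft(xs), np.fft.rfft(ys)
        acc += np.conj(fx) * fy
    pxy = acc / n_seg * scale
    pxy[1:-1] *= 2 if nperseg % 2 == 0 else 1
    if nperseg % 2 != 0:
        pxy[1:] *= 2
    return np.fft.rfftfreq(nperseg, 1 / fs), pxy


def welch_coherence_oracle(x, y, fs, nperseg):
    _, pxy = welch_csd_oracle(x, y, fs, nperseg)
    _, pxx = welch_csd_oracle(x, x, fs, nperseg)
    f, pyy = welch_csd_oracle(y, y, fs, nperseg)
    return f, np.abs(pxy) ** 2 / (pxx.real * pyy.real)


def brute_force_bh(p):
    """Literal Benjamini-Hochberg step-up: sort, scale by m/rank, enforce
    monotonicity from the largest p downwards, undo the sort."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
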