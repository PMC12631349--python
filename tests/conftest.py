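import numpy as np
import pandas as pd
import pytest

import eegdrive as ed


def make_recording(n_channels=4, n_samples=5000, fs=500.0, seed=0,
                   channel_names=None, n_events=6):
    """Small white-noise recording with evenly spaced events."""
    rng = np.random.default_rng(seed)
    names = channel_names or tuple(ed.CHANNELS[:n_channels])
    data = rng.standard_normal((len(names), n_samples))
    onsets = np.sort(np.linspace(min(500, n_samples // 4),
                                 max(n_samples - 1200, n_samples // 2),
                                 n_events).astype(int))
    conditions = [ed.CONDITIONS[i % 4] for i in range(n_events)]
    events = pd.DataFrame({
        "onset_sample": onsets, "condition": conditions,
        "subject": 0, "lap": [i // 2 for i in range(n_events)],
        "segment": [i % 2 for i in range(n_events)],
    })
    return ed.Recording(data=data, fs=fs, channel_names=names, events=events)


@pytest.fixture
def toy_recording():
    return make_recording()


@pytest.fixture(scope="session")
def quick_epochs():
    """Preprocessed epochs from the desk-scale study config (shared)."""
    from eegdrive.pipeline import simulate_and_preprocess

    cfg = ed.quick_config(seed=1)
    epochs, events, gts = simulate_and_preprocess(cfg)
    return cfg, epochs, events, gts


@pytest.fixture(scope="session")
def quick_features(quick_epochs):
    _, epochs, _, _ = quick_epochs
    return ed.assemble(epochs)
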