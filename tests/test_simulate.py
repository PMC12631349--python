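"""Generator properties: determinism, schedule structure, planted-effect
recovery, null calibration and the artifact injector."""

import numpy as np
import pytest

import eegdrive as ed
from eegdrive.oscillations import BandDef, band_power

THETA = BandDef("theta", 4.0, 7.0)


def _small_config(**kw):
    params = dict(n_subjects=1, laps_per_mode=2, segments_per_lap=6,
                  segment_duration=2.0, fs=250.0,
                  channel_names=("AF3", "Fz", "AF4", "Pz"),
                  effects=(), couplings=(), subject_gain_sd=0.0, seed=0)
    params.update(kw)
    return ed.SimConfig(**params)


def _segment_band_power(recording, band, channels):
    """Welch-free per-segment active-window band power, averaged over channels."""
    idx = [recording.channel_index(c) for c in channels]
    fs = recording.fs
    out = []
    for _, ev in recording.events.iterrows():
        on = int(ev["onset_sample"])
        seg = recording.data[idx, on:on + int(1.4 * fs)]
        out.append(band_power(seg, fs, band))
    return np.array(out)


class TestDeterminismAndSchedule:
    def test_identical_seed_bit_identical(self):
        cfg = _small_config(effects=ed.default_effects()[:1],
                            channel_names=ed.CHANNELS, seed=11)
        rec1, ev1, gt1 = ed.generate_recording(cfg, 0)
        rec2, ev2, gt2 = ed.generate_recording(cfg, 0)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        assert ev1.equals(ev2)
        assert gt1.subject_gain == gt2.subject_gain

    def test_schedule_structure(self):
        cfg = _small_config()
        _, events, _ = ed.generate_recording(cfg, 0)
        assert len(events) == cfg.n_laps * cfg.segments_per_lap
        # MD laps precede AD laps; Easy/Hard alternate within lap
        modes = events["condition"].str.split("-").str[0]
        assert (modes[: len(events) // 2] == "MD").all()
        assert (modes[len(events) // 2:] == "AD").all()
        lap0 = events[events["lap"] == 0]["condition"].str.split("-").str[1]
        assert list(lap0) == ["Easy", "Hard"] * 3

    def test_invalid_band_rejected_naming_effect(self):
        eff = ed.PlantedEffect(name="bad_band", channels=("Fz",), band=(4.0, 200.0),
                               base_amplitude=1.0,
                               condition_multipliers=dict.fromkeys(ed.CONDITIONS, 1.0))
        with pytest.raises(ValueError, match="bad_band"):
            _small_config(effects=(eff,))

    def test_subject_id_out_of_range(self):
        with pytest.raises(ValueError):
            ed.generate_recording(_small_config(), 5)


class TestPlantedEffects:
    def test_no_effect_config_equal_power_across_conditions(self):
        cfg = _small_config(laps_per_mode=4, segments_per_lap=10, seed=2)
        rec, events, _ = ed.generate_recording(cfg, 0)
        p = _segment_band_power(rec, THETA, ("Fz",))
        md = p[events["condition"].str.startswith("MD")]
        ad = p[events["condition"].str.startswith("AD")]
        assert md.mean() / ad.mean() == pytest.approx(1.0, abs=0.2)

    def test_planted_theta_ratio_recovered(self):
        eff = ed.PlantedEffect(
            name="theta", channels=("AF3", "Fz", "AF4"), band=(4.0, 7.0),
            base_amplitude=5.0,
            condition_multipliers={"MD-Easy": 2.0, "MD-Hard": 2.0,
                                   "AD-Easy": 1.0, "AD-Hard": 1.0})
        cfg = _small_config(laps_per_mode=3, segments_per_lap=20, seed=3,
                            background_sd=1.0, sensor_noise_sd=0.5, effects=(eff,))
        rec, events, _ = ed.generate_recording(cfg, 0)
        p = _segment_band_power(rec, THETA, ("AF3", "Fz", "AF4"))
        md = p[events["condition"].str.startswith("MD")]
        ad = p[events["condition"].str.startswith("AD")]
        assert md.mean() / ad.mean() == pytest.approx(2.0, rel=0.1)

    def test_default_config_frontal_theta_direction(self, quick_epochs):
        _, epochs, _, _ = quick_epochs
        idx = [epochs.channel_names.index(c) for c in ("AF3", "Fz", "AF4")]
        mask = epochs.time_mask((0.1, 0.8))
        md = ad = 0.0
        powers = {"MD": [], "AD": []}
        for e in range(epochs.n_epochs):
            seg = epochs.data[e][idx][:, mask]
            powers[epochs.labels[e].split("-")[0]].append(
                band_power(seg, epochs.fs, THETA))
        assert np.mean(powers["MD"]) > np.mean(powers["AD"])

    def test_coupling_strength_orders_coherence(self):
        from eegdrive.oscillations import band_coherence
        vals = []
        for strength in (0.0, 0.45, 0.9):
            cpl = ed.PlantedCoupling(
                name="fp", group_a=("Fz",), group_b=("Pz",), band=(4.0, 7.0),
                amplitude=4.0, strength=dict.fromkeys(ed.CONDITIONS, strength))
            cfg = _small_config(laps_per_mode=2, segments_per_lap=10, seed=4,
                                background_sd=1.0, sensor_noise_sd=0.5,
                                couplings=(cpl,))
            rec, _, _ = ed.generate_recording(cfg, 0)
            vals.append(band_coherence(rec.data[rec.channel_index("Fz")],
                                       rec.data[rec.channel_index("Pz")],
                                       rec.fs, THETA, n_segments=32))
        assert vals[0] < vals[1] < vals[2]

    def test_ground_truth_records_realized_multipliers(self):
        cfg = ed.quick_config(seed=5)
        _, _, gt = ed.generate_recording(cfg, 1)
        assert set(gt.effect_multipliers) == {e.name for e in cfg.effects}
        for eff in cfg.effects:
            realized = gt.effect_multipliers[eff.name]
            for cond, m in eff.condition_multipliers.items():
                if m == 1.0:   # no-effect conditions stay exactly at 1
                    assert realized[cond] == 1.0
        assert len(gt.segments) == cfg.n_laps * cfg.segments_per_lap


class TestNullCalibration:
    def test_type_one_error_of_condition_contrast(self):
        """With nothing planted, the within-lap Easy-Hard contrast tested by a
        one-sample t is correctly calibrated (empirical alpha in [.03, .07])."""
        n_reps = 500
        rejections = 0
        for rep in range(n_reps):
            cfg = _small_config(laps_per_mode=3, segments_per_lap=4, seed=10_000 + rep)
            rec, events, _ = ed.generate_recording(cfg, 0)
            logp = np.log(_segment_band_power(rec, THETA, ("Fz",)))
            diffs = []
            for lap in events["lap"].unique():
                sel = events["lap"] == lap
                easy = logp[(sel & events["condition"].str.endswith("Easy")).to_numpy()]
                hard = logp[(sel & events["condition"].str.endswith("Hard")).to_numpy()]
                diffs.append(easy.mean() - hard.mean())
            res = ed.one_sample_t(np.array(diffs), 0.0, tails="two")
            rejections += res.p_raw < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07


class TestArtifacts:
    def test_zero_rates_identity(self, toy_recording):
        out, ann = ed.inject_artifacts(toy_recording, blink_rate=0.0, emg_sd=0.0,
                                       blink_channels=("Fp1", "Fp2"))
        np.testing.assert_array_equal(out.data, toy_recording.data)
        assert len(ann) == 0

    def test_blink_count_matches_rate(self):
        from conftest import make_recording
        rec = make_recording(n_channels=4,
                             channel_names=("Fp1", "Fp2", "AF3", "AF4"),
                             n_samples=30000)  # 60 s at 500 Hz
        counts = [len(ed.inject_artifacts(rec, blink_rate=0.25,
                                          blink_channels=("Fp1", "Fp2"),
                                          seed=s)[1]) for s in range(20)]
        assert np.mean(counts) == pytest.approx(15.0, rel=0.25)

    def test_blinks_raise_low_frequency_variance_on_target_channels(self):
        from conftest import make_recording
        from scipy import signal
        rec = make_recording(n_channels=6, n_samples=30000,
                             channel_names=("Fp1", "Fp2", "AF3", "AF4", "C3", "O1"))
        out, _ = ed.inject_artifacts(rec, blink_rate=0.3,
                                     blink_channels=("Fp1", "Fp2", "AF3", "AF4"),
                                     seed=1)
        sos = signal.butter(4, 4.0, btype="lowpass", fs=rec.fs, output="sos")
        low = signal.sosfiltfilt(sos, out.data - rec.data.mean(), axis=1)
        deltas = low.var(axis=1) - signal.sosfiltfilt(sos, rec.data, axis=1).var(axis=1)
        frontal = deltas[:4]
        others = deltas[4:]
        assert frontal.min() > others.max()

    def test_unknown_channel_rejected(self, toy_recording):
        with pytest.raises(KeyError):
            ed.inject_artifacts(toy_recording, blink_rate=0.1,
                                blink_channels=("Fp9",))
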