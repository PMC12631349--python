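"""Minimum-norm/dSPM operator: regularization constant, limit cases, the
direct ridge-regression oracle, noise normalization and source recovery."""

import numpy as np
import pandas as pd
import pytest

import eegdrive as ed
from eegdrive.inverse import Leadfield, make_toy_leadfield, roi_masks_with_frontal_midline


def _epochs_from_array(data, fs=500.0, tmin=-0.4, channel_names=None):
    n_ep, n_ch, n_t = data.shape
    names = channel_names or tuple(ed.CHANNELS[:n_ch])
    tmax = tmin + (n_t - 1) / fs
    return ed.EpochSet(
        data=data, fs=fs, tmin=tmin, tmax=tmax, channel_names=names,
        labels=np.array([ed.CONDITIONS[i % 4] for i in range(n_ep)]),
        groups=pd.DataFrame({"subject": 0, "lap": 0, "segment": range(n_ep)}),
    )


def _random_leadfield(n_ch=5, n_src=4, seed=0):
    rng = np.random.default_rng(seed)
    gain = rng.standard_normal((n_ch, 3 * n_src))
    pos = rng.standard_normal((n_src, 3))
    normals = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return Leadfield(gain=gain, source_positions=pos, source_normals=normals,
                     channel_names=tuple(ed.CHANNELS[:n_ch]),
                     roi_masks={"Motor": np.array([0, 1])})


class TestMakeInverse:
    def test_snr_three_gives_lambda2_0111(self):
        lf = _random_leadfield()
        cov = np.eye(5)
        inv = ed.make_inverse(lf, cov, snr=3.0)
        assert round(inv.lambda2, 3) == 0.111

    def test_loose_zero_kills_transverse_components(self):
        lf = _random_leadfield()
        inv = ed.make_inverse(lf, np.eye(5), loose=0.0)
        np.testing.assert_allclose(inv.kernel[0::3], 0.0, atol=1e-14)
        np.testing.assert_allclose(inv.kernel[1::3], 0.0, atol=1e-14)
        assert np.abs(inv.kernel[2::3]).max() > 0

    def test_ridge_oracle_loose1_depth0(self):
        """With loose=1, depth=0 the kernel is the ridge solution
        mu * G^T (mu G G^T + lambda2 C)^-1 computed directly."""
        lf = _random_leadfield(5, 4, seed=3)
        rng = np.random.default_rng(1)
        a = rng.standard_normal((5, 5))
        cov = a @ a.T + 5 * np.eye(5)
        inv = ed.make_inverse(lf, cov, snr=3.0, loose=1.0, depth=0.0)
        g, mu, lam = lf.gain, inv.source_scale, inv.lambda2
        expected = mu * g.T @ np.linalg.inv(mu * g @ g.T + lam * cov)
        np.testing.assert_allclose(inv.kernel, expected, rtol=1e-10)

    def test_kernel_norm_shrinks_with_regularization(self):
        lf = _random_leadfield()
        norms = [np.linalg.norm(ed.make_inverse(lf, np.eye(5), snr=s).kernel
                                / ed.make_inverse(lf, np.eye(5), snr=s).source_scale)
                 for s in (10.0, 1.0, 0.1)]
        assert norms[0] > norms[1] > norms[2]

    def test_invalid_parameters_rejected(self):
        lf = _random_leadfield()
        with pytest.raises(ValueError):
            ed.make_inverse(lf, np.eye(5), snr=-1.0)
        with pytest.raises(ValueError):
            ed.make_inverse(lf, np.eye(5), loose=1.5)


class TestNoiseCovariance:
    def test_white_noise_gives_scaled_identity(self):
        rng = np.random.default_rng(0)
        sigma = 2.0
        eps = _epochs_from_array(rng.normal(0, sigma, (200, 4, 501)), tmin=-1.0)
        cov = ed.noise_covariance(eps, window=(-1.0, 0.0), shrinkage=0.0)
        np.testing.assert_allclose(np.diag(cov), sigma ** 2, rtol=0.1)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.1 * sigma ** 2

    def test_identical_channels_rank_one_with_enforced_shrinkage(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 1, 501))
        eps = _epochs_from_array(np.repeat(x, 4, axis=1), tmin=-1.0)
        cov = ed.noise_covariance(eps, window=(-1.0, 0.0), shrinkage=0.0)
        # rank deficiency detected, shrinkage enforced -> still invertible
        assert np.linalg.matrix_rank(cov) == 4

    def test_symmetric(self, quick_epochs):
        _, epochs, _, _ = quick_epochs
        cov = ed.noise_covariance(epochs)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)


@pytest.fixture(scope="module")
def operator():
    lf = make_toy_leadfield(n_sources=96, geometry_seed=0)
    cov = 4.0 * np.eye(29)
    return lf, ed.make_inverse(lf, cov)


class TestApplyInverse:
    def test_linearity_and_zero_input(self, operator):
        lf, inv = operator
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 29, 101))
        eps1 = _epochs_from_array(x, tmin=0.0)
        eps2 = _epochs_from_array(3.0 * x, tmin=0.0)
        s1 = ed.apply_inverse_dspm(eps1, inv)
        s2 = ed.apply_inverse_dspm(eps2, inv)
        np.testing.assert_allclose(s2[0].values, 3.0 * s1[0].values, rtol=1e-10)
        zero = _epochs_from_array(np.zeros((1, 29, 101)), tmin=0.0)
        np.testing.assert_allclose(ed.apply_inverse_dspm(zero, inv)[0].values, 0.0)

    def test_noise_only_dspm_is_order_one(self, operator):
        lf, inv = operator
        rng = np.random.default_rng(3)
        noise = rng.multivariate_normal(np.zeros(29), inv.noise_cov,
                                        size=(100, 101)).transpose(0, 2, 1)
        stcs = ed.apply_inverse_dspm(_epochs_from_array(noise, tmin=0.0), inv)
        mean_abs = np.mean([np.abs(s.values).mean() for s in stcs])
        assert 0.2 < mean_abs < 2.0

    def test_channel_mismatch_rejected(self, operator):
        _, inv = operator
        eps = _epochs_from_array(np.zeros((1, 5, 101)), tmin=0.0)
        with pytest.raises(ValueError, match="channel mismatch"):
            ed.apply_inverse_dspm(eps, inv)

    def test_planted_source_localized(self, operator):
        """A single strong normal-oriented source is recovered at or adjacent
        to the true location in >= 90% of seeds."""
        lf, inv = operator
        pos = lf.source_positions / np.linalg.norm(lf.source_positions,
                                                   axis=1, keepdims=True)
        d = np.arccos(np.clip(pos @ pos.T, -1, 1))
        np.fill_diagonal(d, np.inf)
        adjacency = 1.5 * np.median(d.min(axis=1))
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            true = rng.integers(0, lf.n_sources)
            wave = rng.standard_normal(101)
            gcol = lf.gain[:, 3 * true + 2]
            amp = 10 * 2.0 / np.linalg.norm(gcol)  # 10x the noise sd
            sensors = amp * np.outer(gcol, wave) + rng.normal(0, 2.0, (29, 101))
            stc = ed.apply_inverse_dspm(_epochs_from_array(sensors[None], tmin=0.0),
                                        inv)[0]
            found = int(np.argmax(np.abs(stc.values).mean(axis=1)))
            ang = np.arccos(np.clip(pos[true] @ pos[found], -1, 1))
            hits += ang <= adjacency or found == true
        assert hits >= 0.9 * n_seeds


class TestGeometryAndRois:
    def test_leadfield_deterministic(self):
        lf1 = make_toy_leadfield(geometry_seed=7)
        lf2 = make_toy_leadfield(geometry_seed=7)
        np.testing.assert_array_equal(lf1.gain, lf2.gain)

    def test_distant_sources_have_distinct_gain(self):
        lf = make_toy_leadfield(geometry_seed=0)
        pos = lf.source_positions
        i, j = 0, int(np.argmax(np.linalg.norm(pos - pos[0], axis=1)))
        gi, gj = lf.gain[:, 3 * i + 2], lf.gain[:, 3 * j + 2]
        corr = abs(np.corrcoef(gi, gj)[0, 1])
        assert corr < 0.9

    def test_roi_masks_cover_most_sources_disjointly(self):
        lf = make_toy_leadfield(geometry_seed=0)
        all_idx = np.concatenate(list(lf.roi_masks.values()))
        assert len(all_idx) == len(set(all_idx))           # disjoint
        assert len(all_idx) >= 0.8 * lf.n_sources          # >= 80% coverage
        assert set(lf.roi_masks) == set(ed.ROI_NAMES)

    def test_frontal_midline_union(self):
        lf = make_toy_leadfield(geometry_seed=0)
        masks = roi_masks_with_frontal_midline(lf)
        assert set(masks["FrontalMidline"]) == set(masks["mPFC"]) | set(masks["ACC"])


class TestContrastAndRoi:
    def _stc(self, values, condition="MD-Easy"):
        return ed.SourceEstimate(values=values, fs=500.0, tmin=-0.4,
                                 condition=condition)

    def test_self_contrast_is_zero_and_antisymmetric(self):
        rng = np.random.default_rng(0)
        a = self._stc(rng.standard_normal((4, 10)))
        b = self._stc(rng.standard_normal((4, 10)), "AD-Easy")
        np.testing.assert_allclose(ed.contrast(a, a).values, 0.0)
        np.testing.assert_allclose(ed.contrast(a, b).values,
                                   -ed.contrast(b, a).values)

    def test_mismatched_shapes_rejected(self):
        a = self._stc(np.zeros((4, 10)))
        b = self._stc(np.zeros((5, 10)))
        with pytest.raises(ValueError):
            ed.contrast(a, b)

    def test_roi_timecourse_means(self):
        values = np.zeros((4, 5))
        values[0] = 1.0
        values[1] = 3.0
        stc = self._stc(values)
        tc = ed.roi_timecourse(stc, {"single": np.array([2]),
                                     "pair": np.array([0, 1])})
        np.testing.assert_allclose(tc["single"], 0.0)
        np.testing.assert_allclose(tc["pair"], 2.0)
        with pytest.raises(ValueError):
            ed.roi_timecourse(stc, {"empty": np.array([], dtype=int)})

    def test_window_mean_selector(self):
        tc = np.arange(1001, dtype=float)
        v = ed.window_mean(tc, fs=500.0, tmin=-0.4, window=(0.1, 0.8))
        mask = (np.arange(1001) / 500.0 - 0.4 >= 0.1 - 1e-9) \
            & (np.arange(1001) / 500.0 - 0.4 <= 0.8 + 1e-9)
        assert v == pytest.approx(tc[mask].mean())
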