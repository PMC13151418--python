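"""Preprocessing cascade: pruning, OD, motion handling, filtering, MBLL."""

from dataclasses import replace

import numpy as np
import pytest

from nirsblock.core import (
    BlockDesign,
    BlockEvent,
    ConfigurationError,
    HbSeries,
    ODSeries,
    ProbeLayout,
    RawIntensityScan,
)
from nirsblock.extinction import ExtinctionTable
from nirsblock.preprocess import (
    PreprocessParams,
    bandpass,
    detect_motion,
    intensity_to_od,
    od_to_conc,
    preprocess_scan,
    prune_channels,
    redetect_and_flag,
    spline_correct,
    wavelet_correct,
)
from nirsblock.synthcohort import SimulationConfig, simulate_participant

from conftest import NEAR_SILENT

FS = 10.0
WL = (695.0, 830.0)


def _scan(layout, data):
    design = BlockDesign(events=(), total_duration=data.shape[0] / FS)
    return RawIntensityScan(
        participant="p",
        data=data,
        sampling_rate=FS,
        wavelengths=WL,
        layout=layout,
        design=design,
    )


def _od(layout, data):
    return ODSeries(data, FS, WL, layout)


# ---------------------------------------------------------------------------
# pruning


class TestPruneChannels:
    def test_constant_intensity_retained(self, roi_layout):
        scan = _scan(roi_layout, np.ones((500, 6, 2)))
        assert prune_channels(scan, PreprocessParams()).all()

    def test_sinusoid_snr_thresholding(self, roi_layout):
        t = np.arange(5000) / FS
        data = np.ones((5000, 6, 2))
        data[:, 0, :] = (1.0 + 0.6 * np.sin(2 * np.pi * 0.2 * t))[:, None]  # SNR ~ 2.36
        data[:, 1, :] = (1.0 + 0.8 * np.sin(2 * np.pi * 0.2 * t))[:, None]  # SNR ~ 1.77
        keep = prune_channels(_scan(roi_layout, data), PreprocessParams())
        # independent check of the SNR values the rule should see
        snr0 = data[:, 0, 0].mean() / data[:, 0, 0].std()
        snr1 = data[:, 1, 0].mean() / data[:, 1, 0].std()
        assert snr0 > 2 > snr1
        assert keep[0] and not keep[1] and keep[2:].all()

    def test_boundary_snr_exactly_two_is_retained(self, roi_layout):
        data = np.ones((500, 6, 2))
        data[::2, 0, :] = 1.5
        data[1::2, 0, :] = 0.5  # mean 1, sd 0.5 -> SNR exactly 2
        keep = prune_channels(_scan(roi_layout, data), PreprocessParams())
        assert keep[0]

    def test_nonpositive_channel_pruned(self, roi_layout):
        data = np.ones((500, 6, 2))
        data[100, 3, 0] = 0.0
        keep = prune_channels(_scan(roi_layout, data), PreprocessParams())
        assert not keep[3] and keep[[0, 1, 2, 4, 5]].all()


# ---------------------------------------------------------------------------
# OD conversion


class TestIntensityToOd:
    def test_constant_intensity_zero_od(self, roi_layout):
        od = intensity_to_od(_scan(roi_layout, 2.0 * np.ones((500, 6, 2))))
        np.testing.assert_allclose(od.data, 0.0, atol=1e-12)

    def test_dip_to_base_over_e_gives_unit_od(self, roi_layout):
        data = np.ones((5000, 6, 2))
        data[42, 0, 0] = 1.0 / np.e
        od = intensity_to_od(_scan(roi_layout, data))
        assert od.data[42, 0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_sample_raises_with_location(self, roi_layout):
        data = np.ones((100, 6, 2))
        data[7, 2, 1] = -1.0
        with pytest.raises(ValueError, match="sample 7"):
            intensity_to_od(_scan(roi_layout, data))


# ---------------------------------------------------------------------------
# motion detection


class TestDetectMotion:
    def test_flat_series_empty_mask(self, roi_layout):
        mask = detect_motion(_od(roi_layout, np.zeros((1000, 6, 2))), PreprocessParams())
        assert not mask.any()

    def test_spike_flagged_with_margin(self, roi_layout):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 0.01, (2000, 6, 2))
        data[1000, 0, :] += 0.3
        mask = detect_motion(_od(roi_layout, data), PreprocessParams())
        assert mask[1000, 0]
        # t_mask = 1 s margin each side around the triggering windows
        assert mask[995:1005, 0].all()
        assert not mask[:, 1:].any()

    def test_spike_not_amplitude_flagged(self, roi_layout):
        # same spike with the variance criterion disabled: 0.3 < amp_thresh = 4
        rng = np.random.default_rng(1)
        data = rng.normal(0, 0.01, (2000, 6, 2))
        data[1000, 0, :] += 0.3
        params = PreprocessParams(stdev_thresh=1e12)
        mask = detect_motion(_od(roi_layout, data), params)
        assert not mask.any()

    def test_window_shorter_than_two_samples_rejected(self, roi_layout):
        with pytest.raises(ConfigurationError):
            detect_motion(
                _od(roi_layout, np.zeros((100, 6, 2))), PreprocessParams(t_motion=0.1)
            )

    def test_recall_of_large_spikes_on_physiological_background(self, roi_layout):
        """Spikes at 10x the channel OD sd are recalled >= 90% at defaults."""
        rng = np.random.default_rng(6)
        n_t = 12000
        t = np.arange(n_t) / FS
        data = np.zeros((n_t, 6, 2))
        for ci in range(6):
            background = 0.5 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
            data[:, ci, :] = (background + rng.normal(0, 0.01, n_t))[:, None]
        sd = data[:, 0, 0].std()
        spike_times = np.arange(500, n_t - 500, 1000)
        for st in spike_times:
            data[st : st + 3, :, :] += 10 * sd
        mask = detect_motion(_od(roi_layout, data), PreprocessParams())
        recalled = sum(mask[st : st + 3, 0].all() for st in spike_times)
        assert recalled / len(spike_times) >= 0.9


# ---------------------------------------------------------------------------
# spline correction


class TestSplineCorrect:
    def test_empty_mask_is_noop(self, roi_layout):
        rng = np.random.default_rng(0)
        od = _od(roi_layout, rng.normal(0, 0.01, (500, 6, 2)))
        out = spline_correct(od, np.zeros((500, 6), dtype=bool))
        np.testing.assert_array_equal(out.data, od.data)

    def test_baseline_shift_mostly_removed(self, roi_layout):
        rng = np.random.default_rng(3)
        n_t = 2000
        data = rng.normal(0, 0.005, (n_t, 6, 2))
        shift_at = 1000
        data[shift_at:, 0, :] += 0.5
        mask = np.zeros((n_t, 6), dtype=bool)
        mask[shift_at - 10 : shift_at + 10, 0] = True  # ground-truth flag
        out = spline_correct(_od(roi_layout, data), mask)
        before = np.median(out.data[:shift_at - 10, 0, 0])
        after = np.median(out.data[shift_at + 10 :, 0, 0])
        assert abs(after - before) < 0.2 * 0.5

    def test_clean_segments_unreshaped(self, roi_layout):
        """Samples away from flagged segments keep their waveform exactly
        (level re-anchoring may add a constant; first differences are
        invariant)."""
        rng = np.random.default_rng(4)
        n_t = 1000
        data = rng.normal(0, 0.01, (n_t, 6, 2))
        mask = np.zeros((n_t, 6), dtype=bool)
        mask[400:420, 0] = True
        out = spline_correct(_od(roi_layout, data), mask)
        margin = 10  # t_mask worth of samples
        for sl in (slice(0, 400 - margin), slice(420 + margin, n_t)):
            np.testing.assert_allclose(
                np.diff(out.data[sl, 0, 0]), np.diff(data[sl, 0, 0]), atol=1e-12
            )
        np.testing.assert_array_equal(out.data[:, 1:, :], data[:, 1:, :])


# ---------------------------------------------------------------------------
# wavelet correction


class TestWaveletCorrect:
    def test_slow_sinusoid_preserved(self, roi_layout):
        t = np.arange(4900) / FS
        sig = np.sin(2 * np.pi * 0.05 * t)
        data = np.tile(sig[:, None, None], (1, 6, 2))
        out = wavelet_correct(_od(roi_layout, data))
        rel_err = np.linalg.norm(out.data[:, 0, 0] - sig) / np.linalg.norm(sig)
        assert rel_err < 0.05

    def test_spike_energy_suppressed(self, roi_layout):
        rng = np.random.default_rng(5)
        t = np.arange(4900) / FS
        smooth = 0.1 * np.sin(2 * np.pi * 0.03 * t)
        data = np.tile(smooth[:, None, None], (1, 6, 2))
        spike_idx = np.arange(300, 4600, 500)
        for si in spike_idx:
            data[si : si + 3, :, :] += rng.uniform(0.3, 0.8)
        out = wavelet_correct(_od(roi_layout, data))
        spikes = np.zeros(4900, dtype=bool)
        for si in spike_idx:
            spikes[si : si + 3] = True
        before = np.sum((data[spikes, 0, 0] - smooth[spikes]) ** 2)
        after = np.sum((out.data[spikes, 0, 0] - smooth[spikes]) ** 2)
        assert after <= 0.2 * before

    def test_zero_series_stays_zero(self, roi_layout):
        out = wavelet_correct(_od(roi_layout, np.zeros((4900, 6, 2))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_short_series_passes_through(self, roi_layout):
        data = np.ones((3, 6, 2))
        out = wavelet_correct(_od(roi_layout, data))
        np.testing.assert_array_equal(out.data, data)


# ---------------------------------------------------------------------------
# residual re-detection and block flagging


class TestRedetectAndFlag:
    def _design(self):
        events = tuple(
            BlockEvent("HL" if i % 2 == 0 else "LH", 20.0 + i * 37.0, 15.0)
            for i in range(14)
        )
        return BlockDesign(events=events, total_duration=events[-1].onset + 15.0)

    def _clean_od(self, roi_layout, design):
        n_t = int((design.total_duration + 32.0) * FS)
        rng = np.random.default_rng(0)
        return _od(roi_layout, rng.normal(0, 0.001, (n_t, 6, 2)))

    def test_no_artifacts_all_blocks_valid(self, roi_layout):
        design = self._design()
        od = self._clean_od(roi_layout, design)
        valid = redetect_and_flag(od, PreprocessParams(), design)
        assert valid.all() and valid.shape == (14, 6)

    def test_artifact_at_block5_onset_invalidates_only_block5(self, roi_layout):
        design = self._design()
        od = self._clean_od(roi_layout, design)
        onset5 = design.events[4].onset
        od.data[int(onset5 * FS) : int(onset5 * FS) + 3, 2, :] += 1.0
        valid = redetect_and_flag(od, PreprocessParams(), design)
        assert not valid[4, 2]
        valid[4, 2] = True
        assert valid.all()

    def test_artifact_outside_all_windows_invalidates_nothing(self, roi_layout):
        # the only samples not in any epoch window are > 3 s before block 1
        design = self._design()
        od = self._clean_od(roi_layout, design)
        od.data[80:83, 1, :] += 1.0  # t = 8 s; window of block 1 starts at 17 s
        valid = redetect_and_flag(od, PreprocessParams(), design)
        assert valid.all()


# ---------------------------------------------------------------------------
# band-pass filter


class TestBandpass:
    def _gain(self, freq, roi_layout, n_t=20000):
        t = np.arange(n_t) / FS
        sig = np.sin(2 * np.pi * freq * t)
        od = _od(roi_layout, np.tile(sig[:, None, None], (1, 6, 2)))
        out = bandpass(od)
        trim = slice(n_t // 4, 3 * n_t // 4)
        return np.abs(out.data[trim, 0, 0]).max()

    def test_zero_in_zero_out(self, roi_layout):
        out = bandpass(_od(roi_layout, np.zeros((2000, 6, 2))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_passband_and_stopband_gains(self, roi_layout):
        assert self._gain(0.03, roi_layout) >= 0.9
        assert self._gain(0.5, roi_layout) <= 0.1

    def test_monotone_low_frequency_stopband(self, roi_layout):
        g_slow = self._gain(0.001, roi_layout, n_t=60000)
        g_less_slow = self._gain(0.005, roi_layout, n_t=60000)
        assert g_slow < g_less_slow

    def test_band_above_nyquist_rejected(self, roi_layout):
        with pytest.raises(ConfigurationError):
            bandpass(_od(roi_layout, np.zeros((100, 6, 2))), band_high=6.0)


# ---------------------------------------------------------------------------
# concentration conversion


class TestOdToConc:
    def test_zero_od_zero_conc(self, roi_layout):
        ext = ExtinctionTable()
        hb = od_to_conc(_od(roi_layout, np.zeros((100, 6, 2))), ext)
        np.testing.assert_allclose(hb.data, 0.0)

    def test_two_by_two_solve(self):
        ext = ExtinctionTable(eps_oxy=(1.0, 3.0), eps_deoxy=(2.0, 1.0))
        layout = replace(ProbeLayout.standard(roi_only=True), source_detector_distance=1.0)
        od = ODSeries(np.tile([5.0, 5.0], (4, 6, 1)), FS, WL, layout)
        hb = od_to_conc(od, ext, layout, ppf=1.0)
        np.testing.assert_allclose(hb.data[..., 0], 1.0)  # oxy
        np.testing.assert_allclose(hb.data[..., 1], 2.0)  # deoxy

    def test_missing_wavelength_marks_channel_unavailable(self, roi_layout):
        data = np.random.default_rng(0).normal(size=(50, 6, 2))
        data[:, 4, 1] = np.nan
        hb = od_to_conc(_od(roi_layout, data), ExtinctionTable())
        assert not hb.available[4] and np.isnan(hb.data[:, 4, :]).all()
        assert hb.available[[0, 1, 2, 3, 5]].all()


# ---------------------------------------------------------------------------
# full cascade


class TestCascade:
    def test_shapes_preserved_and_order_logged(self, roi_layout):
        cfg = SimulationConfig(n_participants=1, layout=roi_layout, seed=2)
        scan, _ = simulate_participant(cfg, 0)
        hb, validity, log = preprocess_scan(scan, PreprocessParams())
        assert hb.data.shape == (scan.n_times, 6, 2)
        assert validity.shape == (scan.design.n_blocks, 6)
        assert log["order"][0] == "prune_channels" and log["order"][-1] == "od_to_conc"

    def test_noiseless_output_tracks_bandpassed_truth(self, roi_layout):
        """On artifact-free, physiology-free input the cascade output
        correlates > 0.95 with the band-passed ground-truth series."""
        cfg = SimulationConfig(
            n_participants=1, layout=roi_layout, noise=NEAR_SILENT, seed=8
        )
        scan, truth = simulate_participant(cfg, 0)
        hb, _, _ = preprocess_scan(scan, PreprocessParams())
        true_od = ODSeries(truth.hb_true.data.copy(), FS, WL, roi_layout)
        true_f = bandpass(true_od).data
        for ci in range(6):
            for hi in range(2):
                r = np.corrcoef(hb.data[:, ci, hi], true_f[:, ci, hi])[0, 1]
                assert r > 0.95

    def test_availability_only_shrinks(self, roi_layout):
        cfg = SimulationConfig(n_participants=1, layout=roi_layout, seed=3)
        scan, _ = simulate_participant(cfg, 0)
        scan.data[:, 2, :] *= np.random.default_rng(0).lognormal(0, 1.2, scan.n_times)[:, None]
        hb, validity, log = preprocess_scan(scan, PreprocessParams())
        assert not hb.available[2]
        assert 2 in [roi_layout.index_of(c) for c in log["pruned_channels"]]
        assert not validity[:, 2].any()
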