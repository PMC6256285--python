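"""Mini detection/kinetics and rectification against generator ground truth."""

import numpy as np
import pytest

import synaptoquant as sq
from synaptoquant import ephys
from synaptoquant.synthetic import _epsc_kernel
from conftest import match_onsets


def single_event_trace(amp=20.0, rise=0.5, decay=5.0, onset=0.5, fs=20000.0,
                       dur=2.0, noise=0.0, seed=0):
    n = int(dur * fs)
    samples = np.zeros(n)
    i0 = int(onset * fs)
    kern = _epsc_kernel(np.arange(n - i0) / fs, rise, decay)
    samples[i0:] -= amp * kern
    if noise > 0:
        samples = samples + np.random.default_rng(seed).normal(0, noise, n)
    return ephys.Trace(samples=samples, fs=fs)


class TestDetectMinis:
    def test_flat_trace_yields_no_events(self):
        tr = ephys.Trace(samples=np.zeros(40000), fs=20000.0)
        assert ephys.detect_minis(tr) == []

    def test_single_large_event_detected(self):
        tr = single_event_trace(amp=20.0, noise=2.0, seed=1)
        onsets = ephys.detect_minis(tr, threshold_sd=3.5)
        assert len(onsets) == 1
        assert onsets[0] == pytest.approx(0.5, abs=2e-3)

    def test_dc_offset_does_not_change_detections(self):
        tr = single_event_trace(amp=20.0, noise=2.0, seed=2)
        shifted = ephys.Trace(samples=tr.samples - 137.0, fs=tr.fs)
        assert ephys.detect_minis(tr) == ephys.detect_minis(shifted)

    def test_recall_and_fdr_on_synthetic_train(self):
        tr, gt = sq.gen_mepsc_trace(
            duration_s=60, rate_hz=1.0, amp_median_pa=20.0, amp_sigma=0.15,
            noise_sd_pa=3.0, seed=5,
        )
        det = ephys.detect_minis(tr)
        tp = match_onsets(det, gt.onset_times_s)
        assert tp / len(gt) >= 0.9
        assert (len(det) - tp) / max(1, len(det)) <= 0.1

    def test_low_sampling_rate_rejected(self):
        tr = ephys.Trace(samples=np.zeros(2000), fs=1500.0)
        with pytest.raises(ValueError, match="twice"):
            ephys.detect_minis(tr, lp_cutoff_hz=1000.0)


class TestEventKinetics:
    def test_noiseless_round_trip_recovers_waveform_parameters(self):
        tr = single_event_trace(amp=20.0, rise=0.5, decay=5.0)
        ev = ephys.event_kinetics(tr, 0.5)
        assert ev.peak_amplitude_pa == pytest.approx(20.0, abs=0.5)
        assert ev.decay_tau_ms == pytest.approx(5.0, rel=0.02)
        assert ev.rise_time_10_90_ms < 2.0
        assert ev.charge_pa_ms > 0

    def test_rectangular_pulse_charge_is_area(self):
        fs = 20000.0
        samples = np.zeros(int(1.5 * fs))
        i0 = int(1.0 * fs)
        samples[i0 : i0 + int(0.010 * fs)] = -10.0
        ev = ephys.event_kinetics(ephys.Trace(samples=samples, fs=fs), 1.0)
        assert ev.peak_amplitude_pa == pytest.approx(10.0, abs=1e-9)
        assert ev.charge_pa_ms == pytest.approx(100.0, rel=0.01)

    def test_trace_scaling_scales_amplitude_and_charge_only(self):
        tr = single_event_trace(amp=15.0)
        tr2 = ephys.Trace(samples=tr.samples * 2, fs=tr.fs)
        e1 = ephys.event_kinetics(tr, 0.5)
        e2 = ephys.event_kinetics(tr2, 0.5)
        assert e2.peak_amplitude_pa == pytest.approx(2 * e1.peak_amplitude_pa)
        assert e2.charge_pa_ms == pytest.approx(2 * e1.charge_pa_ms, rel=1e-6)
        assert e2.decay_tau_ms == pytest.approx(e1.decay_tau_ms, rel=1e-3)
        assert e2.rise_time_10_90_ms == pytest.approx(e1.rise_time_10_90_ms, rel=1e-6)

    def test_kinetics_invariant_to_dc_offset(self):
        tr = single_event_trace(amp=25.0)
        off = ephys.Trace(samples=tr.samples + 41.0, fs=tr.fs)
        e1 = ephys.event_kinetics(tr, 0.5)
        e2 = ephys.event_kinetics(off, 0.5)
        assert e2.peak_amplitude_pa == pytest.approx(e1.peak_amplitude_pa, rel=1e-9)
        assert e2.charge_pa_ms == pytest.approx(e1.charge_pa_ms, rel=1e-9)


class TestEnsembleAverage:
    def test_identical_events_average_to_one_event(self):
        fs = 20000.0
        samples = np.zeros(int(3 * fs))
        kern = 20.0 * _epsc_kernel(np.arange(int(0.05 * fs)) / fs, 0.5, 5.0)
        onsets = [0.5, 1.2, 2.0]
        for on in onsets:
            i = int(on * fs)
            samples[i : i + kern.size] -= kern
        tr = ephys.Trace(samples=samples, fs=fs)
        avg = ephys.ensemble_average(tr, onsets, pre_ms=5, post_ms=40)
        single = np.zeros(avg.size)
        single[int(0.005 * fs):] -= kern[: avg.size - int(0.005 * fs)]
        assert np.allclose(avg, single, atol=1e-9)

    def test_noise_averages_toward_clean_template(self, rng):
        fs = 20000.0
        n_ev = 400
        spacing = 0.1
        n = int((n_ev + 1) * spacing * fs)
        samples = np.zeros(n)
        kern = 20.0 * _epsc_kernel(np.arange(int(0.05 * fs)) / fs, 0.5, 5.0)
        onsets = [spacing * (k + 0.5) for k in range(n_ev)]
        for on in onsets:
            i = int(on * fs)
            samples[i : i + kern.size] -= kern[: n - i]
        sd = 3.0
        noisy = ephys.Trace(samples=samples + rng.normal(0, sd, n), fs=fs)
        avg = ephys.ensemble_average(noisy, onsets, pre_ms=2, post_ms=30)
        clean = ephys.ensemble_average(ephys.Trace(samples=samples, fs=fs), onsets,
                                       pre_ms=2, post_ms=30)
        resid = avg - clean
        assert np.sqrt(np.mean(resid**2)) <= 3 * sd / np.sqrt(n_ev)

    def test_mixed_amplitudes_average_linearly(self):
        fs = 20000.0
        samples = np.zeros(int(3 * fs))
        kern = _epsc_kernel(np.arange(int(0.05 * fs)) / fs, 0.5, 5.0)
        onsets = [0.5, 1.5]
        for on, amp in zip(onsets, (10.0, 30.0)):
            i = int(on * fs)
            samples[i : i + kern.size] -= amp * kern
        avg = ephys.ensemble_average(ephys.Trace(samples=samples, fs=fs), onsets)
        assert -avg.min() == pytest.approx(20.0, rel=0.01)


class TestJunctionPotential:
    def test_default_correction_shifts_by_18mv(self):
        assert ephys.correct_junction_potential(0.0) == -18.0

    def test_zero_ljp_is_identity(self):
        assert ephys.correct_junction_potential(-60.0, ljp_mv=0.0) == -60.0

    def test_vector_input_maps_elementwise(self):
        v = np.array([-60.0, 0.0, 60.0])
        assert np.array_equal(
            ephys.correct_junction_potential(v), v - 18.0
        )


class TestRectification:
    def test_linear_iv_gives_unit_ri(self):
        sweeps, _ = sq.gen_iv_sweeps(sq.RectificationModel(block_depth=0.0),
                                     noise_sd_pa=0.0)
        iv = ephys.rectification_analysis(sweeps)
        assert iv.ri == pytest.approx(1.0, abs=1e-3)

    def test_rectifying_model_matches_closed_form_ratio(self):
        model = sq.RectificationModel(block_depth=0.8)
        sweeps, true_ri = sq.gen_iv_sweeps(model, noise_sd_pa=0.0)
        iv = ephys.rectification_analysis(sweeps)
        assert iv.ri == pytest.approx(true_ri, rel=0.01)

    def test_current_scaling_leaves_ri_unchanged(self):
        sweeps, _ = sq.gen_iv_sweeps(sq.RectificationModel(), noise_sd_pa=0.0)
        scaled = {
            v: ephys.Trace(samples=t.samples * 2, fs=t.fs, stim_time_s=t.stim_time_s)
            for v, t in sweeps.items()
        }
        ri1 = ephys.rectification_analysis(sweeps).ri
        ri2 = ephys.rectification_analysis(scaled).ri
        assert ri2 == pytest.approx(ri1, rel=1e-9)

    def test_normalized_currents_reference_most_negative_potential(self):
        sweeps, _ = sq.gen_iv_sweeps(sq.RectificationModel(), noise_sd_pa=0.0)
        iv = ephys.rectification_analysis(sweeps)
        i_min = int(np.argmin(iv.potentials_mv))
        assert abs(iv.normalized_currents[i_min]) == pytest.approx(1.0)

    def test_median_ri_consistent_under_noise(self):
        model = sq.RectificationModel()
        v = np.arange(-60.0, 61.0, 20.0)
        noise = 0.05 * np.abs(model.peak_current_pa(v)).max()
        _, true_ri = sq.gen_iv_sweeps(model, noise_sd_pa=0.0)
        ris = [
            ephys.rectification_analysis(
                sq.gen_iv_sweeps(model, noise_sd_pa=noise, seed=s)[0]
            ).ri
            for s in range(200)
        ]
        assert np.median(ris) == pytest.approx(true_ri, rel=0.05)


class TestSeriesResistanceQC:
    @pytest.mark.parametrize(
        "rs,expected",
        [([10.0, 11.0], True), ([10.0, 12.5], False), ([10.0, 10.0, 10.0], True)],
    )
    def test_twenty_percent_rule(self, rs, expected):
        assert ephys.qc_series_resistance(rs) is expected

    def test_nonpositive_rs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ephys.qc_series_resistance([10.0, -1.0])
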