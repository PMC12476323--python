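"""Template-subtraction denoiser: upcrossing period estimation, median
template extraction and periodic subtraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vibrotissue as vt
from vibrotissue.denoise import fold_multiples


def spike_train(positions, length, amplitude=1.0):
    x = np.zeros(length)
    x[np.asarray(positions)] = amplitude
    return x


class TestDebiasNormalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([1.0, 3.0, 5.0], [-1.0, 0.0, 1.0]),  # mean 3, max-abs 2
            ([0.0, 2.0], [-1.0, 1.0]),  # mean 1, max-abs 1
            ([4.0, 4.0, 4.0], [0.0, 0.0, 0.0]),  # constant maps to zeros
        ],
    )
    def test_hand_computed_examples(self, raw, expected):
        out = vt.debias_normalize(vt.AudioRecording(np.array(raw)))
        np.testing.assert_allclose(out.samples, expected, atol=1e-12)

    def test_postconditions_on_random_signal(self, rng):
        out = vt.debias_normalize(vt.AudioRecording(rng.normal(2.0, 3.0, 5000)))
        assert abs(out.samples.mean()) < 1e-9
        assert np.max(np.abs(out.samples)) <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vt.debias_normalize(vt.AudioRecording(np.array([])))


class TestUpcrossings:
    @pytest.mark.parametrize(
        "samples,theta,expected",
        [
            ([0, 1, 0, 1, 0], 0.5, [1, 3]),
            ([0, 0, 0, 0], 0.7, []),
            ([0.8, 0.9], 0.7, []),  # index 0 has no predecessor
        ],
    )
    def test_examples(self, samples, theta, expected):
        got = vt.upcrossing_indices(np.array(samples, dtype=float), theta)
        assert list(got) == expected

    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=200),
           st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_matches_direct_scan_oracle(self, samples, theta):
        x = np.array(samples)
        oracle = [t for t in range(1, len(x)) if x[t - 1] <= theta < x[t]]
        assert list(vt.upcrossing_indices(x, theta)) == oracle


class TestEstimatePeriod:
    def test_regular_spikes_every_threshold(self):
        # distances all 300 by enumeration
        x = spike_train([100, 400, 700, 1000, 1300], 1500)
        est = vt.estimate_period(vt.AudioRecording(x))
        assert est.dominant_period == 300
        assert set(est.modal_distance_per_threshold.values()) == {300}

    def test_missing_spike_folds_multiples(self):
        # distance multiset {300, 300, 600, 300, 600}: mode 300 survives
        x = spike_train([0, 300, 600, 1200, 1500, 2100], 2200)
        est = vt.estimate_period(vt.AudioRecording(x))
        assert est.dominant_period == 300

    def test_multiplicity_folding_votes(self):
        # high thresholds see every other spike: modal 4096 folds onto 2048
        assert fold_multiples({2048: 10, 4096: 21}) == 2048
        assert fold_multiples({2048: 10, 4097: 5, 6143: 2}) == 2048  # within +-1 sample
        assert fold_multiples({500: 3, 700: 3}) == 500  # tie -> smallest

    def test_no_upcrossings_raises(self):
        with pytest.raises(vt.PeriodEstimationError):
            vt.estimate_period(vt.AudioRecording(np.zeros(5000)))

    def test_default_grid_is_31_interior_thresholds(self):
        grid = vt.default_theta_grid()
        assert grid.size == 31
        assert grid.min() > 0.6 and grid.max() < 0.9

    @pytest.mark.parametrize("period", [512, 1024, 2048, 4096])
    def test_recovers_injected_period_on_generator_output(self, period):
        rec = vt.generate_recording(vt.default_profiles()[2], 2.0, seed=period)
        noisy = vt.inject_interference(rec, vt.InterferenceSpec(period=period, phase_offset=17))
        est = vt.estimate_period(vt.debias_normalize(noisy))
        assert est.dominant_period == period


class TestExtractTemplate:
    def test_periodic_input_recovered_exactly(self, rng):
        chunk = rng.normal(size=250)
        x = np.tile(chunk, 5)
        tpl = vt.extract_template(vt.AudioRecording(x), 250)
        np.testing.assert_array_equal(tpl.values, chunk)
        assert tpl.chunk_count == 5

    def test_outlier_burst_in_one_chunk_ignored(self, rng):
        # median of {p,p,p,p,p+o} is p at every phase
        chunk = rng.normal(size=100)
        x = np.tile(chunk, 5)
        x[230:260] += 40.0
        tpl = vt.extract_template(vt.AudioRecording(x), 100)
        np.testing.assert_array_equal(tpl.values, chunk)

    def test_median_immune_below_half_of_chunks(self, rng):
        # corrupting 3 of 7 chunks (< ceil(7/2) = 4) leaves the template unchanged
        chunk = rng.normal(size=80)
        x = np.tile(chunk, 7)
        for c in (1, 4, 6):
            x[c * 80 : (c + 1) * 80] += rng.normal(10, 5, 80)
        tpl = vt.extract_template(vt.AudioRecording(x), 80)
        np.testing.assert_array_equal(tpl.values, chunk)

    def test_zero_input_zero_template(self):
        tpl = vt.extract_template(vt.AudioRecording(np.zeros(600)), 200)
        assert not tpl.values.any()

    def test_trailing_partial_chunk_excluded(self, rng):
        chunk = rng.normal(size=100)
        x = np.concatenate([np.tile(chunk, 4), np.full(50, 99.0)])
        tpl = vt.extract_template(vt.AudioRecording(x), 100)
        assert tpl.chunk_count == 4
        np.testing.assert_array_equal(tpl.values, chunk)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            vt.extract_template(vt.AudioRecording(np.zeros(150)), 100)


class TestSubtractTemplate:
    def test_periodic_signal_cancels_exactly(self, rng):
        chunk = rng.normal(size=300)
        x = np.tile(chunk, 4)
        tpl = vt.extract_template(vt.AudioRecording(x), 300)
        out = vt.subtract_template(vt.AudioRecording(x), tpl)
        assert np.max(np.abs(out.samples)) < 1e-12

    def test_trailing_partial_period_subtracted_with_prefix(self, rng):
        chunk = rng.normal(size=300)
        x = np.tile(chunk, 4)[:1050]  # 3.5 periods
        tpl = vt.PulseTemplate(values=chunk, period=300, chunk_count=3)
        out = vt.subtract_template(vt.AudioRecording(x), tpl)
        assert np.max(np.abs(out.samples)) < 1e-12

    def test_zero_template_is_identity(self, rng):
        x = rng.normal(size=1000)
        tpl = vt.PulseTemplate(values=np.zeros(128), period=128, chunk_count=3)
        out = vt.subtract_template(vt.AudioRecording(x), tpl)
        np.testing.assert_array_equal(out.samples, x)

    def test_residual_rms_close_to_clean_rms(self):
        # oracle: the generator's clean signal, scaled like the denoiser scales
        clean = vt.generate_recording(vt.default_profiles()[1], 2.0, seed=77)
        spec = vt.InterferenceSpec(period=2048, phase_offset=512)
        noisy = vt.inject_interference(clean, spec)
        normed = vt.debias_normalize(noisy)
        tpl = vt.extract_template(normed, 2048)
        out = vt.subtract_template(normed, tpl)
        scale = np.max(np.abs(noisy.samples - noisy.samples.mean()))
        clean_rms = np.sqrt(np.mean((clean.samples / scale) ** 2))
        out_rms = np.sqrt(np.mean(out.samples**2))
        assert abs(out_rms - clean_rms) / clean_rms < 0.10


class TestDenoise:
    @pytest.mark.parametrize("seed,period", [(1, 400), (2, 777), (3, 2048)])
    def test_strictly_periodic_input_cancels_to_zero(self, seed, period):
        # one dominant positive peak per period -> upcrossings recover the period
        rng = np.random.default_rng(seed)
        chunk = 0.2 * rng.normal(size=period)
        chunk[rng.integers(period)] = 5.0
        x = np.tile(chunk, 4)[: int(3.6 * period)]
        out = vt.denoise(vt.AudioRecording(x))
        assert np.max(np.abs(out.samples)) < 1e-12

    def test_spike_energy_reduced_by_90_percent(self):
        clean = vt.generate_recording(vt.default_profiles()[0], 3.0, seed=55)
        spec = vt.InterferenceSpec(period=2048, phase_offset=300)
        noisy = vt.inject_interference(clean, spec)
        out = vt.denoise(noisy)
        corrupted = vt.debias_normalize(noisy)

        def spike_energy(x):
            return sum(
                float(np.sum(x[max(o - 32, 0) : o + 32] ** 2))
                for o in spec.onsets(len(x))
            )

        assert spike_energy(out.samples) <= 0.10 * spike_energy(corrupted.samples)

    def test_interference_free_recording_nearly_unchanged(self):
        clean = vt.generate_recording(vt.default_profiles()[4], 2.0, seed=99)
        normed = vt.debias_normalize(clean)
        out = vt.denoise(clean)
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert abs(rms(out.samples) - rms(normed.samples)) / rms(normed.samples) < 0.01

    def test_approximately_idempotent(self):
        # the chain renormalizes (peak -> 1), so idempotence is judged at the
        # second pass's own scale: its subtraction must change RMS by < 1%
        clean = vt.generate_recording(vt.default_profiles()[1], 2.0, seed=13)
        noisy = vt.inject_interference(clean, vt.InterferenceSpec(phase_offset=1000))
        once = vt.denoise(noisy)
        twice = vt.denoise(once)
        reference = vt.debias_normalize(once)
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert abs(rms(twice.samples) - rms(reference.samples)) / rms(reference.samples) < 0.01

    def test_no_residual_spikes_above_theta(self):
        # spike train + low-level texture: spikes absent above 0.6 after denoising
        clean = vt.generate_recording(vt.default_profiles()[3], 3.0, seed=21)
        noisy = vt.inject_interference(clean, vt.InterferenceSpec(phase_offset=777))
        out = vt.denoise(noisy)
        assert vt.upcrossing_indices(out.samples, 0.6).size == 0

    def test_explicit_period_bypasses_estimation(self):
        clean = vt.generate_recording(vt.default_profiles()[2], 2.0, seed=8)
        noisy = vt.inject_interference(clean, vt.InterferenceSpec(period=1024))
        out = vt.denoise(noisy, period=1024)
        corrupted = vt.debias_normalize(noisy)
        assert np.max(np.abs(out.samples[:64])) < np.max(np.abs(corrupted.samples[:64]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vt.denoise(vt.AudioRecording(np.array([])))
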