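"""Wavelet transform and ITPC/STP/ERSP measure tests."""

import numpy as np
import pytest

import chirpsa as c
from chirpsa.timefreq import LOG_POWER_EPS

FS = 1000.0
WINDOW = (-500.0, 2750.0)


def sinusoid_epochs(freq, n_trials=1, amplitude=1.0, phase=0.0):
    t = (np.arange(3250) - 500) / FS
    return np.tile(amplitude * np.cos(2 * np.pi * freq * t + phase), (n_trials, 1))


class TestWaveletPlan:
    @pytest.mark.parametrize("freq,cycles", [(2, 1.0), (120, 30.0), (61, 15.5)])
    def test_linear_cycle_map(self, freq, cycles, full_plan):
        assert full_plan.cycles[full_plan.freqs == freq] == pytest.approx(cycles)

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            c.build_wavelet_plan(step=0)
        with pytest.raises(ValueError):
            c.build_wavelet_plan(f_min=50, f_max=10)

    def test_band_plan_matches_full_plan_cycles(self, full_plan):
        band = c.build_band_plan(30, 57, 1)
        sel = (full_plan.freqs >= 30) & (full_plan.freqs <= 57)
        np.testing.assert_allclose(band.cycles, full_plan.cycles[sel])


class TestWaveletTransform:
    def test_frequency_selectivity_and_unit_gain(self, full_plan):
        cube = c.wavelet_transform(sinusoid_epochs(40.0), full_plan)
        col = np.argmin(np.abs(cube.times - 1000))
        power = cube.power()[0, :, col]
        assert full_plan.freqs[np.argmax(power)] == 40.0
        # unit-amplitude sinusoid yields |coef| = 1 at its own frequency
        assert np.abs(cube.coef[0, full_plan.freqs == 40, col]) == pytest.approx(1.0, abs=1e-3)

    def test_gain_is_frequency_independent(self, full_plan):
        for freq in (10.0, 40.0, 90.0):
            cube = c.wavelet_transform(sinusoid_epochs(freq), full_plan)
            col = np.argmin(np.abs(cube.times - 1000))
            gain = np.abs(cube.coef[0, full_plan.freqs == freq, col])
            assert gain == pytest.approx(1.0, abs=1e-2)

    def test_linearity(self, gamma1_plan):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((2, 3250))
        b = rng.standard_normal((2, 3250))
        ca = c.wavelet_transform(a, gamma1_plan).coef
        cb = c.wavelet_transform(b, gamma1_plan).coef
        cab = c.wavelet_transform(a + b, gamma1_plan).coef
        np.testing.assert_allclose(cab, ca + cb, atol=1e-8)

    def test_edge_samples_are_flagged(self, full_plan):
        cube = c.wavelet_transform(sinusoid_epochs(40.0), full_plan)
        low = np.argmin(full_plan.freqs)  # 2 Hz, widest support
        assert not cube.valid[low, 0]
        assert cube.valid[low, np.argmin(np.abs(cube.times - 1000))]
        # validity widens with frequency
        assert cube.valid.sum(axis=1)[low] < cube.valid.sum(axis=1)[-1]

    def test_sample_count_mismatch_rejected(self, gamma1_plan):
        with pytest.raises(ValueError):
            c.wavelet_transform(np.zeros((1, 1000)), gamma1_plan,
                                epoch_window=WINDOW)


class TestITPC:
    def test_identical_trials_have_unit_itpc(self, gamma1_plan):
        cube = c.wavelet_transform(sinusoid_epochs(40.0, n_trials=50), gamma1_plan)
        itpc = c.compute_itpc(cube)
        assert itpc[cube.valid].min() == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_scaling_invariance(self, gamma1_plan):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((20, 3250))
        scales = rng.uniform(0.1, 10.0, size=(20, 1))
        base = c.compute_itpc(c.wavelet_transform(data, gamma1_plan))
        scaled = c.compute_itpc(c.wavelet_transform(data * scales, gamma1_plan))
        np.testing.assert_allclose(scaled, base, atol=1e-10)

    def test_matches_brute_force_resultant(self, gamma1_plan):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((15, 3250))
        cube = c.wavelet_transform(data, gamma1_plan)
        itpc = c.compute_itpc(cube)
        for _ in range(20):
            fi = rng.integers(0, cube.freqs.size)
            ti = rng.integers(0, cube.times.size)
            phases = np.angle(cube.coef[:, fi, ti])
            oracle = np.abs(np.mean(np.exp(1j * phases)))
            assert itpc[fi, ti] == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_mne_reference(self):
        """Cross-check phases/ITPC against an independent Morlet implementation."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(3)
        data = rng.standard_normal((8, 3250))
        plan = c.build_band_plan(30, 40, 5)
        cube = c.wavelet_transform(data, plan, time_step_ms=1.0)
        ours = c.compute_itpc(cube)
        out = mne.time_frequency.tfr_array_morlet(
            data[:, None, :], sfreq=1000.0, freqs=plan.freqs,
            n_cycles=plan.cycles, output="complex", zero_mean=False)
        theirs_unit = out[:, 0] / np.abs(out[:, 0])
        theirs = np.abs(theirs_unit.mean(axis=0))
        sel = cube.valid
        diff = np.abs(ours[sel] - theirs[sel])
        # small phase deviations at near-zero-amplitude cells dominate the
        # tail; the implementations agree closely in the bulk
        assert diff.mean() < 0.01
        assert np.quantile(diff, 0.99) < 0.05


class TestRCritical:
    def test_closed_form_and_limits(self):
        assert c.compute_r_critical(1) == pytest.approx(np.sqrt(np.log(2)), abs=1e-12)
        ns = [1, 10, 100, 1000, 100000]
        vals = [c.compute_r_critical(n) for n in ns]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.01
        with pytest.raises(ValueError):
            c.compute_r_critical(0)

    def test_unrooted_variant(self):
        assert c.compute_r_critical(60, sqrt=False) == pytest.approx(np.log(2) / 60)

    def test_is_median_of_null_resultant(self):
        # uniform phases: raw ITPC exceeds r_critical about half the time
        rng = np.random.default_rng(4)
        n = 60
        r = np.abs(np.mean(np.exp(1j * rng.uniform(0, 2 * np.pi, (2000, n))), axis=1))
        frac = np.mean(r > c.compute_r_critical(n))
        assert frac == pytest.approx(0.5, abs=0.05)


class TestCorrectITPC:
    def test_elementwise_subtraction_examples(self):
        n = 60
        rc = c.compute_r_critical(n)
        assert c.correct_itpc(np.array([rc]), n)[0] == pytest.approx(0.0)
        assert c.correct_itpc(np.array([0.0]), n)[0] == pytest.approx(-np.sqrt(-np.log(0.5) / 60))
        assert c.correct_itpc(np.array([1.0]), 10 ** 9)[0] == pytest.approx(1.0, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            c.correct_itpc(np.array([1.5]), 10)


class TestSTP:
    def test_doubling_amplitude_adds_six_db(self, gamma1_plan):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((10, 3250))
        stp1 = c.compute_stp(c.wavelet_transform(data, gamma1_plan))
        stp2 = c.compute_stp(c.wavelet_transform(2 * data, gamma1_plan))
        np.testing.assert_allclose(stp2 - stp1, 10 * np.log10(4), atol=1e-8)

    def test_deterministic_and_floored_on_silence(self, gamma1_plan):
        data = sinusoid_epochs(40.0, n_trials=3)
        a = c.compute_stp(c.wavelet_transform(data, gamma1_plan))
        b = c.compute_stp(c.wavelet_transform(data, gamma1_plan))
        assert np.array_equal(a, b)
        silent = c.compute_stp(c.wavelet_transform(np.zeros((2, 3250)), gamma1_plan))
        assert np.all(silent == 10 * np.log10(LOG_POWER_EPS))


class TestERSP:
    def test_baseline_window_mean_is_exactly_zero(self, gamma1_plan):
        rng = np.random.default_rng(6)
        cube = c.wavelet_transform(rng.standard_normal((30, 3250)), gamma1_plan)
        ersp = c.compute_ersp(cube)
        base = (cube.times >= -500) & (cube.times < 0)
        for fi in range(cube.freqs.size):
            ok = base & cube.valid[fi]
            assert abs(ersp[fi, ok].mean()) < 1e-10

    def test_stationary_noise_ersp_near_zero(self, gamma1_plan):
        rng = np.random.default_rng(7)
        cube = c.wavelet_transform(rng.standard_normal((200, 3250)), gamma1_plan)
        ersp = c.compute_ersp(cube)
        assert abs(ersp[cube.valid].mean()) < 0.5

    def test_post_stimulus_amplitude_doubling(self, gamma1_plan):
        t = (np.arange(3250) - 500) / FS
        x = np.cos(2 * np.pi * 40 * t) * np.where(t >= 0, 2.0, 1.0)
        cube = c.wavelet_transform(np.tile(x, (3, 1)), gamma1_plan)
        # keep the baseline clear of wavelet smearing around the step at 0
        ersp = c.compute_ersp(cube, baseline_window=(-450.0, -150.0))
        col = np.argmin(np.abs(cube.times - 1000))
        assert ersp[cube.freqs == 39, col][0] == pytest.approx(10 * np.log10(4), abs=0.3)

    def test_fully_invalid_baseline_names_frequency(self):
        plan = c.build_wavelet_plan(2, 10, 2, 1, 3, FS)
        data = np.zeros((2, 700))
        cube = c.wavelet_transform(data, plan, epoch_window=(-100.0, 600.0))
        with pytest.raises(ValueError, match="2 Hz"):
            c.compute_ersp(cube, baseline_window=(-100.0, 0.0))
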