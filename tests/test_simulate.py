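"""Trace simulator: recipe sampling, rendering, noise, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octflux.errors import DegenerateTraceError, InfeasibleRecipeError
from octflux.simulate import (
    DEFAULT_T,
    HierarchicalDistConfig,
    TimeTrace,
    TraceRecipe,
    add_slow_component,
    add_speckle_noise,
    generate_dataset,
    normalize_trace,
    render_clean_trace,
    sample_interpeak_gaps,
    sample_trace_recipe,
)

FWHM_FACTOR = 2 * np.sqrt(2 * np.log(2))


class TestRecipeSampling:
    def test_zero_flux_gives_zero_peaks(self, rng):
        r = sample_trace_recipe(0.0, rng=rng)
        assert r.n_peaks == 0
        assert r.flux_label == 0.0

    def test_peak_count_and_label_follow_rounding(self, rng):
        # 50 RBC/s * 0.768 s = 38.4 -> 38 peaks, label 38/0.768
        r = sample_trace_recipe(50.0, rng=rng)
        assert r.n_peaks == 38
        assert r.flux_label == pytest.approx(38 / DEFAULT_T)
        assert r.flux_label == pytest.approx(49.479, abs=0.01)

    def test_negative_flux_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_trace_recipe(-1.0, rng=rng)

    def test_overfull_window_is_infeasible(self, rng):
        with pytest.raises(InfeasibleRecipeError):
            sample_trace_recipe(500.0, rng=rng)  # 384 peaks x 3 ms > 0.768 s

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(flux=st.floats(min_value=0.0, max_value=120.0))
    def test_recipe_invariants(self, flux):
        r = sample_trace_recipe(flux, rng=np.random.default_rng(7))
        assert r.n_peaks == round(flux * DEFAULT_T)
        if r.n_peaks:
            assert np.all(np.diff(r.peak_times) > 0)
            assert r.peak_times[0] >= 0 and r.peak_times[-1] < r.duration
            assert np.all((r.peak_heights > 0) & (r.peak_heights <= 1))
            assert np.all(r.peak_fwhms > 0)
        assert 0 <= r.noise_amplitude <= 1
        assert 0 <= r.sine_freq <= 16
        assert 0 <= r.sine_amp <= 0.5

    def test_mean_interpeak_time_is_inverse_flux(self):
        # before window rescaling, gaps average 1/flux (within 5%)
        rng = np.random.default_rng(3)
        cfg = HierarchicalDistConfig()
        for flux in (20.0, 50.0, 100.0):
            gaps = sample_interpeak_gaps(flux, 20000, cfg, rng)
            assert np.mean(gaps) == pytest.approx(1 / flux, rel=0.05)

    def test_interpeak_dispersion_exceeds_poisson_at_low_flux(self):
        # CV matches the configured law within 10%; a Poisson process has
        # CV 1, which the defaults exceed at low flux and approach at high
        rng = np.random.default_rng(4)
        cfg = HierarchicalDistConfig()
        cvs = {}
        for flux in (10.0, 100.0):
            gaps = sample_interpeak_gaps(flux, 50000, cfg, rng)
            cv = np.std(gaps) / np.mean(gaps)
            assert cv == pytest.approx(cfg.interpeak_cv(flux), rel=0.10)
            cvs[flux] = cv
        assert cvs[10.0] > 1.3
        assert 1.0 < cvs[100.0] < 1.35


class TestRendering:
    def test_zero_peaks_render_to_zero(self, rng):
        r = sample_trace_recipe(0.0, rng=rng)
        trace = render_clean_trace(r)
        assert np.all(trace.samples == 0)

    def test_single_pulse_matches_fwhm_definition(self):
        dt, n = 1.5e-3, 512
        r = TraceRecipe(
            flux_label=1 / (n * dt),
            peak_times=np.array([0.384]),  # 256 * dt: on the sample grid
            peak_heights=np.array([1.0]),
            peak_fwhms=np.array([12e-3]),  # half height 4 samples from center
            noise_amplitude=0.0, sine_freq=0.0, sine_amp=0.0, sine_phase=0.0,
            duration=n * dt, dt=dt,
        )
        y = render_clean_trace(r, n, dt).samples
        assert y[256] == pytest.approx(1.0, abs=1e-6)
        # half height at +/- FWHM/2 from the center
        assert y[252] == pytest.approx(0.5, abs=1e-6)
        assert y[260] == pytest.approx(0.5, abs=1e-6)

    def test_two_separated_pulses_superpose_independently(self):
        dt, n = 1.5e-3, 512
        r = TraceRecipe(
            flux_label=2 / (n * dt),
            peak_times=np.array([0.3, 0.402]),  # samples 200 and 268
            peak_heights=np.array([0.5, 1.0]),
            peak_fwhms=np.array([10e-3, 10e-3]),
            noise_amplitude=0.0, sine_freq=0.0, sine_amp=0.0, sine_phase=0.0,
            duration=n * dt, dt=dt,
        )
        y = render_clean_trace(r, n, dt).samples
        # pulses 100 ms apart with 10 ms FWHM overlap by < 1e-6
        assert y[200] == pytest.approx(0.5, abs=1e-5)
        assert y[268] == pytest.approx(1.0, abs=1e-5)

    def test_duration_mismatch_rejected(self, rng):
        r = sample_trace_recipe(10.0, rng=rng)
        with pytest.raises(ValueError):
            render_clean_trace(r, n_samples=100, dt=1.5e-3)


class TestSpeckleNoise:
    def test_zero_amplitude_is_identity(self, rng):
        trace = TimeTrace(np.linspace(0, 1, 100), dt=1e-3)
        out = add_speckle_noise(trace, 0.0, rng=rng)
        assert out is trace

    def test_noise_only_mean_is_twice_amplitude_squared(self):
        # at S=0 the intensity is |N|^2, exponential with mean 2 a^2
        rng = np.random.default_rng(5)
        trace = TimeTrace(np.zeros(10**6), dt=1e-3)
        for a in (0.3, 0.7):
            out = add_speckle_noise(trace, a, rng=rng)
            assert np.mean(out.samples) == pytest.approx(2 * a**2, rel=0.02)

    def test_negative_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            add_speckle_noise(TimeTrace(np.zeros(10), dt=1e-3), -0.1, rng=rng)

    def test_per_trace_modulus_gives_constant_floor(self):
        rng = np.random.default_rng(6)
        trace = TimeTrace(np.zeros(1000), dt=1e-3)
        out = add_speckle_noise(trace, 0.5, rng=rng, modulus_mode="per_trace")
        assert np.ptp(out.samples) == pytest.approx(0.0, abs=1e-12)


class TestSlowComponent:
    def test_zero_amplitude_is_identity(self):
        trace = TimeTrace(np.linspace(0, 1, 64), dt=1e-3)
        assert add_slow_component(trace, 5.0, 0.0) is trace

    def test_cycle_count_matches_freq_times_duration(self):
        # 1.5 Hz over 0.768 s completes 1.152 cycles
        n, dt = 512, 1.5e-3
        trace = TimeTrace(np.zeros(n), dt=dt)
        out = add_slow_component(trace, 1.5, 0.3, phase=0.0)
        phase_span = 2 * np.pi * 1.5 * (n * dt)
        assert phase_span / (2 * np.pi) == pytest.approx(1.152)
        assert out.samples[0] == pytest.approx(0.0, abs=1e-12)
        assert np.max(out.samples) == pytest.approx(0.3, abs=1e-3)

    def test_zero_frequency_gives_constant_offset(self):
        trace = TimeTrace(np.zeros(64), dt=1e-3)
        out = add_slow_component(trace, 0.0, 0.25, phase=np.pi / 2)
        assert np.allclose(out.samples, 0.25)


class TestNormalization:
    def test_plain_min_max(self):
        trace = TimeTrace(np.array([0.0, 2.0, 4.0]), dt=1e-3)
        out = normalize_trace(trace, robust=False)
        assert np.allclose(out.samples, [0, 0.5, 1])
        assert out.normalized

    def test_idempotent_on_normalized(self):
        trace = TimeTrace(np.array([0.0, 0.5, 1.0]), dt=1e-3, normalized=True)
        assert normalize_trace(trace) is trace

    def test_robust_mode_clips_outlier(self, rng):
        base = rng.uniform(0, 1, 1000)
        base[500] = 10 * np.percentile(base, 99)
        out = normalize_trace(TimeTrace(base, dt=1e-3))
        assert out.samples[500] == pytest.approx(1.0)
        assert np.all((out.samples >= 0) & (out.samples <= 1))

    def test_constant_trace_rejected(self):
        with pytest.raises(DegenerateTraceError):
            normalize_trace(TimeTrace(np.ones(100), dt=1e-3))


class TestDatasetGeneration:
    def test_shapes_and_balance(self, small_dataset):
        # 12 categories x 10 traces of 512 samples
        assert small_dataset.traces.shape == (120, 512)
        assert len(small_dataset.recipes) == 120

    def test_labels_fall_inside_their_category(self, small_dataset):
        edges = np.asarray(small_dataset.meta["category_edges"])
        labels = np.sort(small_dataset.labels.reshape(12, 10), axis=1)
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            cat = small_dataset.labels[i * 10 : (i + 1) * 10]
            assert np.all((cat >= lo) & (cat < hi))

    def test_traces_are_normalized(self, small_dataset):
        assert small_dataset.traces.min() >= 0
        assert small_dataset.traces.max() <= 1

    def test_identical_seeds_reproduce_identical_datasets(self):
        a = generate_dataset(per_category=3, rng=9)
        b = generate_dataset(per_category=3, rng=9)
        assert np.array_equal(a.traces, b.traces)
        assert np.array_equal(a.labels, b.labels)

    def test_per_category_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_dataset(per_category=0)
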