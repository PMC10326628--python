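import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramanomics.spectra_io import Spectrum
from ramanomics.synthetic_data import GeneratorConfig, generate_cohort, gaussian_band
from ramanomics.preprocess import (
    BandError, DegenerateInputError, ParameterError, PreprocessConfig,
    clip_band, detect_outlier_spectra, normalize_minmax, preprocess_batch,
    preprocess_pipeline, remove_cosmic_spikes, smooth_sg, snip_baseline,
)


def flat_spectrum(n=200, value=1.0, start=600.0, **kw):
    x = start + np.arange(n, dtype=float)
    return Spectrum(shifts=x, intensities=np.full(n, value), **kw)


# ---------------------------------------------------------------- despiking

def test_injected_spike_replaced_close_to_clean():
    """A 2-channel spike 10x the local signal is removed to within noise."""
    cfg = GeneratorConfig(n_samples=2, replicates_per_sample=1, spike_rate=0.0, seed=3)
    spectra, _, _ = generate_cohort(cfg)
    for s in spectra:
        clean = s.intensities.copy()
        spiked = clean.copy()
        pos = 700  # mid-axis, baseline-dominated region
        spiked[pos] += 10 * abs(clean[pos])
        spiked[pos + 1] += 7 * abs(clean[pos])
        out = remove_cosmic_spikes(s.with_intensities(spiked))
        noise_sd = 0.02
        assert np.max(np.abs(out.intensities[[pos, pos + 1]] - clean[[pos, pos + 1]])) < 3 * noise_sd
        mask = np.ones(len(s), dtype=bool)
        mask[[pos, pos + 1]] = False
        np.testing.assert_array_equal(out.intensities[mask], spiked[mask])


def test_spike_free_spectra_pass_through_unchanged(small_cohort):
    cfg = GeneratorConfig(n_samples=10, replicates_per_sample=3, spike_rate=0.0, seed=8)
    spectra, _, _ = generate_cohort(cfg)
    for s in spectra:
        out = remove_cosmic_spikes(s)
        np.testing.assert_array_equal(out.intensities, s.intensities)


def test_broad_genuine_band_untouched():
    """A real band (FWHM 12 cm^-1, 10x noise) is wider than any spike."""
    rng = np.random.default_rng(4)
    x = np.arange(600.0, 1000.0)
    noise_sd = 0.02
    y = gaussian_band(x, 800.0, 10 * noise_sd * 10, 12 / 2.3548) + rng.normal(0, noise_sd, x.size)
    s = Spectrum(shifts=x, intensities=y)
    out = remove_cosmic_spikes(s)
    band = (x > 770) & (x < 830)
    np.testing.assert_array_equal(out.intensities[band], y[band])


# ---------------------------------------------------------------- clipping

def test_clip_band_channel_arithmetic():
    x = np.arange(50.0, 2000.5, 1.0)
    s = Spectrum(shifts=x, intensities=np.ones_like(x))
    out = clip_band(s)
    assert len(out) == 1201  # 600..1800 inclusive at 1 cm^-1
    assert out.shifts[0] == 600.0 and out.shifts[-1] == 1800.0


def test_clip_band_identity_when_already_clipped():
    x = np.arange(600.0, 1801.0)
    s = Spectrum(shifts=x, intensities=np.sin(x))
    out = clip_band(s)
    np.testing.assert_array_equal(out.shifts, s.shifts)
    np.testing.assert_array_equal(out.intensities, s.intensities)


def test_clip_band_empty_intersection_errors():
    x = np.arange(50.0, 1801.0)
    s = Spectrum(shifts=x, intensities=np.ones_like(x))
    with pytest.raises(BandError):
        clip_band(s, PreprocessConfig(band_low=1900.0, band_high=1950.0))


# ---------------------------------------------------------------- smoothing

def test_savgol_reproduces_cubic_exactly():
    x = np.arange(600.0, 1801.0)
    t = (x - x[0]) / (x[-1] - x[0])
    y = 2.0 - 3.0 * t + 0.5 * t ** 2 + 4.0 * t ** 3
    s = Spectrum(shifts=x, intensities=y)
    out = smooth_sg(s)  # window 11, order 3
    np.testing.assert_allclose(out.intensities, y, atol=1e-9)


def test_savgol_reduces_white_noise_variance():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = np.arange(600.0, 1801.0)
        y = rng.normal(0.0, 1.0, x.size)
        out = smooth_sg(Spectrum(shifts=x, intensities=y))
        assert out.intensities.std() < y.std()


def test_savgol_impulse_response_matches_least_squares_oracle():
    """Central SG coefficients equal a direct polynomial-fit projection."""
    n, window, order = 51, 11, 3
    x = np.arange(600.0, 600.0 + n)
    y = np.zeros(n)
    y[n // 2] = 1.0
    out = smooth_sg(Spectrum(shifts=x, intensities=y),
                    PreprocessConfig(sg_window=window, sg_order=order))
    # oracle: weight of the impulse at offset d is row 0 of the LS smoother
    half = window // 2
    A = np.vander(np.arange(-half, half + 1), order + 1, increasing=True)
    H = A @ np.linalg.pinv(A)  # hat matrix of the windowed polynomial fit
    for offset in range(-half, half + 1):
        assert out.intensities[n // 2 + offset] == pytest.approx(H[half + offset, half], abs=1e-12)


def test_savgol_shorter_than_window_errors():
    s = flat_spectrum(n=8)
    with pytest.raises(ParameterError):
        smooth_sg(s)


# ---------------------------------------------------------------- SNIP

def test_snip_recovers_peakless_baseline():
    """On a pure background curve the corrected residual is near zero."""
    cfg = GeneratorConfig(n_samples=3, replicates_per_sample=1, noise_sd=0.0,
                          spike_rate=0.0, seed=11)
    spectra, _, truth = generate_cohort(cfg)
    for s in spectra:
        baseline_only = s.with_intensities(truth.baselines[s.spectrum_id])
        clipped = clip_band(baseline_only)
        _, corrected = snip_baseline(clipped)
        assert np.max(np.abs(corrected.intensities)) < 0.05 * clipped.intensities.max()


def test_snip_single_band_on_constant_offset():
    x = np.arange(600.0, 1801.0)
    A, c = 2.0, 5.0
    y = gaussian_band(x, 1200.0, A, 12 / 2.3548) + c
    baseline, corrected = snip_baseline(Spectrum(shifts=x, intensities=y))
    peak = corrected.intensities[x == 1200.0][0]
    assert abs(peak - A) < 0.10 * A
    away = (np.abs(x - 1200.0) > 100) & (x > 650) & (x < 1750)
    assert np.max(np.abs(baseline.intensities[away] - c)) < 0.05 * c


def test_snip_zero_spectrum_maps_to_zero():
    s = flat_spectrum(value=0.0)
    baseline, corrected = snip_baseline(s)
    np.testing.assert_array_equal(baseline.intensities, 0.0)
    np.testing.assert_array_equal(corrected.intensities, 0.0)


def test_snip_invariants_on_synthetic_batch(small_cohort):
    spectra, _, _ = small_cohort
    for s in spectra[:10]:
        clipped = clip_band(s)
        baseline, corrected = snip_baseline(clipped)
        assert np.all(baseline.intensities <= clipped.intensities + 1e-9)
        np.testing.assert_allclose(baseline.intensities + corrected.intensities,
                                   clipped.intensities, atol=1e-9)


# ---------------------------------------------------------------- normalize

def test_minmax_normalization_values():
    s = flat_spectrum(n=3, start=600.0)
    s = s.with_intensities(np.array([2.0, 4.0, 6.0]))
    out = normalize_minmax(s)
    np.testing.assert_allclose(out.intensities, [0.0, 0.5, 1.0])


def test_minmax_identity_when_bounds_attained():
    y = np.array([0.0, 0.25, 1.0, 0.5])
    s = Spectrum(shifts=np.arange(600.0, 604.0), intensities=y)
    np.testing.assert_allclose(normalize_minmax(s).intensities, y)


def test_minmax_constant_spectrum_errors():
    with pytest.raises(DegenerateInputError):
        normalize_minmax(flat_spectrum(value=3.0))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0))
def test_minmax_affine_invariance(a, b):
    rng = np.random.default_rng(0)
    y = rng.normal(0.0, 1.0, 64)
    x = np.arange(600.0, 664.0)
    base = normalize_minmax(Spectrum(shifts=x, intensities=y)).intensities
    scaled = normalize_minmax(Spectrum(shifts=x, intensities=a * y + b)).intensities
    np.testing.assert_allclose(scaled, base, atol=1e-9)


# ---------------------------------------------------------------- pipeline

def test_pipeline_output_shape_and_bounds(small_cohort):
    spectra, _, _ = small_cohort
    out = preprocess_pipeline(spectra[0])
    assert len(out) == 1201
    assert out.intensities.min() == 0.0
    assert out.intensities.max() == 1.0


def test_pipeline_idempotent_up_to_resmoothing(small_cohort):
    spectra, _, _ = small_cohort
    once = preprocess_pipeline(spectra[0])
    twice = preprocess_pipeline(once)
    rms = np.sqrt(np.mean((twice.intensities - once.intensities) ** 2))
    assert rms < 0.02  # residual change dominated by re-smoothing


def test_batch_preserves_order_and_count(small_cohort):
    spectra, _, _ = small_cohort
    out = preprocess_batch(spectra)
    assert len(out) == len(spectra)
    assert [s.spectrum_id for s in out] == [s.spectrum_id for s in spectra]


def test_pipeline_keep_intermediates_stages(small_cohort):
    spectra, _, _ = small_cohort
    final, stages = preprocess_pipeline(spectra[0], keep_intermediates=True)
    assert set(stages) == {"despiked", "clipped", "smoothed", "baseline",
                           "corrected", "normalized"}
    np.testing.assert_array_equal(stages["normalized"].intensities, final.intensities)


# ---------------------------------------------------------------- outliers

def test_outlier_screen_false_positive_rate_on_clean_batches():
    """At the 99.9% quantile, a clean batch loses at most ~1% of spectra."""
    total, rejected = 0, 0
    for seed in range(10):
        cfg = GeneratorConfig(n_samples=30, replicates_per_sample=2,
                              spike_rate=0.0, seed=100 + seed)
        spectra, _, _ = generate_cohort(cfg)
        report = detect_outlier_spectra(preprocess_batch(spectra))
        total += len(spectra)
        rejected += len(report.rejected)
    assert rejected / total <= 0.01


def test_planted_noise_spectra_have_largest_distances(processed_small):
    processed, _, _ = processed_small
    rng = np.random.default_rng(0)
    batch = list(processed)
    corrupted_ids = []
    for i in range(5):
        idx = 10 + 17 * i
        noise = rng.uniform(0.0, 1.0, len(batch[idx]))
        batch[idx] = batch[idx].with_intensities(noise)
        corrupted_ids.append(batch[idx].spectrum_id)
    report = detect_outlier_spectra(batch)
    worst5 = sorted(report.distances, key=report.distances.get, reverse=True)[:5]
    assert set(worst5) == set(corrupted_ids)
    assert set(corrupted_ids) <= {s.spectrum_id for s in report.rejected}


def test_identical_spectra_degenerate_covariance_keeps_all():
    x = np.arange(600.0, 700.0)
    batch = [Spectrum(shifts=x, intensities=np.ones_like(x),
                      spectrum_id=f"id{i}", sample_id=f"S{i}") for i in range(12)]
    report = detect_outlier_spectra(batch)
    assert len(report.kept) == 12
    assert report.rejected == []
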