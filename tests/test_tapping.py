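"""Tapping-feature tests: rescaling, band integrals, period segmentation,
the SVD periodicity measure and the composite score."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from magtremor.spectral import SampledSignal, Spectrum, dft_spectrum
from magtremor.tapping import (
    PeriodMatrix,
    TapTake,
    amxfr,
    band_integrals,
    extract_features,
    ftts,
    low_velocity_fraction,
    periodicity_measure,
    rescale,
    segment_periods,
    spectra_ttest,
    velocity,
)

RATE = 62.0


def periodic_taps(freq=5.0, duration=3.0, rate=RATE):
    """Exactly periodic tap train: an integer-length raised-cosine-squared
    template tiled verbatim, so every period is sample-identical."""
    period_n = int(round(rate / freq))
    u = np.arange(period_n) / period_n
    template = ((1 - np.cos(2 * np.pi * u)) / 2) ** 2
    n_tiles = int(round(duration * rate / period_n))
    return np.tile(template, n_tiles)


class TestRescale:
    def test_bounds_and_affine(self):
        z = np.array([2.0, 5.0, 3.0, 8.0])
        out = rescale(z)
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.allclose(out, (z - 2.0) / 6.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            rescale(np.ones(10))

    @given(st.floats(-100, 100), st.floats(0.1, 50))
    def test_shift_scale_invariance(self, shift, scale):
        z = periodic_taps()
        assert np.allclose(rescale(scale * z + shift), rescale(z), atol=1e-9)


class TestVelocity:
    def test_linear_ramp(self):
        z = np.linspace(0.0, 1.0, 63)  # 1 unit over 1 s at 62 Sa/s
        v = velocity(z, RATE)
        assert len(v) == 62
        assert np.allclose(v, 1.0)

    def test_low_velocity_fraction(self):
        v = np.array([0.1, -0.2, 2.0, -3.0])
        assert low_velocity_fraction(v, 1.0) == 0.5
        assert low_velocity_fraction(v, 0.0) == 0.0


class TestBandIntegrals:
    def test_flat_spectrum_fractions(self):
        """Uniform amplitude: the band weight is just the width ratio."""
        freqs = np.linspace(0.0, 31.0, 500)
        amp = np.ones_like(freqs)
        spec = Spectrum(freqs=freqs, amp_linear=amp, amp_db=np.zeros_like(amp))
        i14, i412 = band_integrals(spec)
        assert i14 == pytest.approx(100 * 3 / 31, rel=1e-9)
        assert i412 == pytest.approx(100 * 8 / 31, rel=1e-9)

    def test_single_bin_mass(self):
        """A narrow triangle centered at 2.5 Hz lands entirely in int1_4."""
        freqs = np.linspace(0.0, 31.0, 3101)  # 0.01 Hz pitch
        amp = np.maximum(0.0, 1.0 - np.abs(freqs - 2.5) / 0.05)
        spec = Spectrum(freqs=freqs, amp_linear=amp, amp_db=amp)
        i14, i412 = band_integrals(spec)
        assert i14 == pytest.approx(100.0, abs=1e-6)
        assert i412 == pytest.approx(0.0, abs=1e-6)

    def test_endpoint_interpolation_exact_on_ramp(self):
        """A linear ramp is integrated exactly by the trapezoid rule even when
        the band edges (1, 4, 12 Hz) fall between grid points."""
        freqs = np.linspace(0.0, 31.0, 100)  # pitch 0.313 Hz, misses 1/4/12
        assert not np.any(np.isin([1.0, 4.0, 12.0], freqs))
        spec = Spectrum(freqs=freqs, amp_linear=freqs.copy(), amp_db=freqs.copy())
        i14, i412 = band_integrals(spec)
        assert i14 == pytest.approx(100 * (16 - 1) / 961, rel=1e-12)
        assert i412 == pytest.approx(100 * (144 - 16) / 961, rel=1e-12)

    def test_insufficient_span_rejected(self):
        freqs = np.linspace(0.0, 20.0, 100)
        spec = Spectrum(freqs=freqs, amp_linear=np.ones(100), amp_db=np.zeros(100))
        with pytest.raises(ValueError):
            band_integrals(spec)


class TestSegmentation:
    def test_periodic_signal_periods(self):
        z = periodic_taps(freq=5.0, duration=3.0)
        Z = segment_periods(z, RATE)
        # 5 Hz over 3 s -> ~15 taps; interior peaks give ~13-14 periods
        assert 12 <= Z.n_periods <= 15
        # all inter-peak spans equal up to one sample -> durations ~0.2 s
        assert np.allclose(Z.durations, 0.2, atol=1.5 / RATE)
        assert np.all(Z.peak_amplitudes > 0.7)

    def test_rows_resampled_to_common_length(self):
        z = periodic_taps()
        Z = segment_periods(z, RATE)
        assert Z.rows.shape[1] == int(round(np.median(np.diff(
            np.concatenate([Z.peak_indices, [Z.peak_indices[-1] +
                            round(Z.durations[-1] * RATE)]])))))

    def test_too_few_peaks_rejected(self):
        z = periodic_taps(freq=5.0, duration=0.3)
        with pytest.raises(ValueError):
            segment_periods(z, RATE)

    def test_small_ripple_ignored(self):
        """Sub-prominence ripple must not create extra periods."""
        z = periodic_taps()
        ripple = 0.05 * np.sin(2 * np.pi * 20.0 * np.arange(len(z)) / RATE)
        Z_clean = segment_periods(z, RATE)
        Z_noisy = segment_periods(np.clip(z + ripple, 0, None), RATE)
        assert abs(Z_noisy.n_periods - Z_clean.n_periods) <= 1


class TestPeriodicityMeasure:
    def test_rank_one_matrix_gives_one(self):
        row = np.sin(np.linspace(0, np.pi, 12))
        rows = np.outer([1.0, 2.0, 0.5, 1.5], row)
        Z = PeriodMatrix(rows=rows, peak_indices=np.arange(4),
                         peak_amplitudes=np.ones(4), durations=np.ones(4))
        assert periodicity_measure(Z) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rows_give_one_over_m(self):
        rows = np.eye(5)
        Z = PeriodMatrix(rows=rows, peak_indices=np.arange(5),
                         peak_amplitudes=np.ones(5), durations=np.ones(5))
        assert periodicity_measure(Z) == pytest.approx(0.2, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            rows = rng.normal(size=(6, 15))
            Z = PeriodMatrix(rows=rows, peak_indices=np.arange(6),
                             peak_amplitudes=np.ones(6), durations=np.ones(6))
            pm = periodicity_measure(Z)
            assert 0.0 < pm <= 1.0
            assert pm >= 1.0 / 6 - 1e-12

    def test_perfect_periodic_signal_exact_one(self):
        """End-to-end: identical periods stack to a rank-one matrix."""
        Z = segment_periods(periodic_taps(freq=5.0, duration=3.0), RATE)
        assert periodicity_measure(Z) == 1.0

    def test_invariant_to_row_permutation(self, rng):
        rows = rng.normal(size=(7, 10))
        meta = dict(peak_indices=np.arange(7), peak_amplitudes=np.ones(7),
                    durations=np.ones(7))
        a = periodicity_measure(PeriodMatrix(rows=rows, **meta))
        b = periodicity_measure(PeriodMatrix(rows=rows[::-1].copy(), **meta))
        assert a == pytest.approx(b, abs=1e-12)


class TestScores:
    def test_amxfr_definition(self):
        Z = PeriodMatrix(rows=np.zeros((3, 4)), peak_indices=np.arange(3),
                         peak_amplitudes=np.array([1.0, 0.8, 0.6]),
                         durations=np.array([0.2, 0.25, 0.3]))
        expected = np.mean([1.0 / 0.2, 0.8 / 0.25, 0.6 / 0.3])
        assert amxfr(Z) == pytest.approx(expected)

    def test_ftts_composition(self):
        assert ftts(1.0, 4.0) == pytest.approx(1.6)
        assert ftts(0.6, 10.0) == 0.0

    def test_extract_features_healthy_take(self):
        take = TapTake(z_raw=periodic_taps(freq=5.0, duration=3.0), label="no-disease")
        f = extract_features(take)
        assert f.pm == 1.0
        assert f.int4_12 > f.int1_4
        assert f.ftts == pytest.approx((f.pm - 0.6) * f.amxfr)
        assert f.label == "no-disease"
        # ~5 taps/s at amplitude 1 -> amxfr near 5
        assert 4.0 < f.amxfr < 6.0

    def test_generated_conditions_separate(self):
        """Disease takes score lower pm and ftts than healthy takes."""
        from magtremor.simulate import TapSpec, ft_signal

        pm_h, pm_d, ft_h, ft_d = [], [], [], []
        for seed in range(8):
            fh = extract_features(TapTake(
                z_raw=ft_signal(TapSpec(condition="no-disease", seed=seed)).values))
            fd = extract_features(TapTake(
                z_raw=ft_signal(TapSpec(condition="disease", seed=seed)).values))
            pm_h.append(fh.pm), pm_d.append(fd.pm)
            ft_h.append(fh.ftts), ft_d.append(fd.ftts)
        assert np.mean(pm_h) > np.mean(pm_d)
        assert np.mean(ft_h) > np.mean(ft_d)


class TestSpectraTtest:
    def test_identical_groups_not_flagged(self):
        t = np.arange(186) / RATE
        specs = [dft_spectrum(SampledSignal(
            values=np.sin(2 * np.pi * 5 * t) + 0.01 * np.random.default_rng(s).normal(size=186),
            rate=RATE), reference=1.0) for s in range(8)]
        flags = spectra_ttest(specs[:4], specs[4:])
        assert np.mean(flags) < 0.2

    def test_distinct_tone_flagged(self):
        t = np.arange(186) / RATE
        rngs = [np.random.default_rng(s) for s in range(8)]
        a = [dft_spectrum(SampledSignal(
            values=np.sin(2 * np.pi * 5 * t) + 0.01 * r.normal(size=186),
            rate=RATE), reference=1.0) for r in rngs[:4]]
        b = [dft_spectrum(SampledSignal(
            values=np.sin(2 * np.pi * 10 * t) + 0.01 * r.normal(size=186),
            rate=RATE), reference=1.0) for r in rngs[4:]]
        flags = spectra_ttest(a, b)
        freqs = a[0].freqs
        assert flags[np.argmin(np.abs(freqs - 5.0))]
        assert flags[np.argmin(np.abs(freqs - 10.0))]

    def test_mismatched_grids_rejected(self):
        t1 = np.arange(186) / RATE
        t2 = np.arange(200) / RATE
        a = [dft_spectrum(SampledSignal(values=np.sin(t1), rate=RATE))] * 2
        b = [dft_spectrum(SampledSignal(values=np.sin(t2), rate=RATE))] * 2
        with pytest.raises(ValueError):
            spectra_ttest(a, b)
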