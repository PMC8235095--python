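"""Frequency-domain pipeline for tracked coordinate signals.

The tremor and stop-movement analyses share the same chain: high-pass IIR
filtering to strip the imposed carrier trajectory, a rectangular-window DFT
with amplitudes in dB (20·log10 of the amplitude over a stated 0 dB
reference, by default the post-filter time-domain maximum), and, for
non-stationary signals, a moving-window spectrogram used to locate the time
at which the dominant oscillation changes regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SampledSignal",
    "Spectrum",
    "Spectrogram",
    "DetectionError",
    "highpass",
    "dft_spectrum",
    "dominant_frequency",
    "spectrogram",
    "frequency_change_time",
]

DB_FLOOR = -240.0  # clamp for amplitudes below 1e-12 of the reference


class DetectionError(RuntimeError):
    """No frequency-regime switch found in a spectrogram."""


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled scalar series."""

    values: np.ndarray
    rate: float = 62.0
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("signal values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate

    def slice(self, t_lo: float, t_hi: float) -> "SampledSignal":
        """Samples with t_lo <= t < t_hi."""
        mask = (self.times >= t_lo) & (self.times < t_hi)
        return SampledSignal(values=self.values[mask], rate=self.rate, label=self.label)


@dataclass(frozen=True)
class Spectrum:
    """One-sided amplitude spectrum with its dB representation."""

    freqs: np.ndarray
    amp_linear: np.ndarray
    amp_db: np.ndarray
    reference: float = 1.0


@dataclass(frozen=True)
class Spectrogram:
    window_times: np.ndarray  # window centers, s
    freqs: np.ndarray
    amp_linear: np.ndarray  # (n_windows, n_freqs)
    amp_db: np.ndarray
    window_frac: float = 0.3
    overlap: float = 0.5

    def __post_init__(self):
        if not (0 < self.window_frac < 1 and 0 < self.overlap < 1):
            raise ValueError("window_frac and overlap must be in (0, 1)")
        if self.amp_db.shape != (len(self.window_times), len(self.freqs)):
            raise ValueError("amplitude matrix inconsistent with axes")


def design_highpass(cutoff_hz: float, rate: float, order: int = 8) -> np.ndarray:
    """Butterworth high-pass in second-order sections (−3 dB at the cutoff)."""
    if not (0 < cutoff_hz < rate / 2):
        raise ValueError("cutoff must lie in (0, Nyquist)")
    return sps.butter(order, cutoff_hz, btype="highpass", fs=rate, output="sos")


def highpass(
    signal: SampledSignal,
    cutoff_hz: float,
    order: int = 8,
    zero_phase: bool = True,
) -> SampledSignal:
    """8th-order IIR (Butterworth) high-pass.

    Applied forward-backward by default so the filter is zero-phase: change
    points and tap timings are not shifted, at the price of doubling the
    magnitude attenuation.  ``zero_phase=False`` gives the single-pass
    causal filter.
    """
    sos = design_highpass(cutoff_hz, signal.rate, order)
    fn = sps.sosfiltfilt if zero_phase else sps.sosfilt
    return SampledSignal(values=fn(sos, signal.values), rate=signal.rate,
                         label=signal.label)


def _one_sided_amplitude(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(values)
    y = np.fft.rfft(values) / n
    amp = np.abs(y)
    # fold negative frequencies onto the positive side (bins with a conjugate pair)
    upper = n // 2 if n % 2 == 0 else (n + 1) // 2
    amp[1:upper] *= 2.0
    return np.fft.rfftfreq(n, 1.0), amp


def dft_spectrum(signal: SampledSignal, reference="max") -> Spectrum:
    """Rectangular-window one-sided DFT amplitude spectrum.

    ``reference="max"`` sets the 0 dB level to the maximum absolute value of
    the (already filtered) time-domain signal; a scalar fixes it explicitly.
    """
    if len(signal) < 2:
        raise ValueError("signal must have at least 2 samples")
    f_norm, amp = _one_sided_amplitude(signal.values)
    freqs = f_norm * signal.rate
    ref = float(np.max(np.abs(signal.values))) if reference == "max" else float(reference)
    if ref <= 0:
        ref = 1.0
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.maximum(amp / ref, 1e-12))
    db = np.maximum(db, DB_FLOOR)
    return Spectrum(freqs=freqs, amp_linear=amp, amp_db=db, reference=ref)


def dominant_frequency(spectrum: Spectrum, band) -> float:
    """Frequency of the largest-amplitude bin within [f_lo, f_hi].

    Ties break toward the lower frequency.
    """
    f_lo, f_hi = band
    mask = (spectrum.freqs >= f_lo) & (spectrum.freqs <= f_hi)
    if not np.any(mask):
        raise ValueError("band contains no spectral bins")
    idx = int(np.argmax(spectrum.amp_linear[mask]))
    return float(spectrum.freqs[mask][idx])


def spectrogram(
    signal: SampledSignal,
    window_frac: float = 0.3,
    overlap: float = 0.5,
) -> Spectrogram:
    """Rectangular-window DFT on moving windows.

    The window spans ``window_frac`` of the total sample count and advances
    by ``1 - overlap`` of its own length; a trailing partial window is
    dropped.  dB values are relative to the global maximum amplitude.
    """
    n = len(signal)
    win = int(round(window_frac * n))
    if win < 4:
        raise ValueError("window shorter than 4 samples")
    hop = max(int(round(win * (1.0 - overlap))), 1)
    starts = range(0, n - win + 1, hop)
    rows, centers = [], []
    freqs = np.fft.rfftfreq(win, 1.0) * signal.rate
    for s in starts:
        _, amp = _one_sided_amplitude(signal.values[s : s + win])
        rows.append(amp)
        centers.append((s + win / 2.0) / signal.rate)
    if not rows:
        raise ValueError("signal shorter than one window")
    amp = np.array(rows)
    ref = float(np.max(amp)) or 1.0
    with np.errstate(divide="ignore"):
        db = np.maximum(20.0 * np.log10(np.maximum(amp / ref, 1e-12)), DB_FLOOR)
    return Spectrogram(
        window_times=np.array(centers),
        freqs=freqs,
        amp_linear=amp,
        amp_db=db,
        window_frac=window_frac,
        overlap=overlap,
    )


def frequency_change_time(spg: Spectrogram, band_a, band_b) -> float:
    """Time at which spectral dominance switches from band_a to band_b.

    Each window is labeled by which of the two bands contains its strongest
    bin; the reported time is the midpoint between the centers of the last
    a-dominated window and the first b-dominated window after it.
    """
    a_lo, a_hi = band_a
    b_lo, b_hi = band_b
    if max(a_lo, b_lo) <= min(a_hi, b_hi):
        raise ValueError("bands must be disjoint")
    mask_a = (spg.freqs >= a_lo) & (spg.freqs <= a_hi)
    mask_b = (spg.freqs >= b_lo) & (spg.freqs <= b_hi)
    if not (np.any(mask_a) and np.any(mask_b)):
        raise ValueError("bands contain no spectral bins")
    peak_a = spg.amp_linear[:, mask_a].max(axis=1)
    peak_b = spg.amp_linear[:, mask_b].max(axis=1)
    labels = np.where(peak_a >= peak_b, "a", "b")
    a_idx = np.flatnonzero(labels == "a")
    if len(a_idx) == 0 or len(a_idx) == len(labels):
        raise DetectionError("no dominance switch between the two bands")
    last_a = int(a_idx[-1])
    b_after = np.flatnonzero(labels[last_a + 1 :] == "b")
    if len(b_after) == 0:
        raise DetectionError("no dominance switch between the two bands")
    first_b = last_a + 1 + int(b_after[0])
    return float((spg.window_times[last_a] + spg.window_times[first_b]) / 2.0)
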