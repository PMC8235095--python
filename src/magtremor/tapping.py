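"""Finger-tapping feature extraction.

Each take is the z coordinate of the fingertip, rescaled per take to [0, 1]
so features are subject- and geometry-independent.  Features:

* ``int1_4`` / ``int4_12`` — percentage of the amplitude-spectrum integral
  over 1–4 Hz (where bradykinetic energy concentrates) and 4–12 Hz (healthy
  tap fundamental ~5 Hz plus first harmonic) relative to the full 0–31 Hz
  band.
* ``pm`` — SVD periodicity measure: the signal is split at tap peaks into
  periods, each linearly resampled to the median period length and stacked
  into a matrix Z; pm = sigma_1^2 / sum_i sigma_i^2 from the singular values
  of Z.  Perfectly periodic signals give pm = 1.
* ``amxfr`` — mean over periods of (peak amplitude / period duration), an
  amplitude-times-frequency speed score.
* ``ftts`` — composite finger-tapping test score (pm − 0.6) · amxfr.
* ``low_vel_frac`` — auxiliary fraction of samples below a velocity
  threshold (retained for completeness; weakly discriminative on its own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from scipy.linalg import svdvals

from .spectral import SampledSignal, Spectrum, dft_spectrum

__all__ = [
    "TapTake",
    "PeriodMatrix",
    "TapFeatures",
    "rescale",
    "velocity",
    "low_velocity_fraction",
    "band_integrals",
    "segment_periods",
    "periodicity_measure",
    "amxfr",
    "ftts",
    "extract_features",
    "spectra_ttest",
]

# Peak-picking defaults: prominence on the [0, 1] rescaled signal and a
# refractory separation that still admits tap rates up to ~12 Hz.
PEAK_PROMINENCE = 0.3
PEAK_MIN_SEPARATION_S = 0.08
LOW_VELOCITY_THRESHOLD = 1.0  # s^-1, on the rescaled coordinate


def rescale(z_raw) -> np.ndarray:
    """Affine map of a take to [0, 1]: (z − min) / (max − min)."""
    z = np.asarray(z_raw, dtype=float)
    lo, hi = float(np.min(z)), float(np.max(z))
    if hi <= lo:
        raise ValueError("constant signal cannot be rescaled")
    return (z - lo) / (hi - lo)


@dataclass(frozen=True)
class TapTake:
    """One tapping recording with its rescaled series."""

    z_raw: np.ndarray
    rate: float = 62.0
    label: str = "unknown"

    def __post_init__(self):
        object.__setattr__(self, "z_raw", np.asarray(self.z_raw, dtype=float))
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def z_sc(self) -> np.ndarray:
        return rescale(self.z_raw)

    @property
    def signal(self) -> SampledSignal:
        return SampledSignal(values=self.z_sc, rate=self.rate, label="z_sc")


def velocity(z_sc, rate: float) -> np.ndarray:
    """First-order finite-difference velocity; length = len(z) − 1."""
    z = np.asarray(z_sc, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 samples for a finite difference")
    return np.diff(z) * rate


def low_velocity_fraction(vel, threshold: float) -> float:
    """Fraction of samples with |v| below the threshold."""
    if threshold <= 0:
        return 0.0
    v = np.asarray(vel, dtype=float)
    return float(np.mean(np.abs(v) < threshold))


def _band_integral(freqs: np.ndarray, amp: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of amp over [lo, hi] with interpolated endpoints."""
    grid = np.union1d(freqs[(freqs > lo) & (freqs < hi)], [lo, hi])
    vals = np.interp(grid, freqs, amp)
    return float(np.trapezoid(vals, grid))


def band_integrals(spectrum: Spectrum, use_db: bool = False) -> tuple[float, float]:
    """(int1_4, int4_12): percentage band weights of the amplitude spectrum.

    Integrates the linear amplitude A(f) by default (``use_db=True`` switches
    to the dB representation for sensitivity analysis).  Requires the
    spectrum to span the full 0–31 Hz analysis band.
    """
    if spectrum.freqs[-1] < 31.0 - 1e-9:
        raise ValueError("spectrum must cover 0-31 Hz")
    amp = spectrum.amp_db if use_db else spectrum.amp_linear
    total = _band_integral(spectrum.freqs, amp, 0.0, 31.0)
    if total == 0:
        raise ValueError("zero total spectral weight")
    i14 = 100.0 * _band_integral(spectrum.freqs, amp, 1.0, 4.0) / total
    i412 = 100.0 * _band_integral(spectrum.freqs, amp, 4.0, 12.0) / total
    return i14, i412


@dataclass(frozen=True)
class PeriodMatrix:
    """Stack of per-period samples, resampled to a common (median) length.

    Row i holds period i (from peak k_i up to, but excluding, peak k_{i+1});
    the trailing partial period after the last detected peak is dropped.
    """

    rows: np.ndarray  # (m, n_median)
    peak_indices: np.ndarray  # the m peaks opening each period
    peak_amplitudes: np.ndarray  # A_i = z_sc(k_i)
    durations: np.ndarray  # T_i, seconds

    def __post_init__(self):
        if self.rows.ndim != 2:
            raise ValueError("rows must be a 2-D matrix")
        m = self.rows.shape[0]
        if not (len(self.peak_indices) == len(self.peak_amplitudes)
                == len(self.durations) == m):
            raise ValueError("per-period metadata length mismatch")

    @property
    def n_periods(self) -> int:
        return self.rows.shape[0]


def segment_periods(
    z_sc,
    rate: float,
    prominence: float = PEAK_PROMINENCE,
    min_separation_s: float = PEAK_MIN_SEPARATION_S,
) -> PeriodMatrix:
    """Split a rescaled take into tap periods delimited by local maxima.

    Peaks need a prominence of ``prominence`` (on the [0, 1] scale) and a
    minimum separation, which suppresses tremor ripple without losing fast
    taps.  Each inter-peak span is resampled to the median period length by
    linear interpolation.
    """
    z = np.asarray(z_sc, dtype=float)
    distance = max(int(round(min_separation_s * rate)), 1)
    peaks, _ = sps.find_peaks(z, prominence=prominence, distance=distance)
    if len(peaks) < 3:
        raise ValueError(
            f"only {len(peaks)} peaks found; need at least 3 to form periods"
        )
    lengths = np.diff(peaks)
    n_med = int(round(float(np.median(lengths))))
    rows = np.empty((len(peaks) - 1, n_med))
    for i in range(len(peaks) - 1):
        seg = z[peaks[i] : peaks[i + 1]]
        src = np.arange(len(seg))
        rows[i] = np.interp(np.linspace(0.0, len(seg) - 1, n_med), src, seg)
    return PeriodMatrix(
        rows=rows,
        peak_indices=peaks[:-1].copy(),
        peak_amplitudes=z[peaks[:-1]].copy(),
        durations=lengths / rate,
    )


def periodicity_measure(Z: PeriodMatrix) -> float:
    """pm = sigma_1^2 / sum(sigma_i^2) from the SVD of the period matrix.

    Equals 1 iff the matrix has rank one (all periods proportional); always
    in (0, 1].
    """
    if Z.rows.shape[0] < 2:
        raise ValueError("need at least 2 periods")
    s = svdvals(Z.rows)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("degenerate all-zero period matrix")
    return float(s[0] ** 2 / total)


def amxfr(Z: PeriodMatrix) -> float:
    """Mean amplitude-over-duration across periods, s^-1.

    The normalization divides by the number of summed periods (the same
    index set as A_i and T_i).
    """
    if np.any(Z.durations <= 0):
        raise ValueError("period durations must be positive")
    return float(np.mean(Z.peak_amplitudes / Z.durations))


def ftts(pm: float, amxfr_value: float) -> float:
    """Finger-tapping test score (pm − 0.6) · amxfr."""
    return (pm - 0.6) * amxfr_value


@dataclass(frozen=True)
class TapFeatures:
    int1_4: float
    int4_12: float
    pm: float
    amxfr: float
    ftts: float
    low_vel_frac: float
    n_periods: int
    label: str = "unknown"

    def subset(self, names) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)


def extract_features(
    take: TapTake,
    velocity_threshold: float = LOW_VELOCITY_THRESHOLD,
) -> TapFeatures:
    """Full feature vector of one take.

    The spectrum is computed on the rescaled coordinate with no low-frequency
    cutoff (0 dB reference z_sc = 1), so slow disease components are kept.
    """
    z = take.z_sc
    spec = dft_spectrum(take.signal, reference=1.0)
    i14, i412 = band_integrals(spec)
    Z = segment_periods(z, take.rate)
    pm = periodicity_measure(Z)
    am = amxfr(Z)
    vel = velocity(z, take.rate)
    return TapFeatures(
        int1_4=i14,
        int4_12=i412,
        pm=pm,
        amxfr=am,
        ftts=ftts(pm, am),
        low_vel_frac=low_velocity_fraction(vel, velocity_threshold),
        n_periods=Z.n_periods,
        label=take.label,
    )


def spectra_ttest(
    group_a: list,
    group_b: list,
    alpha: float = 0.05,
    use_db: bool = True,
) -> np.ndarray:
    """Per-bin equal-variance two-sample t-test between two spectrum groups.

    Returns a boolean flag per frequency bin, True where the hypothesis of a
    common amplitude distribution is rejected at level ``alpha``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 spectra per group")
    ref = group_a[0].freqs
    for s in list(group_a) + list(group_b):
        if len(s.freqs) != len(ref) or not np.allclose(s.freqs, ref):
            raise ValueError("spectra must share a common frequency grid")
    attr = "amp_db" if use_db else "amp_linear"
    a = np.array([getattr(s, attr) for s in group_a])
    b = np.array([getattr(s, attr) for s in group_b])
    _, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    return np.asarray(p) < alpha
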