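"""Welch spectral estimation and the band measures built on it.

All spectra use the same estimator setup: Hann window of 3 s (300 samples at
100 samples/s), 75% overlap, zero-padded to 2^16 FFT points (grid spacing
~0.0015 Hz), density scaling.  On a 10 s segment this averages 10 windowed
periodograms.

On top of the raw spectra this module provides:

* ``band_measure`` — spectral peak, the −3 dB (half-power) band around it,
  that band's integrated power and the total power in the 2–10 Hz analysis
  band.  The half-power bandwidth is a tremor-regularity measure: a regular
  tremor concentrates its power in a narrow line.
* ``cross_phase_deg`` — the absolute cross-spectral phase at the peak,
  folded to [0, 180]°; in-phase motion of the two axes gives ~0°,
  anti-phase motion ~180°.
* ``secondwise_concentration`` — the "1 s coherence" statistic: the record
  is cut into consecutive 1 s blocks, each block's Hann-windowed
  periodogram (auto, or cross-magnitude for an axis pair) is reduced to the
  ratio (half-power-band power) / (total 2–10 Hz power), and the mean,
  variance, skewness and kurtosis of the 10 ratios summarize how stable the
  spectral concentration is from second to second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

# Estimator parameters (shared by every spectrum in the pipeline)
WINDOW_SECONDS = 3.0
OVERLAP_FRACTION = 0.75
N_FFT = 2 ** 16
ANALYSIS_BAND = (2.0, 10.0)  # Hz


@dataclass
class Spectrum:
    freqs: np.ndarray
    values: np.ndarray          # real (auto, msc) or complex (cross)
    kind: str                   # "auto" | "cross" | "msc"
    df: float
    source_channels: tuple[str, ...] = ()


@dataclass
class BandMeasure:
    f_peak: float
    amp_peak: float
    band_lo: float
    band_hi: float
    bw_3db: float
    power_3db: float
    total_power: float


@dataclass
class SecondwiseConcentration:
    ratios: np.ndarray
    mean: float
    variance: float
    skewness: float
    kurtosis: float             # non-excess: exactly 3 for a normal sample
    flagged_blocks: int = 0     # all-zero blocks whose ratio was set to 0


def _welch_args(fs: float) -> dict:
    nperseg = int(round(WINDOW_SECONDS * fs))
    return dict(
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * OVERLAP_FRACTION)),
        nfft=N_FFT,
        detrend=False,
        scaling="density",
    )


def welch_auto(x: np.ndarray, fs: float, channels: tuple[str, ...] = ()) -> Spectrum:
    """Welch auto power spectral density of one channel."""
    if len(x) < int(round(WINDOW_SECONDS * fs)):
        raise ValueError("segment shorter than one Welch window")
    f, pxx = signal.welch(x, **_welch_args(fs))
    return Spectrum(f, pxx, "auto", fs / N_FFT, channels)


def welch_cross(x: np.ndarray, y: np.ndarray, fs: float,
                channels: tuple[str, ...] = ()) -> Spectrum:
    """Welch cross power spectral density (complex) of a channel pair."""
    if len(x) < int(round(WINDOW_SECONDS * fs)):
        raise ValueError("segment shorter than one Welch window")
    f, pxy = signal.csd(x, y, **_welch_args(fs))
    return Spectrum(f, pxy, "cross", fs / N_FFT, channels)


def msc(x: np.ndarray, y: np.ndarray, fs: float,
        channels: tuple[str, ...] = ()) -> Spectrum:
    """Magnitude squared coherence |S_xy|^2 / (S_xx S_yy), same windowing."""
    nperseg = int(round(WINDOW_SECONDS * fs))
    if len(x) < 2 * nperseg - int(round(nperseg * OVERLAP_FRACTION)):
        raise ValueError("fewer than two averaging windows: coherence degenerate")
    args = _welch_args(fs)
    args.pop("scaling")
    f, cxy = signal.coherence(x, y, **args)
    return Spectrum(f, np.clip(cxy, 0.0, 1.0), "msc", fs / N_FFT, channels)


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> slice:
    lo = int(np.searchsorted(freqs, band[0], side="left"))
    hi = int(np.searchsorted(freqs, band[1], side="right"))
    if hi <= lo:
        raise ValueError(f"spectrum does not cover band {band}")
    return slice(lo, hi)


def peak_frequency(s: Spectrum, band: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Frequency of the magnitude maximum within `band` (lowest bin on ties)."""
    sl = _band_slice(s.freqs, band)
    mag = np.abs(s.values[sl])
    return float(s.freqs[sl][int(np.argmax(mag))])


def band_measure(s: Spectrum, search_band: tuple[float, float] = ANALYSIS_BAND) -> BandMeasure:
    """Peak, −3 dB band, band power and total power of a spectrum.

    The −3 dB band is the maximal contiguous frequency run containing the
    peak where the magnitude stays at or above half the peak magnitude.
    Powers are trapezoidal integrals of the magnitude density.
    """
    sl = _band_slice(s.freqs, search_band)
    f = s.freqs[sl]
    mag = np.abs(s.values[sl])
    i_peak = int(np.argmax(mag))
    peak = mag[i_peak]
    half = peak / 2.0
    lo = i_peak
    while lo > 0 and mag[lo - 1] >= half:
        lo -= 1
    hi = i_peak
    while hi < len(mag) - 1 and mag[hi + 1] >= half:
        hi += 1
    power_3db = float(np.trapezoid(mag[lo:hi + 1], f[lo:hi + 1])) if hi > lo else 0.0
    total_power = float(np.trapezoid(mag, f))
    return BandMeasure(
        f_peak=float(f[i_peak]),
        amp_peak=float(peak),
        band_lo=float(f[lo]),
        band_hi=float(f[hi]),
        bw_3db=float(f[hi] - f[lo]),
        power_3db=power_3db,
        total_power=total_power,
    )


def value_at(s: Spectrum, f0: float) -> complex | float:
    """Spectrum value at the grid bin nearest f0."""
    i = int(np.argmin(np.abs(s.freqs - f0)))
    return s.values[i]


def cross_phase_deg(s: Spectrum, f_peak: float) -> float:
    """Absolute cross-spectral phase at the bin nearest f_peak, in [0, 180]°."""
    v = value_at(s, f_peak)
    if np.abs(v) == 0.0:
        raise ValueError(f"zero cross-spectral magnitude at {f_peak} Hz")
    return float(abs(np.degrees(np.angle(v))))


# ---------------------------------------------------------------------------
# Per-second spectral concentration ("1 s coherence")
# ---------------------------------------------------------------------------

def _block_periodogram(block: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    w = signal.get_window("hann", len(block))
    spec = np.fft.rfft(block * w, n=N_FFT)
    freqs = np.fft.rfftfreq(N_FFT, 1.0 / fs)
    return freqs, spec


def secondwise_concentration(
    x: np.ndarray,
    y: np.ndarray | None = None,
    fs: float = 100.0,
) -> SecondwiseConcentration:
    """Second-by-second (half-power power)/(total power) ratios and moments.

    With one channel the per-block spectrum is the Hann periodogram; with a
    pair it is the magnitude of the cross periodogram X(f)·conj(Y(f)).
    Moments over the ratios are population moments; kurtosis is non-excess
    (m4/m2^2, normal → 3).  An all-zero block has no defined ratio; it is
    recorded as 0 and counted in ``flagged_blocks``.
    """
    n_block = int(round(fs))
    n_blocks = len(x) // n_block
    if n_blocks < 2:
        raise ValueError("need at least 2 s of signal")
    ratios = np.empty(n_blocks)
    flagged = 0
    for k in range(n_blocks):
        bx = x[k * n_block:(k + 1) * n_block]
        if y is None:
            freqs, sx = _block_periodogram(bx, fs)
            mag = np.abs(sx) ** 2
        else:
            by = y[k * n_block:(k + 1) * n_block]
            freqs, sx = _block_periodogram(bx, fs)
            _, sy = _block_periodogram(by, fs)
            mag = np.abs(sx * np.conj(sy))
        spec = Spectrum(freqs, mag, "auto", fs / N_FFT)
        if not np.any(mag[_band_slice(freqs, ANALYSIS_BAND)] > 0):
            ratios[k] = 0.0
            flagged += 1
            continue
        bm = band_measure(spec)
        ratios[k] = bm.power_3db / bm.total_power if bm.total_power > 0 else 0.0
    m = float(np.mean(ratios))
    d = ratios - m
    m2 = float(np.mean(d ** 2))
    if m2 > 0:
        skew = float(np.mean(d ** 3) / m2 ** 1.5)
        kurt = float(np.mean(d ** 4) / m2 ** 2)
    else:
        skew, kurt = 0.0, 0.0
    return SecondwiseConcentration(ratios, m, m2, skew, kurt, flagged)
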