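"""The canonical 63-feature vector of one inertial tremor segment.

Feature families (Table units in parentheses):

* spectral peak frequencies of each axis PSD and of the a_y–a_z
  cross-spectrum (Hz);
* spectral densities at the peak for the a_y–a_z cross-spectrum and the
  a_y, a_z and w_x auto-spectra (m^2/s^4/Hz, (deg/s)^2/Hz);
* a_y–a_z coupling: Pearson correlation, magnitude squared coherence at
  the peak, absolute cross-spectral phase (deg);
* half-power (−3 dB) band powers and bandwidths of the cross-spectrum and
  the w_x, a_y, a_z auto-spectra;
* per-second spectral-concentration statistics (mean/variance/skewness/
  kurtosis) for the a_y–a_z cross-spectrum and the w_x auto-spectrum;
* peak-to-peak amplitudes of all six filtered channels (accelerometer in
  mG, gyroscope in deg/s) and the two vectorial magnitudes;
* the sum of the first two harmonics on a_z (fundamental + 2nd harmonic
  spectral densities);
* db2 3-level wavelet band summaries (RMS of the a3/d3/d2/d1 coefficient
  arrays) of each *raw* channel — raw because the approximation band keeps
  the gravity component that filtering would remove.

All spectral and time-domain features are computed on the 2–10 Hz filtered
channels; only the wavelet summaries see the raw channels.  Accelerations
are converted g → m/s^2 before spectral estimation and before the wavelet
transform so densities come out in m^2/s^4/Hz and summaries in m/s^2.
"""

from __future__ import annotations

import math

import numpy as np
import pywt

from .preprocess import bandpass, periodicity_check, QCResult
from .segmentio import FEATURE_NAMES, SegmentRecord
from .spectral import (
    band_measure,
    cross_phase_deg,
    msc,
    secondwise_concentration,
    value_at,
    welch_auto,
    welch_cross,
)

G_TO_MS2 = 9.80665


class NotClassifiableError(Exception):
    """Segment failed the periodicity quality check."""

    def __init__(self, qc: QCResult):
        super().__init__(f"segment not classifiable: {qc.reason}")
        self.qc = qc


def peak_to_peak(x: np.ndarray) -> float:
    """max − min of a channel, in the channel's own units."""
    return float(np.ptp(x))


def vector_magnitude(p2p_x: float, p2p_y: float, p2p_z: float) -> float:
    return math.sqrt(p2p_x ** 2 + p2p_y ** 2 + p2p_z ** 2)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input to Pearson correlation")
    return float(np.corrcoef(x, y)[0, 1])


def harmonics_sum_az(spectrum, f_peak: float) -> float:
    """Spectral density at the fundamental plus at the 2nd harmonic."""
    if 2 * f_peak > spectrum.freqs[-1]:
        raise ValueError("2nd harmonic beyond Nyquist")
    return float(np.abs(value_at(spectrum, f_peak)) + np.abs(value_at(spectrum, 2 * f_peak)))


def wavelet_band_summaries(x: np.ndarray) -> tuple[float, float, float, float]:
    """RMS of the (a3, d3, d2, d1) bands of a db2 3-level decomposition.

    Periodic extension ('periodization') keeps the transform orthonormal,
    so a constant input c yields an a3 band of value c·2^{3/2}.
    """
    coeffs = pywt.wavedec(x, "db2", level=3, mode="periodization")
    a3, d3, d2, d1 = coeffs
    rms = lambda c: float(np.sqrt(np.mean(np.square(c))))
    return rms(a3), rms(d3), rms(d2), rms(d1)


def extract_features(seg: SegmentRecord, check_qc: bool = True) -> dict[str, float]:
    """Compute the 63 canonical features of one segment.

    Raises :class:`NotClassifiableError` if the segment fails the
    periodicity quality check (disable with ``check_qc=False`` for
    diagnostics only).  Deterministic: identical segments give bitwise
    identical vectors.
    """
    filt = bandpass(seg)
    if check_qc:
        qc = periodicity_check(filt)
        if not qc.passed:
            raise NotClassifiableError(qc)

    fs = seg.fs
    # filtered channels in physical units for spectral densities
    ay = filt.a_y * G_TO_MS2
    az = filt.a_z * G_TO_MS2
    ax = filt.a_x * G_TO_MS2
    wx, wy, wz = filt.w_x, filt.w_y, filt.w_z

    psd = {
        "a_x": welch_auto(ax, fs), "a_y": welch_auto(ay, fs), "a_z": welch_auto(az, fs),
        "w_x": welch_auto(wx, fs), "w_y": welch_auto(wy, fs), "w_z": welch_auto(wz, fs),
    }
    cross = welch_cross(ay, az, fs, ("a_y", "a_z"))
    coh = msc(ay, az, fs, ("a_y", "a_z"))

    bm_cross = band_measure(cross)
    bm = {name: band_measure(psd[name]) for name in ("w_x", "a_y", "a_z")}
    conc_cross = secondwise_concentration(ay, az, fs=fs)
    conc_wx = secondwise_concentration(wx, fs=fs)

    f: dict[str, float] = {}
    f["freq_ayaz_cross"] = bm_cross.f_peak
    f["amp_ayaz_cross"] = bm_cross.amp_peak
    f["amp_wx"] = bm["w_x"].amp_peak
    f["msc_ayaz"] = float(np.real(value_at(coh, bm_cross.f_peak)))
    f["corr_ayaz"] = pearson_corr(filt.a_y, filt.a_z)
    f["phase_ayaz_deg"] = cross_phase_deg(cross, bm_cross.f_peak)
    f["p3db_ayaz"] = bm_cross.power_3db
    f["p3db_wx"] = bm["w_x"].power_3db
    f["p3db_ay"] = bm["a_y"].power_3db
    f["p3db_az"] = bm["a_z"].power_3db
    f["bw3db_ayaz"] = bm_cross.bw_3db
    f["bw3db_wx"] = bm["w_x"].bw_3db
    f["bw3db_ay"] = bm["a_y"].bw_3db
    f["bw3db_az"] = bm["a_z"].bw_3db
    f["amp_ay"] = bm["a_y"].amp_peak
    f["amp_az"] = bm["a_z"].amp_peak
    f["conc1s_mean_ayaz"] = conc_cross.mean
    f["conc1s_mean_wx"] = conc_wx.mean
    f["conc1s_var_ayaz"] = conc_cross.variance
    f["conc1s_var_wx"] = conc_wx.variance
    f["conc1s_skew_ayaz"] = conc_cross.skewness
    f["conc1s_skew_wx"] = conc_wx.skewness
    f["conc1s_kurt_ayaz"] = conc_cross.kurtosis
    f["conc1s_kurt_wx"] = conc_wx.kurtosis
    for name, key in (("a_x", "freq_ax"), ("a_y", "freq_ay"), ("a_z", "freq_az"),
                      ("w_x", "freq_wx"), ("w_y", "freq_wy"), ("w_z", "freq_wz")):
        f[key] = band_measure(psd[name]).f_peak

    p2p_acc = {n: peak_to_peak(getattr(filt, n)) * 1000.0 for n in ("a_x", "a_y", "a_z")}
    p2p_gyro = {n: peak_to_peak(getattr(filt, n)) for n in ("w_x", "w_y", "w_z")}
    f["p2p_ax"], f["p2p_ay"], f["p2p_az"] = p2p_acc["a_x"], p2p_acc["a_y"], p2p_acc["a_z"]
    f["p2p_acc_mag"] = vector_magnitude(*p2p_acc.values())
    f["p2p_wx"], f["p2p_wy"], f["p2p_wz"] = p2p_gyro["w_x"], p2p_gyro["w_y"], p2p_gyro["w_z"]
    f["p2p_gyro_mag"] = vector_magnitude(*p2p_gyro.values())

    f["harm2_az"] = harmonics_sum_az(psd["a_z"], bm["a_z"].f_peak)

    raw = {
        "ax": seg.a_x * G_TO_MS2, "ay": seg.a_y * G_TO_MS2, "az": seg.a_z * G_TO_MS2,
        "wx": seg.w_x, "wy": seg.w_y, "wz": seg.w_z,
    }
    for short, x in raw.items():
        a3, d3, d2, d1 = wavelet_band_summaries(x)
        f[f"wav_{short}_a3"] = a3
        f[f"wav_{short}_d3"] = d3
        f[f"wav_{short}_d2"] = d2
        f[f"wav_{short}_d1"] = d1

    assert set(f) == set(FEATURE_NAMES)
    return {name: f[name] for name in FEATURE_NAMES}
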