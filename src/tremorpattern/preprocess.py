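"""Band-pass filtering and the periodicity quality check.

Rest tremor lives in the 4–8 Hz range; all channels are band-pass filtered
to 2–10 Hz with a 4th-order Butterworth applied forward and backward
(zero phase, squared magnitude response), which removes the gravity offset
and out-of-band noise without shifting oscillation peaks in time.

A segment is accepted for feature extraction only if it actually contains
tremor: the dominant (largest peak-to-peak) acceleration axis must show a
spectral magnitude peak within 3–8 Hz, and its zero-crossing count must be
at least half the number a pure sine at that peak frequency would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .segmentio import SegmentRecord
from .spectral import welch_auto, peak_frequency

PEAK_SEARCH_BAND = (2.0, 10.0)   # Hz, where the spectral maximum is located
PEAK_ACCEPT_BAND = (3.0, 8.0)    # Hz, where it must fall to pass QC


@dataclass
class FilterSpec:
    order: int = 4
    band: tuple[float, float] = (2.0, 10.0)

    def validate(self, fs: float) -> None:
        if not (0.0 < self.band[0] < self.band[1] < fs / 2.0):
            raise ValueError(f"band {self.band} outside (0, {fs / 2}) Hz")
        if self.order <= 0 or self.order % 2:
            raise ValueError("filter order must be positive and even")


@dataclass
class QCResult:
    passed: bool
    dominant_axis: str
    f_peak: float
    zero_crossings: int
    zc_threshold: int
    reason: str = ""


def bandpass_channel(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Forward-backward Butterworth band-pass of one channel."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    sos = signal.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    # odd-reflection padding well beyond the filter's transient (~3 time
    # constants of the 2 Hz edge)
    padlen = min(len(x) - 1, int(3 * fs / spec.band[0]))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def bandpass(seg: SegmentRecord, spec: FilterSpec | None = None) -> SegmentRecord:
    """Filter all six channels identically; returns a new record."""
    filtered = {
        name: bandpass_channel(x, seg.fs, spec) for name, x in seg.channels().items()
    }
    return seg.with_channels(**filtered)


def dominant_axis(seg: SegmentRecord) -> str:
    """Accelerometer axis with the largest peak-to-peak amplitude.

    Ties are broken in the fixed order a_y, a_z, a_x (the flexo-extension
    axes first).
    """
    order = ("a_y", "a_z", "a_x")
    p2p = {name: float(np.ptp(getattr(seg, name))) for name in order}
    return max(order, key=lambda name: (p2p[name], -order.index(name)))


def periodicity_check(seg: SegmentRecord) -> QCResult:
    """Accept or reject a *filtered* segment on periodicity grounds.

    f_peak is the global Welch-spectrum maximum of the dominant
    acceleration axis within 2–10 Hz; the segment passes if f_peak lies in
    [3, 8] Hz and the dominant axis crosses zero at least ceil(f_peak * T)
    times (half the 2·f_peak·T crossings of a pure sine).  Failure is a
    value, not an error.
    """
    axis = dominant_axis(seg)
    x = getattr(seg, axis)
    spectrum = welch_auto(x, seg.fs, (axis,))
    f_peak = peak_frequency(spectrum, PEAK_SEARCH_BAND)
    xc = x - np.mean(x)
    zc = int(np.count_nonzero(np.signbit(xc[1:]) != np.signbit(xc[:-1])))
    threshold = int(np.ceil(f_peak * seg.duration))
    if not (PEAK_ACCEPT_BAND[0] <= f_peak <= PEAK_ACCEPT_BAND[1]):
        return QCResult(False, axis, f_peak, zc, threshold, "peak_out_of_band")
    if zc < threshold:
        return QCResult(False, axis, f_peak, zc, threshold, "aperiodic")
    return QCResult(True, axis, f_peak, zc, threshold)
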