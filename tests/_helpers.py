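"""Shared constructors for synthetic test signals."""

from __future__ import annotations

import numpy as np

from tremorpattern import SegmentRecord

FS = 100.0
N = 1000


def make_segment(seg_id: str = "seg", fs: float = FS, n: int = N,
                 label: str = "unknown", **channels: np.ndarray) -> SegmentRecord:
    """Segment with given channels; unspecified channels are zero."""
    base = {name: np.zeros(n) for name in ("a_x", "a_y", "a_z", "w_x", "w_y", "w_z")}
    base.update(channels)
    return SegmentRecord(segment_id=seg_id, fs=fs, label=label,
                         provenance="synthetic", **base)


def sine(freq: float, amp: float = 1.0, phase: float = 0.0,
         fs: float = FS, n: int = N) -> np.ndarray:
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)
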