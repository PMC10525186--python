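"""Data model and file I/O for inertial tremor segments, feature tables and models.

A *segment* is a 10 s, 100 sample/s recording from a 6-axis inertial
measurement unit worn on the tremulous hand: three acceleration channels
(``a_x, a_y, a_z``, in g) and three angular-rate channels
(``w_x, w_y, w_z``, in deg/s).  Segments may carry a tremor-pattern label:
``"A"`` (alternating antagonist-muscle contraction, the Parkinsonian
pattern) or ``"S"`` (synchronous contraction, the essential-tremor-like
pattern).

On disk a segment is a plain CSV file, one row per sample, preceded by a
single ``#``-prefixed JSON metadata header.  Feature tables are CSV with a
``segment_id`` and ``label`` column followed by the 63 canonical feature
columns.  Model artifacts are directories holding a ``model.json`` metadata
document plus an opaque fitted-state blob.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Canonical feature names
# ---------------------------------------------------------------------------

#: The 63 canonical feature names, in fixed order.  Every producer and
#: consumer of feature vectors (extractor, statistics table, model subsets)
#: uses exactly this list.
FEATURE_NAMES: tuple[str, ...] = (
    # cross-spectral / coupling features on the flexo-extension axes
    "freq_ayaz_cross",      # a_y-a_z cross-spectral peak frequency (Hz)
    "amp_ayaz_cross",       # cross-spectral density at the peak (m^2/s^4/Hz)
    "amp_wx",               # w_x spectral density at the peak ((deg/s)^2/Hz)
    "msc_ayaz",             # a_y-a_z magnitude squared coherence at the peak
    "corr_ayaz",            # Pearson correlation of filtered a_y and a_z
    "phase_ayaz_deg",       # |cross-spectral phase| at the peak (deg, 0-180)
    # 3 dB band powers
    "p3db_ayaz",            # a_y-a_z cross-spectrum (m^2/s^4)
    "p3db_wx",              # ((deg/s)^2)
    "p3db_ay",              # (m^2/s^4)
    "p3db_az",
    # 3 dB bandwidths (Hz)
    "bw3db_ayaz",
    "bw3db_wx",
    "bw3db_ay",
    "bw3db_az",
    # single-axis accelerometer spectral amplitudes (m^2/s^4/Hz)
    "amp_ay",
    "amp_az",
    # second-by-second spectral concentration ("1 s coherence") statistics
    "conc1s_mean_ayaz",
    "conc1s_mean_wx",
    "conc1s_var_ayaz",
    "conc1s_var_wx",
    "conc1s_skew_ayaz",
    "conc1s_skew_wx",
    "conc1s_kurt_ayaz",
    "conc1s_kurt_wx",
    # single-axis spectral peak frequencies (Hz)
    "freq_ax",
    "freq_ay",
    "freq_az",
    "freq_wx",
    "freq_wy",
    "freq_wz",
    # peak-to-peak amplitudes (accelerometer in mG, gyroscope in deg/s)
    "p2p_ax",
    "p2p_ay",
    "p2p_az",
    "p2p_acc_mag",          # vectorial magnitude of the accelerometer p2p triplet
    "p2p_wx",
    "p2p_wy",
    "p2p_wz",
    "p2p_gyro_mag",         # vectorial magnitude of the gyroscope p2p triplet
    # harmonic content
    "harm2_az",             # sum of first two harmonics on a_z (m^2/s^4/Hz)
    # wavelet band summaries: db2, 3 levels, RMS per band
    # (accelerometer in m/s^2, gyroscope in deg/s)
    "wav_ax_a3", "wav_ax_d3", "wav_ax_d2", "wav_ax_d1",
    "wav_ay_a3", "wav_ay_d3", "wav_ay_d2", "wav_ay_d1",
    "wav_az_a3", "wav_az_d3", "wav_az_d2", "wav_az_d1",
    "wav_wx_a3", "wav_wx_d3", "wav_wx_d2", "wav_wx_d1",
    "wav_wy_a3", "wav_wy_d3", "wav_wy_d2", "wav_wy_d1",
    "wav_wz_a3", "wav_wz_d3", "wav_wz_d2", "wav_wz_d1",
)

assert len(FEATURE_NAMES) == 63

CHANNEL_NAMES: tuple[str, ...] = ("a_x", "a_y", "a_z", "w_x", "w_y", "w_z")

#: Sensor full-scale ranges (clip limits for the simulator, validation
#: bounds for file input): accelerometer +/-2 g, gyroscope +/-500 deg/s.
ACC_FULL_SCALE_G = 2.0
GYRO_FULL_SCALE_DPS = 500.0

_CSV_COLUMNS = ("t_s", "ax_g", "ay_g", "az_g", "wx_dps", "wy_dps", "wz_dps")


class SegmentFormatError(ValueError):
    """Raised when a segment file violates the on-disk contract."""


# ---------------------------------------------------------------------------
# SegmentRecord
# ---------------------------------------------------------------------------

@dataclass
class SegmentRecord:
    """One 6-channel inertial recording segment.

    Accelerations are in g, angular rates in deg/s — the raw units streamed
    by the sensor.  Unit conversions (g to m/s^2, g to mG) happen inside
    feature extraction only.
    """

    segment_id: str
    subject_id: str = ""
    fs: float = 100.0
    a_x: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a_y: np.ndarray = field(default_factory=lambda: np.zeros(0))
    a_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    w_x: np.ndarray = field(default_factory=lambda: np.zeros(0))
    w_y: np.ndarray = field(default_factory=lambda: np.zeros(0))
    w_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    label: str = "unknown"          # "A", "S" or "unknown"
    provenance: str = "measured"    # "measured" or "synthetic"
    gen_params_id: str | None = None

    @property
    def n_samples(self) -> int:
        return int(self.a_x.shape[0])

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNEL_NAMES}

    def acc(self) -> np.ndarray:
        """Accelerometer channels stacked (3, n) in g."""
        return np.vstack([self.a_x, self.a_y, self.a_z])

    def gyro(self) -> np.ndarray:
        """Gyroscope channels stacked (3, n) in deg/s."""
        return np.vstack([self.w_x, self.w_y, self.w_z])

    def validate(self) -> None:
        """Raise ``SegmentFormatError`` on any violated invariant."""
        n = self.n_samples
        for name, x in self.channels().items():
            if x.shape != (n,):
                raise SegmentFormatError(
                    f"channel {name} has {x.shape[0]} samples, expected {n}"
                )
            if not np.all(np.isfinite(x)):
                raise SegmentFormatError(f"channel {name} contains non-finite values")
        if self.fs <= 20.0:
            raise SegmentFormatError(
                f"fs={self.fs} samples/s puts the 10 Hz analysis band at or "
                "above Nyquist"
            )
        if self.label not in ("A", "S", "unknown"):
            raise SegmentFormatError(f"label must be A, S or unknown, got {self.label!r}")
        for name in ("a_x", "a_y", "a_z"):
            if np.any(np.abs(getattr(self, name)) > ACC_FULL_SCALE_G + 1e-12):
                raise SegmentFormatError(
                    f"{name} exceeds the ±{ACC_FULL_SCALE_G} g sensor range"
                )
        for name in ("w_x", "w_y", "w_z"):
            if np.any(np.abs(getattr(self, name)) > GYRO_FULL_SCALE_DPS + 1e-9):
                raise SegmentFormatError(
                    f"{name} exceeds the ±{GYRO_FULL_SCALE_DPS} deg/s sensor range"
                )

    def with_channels(self, **channels: np.ndarray) -> "SegmentRecord":
        """Return a copy with some channels replaced (used by filtering)."""
        return dataclasses.replace(self, **channels)


# ---------------------------------------------------------------------------
# Segment CSV I/O
# ---------------------------------------------------------------------------

def write_segment(seg: SegmentRecord, path: str | Path) -> Path:
    """Write a segment to CSV with a ``#``-prefixed JSON metadata header.

    The round-trip through :func:`read_segment` is lossless to at least
    nine significant digits (values are written with ``repr``-exact float
    formatting).
    """
    seg.validate()
    path = Path(path)
    meta = {
        "segment_id": seg.segment_id,
        "subject_id": seg.subject_id,
        "fs": seg.fs,
        "n_samples": seg.n_samples,
        "label": seg.label,
        "provenance": seg.provenance,
        "gen_params_id": seg.gen_params_id,
    }
    t = np.arange(seg.n_samples) / seg.fs
    cols = [t, seg.a_x, seg.a_y, seg.a_z, seg.w_x, seg.w_y, seg.w_z]
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        for row in zip(*cols):
            fh.write(",".join(format(v, ".12g") for v in row) + "\n")
    return path


def read_segment(path: str | Path) -> SegmentRecord:
    """Read a segment CSV written by :func:`write_segment`.

    Raises :class:`SegmentFormatError` naming the offending line for a
    malformed header, wrong column count, non-numeric cell, or a declared
    sample count that does not match the data.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise SegmentFormatError(f"{path}: line 1: missing '#' JSON metadata header")
    try:
        meta = json.loads(lines[0].lstrip("# "))
    except json.JSONDecodeError as exc:
        raise SegmentFormatError(f"{path}: line 1: malformed JSON header: {exc}") from exc
    if len(lines) < 2 or lines[1].split(",") != list(_CSV_COLUMNS):
        raise SegmentFormatError(
            f"{path}: line 2: expected column header {','.join(_CSV_COLUMNS)}"
        )
    data: list[list[float]] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != len(_CSV_COLUMNS):
            raise SegmentFormatError(
                f"{path}: line {lineno}: expected {len(_CSV_COLUMNS)} columns, "
                f"got {len(cells)}"
            )
        try:
            data.append([float(c) for c in cells])
        except ValueError as exc:
            raise SegmentFormatError(f"{path}: line {lineno}: non-numeric cell") from exc
    arr = np.asarray(data, dtype=float)
    declared = meta.get("n_samples")
    if declared is not None and declared != arr.shape[0]:
        raise SegmentFormatError(
            f"{path}: header declares n_samples={declared} but file has "
            f"{arr.shape[0]} data rows"
        )
    seg = SegmentRecord(
        segment_id=str(meta.get("segment_id", path.stem)),
        subject_id=str(meta.get("subject_id", "")),
        fs=float(meta.get("fs", 100.0)),
        a_x=arr[:, 1].copy(), a_y=arr[:, 2].copy(), a_z=arr[:, 3].copy(),
        w_x=arr[:, 4].copy(), w_y=arr[:, 5].copy(), w_z=arr[:, 6].copy(),
        label=str(meta.get("label", "unknown")),
        provenance=str(meta.get("provenance", "measured")),
        gen_params_id=meta.get("gen_params_id"),
    )
    try:
        seg.validate()
    except SegmentFormatError as exc:
        raise SegmentFormatError(f"{path}: {exc}") from exc
    return seg


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def feature_table(rows: Iterable[tuple[str, str, dict[str, float]]]) -> pd.DataFrame:
    """Build a feature table from ``(segment_id, label, features)`` rows."""
    records = []
    for segment_id, label, feats in rows:
        rec = {"segment_id": segment_id, "label": label}
        rec.update({name: feats[name] for name in FEATURE_NAMES})
        records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=["segment_id", "label", *FEATURE_NAMES]
    )


def validate_feature_table(ft: pd.DataFrame) -> None:
    missing = [n for n in FEATURE_NAMES if n not in ft.columns]
    if missing:
        raise SegmentFormatError(f"feature table missing columns: {missing}")
    extra = [
        c for c in ft.columns
        if c not in FEATURE_NAMES and c not in ("segment_id", "label")
    ]
    if extra:
        raise SegmentFormatError(f"feature table has unknown columns: {extra}")
    if ft[list(FEATURE_NAMES)].isna().any().any():
        bad = ft.columns[ft.isna().any()].tolist()
        raise SegmentFormatError(f"feature table has missing values in: {bad}")


def write_feature_table(ft: pd.DataFrame, path: str | Path) -> Path:
    validate_feature_table(ft)
    path = Path(path)
    ordered = ft[["segment_id", "label", *FEATURE_NAMES]]
    ordered.to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    ft = pd.read_csv(path, comment="#")
    validate_feature_table(ft)
    ft = ft[["segment_id", "label", *FEATURE_NAMES]]
    return ft.astype({name: float for name in FEATURE_NAMES})


# ---------------------------------------------------------------------------
# Model artifacts
# ---------------------------------------------------------------------------

@dataclass
class ModelArtifact:
    """A trained classifier plus the metadata needed to apply and audit it.

    ``feature_subset`` is always a prefix of ``ranking`` (the full
    importance-sorted feature list); classification requires every name in
    the subset to be present in the input.
    """

    algorithm: str                      # "RF" or "XGB"
    hyperparameters: dict
    ranking: list[str]                  # all 63 names, importance-sorted
    feature_subset: list[str]           # prefix of `ranking` actually used
    fitted_model: object                # opaque fitted sklearn/xgboost estimator
    training_metrics: dict | None = None
    seed: int | None = None
    created: str | None = None

    def __post_init__(self) -> None:
        if self.ranking[: len(self.feature_subset)] != list(self.feature_subset):
            raise ValueError("feature_subset must be a prefix of the stored ranking")


def save_model(artifact: ModelArtifact, model_dir: str | Path) -> Path:
    import joblib

    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "algorithm": artifact.algorithm,
        "hyperparameters": artifact.hyperparameters,
        "ranking": artifact.ranking,
        "feature_subset": artifact.feature_subset,
        "training_metrics": artifact.training_metrics,
        "seed": artifact.seed,
        "created": artifact.created,
    }
    (model_dir / "model.json").write_text(json.dumps(meta, indent=2, default=float))
    joblib.dump(artifact.fitted_model, model_dir / "fitted_state.joblib")
    return model_dir


def load_model(model_dir: str | Path) -> ModelArtifact:
    import joblib

    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "model.json").read_text())
    fitted = joblib.load(model_dir / "fitted_state.joblib")
    return ModelArtifact(
        algorithm=meta["algorithm"],
        hyperparameters=meta["hyperparameters"],
        ranking=meta["ranking"],
        feature_subset=meta["feature_subset"],
        fitted_model=fitted,
        training_metrics=meta.get("training_metrics"),
        seed=meta.get("seed"),
        created=meta.get("created"),
    )
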