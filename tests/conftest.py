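"""Session-scoped synthetic-experiment fixtures shared across test modules.

The expensive artifacts (the 168-segment dataset at the reference study
size, its feature table, and the trained RF/XGB experiments) are computed
once per session and reused by the statistics, learning and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import tremorpattern as tp
from tremorpattern.segmentio import feature_table


@pytest.fixture(scope="session")
def dataset168() -> list[tp.SegmentRecord]:
    """91 alternating + 77 synchronous segments, matching the study's counts."""
    return tp.generate_class("A", 91, 42) + tp.generate_class("S", 77, 42)


@pytest.fixture(scope="session")
def features168(dataset168) -> pd.DataFrame:
    rows = []
    for seg in dataset168:
        rows.append((seg.segment_id, seg.label, tp.extract_features(seg, check_qc=True)))
    return feature_table(rows)


@pytest.fixture(scope="session")
def experiment(features168) -> dict:
    """Full learning procedure (split/rank/incremental/CV/evaluate), both models."""
    out = {}
    for algorithm in ("RF", "XGB"):
        cfg = tp.TrainConfig(algorithm=algorithm, seed=42)
        train, test = tp.split_dataset(features168, cfg)
        ranking = tp.rank_features(train, cfg)
        artifact, curve = tp.incremental_train(train, test, ranking, cfg)
        report = tp.evaluate(artifact, test)
        out[algorithm] = {
            "cfg": cfg, "train": train, "test": test, "ranking": ranking,
            "artifact": artifact, "curve": curve, "report": report,
        }
    return out
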