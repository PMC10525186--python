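"""Learning procedure: splitting, ranking, CV shape, metrics, classification."""

import numpy as np
import pandas as pd
import pytest

import tremorpattern as tp
from tremorpattern.mlpattern import (
    TrainConfig,
    _confusion_metrics,
    cross_validate,
    evaluate,
    incremental_train,
    rank_features,
    split_dataset,
)
from tremorpattern.segmentio import FEATURE_NAMES, ModelArtifact, feature_table

from _helpers import make_segment, sine


def _informative_table(rng, n_a=40, n_s=40, informative=("amp_wx",), sep=6.0):
    rows = []
    for label, n in (("A", n_a), ("S", n_s)):
        for i in range(n):
            feats = {name: float(rng.standard_normal()) for name in FEATURE_NAMES}
            if label == "A":
                for name in informative:
                    feats[name] += sep
            rows.append((f"{label}{i}", label, feats))
    return feature_table(rows)


class TestSplit:
    def test_study_sized_split_is_stratified_84_84(self, features168):
        cfg = TrainConfig(seed=0)
        train, test = split_dataset(features168, cfg)
        assert len(train) == len(test) == 84
        for half in (train, test):
            counts = half["label"].value_counts()
            assert counts["A"] in (45, 46)
            assert counts["S"] in (38, 39)

    def test_partition_and_determinism(self, features168):
        cfg = TrainConfig(seed=5)
        tr1, te1 = split_dataset(features168, cfg)
        tr2, te2 = split_dataset(features168, cfg)
        assert sorted(tr1.segment_id) == sorted(tr2.segment_id)
        ids = set(tr1.segment_id) | set(te1.segment_id)
        assert ids == set(features168.segment_id)
        assert not (set(tr1.segment_id) & set(te1.segment_id))

    def test_split_independent_of_cv_stream(self, features168):
        """The split is keyed by its own derived seed, so equal root seeds
        give equal splits regardless of what the CV stream consumes."""
        cfg = TrainConfig(seed=5)
        assert cfg.split_seed != cfg.cv_seed
        tr1, _ = split_dataset(features168, cfg)
        tr2, _ = split_dataset(features168, TrainConfig(algorithm="XGB", seed=5))
        assert list(tr1.segment_id) == list(tr2.segment_id)


class TestRanking:
    @pytest.mark.parametrize("algorithm", ["RF", "XGB"])
    def test_perfectly_separating_feature_ranks_first(self, algorithm):
        rng = np.random.default_rng(0)
        ft = _informative_table(rng, informative=("corr_ayaz",), sep=12.0)
        ranking = rank_features(ft, TrainConfig(algorithm=algorithm, seed=1))
        assert sorted(ranking) == sorted(FEATURE_NAMES)
        assert ranking[0] == "corr_ayaz"

    def test_duplicated_feature_occupies_adjacent_ranks(self):
        rng = np.random.default_rng(1)
        ft = _informative_table(rng, informative=("amp_wx",), sep=4.0)
        ft["amp_ay"] = ft["amp_wx"]  # exact duplicate of the signal
        ranking = rank_features(ft, TrainConfig(algorithm="RF", seed=2))
        assert abs(ranking.index("amp_wx") - ranking.index("amp_ay")) == 1


class TestCrossValidate:
    def test_emits_exactly_25_fold_rows(self, features168, experiment):
        cv = cross_validate(experiment["RF"]["train"], ["p3db_wx", "amp_wx"],
                            TrainConfig(seed=3))
        assert len(cv["folds"]) == 25
        assert set(cv["mean"]) == {"accuracy", "kappa", "sensitivity", "specificity"}
        assert ((cv["folds"]["accuracy"] >= 0) & (cv["folds"]["accuracy"] <= 1)).all()

    def test_perfectly_separable_data_scores_one(self):
        rng = np.random.default_rng(2)
        ft = _informative_table(rng, informative=("amp_wx",), sep=20.0)
        cv = cross_validate(ft, ["amp_wx"], TrainConfig(seed=4))
        assert cv["mean"]["accuracy"] == 1.0
        assert cv["mean"]["kappa"] == 1.0

    def test_label_permuted_data_scores_at_chance(self):
        rng = np.random.default_rng(3)
        ft = _informative_table(rng, informative=(), sep=0.0)
        cv = cross_validate(ft, list(FEATURE_NAMES[:10]), TrainConfig(seed=5))
        assert abs(cv["mean"]["kappa"]) < 0.25
        assert abs(cv["mean"]["accuracy"] - 0.5) < 0.15


class TestMetrics:
    def test_kappa_hand_computed_confusion_example(self):
        """TP=40 FN=5 FP=5 TN=34: p_o=74/84, p_e=(45·45+39·39)/84²,
        accuracy 0.881, kappa 0.761."""
        y_true = np.array([1] * 45 + [0] * 39)
        y_pred = np.array([1] * 40 + [0] * 5 + [1] * 5 + [0] * 34)
        m = _confusion_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(74 / 84, abs=1e-9)
        assert m["kappa"] == pytest.approx(0.761, abs=1e-3)
        assert m["sensitivity"] == pytest.approx(40 / 45)
        assert m["specificity"] == pytest.approx(34 / 39)
        assert m["ppv"] == pytest.approx(40 / 45)
        assert m["npv"] == pytest.approx(34 / 39)

    def test_evaluate_matches_hand_confusion_via_stub_model(self):
        class Stub:
            def __init__(self, probs):
                self.probs = np.asarray(probs)

            def predict_proba(self, X):
                return np.column_stack([1 - self.probs, self.probs])

        labels = ["A"] * 45 + ["S"] * 39
        probs = [0.9] * 40 + [0.1] * 5 + [0.9] * 5 + [0.1] * 34
        ft = feature_table(
            [(f"s{i}", lab, {n: 0.0 for n in FEATURE_NAMES})
             for i, lab in enumerate(labels)])
        art = ModelArtifact("RF", {}, list(FEATURE_NAMES), [FEATURE_NAMES[0]],
                            fitted_model=Stub(probs))
        rep = evaluate(art, ft)
        assert rep["accuracy"] == pytest.approx(74 / 84, abs=1e-9)
        assert rep["kappa"] == pytest.approx(0.761, abs=1e-3)
        lo, hi = rep["accuracy_ci95"]
        assert lo < rep["accuracy"] < hi
        # two-level probs: AUC = (concordant + ties/2) / pairs
        #                      = (40·34 + (40·5 + 5·34)/2) / (45·39)
        assert rep["auc"] == pytest.approx(1545 / 1755, abs=1e-9)

    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0, 1])
        m = _confusion_metrics(y, y)
        assert m["accuracy"] == m["kappa"] == 1.0

    def test_evaluate_invariant_to_row_order(self, experiment):
        art = experiment["RF"]["artifact"]
        test = experiment["RF"]["test"]
        shuffled = test.sample(frac=1.0, random_state=0).reset_index(drop=True)
        r1, r2 = evaluate(art, test), evaluate(art, shuffled)
        assert r1["accuracy"] == r2["accuracy"]
        assert r1["auc"] == pytest.approx(r2["auc"], abs=1e-12)

    def test_roc_is_monotone(self, experiment):
        pts = experiment["RF"]["report"]["roc_points"]
        fpr = [p["fpr"] for p in pts]
        tpr = [p["tpr"] for p in pts]
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))


class TestIncremental:
    def test_single_informative_feature_selects_k1(self):
        rng = np.random.default_rng(4)
        train = _informative_table(rng, 30, 30, informative=("msc_ayaz",), sep=20.0)
        test = _informative_table(rng, 20, 20, informative=("msc_ayaz",), sep=20.0)
        cfg = TrainConfig(algorithm="RF", seed=6)
        ranking = rank_features(train, cfg)
        assert ranking[0] == "msc_ayaz"
        art, curve = incremental_train(train, test, ranking, cfg)
        assert len(art.feature_subset) == 1
        assert len(curve) == 63
        assert curve["testing_accuracy"].between(0, 1).all()

    def test_best_subset_is_compact_on_study_scale_data(self, experiment):
        """The selected prefixes stay small (the reference procedure selected
        6 features for RF and 13 for XGB at this dataset size)."""
        for algo in ("RF", "XGB"):
            assert 1 <= len(experiment[algo]["artifact"].feature_subset) <= 45

    def test_top_features_come_from_reported_families(self, experiment):
        """The RF top-6 should be dominated by reference-gyro-axis power/
        amplitude and a_y/a_z coupling or wavelet-detail features."""
        top6 = experiment["RF"]["ranking"][:6]
        families = ("_wx", "corr_ayaz", "msc_ayaz", "wav_az", "wav_ay",
                    "p3db", "amp_", "p2p")
        assert sum(any(f in name for f in families) for name in top6) >= 5


class TestClassify:
    def test_out_of_band_segment_fails_with_reason(self, experiment):
        seg = make_segment("bad", a_y=sine(9.5, 0.3))
        out = tp.classify_segment(seg, experiment["RF"]["artifact"])
        assert out == {"label": "fail", "reason": "peak_out_of_band"}

    def test_synthetic_segments_classified_correctly(self, experiment):
        art = experiment["RF"]["artifact"]
        hits = 0
        segs = tp.generate_class("A", 25, seed=404)
        for seg in segs:
            out = tp.classify_segment(seg, art)
            assert out["label"] in ("A", "S")
            hits += out["label"] == "A" and out["prob_A"] > 0.5
        assert hits >= 23  # ≥ ~95% of fresh class-A draws

    def test_classification_deterministic(self, experiment):
        seg = tp.generate_class("S", 1, seed=77)[0]
        art = experiment["XGB"]["artifact"]
        assert tp.classify_segment(seg, art) == tp.classify_segment(seg, art)


def test_artifact_save_load_round_trip(tmp_path, experiment):
    art = experiment["RF"]["artifact"]
    tp.save_model(art, tmp_path / "m")
    back = tp.load_model(tmp_path / "m")
    assert back.feature_subset == art.feature_subset
    assert back.ranking == art.ranking
    seg = tp.generate_class("A", 1, seed=55)[0]
    assert tp.classify_segment(seg, back) == tp.classify_segment(seg, art)
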