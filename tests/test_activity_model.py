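"""Feature assembly, SVM training/scoring, cross-validation, ROC and PR."""

import numpy as np
import pytest

from guidecraft.activity_model import (
    N_FEATURES,
    TrainedModel,
    assemble_features,
    crossvalidate,
    feature_names,
    pr_curve,
    predict_scores,
    roc_auc,
    train_svm,
)
from guidecraft.screen_io import LabeledScreen, ScreenRecord, label_by_percentile
from .conftest import TINY_GRID, random_guides


class TestAssembleFeatures:
    def test_vector_length_and_manifest_agree(self, rng):
        names = feature_names()
        assert len(names) == N_FEATURES
        for guide in random_guides(rng, 5):
            assert assemble_features(guide).shape == (N_FEATURES,)

    def test_deterministic(self):
        g = "ACGUACGUACGUACGUACGA"
        assert np.array_equal(assemble_features(g), assemble_features(g))

    def test_all_a_guide_values(self):
        v = dict(zip(feature_names(), assemble_features("A" * 20)))
        assert v["gc"] == 0.0
        assert v["mono_A"] == 20
        assert v["self_fold_dg"] == 0.0
        assert v["repetitive"] == 1.0  # AAAAA run


def _separable_screen(n_per_class=15):
    """A-rich guides active, G/C-rich inactive: trivially separable."""
    rng = np.random.default_rng(0)
    recs, acts = [], []
    for i in range(n_per_class):
        a = "".join(rng.choice(list("AU"), size=20))
        g = "".join(rng.choice(list("GC"), size=20))
        recs += [
            ScreenRecord(guide_seq=a, gene_id=f"g{i % 3}", activity=10.0 + i),
            ScreenRecord(guide_seq=g, gene_id=f"g{i % 3}", activity=-10.0 - i),
        ]
    return label_by_percentile(recs, top=0.5, bottom=0.5)


class TestTrainSvm:
    def test_separable_screen_trains_to_auc_1(self):
        lab = _separable_screen()
        model = train_svm(lab, grid=TINY_GRID, seed=0, prefilter=False)
        recs, y = lab.training_records()
        scores = model.predict_scores([r.guide_seq for r in recs])
        assert roc_auc(scores, y) == 1.0

    def test_single_class_errors(self):
        lab = _separable_screen()
        lab.labels = ["functional" if l == "non-functional" else l for l in lab.labels]
        with pytest.raises(ValueError):
            train_svm(lab, grid=TINY_GRID, prefilter=False)

    def test_save_load_scores_identical(self, tmp_path, small_model, rng):
        p = tmp_path / "model.joblib"
        small_model.save(p)
        reloaded = TrainedModel.load(p)
        guides = random_guides(rng, 10)
        assert np.array_equal(
            small_model.predict_scores(guides), reloaded.predict_scores(guides)
        )

    def test_scores_in_unit_interval_and_order_invariant(self, small_model, rng):
        guides = random_guides(rng, 12)
        s = predict_scores(small_model, guides)
        assert ((0 <= s) & (s <= 1)).all()
        perm = rng.permutation(len(guides))
        s_perm = predict_scores(small_model, [guides[i] for i in perm])
        assert np.allclose(s[perm], s_perm)

    def test_manifest_mismatch_refused(self, small_model):
        import dataclasses

        tampered = dataclasses.replace(
            small_model, manifest=dict(small_model.manifest, hash="0" * 64)
        )
        with pytest.raises(ValueError, match="manifest"):
            tampered.predict_scores(["A" * 20])


class TestCrossvalidate:
    def test_tenfold_scores_every_record_once(self, small_labeled):
        cv = crossvalidate(small_labeled, "tenfold", seed=0, grid=TINY_GRID)
        assert np.isfinite(cv.scores).all()
        assert len(cv.scores) == len(cv.labels)
        assert set(np.unique(cv.fold_ids)) == set(range(10))

    def test_gene_mode_gives_one_fold_per_gene(self, small_labeled):
        cv = crossvalidate(small_labeled, "leave-one-gene-out", seed=0, grid=TINY_GRID)
        genes = {
            r.gene_id for r in small_labeled.functional + small_labeled.nonfunctional
        }
        assert len(set(np.unique(cv.fold_ids))) == len(genes) == 9

    def test_gene_mode_requires_two_genes(self):
        recs = [
            ScreenRecord(guide_seq="ACGUACGUACGUACGUACGA", gene_id="only", activity=float(i))
            for i in range(40)
        ]
        lab = label_by_percentile(recs)
        with pytest.raises(ValueError, match="2 genes"):
            crossvalidate(lab, "leave-one-gene-out", grid=TINY_GRID)

    def test_unknown_mode_rejected(self, small_labeled):
        with pytest.raises(ValueError):
            crossvalidate(small_labeled, "fivefold")


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        scores = rng.random(200)
        scores[rng.random(200) < 0.3] = 0.5  # inject ties
        labels = (rng.random(200) < 0.4).astype(int)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = (rng.random(100) < 0.5).astype(int)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(5 * scores), labels)
        )


class TestPrCurve:
    def test_perfect_ranking_precision_one_at_every_usable_threshold(self):
        curve = pr_curve([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        # with perfect ranking, precision stays 1.0 at every threshold down
        # to (and including) the one that first reaches full recall
        full = int(np.argmax(curve["recall"] >= 1.0))
        assert np.allclose(curve["precision"][: full + 1], 1.0)
        assert curve["recall"][full] == 1.0

    def test_random_scores_hover_at_baseline(self, rng):
        labels = (rng.random(2000) < 0.4).astype(int)
        curve = pr_curve(rng.random(2000), labels)
        assert curve["baseline"] == pytest.approx(labels.mean())
        # precision at generous recall stays near the positive fraction
        deep = curve["precision"][curve["recall"] > 0.5]
        assert np.abs(deep - labels.mean()).max() < 0.08

    def test_thresholds_descend(self, rng):
        curve = pr_curve(rng.random(50), (rng.random(50) < 0.5).astype(int))
        assert (np.diff(curve["threshold"]) <= 0).all()

    def test_background_precision_of_validation_screen(self):
        # a validation screen with 113 functional of 279 tested guides -> 40.5 % precision background
        labels = np.array([1] * 113 + [0] * 166)
        curve = pr_curve(np.linspace(0, 1, 279), labels)
        assert curve["baseline"] * 100 == pytest.approx(40.5, abs=0.05)
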