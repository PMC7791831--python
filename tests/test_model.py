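"""Per-motif classifier training, evaluation metrics, and persistence."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _helpers import mann_whitney_auc
from nanostoich import simulate
from nanostoich.model import (
    TrainConfig,
    ModelBundle,
    confusion_metrics,
    cross_validate,
    enumerate_rrach_motifs,
    predict_many,
    predict_site,
    roc_auc,
    train_bundle,
)
from nanostoich.sigio import SiteFeatureVector


class TestMotifEnumeration:
    def test_twelve_motifs_from_degenerate_code(self):
        motifs = enumerate_rrach_motifs()
        assert len(motifs) == 12
        assert motifs == sorted(motifs)
        brute = sorted(
            "".join(p) for p in itertools.product("AG", "AG", "A", "C", "ACT")
        )
        assert motifs == brute

    def test_known_members(self):
        motifs = enumerate_rrach_motifs()
        assert "GGACT" in motifs and "AGACT" in motifs


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 0, 10, 0), (1.0, 0.0, 1.0)),
            ((3, 1, 4, 1), (0.75, 0.2, 7 / 9)),
            ((0, 0, 5, 5), (0.0, 0.0, 0.5)),
        ],
    )
    def test_printed_formulas(self, counts, expected):
        assert confusion_metrics(*counts) == pytest.approx(expected)

    def test_zero_denominator_flagged_as_nan(self):
        tpr, fpr, acc = confusion_metrics(0, 1, 1, 0)
        assert math.isnan(tpr) and fpr == 0.5 and acc == 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 1)


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_interleaved_ranking_equals_pair_fraction(self):
        # concordant pairs: (0.9,0.1), (0.9,0.8), (0.2,0.1); discordant: (0.2,0.8)
        _, auc = roc_auc([0.9, 0.1, 0.8, 0.2], [1, 0, 0, 1])
        assert auc == pytest.approx(mann_whitney_auc([0.9, 0.1, 0.8, 0.2], [1, 0, 0, 1]))
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])

    def test_roc_monotone_and_anchored(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        points, _ = roc_auc(scores, labels)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)
        assert tuple(points[0]) == (0.0, 0.0) and tuple(points[-1]) == (1.0, 1.0)

    def test_exhaustive_small_instances_match_pair_counting(self):
        # every labeling and a tie-rich score grid for n <= 6,
        # plus random instances up to n = 12
        for n in range(2, 7):
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    scores = [((i * 7) % 3) / 2 for i in range(n)]  # many ties
                    _, auc = roc_auc(scores, list(labels))
                    assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_larger_instances_match_pair_counting(self, data):
        n = data.draw(st.integers(13, 60))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0]),
                     min_size=n, max_size=n)
        )
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)


def _toy_labeled(rng, n_per_class=30, motifs=None, separation=3.0):
    """Tiny synthetic feature set with a mean shift on the center base."""
    motifs = motifs or enumerate_rrach_motifs()
    out = []
    for mi, motif in enumerate(motifs):
        for label in (0, 1):
            for i in range(n_per_class):
                feats = rng.normal(0, 1, 20)
                feats[3::4] = rng.integers(3, 15, 5)  # dwell-like
                if label:
                    feats[8] += separation
                    feats[9] += separation
                out.append(
                    (SiteFeatureVector(f"{motif}_{label}_{i}", "t", 2, motif, feats), label)
                )
    return out


class TestTrainBundle:
    def test_bundle_has_all_twelve_motifs_and_separates_classes(self):
        rng = np.random.default_rng(2)
        labeled = _toy_labeled(rng)
        bundle, report = train_bundle(labeled, TrainConfig(seed=0))
        assert sorted(bundle.models) == enumerate_rrach_motifs()
        assert all(m.trainable for m in bundle.models.values())
        assert report.auc > 0.9

    def test_persistence_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        labeled = _toy_labeled(rng, n_per_class=20)
        bundle, _ = train_bundle(labeled, TrainConfig(seed=0))
        vectors = [v for v, _ in labeled[:50]]
        before = predict_many(bundle, vectors)
        path = tmp_path / "bundle.nsm"
        bundle.save(path)
        reloaded = ModelBundle.load(path)
        after = predict_many(reloaded, vectors)
        np.testing.assert_array_equal(before, after)

    def test_single_class_motif_flagged_untrainable(self):
        rng = np.random.default_rng(4)
        labeled = _toy_labeled(rng, n_per_class=10, motifs=enumerate_rrach_motifs()[1:])
        # first motif gets only unmodified examples
        first = enumerate_rrach_motifs()[0]
        for i in range(10):
            feats = rng.normal(0, 1, 20)
            feats[3::4] = 5
            labeled.append((SiteFeatureVector(f"x{i}", "t", 2, first, feats), 0))
        bundle, _ = train_bundle(labeled, TrainConfig(seed=0))
        assert not bundle.models[first].trainable
        probe = SiteFeatureVector("probe", "t", 2, first, np.zeros(20))
        with pytest.raises(ValueError, match="no model for motif"):
            predict_site(bundle, probe)

    def test_same_seed_reproduces_heldout_scores(self):
        rng = np.random.default_rng(5)
        labeled = _toy_labeled(rng, n_per_class=15)
        _, r1 = train_bundle(labeled, TrainConfig(seed=9))
        _, r2 = train_bundle(labeled, TrainConfig(seed=9))
        assert (r1.tp, r1.fp, r1.tn, r1.fn) == (r2.tp, r2.fp, r2.tn, r2.fn)
        assert r1.auc == r2.auc


class TestCrossValidate:
    def test_minimal_two_fold_run(self):
        rng = np.random.default_rng(6)
        motif = "GGACT"
        labeled = []
        for label in (0, 1):
            for i in range(2):
                feats = rng.normal(label * 4.0, 1, 20)
                labeled.append((SiteFeatureVector(f"{label}{i}", "t", 2, motif, feats), label))
        report = cross_validate(labeled, folds=2, seed=0)
        assert 0.0 <= report.auc <= 1.0
        assert report.tp + report.fp + report.tn + report.fn == 4

    def test_more_folds_than_examples_rejected(self):
        rng = np.random.default_rng(7)
        labeled = _toy_labeled(rng, n_per_class=1, motifs=["GGACT"])
        with pytest.raises(ValueError, match="fewer examples"):
            cross_validate(labeled, folds=10, seed=0)

    def test_auc_monotone_in_modification_shift(self):
        """A larger current shift can only make detection easier."""
        aucs = []
        for shift in (0.0, 1.5, 4.0):
            params = simulate.SimParams(seed=3, mod_shift=shift,
                                        mod_dwell_factor=1.0 if shift == 0 else 1.5)
            labeled = simulate.simulate_labeled_events(params, 60)
            report = cross_validate(labeled.vectors(), folds=3, seed=3)
            aucs.append(report.auc)
        assert aucs[0] == pytest.approx(0.5, abs=0.1)
        assert aucs[1] >= aucs[0] - 0.005
        assert aucs[2] >= aucs[1] - 0.005


class TestPredict:
    def test_probabilities_in_unit_interval(self, trained_bundle):
        bundle, _ = trained_bundle
        params = simulate.SimParams(seed=12)
        mix = simulate.simulate_mixture(params, 0.5, 10, 4)
        probs = predict_many(bundle, mix.center_vectors())
        assert np.all((probs >= 0) & (probs <= 1))

    def test_strongly_shifted_reads_called_confidently(self, trained_bundle):
        bundle, _ = trained_bundle
        params = simulate.SimParams(seed=13)
        modified = simulate.simulate_mixture(params, 1.0, 40, 2, tag=1)
        unmodified = simulate.simulate_mixture(params, 0.0, 40, 2, tag=2)
        p_mod = predict_many(bundle, modified.center_vectors())
        p_unm = predict_many(bundle, unmodified.center_vectors())
        assert np.median(p_mod) > 0.8
        assert np.median(p_unm) < 0.2

    def test_schema_mismatch_rejected_on_load(self, tmp_path, trained_bundle):
        import json
        import zipfile

        bundle, _ = trained_bundle
        path = tmp_path / "bundle.nsm"
        bundle.save(path)
        # tamper with the schema version
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            blobs = {n: zf.read(n) for n in zf.namelist() if n != "meta.json"}
        meta["schema_version"] = "other-schema"
        bad = tmp_path / "bad.nsm"
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            for n, b in blobs.items():
                zf.writestr(n, b)
        with pytest.raises(ValueError, match="schema"):
            ModelBundle.load(bad)
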