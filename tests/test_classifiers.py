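import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airwayspec.classifiers import (
    Classification,
    FitError,
    KnnModel,
    LabeledFeatureSet,
    evaluate,
    knn_classify,
    lda_classify,
    lda_confidence,
    lda_fit,
    minkowski_distance,
)
from airwayspec.io import ESOPHAGUS, TRACHEA, ValidationError

from conftest import fv, random_feature_set
from oracles import brute_knn


class TestMinkowski:
    def test_identity_and_pythagorean(self):
        a, b = fv(0, 0), fv(3, 4, acq_index=2)
        assert minkowski_distance(a, a) == 0.0
        assert minkowski_distance(a, b, p=2) == 5.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.floats(-5, 5) for _ in range(4)]))
    def test_p1_is_sum_of_absolute_differences(self, coords):
        x1, y1, x2, y2 = coords
        a, b = fv(x1, y1), fv(x2, y2, acq_index=2)
        assert minkowski_distance(a, b, p=1) == pytest.approx(
            abs(x1 - x2) + abs(y1 - y2))

    def test_order_below_one_rejected(self):
        with pytest.raises(ValueError):
            minkowski_distance(fv(0, 0), fv(1, 1, acq_index=2), p=0.5)


def worked_example_training():
    """A cohort engineered so one query's 11-member inclusive voting set
    holds 8 tracheal and 3 esophageal votes."""
    pts, labels = [], []
    # the query itself
    pts.append(fv(0.80, 0.80, pair_id=1, organ=TRACHEA, acq_index=1))
    labels.append(TRACHEA)
    # 7 tracheal and 2 esophageal close neighbors
    for i in range(7):
        pts.append(fv(0.80 + 0.001 * (i + 1), 0.80, pair_id=2,
                      organ=TRACHEA, acq_index=i + 1))
        labels.append(TRACHEA)
    for i in range(2):
        pts.append(fv(0.80, 0.80 + 0.001 * (i + 1), pair_id=3,
                      organ=ESOPHAGUS, acq_index=i + 1))
        labels.append(ESOPHAGUS)
    # one more esophageal point, still nearer than nothing else exists
    pts.append(fv(0.85, 0.85, pair_id=4, organ=ESOPHAGUS, acq_index=1))
    labels.append(ESOPHAGUS)
    return LabeledFeatureSet(points=pts, labels=labels), pts[0]


class TestKnn:
    def test_eight_of_eleven_tracheal_votes(self):
        train, query = worked_example_training()
        model = KnnModel(training=train, k=10, p=2.0)
        c = knn_classify(model, query, query_in_training=True)
        assert c.label == TRACHEA
        assert c.confidence == pytest.approx(100.0 * 8 / 11)
        assert round(c.confidence, 1) == 72.7

    def test_unanimous_neighborhood_gives_100(self):
        pts = [fv(0.8 + 0.001 * i, 0.8, organ=TRACHEA, acq_index=i + 1)
               for i in range(12)]
        pts += [fv(2.0, 2.0, organ=ESOPHAGUS, acq_index=50),
                fv(2.1, 2.0, organ=ESOPHAGUS, acq_index=51)]
        labels = [TRACHEA] * 12 + [ESOPHAGUS] * 2
        model = KnnModel(training=LabeledFeatureSet(points=pts, labels=labels))
        c = knn_classify(model, pts[0], query_in_training=True)
        assert c.label == TRACHEA and c.confidence == 100.0

    @pytest.mark.parametrize("p", [1.0, 2.0, 3.0])
    def test_agrees_with_exhaustive_sort_oracle(self, p):
        rng = np.random.default_rng(19)
        pts, labels = random_feature_set(rng, 200)
        metas = [pt.meta for pt in pts]
        coords = [(pt.r543, pt.r578) for pt in pts]
        model = KnnModel(training=LabeledFeatureSet(points=pts, labels=labels),
                         k=10, p=p)
        for qi in range(0, 200, 3):
            got = knn_classify(model, pts[qi], query_in_training=True)
            exp_label, exp_conf = brute_knn(coords, labels, metas, qi, k=10, p=p)
            assert got.label == exp_label
            assert got.confidence == pytest.approx(exp_conf)

    def test_resubstitution_self_vote_floor(self):
        # even when every neighbor disagrees, the self-vote caps the
        # wrong-class confidence at k/(k+1)
        pts = [fv(0.8, 0.8, organ=TRACHEA, acq_index=1)]
        pts += [fv(0.8 + 0.001 * (i + 1), 0.8, organ=ESOPHAGUS, acq_index=i + 1,
                   pair_id=2) for i in range(11)]
        labels = [TRACHEA] + [ESOPHAGUS] * 11
        model = KnnModel(training=LabeledFeatureSet(points=pts, labels=labels))
        c = knn_classify(model, pts[0], query_in_training=True)
        assert c.label == ESOPHAGUS
        assert c.confidence == pytest.approx(100.0 * 10 / 11)

    def test_even_vote_tie_broken_by_nearest_neighbor(self):
        pts = [fv(-1.0, 0.0, organ=TRACHEA, acq_index=1),
               fv(2.0, 0.0, organ=ESOPHAGUS, acq_index=1, pair_id=2),
               fv(-3.0, 0.0, organ=TRACHEA, acq_index=2),
               fv(4.0, 0.0, organ=ESOPHAGUS, acq_index=2, pair_id=2)]
        labels = [TRACHEA, ESOPHAGUS, TRACHEA, ESOPHAGUS]
        model = KnnModel(training=LabeledFeatureSet(points=pts, labels=labels),
                         k=2, p=2.0)
        c = knn_classify(model, fv(0.0, 0.0, pair_id=9, acq_index=9))
        assert c.tie_broken
        assert c.label == TRACHEA  # nearest neighbor at distance 1
        assert c.confidence == 50.0

    def test_k_plus_one_must_fit_training(self):
        pts, labels = random_feature_set(np.random.default_rng(1), 10)
        with pytest.raises(ValidationError):
            KnnModel(training=LabeledFeatureSet(points=pts, labels=labels), k=10)


class TestLda:
    def test_identity_covariance_gives_perpendicular_bisector(self):
        rng = np.random.default_rng(5)
        mu_t, mu_e = np.array([0.7, 0.7]), np.array([1.1, 0.9])
        pts, labels = [], []
        for i in range(300):
            z = rng.normal(0, 0.02, 2)
            pts.append(fv(*(mu_t + z), organ=TRACHEA, acq_index=i + 1))
            labels.append(TRACHEA)
            z = rng.normal(0, 0.02, 2)
            pts.append(fv(*(mu_e + z), organ=ESOPHAGUS, acq_index=i + 1, pair_id=2))
            labels.append(ESOPHAGUS)
        model = lda_fit(LabeledFeatureSet(points=pts, labels=labels))
        # direction ~ mean difference, boundary passes through the midpoint
        w_hat = model.w / np.linalg.norm(model.w)
        d_hat = (mu_e - mu_t) / np.linalg.norm(mu_e - mu_t)
        assert abs(float(w_hat @ d_hat)) > 0.99
        mid = fv(*((mu_t + mu_e) / 2), pair_id=3, acq_index=999)
        assert model.boundary_distance(mid) < 0.01 * np.linalg.norm(mu_e - mu_t)

    def test_label_swap_negates_w_and_preserves_labels(self):
        rng = np.random.default_rng(6)
        pts, labels = random_feature_set(rng, 60, cluster_gap=0.4)
        model = lda_fit(LabeledFeatureSet(points=pts, labels=labels))
        swapped_pts = [fv(p.r543, p.r578,
                          pair_id=p.meta.pair_id,
                          organ=TRACHEA if l == ESOPHAGUS else ESOPHAGUS,
                          acq_index=p.meta.acq_index)
                       for p, l in zip(pts, labels)]
        swapped_labels = [TRACHEA if l == ESOPHAGUS else ESOPHAGUS for l in labels]
        model2 = lda_fit(LabeledFeatureSet(points=swapped_pts,
                                           labels=swapped_labels))
        np.testing.assert_allclose(model2.w, -model.w, rtol=1e-9)
        for p in pts:
            l1 = lda_classify(model, p).label
            l2 = lda_classify(model2, p).label
            assert l1 == (TRACHEA if l2 == ESOPHAGUS else ESOPHAGUS)

    def test_agreement_with_sklearn_reference(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis").LinearDiscriminantAnalysis
        rng = np.random.default_rng(8)
        pts, labels = random_feature_set(rng, 150, cluster_gap=0.15)
        model = lda_fit(LabeledFeatureSet(points=pts, labels=labels))
        X = np.array([[p.r543, p.r578] for p in pts])
        ref = sklearn_lda(priors=[0.5, 0.5]).fit(X, labels)
        ours = [lda_classify(model, p).label for p in pts]
        theirs = list(ref.predict(X))
        assert ours == theirs

    def test_classification_sign_and_reflection(self):
        rng = np.random.default_rng(9)
        pts, labels = random_feature_set(rng, 80, cluster_gap=0.5)
        model = lda_fit(LabeledFeatureSet(points=pts, labels=labels))
        x = pts[0]
        # reflect across the boundary: x' = x - 2 g(x) w / |w|^2
        g = model.discriminant(x)
        w2 = float(model.w @ model.w)
        arr = x.as_array() - 2.0 * g * model.w / w2
        mirrored = fv(arr[0], arr[1], pair_id=7, acq_index=77)
        assert lda_classify(model, x).label != lda_classify(model, mirrored).label

    def test_zero_discriminant_classified_trachea(self):
        # integer-friendly weights so the discriminant is exactly zero
        from airwayspec.classifiers import LdaModel
        model = LdaModel(w=np.array([1.0, 1.0]), b=-2.0, d_max=1.0)
        c = lda_classify(model, fv(1.0, 1.0))
        assert c.label == TRACHEA
        assert c.confidence == pytest.approx(63.0, abs=1e-12)

    def test_degenerate_training_rejected(self):
        pts = [fv(0.8, 0.8, organ=TRACHEA, acq_index=i + 1) for i in range(3)]
        pts += [fv(0.9, 0.9, organ=ESOPHAGUS, acq_index=i + 1, pair_id=2)
                for i in range(3)]
        labels = [TRACHEA] * 3 + [ESOPHAGUS] * 3
        with pytest.raises(FitError):
            lda_fit(LabeledFeatureSet(points=pts, labels=labels))


class TestLdaConfidence:
    def _model(self):
        rng = np.random.default_rng(12)
        pts, labels = random_feature_set(rng, 100, cluster_gap=0.4)
        return lda_fit(LabeledFeatureSet(points=pts, labels=labels)), pts

    def test_endpoints_and_halfway_value(self):
        model, pts = self._model()
        t = model.b / float(model.w @ model.w)
        on_boundary = fv(*(-t * model.w), pair_id=7, acq_index=77)
        assert lda_confidence(model, on_boundary) == pytest.approx(63.0, abs=1e-6)
        # furthest training point anchors 100%
        dists = [model.boundary_distance(p) for p in pts]
        far = pts[int(np.argmax(dists))]
        assert lda_confidence(model, far) == pytest.approx(100.0, abs=1e-9)
        # halfway in normalized distance: 100 * exp(-kappa/2)
        w_unit = model.w / np.linalg.norm(model.w)
        arr = on_boundary.as_array() + 0.5 * model.d_max * w_unit
        half = fv(arr[0], arr[1], pair_id=7, acq_index=78)
        expected = 100.0 * math.exp(-math.log(100.0 / 63.0) / 2.0)
        assert lda_confidence(model, half) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(79.4, abs=0.05)

    def test_monotone_and_bounded_on_training(self):
        model, pts = self._model()
        scored = sorted((model.boundary_distance(p), lda_confidence(model, p))
                        for p in pts)
        confs = [c for _, c in scored]
        assert all(b >= a - 1e-12 for a, b in zip(confs, confs[1:]))
        assert all(63.0 - 1e-9 <= c <= 100.0 + 1e-9 for c in confs)


class TestEvaluate:
    def test_hand_computed_toy_cohort(self):
        preds = [Classification(TRACHEA, 100.0),
                 Classification(TRACHEA, 80.0),
                 Classification(ESOPHAGUS, 60.0),
                 Classification(TRACHEA, 70.0)]
        truth = [TRACHEA, TRACHEA, ESOPHAGUS, ESOPHAGUS]
        r = evaluate(preds, truth)
        # errors: 0, 0.2, 0.4, 0.7 -> mse = (0 + .04 + .16 + .49)/4
        assert r.n_correct == 3
        assert r.accuracy == pytest.approx(0.75)
        assert r.mse == pytest.approx((0.04 + 0.16 + 0.49) / 4)
        assert r.psnr_db == pytest.approx(10 * math.log10(4 / 0.69))

    def test_perfect_cohort_reports_infinite_psnr(self):
        preds = [Classification(TRACHEA, 100.0)] * 4
        r = evaluate(preds, [TRACHEA] * 4)
        assert r.mse == 0.0 and math.isinf(r.psnr_db)
        assert r.accuracy == 1.0

    def test_psnr_strictly_decreasing_in_mse(self):
        confs = [99.0, 95.0, 90.0, 70.0]
        reports = [evaluate([Classification(TRACHEA, c)], [TRACHEA])
                   for c in confs]
        mses = [r.mse for r in reports]
        psnrs = [r.psnr_db for r in reports]
        assert mses == sorted(mses)
        assert psnrs == sorted(psnrs, reverse=True)

    def test_accuracy_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(14)
        labels = [TRACHEA if rng.random() < 0.5 else ESOPHAGUS for _ in range(40)]
        preds = [Classification(
            TRACHEA if rng.random() < 0.5 else ESOPHAGUS, 80.0)
            for _ in range(40)]
        flip = {TRACHEA: ESOPHAGUS, ESOPHAGUS: TRACHEA}
        r1 = evaluate(preds, labels)
        r2 = evaluate([Classification(flip[p.label], p.confidence) for p in preds],
                      [flip[t] for t in labels])
        assert r1.accuracy == r2.accuracy
        assert r1.mse == r2.mse

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])
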