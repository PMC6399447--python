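"""Cohen's kappa and the multi-annotator agreement machinery."""

from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import histopat as hp
from histopat.agreement import (
    AnnotationSet,
    kappa_bootstrap_ci,
    proportion_ci,
    read_annotation_csv,
    robust_agreement_indicators,
    write_annotation_csv,
)
from histopat.patterns import CANCER_CLASSES, PatternClass, SlideLabel

P = PatternClass


def brute_force_kappa(a, b):
    """Confusion-matrix evaluation of (p_o - p_e) / (1 - p_e)."""
    cats = sorted(set(a) | set(b))
    n = len(a)
    conf = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        conf[cats.index(x), cats.index(y)] += 1
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e >= 1 - 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


class TestCohensKappa:
    def test_identical_non_constant_is_one(self):
        seq = ["a", "b", "a", "c"]
        assert hp.cohens_kappa(seq, seq) == 1.0

    def test_2x2_worked_example(self):
        # confusion counts [[20, 5], [10, 15]]: p_o=0.7, p_e=0.5, kappa=0.4
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert hp.cohens_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_independent_sequences_near_zero(self):
        rng = np.random.default_rng(0)
        n = 20000
        a = rng.choice(["a", "b", "c"], size=n, p=[0.5, 0.3, 0.2])
        b = rng.choice(["a", "b", "c"], size=n, p=[0.5, 0.3, 0.2])
        assert abs(hp.cohens_kappa(list(a), list(b))) < 0.02

    def test_degenerate_constant_conventions(self):
        assert hp.cohens_kappa(["a"] * 5, ["a"] * 5) == 1.0
        assert hp.cohens_kappa(["a"] * 5, ["b"] * 5) == 0.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            hp.cohens_kappa(["a"], ["a", "b"])
        with pytest.raises(ValueError):
            hp.cohens_kappa([], [])

    def test_matches_brute_force_and_sklearn_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            k = int(rng.integers(2, 5))
            a = list(rng.integers(0, k, n))
            b = list(rng.integers(0, k, n))
            ours = hp.cohens_kappa(a, b)
            assert ours == pytest.approx(brute_force_kappa(a, b), abs=1e-12)
            assert -1 <= ours <= 1
            if len(set(a)) > 1 or len(set(b)) > 1:
                ref = cohen_kappa_score(a, b)
                if np.isfinite(ref):
                    assert ours == pytest.approx(ref, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = list(rng.integers(0, 3, 40))
        b = list(rng.integers(0, 3, 40))
        assert hp.cohens_kappa(a, b) == pytest.approx(hp.cohens_kappa(b, a), abs=1e-15)


def sets_from_predominants(*columns, minors=None):
    """Build aligned AnnotationSets from per-annotator predominant lists."""
    out = []
    for ai, col in enumerate(columns):
        labels = {}
        for si, cls in enumerate(col):
            minor = frozenset() if minors is None else minors[ai][si]
            labels[f"s{si:03d}"] = (
                SlideLabel.benign() if cls is None else SlideLabel(cls, minor)
            )
        out.append(AnnotationSet(f"ann{ai}", labels))
    return out


class TestPredominantAgreement:
    def test_identical_and_symmetric(self):
        rng = np.random.default_rng(1)
        col = [CANCER_CLASSES[i] for i in rng.integers(0, 5, 30)]
        col2 = [CANCER_CLASSES[i] for i in rng.integers(0, 5, 30)]
        a, b = sets_from_predominants(col, col2)
        assert hp.predominant_agreement(a, a) == 1.0
        assert hp.predominant_agreement(a, b) == hp.predominant_agreement(b, a)

    def test_counted_fraction(self):
        col_a = [P.ACINAR] * 143
        col_b = [P.ACINAR] * 95 + [P.SOLID] * 48
        a, b = sets_from_predominants(col_a, col_b)
        assert hp.predominant_agreement(a, b) == pytest.approx(95 / 143)

    def test_disjoint_slide_sets_rejected(self):
        a = AnnotationSet("a", {"s1": SlideLabel(P.SOLID)})
        b = AnnotationSet("b", {"s2": SlideLabel(P.SOLID)})
        with pytest.raises(ValueError):
            hp.predominant_agreement(a, b)


class TestDetectionKappa:
    def test_absent_pattern_everywhere_degenerate_one(self):
        a, b = sets_from_predominants([P.SOLID] * 10, [P.SOLID] * 10)
        assert hp.per_class_detection_kappa(a, b, P.MICROPAPILLARY) == 1.0

    def test_binary_confusion_hand_value(self):
        # [[50, 10], [10, 30]]: p_o=0.8, p_e=0.6*0.6+0.4*0.4=0.52
        pres_a = [True] * 60 + [False] * 40
        pres_b = [True] * 50 + [False] * 10 + [True] * 10 + [False] * 30
        col_a = [P.ACINAR if v else P.SOLID for v in pres_a]
        col_b = [P.ACINAR if v else P.SOLID for v in pres_b]
        a, b = sets_from_predominants(col_a, col_b)
        want = (0.8 - 0.52) / (1 - 0.52)
        assert hp.per_class_detection_kappa(a, b, P.ACINAR) == pytest.approx(want)

    def test_presence_union_of_predominant_and_minor(self):
        lab_pred = SlideLabel(P.ACINAR)
        lab_minor = SlideLabel(P.SOLID, frozenset({P.ACINAR}))
        assert P.ACINAR in lab_pred.patterns
        assert P.ACINAR in lab_minor.patterns
        a = AnnotationSet("a", {"s": lab_pred})
        b = AnnotationSet("b", {"s": lab_minor})
        assert hp.per_class_detection_kappa(a, b, P.ACINAR) == 1.0

    def test_benign_rejected(self):
        a, b = sets_from_predominants([P.SOLID], [P.SOLID])
        with pytest.raises(ValueError):
            hp.per_class_detection_kappa(a, b, P.BENIGN)


class TestRobustAgreement:
    def test_all_identical_is_one(self):
        cols = [[P.ACINAR, P.SOLID, P.LEPIDIC]] * 4
        sets = sets_from_predominants(*cols)
        assert hp.robust_agreement(sets[0], sets[1:]) == 1.0

    def test_single_match_not_counted(self):
        # target matches exactly one other on the only slide
        sets = sets_from_predominants(
            [P.ACINAR], [P.ACINAR], [P.SOLID], [P.LEPIDIC]
        )
        assert hp.robust_agreement(sets[0], sets[1:]) == 0.0
        # two matches qualify
        sets2 = sets_from_predominants(
            [P.ACINAR], [P.ACINAR], [P.ACINAR], [P.LEPIDIC]
        )
        assert hp.robust_agreement(sets2[0], sets2[1:]) == 1.0

    def test_counted_fraction_and_indicators(self):
        rng = np.random.default_rng(5)
        cols = [
            [CANCER_CLASSES[i] for i in rng.integers(0, 2, 143)] for _ in range(4)
        ]
        sets = sets_from_predominants(*cols)
        ind = robust_agreement_indicators(sets[0], sets[1:])
        assert hp.robust_agreement(sets[0], sets[1:]) == pytest.approx(ind.mean())

    def test_wrong_number_of_others_rejected(self):
        sets = sets_from_predominants([P.ACINAR], [P.ACINAR], [P.SOLID])
        with pytest.raises(ValueError):
            hp.robust_agreement(sets[0], sets[1:])


class TestConfidenceIntervals:
    def test_normal_approximation_closed_form(self):
        lo, hi = proportion_ci(0.5, 100)
        assert lo == pytest.approx(0.5 - 1.959964 * 0.05, abs=1e-4)
        assert hi == pytest.approx(0.5 + 1.959964 * 0.05, abs=1e-4)

    def test_boundary_degenerate_and_exact_alternative(self):
        lo, hi = proportion_ci(1.0, 50)
        assert (lo, hi) == (1.0, 1.0)
        lo_e, hi_e = proportion_ci(1.0, 50, exact=True)
        assert lo_e < 1.0 and hi_e == 1.0

    def test_kappa_bootstrap_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        a = list(rng.integers(0, 3, 60))
        b = [x if rng.random() < 0.8 else (x + 1) % 3 for x in a]
        point = hp.cohens_kappa(a, b)
        lo, hi = kappa_bootstrap_ci(a, b, n_boot=500, seed=0)
        assert lo <= point <= hi

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0.5, 1)


class TestCompareMetrics:
    def test_identical_sequences(self):
        t, p = hp.compare_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert t == 0.0 and p == 1.0

    def test_equal_means_different_order(self):
        t, p = hp.compare_metrics([1, 0, 1, 0], [0, 1, 0, 1])
        assert p == pytest.approx(1.0)

    def test_separated_means_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.6, 0.2, 50)
        b = rng.normal(0.9, 0.2, 50)
        t, p = hp.compare_metrics(a, b)
        assert p < 0.05

    def test_zero_variance_degenerate(self):
        t, p = hp.compare_metrics([1, 1, 1], [0, 0, 0])
        assert p == 0.0


class TestAverageMetrics:
    def test_four_identical_sets_saturate(self):
        rng = np.random.default_rng(8)
        col = [CANCER_CLASSES[i] for i in rng.integers(0, 5, 20)]
        sets = sets_from_predominants(col, col, col, col)
        rep = hp.average_metrics(sets, with_ci=False)
        assert all(v == 1.0 for v in rep.average_kappa.values())
        assert all(v == 1.0 for v in rep.average_agreement.values())
        assert all(v == 1.0 for v in rep.robust.values())

    def test_per_annotator_average_recomputable_from_pairwise(self):
        sets, _ = hp.generate_annotation_sets(60, (0.1, 0.15, 0.2), seed=9)
        rep = hp.average_metrics(sets, with_ci=False)
        for name in rep.annotators:
            pair_vals = [
                pw.kappa_predom for key, pw in rep.pairwise.items() if name in key
            ]
            assert len(pair_vals) == 3
            assert rep.average_kappa[name] == pytest.approx(np.mean(pair_vals))

    def test_pairwise_matrix_symmetric(self):
        sets, _ = hp.generate_annotation_sets(40, (0.1, 0.2, 0.3), seed=1)
        rep = hp.average_metrics(sets, with_ci=False)
        m = rep.kappa_matrix()
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.isnan(np.diag(m.values)).all()

    def test_wrong_set_count_rejected_in_strict_mode(self):
        sets, _ = hp.generate_annotation_sets(10, (0.1, 0.2, 0.3), seed=1)
        with pytest.raises(ValueError):
            hp.average_metrics(sets[:3])
        rep = hp.average_metrics(sets[:3], strict_four=False, with_ci=False)
        assert len(rep.pairwise) == 3


def test_heatmap_rendering_writes_figure(tmp_path):
    sets, _ = hp.generate_annotation_sets(20, (0.1, 0.2, 0.2), seed=6)
    rep = hp.average_metrics(sets, with_ci=False)
    out = tmp_path / "heatmaps.png"
    from histopat.agreement import render_agreement_heatmaps

    render_agreement_heatmaps(rep, out)
    assert out.exists() and out.stat().st_size > 0


def test_annotation_csv_round_trip(tmp_path):
    sets, _ = hp.generate_annotation_sets(15, (0.2, 0.2, 0.2), seed=4)
    path = tmp_path / "annos.csv"
    write_annotation_csv(sets, path)
    back = read_annotation_csv(path)
    assert {s.annotator_id for s in back} == {s.annotator_id for s in sets}
    by = {s.annotator_id: s for s in back}
    for s in sets:
        assert by[s.annotator_id].labels == s.labels
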