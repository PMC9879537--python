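"""Metrics, breadth, sample downsampling, and alignment identity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expresso.core import ExpressionMap
from expresso.errors import EvaluationError
from expresso.evaluation import (
    downsample_by_clustering,
    expression_breadth,
    nw_identity,
    precision_recall,
    roc_auc,
    sensitivity_specificity,
)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, *_ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, *_ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_four_score_example_by_exhaustive_pair_counting(self):
        scores = [0.9, 0.8, 0.4, 0.3]
        labels = [1, 0, 1, 0]
        # Mann-Whitney oracle: fraction of (pos, neg) pairs correctly ordered
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        oracle = np.mean(
            [1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg]
        )
        assert oracle == 0.75
        auc, *_ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.9], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1), st.booleans()), min_size=4, max_size=40))
    def test_matches_mann_whitney_oracle_and_complement_rule(self, data):
        scores = [s for s, _ in data]
        labels = [int(l) for _, l in data]
        if len(set(labels)) < 2:
            return
        pos = [s for s, l in zip(scores, labels) if l]
        neg = [s for s, l in zip(scores, labels) if not l]
        oracle = np.mean(
            [1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg]
        )
        auc, *_ = roc_auc(scores, labels)
        assert auc == pytest.approx(oracle)
        if len(set(scores)) == len(scores):  # tie-free
            auc_neg, *_ = roc_auc([-s for s in scores], labels)
            assert auc + auc_neg == pytest.approx(1.0)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a1, *_ = roc_auc(scores, labels)
        a2, *_ = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)


class TestPrecisionRecall:
    def test_perfect_separation_has_precision_one_at_full_recall(self):
        ap, precision, recall, _ = precision_recall([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ap == 1.0
        assert precision[recall == 1.0].max() == 1.0

    def test_constant_scores_give_prevalence_precision(self):
        ap, precision, recall, _ = precision_recall([0.5] * 4, [1, 0, 0, 0])
        at_full_recall = precision[recall == 1.0]
        assert at_full_recall[0] == pytest.approx(0.25)

    def test_curve_matches_brute_force_threshold_sweep(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([1, 0, 1, 0])
        _, precision, recall, thresholds = precision_recall(scores, labels)
        for t, p, r in zip(thresholds, precision[:-1], recall[:-1]):
            pred = scores >= t
            tp = int(np.sum(pred & (labels == 1)))
            fp = int(np.sum(pred & (labels == 0)))
            fn = int(np.sum(~pred & (labels == 1)))
            assert p == pytest.approx(tp / (tp + fp))
            assert r == pytest.approx(tp / (tp + fn))


class TestSensitivitySpecificity:
    def test_perfect_classifier(self):
        sens, spec, counts = sensitivity_specificity(
            [1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0], threshold=0.5
        )
        assert (sens, spec) == (1.0, 1.0)
        assert counts.total == 4

    def test_threshold_zero_marks_everything_positive(self):
        sens, spec, _ = sensitivity_specificity(
            [0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0], threshold=0.0
        )
        assert (sens, spec) == (1.0, 0.0)

    def test_hand_counted_example(self):
        sens, spec, counts = sensitivity_specificity(
            [0.9, 0.6, 0.4], [1, 0, 1], threshold=0.5
        )
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (1, 1, 1, 0)
        assert (sens, spec) == (0.5, 0.0)

    def test_score_at_threshold_counts_negative(self):
        sens, spec, counts = sensitivity_specificity(
            [0.5, 0.7], [1, 0], threshold=0.5
        )
        assert counts.FN == 1  # exactly-at-threshold is predicted negative


class TestExpressionBreadth:
    def test_uniform_profile_has_breadth_one(self):
        assert expression_breadth([7, 7, 7, 7]) == 1.0

    def test_single_sample_expression(self):
        profile = [0] * 9 + [100]
        assert expression_breadth(profile, min_fraction_of_max=0.1) == pytest.approx(0.1)

    def test_all_zero_profile_unclassifiable(self):
        assert np.isnan(expression_breadth([0, 0, 0]))


class TestBreadthStratifiedClassification:
    def test_broad_pattern_genes_classify_at_least_as_well_as_narrow(self, small_sim):
        """Genes expressed across many samples give the classifier more signal
        than narrowly expressed ones."""
        from expresso.classifier import compute_expression_scores
        from expresso.core import GenePair
        from expresso.evaluation import stratify_by_breadth

        sim = small_sim
        es = compute_expression_scores(
            sim.map_a, sim.map_b, sim.orthopairs, orthogroups=[],
            n_iterations=3, k=10, base_seed=2,
        )
        _, broad_a, narrow_a = stratify_by_breadth(sim.map_a)
        pos = sim.orthopairs.as_set()
        rows = [
            (GenePair(*t), s, 1 if GenePair(*t) in pos else 0)
            for t, s in es.frame["final_es"].items()
        ]
        aucs = {}
        for name, geneset in [("broad", broad_a), ("narrow", narrow_a)]:
            sub = [(s, l) for p, s, l in rows if p.gene_a in geneset]
            aucs[name], *_ = roc_auc([s for s, _ in sub], [l for _, l in sub])
        assert aucs["broad"] >= aucs["narrow"]


class TestDownsampling:
    def _map(self, arr, cols):
        return ExpressionMap(
            "sp",
            pd.DataFrame(np.asarray(arr), index=[f"g{i}" for i in range(len(arr))], columns=cols),
        )

    def test_identical_columns_collapse_to_one(self):
        emap = self._map([[5, 5], [1, 1], [9, 9]], ["s1", "s2"])
        red = downsample_by_clustering(emap, cut_height=0.05, seed=0)
        assert red.n_samples == 1
        assert red.gene_ids == emap.gene_ids

    def test_cut_above_root_keeps_single_sample(self):
        rng = np.random.default_rng(0)
        emap = self._map(rng.integers(0, 100, (20, 5)), [f"s{i}" for i in range(5)])
        red = downsample_by_clustering(emap, cut_height=1.99, seed=0)
        assert red.n_samples == 1

    def test_cut_below_all_merges_is_identity(self):
        rng = np.random.default_rng(1)
        emap = self._map(rng.integers(0, 100, (30, 6)), [f"s{i}" for i in range(6)])
        red = downsample_by_clustering(emap, cut_height=1e-6, seed=0)
        assert red.n_samples == 6
        pd.testing.assert_frame_equal(red.data, emap.data)

    def test_exclusion_list_drops_labels_first(self):
        emap = self._map(
            [[1, 2, 3, 4], [5, 6, 7, 8]], ["anther.1", "anther.2", "root.1", "root.2"]
        )
        red = downsample_by_clustering(
            emap, cut_height=1e-6, seed=0, exclude_labels={"anther"}
        )
        assert set(red.sample_labels) == {"root"}


def _affine_alignment_oracle(a, b, subst, gap_open, gap_extend):
    """Enumerate every global alignment of two short sequences; return max score.

    Alignments are built column by column: match, gap-in-a, or gap-in-b, with
    affine scoring (first gap residue gap_open, extensions gap_extend).
    """
    best = [-np.inf]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + subst[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            rec(i + 1, j, score + cost, "a")
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            rec(i, j + 1, score + cost, "b")

    rec(0, 0, 0.0, "m")
    return best[0]


class TestNwIdentity:
    def test_identical_sequences(self):
        res = nw_identity("MKVLA", "MKVLA")
        assert res.identity == 1.0
        assert res.aligned_length == 5
        assert res.identical_positions == 5

    def test_terminal_gap_example(self):
        res = nw_identity("MKVA", "MKV")
        assert res.aligned_length == 4
        assert res.identical_positions == 3
        assert res.identity == pytest.approx(0.75)

    def test_empty_or_invalid_sequences_rejected(self):
        with pytest.raises(EvaluationError):
            nw_identity("", "MKV")
        with pytest.raises(EvaluationError):
            nw_identity("MKO", "MKV")  # O is not an amino-acid code

    @pytest.mark.parametrize(
        "a,b",
        [
            ("MKV", "MV"),
            ("ACDEFG", "ADG"),
            ("WWW", "WAW"),
            ("MKVLAG", "KVLG"),
            ("HHH", "PPP"),
        ],
    )
    def test_score_matches_brute_force_enumeration(self, a, b):
        from Bio.Align import substitution_matrices

        subst = substitution_matrices.load("BLOSUM62")
        expected = _affine_alignment_oracle(a, b, subst, -11.0, -1.0)
        res = nw_identity(a, b)
        assert res.score == pytest.approx(expected)
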