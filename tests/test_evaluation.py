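import numpy as np
import pandas as pd
import pytest
from scipy import stats

from squigselect import evaluation as ev


def auroc_pairwise(probs, labels):
    """Brute-force pairwise AUROC oracle (ties count one half)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def u1_pairwise(control, treatment):
    total = 0.0
    for a in control:
        for b in treatment:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total


class TestClassificationMetrics:
    def test_perfect_separation(self):
        rep = ev.classification_metrics([0.9, 0.1], [1, 0])
        assert rep.accuracy == 1.0
        assert rep.auroc == 1.0
        assert rep.tpr == 1.0 and rep.fpr == 0.0
        assert rep.tpr_fpr_ratio == float("inf")

    def test_auroc_equals_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            rep = ev.classification_metrics(p, y)
            assert rep.auroc == pytest.approx(auroc_pairwise(p, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUROC"):
            ev.classification_metrics([0.4, 0.5], [1, 1])

    def test_per_biotype_accuracy_matches_partition(self):
        rep = ev.classification_metrics(
            [0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0],
            biotypes=["mRNA", "mRNA", "lncRNA", "lncRNA"])
        assert rep.per_biotype_accuracy["mRNA"] == 0.5  # one of two correct
        assert rep.per_biotype_accuracy["lncRNA"] == 0.5


class TestThresholdSelection:
    def test_confident_at_two_seconds_is_correct(self):
        out = ev.threshold_selection({2: np.array([0.95]), 3: np.array([np.nan]),
                                      4: np.array([np.nan])}, [1],
                                     candidates=(0.9,))
        assert out.loc[0.9, "correct"] == 1.0

    def test_never_confident_is_undecided(self):
        out = ev.threshold_selection({n: np.array([0.7]) for n in (2, 3, 4)}, [1],
                                     candidates=(0.9,))
        assert out.loc[0.9, "undecided"] == 1.0

    def test_first_exceedance_wins(self):
        # at T=0.6 the 2 s probability decides; the later 0.05 (which would
        # flip the call) must never be consulted
        probs = {2: np.array([0.7]), 3: np.array([0.05]), 4: np.array([0.05])}
        out = ev.threshold_selection(probs, [1], candidates=(0.6,))
        assert out.loc[0.6, "correct"] == 1.0

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(1)
        probs = {n: rng.random(50) for n in (2, 3, 4)}
        out = ev.threshold_selection(probs, rng.integers(0, 2, 50))
        np.testing.assert_allclose(out.sum(axis=1), 1.0)


class TestProbabilityOfSuperiority:
    def test_complete_separation(self):
        es = ev.probability_of_superiority([3, 4], [1, 2])
        assert es.u1 == 4.0 and es.ps == 1.0

    def test_tie_convention(self):
        es = ev.probability_of_superiority([5], [5])
        assert es.ps == 0.5

    def test_equal_distributions_near_half(self):
        rng = np.random.default_rng(2)
        es = ev.probability_of_superiority(rng.standard_normal(2000),
                                           rng.standard_normal(2000))
        assert abs(es.ps - 0.5) <= 0.05

    def test_rank_and_pairwise_constructions_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 20, size=int(rng.integers(2, 40))).astype(float)
            y = rng.integers(0, 20, size=int(rng.integers(2, 40))).astype(float)
            es = ev.probability_of_superiority(x, y)
            assert es.u1 == pytest.approx(u1_pairwise(x, y), abs=1e-9)
            # independent route: scipy's Mann-Whitney U statistic
            assert es.u1 == pytest.approx(
                stats.mannwhitneyu(x, y, alternative="greater").statistic, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.probability_of_superiority([], [1.0])


class TestPercentChangeTable:
    def test_worked_example(self):
        out = ev.percent_change_table({"A": 100, "B": 50, "C": 2},
                                      {"A": 10, "B": 60, "C": 1})
        assert "C" not in out.index  # < 30 in both conditions
        assert out.loc["A", "percent_change"] == pytest.approx(-90.0)
        assert out.loc["B", "percent_change"] == pytest.approx(20.0)
        assert len(out) == 2

    def test_identical_tables_zero_change(self):
        counts = {"A": 100, "B": 60}
        out = ev.percent_change_table(counts, counts)
        assert (out.percent_change == 0).all()

    def test_control_mass_filter(self):
        # D sits in the tail beyond the 95% control mass and is dropped
        # even though it clears the count filter
        ctrl = {"A": 800, "B": 150, "C": 40, "D": 35}
        out = ev.percent_change_table(ctrl, ctrl)
        assert list(out.index) == ["A", "B", "C"]

    def test_lncrna_overlap_exclusion(self):
        biotypes = {"A": "mRNA", "L1": "lncRNA", "L2": "lncRNA"}
        exons = {"L1": [(0, 100)], "L2": [(500, 600)]}
        coding = [(50, 150)]
        out = ev.percent_change_table(
            {"A": 100, "L1": 90, "L2": 80}, {"A": 100, "L1": 90, "L2": 80},
            biotypes=biotypes, exons=exons, coding_exons=coding,
            exclude_lncrna_overlap=True)
        assert "L1" not in out.index  # shares bases 50-100 with a coding exon
        assert "L2" in out.index

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ev.percent_change_table({"A": 100}, {"A": 100}, biotypes={},
                                    exons={}, coding_exons=[],
                                    exclude_lncrna_overlap=True)

    def test_input_order_invariance(self):
        a = {"A": 100, "B": 50, "C": 40}
        b = {"C": 40, "A": 100, "B": 50}
        t = {"A": 90, "B": 55, "C": 45}
        pd.testing.assert_frame_equal(ev.percent_change_table(a, t),
                                      ev.percent_change_table(b, t))


class TestRelativeAbundance:
    def test_even_split(self):
        fa, fb, r, p = ev.relative_abundance({"A": 50, "B": 50, "C": 30},
                                             {"A": 50, "B": 50, "C": 30})
        assert fa["A"] == pytest.approx(50 / 130)
        assert fa.sum() == pytest.approx(1.0)

    def test_scale_invariance_gives_perfect_correlation(self):
        c1 = {"A": 50, "B": 30, "C": 20}
        c2 = {k: 2 * v for k, v in c1.items()}
        _, _, r, _ = ev.relative_abundance(c1, c2)
        assert r == pytest.approx(1.0)

    def test_matches_direct_pearson(self):
        c1 = {"A": 50, "B": 30, "C": 20, "D": 15, "E": 12}
        c2 = {"A": 40, "B": 45, "C": 11, "D": 30, "E": 22}
        fa, fb, r, p = ev.relative_abundance(c1, c2)
        r2, p2 = stats.pearsonr(fa.values, fb.values)
        assert r == pytest.approx(r2) and p == pytest.approx(p2)

    def test_low_count_exclusion_and_renormalization(self):
        fa, fb, _, _ = ev.relative_abundance({"A": 100, "B": 100, "C": 5, "D": 20},
                                             {"A": 100, "B": 100, "C": 5, "D": 20})
        assert "C" not in fa.index
        assert fa.sum() == pytest.approx(1.0)

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError):
            ev.relative_abundance({"A": 50, "B": 50}, {"A": 50, "B": 50})


class TestBiasAudit:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["class", "transcript_id", "decision"])

    def test_all_correct(self):
        df = self._frame([("target", "t1", "reject"), ("nontarget", "t2", "accept")])
        out = ev.bias_audit(df, targets=["target"])
        assert (out["correct"] == 1.0).all()

    def test_all_undecided(self):
        df = self._frame([("target", "t1", "no_decision")] * 3)
        out = ev.bias_audit(df, targets=["target"])
        assert out.loc["target", "no_decision"] == 1.0

    def test_mixed_table_matches_hand_tally(self):
        rows = ([("target", "t1", "reject")] * 5       # correct
                + [("target", "t1", "accept")] * 2     # incorrect
                + [("target", "t1", "no_decision")] * 3)
        out = ev.bias_audit(self._frame(rows), targets=["target"])
        assert out.loc["target"].tolist() == pytest.approx([0.5, 0.2, 0.3])
        per_tx = ev.bias_audit(self._frame(rows), targets=["target"],
                               group_by="transcript_id")
        assert per_tx.loc["t1"].tolist() == pytest.approx([0.5, 0.2, 0.3])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        rows = [(rng.choice(["target", "nontarget"]), "t",
                 rng.choice(["accept", "reject", "no_decision"]))
                for _ in range(50)]
        out = ev.bias_audit(self._frame(rows), targets=["target"])
        np.testing.assert_allclose(out.sum(axis=1), 1.0)


class TestCoverage:
    def test_full_length_read(self):
        assert ev.covered_fraction((0, 100), 100) == 1.0
        np.testing.assert_array_equal(ev.coverage_profile([(0, 100)], 100),
                                      np.full(100, 100.0))

    def test_half_truncated(self):
        assert ev.covered_fraction((0, 50), 100) == 0.5

    def test_three_read_step_function(self):
        prof = ev.coverage_profile([(0, 4), (0, 2), (1, 3)], 4)
        np.testing.assert_allclose(prof, [200 / 3, 100.0, 200 / 3, 100 / 3])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            ev.covered_fraction((0, 101), 100)
        with pytest.raises(ValueError):
            ev.coverage_profile([(-1, 5)], 100)


class TestCountsFromRun:
    def _table(self):
        return pd.DataFrame({
            "condition": ["control", "control", "treatment", "treatment"],
            "transcript_id": ["A", "A", "A", "B"],
            "delivered_transcript_samples": [8600, 8600, 2000, 8600],
        })

    def test_read_counts_with_mappability_filter(self):
        ctrl, trt = ev.counts_from_run(self._table(), samples_per_nt=43)
        assert ctrl["A"] == 2
        # the 2000-sample truncation (< 1 s of transcript) is unmappable
        assert "A" not in trt.index
        assert trt["B"] == 1

    def test_nucleotide_counts(self):
        ctrl, trt = ev.counts_from_run(self._table(), samples_per_nt=43,
                                       unit="nucleotides")
        assert ctrl["A"] == pytest.approx(2 * 8600 / 43)
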