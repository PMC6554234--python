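"""Metric suite, fold splitting, ROC/AUC, CV harness, composition analysis."""

import numpy as np
import pytest
import scipy.stats

from acpred import (
    ConfusionCounts,
    LabeledDataset,
    Peptide,
    aa_composition,
    composition_comparison,
    compute_metrics,
    confusion,
    cross_validate,
    generate_dataset,
    kfold_split,
    roc_auc,
)
from acpred.evaluation import METRIC_NAMES


def brute_force_metrics(tp, tn, fp, fn):
    """Independent re-derivation of the five confusion metrics (fractions)."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / den**0.5 if den else 0.0
    return acc, sens, spec, prec, mcc


class TestConfusion:
    def test_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.FP == 0 and c.FN == 0

    def test_all_positive_prediction(self):
        y = [1] * 50 + [0] * 50
        c = confusion(y, [1] * 100)
        assert (c.TP, c.FP, c.TN, c.FN) == (50, 50, 0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_total_invariant(self):
        c = confusion([1, 0, 1, 0, 1], [0, 0, 1, 1, 1])
        assert c.total == 5


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert (m.acc, m.sens, m.spec, m.prec, m.mcc) == (100, 100, 100, 100, 100)

    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(TP=90, FN=10, TN=80, FP=20))
        assert m.sens == pytest.approx(90.0)
        assert m.spec == pytest.approx(80.0)
        assert m.acc == pytest.approx(85.0)
        assert m.prec == pytest.approx(100 * 90 / 110)
        assert m.mcc == pytest.approx(100 * 7000 / np.sqrt(110 * 100 * 100 * 90))

    def test_zero_denominator_convention(self, caplog):
        with caplog.at_level("WARNING"):
            m = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert m.prec == 0.0 and m.mcc == 0.0
        assert any("zero denominator" in r.message for r in caplog.records)

    def test_brute_force_on_random_tables(self):
        """Formulas agree with an independent implementation on 1,000 tables."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 60, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            acc, sens, spec, prec, mcc = brute_force_metrics(tp, tn, fp, fn)
            assert m.acc == pytest.approx(100 * acc, abs=1e-9)
            assert m.sens == pytest.approx(100 * sens, abs=1e-9)
            assert m.spec == pytest.approx(100 * spec, abs=1e-9)
            assert m.prec == pytest.approx(100 * prec, abs=1e-9)
            assert m.mcc == pytest.approx(100 * mcc, abs=1e-9)

    def test_mcc_symmetric_under_class_swap(self):
        """Swapping classes and predictions together leaves MCC (and Acc) fixed."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, tn, fp, fn = (int(v) + 1 for v in rng.integers(0, 40, size=4))
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            swapped = compute_metrics(ConfusionCounts(TP=tn, TN=tp, FP=fn, FN=fp))
            assert m.mcc == pytest.approx(swapped.mcc, abs=1e-9)
            assert m.acc == pytest.approx(swapped.acc, abs=1e-9)


class TestKfoldSplit:
    def test_equal_sizes_740(self):
        labels = np.r_[np.ones(376), np.zeros(364)]
        split = kfold_split(740, labels=labels, seed=1)
        assert sorted(len(t) for t in split.test_indices) == [148] * 5

    def test_remainder_distribution_742(self):
        labels = np.r_[np.ones(371), np.zeros(371)]
        split = kfold_split(742, labels=labels, seed=1)
        assert sorted(len(t) for t in split.test_indices) == [148, 148, 148, 149, 149]

    def test_determinism(self):
        labels = np.r_[np.ones(30), np.zeros(30)]
        a = kfold_split(60, labels=labels, seed=9)
        b = kfold_split(60, labels=labels, seed=9)
        for ta, tb in zip(a.test_indices, b.test_indices):
            assert np.array_equal(ta, tb)

    def test_partition_and_no_leakage(self):
        labels = np.r_[np.ones(23), np.zeros(30)]
        split = kfold_split(53, labels=labels, seed=4)
        seen = np.concatenate(split.test_indices)
        assert np.array_equal(np.sort(seen), np.arange(53))
        for train, test in split.folds():
            assert np.intersect1d(train, test).size == 0

    def test_stratification_balances_classes(self):
        labels = np.r_[np.ones(40), np.zeros(60)]
        split = kfold_split(100, labels=labels, seed=2)
        for test in split.test_indices:
            assert labels[test].sum() == 8  # 40/5 positives per fold

    def test_unstratified_mode(self):
        split = kfold_split(20, n_folds=4, seed=0, stratified=False)
        assert sorted(len(t) for t in split.test_indices) == [5] * 4

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(10, n_folds=1, stratified=False)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(77)
        y = rng.integers(0, 2, size=2000)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=2000)
        _, auc = roc_auc(y, rng.random(2000))
        assert abs(auc - 0.5) < 0.05

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_mann_whitney(self, seed):
        """AUC = U/(n₊·n₋), the rank-statistic identity (no ties)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        y = np.r_[np.ones(n), np.zeros(n)]
        s = rng.normal(size=2 * n) + 0.4 * y
        _, auc = roc_auc(y, s)
        u_stat = scipy.stats.mannwhitneyu(s[y == 1], s[y == 0]).statistic
        assert auc == pytest.approx(u_stat / (n * n), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0, 1], [np.nan, 0.5])


@pytest.fixture(scope="module")
def small_dataset():
    return generate_dataset(n_positive=30, n_negative=30, seed=5,
                            length_range=(10, 30))


def fast_lstm(seed):
    from acpred.lstm import LSTMClassifier, LSTMConfig

    return LSTMClassifier(LSTMConfig(hidden_units=16, epochs=8, seed=seed))


class TestCrossValidate:
    def test_mean_is_arithmetic_mean_and_sd_is_sample_sd(self, small_dataset):
        report = cross_validate(small_dataset, "nb", seed=1)
        for metric in METRIC_NAMES:
            values = [getattr(m, metric) for m in report.per_fold]
            assert report.mean(metric) == pytest.approx(np.mean(values), abs=1e-9)
            assert report.sd(metric) == pytest.approx(np.std(values, ddof=1), abs=1e-9)

    def test_end_to_end_determinism(self, small_dataset):
        a = cross_validate(small_dataset, fast_lstm, seed=3)
        b = cross_validate(small_dataset, fast_lstm, seed=3)
        assert a.to_json() == b.to_json()

    def test_unknown_model_lists_available(self, small_dataset):
        with pytest.raises(ValueError, match="lstm"):
            cross_validate(small_dataset, "perceptron")

    def test_single_class_dataset_rejected(self):
        ds = LabeledDataset(
            [Peptide(f"p{i}", s, 1) for i, s in enumerate(["ACDE", "CDEF", "KLMN",
                                                           "MNPQ", "QRST"])]
        )
        with pytest.raises(ValueError, match="both classes"):
            cross_validate(ds, "nb")

    def test_report_table_layout(self, small_dataset):
        report = cross_validate(small_dataset, "nb", seed=1)
        frame = report.as_frame()
        assert list(frame.index) == [f"fold{i}" for i in range(1, 6)] + ["mean", "sd"]
        text = report.summary()
        assert "Mean" in text and "SD" in text


class TestComposition:
    def test_homopolymer(self):
        comp = aa_composition([Peptide("p", "AAAA")])
        assert comp[0] == 1.0 and comp[1:].sum() == 0.0

    def test_two_residue_mix(self):
        comp = aa_composition([Peptide("a", "AC"), Peptide("b", "CA")])
        assert comp[0] == 0.5 and comp[1] == 0.5

    def test_mixture_conservation(self, small_dataset):
        """Total composition is the residue-count-weighted class mixture."""
        pos, neg = small_dataset.positives(), small_dataset.negatives()
        n_pos = sum(len(p) for p in pos)
        n_neg = sum(len(p) for p in neg)
        mixed = (n_pos * aa_composition(pos) + n_neg * aa_composition(neg)) / (
            n_pos + n_neg
        )
        assert np.allclose(aa_composition(small_dataset), mixed, atol=1e-12)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            aa_composition([])

    def test_comparison_columns_sum_to_one(self, small_dataset):
        table = composition_comparison(small_dataset)
        for col in ("positive", "negative", "total"):
            assert table[col].sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(
            table["difference"], table["positive"] - table["negative"]
        )

    def test_enriched_residues_stand_out(self):
        """Generator-enriched residues show higher positive-class fractions."""
        ds = generate_dataset(
            n_positive=150, n_negative=150, seed=11,
            enriched_positive=frozenset("FHI"), enriched_negative=frozenset("LQ"),
        )
        table = composition_comparison(ds).set_index("residue")
        for aa in "FHI":
            assert table.loc[aa, "positive"] > table.loc[aa, "negative"]

    def test_identical_classes_show_no_signal(self):
        """enrichment 1: |positive − negative| < 0.02 at 10⁴ residues/class."""
        ds = generate_dataset(
            n_positive=400, n_negative=400, seed=13, enrichment_factor=1.0,
            length_range=(25, 25),
        )
        table = composition_comparison(ds)
        assert table["difference"].abs().max() < 0.02

    def test_single_class_rejected(self):
        ds = LabeledDataset([Peptide("p", "ACDE", 1), Peptide("q", "CDEF", 1)])
        with pytest.raises(ValueError):
            composition_comparison(ds)
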