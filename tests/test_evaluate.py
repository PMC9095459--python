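"""Multi-label metrics and the repeated two-fold shuffle protocol."""

import numpy as np
import pytest

from binburden.evaluate import (
    PipelineSpec,
    ShuffleProtocol,
    exact_match_rate,
    hamming_loss,
    per_label_precision_recall,
    powerset_encode,
    two_fold_shuffle,
    _eligible,
)
from binburden.models import MLPConfig, PhenotypeMatrix
from binburden.select import RFParams
from binburden.variants import FunctionalCategory as FC

FAST_SPEC = PipelineSpec(RFParams(30, seed=0), MLPConfig(hidden_layer_sizes=(8,), max_iter=200, seed=0))


class TestHammingLoss:
    def test_perfect_prediction_is_zero(self, rng):
        Y = rng.integers(0, 2, (10, 8))
        assert hamming_loss(Y, Y) == 0.0

    def test_complement_is_one(self, rng):
        Y = rng.integers(0, 2, (10, 8))
        assert hamming_loss(Y, 1 - Y) == 1.0

    def test_direct_definition(self):
        t = np.array([[1, 0, 0, 1, 0, 0, 0, 0]])
        p = np.array([[1, 1, 0, 0, 0, 0, 0, 0]])
        assert hamming_loss(t, p) == 0.25

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            hamming_loss(np.zeros((2, 8)), np.zeros((3, 8)))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            hamming_loss(np.full((1, 8), 2), np.zeros((1, 8)))


class TestExactMatch:
    def test_identical_is_one(self, rng):
        Y = rng.integers(0, 2, (10, 8))
        assert exact_match_rate(Y, Y) == 1.0

    def test_one_wrong_label_in_one_of_two_rows(self):
        t = np.zeros((2, 8), dtype=int)
        p = t.copy()
        p[0, 3] = 1
        assert exact_match_rate(t, p) == 0.5

    def test_union_bound_against_hamming(self, rng):
        for _ in range(50):
            t = rng.integers(0, 2, (20, 8))
            p = rng.integers(0, 2, (20, 8))
            assert exact_match_rate(t, p) >= 1.0 - 8.0 * hamming_loss(t, p) - 1e-12


class TestPerLabelPrecisionRecall:
    def test_perfect_prediction(self, rng):
        Y = (rng.random((30, 8)) < 0.5).astype(int)
        Y[0] = 1  # every label has at least one positive
        p, r, pu, ru = per_label_precision_recall(Y, Y)
        assert (p == 1).all() and (r == 1).all()
        assert not pu.any() and not ru.any()

    def test_all_zero_predictions_flagged(self, rng):
        Y = rng.integers(0, 2, (10, 8))
        Y[0] = 1
        p, r, pu, ru = per_label_precision_recall(Y, np.zeros_like(Y))
        assert (p == 0).all() and (r == 0).all()
        assert pu.all() and not ru.any()

    def test_direct_formula(self):
        # one column: TP=2, FP=1, FN=1
        t = np.array([[1], [1], [0], [1]])
        p = np.array([[1], [1], [1], [0]])
        prec, rec, _, _ = per_label_precision_recall(t, p)
        assert prec[0] == pytest.approx(2 / 3)
        assert rec[0] == pytest.approx(2 / 3)


def test_metrics_match_bruteforce_double_loops(rng):
    """Vectorized metrics agree bit-exactly with index-by-index loops."""
    for _ in range(100):
        m = int(rng.integers(1, 12))
        t = rng.integers(0, 2, (m, 8))
        p = rng.integers(0, 2, (m, 8))
        mism = sum(1 for i in range(m) for j in range(8) if t[i, j] != p[i, j])
        exact = sum(1 for i in range(m) if all(t[i, j] == p[i, j] for j in range(8)))
        assert hamming_loss(t, p) == mism / (8 * m)
        assert exact_match_rate(t, p) == exact / m


def test_powerset_encoding_bijective_on_patterns(rng):
    Y = rng.integers(0, 2, (200, 8))
    codes = powerset_encode(Y)
    patterns = {tuple(row) for row in Y}
    assert len(set(codes)) == len(patterns)
    assert codes.min() >= 0 and codes.max() < 256


class TestEligibility:
    def make_phen(self):
        Y = np.zeros((6, 8), dtype=int)
        Y[0, 0] = 1  # single diagnosis
        Y[1, [0, 1]] = 1  # double
        Y[2, :6] = 1  # six diagnoses
        return PhenotypeMatrix([f"s{i}" for i in range(6)], Y)

    def test_case_control_uses_everyone(self):
        mask, y = _eligible("case_control", self.make_phen())
        assert mask.all()
        assert y.tolist() == [1, 1, 1, 0, 0, 0]

    def test_single_diagnosis_excludes_multimorbid(self):
        mask, y = _eligible("single_diagnosis_vs_control", self.make_phen())
        assert mask.tolist() == [True, False, False, True, True, True]
        assert y.tolist() == [1, 0, 0, 0]

    def test_multilabel_uses_patients_only(self):
        mask, Y = _eligible("multilabel", self.make_phen())
        assert mask.tolist() == [True, True, True, False, False, False]
        assert Y.shape == (3, 8)


class TestTwoFoldShuffle:
    def test_reports_reproducible_bit_for_bit(self, small_cohort):
        X = small_cohort.counts[FC.NONSYNONYMOUS]
        protocol = ShuffleProtocol("case_control", n_rounds=2, base_seed=5)
        r1 = two_fold_shuffle(X, small_cohort.phenotypes, protocol, FAST_SPEC)
        r2 = two_fold_shuffle(X, small_cohort.phenotypes, protocol, FAST_SPEC)
        assert r1.metrics == r2.metrics
        assert r1.round_seeds == r2.round_seeds == [5, 6]

    def test_multilabel_metrics_present_and_bounded(self, small_cohort):
        X = small_cohort.counts[FC.INTRONIC]
        protocol = ShuffleProtocol("multilabel", n_rounds=2, base_seed=1)
        rep = two_fold_shuffle(X, small_cohort.phenotypes, protocol, FAST_SPEC)
        assert set(rep.metrics) == {"hamming_loss", "exact_match_rate", "accuracy_per_cell"}
        for vals in rep.metrics.values():
            assert all(0.0 <= v <= 1.0 for v in vals)
        summary = rep.per_label_summary()
        assert summary.shape == (8, 4)
        # union bound holds on the round means too
        assert rep.mean("exact_match_rate") >= 1 - 8 * rep.mean("hamming_loss") - 1e-12

    def test_single_diagnosis_task_runs(self, small_cohort):
        X = small_cohort.counts[FC.UTR]
        rep = two_fold_shuffle(
            X, small_cohort.phenotypes, ShuffleProtocol("single_diagnosis_vs_control", 2, 3), FAST_SPEC
        )
        assert len(rep.metrics["accuracy"]) == 2

    def test_mean_sd_recomputable_from_rounds(self, small_cohort):
        X = small_cohort.counts[FC.NCRNA]
        rep = two_fold_shuffle(
            X, small_cohort.phenotypes, ShuffleProtocol("case_control", 3, 0), FAST_SPEC
        )
        vals = rep.metrics["accuracy"]
        assert rep.mean("accuracy") == pytest.approx(np.mean(vals))
        assert rep.sd("accuracy") == pytest.approx(np.std(vals, ddof=1))

    def test_rejects_single_class_cohort(self):
        phen = PhenotypeMatrix([f"s{i}" for i in range(8)], np.zeros((8, 8), dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            two_fold_shuffle(np.ones((8, 3)), phen, ShuffleProtocol("case_control", 1, 0), FAST_SPEC)

    def test_rejects_bad_protocol(self):
        with pytest.raises(ValueError, match="task"):
            ShuffleProtocol("threefold", 1, 0)
        with pytest.raises(ValueError, match="n_rounds"):
            ShuffleProtocol("case_control", 0, 0)

    def test_report_tsv_round_trip(self, small_cohort, tmp_path):
        X = small_cohort.counts[FC.STOPCODON]
        rep = two_fold_shuffle(
            X, small_cohort.phenotypes, ShuffleProtocol("case_control", 2, 0), FAST_SPEC
        )
        path = tmp_path / "report.tsv"
        rep.to_tsv(path)
        assert path.read_text().startswith("metric\tmean\tsd")
        assert len(rep.rounds_frame()) == 2
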