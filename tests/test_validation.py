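"""Metrics identities, record-wise fold plans, selection and repeated CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shockadvice import (
    ClassifierSpec,
    CnnConfig,
    GridSpec,
    build_cnne,
    compute_metrics,
    make_record_folds,
    train_cnne,
    validate_cv,
)
from shockadvice.records import ChannelStack
from shockadvice.validation import MetricsReport, best_by_accuracy, grid_search_select


class TestMetrics:
    def test_hand_counted_confusion_table(self):
        # TP=9 FN=1 TN=98 FP=2 -> Se=90, Sp=98, Ac=9700/110*?  -> 97.27, BER=6
        y = np.array([1] * 10 + [0] * 100)
        p = np.array([1] * 9 + [0] + [0] * 98 + [1] * 2)
        m = compute_metrics(y, p)
        assert (m.tp, m.fn, m.tn, m.fp) == (9, 1, 98, 2)
        assert m.se == pytest.approx(90.0)
        assert m.sp == pytest.approx(98.0)
        assert m.ac == pytest.approx(97.27, abs=0.01)
        assert m.ber == pytest.approx(6.0)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        m = compute_metrics(y, y)
        assert (m.ac, m.se, m.sp, m.ber) == (100.0, 100.0, 100.0, 0.0)

    def test_always_nsh_predictor(self):
        y = np.array([1, 0, 0, 1, 0])
        m = compute_metrics(y, np.zeros(5, dtype=int))
        assert (m.se, m.sp, m.ber) == (0.0, 100.0, 50.0)

    @settings(derandomize=True, max_examples=200)
    @given(tp=st.integers(0, 50), fn=st.integers(0, 50),
           tn=st.integers(0, 50), fp=st.integers(0, 50))
    def test_ber_identity_on_random_tables(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        y = np.array([1] * (tp + fn) + [0] * (tn + fp))
        p = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        m = compute_metrics(y, p)
        assert m.ber + (m.se + m.sp) / 2 == pytest.approx(100.0, abs=1e-9)
        for v in (m.ac, m.se, m.sp, m.ber):
            assert 0.0 <= v <= 100.0

    def test_absent_positive_class_warns_and_uses_sp(self):
        y = np.zeros(10, dtype=int)
        p = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning):
            m = compute_metrics(y, p)
        assert m.se is None
        assert m.ber == pytest.approx(100.0 - m.sp)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])

    def test_final_algorithm_chosen_by_highest_accuracy(self):
        def rpt(ac):
            return MetricsReport(tp=1, fn=0, tn=1, fp=0, ac=ac, se=100.0,
                                 sp=100.0, ber=0.0)

        reports = {"BS": rpt(99.2), "fCNN": rpt(98.4), "KNN": rpt(98.7)}
        assert best_by_accuracy(reports) == "BS"


class TestFoldPlans:
    def test_17_records_5_folds_sizes(self):
        plan = make_record_folds([f"r{i}" for i in range(17)], 5, seed=0)
        sizes = sorted(
            (np.array(list(plan.assignment.values())) == f).sum() for f in range(5)
        )
        assert sizes == [3, 3, 3, 4, 4]

    def test_leave_one_record_out(self):
        plan = make_record_folds(["a", "b", "c", "d", "e"], 5, seed=1)
        assert sorted(plan.assignment.values()) == [0, 1, 2, 3, 4]

    def test_same_seed_identical_assignment(self):
        ids = [f"r{i}" for i in range(12)]
        assert make_record_folds(ids, 4, seed=9).assignment == \
            make_record_folds(ids, 4, seed=9).assignment

    def test_every_record_in_exactly_one_fold(self):
        ids = [f"r{i}" for i in range(11)]
        plan = make_record_folds(ids, 3, seed=2)
        assert sorted(plan.assignment) == sorted(ids)
        for train, test in plan.splits():
            assert not (train & test)
            assert train | test == set(ids)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            make_record_folds(["a", "b"], 5)


def _tiny_stacks(n_records=4, per_record=6, length=400, seed=0):
    """Frequency-separable stacks with record structure, no MVMD needed."""
    t = np.arange(length) / 250.0
    stacks = []
    for r in range(n_records):
        for i in range(per_record):
            rr = np.random.default_rng(seed + 100 * r + i)
            lab = i % 2
            f = 4.0 if lab else 12.0
            sig = np.sin(2 * np.pi * f * t + rr.uniform(0, 6)) + 0.1 * rr.normal(size=length)
            stacks.append(ChannelStack(pecg=sig, sh_signal=sig, nsh_signal=sig,
                                       label=lab, record_id=f"rec{r}"))
    return stacks


class TestValidateCv:
    def test_leakage_between_extractor_and_eval_is_fatal(self):
        stacks = _tiny_stacks(n_records=4)
        extractor = build_cnne(CnnConfig(ns=1, nd=1, input_len=400))
        extractor.train_record_ids = {"rec0"}
        with pytest.raises(RuntimeError, match="leakage|evaluation records"):
            validate_cv(stacks, extractor, ClassifierSpec(name="BS"), k=2, reps=1)

    def test_repeated_cv_aggregation(self):
        train = _tiny_stacks(n_records=3, seed=0)
        evals = _tiny_stacks(n_records=4, seed=50)
        for s in evals:
            s.record_id = "ev" + s.record_id
        cfg = CnnConfig(ns=1, nd=1, input_len=400, epochs=4, batch_size=16)
        extractor = train_cnne(build_cnne(cfg, seed=1), train, seed=1)
        rep = validate_cv(evals, extractor, ClassifierSpec(name="BS"), k=2,
                          reps=3, seed=5)
        assert rep.n_reps == 3
        assert 0.0 <= rep.ac <= 100.0
        assert rep.ber + (rep.se + rep.sp) / 2 == pytest.approx(100.0, abs=1e-6)
        assert min(rep.rep_ac) <= rep.ac <= max(rep.rep_ac)

    def test_perfectly_separable_gives_perfect_scores(self):
        train = _tiny_stacks(n_records=3, seed=0)
        evals = _tiny_stacks(n_records=4, seed=77)
        for s in evals:
            s.record_id = "ev" + s.record_id
        cfg = CnnConfig(ns=2, nd=1, input_len=400, epochs=15, batch_size=16)
        extractor = train_cnne(build_cnne(cfg, seed=2), train, seed=2)
        rep = validate_cv(evals, extractor, ClassifierSpec(name="BS"), k=2,
                          reps=2, seed=3)
        assert rep.ac == pytest.approx(100.0)
        assert rep.ber == pytest.approx(0.0)
        assert rep.ac_std == pytest.approx(0.0)


class TestGridSearch:
    def test_grid_size_is_cartesian_product(self):
        g = GridSpec(ns=(1, 3), nd=(1, 2, 3), lr=(0.005, 0.01, 0.02),
                     momentum=(0.7, 0.8, 0.9), dropout=(0.1, 0.15, 0.2))
        assert len(g) == 2 * 3 * 3 * 3 * 3 == 162
        assert len(g.configs(input_len=400)) == 162

    def test_single_config_grid_wins_everywhere(self):
        stacks = _tiny_stacks(n_records=5, per_record=4)
        cfg = CnnConfig(ns=1, nd=1, input_len=400, epochs=2, batch_size=16)
        res = grid_search_select(stacks, [cfg], selectors=("KNN",), k=2, seed=0)
        assert res["fCNN"].config == cfg
        assert res["KNN"].config == cfg

    def test_selection_reproducible_and_minimal(self):
        stacks = _tiny_stacks(n_records=5, per_record=4)
        configs = [
            CnnConfig(ns=1, nd=1, lr=0.005, input_len=400, epochs=2, batch_size=16),
            CnnConfig(ns=1, nd=1, lr=0.02, input_len=400, epochs=2, batch_size=16),
        ]
        r1 = grid_search_select(stacks, configs, selectors=("KNN",), k=2, seed=4)
        r2 = grid_search_select(stacks, configs, selectors=("KNN",), k=2, seed=4)
        for scorer in r1:
            assert r1[scorer].config == r2[scorer].config
            assert r1[scorer].cv_ber == r2[scorer].cv_ber
            assert r1[scorer].cv_ber == min(b for _, b in r1[scorer].per_config_ber)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_select(_tiny_stacks(), [], k=2)
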