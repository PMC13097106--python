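"""Adverse-event labelling, group tests, discriminant analysis, ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hydronirs.cohort import (
    SessionLabel,
    auc_timecourse,
    feature_subset_search,
    group_compare,
    label_idh,
    lda_fit_score,
    roc_auc,
)


class TestSessionLabel:
    def test_adverse_iff_events_nonempty(self):
        assert not SessionLabel("a").adverse_event
        assert SessionLabel("b", events=[(30.0, "cramping")]).adverse_event

    def test_unknown_event_type_rejected(self):
        with pytest.raises(ValueError):
            SessionLabel("c", events=[(10.0, "sneezing")])


class TestLabelIDH:
    def test_systolic_drop_of_22_flagged(self):
        times = label_idh([(0.0, 140.0, 100.0), (30.0, 118.0, 95.0)])
        assert times == [30.0]

    def test_constant_pressure_no_events(self):
        records = [(t, 130.0, 95.0) for t in (0.0, 15.0, 30.0)]
        assert label_idh(records) == []

    def test_sub_threshold_drops_not_flagged(self):
        # SBP down 19, MAP down 9: both just below the rule boundary
        times = label_idh([(0.0, 140.0, 100.0), (15.0, 121.0, 91.0)])
        assert times == []

    def test_boundary_drops_flagged(self):
        assert label_idh([(0.0, 140.0, 100.0), (15.0, 120.0, 100.0)]) == [15.0]
        assert label_idh([(0.0, 140.0, 100.0), (15.0, 125.0, 90.0)]) == [15.0]

    def test_missing_baseline_warns_and_returns_empty(self):
        records = [(0.0, np.nan, np.nan), (15.0, 100.0, 70.0)]
        with pytest.warns(UserWarning, match="baseline"):
            assert label_idh(records) == []

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            label_idh([(0.0, 140.0, 100.0)])


class TestGroupCompare:
    def test_identical_groups(self):
        g = group_compare([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                          [True, True, True, False, False, False])
        assert g.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert g.p_value == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        g = group_compare([1.0, 2.0, 3.0, 11.0, 12.0, 13.0],
                          [False, False, False, True, True, True])
        assert g.p_value < 0.01
        assert g.mean_pos - g.mean_neg == pytest.approx(10.0)

    def test_matches_pooled_t_formula(self, rng):
        x = rng.normal(0.0, 1.0, 9)
        y = rng.normal(0.5, 1.2, 18)
        vals = np.concatenate([x, y])
        labels = np.array([False] * 9 + [True] * 18)
        g = group_compare(vals, labels)
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
            x.size + y.size - 2
        )
        t_direct = (y.mean() - x.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
        assert g.t_statistic == pytest.approx(t_direct, rel=1e-12)

    def test_missing_values_dropped(self):
        g = group_compare([1.0, np.nan, 2.0, 5.0, 6.0, np.nan, 7.0],
                          [False, False, False, True, True, True, True])
        assert g.n_neg == 2 and g.n_pos == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0, np.nan, np.nan],
                          [False, False, True, True])


def _table(x, y):
    df = pd.DataFrame({"f": x})
    df["adverse_event"] = y
    return df


class TestLDA:
    def test_well_separated_classes(self, rng):
        x = np.concatenate([rng.normal(0.0, 1.0, 50), rng.normal(5.0, 1.0, 50)])
        y = np.array([False] * 50 + [True] * 50)
        res = lda_fit_score(_table(x, y), ["f"], validation="resubstitution")
        accuracy = (res.tp + res.tn) / 100.0
        assert accuracy >= 0.98
        assert res.auc > 0.99
        assert res.tp + res.tn + res.fp + res.fn == 100

    def test_duplicated_feature_column_gives_same_scores(self, rng):
        x = np.concatenate([rng.normal(0.0, 1.0, 30), rng.normal(1.5, 1.0, 30)])
        y = np.array([False] * 30 + [True] * 30)
        df = pd.DataFrame({"f1": x, "f2": x.copy()})
        df["adverse_event"] = y
        single = lda_fit_score(df, ["f1"])
        double = lda_fit_score(df, ["f1", "f2"])
        # ridge absorbs the exact collinearity; scores agree after the
        # w-vector split across the two identical columns
        assert np.allclose(double.scores, single.scores, atol=1e-6)

    def test_permuted_labels_auc_centred_on_half(self, rng):
        # classical permutation null: scores from one fitted model, labels
        # permuted -- exchangeability makes the expected AUC exactly 0.5.
        # (Re-fitting per permutation would bias the mean: optimistically
        # for resubstitution, pessimistically for leave-one-out.)
        x = rng.standard_normal(40)
        y0 = np.array([True] * 20 + [False] * 20)
        res = lda_fit_score(_table(x, y0), ["f"])
        aucs = []
        for _ in range(100):
            _, auc = roc_auc(res.scores, rng.permutation(y0))
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_loocv_scores_each_subject_without_itself(self, rng):
        x = np.concatenate([rng.normal(0.0, 1.0, 10), rng.normal(3.0, 1.0, 10)])
        y = np.array([False] * 10 + [True] * 10)
        res = lda_fit_score(_table(x, y), ["f"], validation="loocv")
        assert res.validation_tag == "loocv"
        assert res.scores.size == 20

    def test_rows_with_missing_subset_values_dropped(self, rng):
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
        x[3] = np.nan
        y = np.array([False] * 10 + [True] * 10)
        res = lda_fit_score(_table(x, y), ["f"])
        assert res.n_dropped_missing == 1
        assert len(res.subject_ids) == 19

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit_score(_table([1.0, 2.0, 3.0], [True, False, False]), ["f"])


class TestROC:
    def test_perfect_separation(self):
        _, auc = roc_auc([1.0, 2.0, 3.0, 10.0, 11.0],
                         [False, False, False, True, True])
        assert auc == 1.0

    def test_all_scores_equal_gives_half(self):
        _, auc = roc_auc([1.0] * 10, [True] * 5 + [False] * 5)
        assert auc == pytest.approx(0.5)

    def test_matches_brute_force_concordance(self, rng):
        for n in (5, 12, 30):
            scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                labels[0] = not labels[0]
            _, auc = roc_auc(scores, labels)
            pos = scores[labels]
            neg = scores[~labels]
            conc = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p, q in itertools.product(pos, neg)
            ) / (pos.size * neg.size)
            assert auc == pytest.approx(conc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])


class TestSubsetSearch:
    def test_number_of_subsets_evaluated(self, rng):
        df = pd.DataFrame(rng.standard_normal((20, 5)),
                          columns=list("abcde"))
        df["adverse_event"] = [True] * 10 + [False] * 10
        ranking = feature_subset_search(df, max_subset_size=3)
        assert len(ranking) == 5 + 10 + 10  # C(5,1)+C(5,2)+C(5,3)

    def test_informative_feature_ranks_first_among_noise(self, rng):
        n = 60
        y = np.array([True] * 30 + [False] * 30)
        df = pd.DataFrame(rng.standard_normal((n, 4)),
                          columns=["n1", "n2", "n3", "n4"])
        df["signal"] = np.where(y, 1.3, 0.0) + rng.standard_normal(n)
        df["adverse_event"] = y
        ranking = feature_subset_search(df, max_subset_size=1)
        assert ranking.iloc[0]["subset"] == ("signal",)

    def test_default_subset_size_is_three(self, rng):
        df = pd.DataFrame(rng.standard_normal((12, 4)), columns=list("abcd"))
        df["adverse_event"] = [True] * 6 + [False] * 6
        ranking = feature_subset_search(df)
        assert ranking["size"].max() == 3


class TestAUCTimecourse:
    def _traces(self, values_by_subject, grid):
        return pd.DataFrame.from_dict(values_by_subject, orient="index",
                                      columns=grid)

    def test_label_aligned_feature_gives_auc_one_everywhere(self, rng):
        grid = np.linspace(0.0, 100.0, 11)
        subjects = {f"s{i}": np.full(11, 1.0 + i) for i in range(10)}
        traces = {"f": self._traces(subjects, grid)}
        labels = pd.Series({f"s{i}": i >= 5 for i in range(10)})
        out = auc_timecourse(traces, labels, ("f",))
        assert len(out) == 11
        assert np.allclose(out["auc"], 1.0)

    def test_permuted_labels_stay_near_chance(self, rng):
        # with 200 subjects the resubstitution optimism of the per-point fit
        # is small, so the permutation mean sits in the chance band
        n = 200
        grid = np.linspace(0.0, 100.0, 6)
        subjects = {f"s{i}": rng.standard_normal(6) for i in range(n)}
        traces = {"f": self._traces(subjects, grid)}
        aucs = []
        for _ in range(50):
            labels = pd.Series(dict(zip(
                subjects, rng.permutation([True] * (n // 2) + [False] * (n // 2))
            )))
            out = auc_timecourse(traces, labels, ("f",),
                                 validation="resubstitution")
            aucs.append(out["auc"].mean())
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_grid_length_matches_resolution(self, rng):
        grid = np.linspace(0.0, 100.0, 101)
        subjects = {f"s{i}": rng.standard_normal(101) for i in range(8)}
        labels = pd.Series({f"s{i}": i % 2 == 0 for i in range(8)})
        out = auc_timecourse({"f": self._traces(subjects, grid)}, labels, ("f",),
                             validation="resubstitution")
        assert len(out) == 101
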