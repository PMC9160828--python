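"""Labeling rules, balanced sampling combinatorics, and the LOO engine contracts."""

import json

import numpy as np
import pytest

from tmsresp import (
    SubjectRecord,
    label_subjects,
    max_balanced_subset,
    n_trials_required,
    run_loo,
    direct_classification,
    size_sweep,
    permutation_null_band,
    TMS_POS,
    TMS_NEG,
)
from tmsresp.errors import ParameterError, TmsrespError


class TestLabelSubjects:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(18, 21, TMS_POS), (20, 20, TMS_POS), (22, 19, TMS_NEG)],
    )
    def test_labeling_rules(self, pre, post, expected):
        recs = label_subjects([{"subject_id": "P1", "mmse_pre": pre, "mmse_post": post}])
        assert recs[0].label == expected

    def test_missing_score_names_subject(self):
        with pytest.raises(ParameterError, match="P7"):
            label_subjects([{"subject_id": "P7", "mmse_pre": 18, "mmse_post": None}])

    def test_out_of_range_score(self):
        with pytest.raises(ParameterError):
            label_subjects([{"subject_id": "P1", "mmse_pre": 35, "mmse_post": 20}])

    def test_inconsistent_record_rejected(self):
        with pytest.raises(ParameterError):
            SubjectRecord("P1", 20, 15, TMS_POS)


class TestBalancedSampling:
    @pytest.mark.parametrize(
        "n_pos,n_neg,expected_total",
        [(7, 6, 12), (8, 5, 10), (3, 3, 6)],
    )
    def test_maximal_balanced_size(self, n_pos, n_neg, expected_total, rng):
        ids = {
            TMS_POS: [f"p{i}" for i in range(n_pos)],
            TMS_NEG: [f"n{i}" for i in range(n_neg)],
        }
        subset = max_balanced_subset(ids, rng)
        sizes = [len(v) for v in subset.values()]
        assert sum(sizes) == expected_total
        assert sizes[0] == sizes[1]

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ParameterError):
            max_balanced_subset({TMS_POS: ["a"], TMS_NEG: []}, rng)

    def test_trial_counts(self):
        # balanced input: a single distinct subset before train/val partitioning
        assert n_trials_required(6, 6, val_per_class=0) == 1
        # one surplus: C(7,1) = 7 distinct subsets
        assert n_trials_required(7, 6, val_per_class=0) == 7
        # partition factor C(6,1)^2 = 36 caps at the default 50
        assert n_trials_required(7, 6, cap=50, val_per_class=1) == 50
        assert n_trials_required(6, 6, cap=50, val_per_class=1) == 36


def make_cohort_features(rng, n_pos=4, n_neg=3, n_feat=20, effect=0.0):
    subjects, rows = [], []
    for i in range(n_pos + n_neg):
        label = TMS_POS if i < n_pos else TMS_NEG
        pre = 20
        post = 22 if label == TMS_POS else 18
        subjects.append(SubjectRecord(f"S{i:02d}", pre, post, label))
        shift = effect if label == TMS_POS else 0.0
        rows.append(rng.standard_normal(n_feat) + shift)
    return np.vstack(rows), subjects


class TestLOOEngine:
    def test_one_entry_per_subject(self, rng):
        X, subjects = make_cohort_features(rng, effect=1.0)
        rep = run_loo(X, subjects, seed=0, trial_cap=5)
        assert len(rep.per_subject) == len(subjects)
        assert set(rep.per_subject) == {s.subject_id for s in subjects}

    def test_separable_cohort_perfect(self, rng):
        X, subjects = make_cohort_features(rng, effect=8.0)
        rep = run_loo(X, subjects, seed=0, trial_cap=5)
        assert rep.overall_mean == 100.0

    def test_chance_under_feature_shuffle(self, rng):
        # no class signal: accuracy must sit inside the exact chance band
        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, subjects = make_cohort_features(r, n_pos=8, n_neg=6, effect=0.0)
            rep = run_loo(X, subjects, seed=seed, trial_cap=10, keep_audit=False)
            accs.append(rep.overall_mean)
        lo, hi = permutation_null_band(5 * 14, level=0.99)
        assert lo <= np.mean(accs) <= hi

    def test_overall_mean_is_mean_of_trial_outcomes(self, rng):
        X, subjects = make_cohort_features(rng, effect=1.0)
        rep = run_loo(X, subjects, seed=1, trial_cap=6)
        outcomes = [100.0 * a["correct"] for a in rep.audit]
        assert rep.overall_mean == pytest.approx(np.mean(outcomes))

    def test_split_plans_balanced_and_leak_free(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=5, n_neg=4, effect=0.5)
        labels = {s.subject_id: s.label for s in subjects}
        rep = run_loo(X, subjects, seed=2, trial_cap=8)
        seen_tests = set()
        for entry in rep.audit:
            seen_tests.add(entry["test_id"])
            train, val, test = set(entry["train_ids"]), set(entry["val_ids"]), {entry["test_id"]}
            assert not (train & val) and not (train & test) and not (val & test)
            for ids in (train, val):
                pos = sum(labels[i] == TMS_POS for i in ids)
                assert pos * 2 == len(ids)
        # LOO coverage: every subject tested exactly once (as a fold)
        assert seen_tests == {s.subject_id for s in subjects}

    def test_seed_determinism_bit_identical(self, rng):
        X, subjects = make_cohort_features(rng, effect=0.3)
        r1 = run_loo(X, subjects, seed=9)
        r2 = run_loo(X, subjects, seed=9)
        assert r1.to_json() == r2.to_json()

    def test_infeasible_class_count_rejected(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=4, n_neg=1)
        with pytest.raises(ParameterError):
            run_loo(X, subjects)

    def test_report_json_serializable(self, rng):
        X, subjects = make_cohort_features(rng, effect=1.0)
        rep = run_loo(X, subjects, seed=0, trial_cap=3)
        payload = json.loads(rep.to_json())
        assert "config_hash" in payload
        assert 0 <= payload["overall_mean"] <= 100


def test_cohort_level_entry_matches_feature_level(small_cohort, small_features):
    from tmsresp import mc_leave_one_out

    X, provenance, subject_ids = small_features
    order = {s.subject_id: s for s in small_cohort.subjects}
    subjects = [order[sid] for sid in subject_ids]
    sel = {"method": "band_restrict", "band": "theta"}
    rep_cohort = mc_leave_one_out(small_cohort, selector_config=sel, seed=3,
                                  trial_cap=4, keep_audit=False)
    rep_features = run_loo(X, subjects, provenance=provenance, selector_config=sel,
                           seed=3, trial_cap=4, keep_audit=False)
    assert rep_cohort.per_subject == rep_features.per_subject


class TestDirectClassification:
    def test_train_size_nine_of_fourteen(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=8, n_neg=6, effect=1.0)
        rep = direct_classification(X, subjects, train_fraction=9 / 14,
                                    n_random_trials=5, seed=0)
        assert len(rep.audit[0]["train_ids"]) == 9

    def test_default_trial_count(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=8, n_neg=6, effect=2.0)
        rep = direct_classification(X, subjects, seed=0)
        assert rep.config["n_random_trials"] == 50
        assert len(rep.audit) == 50

    def test_separable_mean_100_sd_0(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=8, n_neg=6, effect=8.0)
        rep = direct_classification(X, subjects, n_random_trials=10, seed=0)
        assert rep.overall_mean == 100.0
        assert rep.trial_sd == 0.0

    def test_infeasible_fraction_rejected(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=2, n_neg=2)
        with pytest.raises(ParameterError):
            direct_classification(X, subjects, train_fraction=0.99)


class TestSizeSweep:
    def test_separable_all_sizes_perfect_and_row_count(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=5, n_neg=4, effect=8.0)
        table = size_sweep(X, subjects, mode="train-size", seed=0, trial_cap=4)
        # feasible per-class train sizes: 1 .. (min_count - 1) - val_per_class
        assert len(table) == 2
        assert np.all(table["mean_accuracy"] == 100.0)

    def test_val_size_mode_rows(self, rng):
        X, subjects = make_cohort_features(rng, n_pos=5, n_neg=4, effect=8.0)
        table = size_sweep(X, subjects, mode="val-size", seed=0, trial_cap=4)
        assert len(table) >= 1
        assert set(table.columns) == {"size", "mean_accuracy", "sd"}

    def test_unknown_mode(self, rng):
        X, subjects = make_cohort_features(rng)
        with pytest.raises(ParameterError):
            size_sweep(X, subjects, mode="bogus")
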