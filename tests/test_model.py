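"""Label binarization, combinations, LOOCV, pooled AUC, popularity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from physiomot import (
    LabeledFeatureTable,
    binarize_cgis,
    enumerate_combinations,
    feature_popularity,
    loocv_experiment,
    pooled_auc,
    run_full_experiment,
)


class TestBinarize:
    @pytest.mark.parametrize(
        "score,label",
        [(1, "low"), (4, "low"), (5, "high"), (7, "high")],
    )
    def test_threshold_rule(self, score, label):
        assert binarize_cgis(score) == label

    def test_out_of_range_rejected(self):
        for bad in (0, 8, 3.5):
            with pytest.raises(ValueError):
                binarize_cgis(bad)


class TestCombinations:
    def test_fifteen_subsets(self):
        combos = enumerate_combinations()
        assert len(combos) == 15
        assert len(set(combos)) == 15

    def test_thirteenth_is_hrv_mste_msnr(self):
        assert enumerate_combinations()[12] == ("HRV", "MSTE", "MSNR")

    def test_each_family_in_eight_subsets(self):
        combos = enumerate_combinations()
        for fam in ("HRV", "ACT", "MSTE", "MSNR"):
            assert sum(fam in c for c in combos) == 8


class TestPooledAuc:
    def test_perfect_ordering(self):
        assert pooled_auc([0.9, 0.8, 0.2, 0.1], ["high", "high", "low", "low"]) == 1.0

    def test_pairwise_bruteforce_example(self):
        probs = np.array([0.9, 0.8, 0.1, 0.7])
        labels = np.array(["high", "high", "low", "low"])
        assert pooled_auc(probs, labels) == 1.0  # all 4 ordered pairs correct

    def test_all_ties_give_half(self):
        assert pooled_auc([0.5] * 6, ["high"] * 3 + ["low"] * 3) == 0.5

    def test_matches_pair_counting_and_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            probs = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            correct = ties = 0
            for i, j in itertools.product(np.flatnonzero(y == 1), np.flatnonzero(y == 0)):
                if probs[i] > probs[j]:
                    correct += 1
                elif probs[i] == probs[j]:
                    ties += 1
            brute = (correct + 0.5 * ties) / (np.sum(y == 1) * np.sum(y == 0))
            assert pooled_auc(probs, y) == pytest.approx(brute)
            assert pooled_auc(probs, y) == pytest.approx(roc_auc_score(y, probs))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        probs = rng.random(20)
        y = rng.integers(0, 2, 20)
        base = pooled_auc(probs, y)
        assert pooled_auc(np.exp(3 * probs), y) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pooled_auc([0.1, 0.9], ["low", "low"])


def make_table(n_patients=12, visits_extra=4, effect=2.0, n_features=6, seed=0):
    """Synthetic feature table: feature 0 carries the group effect."""
    rng = np.random.default_rng(seed)
    pids, labels, rows = [], [], []
    for i in range(n_patients):
        lab = "high" if i % 2 else "low"
        for _ in range(1 + (1 if i < visits_extra else 0)):
            x = rng.normal(0, 1, n_features)
            if lab == "high":
                x[0] += effect
            rows.append(x)
            pids.append(f"P{i:02d}")
            labels.append(lab)
    cols = [f"hrv_f{j}" for j in range(n_features // 2)] + [
        f"mste_f{j}" for j in range(n_features - n_features // 2)
    ]
    return LabeledFeatureTable(pd.DataFrame(rows, columns=cols), np.array(pids), np.array(labels))


class TestLoocv:
    def test_model_count_is_reps_times_patients(self):
        table = make_table(n_patients=8)
        res = loocv_experiment(table, list(table.features.columns), n_reps=5, base_seed=1)
        assert res.n_models == 5 * 8

    def test_separable_table_high_auc(self):
        table = make_table(effect=3.0, seed=2)
        res = loocv_experiment(table, list(table.features.columns), n_reps=3, base_seed=1)
        assert res.pooled_auc_value >= 0.9

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(3)
        aucs = []
        for k in range(10):
            table = make_table(effect=3.0, seed=4)
            perm = rng.permutation(len(table.labels))
            # permute labels within the patient structure: shuffle patient labels
            pid_order = np.unique(table.patient_ids)
            lab_map = dict(zip(pid_order, rng.permutation(
                [table.labels[table.patient_ids == p][0] for p in pid_order])))
            shuffled = np.array([lab_map[p] for p in table.patient_ids])
            t2 = LabeledFeatureTable(table.features, table.patient_ids, shuffled)
            res = loocv_experiment(t2, list(t2.features.columns), n_reps=2, base_seed=k)
            aucs.append(res.pooled_auc_value)
        assert 0.3 <= np.median(aucs) <= 0.7

    def test_deterministic_given_seed(self):
        table = make_table()
        a = loocv_experiment(table, list(table.features.columns), n_reps=2, base_seed=5)
        b = loocv_experiment(table, list(table.features.columns), n_reps=2, base_seed=5)
        assert np.array_equal(a.pooled_probs, b.pooled_probs)
        assert a.selected_lambdas == b.selected_lambdas

    def test_no_leakage_constant_training_column_dropped(self):
        """A column constant on every training fold cannot influence scores."""
        table = make_table()
        base = loocv_experiment(table, list(table.features.columns), n_reps=2, base_seed=0)
        feats = table.features.copy()
        feats["mste_const"] = 1.0  # constant everywhere: zero train variance
        t2 = LabeledFeatureTable(feats, table.patient_ids, table.labels)
        res = loocv_experiment(t2, list(t2.features.columns), n_reps=2, base_seed=0)
        assert np.allclose(res.pooled_probs, base.pooled_probs)
        assert all(c["mste_const"] == 0.0 for c in res.coefficients)


class TestPopularity:
    def test_values_on_count_grid_and_bookkeeping(self):
        table = make_table(effect=3.0)
        res = loocv_experiment(table, list(table.features.columns), n_reps=3, base_seed=2)
        rho = feature_popularity(res)
        m = res.n_models
        assert np.allclose(np.round(rho * m), rho * m)
        total_selected = sum(
            sum(abs(w) > 1e-10 for w in c.values()) for c in res.coefficients
        )
        assert int(round(rho.sum() * m)) == total_selected

    def test_effect_feature_most_popular(self):
        table = make_table(effect=3.0, seed=6)
        res = loocv_experiment(table, list(table.features.columns), n_reps=3, base_seed=3)
        assert feature_popularity(res).index[0] == "hrv_f0"

    def test_never_selected_feature_scores_zero(self):
        table = make_table(effect=3.0, seed=7)
        res = loocv_experiment(table, list(table.features.columns), n_reps=2, base_seed=1)
        res.coefficients = [dict.fromkeys(c, 0.0) | {"hrv_f0": 1.0} for c in res.coefficients]
        rho = feature_popularity(res)
        assert rho["hrv_f0"] == 1.0
        assert (rho.drop("hrv_f0") == 0.0).all()


class TestRunFullExperiment:
    def test_runs_available_combinations(self):
        table = make_table()  # table only carries HRV and MSTE columns
        with pytest.warns(UserWarning):
            results = run_full_experiment(table, n_reps=1, base_seed=0)
        # combinations containing ACT/MSNR reduce to HRV/MSTE columns or skip
        assert ("HRV",) in results and ("MSTE",) in results
        assert all(r.n_models > 0 for r in results.values())
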