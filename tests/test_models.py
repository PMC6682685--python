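"""Patient-grouped splits, feature reduction and model evaluation."""

import numpy as np
import pandas as pd
import pytest

from radiorobust.models import (
    LR_GRID_SMALL,
    evaluate,
    fit_classifier,
    patient_splits,
    pca_reduce,
    rfe_select,
    run_experiment,
)


class _Stub:
    """Deterministic scorer standing in for a fitted model."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, float)

    def predict_proba(self, x):
        return np.column_stack([1 - self.scores, self.scores])


class TestPatientSplits:
    def _labels(self, n_pos=10, n_neg=40):
        ids = [f"P{i}" for i in range(n_pos + n_neg)]
        return pd.Series([1] * n_pos + [0] * n_neg, index=ids)

    def test_stratified_counts(self):
        plan = patient_splits(self._labels(), n_rep=5, test_frac=0.2, seed=0)
        lab = self._labels()
        for train, test in plan.repetitions:
            assert sum(lab[t] for t in test) == 2
            assert len(test) == 10

    def test_no_overlap_and_determinism(self):
        a = patient_splits(self._labels(), n_rep=4, seed=3)
        b = patient_splits(self._labels(), n_rep=4, seed=3)
        assert a.repetitions == b.repetitions
        for train, test in a.repetitions:
            assert not set(train) & set(test)

    def test_singleton_class_rejected(self):
        lab = pd.Series([1, 0, 0, 0], index=list("abcd"))
        with pytest.raises(ValueError):
            patient_splits(lab)


class TestRFE:
    def _planted(self, rng, n_noise=20, n_per_pat=3, n_pat=16):
        rows = []
        for p in range(n_pat):
            y = int(p < n_pat // 2)
            for s in range(n_per_pat):
                x = rng.normal(size=5 + n_noise)
                x[:5] += 1.6 * y
                rows.append((f"P{p}", y, x))
        groups = [r[0] for r in rows]
        ys = np.array([r[1] for r in rows])
        xs = pd.DataFrame(
            [r[2] for r in rows],
            columns=[f"inf{i}" for i in range(5)]
            + [f"noise{i}" for i in range(n_noise)],
        )
        return xs, ys, groups

    def test_recovers_planted_informative_features(self):
        rng = np.random.default_rng(2024)
        hits = 0
        for rep in range(3):
            xs, ys, groups = self._planted(rng)
            sel = rfe_select(xs, ys, groups, n_folds=5, seed=rep)
            n_inf = sum(1 for s in sel if s.startswith("inf"))
            hits += n_inf >= 4
        assert hits >= 2

    def test_single_feature_passthrough(self, rng):
        xs = pd.DataFrame({"only": rng.normal(size=12)})
        sel = rfe_select(xs, np.arange(12) % 2, [f"P{i}" for i in range(12)])
        assert sel == ["only"]

    def test_perfect_separator_is_kept(self, rng):
        n = 24
        y = np.arange(n) % 2
        xs = pd.DataFrame(
            {"sep": y + 0.01 * rng.normal(size=n),
             "junk": rng.normal(size=n),
             "junk2": rng.normal(size=n)}
        )
        groups = [f"P{i}" for i in range(n)]
        sel = rfe_select(xs, y, groups, n_folds=4, seed=0)
        assert "sep" in sel


class TestPCA:
    def test_exact_rank_recovered(self, rng):
        basis = rng.normal(size=(3, 10))
        data = rng.normal(size=(50, 3)) @ basis
        data += 1e-9 * rng.normal(size=data.shape)
        _, n = pca_reduce(pd.DataFrame(data))
        assert n == 3

    def test_isotropic_needs_most_components(self, rng):
        data = pd.DataFrame(rng.normal(size=(500, 10)))
        _, n = pca_reduce(data)
        assert n >= 9

    def test_duplicated_columns_do_not_add_components(self, rng):
        base = pd.DataFrame(rng.normal(size=(40, 4)),
                            columns=[f"c{i}" for i in range(4)])
        dup = pd.concat([base, base.add_suffix("_d")], axis=1)
        _, n1 = pca_reduce(base)
        _, n2 = pca_reduce(dup)
        assert n2 == n1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(pd.DataFrame(np.ones((10, 3))))


class TestFitAndEvaluate:
    def test_separable_data_perfect_training_auroc(self, rng):
        n = 40
        y = np.arange(n) % 2
        x = np.column_stack([y + 0.05 * rng.normal(size=n),
                             rng.normal(size=n)])
        groups = [f"P{i}" for i in range(n)]
        for kind in ("rf", "lr"):
            grid = None if kind == "rf" else LR_GRID_SMALL
            if kind == "rf":
                grid = {"n_estimators": [50], "max_depth": [10],
                        "min_samples_split": [2], "min_samples_leaf": [1]}
            model = fit_classifier(kind, x, y, groups, param_grid=grid)
            assert evaluate(model, x, y)["auroc"] == 1.0

    def test_same_seed_same_hyperparameters(self, rng):
        n = 30
        y = np.arange(n) % 2
        x = rng.normal(size=(n, 4)) + y[:, None]
        groups = [f"P{i}" for i in range(n)]
        m1 = fit_classifier("lr", x, y, groups, param_grid=LR_GRID_SMALL, seed=5)
        m2 = fit_classifier("lr", x, y, groups, param_grid=LR_GRID_SMALL, seed=5)
        assert m1.get_params() == m2.get_params()

    def test_perfect_scores_all_metrics_one(self):
        y = np.array([1, 1, 0, 0])
        m = _Stub([1.0, 1.0, 0.0, 0.0])
        res = evaluate(m, np.zeros((4, 1)), y)
        assert all(v == 1.0 for v in res.values())

    def test_constant_scores_auroc_half(self):
        y = np.array([1, 0, 1, 0])
        res = evaluate(_Stub([0.5] * 4), np.zeros((4, 1)), y)
        assert res["auroc"] == 0.5

    def test_contingency_arithmetic(self):
        # TP=9 FN=1 TN=8 FP=2 -> sens .9 spec .8 acc .85
        y = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 9 + [0.1] + [0.1] * 8 + [0.9] * 2)
        res = evaluate(_Stub(scores), np.zeros((20, 1)), y)
        assert res["sensitivity"] == pytest.approx(0.9)
        assert res["specificity"] == pytest.approx(0.8)
        assert res["accuracy"] == pytest.approx(0.85)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_Stub([0.5, 0.5]), np.zeros((2, 1)), np.array([1, 1]))


class TestRunExperiment:
    def test_leakage_audit_records_only_train_patients(self, rng):
        pats = [f"P{i}" for i in range(12)]
        lab = pd.Series([1] * 4 + [0] * 8, index=pats)
        rows = []
        for p in pats:
            for s in range(3):
                rows.append(
                    {"patient_id": p, "slice_index": s, "label": lab[p],
                     **{f"f{i}": v for i, v in
                        enumerate(rng.normal(size=6))}}
                )
        tab = pd.DataFrame(rows)
        plan = patient_splits(lab, n_rep=2, seed=0)
        res = run_experiment(tab, "pca", "lr", plan,
                             param_grid=LR_GRID_SMALL, seed=0)
        for (train, test), fitted in zip(plan.repetitions, res.fit_patients):
            assert set(fitted) == set(train)
            assert not set(fitted) & set(test)

    def test_aggregate_reproduces_hand_statistics(self):
        from radiorobust.models import EvalResult

        res = EvalResult(per_rep=pd.DataFrame(
            {"auroc": [0.6, 0.8], "sensitivity": [1, 0],
             "specificity": [0, 1], "accuracy": [0.5, 0.5]}
        ))
        agg = res.aggregate()
        assert agg["auroc_mean"] == pytest.approx(0.7)
        assert agg["auroc_sd"] == pytest.approx(np.std([0.6, 0.8], ddof=1))
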