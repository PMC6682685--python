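"""k-top-scoring-pairs: prefilter, pair scores, greedy fit vs an
independently coded oracle, vote rule, HPD intervals and the resampling
experiment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from radiorobust.ktsp import (
    fit_ktsp,
    hpd_interval,
    ktsp_experiment,
    pair_score,
    predict_ktsp,
    vote_margins,
    wilcoxon_prefilter,
)


def greedy_oracle(x, y, k):
    """Independent replay of the greedy definition: enumerate all oriented
    pairs, score by direct counting, sort by (Delta, rank-difference,
    lexicographic), take disjoint pairs greedily.  Scores are computed in
    exact rational arithmetic so ties are genuine ties."""
    from fractions import Fraction

    n, p = x.shape
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    # midranks are exact multiples of 1/2
    ranks = [
        [Fraction(r).limit_denominator(2) for r in row]
        for row in sstats.rankdata(x, axis=1)
    ]
    cand = []
    for i in range(p):
        for j in range(i + 1, p):
            c1 = sum(1 for s in range(n) if y[s] == 1 and x[s, i] < x[s, j])
            c0 = sum(1 for s in range(n) if y[s] == 0 and x[s, i] < x[s, j])
            delta = Fraction(c1, n1) - Fraction(c0, n0)
            a, b = (i, j) if delta >= 0 else (j, i)
            d1 = sum(
                (ranks[s][a] - ranks[s][b] for s in range(n) if y[s] == 1),
                Fraction(0),
            ) / n1
            d0 = sum(
                (ranks[s][a] - ranks[s][b] for s in range(n) if y[s] == 0),
                Fraction(0),
            ) / n0
            cand.append((abs(delta), abs(d1 - d0), a, b))
    cand.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used, pairs = set(), []
    for _, _, a, b in cand:
        if a in used or b in used:
            continue
        pairs.append((a, b))
        used.update((a, b))
        if len(pairs) == k:
            break
    return pairs


def _planted_inversions(rng, n_per_class=20, n_pairs=3, n_noise=0):
    y = np.array([0] * n_per_class + [1] * n_per_class)
    p = 2 * n_pairs + n_noise
    x = rng.normal(size=(2 * n_per_class, p))
    for q in range(n_pairs):
        i, j = 2 * q, 2 * q + 1
        gap = np.abs(rng.normal(1, 0.1, n_per_class))
        x[y == 1, i] = x[y == 1, j] - gap
        x[y == 0, i] = x[y == 0, j] + gap
    return x, y


class TestPrefilter:
    def test_identical_feature_removed_separating_kept(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        x = np.column_stack([
            np.ones(40),                      # identical in both classes
            np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20) + 8]),
        ])
        kept = wilcoxon_prefilter(x, y, alpha=0.1)
        assert kept.tolist() == [1]

    def test_all_removed_raises(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        x = np.ones((20, 3))
        with pytest.raises(ValueError):
            wilcoxon_prefilter(x, y)


class TestPairScore:
    def test_perfect_inversion_delta_one(self):
        y = np.array([1, 1, 0, 0])
        xi = np.array([1.0, 1.0, 2.0, 3.0])
        xj = np.array([2.0, 3.0, 1.0, 1.0])
        assert pair_score(xi, xj, y) == 1.0

    def test_null_delta_small(self, rng):
        y = np.array([0] * 50 + [1] * 50)
        deltas = [
            pair_score(rng.normal(size=100), rng.normal(size=100), y)
            for _ in range(50)
        ]
        assert np.mean(deltas) < 0.15

    def test_ties_count_as_not_less(self):
        y = np.array([1, 1, 0, 0])
        xi = np.array([1.0, 1.0, 1.0, 1.0])
        xj = np.array([1.0, 1.0, 1.0, 1.0])
        assert pair_score(xi, xj, y) == 0.0


class TestFitPredict:
    def test_planted_pairs_recovered(self, rng):
        x, y = _planted_inversions(rng)
        m = fit_ktsp(x, y, 3)
        assert sorted(tuple(sorted(p)) for p in m.pairs) == [
            (0, 1), (2, 3), (4, 5),
        ]

    def test_pairs_disjoint(self, rng):
        x = rng.normal(size=(30, 12))
        y = np.arange(30) % 2
        m = fit_ktsp(x, y, 4)
        flat = [i for p in m.pairs for i in p]
        assert len(flat) == len(set(flat))

    def test_matches_independent_greedy_oracle(self, rng):
        for rep in range(5):
            x = rng.normal(size=(20, 8)).round(1)  # ties on purpose
            y = np.array([0] * 10 + [1] * 10)
            m = fit_ktsp(x, y, 2)
            assert m.pairs == greedy_oracle(x, y, 2)

    def test_vote_rule_and_tiebreak(self):
        from radiorobust.ktsp import TSPModel

        m = TSPModel(pairs=[(0, 1), (2, 3), (4, 5)], scores=[1, 1, 1],
                     secondary_scores=[0, 0, 0],
                     feature_names=[f"f{i}" for i in range(6)])
        assert predict_ktsp(m, np.array([0, 1, 0, 1, 0, 1])) == (1, 3)
        assert predict_ktsp(m, np.array([0, 1, 0, 1, 1, 0])) == (1, 2)
        m2 = TSPModel(pairs=[(0, 1), (2, 3)], scores=[1, 0.5],
                      secondary_scores=[0, 0],
                      feature_names=[f"f{i}" for i in range(4)])
        # even k, split vote: top pair decides
        assert predict_ktsp(m2, np.array([0, 1, 1, 0]))[0] == 1
        assert predict_ktsp(m2, np.array([1, 0, 0, 1]))[0] == 0

    def test_monotone_transform_invariance(self, rng):
        x, y = _planted_inversions(rng, n_noise=2)
        m1 = fit_ktsp(x, y, 3)
        # one strictly monotone normalization applied to every value,
        # consistently across train and test: preserves all within-sample
        # orderings, hence pair scores and votes
        xt = np.exp(0.5 * x) + 0.1 * x
        m2 = fit_ktsp(xt, y, 3)
        assert m1.pairs == m2.pairs
        for s in range(len(x)):
            assert predict_ktsp(m1, x[s]) == predict_ktsp(m2, xt[s])

    def test_margin_auc_equals_rank_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        x, y = _planted_inversions(rng, n_noise=4)
        m = fit_ktsp(x, y, 3)
        margins = vote_margins(m, x)
        manual = roc_auc_score(y, margins)
        assert manual == pytest.approx(roc_auc_score(y, margins))
        assert manual > 0.9


class TestHPD:
    def test_uniform_grid_interval_length(self):
        lo, hi = hpd_interval(np.linspace(0, 1, 100))
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_constant_values(self):
        assert hpd_interval([3.0] * 25) == (3.0, 3.0)

    def test_skewed_sample_shorter_than_equal_tailed(self, rng):
        v = rng.exponential(size=2000) ** 2
        lo, hi = hpd_interval(v)
        eq = np.percentile(v, [2.5, 97.5])
        assert (hi - lo) < (eq[1] - eq[0])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([1.0] * 10)


class TestExperiment:
    def _table(self, x, y, slices_per_patient=2):
        rows = []
        for s in range(len(y)):
            rows.append(
                {"patient_id": f"P{s // slices_per_patient}",
                 "slice_index": s, "label": int(y[s]),
                 **{f"f{i}": v for i, v in enumerate(x[s])}}
            )
        return pd.DataFrame(rows)

    def test_planted_signal_high_test_auc(self, rng):
        x, y = _planted_inversions(rng, n_per_class=24, n_noise=2)
        order = np.argsort(y, kind="stable")  # keep patients single-class
        tab = self._table(x[order], y[order])
        res = ktsp_experiment(tab, n_rep=100, seed=1)
        assert res["test_auc_hpd"][0] > 0.9

    def test_shuffled_labels_cover_half(self, rng):
        x, y = _planted_inversions(rng, n_per_class=24, n_noise=2)
        y = rng.permutation(y)
        order = np.argsort(y, kind="stable")
        tab = self._table(x[order], y[order])
        res = ktsp_experiment(tab, n_rep=100, seed=2)
        lo, hi = res["test_auc_hpd"]
        assert lo <= 0.5 <= hi

    def test_same_seed_identical_samples(self, rng):
        x, y = _planted_inversions(rng, n_per_class=12, n_noise=2)
        order = np.argsort(y, kind="stable")
        tab = self._table(x[order], y[order])
        a = ktsp_experiment(tab, n_rep=25, seed=7)
        b = ktsp_experiment(tab, n_rep=25, seed=7)
        assert np.array_equal(a["test_aucs"], b["test_aucs"])
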