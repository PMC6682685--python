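"""k-top-scoring-pairs (kTSP) classification.

kTSP classifies a sample by majority vote over k disjoint feature pairs
(i, j) whose ordering x_i < x_j is inverted between the two classes.  The
primary pair score is Delta = |P(x_i < x_j | class 1) - P(x_i < x_j |
class 0)|; ties in Delta are broken by the average within-profile
rank-difference and then lexicographically.  Because the rule depends only
on within-sample orderings, it is invariant to any strictly monotone
transform applied consistently per feature — robust to normalization.

The experiment protocol: features significantly differential between the
classes (two-sided rank-sum test, Benjamini-Hochberg adjusted p < 0.1) are
retained inside each repetition's training data; patients are split 70:30
with grouping (all slices of a patient stay together); k ranges over 3..15
chosen by training AUC; the test-AUC distribution over repetitions is
summarized by its 95% highest-posterior-density interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class TSPModel:
    """k disjoint top-scoring pairs with their scores and vote rule.

    ``pairs[p] = (i, j)`` votes for class 1 when ``x_i < x_j``.  Pairs are
    sorted by non-increasing score; even-k vote ties defer to the
    top-scoring pair's indicator.
    """

    pairs: List[Tuple[int, int]]
    scores: List[float]
    secondary_scores: List[float]
    feature_names: List[str]

    @property
    def k(self) -> int:
        return len(self.pairs)


def wilcoxon_prefilter(
    x: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.1,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """Indices (or names) of features differential between classes.

    Two-sided Wilcoxon rank-sum test per feature with Benjamini-Hochberg
    adjustment; keeps adjusted p < ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    g1, g0 = x[labels == 1], x[labels == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("both classes need at least 2 samples")
    pvals = np.ones(x.shape[1])
    for f in range(x.shape[1]):
        if np.ptp(x[:, f]) == 0:
            pvals[f] = 1.0
            continue
        pvals[f] = sstats.mannwhitneyu(
            g1[:, f], g0[:, f], alternative="two-sided"
        ).pvalue
    keep = multipletests(pvals, alpha=alpha, method="fdr_bh")[1] < alpha
    if not keep.any():
        raise ValueError(
            f"all {x.shape[1]} features removed by the prefilter"
        )
    idx = np.flatnonzero(keep)
    if names is not None:
        return np.asarray(names)[idx]
    return idx


def pair_score(
    xi: np.ndarray, xj: np.ndarray, labels: np.ndarray
) -> float:
    """Delta = |P(x_i < x_j | 1) - P(x_i < x_j | 0)|; ties x_i = x_j count
    as not-less-than."""
    labels = np.asarray(labels)
    less = np.asarray(xi) < np.asarray(xj)
    p1 = less[labels == 1].mean()
    p0 = less[labels == 0].mean()
    return float(abs(p1 - p0))


def _score_matrices(x: np.ndarray, labels: np.ndarray):
    """P(x_i < x_j | class) for both classes, chunked over i."""
    n, p = x.shape
    m1 = labels == 1
    m0 = labels == 0
    frac1 = np.empty((p, p))
    frac0 = np.empty((p, p))
    chunk = max(1, int(2e6 / max(n * p, 1)))
    for s in range(0, p, chunk):
        e = min(p, s + chunk)
        less = x[:, s:e, None] < x[:, None, :]
        frac1[s:e] = less[m1].mean(axis=0)
        frac0[s:e] = less[m0].mean(axis=0)
    return frac1, frac0


def fit_ktsp(
    x: np.ndarray,
    labels: np.ndarray,
    k: int,
    feature_names: Sequence[str] | None = None,
) -> TSPModel:
    """Greedy selection of the k highest-scoring disjoint pairs.

    Pair orientation is chosen so the vote x_i < x_j indicates class 1.
    Ties in Delta break by larger rank-difference secondary score, then
    lexicographically.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n, p = x.shape
    if p < 2 * k:
        raise ValueError(f"need at least {2 * k} features, got {p}")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    frac1, frac0 = _score_matrices(x, labels)
    delta = frac1 - frac0  # delta[i, j] > 0: x_i < x_j indicates class 1
    ranks = sstats.rankdata(x, axis=1)
    d1 = ranks[labels == 1].mean(axis=0)
    d0 = ranks[labels == 0].mean(axis=0)

    # both scores are exact multiples of small rationals (class-fractions
    # of counts / of midranks); quantize so equal scores tie exactly and
    # the documented lexicographic tie-break is deterministic
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    q_delta = n1 * n0
    q_gamma = 2 * n1 * n0

    cand = []
    for i in range(p):
        for j in range(i + 1, p):
            if delta[i, j] >= 0:
                a, b = i, j
            else:
                a, b = j, i
            score = round(abs(delta[i, j]) * q_delta) / q_delta
            gamma = abs((d1[a] - d1[b]) - (d0[a] - d0[b]))
            gamma = round(gamma * q_gamma) / q_gamma
            cand.append((score, gamma, a, b))
    # non-increasing score, then secondary, then lexicographic
    cand.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used = set()
    pairs, scores, gammas = [], [], []
    for score, gamma, a, b in cand:
        if a in used or b in used:
            continue
        pairs.append((a, b))
        scores.append(score)
        gammas.append(gamma)
        used.update((a, b))
        if len(pairs) == k:
            break
    if len(pairs) < k:
        raise ValueError("could not assemble k disjoint pairs")
    return TSPModel(
        pairs=pairs, scores=scores, secondary_scores=gammas,
        feature_names=list(feature_names),
    )


def vote_margins(m: TSPModel, x: np.ndarray, k: int | None = None) -> np.ndarray:
    """Number of class-1 votes per sample using the first ``k`` pairs."""
    x = np.asarray(x, dtype=float)
    kk = m.k if k is None else k
    votes = np.zeros(len(x))
    for a, b in m.pairs[:kk]:
        votes += (x[:, a] < x[:, b]).astype(float)
    return votes


def predict_ktsp(m: TSPModel, sample: np.ndarray) -> Tuple[int, int]:
    """Class and vote margin of one sample.

    Class 1 iff votes > k/2; an even-k tie defers to the top-scoring
    pair's indicator.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1:
        raise ValueError("sample must be 1-D")
    v = int(
        sum(1 for a, b in m.pairs if sample[a] < sample[b])
    )
    if v * 2 > m.k:
        cls = 1
    elif v * 2 < m.k:
        cls = 0
    else:
        a, b = m.pairs[0]
        cls = int(sample[a] < sample[b])
    return cls, v


def hpd_interval(values: Sequence[float], mass: float = 0.95) -> Tuple[float, float]:
    """Shortest contiguous interval over the sorted empirical values
    containing ``ceil(mass * n)`` points."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 20:
        raise ValueError("need at least 20 values")
    m = int(np.ceil(mass * n))
    widths = v[m - 1 :] - v[: n - m + 1]
    i = int(np.argmin(widths))
    return float(v[i]), float(v[i + m - 1])


def _grouped_stratified_split(
    patient_labels: pd.Series, frac: float, rng: np.random.Generator
) -> Tuple[List[str], List[str]]:
    train, test = [], []
    for c in patient_labels.unique():
        ids = list(patient_labels.index[patient_labels == c])
        rng.shuffle(ids)
        n_train = min(max(1, int(round(frac * len(ids)))), len(ids) - 1)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return sorted(train), sorted(test)


def ktsp_experiment(
    features: pd.DataFrame,
    n_rep: int = 5000,
    split: float = 0.7,
    k_min: int = 3,
    k_max: int = 15,
    alpha: float = 0.1,
    seed: int = 0,
) -> Dict:
    """Repeated grouped 70:30 resampling of the kTSP classifier.

    ``features`` is a slice-level table with ``patient_id``, ``label`` and
    feature columns.  Per repetition: split patients stratified by label,
    prefilter features on the training data, fit pair lists up to
    ``k_max``, choose k in [k_min, k_max] by training AUC of the vote
    margins (smallest k on ties), and record the test AUC.  When the
    prefilter retains fewer than ``2 * k_min`` features, the lowest-p
    features are kept instead so a model can still be formed.
    """
    meta = [c for c in ("patient_id", "slice_index", "perturbation_id",
                        "label") if c in features.columns]
    feat_cols = [c for c in features.columns if c not in meta]
    patient_labels = features.groupby("patient_id")["label"].first()
    x_all = features[feat_cols].to_numpy(dtype=float)
    y_all = features["label"].to_numpy()
    pid = features["patient_id"].to_numpy()
    rng = np.random.default_rng(seed)

    train_aucs, test_aucs, chosen_ks = [], [], []
    for _ in range(n_rep):
        tr_ids, te_ids = _grouped_stratified_split(patient_labels, split, rng)
        tr = np.isin(pid, tr_ids)
        te = ~tr
        x_tr, y_tr = x_all[tr], y_all[tr]
        x_te, y_te = x_all[te], y_all[te]
        try:
            idx = wilcoxon_prefilter(x_tr, y_tr, alpha=alpha)
        except ValueError:
            idx = np.array([], dtype=int)
        if len(idx) < 2 * k_min:
            pv = np.array(
                [
                    sstats.mannwhitneyu(
                        x_tr[y_tr == 1, f], x_tr[y_tr == 0, f],
                        alternative="two-sided",
                    ).pvalue
                    if np.ptp(x_tr[:, f]) > 0 else 1.0
                    for f in range(x_tr.shape[1])
                ]
            )
            idx = np.argsort(pv)[: 2 * k_min]
        k_cap = min(k_max, len(idx) // 2)
        model = fit_ktsp(x_tr[:, idx], y_tr, k_cap,
                         feature_names=[feat_cols[i] for i in idx])
        best_k, best_auc = k_min, -np.inf
        for k in range(k_min, k_cap + 1):
            auc = roc_auc_score(y_tr, vote_margins(model, x_tr[:, idx], k))
            if auc > best_auc:
                best_auc, best_k = auc, k
        test_auc = roc_auc_score(
            y_te, vote_margins(model, x_te[:, idx], best_k)
        )
        train_aucs.append(best_auc)
        test_aucs.append(test_auc)
        chosen_ks.append(best_k)

    out = {
        "train_aucs": np.array(train_aucs),
        "test_aucs": np.array(test_aucs),
        "chosen_k": np.array(chosen_ks),
    }
    if n_rep >= 20:
        out["train_auc_hpd"] = hpd_interval(train_aucs)
        out["test_auc_hpd"] = hpd_interval(test_aucs)
    return out
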