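"""Feature robustness via intraclass correlation across perturbed replicates.

For every feature and every perturbation class, the replicate measurements
of each slice (the unperturbed original plus the class's perturbed
versions) form a slices x replicates matrix; the one-way random-effects
single-rater ICC(1,1) of that matrix measures how much of the total
variance is between slices rather than within replicates — i.e. how stable
the feature is under the perturbation.  Features with ICC below the cutoff
(0.75 by default) for *any* class are excluded from downstream modeling.
"""

from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .types import PERTURBATION_CLASSES

META_COLS = ("patient_id", "slice_index", "perturbation_id", "label")


def feature_columns(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c not in META_COLS]


def feature_family(name: str) -> str:
    """Family tag of a feature named ``modality.family.feature`` (the tda
    block reports ``tda`` regardless of homology dimension)."""
    parts = name.split(".")
    return parts[1] if len(parts) > 1 else "unknown"


def icc_oneway(m: np.ndarray) -> float:
    """One-way random-effects single-rater ICC(1,1).

    ``m`` is an (n targets x k replicates) matrix with no missing cells:
    ICC = (MSB - MSW) / (MSB + (k-1) MSW) with between/within mean squares
    from one-way ANOVA over targets.  A constant matrix (the 0/0 case) is
    defined as 1: a feature that never moves is perfectly stable.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise ValueError("m must be 2-D")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 replicates")
    if not np.all(np.isfinite(m)):
        raise ValueError("m contains non-finite values")
    row_means = m.mean(axis=1)
    grand = m.mean()
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((m - row_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 1.0
    return float((msb - msw) / denom)


def icc_oneway_twoway(m: np.ndarray) -> float:
    """Two-way random-effects ICC(2,1) (sensitivity-analysis variant)."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 replicates")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum(
        (m - row_means[:, None] - col_means[None, :] + grand) ** 2
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def icc_table(
    features_original: pd.DataFrame,
    features_perturbed: pd.DataFrame,
    variant: str = "oneway",
) -> pd.DataFrame:
    """Per-feature, per-perturbation-class ICC table.

    ``features_original`` has one row per (patient, slice);
    ``features_perturbed`` one row per (patient, slice, perturbation_id)
    where ``perturbation_id`` is ``klass:param:seed``.  The unperturbed
    original is included as replicate 0 of every class.  Cells that cannot
    be computed (fewer than 2 replicates, non-finite values) are NaN.
    """
    if "perturbation_id" not in features_perturbed.columns:
        raise ValueError("perturbed table lacks perturbation_id")
    icc_fn = icc_oneway if variant == "oneway" else icc_oneway_twoway
    feats = feature_columns(features_original)
    klass_of = features_perturbed["perturbation_id"].str.split(":").str[0]
    out = {}
    for klass in PERTURBATION_CLASSES:
        sub = features_perturbed[klass_of == klass]
        col = np.full(len(feats), np.nan)
        if len(sub):
            # build all replicate matrices in one pivot per class
            wide_all = sub.pivot_table(
                index=["patient_id", "slice_index"],
                columns="perturbation_id",
                values=feats,
            )
            orig_idx = features_original.set_index(
                ["patient_id", "slice_index"]
            )
            if not wide_all.index.isin(orig_idx.index).all():
                raise ValueError(
                    "perturbed manifest has slices absent from original"
                )
            base = orig_idx.loc[wide_all.index]
            for fi, f in enumerate(feats):
                m = np.concatenate(
                    [base[f].to_numpy()[:, None], wide_all[f].to_numpy()],
                    axis=1,
                )
                if m.shape[0] >= 2 and m.shape[1] >= 2 and np.all(
                    np.isfinite(m)
                ):
                    col[fi] = icc_fn(m)
        out[klass] = col
    table = pd.DataFrame(out, index=pd.Index(feats, name="feature"))
    table["family"] = [feature_family(f) for f in feats]
    return table


def family_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ICC per feature family per perturbation class."""
    return table.groupby("family")[list(PERTURBATION_CLASSES)].mean()


def _survives(icc: np.ndarray, cutoff: float) -> np.ndarray:
    # cutoff <= 0 is vacuous (negative ICCs still survive); NaN never does
    with np.errstate(invalid="ignore"):
        ok = icc >= cutoff
    if cutoff <= 0:
        ok = ~np.isnan(icc)
    return ok


def robust_filter(table: pd.DataFrame, cutoff: float = 0.75) -> List[str]:
    """Features whose ICC is >= cutoff for ALL perturbation classes.

    NaN cells count as failures (conservative exclusion).
    """
    icc = table[list(PERTURBATION_CLASSES)].to_numpy()
    keep = np.ones(len(table), dtype=bool)
    for j in range(icc.shape[1]):
        keep &= _survives(icc[:, j], cutoff)
    return [f for f, k in zip(table.index, keep) if k]


def threshold_sweep(
    table: pd.DataFrame, cutoffs: Optional[Iterable[float]] = None
) -> pd.DataFrame:
    """Per-class fraction of features surviving each ICC cutoff.

    Curves are non-increasing in the cutoff; at cutoff 0 every non-NaN
    feature survives.
    """
    if cutoffs is None:
        cutoffs = np.linspace(0.0, 1.0, 21)
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    icc = table[list(PERTURBATION_CLASSES)].to_numpy()
    n = len(table)
    rows = []
    for c in cutoffs:
        rows.append(
            [float(_survives(icc[:, j], c).sum()) / n for j in
             range(icc.shape[1])]
        )
    return pd.DataFrame(
        rows, index=pd.Index(cutoffs, name="cutoff"),
        columns=list(PERTURBATION_CLASSES),
    )
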