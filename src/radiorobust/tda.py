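"""Topological features from sublevel-set cubical persistence of tumor patches.

For each modality channel, the masked patch is filtered by intensity
threshold: the sublevel set {x <= t} grows as t increases, and persistent
homology records when connected components (H0) and loops/tunnels (H1)
appear and disappear.  The resulting barcodes are summarized by four
polynomial features (weighted sums of births, deaths and bar lengths) and
eleven statistics of the birth, death and length distributions, giving
4 modalities x 2 dimensions x 15 descriptors = 120 features per patch.

Conventions (these change H1 counts, so they are fixed and documented):

- pixels are top-dimensional cells; sublevel components use 8-connectivity;
- pixels outside the mask are set to +inf and never enter the filtration;
- essential classes (death = inf) are finite-ized at the masked maximum
  intensity;
- H1 is computed by duality: finite H1 bars of the sublevel filtration are
  death/birth-swapped H0 bars of the superlevel filtration of the same
  image under the complementary 4-connectivity, with the patch exterior
  acting as an always-present background component.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from ._persistence import sublevel_sweep
from .types import Barcode, SlicePatch, modality_list

POLY_NAMES = ("P1", "P2", "P3", "P4")
STAT_NAMES = (
    "n_bars",
    "birth_mean",
    "birth_sd",
    "death_mean",
    "death_sd",
    "death_median",
    "death_skew",
    "length_mean",
    "length_sd",
    "length_max",
    "length_sum",
)

#: descriptors per (modality, homology dimension)
N_PER_DIM = len(POLY_NAMES) + len(STAT_NAMES)


def cubical_persistence(
    channel: np.ndarray, mask: np.ndarray, superlevel: bool = False
) -> Tuple[Barcode, Barcode]:
    """Persistence barcodes (H0, H1) of the masked patch.

    With ``superlevel=True`` the filtration direction is reversed by
    negating the image; intervals are then reported on the negated scale.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    img = np.asarray(channel, dtype=np.float64)
    if superlevel:
        img = -img
    f = np.where(mask, img, np.inf)
    fmax = float(img[mask].max())

    # H0: direct sublevel sweep, 8-connectivity
    pairs0, ess0 = sublevel_sweep(f, connectivity=8)
    h0 = np.concatenate(
        [pairs0, np.column_stack([ess0, np.full(len(ess0), fmax)])], axis=0
    ) if len(ess0) else pairs0
    h0 = h0[np.lexsort((h0[:, 1], h0[:, 0]))]

    # H1 by duality: sweep -f with 4-connectivity; the padded -inf border
    # plays the role of the unenclosed exterior.
    g = np.pad(-f, 1, constant_values=-np.inf)
    pairs1, _ess1 = sublevel_sweep(g, connectivity=4)
    bars1 = []
    for b, d in pairs1:
        if d == -np.inf:  # flood fill of the infinite background
            continue
        s = -d
        m = fmax if b == -np.inf else -b  # essential hole -> finite-ize
        bars1.append((s, m))
    h1 = np.array(bars1, dtype=float).reshape(-1, 2)
    h1 = h1[np.lexsort((h1[:, 1], h1[:, 0]))]

    return Barcode(0, h0), Barcode(1, h1)


def barcode_polynomial(bc: Barcode) -> np.ndarray:
    """Four polynomial barcode descriptors.

    With bar lengths L_i = d_i - b_i and d* = max_i d_i:
    P1 = sum b_i L_i, P2 = sum (d* - d_i) L_i,
    P3 = sum b_i^2 L_i^4, P4 = sum (d* - d_i)^2 L_i^4.
    The empty barcode maps to zeros.
    """
    if bc.n_bars == 0:
        return np.zeros(4)
    b, d = bc.births, bc.deaths
    length = d - b
    dstar = d.max()
    return np.array(
        [
            np.sum(b * length),
            np.sum((dstar - d) * length),
            np.sum(b**2 * length**4),
            np.sum((dstar - d) ** 2 * length**4),
        ]
    )


def barcode_stats(bc: Barcode) -> np.ndarray:
    """Eleven statistics of births, deaths and bar lengths.

    Order follows :data:`STAT_NAMES`.  Empty barcode -> all zeros; a
    singleton barcode has zero spread and zero skewness.  Skewness is the
    bias-uncorrected moment estimator and defined as 0 when the death
    values have zero variance.
    """
    if bc.n_bars == 0:
        return np.zeros(len(STAT_NAMES))
    b, d = bc.births, bc.deaths
    length = d - b
    sd_d = d.std()
    if bc.n_bars > 1 and sd_d > 0:
        skew = float(np.mean(((d - d.mean()) / sd_d) ** 3))
    else:
        skew = 0.0
    return np.array(
        [
            bc.n_bars,
            b.mean(),
            b.std(),
            d.mean(),
            d.std(),
            float(np.median(d)),
            skew,
            length.mean(),
            length.std(),
            length.max(),
            length.sum(),
        ]
    )


def tda_feature_names(modalities: List[str]) -> List[str]:
    names = []
    for m in modalities:
        for dim in (0, 1):
            for p in POLY_NAMES + STAT_NAMES:
                names.append(f"{m}.tda.H{dim}.{p}")
    return names


def extract_tda(
    sp: SlicePatch, superlevel: bool = False
) -> Dict[str, float]:
    """Full topological feature vector of one patch (120 named values)."""
    sp.validate()
    out: Dict[str, float] = {}
    for m in modality_list(sp.channels):
        h0, h1 = cubical_persistence(sp.channels[m], sp.mask, superlevel)
        for dim, bc in ((0, h0), (1, h1)):
            vals = np.concatenate([barcode_polynomial(bc), barcode_stats(bc)])
            for name, v in zip(POLY_NAMES + STAT_NAMES, vals):
                out[f"{m}.tda.H{dim}.{name}"] = float(v)
    return out


def dump_barcodes(path, barcodes: List[Barcode]) -> None:
    """Write barcodes as a 3-column text table: dim birth death."""
    with open(path, "w") as fh:
        fh.write("dim\tbirth\tdeath\n")
        for bc in barcodes:
            for b, d in bc.intervals:
                fh.write(f"{bc.dim}\t{b:.10g}\t{d:.10g}\n")
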