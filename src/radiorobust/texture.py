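"""Texture features of masked tumor patches.

Per modality channel the extractor computes six families following the
IBSI-standard definitions: 19 first-order intensity statistics, 9 2-D shape
descriptors of the mask, 24 gray-level co-occurrence (GLCM), 16 run-length
(GLRLM), 16 size-zone (GLSZM) and 5 neighboring gray-tone difference
(NGTDM) features — 89 per modality, 356 over the four modalities.

Gray-level families operate on a fixed-bin-count discretization (32 levels
over the masked intensity range), which makes them invariant to affine
intensity rescaling.  GLCM uses distance 1 with the four 2-D angles
averaged; GLRLM averages feature values over the four run directions;
zones use 8-connectivity.  Degenerate values (zero-variance denominators,
single-pixel masks) are set to 0 under the logged NaN policy so the
feature table stays dense for ICC computation and modeling.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Tuple

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import graycomatrix
from skimage.measure import regionprops

from .types import SlicePatch, modality_list

log = logging.getLogger(__name__)

N_LEVELS = 32

FAMILY_COUNTS = {
    "firstorder": 19,
    "shape2d": 9,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}

FIRSTORDER_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "P10", "P90", "IQR",
    "Variance", "StdDev", "Skewness", "Kurtosis", "Energy", "TotalEnergy",
    "RMS", "MAD", "RobustMAD", "Entropy", "Uniformity",
)
SHAPE2D_NAMES = (
    "Area", "Perimeter", "PerimeterAreaRatio", "Circularity",
    "MajorAxisLength", "MinorAxisLength", "Elongation", "Eccentricity",
    "MaxDiameter",
)
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_EPS = np.finfo(float).eps


def discretize(
    patch: np.ndarray, mask: np.ndarray, n_levels: int = N_LEVELS
) -> Tuple[np.ndarray, int]:
    """Fixed-bin-count discretization of masked intensities into levels
    1..n_levels; pixels outside the mask map to 0.  A constant region maps
    entirely to level 1."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(patch, dtype=float)
    lo, hi = x[mask].min(), x[mask].max()
    out = np.zeros(x.shape, dtype=np.int64)
    if hi == lo:
        out[mask] = 1
    else:
        lev = np.floor((x[mask] - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
        out[mask] = np.clip(lev, 1, n_levels)
    return out, n_levels


def _finite(values: Dict[str, float], family: str) -> Dict[str, float]:
    """NaN policy: degenerate values are replaced by 0 with a log record."""
    clean = {}
    for k, v in values.items():
        if not np.isfinite(v):
            log.warning("degenerate %s feature %s set to 0", family, k)
            v = 0.0
        clean[k] = float(v)
    return clean


# ---------------------------------------------------------------- first order

def _firstorder(patch: np.ndarray, mask: np.ndarray) -> Dict[str, float]:
    x = np.asarray(patch, dtype=float)[mask]
    n = x.size
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mu, sd = x.mean(), x.std()
    if sd > 0:
        skew = float(np.mean(((x - mu) / sd) ** 3))
        kurt = float(np.mean(((x - mu) / sd) ** 4))
    else:
        skew, kurt = 0.0, 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    disc, nl = discretize(patch, mask)
    counts = np.bincount(disc[mask], minlength=nl + 1)[1:]
    p = counts[counts > 0] / n
    return {
        "Mean": mu,
        "Median": p50,
        "Minimum": x.min(),
        "Maximum": x.max(),
        "Range": x.max() - x.min(),
        "P10": p10,
        "P90": p90,
        "IQR": p75 - p25,
        "Variance": x.var(),
        "StdDev": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(np.sum(x**2)),  # unit in-plane pixel area
        "RMS": float(np.sqrt(np.mean(x**2))),
        "MAD": float(np.abs(x - mu).mean()),
        "RobustMAD": rmad,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Uniformity": float(np.sum(p**2)),
    }


# -------------------------------------------------------------------- shape2d

def _shape2d(mask: np.ndarray) -> Dict[str, float]:
    lab = mask.astype(np.uint8)
    props = regionprops(lab)[0]
    area = float(props.area)
    perim = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    return {
        "Area": area,
        "Perimeter": perim,
        "PerimeterAreaRatio": perim / area,
        "Circularity": 4 * np.pi * area / perim**2 if perim > 0 else 1.0,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "Elongation": minor / major if major > 0 else 1.0,
        "Eccentricity": float(props.eccentricity),
        "MaxDiameter": float(props.feret_diameter_max),
    }


# ----------------------------------------------------------------------- GLCM

def glcm_matrix(
    disc: np.ndarray, n_levels: int, distance: int = 1, angles=None
) -> np.ndarray:
    """Symmetric, angle-pooled, normalized co-occurrence matrix.

    ``disc`` uses 0 for out-of-mask pixels; pairs involving 0 are dropped,
    which restricts co-occurrence to in-mask pixel pairs.  ``angles``
    defaults to the four 2-D directions 0/45/90/135 degrees.
    """
    img = disc.astype(np.uint8)
    if angles is None:
        angles = [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    m = graycomatrix(
        img, [distance], angles, levels=n_levels + 1, symmetric=True
    ).astype(float)
    m = m[1:, 1:, 0, :]  # drop out-of-mask row/col
    m = m.sum(axis=2)  # pool the four 2-D directions
    tot = m.sum()
    if tot == 0:
        return np.zeros((n_levels, n_levels))
    return m / tot


def _glcm_features(p: np.ndarray) -> Dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(i * px))
    muy = float(np.sum(i * py))
    sdx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sdy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))

    k_sum = np.arange(2, 2 * ng + 1)
    pxy_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    pxy_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q))) if q.size else 0.0

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    with np.errstate(divide="ignore", invalid="ignore"):
        outer = np.outer(px, py)
        hxy1 = float(-np.sum(p[outer > 0] * np.log2(outer[outer > 0])))
        hxy2 = float(
            -np.sum(outer[outer > 0] * np.log2(outer[outer > 0]))
        )
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    arg = 1 - np.exp(-2 * (hxy2 - hxy))
    imc2 = float(np.sqrt(arg)) if arg > 0 else 0.0

    if sdx > 0 and sdy > 0:
        corr = (float(np.sum(ii * jj * p)) - mux * muy) / (sdx * sdy)
    else:
        corr = 1.0

    # MCC: sqrt of second-largest eigenvalue of Q
    nz = (px > 0) & (py > 0)
    if nz.sum() > 1:
        psub = p[np.ix_(nz, nz)]
        q = (psub[:, None, :] * psub[None, :, :]) / (
            px[nz][:, None, None] * py[nz][None, None, :]
        )
        q = q.sum(axis=2)
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0)))
    else:
        mcc = 1.0

    da = float(np.sum(k_diff * pxy_diff))
    off = np.abs(ii - jj)
    inv_var_mask = off > 0
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mux,
        "ClusterProminence": float(np.sum((ii + jj - mux - muy) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mux - muy) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mux - muy) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pxy_diff),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * pxy_diff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1 + off))),
        "Idn": float(np.sum(p / (1 + off / ng))),
        "InverseVariance": float(
            np.sum(p[inv_var_mask] / off[inv_var_mask] ** 2)
        ),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * pxy_sum)),
        "SumEntropy": ent(pxy_sum),
        "SumSquares": float(np.sum((ii - mux) ** 2 * p)),
        "MCC": mcc,
    }


# ---------------------------------------------------------------------- GLRLM

def _lines(disc: np.ndarray, direction: str) -> List[np.ndarray]:
    if direction == "0":
        return list(disc)
    if direction == "90":
        return list(disc.T)
    if direction == "45":
        f = np.fliplr(disc)
        return [f.diagonal(k) for k in range(-f.shape[0] + 1, f.shape[1])]
    if direction == "135":
        return [disc.diagonal(k) for k in range(-disc.shape[0] + 1, disc.shape[1])]
    raise ValueError(direction)


def glrlm_matrix(disc: np.ndarray, n_levels: int, direction: str) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] for one direction.

    Out-of-mask pixels (level 0) break runs and are not counted.
    """
    max_len = max(disc.shape)
    r = np.zeros((n_levels, max_len), dtype=float)
    for line in _lines(disc, direction):
        if line.size == 0:
            continue
        # run-length encode
        boundary = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate([[0], boundary])
        ends = np.concatenate([boundary, [line.size]])
        for s, e in zip(starts, ends):
            g = line[s]
            if g > 0:
                r[g - 1, e - s - 1] += 1
    return r


def _rlm_features(r: np.ndarray) -> Dict[str, float]:
    nr = r.sum()
    if nr == 0:
        return {k: 0.0 for k in GLRLM_NAMES}
    ng, nl = r.shape
    i = np.arange(1, ng + 1)[:, None]
    l = np.arange(1, nl + 1)[None, :]
    p = r / nr
    ri = r.sum(axis=1)
    rl = r.sum(axis=0)
    mu_i = np.sum(i * p)
    mu_l = np.sum(l * p)
    pe = p[p > 0]
    return {
        "ShortRunEmphasis": float(np.sum(r / l**2) / nr),
        "LongRunEmphasis": float(np.sum(r * l**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(ri**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(ri**2) / nr**2),
        "RunLengthNonUniformity": float(np.sum(rl**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(rl**2) / nr**2),
        "RunPercentage": float(nr / np.sum(r * l)),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * p)),
        "RunVariance": float(np.sum((l - mu_l) ** 2 * p)),
        "RunEntropy": float(-np.sum(pe * np.log2(pe))),
        "LowGrayLevelRunEmphasis": float(np.sum(r / i**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(r * i**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(r / (i**2 * l**2)) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(r * i**2 / l**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(r * l**2 / i**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(r * i**2 * l**2) / nr),
    }


def _glrlm_features(disc: np.ndarray, n_levels: int) -> Dict[str, float]:
    per_dir = [
        _rlm_features(glrlm_matrix(disc, n_levels, d))
        for d in ("0", "45", "90", "135")
    ]
    return {
        k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES
    }


# ---------------------------------------------------------------------- GLSZM

def glszm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix S[level-1, size-1]; zones are 8-connected regions
    of constant gray level within the mask."""
    max_size = int((disc > 0).sum())
    s = np.zeros((n_levels, max(max_size, 1)), dtype=float)
    structure = np.ones((3, 3), dtype=bool)
    for g in range(1, n_levels + 1):
        sel = disc == g
        if not sel.any():
            continue
        lab, nz = ndi.label(sel, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for size in sizes:
            s[g - 1, size - 1] += 1
    return s


def _szm_features(s: np.ndarray) -> Dict[str, float]:
    nz = s.sum()
    if nz == 0:
        return {k: 0.0 for k in GLSZM_NAMES}
    ng, ns = s.shape
    i = np.arange(1, ng + 1)[:, None]
    z = np.arange(1, ns + 1)[None, :]
    p = s / nz
    si = s.sum(axis=1)
    sz = s.sum(axis=0)
    mu_i = np.sum(i * p)
    mu_z = np.sum(z * p)
    pe = p[p > 0]
    return {
        "SmallAreaEmphasis": float(np.sum(s / z**2) / nz),
        "LargeAreaEmphasis": float(np.sum(s * z**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(si**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(si**2) / nz**2),
        "SizeZoneNonUniformity": float(np.sum(sz**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(sz**2) / nz**2),
        "ZonePercentage": float(nz / np.sum(s * z)),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * p)),
        "ZoneVariance": float(np.sum((z - mu_z) ** 2 * p)),
        "ZoneEntropy": float(-np.sum(pe * np.log2(pe))),
        "LowGrayLevelZoneEmphasis": float(np.sum(s / i**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(s * i**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(s / (i**2 * z**2)) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(s * i**2 / z**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(s * z**2 / i**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(s * i**2 * z**2) / nz),
    }


# ---------------------------------------------------------------------- NGTDM

def _ngtdm_features(disc: np.ndarray, n_levels: int) -> Dict[str, float]:
    inmask = disc > 0
    vals = disc.astype(float)
    vals[~inmask] = 0.0
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nbr_sum = ndi.convolve(vals, kernel, mode="constant")
    nbr_cnt = ndi.convolve(inmask.astype(float), kernel, mode="constant")
    valid = inmask & (nbr_cnt > 0)
    avg = np.zeros_like(vals)
    avg[valid] = nbr_sum[valid] / nbr_cnt[valid]

    n_total = int(valid.sum())
    if n_total == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    for g in range(1, n_levels + 1):
        sel = valid & (disc == g)
        n[g - 1] = sel.sum()
        s[g - 1] = np.abs(g - avg[sel]).sum()
    p = n / n_total
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, n_levels + 1)

    coars_den = float(np.sum(p * s))
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6

    if ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi = p[present][:, None]
        pj = p[present][None, :]
        si_ = s[present][:, None]
        sj_ = s[present][None, :]
        contrast = (
            np.sum(pi * pj * (ii - jj) ** 2) / (ngp * (ngp - 1))
        ) * (s.sum() / n_total)
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)))
        busyness = coars_den / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum(np.abs(ii - jj) * (pi * si_ + pj * sj_) / (pi + pj))
            / n_total
        )
        strength = (
            float(np.sum((pi + pj) * (ii - jj) ** 2)) / s.sum()
            if s.sum() > 0
            else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ------------------------------------------------------------------ dispatch

def family_features(
    patch: np.ndarray, mask: np.ndarray, family: str
) -> Dict[str, float]:
    """Named feature values of one family for one masked channel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if family == "firstorder":
        vals = _firstorder(patch, mask)
    elif family == "shape2d":
        vals = _shape2d(mask)
    elif family == "glcm":
        disc, nl = discretize(patch, mask)
        vals = _glcm_features(glcm_matrix(disc, nl))
    elif family == "glrlm":
        disc, nl = discretize(patch, mask)
        vals = _glrlm_features(disc, nl)
    elif family == "glszm":
        disc, nl = discretize(patch, mask)
        vals = _szm_features(glszm_matrix(disc, nl))
    elif family == "ngtdm":
        disc, nl = discretize(patch, mask)
        vals = _ngtdm_features(disc, nl)
    else:
        raise ValueError(f"unknown family {family!r}")
    assert len(vals) == FAMILY_COUNTS[family]
    return _finite(vals, family)


def texture_feature_names(modalities: List[str]) -> List[str]:
    names = []
    name_map = {
        "firstorder": FIRSTORDER_NAMES,
        "shape2d": SHAPE2D_NAMES,
        "glcm": GLCM_NAMES,
        "glrlm": GLRLM_NAMES,
        "glszm": GLSZM_NAMES,
        "ngtdm": NGTDM_NAMES,
    }
    for m in modalities:
        for fam, fnames in name_map.items():
            names.extend(f"{m}.{fam}.{n}" for n in fnames)
    return names


def extract_texture(sp: SlicePatch) -> Dict[str, float]:
    """Full texture vector of one patch: 6 families x 4 modalities = 356.

    Shape descriptors depend only on the shared mask, so they are computed
    once and emitted per modality to preserve the 89-per-modality layout.
    """
    sp.validate()
    shape_vals = family_features(
        next(iter(sp.channels.values())), sp.mask, "shape2d"
    )
    out: Dict[str, float] = {}
    for m in modality_list(sp.channels):
        ch = sp.channels[m]
        for fam in ("firstorder", "shape2d", "glcm", "glrlm", "glszm", "ngtdm"):
            vals = shape_vals if fam == "shape2d" else family_features(
                ch, sp.mask, fam
            )
            for k, v in vals.items():
                out[f"{m}.{fam}.{k}"] = v
    return out
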