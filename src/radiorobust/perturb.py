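"""Five perturbation classes for probing feature robustness.

Each perturbation produces a "relatively small" change of the kind seen in
test-retest imaging: R rotates image+mask about the mask center of mass
(head repositioning), T applies subpixel translations (regridding), N adds
Gaussian noise scaled to the slice's own wavelet-estimated noise level,
V grows/shrinks the mask along the Euclidean distance transform by a
target area fraction, and C randomizes the contour by probabilistic
superpixel selection.  Identity parameters (0 angle, 0 shift, 0 scale,
f = 0) return the input bit-exactly; class C has no identity.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pywt
import scipy.ndimage as ndi
from skimage.segmentation import slic

from .types import PerturbationSpec, SlicePatch

log = logging.getLogger(__name__)

#: 4 replicates per class keeps the slice x replicate ICC design balanced.
DEFAULT_GRID: Dict[str, List] = {
    "R": [3.0, -6.0, 9.0, -12.0],
    "T": [(0.25, 0.25), (0.5, 0.5), (0.75, 0.75), (0.25, 0.75)],
    "N": [0.5, 1.0, 1.5, 2.0],
    "V": [-0.15, -0.05, 0.05, 0.15],
    "C": [0, 1, 2, 3],
}


def _background_median(sp: SlicePatch, channel: str) -> float:
    outside = ~sp.mask
    vals = sp.channels[channel][outside]
    return float(np.median(vals)) if vals.size else 0.0


def rotate(sp: SlicePatch, angle: float) -> SlicePatch:
    """Rotate channels and mask by ``angle`` degrees about the mask
    center of mass (bilinear; mask re-thresholded at 0.5; out-of-frame
    pixels filled with the background median)."""
    if angle == 0:
        return sp.copy()
    out = sp.copy()
    cy, cx = ndi.center_of_mass(sp.mask)
    theta = np.deg2rad(angle)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    center = np.array([cy, cx])
    offset = center - rot @ center
    for m, ch in sp.channels.items():
        out.channels[m] = ndi.affine_transform(
            ch, rot, offset=offset, order=1, mode="constant",
            cval=_background_median(sp, m),
        )
    mrot = ndi.affine_transform(
        sp.mask.astype(float), rot, offset=offset, order=1,
        mode="constant", cval=0.0,
    )
    out.mask = mrot >= 0.5
    if not out.mask.any():
        raise ValueError(f"rotation by {angle} deg emptied the mask")
    return out


def translate(sp: SlicePatch, dx: float, dy: float) -> SlicePatch:
    """Shift channels and mask by ``(dx, dy)`` pixels (x = columns,
    y = rows) with bilinear resampling; mask re-thresholded at 0.5."""
    if dx == 0 and dy == 0:
        return sp.copy()
    out = sp.copy()
    shift = (dy, dx)
    for m, ch in sp.channels.items():
        out.channels[m] = ndi.shift(
            ch, shift, order=1, mode="constant",
            cval=_background_median(sp, m),
        )
    msh = ndi.shift(sp.mask.astype(float), shift, order=1, mode="constant")
    out.mask = msh >= 0.5
    if not out.mask.any():
        raise ValueError("translation emptied the mask")
    return out


def estimate_noise_sigma(channel: np.ndarray) -> float:
    """Robust noise level: median absolute deviation of the finest-level
    diagonal wavelet detail coefficients divided by 0.6745."""
    ch = np.asarray(channel, dtype=float)
    if min(ch.shape) < 16:
        raise ValueError("patch must be at least 16x16")
    _, (_, _, cd) = pywt.dwt2(ch, "haar")
    return float(np.median(np.abs(cd)) / 0.6745)


def add_noise(sp: SlicePatch, scale: float, seed: int = 0) -> SlicePatch:
    """Add i.i.d. Gaussian noise per channel with standard deviation
    ``scale`` times the channel's own estimated noise level."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if scale == 0:
        return sp.copy()
    out = sp.copy()
    rng = np.random.default_rng(seed)
    for m, ch in sp.channels.items():
        sd = scale * estimate_noise_sigma(ch)
        out.channels[m] = ch + sd * rng.standard_normal(ch.shape)
    return out


def alter_volume(sp: SlicePatch, f: float) -> SlicePatch:
    """Grow (f > 0) or shrink (f < 0) the mask along the signed Euclidean
    distance transform so its area is as close as achievable to
    ``(1 + f)`` times the original; channels unchanged."""
    if f <= -1:
        raise ValueError("f must be > -1")
    if f == 0:
        return sp.copy()
    out = sp.copy()
    inside = ndi.distance_transform_edt(sp.mask)
    outside = ndi.distance_transform_edt(~sp.mask)
    signed = outside - inside  # negative strictly inside
    target = (1 + f) * sp.mask.sum()
    vals = np.unique(signed)
    areas = np.searchsorted(np.sort(signed.ravel()), vals, side="right")
    best = vals[np.argmin(np.abs(areas - target))]
    new_mask = signed <= best
    if not new_mask.any():
        raise ValueError(f"volume alteration f={f} emptied the mask")
    out.mask = new_mask
    return out


def randomize_contour(
    sp: SlicePatch, seed: int = 0, target_superpixel_size: int = 64
) -> SlicePatch:
    """Contour randomization by probabilistic superpixel selection.

    The mean-of-channels image is segmented into superpixels of roughly
    ``target_superpixel_size`` pixels (SLIC, compactness 0.1); each
    superpixel s is included in the new mask with probability equal to its
    overlap fraction |s and mask| / |s|.  Deterministic given ``seed``;
    empty results are retried with derived seeds up to 10 times.
    """
    if not sp.mask.any():
        raise ValueError("mask empty")
    mean_img = np.mean([c for c in sp.channels.values()], axis=0)
    n_segments = max(4, mean_img.size // target_superpixel_size)
    labels = slic(
        mean_img, n_segments=n_segments, compactness=0.1,
        channel_axis=None, start_label=1,
    )
    ids = np.unique(labels)
    eta = np.array(
        [sp.mask[labels == i].mean() for i in ids]
    )
    for attempt in range(10):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, attempt])
        )
        include = rng.random(len(ids)) < eta
        new_mask = np.isin(labels, ids[include])
        if new_mask.any():
            out = sp.copy()
            out.mask = new_mask
            return out
    raise ValueError("contour randomization produced an empty mask")


def apply_perturbation(sp: SlicePatch, spec: PerturbationSpec) -> SlicePatch:
    if spec.klass == "R":
        return rotate(sp, float(spec.param))
    if spec.klass == "T":
        dx, dy = spec.param
        return translate(sp, float(dx), float(dy))
    if spec.klass == "N":
        return add_noise(sp, float(spec.param), seed=spec.seed)
    if spec.klass == "V":
        return alter_volume(sp, float(spec.param))
    if spec.klass == "C":
        return randomize_contour(sp, seed=spec.seed)
    raise ValueError(f"unknown perturbation class {spec.klass!r}")


def perturbation_suite(
    sp: SlicePatch,
    grid: Optional[Dict[str, Sequence]] = None,
    seed: int = 0,
) -> List[Tuple[PerturbationSpec, SlicePatch]]:
    """One perturbed replicate per (class, parameter) of the grid.

    The default grid yields 5 classes x 4 replicates = 20 patches per
    slice.  Member-op failures are logged and skipped.  Deterministic
    given the master ``seed``.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if not grid:
        raise ValueError("grid is empty")
    out: List[Tuple[PerturbationSpec, SlicePatch]] = []
    for klass in ("R", "T", "N", "V", "C"):
        params = grid.get(klass, [])
        for i, param in enumerate(params):
            rep_seed = (seed * 101 + 17 * i + ord(klass)) % (2**31)
            spec = PerturbationSpec(klass=klass, param=param, seed=rep_seed)
            try:
                out.append((spec, apply_perturbation(sp, spec)))
            except ValueError as err:
                log.warning(
                    "skipping %s on %s slice %d: %s",
                    spec.perturbation_id, sp.patient_id, sp.slice_index, err,
                )
    return out
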