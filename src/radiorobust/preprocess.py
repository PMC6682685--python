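"""Volume preprocessing: resampling, bias removal, IQR normalization,
tumor-patch extraction and the 20:3 oversampled slice-selection rule.

The preprocessing contract mirrors a standard glioma radiomics pipeline:
volumes are resampled to isotropic 1 mm spacing (trilinear for intensities,
nearest-neighbor for masks), a smooth multiplicative bias field is removed
by a log-domain polynomial fit, intensities are normalized by the median /
interquartile range of the non-tumor brain region, and axial tumor slices
are cropped to a square patch and rescaled to 142x142 pixels.

Slice selection implements the heavy oversampling of the rare codeleted
class: label-1 scans contribute their 20 largest tumor cross-sections
while label-0 scans contribute only the slices at the 50th, 75th and 100th
percentile of per-slice tumor area (nearest-rank convention, ties broken
toward the lower slice index).
"""

from __future__ import annotations

from typing import List

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize

from .types import SlicePatch, VolumeSet, modality_list

PATCH_SIZE = 142
N_SLICES_POS = 20
PERCENTILES_NEG = (50.0, 75.0, 100.0)


def resample_isotropic(
    vs: VolumeSet, target_spacing: float = 1.0
) -> VolumeSet:
    """Resample all volumes/masks to isotropic ``target_spacing`` mm.

    Grid convention: the output shape is ``round(shape * dx / target)``
    per axis (scipy zoom convention); intensities are interpolated
    trilinearly, masks with nearest-neighbor.
    """
    if any(s <= 0 for s in vs.spacing) or target_spacing <= 0:
        raise ValueError("spacing must be positive")
    factors = tuple(s / target_spacing for s in vs.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        out = vs.copy()
        out.spacing = (target_spacing,) * 3
        return out
    volumes = {
        m: ndi.zoom(v, factors, order=1) for m, v in vs.volumes.items()
    }
    brain = ndi.zoom(vs.brain_mask.astype(np.uint8), factors, order=0) > 0
    tumor = ndi.zoom(vs.tumor_mask.astype(np.uint8), factors, order=0) > 0
    out = VolumeSet(
        patient_id=vs.patient_id,
        volumes=volumes,
        spacing=(target_spacing,) * 3,
        brain_mask=brain,
        tumor_mask=tumor & brain,
        label=vs.label,
        age=vs.age,
        sex=vs.sex,
        kps=vs.kps,
    )
    return out


def _poly_basis(coords: np.ndarray, order: int) -> np.ndarray:
    z, y, x = coords
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((z**i) * (y**j) * (x**k))
    return np.stack(cols, axis=-1)


def bias_correct(
    vs: VolumeSet, order: int = 3, max_fit_voxels: int = 20000
) -> VolumeSet:
    """Remove a smooth multiplicative field by a log-domain polynomial fit.

    The log-intensity inside the brain mask is fitted with a polynomial of
    total degree <= ``order``; the fitted field (normalized to unit
    geometric mean in the brain) is divided out.  A multiplicative field is
    identifiable only up to a global factor, so recovery of a corrupted
    image is exact only modulo one scalar.  Non-positive intensities are
    handled by a shift before taking logarithms.
    """
    if not vs.brain_mask.any():
        raise ValueError("brain mask empty")
    out = vs.copy()
    # fit on normal-appearing tissue so tumor contrast does not leak into
    # the estimated field; apply to the whole brain
    fit_region = vs.brain_mask & ~vs.tumor_mask
    if fit_region.sum() < 500:
        fit_region = vs.brain_mask
    idx = np.argwhere(fit_region)
    rng = np.random.default_rng(0)  # subsampling only; fit is deterministic
    if len(idx) > max_fit_voxels:
        idx = idx[rng.choice(len(idx), max_fit_voxels, replace=False)]
    shape = np.array(vs.brain_mask.shape, dtype=float)
    coords_fit = (idx / shape).T * 2 - 1
    basis_fit = _poly_basis(coords_fit, order)
    full_idx = np.argwhere(vs.brain_mask)
    coords_full = (full_idx / shape).T * 2 - 1
    basis_full = _poly_basis(coords_full, order)
    for m, vol in vs.volumes.items():
        vals = vol[tuple(idx.T)]
        shift = 0.0
        lo = vol[vs.brain_mask].min()
        if lo <= 0:
            shift = -lo + 1e-3 * max(1.0, abs(lo))
        logv = np.log(vals + shift)
        coef, *_ = np.linalg.lstsq(basis_fit, logv, rcond=None)
        field_log = basis_full @ coef
        field = np.exp(field_log - field_log.mean())
        corrected = vol.copy()
        corrected[vs.brain_mask] = (
            vol[vs.brain_mask] + shift
        ) / field - shift
        out.volumes[m] = corrected
    return out


def normalize_iqr(vs: VolumeSet, min_ref_voxels: int = 100) -> VolumeSet:
    """Normalize each modality by the non-tumor brain median and IQR.

    The reference region is ``brain_mask & ~tumor_mask``; after
    normalization its median is exactly 0 and its interquartile range
    exactly 1 (quartiles by linear interpolation).  The operation is
    idempotent.
    """
    ref = vs.brain_mask & ~vs.tumor_mask
    if ref.sum() < min_ref_voxels:
        raise ValueError(
            f"non-tumor brain region has only {int(ref.sum())} voxels"
        )
    out = vs.copy()
    for m, vol in vs.volumes.items():
        r = vol[ref]
        q25, q50, q75 = np.percentile(r, [25, 50, 75])
        iqr = q75 - q25
        if iqr == 0:
            raise ValueError(f"degenerate reference IQR for modality {m}")
        out.volumes[m] = (vol - q50) / iqr
    return out


def extract_patch(
    vs: VolumeSet, slice_index: int, size: int = PATCH_SIZE
) -> SlicePatch:
    """Crop one axial slice to the tumor bounding box, pad to square, and
    rescale to ``size`` x ``size`` (bilinear channels; mask bilinear then
    thresholded at 0.5)."""
    tslice = vs.tumor_mask[:, :, slice_index]
    if not tslice.any():
        raise ValueError(f"no tumor on slice {slice_index}")
    rows = np.flatnonzero(tslice.any(axis=1))
    cols = np.flatnonzero(tslice.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    h, w = r1 - r0, c1 - c0
    side = max(h, w)
    # symmetric padding to square
    pr = side - h
    pc = side - w
    pad_r = (pr // 2, pr - pr // 2)
    pad_c = (pc // 2, pc - pc // 2)

    def crop_pad(img, fill_edge):
        sub = img[r0:r1, c0:c1]
        mode = "edge" if fill_edge else "constant"
        return np.pad(sub, (pad_r, pad_c), mode=mode)

    channels = {}
    for m in vs.volumes:
        sq = crop_pad(vs.volumes[m][:, :, slice_index], fill_edge=True)
        channels[m] = resize(
            sq.astype(float), (size, size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    msq = crop_pad(tslice.astype(float), fill_edge=False)
    mask = (
        resize(msq, (size, size), order=1, mode="constant",
               anti_aliasing=False, preserve_range=True) >= 0.5
    )
    if not mask.any():
        # sub-pixel tumors can vanish under the 0.5 threshold; keep the peak
        mask = resize(msq, (size, size), order=0, mode="constant",
                      preserve_range=True) > 0
    sp = SlicePatch(
        patient_id=vs.patient_id,
        slice_index=int(slice_index),
        channels=channels,
        mask=mask,
        label=vs.label,
    )
    sp.validate()
    return sp


def tumor_slice_areas(vs: VolumeSet) -> np.ndarray:
    """Per-axial-slice tumor cross-sectional area (pixel counts)."""
    return vs.tumor_mask.sum(axis=(0, 1))


def select_slices(vs: VolumeSet) -> List[int]:
    """Slice indices under the 20:3 oversampling rule.

    label 1: the (up to) 20 slices with largest tumor area, in descending
    area order; label 0: the slices at the 50th, 75th and 100th nearest-rank
    percentile of per-slice tumor area.  Ties broken toward the lower slice
    index; duplicates removed.
    """
    areas = tumor_slice_areas(vs)
    bearing = np.flatnonzero(areas > 0)
    if len(bearing) == 0:
        raise ValueError("no tumor-bearing slices")
    if vs.label == 1:
        order = sorted(bearing, key=lambda i: (-areas[i], i))
        return [int(i) for i in order[:N_SLICES_POS]]
    asc = sorted(bearing, key=lambda i: (areas[i], i))
    n = len(asc)
    out: List[int] = []
    for p in PERCENTILES_NEG:
        rank = max(1, int(np.ceil(p / 100.0 * n)))
        idx = int(asc[rank - 1])
        if idx not in out:
            out.append(idx)
    return out


def patches_from_volume(vs: VolumeSet, size: int = PATCH_SIZE) -> List[SlicePatch]:
    """Selected, extracted tumor patches of one preprocessed volume."""
    return [extract_patch(vs, k, size) for k in select_slices(vs)]
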