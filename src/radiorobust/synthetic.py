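"""Synthetic phantom cohorts with known topology and plantable class signal.

Real studies of 1p/19q codeletion use multi-institutional glioma MRI with
manual tumor segmentations.  This module generates a stand-in cohort at desk
scale: four co-registered modality volumes with distinct tissue contrasts, a
lumpy tumor inside an ellipsoidal brain, per-modality Gaussian noise, an
optional smooth multiplicative bias field, and a configurable class-dependent
signal so that every downstream stage can be tested against ground truth.

Two signal types can be planted:

``topology-holes``
    codeleted (label 1) tumors contain ring-like hypointense sub-structures,
    adding long H1 persistence bars that topological features can detect;
``texture-contrast``
    the intra-tumor random texture has a class-dependent autocorrelation
    length, detectable by gray-level co-occurrence statistics.

Every generated object is a pure function of ``(config, seed, patient_index)``.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .types import MODALITIES, CohortConfig, SlicePatch, VolumeSet

# Baseline tissue intensities per modality (arbitrary units): distinct
# contrast between brain tissue and tumor for each sequence.
_TISSUE = {
    "T1": (1.0, 0.70),
    "T1post": (1.0, 1.35),
    "T2": (0.8, 1.30),
    "FLAIR": (0.9, 1.40),
}

_RETRY_CAP = 20


def _smooth_noise_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with correlation length
    ``length`` voxels, built by smoothing white noise."""
    w = rng.standard_normal(shape)
    f = ndi.gaussian_filter(w, sigma=length, mode="nearest")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return d <= 1.0


def _lumpy_tumor(
    rng: np.random.Generator, shape, brain: np.ndarray, radius: float
) -> np.ndarray:
    """Union of random balls around a jittered center: an irregular blob
    whose contour makes volume/contour perturbations non-trivial."""
    center = np.array(shape) / 2.0 + rng.uniform(-6, 6, size=3)
    tumor = np.zeros(shape, dtype=bool)
    n_balls = rng.integers(5, 9)
    for _ in range(n_balls):
        offs = rng.uniform(-0.55 * radius, 0.55 * radius, size=3)
        r = radius * rng.uniform(0.55, 0.95)
        ball_center = center + offs
        tumor |= _ellipsoid_mask(shape, ball_center, (r, r, 0.75 * r))
    # clip to the interior of the brain so tumor_mask subset of brain_mask
    interior = ndi.binary_erosion(brain, iterations=2)
    return tumor & interior


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def _plant_rings(
    rng: np.random.Generator,
    vol_shape,
    tumor: np.ndarray,
    magnitude: float,
) -> np.ndarray:
    """Binary mask of ring-like (axial annulus) sub-structures inside the
    tumor; returned shell is set hypointense by the caller."""
    shell = np.zeros(vol_shape, dtype=bool)
    n_rings = max(1, int(round(1 + magnitude)))
    core = ndi.binary_erosion(tumor, iterations=4)
    if not core.any():
        core = tumor
    # ring axes run through the whole tumor depth so every large axial
    # cross-section carries at least one annulus
    proj = core.any(axis=2)
    idx2d = np.argwhere(proj)
    yy, xx = np.ogrid[0 : vol_shape[0], 0 : vol_shape[1]]
    for _ in range(n_rings):
        cy, cx = idx2d[rng.integers(len(idx2d))]
        r = rng.uniform(3.5, 5.5)
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ring2d = np.abs(rho - r) <= 1.25
        shell |= ring2d[:, :, None] & tumor
    return shell


def make_phantom_volume(
    config: CohortConfig, patient_index: int, label: int
) -> VolumeSet:
    """Generate one patient's phantom study.

    Deterministic given ``(config.seed, patient_index)``.  The tumor is a
    lumpy union of balls inside an ellipsoidal brain; the label-dependent
    signal is injected according to ``config.effect``.  Raises ``RuntimeError``
    if a valid tumor cannot be placed within the retry cap.
    """
    config.validate()
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, patient_index])
    )
    shape = tuple(config.shape)
    center = np.array(shape) / 2.0
    semi = np.array(shape) * 0.42
    brain = _ellipsoid_mask(shape, center, semi)

    tumor = None
    for _ in range(_RETRY_CAP):
        cand = _lumpy_tumor(rng, shape, brain, config.tumor_radius)
        if cand.any() and not _touches_boundary(cand):
            tumor = cand
            break
    if tumor is None:
        raise RuntimeError(
            f"could not place a valid tumor for patient {patient_index}"
        )

    # intra-tumor texture field; correlation length may carry the class signal
    length = 1.5
    if config.effect == "texture-contrast" and label == 1:
        length = 1.5 + 1.5 * config.effect_magnitude
    texture = _smooth_noise_field(rng, shape, length)

    ring_shell = None
    if config.effect == "topology-holes" and label == 1:
        ring_shell = _plant_rings(rng, shape, tumor, config.effect_magnitude)

    bias = None
    if config.bias_field:
        zz, yy, xx = np.meshgrid(
            *[np.linspace(-1, 1, s) for s in shape], indexing="ij"
        )
        c = rng.uniform(-1, 1, size=3)
        bias = 1.0 + config.bias_amplitude * (
            c[0] * xx + c[1] * yy + c[2] * zz
        ) / max(1e-9, np.abs(c).sum())

    volumes = {}
    for m in MODALITIES:
        tissue, tum = _TISSUE[m]
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain] = tissue
        vol[tumor] = tum
        vol += 0.15 * tum * texture * tumor
        if ring_shell is not None:
            depth = min(0.25 * config.effect_magnitude, 0.6)
            vol[ring_shell] = tum * (1.0 - 0.4 - depth)
        if bias is not None:
            vol *= bias
        sigma = config.noise_sigma.get(m, 0.0)
        if sigma > 0:
            vol += sigma * rng.standard_normal(shape)
        volumes[m] = vol

    age = float(np.clip(rng.normal(50.0, 12.0), 18.0, 90.0))
    kps = int(rng.choice([60, 70, 80, 90, 100]))
    sex = str(rng.choice(["M", "F"]))
    vs = VolumeSet(
        patient_id=f"P{patient_index:03d}",
        volumes=volumes,
        spacing=tuple(config.spacing),
        brain_mask=brain,
        tumor_mask=tumor,
        label=int(label),
        age=age,
        sex=sex,
        kps=kps,
    )
    vs.validate()
    return vs


def make_cohort(config: CohortConfig) -> Tuple[List[VolumeSet], pd.DataFrame]:
    """Generate ``n_pos + n_neg`` phantom patients plus the label table.

    Codeleted (label 1) patients come first.  The label table has columns
    ``patient_id, label, age, sex, kps`` and serializes directly to CSV.
    """
    config.validate()
    labels = [1] * config.n_pos + [0] * config.n_neg
    cohort = [
        make_phantom_volume(config, i, lab) for i, lab in enumerate(labels)
    ]
    table = pd.DataFrame(
        {
            "patient_id": [vs.patient_id for vs in cohort],
            "label": [vs.label for vs in cohort],
            "age": [vs.age for vs in cohort],
            "sex": [vs.sex for vs in cohort],
            "kps": [vs.kps for vs in cohort],
        }
    )
    return cohort, table


def _circle_dist(size: int, cy: float, cx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)


def make_tda_phantom(
    shape: str, levels: Sequence[float] = (0.0,), size: int = 32
) -> SlicePatch:
    """Single-slice phantom with analytically known Betti numbers.

    ``shape`` is one of ``constant`` (one component, no hole), ``disk``
    (filled disk), ``annulus`` (one hole) or ``double_annulus`` (two holes,
    connected by a bridge).  The figure takes intensity ``levels[0]``; if a
    second level is supplied, hole interiors are filled at ``levels[1]`` and
    included in the mask (producing finite H1 bars); otherwise holes are
    excluded from the mask (essential H1 classes).
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    levels = list(levels)
    if len(levels) > 1 and not all(
        a < b for a, b in zip(levels, levels[1:])
    ):
        raise ValueError("levels must be strictly increasing")
    lo = float(levels[0])
    fill = float(levels[1]) if len(levels) > 1 else None

    img = np.zeros((size, size), dtype=float)
    mask = np.zeros((size, size), dtype=bool)
    c = (size - 1) / 2.0

    if shape == "constant":
        mask[2:-2, 2:-2] = True
        img[mask] = lo
    elif shape == "disk":
        d = _circle_dist(size, c, c)
        mask = d <= size * 0.35
        img[mask] = lo
    elif shape == "annulus":
        d = _circle_dist(size, c, c)
        ring = (d <= size * 0.35) & (d >= size * 0.18)
        hole = d < size * 0.18
        mask = ring.copy()
        img[ring] = lo
        if fill is not None:
            mask |= hole
            img[hole] = fill
    elif shape == "double_annulus":
        cx1, cx2 = size * 0.28, size * 0.72
        r_out, r_in = size * 0.20, size * 0.10
        d1 = _circle_dist(size, c, cx1)
        d2 = _circle_dist(size, c, cx2)
        ring = ((d1 <= r_out) & (d1 >= r_in)) | ((d2 <= r_out) & (d2 >= r_in))
        # bridge keeps the figure connected (beta0 = 1)
        bridge = np.zeros_like(ring)
        row = int(round(c))
        bridge[row - 1 : row + 2, int(cx1) : int(cx2) + 1] = True
        bridge &= ~((d1 < r_in) | (d2 < r_in))
        ring |= bridge
        hole = (d1 < r_in) | (d2 < r_in)
        mask = ring.copy()
        img[ring] = lo
        if fill is not None:
            mask |= hole
            img[hole] = fill
    else:
        raise ValueError(f"unknown phantom shape {shape!r}")

    sp = SlicePatch(
        patient_id="phantom",
        slice_index=0,
        channels={m: img.copy() for m in MODALITIES},
        mask=mask,
        label=0,
    )
    sp.validate()
    return sp
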