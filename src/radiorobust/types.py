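"""Core data containers shared across the pipeline.

A :class:`VolumeSet` holds one patient's co-registered multi-modal MRI study
(T1, T1-post, T2, FLAIR) together with brain/tumor masks, the binary
1p/19q-codeletion label and clinical covariates.  A :class:`SlicePatch` is a
single axial tumor patch (142x142 by default) with one channel per modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

#: Canonical modality order used for every per-modality feature layout.
MODALITIES: Tuple[str, ...] = ("T1", "T1post", "T2", "FLAIR")

#: Perturbation class codes: rotation, noise, translation, volume, contour.
PERTURBATION_CLASSES: Tuple[str, ...] = ("R", "N", "T", "V", "C")


@dataclass
class VolumeSet:
    """One patient's registered multi-modal volumes, masks and metadata."""

    patient_id: str
    volumes: Dict[str, np.ndarray]
    spacing: Tuple[float, float, float]
    brain_mask: np.ndarray
    tumor_mask: np.ndarray
    label: int
    age: float = 50.0
    sex: str = "F"
    kps: int = 90

    def validate(self) -> None:
        shapes = {m: v.shape for m, v in self.volumes.items()}
        ref = self.brain_mask.shape
        for m, s in shapes.items():
            if s != ref:
                raise ValueError(f"volume {m} shape {s} != mask shape {ref}")
        if self.tumor_mask.shape != ref:
            raise ValueError("tumor mask shape mismatch")
        if not np.all(self.tumor_mask <= self.brain_mask):
            raise ValueError("tumor mask not contained in brain mask")
        if not self.tumor_mask.any():
            raise ValueError("tumor mask empty")
        for m, v in self.volumes.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite intensities in {m}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    def copy(self) -> "VolumeSet":
        return replace(
            self,
            volumes={m: v.copy() for m, v in self.volumes.items()},
            brain_mask=self.brain_mask.copy(),
            tumor_mask=self.tumor_mask.copy(),
        )


@dataclass
class SlicePatch:
    """One axial tumor patch: 4 modality channels + binary mask + identity."""

    patient_id: str
    slice_index: int
    channels: Dict[str, np.ndarray]
    mask: np.ndarray
    label: int

    def validate(self) -> None:
        ref = self.mask.shape
        for m, c in self.channels.items():
            if c.shape != ref:
                raise ValueError(f"channel {m} shape {c.shape} != mask {ref}")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"non-finite intensities in channel {m}")
        if not self.mask.any():
            raise ValueError("patch mask empty")

    def copy(self) -> "SlicePatch":
        return replace(
            self,
            channels={m: c.copy() for m, c in self.channels.items()},
            mask=self.mask.copy(),
        )


@dataclass
class CohortConfig:
    """Parameters of the synthetic phantom cohort generator.

    Defaults emulate the study cohort shape: a severe ~1:10 class imbalance
    (13 codeleted vs 130 non-codeleted patients), four modalities with
    distinct tissue contrasts, per-modality Gaussian noise and an optional
    smooth multiplicative bias field.  ``effect`` plants a class-dependent
    signal: ``"topology-holes"`` gives codeleted tumors ring-like hypointense
    sub-structures (extra H1 topology), ``"texture-contrast"`` changes the
    intra-tumor autocorrelation length, ``"none"`` yields a null cohort.
    """

    n_pos: int = 13
    n_neg: int = 130
    shape: Tuple[int, int, int] = (96, 96, 64)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: Dict[str, float] = field(
        default_factory=lambda: {m: 0.02 for m in MODALITIES}
    )
    bias_field: bool = False
    bias_amplitude: float = 0.3
    effect: str = "none"
    effect_magnitude: float = 1.0
    tumor_radius: float = 14.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.effect not in ("none", "texture-contrast", "topology-holes"):
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect_magnitude < 0:
            raise ValueError("effect magnitude must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class Barcode:
    """Persistence intervals (birth, death) for one homology dimension.

    Essential classes are finite-ized at the masked maximum intensity before
    storage, so every death is finite and ``death >= birth`` holds throughout.
    """

    dim: int
    intervals: np.ndarray  # (n, 2) float array of (birth, death)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.intervals = arr

    @property
    def n_bars(self) -> int:
        return len(self.intervals)

    @property
    def births(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def lengths(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]


@dataclass(frozen=True)
class PerturbationSpec:
    """Identifies one perturbed replicate: class code, parameter, seed."""

    klass: str
    param: object
    seed: int = 0

    @property
    def perturbation_id(self) -> str:
        return f"{self.klass}:{self.param}:{self.seed}"


def modality_list(channels: Dict[str, np.ndarray]) -> List[str]:
    """Modalities of a patch in canonical order, extras appended sorted."""
    known = [m for m in MODALITIES if m in channels]
    extra = sorted(set(channels) - set(MODALITIES))
    return known + extra
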