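"""Resampling, bias removal, IQR normalization, patch extraction and the
oversampled slice-selection rule."""

import numpy as np
import pytest

from radiorobust.preprocess import (
    bias_correct,
    extract_patch,
    normalize_iqr,
    patches_from_volume,
    resample_isotropic,
    select_slices,
)
from radiorobust.synthetic import make_phantom_volume
from radiorobust.types import CohortConfig, VolumeSet

SMALL = dict(shape=(48, 48, 32), tumor_radius=7.0)


def _phantom(label=1, seed=2, **kw):
    cfg = CohortConfig(n_pos=1, n_neg=1, seed=seed, **{**SMALL, **kw})
    return make_phantom_volume(cfg, 0, label)


def _tiny_volume(ref_vals, tumor_val):
    """A minimal volume whose non-tumor brain voxels are exactly ref_vals."""
    n = len(ref_vals) + 1
    vol = np.zeros((n, 1, 1))
    vol[: len(ref_vals), 0, 0] = ref_vals
    vol[-1, 0, 0] = tumor_val
    brain = np.ones((n, 1, 1), bool)
    tumor = np.zeros((n, 1, 1), bool)
    tumor[-1] = True
    return VolumeSet(
        patient_id="T", volumes={"T1": vol}, spacing=(1, 1, 1),
        brain_mask=brain, tumor_mask=tumor, label=0,
    )


class TestResample:
    def test_identity_at_target_spacing(self):
        vs = _phantom()
        out = resample_isotropic(vs, 1.0)
        assert out.brain_mask.shape == vs.brain_mask.shape
        assert np.allclose(out.volumes["T1"], vs.volumes["T1"])

    def test_upsampling_doubles_shape(self):
        vs = _phantom()
        vs.spacing = (2.0, 2.0, 2.0)
        out = resample_isotropic(vs, 1.0)
        # scipy zoom convention: round(shape * factor)
        assert out.brain_mask.shape == tuple(2 * s for s in SMALL["shape"])

    def test_mask_volume_conserved(self):
        vs = _phantom()
        vs.spacing = (2.0, 2.0, 2.0)
        out = resample_isotropic(vs, 1.0)
        ratio = out.tumor_mask.sum() / vs.tumor_mask.sum()
        assert 8 * 0.9 <= ratio <= 8 * 1.1

    def test_degenerate_spacing_rejected(self):
        vs = _phantom()
        vs.spacing = (0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            resample_isotropic(vs)


class TestBiasCorrect:
    def test_no_bias_is_near_identity(self):
        vs = _phantom()
        out = bias_correct(vs)
        inb = vs.brain_mask
        rel = np.abs(out.volumes["T1"][inb] - vs.volumes["T1"][inb])
        assert np.median(rel / np.abs(vs.volumes["T1"][inb]).mean()) < 0.05

    def test_recovers_planted_linear_field(self):
        vs = _phantom(seed=4)
        w = vs.brain_mask.shape[0]
        x = np.arange(w)[:, None, None] / w
        field = 1 + 0.3 * np.broadcast_to(x, vs.brain_mask.shape)
        corrupted = vs.copy()
        for m in corrupted.volumes:
            corrupted.volumes[m] = vs.volumes[m] * field
        out = bias_correct(corrupted)
        inb = vs.brain_mask
        got, want = out.volumes["T1"][inb], vs.volumes["T1"][inb]
        # the field is identifiable only up to a global factor
        scale = np.dot(want, got) / np.dot(got, got)
        rmse = np.sqrt(np.mean((scale * got - want) ** 2))
        assert rmse / np.sqrt(np.mean(want**2)) < 0.05

    def test_reduces_coefficient_of_variation(self):
        vs = _phantom(seed=5)
        const = vs.copy()
        w = vs.brain_mask.shape[0]
        x = np.arange(w)[:, None, None] / w
        field = 1 + 0.4 * np.broadcast_to(x, vs.brain_mask.shape)
        for m in const.volumes:
            const.volumes[m] = np.where(vs.brain_mask, 1.0, 0.0) * field
        out = bias_correct(const)
        inb = vs.brain_mask

        def cov(v):
            return v[inb].std() / v[inb].mean()

        assert cov(out.volumes["T1"]) < cov(const.volumes["T1"])


class TestNormalizeIQR:
    def test_reference_region_is_standardized(self):
        vs = _phantom()
        out = normalize_iqr(vs)
        ref = out.brain_mask & ~out.tumor_mask
        for m, v in out.volumes.items():
            q25, q50, q75 = np.percentile(v[ref], [25, 50, 75])
            assert q50 == pytest.approx(0.0, abs=1e-12)
            assert q75 - q25 == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        vs = _phantom()
        scaled = vs.copy()
        for m in scaled.volumes:
            scaled.volumes[m] = 3.5 * vs.volumes[m] - 2.0
        a = normalize_iqr(vs)
        b = normalize_iqr(scaled)
        assert np.allclose(a.volumes["T1"], b.volumes["T1"])

    def test_hand_computed_quartiles(self):
        # reference {1..5}: median 3, IQR 2 under linear-interpolation
        # quartiles; the value 100 sits in the tumor and is excluded
        vs = _tiny_volume([1, 2, 3, 4, 5], 100.0)
        out = normalize_iqr(vs, min_ref_voxels=5)
        ref_vals = out.volumes["T1"][:5, 0, 0]
        assert np.allclose(ref_vals, [-1, -0.5, 0, 0.5, 1])

    def test_idempotent(self):
        vs = _phantom()
        once = normalize_iqr(vs)
        twice = normalize_iqr(once)
        assert np.allclose(once.volumes["T1"], twice.volumes["T1"])

    def test_degenerate_reference_rejected(self):
        vs = _tiny_volume([2, 2, 2, 2, 2], 9.0)
        with pytest.raises(ValueError):
            normalize_iqr(vs, min_ref_voxels=5)


class TestExtractPatch:
    def test_output_shape_and_mask(self):
        vs = _phantom()
        k = select_slices(vs)[0]
        sp = extract_patch(vs, k)
        assert sp.mask.shape == (142, 142)
        for c in sp.channels.values():
            assert c.shape == (142, 142)
        assert sp.mask.any()

    def test_empty_slice_rejected(self):
        vs = _phantom()
        empty = int(np.flatnonzero(vs.tumor_mask.sum(axis=(0, 1)) == 0)[0])
        with pytest.raises(ValueError):
            extract_patch(vs, empty)

    def test_aspect_preserving_square_pad(self):
        # a 6x12 rectangular tumor slice must stay a rectangle of the same
        # 1:2 aspect after the square pad + rescale
        vol = np.zeros((32, 32, 3))
        brain = np.ones((32, 32, 3), bool)
        tumor = np.zeros((32, 32, 3), bool)
        tumor[13:19, 10:22, 1] = True
        vs = VolumeSet(
            patient_id="A", volumes={"T1": vol}, spacing=(1, 1, 1),
            brain_mask=brain, tumor_mask=tumor, label=0,
        )
        sp = extract_patch(vs, 1)
        rows = np.flatnonzero(sp.mask.any(axis=1))
        cols = np.flatnonzero(sp.mask.any(axis=0))
        aspect = (rows[-1] - rows[0] + 1) / (cols[-1] - cols[0] + 1)
        assert aspect == pytest.approx(0.5, rel=0.1)


class TestSelectSlices:
    def _with_areas(self, areas, label):
        nz = len(areas)
        vol = np.zeros((40, 40, nz))
        brain = np.ones((40, 40, nz), bool)
        tumor = np.zeros((40, 40, nz), bool)
        for k, a in enumerate(areas):
            if a > 0:
                side = int(np.ceil(np.sqrt(a)))
                flat = np.zeros(side * side, bool)
                flat[:a] = True
                tumor[5 : 5 + side, 5 : 5 + side, k] = flat.reshape(side, side)
        return VolumeSet(
            patient_id="S", volumes={"T1": vol}, spacing=(1, 1, 1),
            brain_mask=brain, tumor_mask=tumor, label=label,
        )

    def test_codeleted_takes_20_largest_descending(self):
        areas = list(range(1, 31))  # 30 tumor slices
        vs = self._with_areas(areas, label=1)
        sel = select_slices(vs)
        assert len(sel) == 20
        got = [areas[k] for k in sel]
        assert got == sorted(got, reverse=True)
        assert min(got) == 11  # the 20 largest of 1..30

    def test_codeleted_caps_at_available(self):
        vs = self._with_areas([3, 5, 8, 2, 9, 4, 7, 6], label=1)
        assert len(select_slices(vs)) == 8

    def test_non_codeleted_nearest_rank_percentiles(self):
        areas = list(range(1, 10))  # 9 slices, areas 1..9
        vs = self._with_areas(areas, label=0)
        sel = select_slices(vs)
        assert [areas[k] for k in sel] == [5, 7, 9]

    def test_bounds_always_hold(self):
        for label in (0, 1):
            vs = _phantom(label=label)
            sel = select_slices(vs)
            assert len(sel) <= (20 if label == 1 else 3)
            assert len(sel) == len(set(sel))

    def test_patches_from_volume_roundtrip(self):
        vs = _phantom(label=0)
        patches = patches_from_volume(vs)
        assert len(patches) == len(select_slices(vs))
        for sp in patches:
            assert sp.label == 0 and sp.mask.any()
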