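"""Baseline and contour-focused registration on small phantoms."""

import numpy as np
import pytest

from spinefuse import (
    ContourMask,
    ImageVolume,
    LesionAnnotation,
    PhantomSpec,
    generate_phantom_pair,
    joint_histogram,
    make_rigid,
    nmi,
    register_baseline,
    register_contour_focused,
    run_arir_workflow,
)
from spinefuse import RegistrationOptions
from spinefuse.errors import InvalidParameterError
from spinefuse.geometry import decompose_difference
from tests.conftest import SMALL_KW, volume_center

# sub-voxel baseline accuracy needs the full-resolution pyramid level
FULL_BASELINE = RegistrationOptions(baseline_pyramid_factors=(4, 2, 1))


def max_errors(result_t, truth_t, center):
    err = decompose_difference(result_t, truth_t, center=center)
    mt = max(abs(err.dt_lr), abs(err.dt_ap), abs(err.dt_cc))
    mr = max(abs(err.dr_axial), abs(err.dr_coronal), abs(err.dr_sagittal))
    return mt, mr


class TestBaseline:
    def test_self_registration_returns_identity(self, noisefree_pair):
        primary = noisefree_pair[0]
        copy = ImageVolume(primary.voxels.copy(), primary.spacing, primary.origin)
        result = register_baseline(primary, copy)
        t = result.transform
        assert np.all(np.abs(t.translation) <= 0.1)
        assert np.all(np.abs(t.angles_deg) <= 0.1)

    def test_pure_translation_recovered_within_half_voxel(self, small_spec):
        center = volume_center(small_spec)
        truth_t = make_rigid(3.0, -2.0, 4.0, center=center)
        primary, secondary, _ = generate_phantom_pair(small_spec.with_transform(truth_t))
        result = register_baseline(primary, secondary, FULL_BASELINE)
        err = decompose_difference(result.transform, truth_t, center=center)
        half_voxel = np.asarray(small_spec.spacing) / 2.0
        assert abs(err.dt_lr) <= half_voxel[0]
        assert abs(err.dt_ap) <= half_voxel[1]
        assert abs(err.dt_cc) <= half_voxel[2]

    def test_axial_rotation_recovered(self, small_spec):
        center = volume_center(small_spec)
        truth_t = make_rigid(rz=2.0, center=center)
        primary, secondary, _ = generate_phantom_pair(small_spec.with_transform(truth_t))
        result = register_baseline(primary, secondary, FULL_BASELINE)
        _, mr = max_errors(result.transform, truth_t, center)
        assert mr <= 0.5

    def test_translation_equivariance(self, small_spec):
        """An extra known shift in the truth moves the recovery by that shift."""
        center = volume_center(small_spec)
        t_a = make_rigid(2.0, 1.0, -1.0, center=center)
        extra = np.array([0.0, 0.0, 2.0])
        t_b = make_rigid(2.0, 1.0, 1.0, center=center)
        rec = []
        for truth_t in (t_a, t_b):
            p, s, _ = generate_phantom_pair(small_spec.with_transform(truth_t))
            rec.append(register_baseline(p, s, FULL_BASELINE).transform.translation)
        assert np.allclose(rec[1] - rec[0], extra, atol=0.3)

    def test_metric_value_in_unit_interval(self, misaligned_pair):
        primary, secondary, _, _ = misaligned_pair
        result = register_baseline(primary, secondary)
        assert 0.0 <= result.metric_value <= 1.0
        assert result.n_evaluations > 0
        assert result.pyramid_trace


class TestContourFocused:
    def _mask(self, primary, truth):
        m = truth.structure_masks["bone"] | truth.structure_masks["hardware"]
        return ContourMask(m, (0.0, primary.shape[2] * primary.spacing[2]), int(m.sum()))

    def test_fixed_point_at_optimum(self, noisefree_pair):
        """Starting at the noise-free optimum, the result stays there."""
        primary, secondary, truth = noisefree_pair  # identity truth
        mask = self._mask(primary, truth)
        init = make_rigid(center=mask.centroid_mm(primary))
        result = register_contour_focused(primary, secondary, mask, init)
        assert np.all(np.abs(result.transform.translation) <= 0.2)
        assert np.all(np.abs(result.transform.angles_deg) <= 0.2)
        init_nmi = nmi(joint_histogram(primary, secondary, init, mask))
        assert result.metric_value >= init_nmi - 1e-9

    def test_never_returns_below_init(self, misaligned_pair):
        primary, secondary, truth, truth_t = misaligned_pair
        mask = self._mask(primary, truth)
        init = make_rigid(
            truth_t.tx + 1.5, truth_t.ty - 1.0, truth_t.tz + 1.0,
            truth_t.rx, truth_t.ry, truth_t.rz, truth_t.center,
        )
        result = register_contour_focused(primary, secondary, mask, init)
        init_nmi = nmi(joint_histogram(primary, secondary, init, mask))
        assert result.metric_value >= init_nmi - 1e-9

    def test_empty_mask_rejected(self, noisefree_pair):
        primary, secondary, _ = noisefree_pair
        empty = ContourMask(np.zeros(primary.shape, dtype=bool), (0.0, 1.0), 0)
        with pytest.raises(InvalidParameterError):
            register_contour_focused(primary, secondary, empty, make_rigid())

    def test_distractor_outside_mask_does_not_bias_contour(self, small_spec):
        """Anatomy change away from the spine misleads the whole-image metric
        but not the contour-restricted one."""
        center = volume_center(small_spec)
        truth_t = make_rigid(2.0, -1.5, 2.5, center=center)
        primary, secondary, truth = generate_phantom_pair(
            small_spec.with_transform(truth_t)
        )
        # paint a bright soft-tissue blob at different anterior positions
        nx, ny, nz = primary.shape
        sx, sy, sz = primary.spacing
        x = np.arange(nx)[:, None, None] * sx
        y = np.arange(ny)[None, :, None] * sy
        z = np.arange(nz)[None, None, :] * sz
        cx = (nx - 1) * sx / 2
        zc = (nz - 1) * sz / 2
        blob_p = (x - cx) ** 2 + (y - 16.0) ** 2 + (z - zc) ** 2 <= 12.0**2
        blob_s = (x - (cx + 10.0)) ** 2 + (y - 16.0) ** 2 + (z - (zc - 12.0)) ** 2 <= 12.0**2
        primary.voxels[blob_p] = 400.0
        secondary.voxels[blob_s] = 400.0

        ann = LesionAnnotation(
            tuple(small_spec.lesion_levels), tuple(truth.level_boundaries)
        )
        result, _ = run_arir_workflow(primary, secondary, ann)
        mt, mr = max_errors(result.transform, truth_t, center)
        assert mt <= 1.0 and mr <= 1.0
        baseline_mt, _ = max_errors(result.baseline_transform, truth_t, center)
        assert mt <= baseline_mt + 1e-9


class TestWorkflow:
    def test_recovers_truth_with_noise(self, small_spec):
        center = volume_center(small_spec)
        truth_t = make_rigid(3.0, -2.0, 4.0, 1.0, -0.5, 1.5, center)
        primary, secondary, truth = generate_phantom_pair(
            small_spec.with_transform(truth_t)
        )
        ann = LesionAnnotation(
            tuple(small_spec.lesion_levels), tuple(truth.level_boundaries)
        )
        result, mask = run_arir_workflow(primary, secondary, ann)
        mt, mr = max_errors(result.transform, truth_t, center)
        assert mt <= 1.0 and mr <= 1.0
        assert mask.voxel_count > 0

    def test_workflow_deterministic(self, misaligned_pair, small_spec_noisefree):
        primary, secondary, truth, _ = misaligned_pair
        ann = LesionAnnotation(
            tuple(small_spec_noisefree.lesion_levels), tuple(truth.level_boundaries)
        )
        r1, _ = run_arir_workflow(primary, secondary, ann)
        r2, _ = run_arir_workflow(primary, secondary, ann)
        t1, t2 = r1.transform, r2.transform
        assert (t1.tx, t1.ty, t1.tz, t1.rx, t1.ry, t1.rz) == (
            t2.tx, t2.ty, t2.tz, t2.rx, t2.ry, t2.rz
        )
        assert r1.metric_value == r2.metric_value
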