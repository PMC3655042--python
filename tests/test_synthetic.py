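"""Synthetic study generator: analytic truth, noise model, voxel phantom."""

import math

import numpy as np
import pytest

from petdosim import (
    F18,
    OrganKineticsSpec,
    StudyDesign,
    decay_factor,
    make_sphere_mask,
    organ_tac_from_voi,
    render_dynamic_phantom,
    sample_td_study,
    true_fia,
    true_residence_time,
)
from petdosim.petquant import FrameSchedule
from petdosim.synthetic import design_residence_time

SHORT_SCHEDULE = FrameSchedule.from_spec([(3, 600.0), (3, 1200.0)])


def _spec(**kw):
    return OrganKineticsSpec(**kw)


def test_true_fia_zero_amplitudes():
    spec = _spec(kinetics={"liver": ((0.0,), (1.0,))})
    assert true_fia(spec, "liver", 0.7) == 0.0


def test_true_fia_trapped_component_decays_physically():
    spec = _spec(kinetics={"liver": ((0.3,), (0.0,))})
    assert true_fia(spec, "liver", 2.0) == pytest.approx(
        0.3 * decay_factor(F18, 2.0), rel=1e-12
    )


def test_true_fia_closed_form():
    k = math.log(2) / 3.0
    spec = _spec(kinetics={"liver": ((0.3,), (k,))})
    assert true_fia(spec, "liver", 3.0) == pytest.approx(
        0.15 * decay_factor(F18, 3.0), rel=1e-12
    )


def test_activity_conservation_of_default_kinetics():
    # organs plus urinary excretion never exceed the injected activity
    spec = _spec()
    t = np.linspace(0.0, 10.0, 500)
    organs = sum(
        np.array([true_fia(spec, o, ti) for ti in t]) for o in spec.kinetics
    )
    lam_b = math.log(2) / spec.urinary_half_life_h
    urine = (
        spec.urinary_fraction
        * (1.0 - np.exp(-lam_b * t))
        * decay_factor(F18, t)
    )
    assert np.all(organs + urine <= decay_factor(F18, t) + 1e-12)


def test_true_residence_trapped_convention_bounds_full_clearance():
    spec = _spec()
    for organ in ("liver", "kidneys"):
        trapped = true_residence_time(spec, organ, trapped_after_h=2.0)
        cleared = true_residence_time(spec, organ, trapped_after_h=None)
        assert trapped >= cleared  # freezing clearance can only add activity


def test_noiseless_study_measurements_equal_truth():
    spec = _spec()
    design = StudyDesign(measurement_cv=0.0, mass_cv=0.0, seed=5)
    table = sample_td_study(spec, design)
    row = table.records[
        (table.records.organ == "liver") & (table.records.time_post_injection_min == 30.0)
    ].iloc[0]
    delay_decay = decay_factor(F18, design.counting_delay_min / 60.0)
    want = true_fia(spec, "liver", 0.5) * design.injected_activity_bq * delay_decay
    assert row["measured_activity_bq"] == pytest.approx(want, rel=1e-12)
    assert row["sample_mass_g"] == pytest.approx(spec.organ_mass_g("liver"), rel=1e-12)


def test_same_seed_reproduces_identical_tables():
    spec = _spec()
    a = sample_td_study(spec, StudyDesign(seed=11))
    b = sample_td_study(spec, StudyDesign(seed=11))
    assert a.records.equals(b.records)
    c = sample_td_study(spec, StudyDesign(seed=12))
    assert not a.records.equals(c.records)


def test_study_shape_matches_design():
    spec = _spec()
    design = StudyDesign(animals_per_point=4)
    table = sample_td_study(spec, design)
    assert len(table.records) == 6 * 4 * len(spec.kinetics)
    assert table.records["animal_id"].nunique() == 24


def test_design_oracle_matches_analytic_for_dense_sampling():
    # with dense sampling the piecewise-linear design tau converges on the
    # analytic trapped-tail tau
    spec = _spec()
    dense = np.linspace(1.0 / 60.0, 2.0, 400)
    got = design_residence_time(spec, "liver", dense)
    want = true_residence_time(spec, "liver", trapped_after_h=2.0)
    assert got == pytest.approx(want, rel=5e-4)


def test_phantom_whole_organ_means_recover_truth_without_blur():
    spec = _spec()
    series, masks, truth = render_dynamic_phantom(
        spec, schedule=SHORT_SCHEDULE, psf_fwhm_mm=0.0
    )
    for organ, voi in masks.items():
        samples = organ_tac_from_voi(
            series, voi, 9.19e6, F18, organ_volume_ml=truth["volumes_ml"][organ]
        )
        got = np.array([v for _, v in samples])
        np.testing.assert_allclose(got, truth["fia"][organ], rtol=3e-2)


def test_phantom_conserves_activity_per_frame():
    spec = _spec()
    series, masks, truth = render_dynamic_phantom(
        spec, schedule=SHORT_SCHEDULE, psf_fwhm_mm=0.0
    )
    lam = F18.decay_constant
    start_h = series.schedule.start_s / 3600.0
    dt_h = series.schedule.duration_s / 3600.0
    in_frame = -np.expm1(-lam * dt_h) / (lam * dt_h)
    for j in (0, series.schedule.n_frames - 1):
        physical = (
            series.voxels[..., j].sum()
            * series.voxel_volume_ml
            * decay_factor(F18, start_h[j])
            * in_frame[j]
        )
        want = sum(truth["fia"][o][j] for o in masks) * 9.19e6
        assert physical == pytest.approx(want, rel=1e-3)


def test_blur_conserves_total_activity_within_one_percent():
    spec = _spec()
    sharp, _, _ = render_dynamic_phantom(spec, schedule=SHORT_SCHEDULE, psf_fwhm_mm=0.0)
    blurred, _, _ = render_dynamic_phantom(spec, schedule=SHORT_SCHEDULE, psf_fwhm_mm=1.5)
    ratio = blurred.voxels[..., 0].sum() / sharp.voxels[..., 0].sum()
    assert ratio == pytest.approx(1.0, abs=0.01)


def test_blur_produces_partial_volume_loss_and_spillover():
    spec = _spec()
    frame = 3
    sharp, masks, truth = render_dynamic_phantom(
        spec, schedule=SHORT_SCHEDULE, psf_fwhm_mm=0.0
    )
    sphere = make_sphere_mask(
        (16.0, 16.0, 4.0), 2.0, sharp.voxels.shape[:3], sharp.voxel_size_mm, "testes"
    )
    from scipy import ndimage

    organ_union = np.zeros(sharp.voxels.shape[:3], dtype=bool)
    for voi in masks.values():
        organ_union |= voi.mask
    shell = ndimage.binary_dilation(masks["liver"].mask, iterations=3) & ~organ_union

    hot_prev, cold_prev = None, None
    for fwhm in (0.5, 1.5, 2.5):
        blurred, _, t = render_dynamic_phantom(
            spec, schedule=SHORT_SCHEDULE, psf_fwhm_mm=fwhm
        )
        hot = organ_tac_from_voi(
            blurred, sphere, 9.19e6, F18, organ_volume_ml=t["volumes_ml"]["testes"]
        )[frame][1]
        cold = float(blurred.voxels[shell, frame].mean())
        assert hot < truth["fia"]["testes"][frame]  # partial-volume underestimation
        assert cold > 0.0  # spill-over into surrounding tissue
        if hot_prev is not None:
            assert hot < hot_prev  # monotone loss with resolution degradation
            assert cold > cold_prev  # monotone spill-over growth
        hot_prev, cold_prev = hot, cold


def test_overlapping_or_out_of_grid_organs_rejected():
    spec = _spec()
    with pytest.raises(ValueError, match="outside"):
        render_dynamic_phantom(
            spec,
            geometry={"liver": ((2.0, 2.0, 2.0), (8.0, 8.0, 8.0))},
            schedule=SHORT_SCHEDULE,
        )
    with pytest.raises(ValueError, match="overlap"):
        render_dynamic_phantom(
            spec,
            geometry={
                "liver": ((16.0, 16.0, 14.0), (8.0, 8.0, 6.0)),
                "heart": ((16.0, 16.0, 16.0), (3.0, 3.0, 3.0)),
            },
            schedule=SHORT_SCHEDULE,
        )


def test_amplitude_overflow_rejected():
    with pytest.raises(ValueError, match="> 1"):
        _spec(kinetics={"liver": ((0.9,), (1.0,)), "kidneys": ((0.2,), (1.0,))})
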