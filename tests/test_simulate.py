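"""Synthetic-CBCT simulator: deformation, projection, sinogram mixing,
reconstruction, isocentre sampling and field-of-view truncation."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from cbctrepair.phantom import PhantomSpec, body_mask, make_thorax_phantom
from cbctrepair.simulate import (
    IsocentrePoint,
    SimParams,
    apply_fov_mask,
    back_project,
    elastic_deform,
    forward_project,
    mix_sinograms,
    sample_isocentre,
    simulate_scbct_slice,
)


# -- elastic deformation ----------------------------------------------------

def test_zero_displacement_is_identity(desk_phantom, desk_sim_params):
    p = SimParams(deform_max_disp=0.0, deform_grid_spacing=16)
    np.testing.assert_array_equal(elastic_deform(desk_phantom, p, seed=3), desk_phantom)


def test_constant_image_survives_warping():
    const = np.full((64, 64), 123.0, np.float32)
    p = SimParams(deform_grid_spacing=16, deform_max_disp=5.0)
    np.testing.assert_allclose(elastic_deform(const, p, seed=3), const, atol=1e-4)


def test_deformation_moves_body_edge_but_stays_bounded(desk_phantom, desk_sim_params):
    warped = elastic_deform(desk_phantom, desk_sim_params, seed=3)
    m0, m1 = body_mask(desk_phantom), body_mask(warped)
    edge1 = m1 ^ (distance_transform_edt(m1) > 1)
    # distance from each warped-edge pixel to the original boundary
    dist_to_orig_edge = distance_transform_edt(~(m0 ^ (distance_transform_edt(m0) > 1)))
    d = dist_to_orig_edge[edge1]
    assert d.mean() > 0
    assert d.max() <= desk_sim_params.deform_max_disp + 1.5  # +interpolation slack


def test_deform_grid_spacing_validation(desk_phantom):
    with pytest.raises(ValueError, match="grid_spacing"):
        elastic_deform(desk_phantom, SimParams(deform_grid_spacing=128), seed=0)


def test_deform_determinism(desk_phantom, desk_sim_params):
    a = elastic_deform(desk_phantom, desk_sim_params, seed=9)
    b = elastic_deform(desk_phantom, desk_sim_params, seed=9)
    np.testing.assert_array_equal(a, b)


# -- forward projection -----------------------------------------------------

def test_air_with_matching_offset_projects_to_zero():
    air = np.full((64, 64), -1000.0, np.float32)
    s = forward_project(air, SimParams(n_angles=45, attenuation_offset=1000.0))
    assert np.abs(s.values).max() == 0.0


def test_centered_disc_mass_conserved_across_angles():
    rr, cc = np.ogrid[:64, :64]
    disc = np.where((rr - 31.5) ** 2 + (cc - 31.5) ** 2 <= 400, 0.0, -1024.0)
    s = forward_project(disc.astype(np.float32), SimParams(n_angles=90))
    sums = s.values.sum(axis=1)
    assert (sums.max() - sums.min()) / sums.mean() < 0.01


def test_central_hot_pixel_peaks_at_central_bin():
    img = np.zeros((65, 65), np.float32)
    img[32, 32] = 3000.0
    s = forward_project(img, SimParams(n_angles=90, attenuation_offset=0.0))
    center_bin = s.values.shape[1] // 2
    assert np.all(np.argmax(s.values, axis=1) == center_bin)


# -- sinogram mixing --------------------------------------------------------

def test_mixing_with_zero_budget_is_identity(desk_phantom):
    p = SimParams(n_angles=45, max_replace_fraction=0.0)
    s = forward_project(desk_phantom, p)
    s2 = forward_project(elastic_deform(desk_phantom, SimParams(deform_grid_spacing=16), 1), p)
    out, frac = mix_sinograms(s, s2, p, seed=11)
    assert frac == 0.0
    np.testing.assert_array_equal(out.values, s.values)


def test_mixing_with_itself_changes_nothing(desk_phantom):
    p = SimParams(n_angles=45)
    s = forward_project(desk_phantom, p)
    out, _ = mix_sinograms(s, s, p, seed=11)
    np.testing.assert_array_equal(out.values, s.values)


def test_realised_fraction_bounded_and_deterministic(desk_phantom):
    p = SimParams(n_angles=45)
    s = forward_project(desk_phantom, p)
    s2 = forward_project(elastic_deform(desk_phantom, SimParams(deform_grid_spacing=16), 2), p)
    out, frac = mix_sinograms(s, s2, p, seed=11)
    differing = np.count_nonzero(out.values != s.values)
    assert differing / s.values.size <= 0.10
    assert frac <= 0.10
    out_b, frac_b = mix_sinograms(s, s2, p, seed=11)
    assert frac_b == frac
    np.testing.assert_array_equal(out_b.values, out.values)


def test_mixing_shape_mismatch_rejected(desk_phantom):
    pa, pb = SimParams(n_angles=45), SimParams(n_angles=60)
    with pytest.raises(ValueError, match="shape"):
        mix_sinograms(
            forward_project(desk_phantom, pa), forward_project(desk_phantom, pb), pa, 0
        )


def test_replacement_fraction_distribution(desk_phantom):
    """Uniform(0, 0.10) draw: all fractions bounded, mean near 0.05."""
    p = SimParams(n_angles=45)
    s = forward_project(desk_phantom, p)
    s2 = forward_project(elastic_deform(desk_phantom, SimParams(deform_grid_spacing=16), 3), p)
    fracs = [mix_sinograms(s, s2, p, seed=k)[1] for k in range(100)]
    assert max(fracs) <= 0.10
    assert 0.04 <= np.mean(fracs) <= 0.06  # 0.05 +- 20%


# -- reconstruction ---------------------------------------------------------

def test_fbp_roundtrip_error_small(desk_phantom, desk_sim_params):
    rec = back_project(forward_project(desk_phantom, desk_sim_params), 128, desk_sim_params)
    interior = slice(10, 118)
    mae = np.abs(rec[interior, interior] - desk_phantom[interior, interior]).mean()
    assert mae < 60.0  # fixture-calibrated FBP tolerance


def test_zero_sinogram_reconstructs_to_clamped_floor():
    from cbctrepair.simulate import Sinogram

    p = SimParams(n_angles=45)
    s = Sinogram(np.zeros((45, 92)), p.angles)
    rec = back_project(s, 64, p)
    assert np.all(rec == -1024.0)


def test_mixed_sinogram_reconstruction_contains_streaks(desk_phantom, desk_sim_params):
    s = forward_project(desk_phantom, desk_sim_params)
    s2 = forward_project(elastic_deform(desk_phantom, desk_sim_params, 4), desk_sim_params)
    mixed, frac = mix_sinograms(s, s2, desk_sim_params, seed=7)
    assert frac > 0
    clean = back_project(s, 128, desk_sim_params)
    streaked = back_project(mixed, 128, desk_sim_params)
    assert np.abs(streaked - clean).mean() > 0


def test_streak_severity_monotone_in_replacement_fraction(desk_phantom, desk_sim_params):
    maes = []
    for f in (0.0, 0.02, 0.05, 0.10):
        pair = simulate_scbct_slice(desk_phantom, desk_sim_params, seed=9, force_fraction=f)
        inside = pair.streak_gt != 0
        maes.append(np.abs(pair.scbct - pair.streak_gt)[inside].mean())
    assert all(b >= a for a, b in zip(maes, maes[1:]))


# -- isocentre and field of view -------------------------------------------

def test_small_body_cannot_be_truncated():
    mask = np.zeros((64, 64), bool)
    rr, cc = np.ogrid[:64, :64]
    mask[(rr - 32) ** 2 + (cc - 32) ** 2 <= 25] = True
    with pytest.raises(RuntimeError, match="cannot truncate"):
        sample_isocentre(mask, SimParams(fov_radius=128), seed=5)


def test_sampled_isocentre_leaves_body_partially_outside(desk_phantom, desk_sim_params):
    mask = body_mask(desk_phantom)
    iso = sample_isocentre(mask, desk_sim_params, seed=5)
    rows, cols = np.nonzero(mask)
    outside = ((rows - iso.row) ** 2 + (cols - iso.col) ** 2) > desk_sim_params.fov_radius**2
    assert outside.sum() >= desk_sim_params.min_outside_fraction * rows.size
    assert mask[int(iso.row), int(iso.col)]
    again = sample_isocentre(mask, desk_sim_params, seed=5)
    assert (again.row, again.col) == (iso.row, iso.col)


def test_fov_mask_noop_when_disc_covers_image():
    img = np.full((64, 64), 7.0, np.float32)
    out = apply_fov_mask(img, IsocentrePoint(32, 32), SimParams(fov_radius=64))
    np.testing.assert_array_equal(out, img)


def test_fov_mask_count_matches_exhaustive_distance_check():
    img = np.ones((512, 512), np.float32)
    p = SimParams(fov_radius=128)
    out = apply_fov_mask(img, IsocentrePoint(256, 256), p)
    rr, cc = np.ogrid[:512, :512]
    expected = np.count_nonzero((rr - 256) ** 2 + (cc - 256) ** 2 <= 128**2)
    assert np.count_nonzero(out) == expected
    # no surviving pixel farther than the radius
    rows, cols = np.nonzero(out)
    assert ((rows - 256) ** 2 + (cols - 256) ** 2).max() <= 128**2


# -- full chain -------------------------------------------------------------

def test_simulation_is_deterministic(desk_phantom, desk_sim_params):
    a = simulate_scbct_slice(desk_phantom, desk_sim_params, seed=21)
    b = simulate_scbct_slice(desk_phantom, desk_sim_params, seed=21)
    np.testing.assert_array_equal(a.scbct, b.scbct)
    np.testing.assert_array_equal(a.streak_gt, b.streak_gt)
    assert a.isocentre == b.isocentre and a.replaced_fraction == b.replaced_fraction


def test_pair_geometry_and_streak_content(desk_phantom, desk_sim_params):
    pair = simulate_scbct_slice(desk_phantom, desk_sim_params, seed=21)
    rr, cc = np.ogrid[:128, :128]
    outside = ((rr - pair.isocentre.row) ** 2 + (cc - pair.isocentre.col) ** 2) > \
        desk_sim_params.fov_radius**2
    assert np.all(pair.scbct[outside] == 0)
    assert np.all(pair.streak_gt[outside] == 0)
    inside = ~outside
    assert np.abs(pair.scbct - pair.streak_gt)[inside].mean() > 0
    np.testing.assert_array_equal(pair.streak_gt[inside], pair.full_gt[inside])
    assert pair.replaced_fraction <= desk_sim_params.max_replace_fraction


def test_roundtrip_with_no_corruption_matches_masked_ct(desk_phantom):
    p = SimParams(fov_radius=32.0, n_angles=90, deform_grid_spacing=16, deform_max_disp=0.0)
    pair = simulate_scbct_slice(desk_phantom, p, seed=2, force_fraction=0.0)
    inside = pair.streak_gt != 0
    assert np.abs(pair.scbct - pair.streak_gt)[inside].mean() < 60.0
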