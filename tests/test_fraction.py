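"""Integrated-fluorescence measurement: segmentation, spots, fractions."""

import numpy as np
import pytest

from cenquant import fraction
from cenquant.stack import ImageStack
from cenquant.synthetic import (CellSimSpec, make_bead_stack, make_cell_stack,
                                _render_point_source)
from cenquant.pipeline import analyze_cell_stack


# -- flatfield --------------------------------------------------------------

def make_stack(arr):
    return ImageStack(voxels=arr[None], channels=["fluor"])


def test_flatfield_uniform_reference_is_identity():
    rng = np.random.default_rng(0)
    stack = make_stack(rng.uniform(10, 20, size=(3, 8, 8)))
    out = fraction.flatfield_correct(stack, np.full((8, 8), 7.0))
    assert np.allclose(out.voxels, stack.voxels)


def test_flatfield_halves_doubled_side():
    img = np.full((1, 4, 8), 100.0)
    ref = np.ones((4, 8))
    ref[:, :4] = 2.0
    out = fraction.flatfield_correct(make_stack(img), ref)
    left, right = out.voxels[0, 0, :, :4], out.voxels[0, 0, :, 4:]
    assert np.allclose(left.mean() / right.mean(), 0.5)


def test_flatfield_round_trip_removes_vignetting():
    rng = np.random.default_rng(1)
    true = rng.uniform(50, 60, size=(4, 32, 32))
    yy, xx = np.mgrid[:32, :32]
    vignette = 1 - 0.4 * (((yy - 16) / 16) ** 2 + ((xx - 16) / 16) ** 2) / 2
    seen = true * (vignette / vignette.mean())[None]
    out = fraction.flatfield_correct(make_stack(seen), vignette)
    assert np.max(np.abs(out.voxels[0] / true - 1)) < 1e-3


def test_flatfield_rejects_nonpositive_reference():
    with pytest.raises(ValueError):
        fraction.flatfield_correct(make_stack(np.ones((2, 4, 4))),
                                   np.zeros((4, 4)))


# -- segmentation -----------------------------------------------------------

def test_segmentation_recovers_cell(default_cell):
    _, stack, truth = default_cell
    vols = fraction.segment_cell_volume(stack.channel("exclusion"))
    assert len(vols) == 2  # labelled cell + negative neighbour, sorted by size
    assert vols[0].voxel_count >= vols[1].voxel_count
    jaccard = max(
        (v.mask & truth.cell_mask).sum() / (v.mask | truth.cell_mask).sum()
        for v in vols
    )
    assert jaccard >= 0.95


def test_segmentation_rejects_bright_frame():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError, match="no cell"):
        fraction.segment_cell_volume(rng.normal(600, 5, size=(8, 32, 32)))


def test_nuclear_marker_segmentation(default_cell):
    _, stack, truth = default_cell
    vols = fraction.segment_cell_volume(stack.channel("nuclear"), mode="marker")
    jaccard = ((vols[0].mask & truth.nucleus_mask).sum()
               / (vols[0].mask | truth.nucleus_mask).sum())
    assert jaccard >= 0.95


# -- totals -----------------------------------------------------------------

def test_total_fluorescence_removes_uniform_background():
    arr = np.full((2, 20, 20), 5.0)
    mask = np.zeros_like(arr, dtype=bool)
    mask[:, 5:10, 5:10] = True
    arr[mask] += 3.0
    vol = fraction.CellVolume(mask=mask)
    bg = [np.s_[0:3, 0:3]]
    bg_mask = np.zeros((20, 20), dtype=bool)
    bg_mask[0:3, 0:3] = True
    total = fraction.total_fluorescence(arr, vol, [bg_mask])
    assert total == pytest.approx(3.0 * mask.sum())


def test_total_fluorescence_rejects_overlapping_background():
    arr = np.ones((1, 10, 10))
    mask = np.zeros_like(arr, dtype=bool)
    mask[:, 2:6, 2:6] = True
    bad = np.zeros((10, 10), dtype=bool)
    bad[4:8, 4:8] = True
    with pytest.raises(ValueError, match="overlap"):
        fraction.total_fluorescence(arr, fraction.CellVolume(mask=mask), [bad])


def test_empty_volume_rejected():
    with pytest.raises(ValueError):
        fraction.CellVolume(mask=np.zeros((2, 4, 4), dtype=bool))


def test_noise_free_total_conserves_deposited_photons():
    """Generator -> measurement round trip is exact without noise/background."""
    spec = CellSimSpec(noise_model="none", background_level=0.0,
                       autofluorescence_per_voxel=0.0,
                       include_negative_cell=False, seed=3)
    stack, truth = make_cell_stack(spec)
    vol = fraction.CellVolume(mask=truth.cell_mask)
    bg = fraction.auto_background_regions([truth.cell_mask], stack.shape)
    total = fraction.total_fluorescence(stack.channel("fluor"), vol, bg)
    assert total == pytest.approx(truth.total_photons, rel=1e-6)


def test_autofluorescence_correction(default_cell):
    _, stack, truth = default_cell
    fluor = stack.channel("fluor")
    pos = fraction.CellVolume(mask=truth.cell_mask)
    neg = fraction.CellVolume(mask=truth.negative_mask)
    bg = fraction.auto_background_regions(
        [truth.cell_mask, truth.negative_mask], stack.shape)
    total = fraction.total_fluorescence(fluor, pos, bg)
    corrected, correction, clipped = fraction.autofluorescence_correct(
        total, pos, fluor, [neg], bg)
    assert not clipped
    assert corrected == pytest.approx(truth.total_photons, rel=0.02)
    assert correction == pytest.approx(
        truth.autofluorescence_per_voxel * pos.voxel_count, rel=0.05)


# -- spots ------------------------------------------------------------------

def spot_image(coords, photons=10_000.0, shape=(5, 64, 64), sigma=0.8):
    arr = np.zeros(shape)
    for c in coords:
        _render_point_source(arr, c, 0.7, sigma, photons)
    return arr


def test_detects_k_separated_spots_at_true_coordinates():
    coords = [(2, 12, 12), (2, 12, 40), (2, 40, 20), (3, 44, 48), (1, 30, 34)]
    arr = spot_image(coords)
    spots = fraction.detect_centromeres(arr)
    assert len(spots) == len(coords)
    for s in spots:
        d = min(np.hypot(c[1] - s.y, c[2] - s.x) for c in coords)
        assert d <= 1.0


def test_blank_image_yields_no_spots():
    assert fraction.detect_centromeres(np.zeros((3, 32, 32))) == []


def test_elongated_object_excluded_by_shape_filters():
    arr = np.zeros((1, 40, 40))
    arr[0, 18:21, 8:32] = 100.0  # a bar: fails circularity and Feret
    bar_spots = fraction.detect_centromeres(arr)
    assert bar_spots == []


def test_measure_spot_flat_field_is_zero():
    arr = np.full((1, 21, 21), 13.0)
    spot = fraction.Spot(x=10, y=10, z=0)
    out = fraction.measure_spot(arr, spot)
    assert out.corrected_signal == pytest.approx(0.0, abs=1e-9)


def test_measure_spot_point_source_mass():
    """On zero background the disk integral matches the analytic PSF mass."""
    sigma = 0.8
    arr = np.zeros((1, 41, 41))
    _render_point_source(arr, (0, 20.0, 20.0), 0.5, sigma, 10_000.0)
    out = fraction.measure_spot(arr, fraction.Spot(x=20, y=20, z=0))
    in_disk = 1 - np.exp(-2.5 ** 2 / (2 * sigma ** 2))
    assert out.raw_integral == pytest.approx(10_000.0 * in_disk, rel=0.02)
    assert out.corrected_signal <= out.raw_integral


def test_annulus_handles_gradient_better_than_global():
    """Local annulus background tracks a gradient a global estimate misses."""
    yy = np.arange(41, dtype=float)
    gradient = np.tile(10 + 2 * yy[:, None], (1, 41))[None]
    arr = gradient.copy()
    _render_point_source(arr, (0, 10.0, 20.0), 0.5, 0.8, 10_000.0)
    out = fraction.measure_spot(arr, fraction.Spot(x=20, y=10, z=0))
    true_sig = out.raw_integral - gradient[0, 10, 20] * 21  # 21 px in the disk
    global_bg = gradient.mean() * 21
    global_est = out.raw_integral - global_bg
    assert abs(out.corrected_signal - true_sig) < abs(global_est - true_sig)


# -- oversampling -----------------------------------------------------------

def plane_profile_stack(profiles):
    """Beads as single-pixel columns with prescribed per-plane intensities."""
    n_planes = max(len(p) for p in profiles)
    arr = np.zeros((n_planes, 32, 32 * len(profiles)))
    for i, prof in enumerate(profiles):
        for z, v in enumerate(prof):
            arr[z, 16, 16 + 32 * i] = v
    return arr


def test_oversampling_hand_example():
    arr = plane_profile_stack([(0.25, 0.5, 1.0, 0.5, 0.25)])
    assert fraction.oversampling_factor(arr) == pytest.approx(2.5)


def test_oversampling_single_plane_is_one():
    arr = plane_profile_stack([(0.0, 1.0, 0.0)])
    assert fraction.oversampling_factor(arr) == pytest.approx(1.0)


def test_oversampling_averages_beads():
    arr = plane_profile_stack([(1.0, 1.0), (1.0, 1.0, 1.0)])
    assert fraction.oversampling_factor(arr) == pytest.approx(2.5)


def test_coarse_z_step_approaches_one():
    beads = make_bead_stack(psf_sigma_z=100.0, z_step=2000.0, n_beads=9, seed=0)
    assert fraction.oversampling_factor(beads) == pytest.approx(1.0, abs=0.02)


def test_bead_count_validation():
    with pytest.raises(ValueError):
        make_bead_stack(n_beads=0)


# -- the fraction -----------------------------------------------------------

def test_recovers_ground_truth_fraction(default_cell, default_beads):
    """The full measurement recovers the ~0.44% regime within +/-10%."""
    _, stack, truth = default_cell
    res = analyze_cell_stack(stack, bead_stack=default_beads)
    assert len(res.spots) == 46
    rel = res.mean_fraction / truth.fraction_per_centromere - 1
    assert abs(rel) < 0.10


def test_fraction_scale_invariance(default_cell, default_beads):
    """Scaling the whole stack by a constant leaves every fraction unchanged."""
    _, stack, truth = default_cell
    res1 = analyze_cell_stack(stack, bead_stack=default_beads)
    scaled = ImageStack(voxels=stack.voxels * 3.7, channels=list(stack.channels),
                        pixel_size_nm=stack.pixel_size_nm,
                        z_step_nm=stack.z_step_nm)
    res2 = analyze_cell_stack(scaled, bead_stack=default_beads)
    assert np.allclose(np.sort(res1.fractions), np.sort(res2.fractions),
                       rtol=1e-9)


def test_nuclear_route_recovers_nuclear_fraction(default_cell, default_beads):
    """Fractions of the nuclear pool reproduce the ~0.73% regime."""
    _, stack, truth = default_cell
    res = analyze_cell_stack(stack, volume="nucleus", bead_stack=default_beads)
    rel = res.mean_fraction / truth.nuclear_fraction_per_centromere - 1
    assert abs(rel) < 0.10


def test_degenerate_single_spot_fraction_is_one():
    """All molecules in one focus, no pool: the fraction is ~1."""
    spec = CellSimSpec(n_centromeres=1, molecules_per_centromere=10_000,
                      total_molecules=10_000, noise_model="none",
                      background_level=0.0, autofluorescence_per_voxel=0.0,
                      include_negative_cell=False, seed=4)
    stack, truth = make_cell_stack(spec)
    assert truth.fraction_per_centromere == 1.0
    vol = fraction.CellVolume(mask=truth.cell_mask)
    bg = fraction.auto_background_regions([truth.cell_mask], stack.shape)
    spots = fraction.detect_centromeres(stack.channel("fluor"))
    assert len(spots) == 1
    # z-summed measurement (factor = sum/max over the focus itself)
    fluor = stack.channel("fluor")
    zsum = np.array([fraction.measure_spot(fluor, fraction.Spot(
        x=spots[0].x, y=spots[0].y, z=z)).corrected_signal
        for z in range(stack.n_planes)])
    factor = zsum.sum() / zsum.max()
    res = fraction.centromeric_fraction(fluor, vol, spots, factor,
                                        background_regions=bg)
    assert res.fractions[0] == pytest.approx(1.0, rel=0.02)


# -- spread normalization ---------------------------------------------------

def test_spread_normalize_unit_mean():
    import pandas as pd
    table = pd.DataFrame({"cell_id": [1, 1, 1, 1], "intensity": [2.0, 2, 2, 2]})
    out = fraction.spread_normalize(table)
    assert np.allclose(out["normalized"], 1.0)
    with pytest.raises(ValueError):
        fraction.spread_normalize(table.iloc[0:0])


def test_marked_centromere_deficit():
    """A marked centromere at 75% of the cell mean shows a ~25% deficit."""
    import pandas as pd
    rng = np.random.default_rng(5)
    rows = []
    for cell in range(30):
        scale = rng.uniform(0.5, 2.0)  # per-cell staining efficiency
        for i in range(46):
            marked = i == 0
            base = 0.75 if marked else 1.02
            rows.append({"cell_id": cell, "marked": marked,
                         "intensity": scale * base * rng.normal(1, 0.05)})
    res = fraction.marked_vs_rest(pd.DataFrame(rows))
    assert res["relative_difference"] == pytest.approx(-0.26, abs=0.04)
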