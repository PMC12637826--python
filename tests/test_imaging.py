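"""Imaging operations against closed-form and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu as skimage_otsu

from vtwin.imaging import (
    AHAMap,
    ImageVolume,
    TissueLabelVolume,
    classify_tissue,
    otsu_threshold,
    partition_aha,
    read_nifti,
    resample_isotropic,
    segment_proportions,
    write_nifti,
)
from vtwin.labels import BACKGROUND, FIBROSIS, NORMAL, SCAR


# ---------------------------------------------------------------- resample

def test_resample_identity_preserves_values():
    rng = np.random.default_rng(0)
    vol = ImageVolume(values=rng.random((1, 20, 20)), spacing_mm=(0.35, 0.35, 0.35))
    out = resample_isotropic(vol, 0.35)
    assert out.spacing_mm == (0.35, 0.35, 0.35)
    np.testing.assert_allclose(out.values, vol.values, atol=1e-12)


def test_resample_constant_stays_constant():
    vol = ImageVolume(values=np.full((1, 15, 31), 7.0), spacing_mm=(1.0, 0.5, 0.5))
    out = resample_isotropic(vol, 0.2)
    np.testing.assert_allclose(out.values, 7.0)


def test_resample_linear_ramp_matches_closed_form():
    """2x upsampling of a linear ramp: trilinear interpolation is exact."""
    nx = 11
    ramp = np.tile(np.arange(nx, dtype=float) * 2.0, (1, 5, 1))
    vol = ImageVolume(values=ramp, spacing_mm=(1.0, 1.0, 1.0))
    out = resample_isotropic(vol, 0.5)
    # new voxel centers sit at x = 0.5*k mm; ramp value = 2*x
    expect = 2.0 * (0.5 * np.arange(out.values.shape[2]))
    np.testing.assert_allclose(out.values[0, 0], expect, atol=1e-9)
    # physical extent preserved within one voxel
    old_span = (nx - 1) * 1.0
    new_span = (out.values.shape[2] - 1) * 0.5
    assert abs(old_span - new_span) <= 0.5


def test_resample_rejects_nonpositive_target():
    vol = ImageVolume(values=np.zeros((1, 5, 5)), spacing_mm=(1, 1, 1))
    with pytest.raises(ValueError, match="target"):
        resample_isotropic(vol, 0.0)


# -------------------------------------------------------------------- otsu

def _otsu_brute_force(values, bins=256):
    """Exhaustive between-class variance scan over all bin boundaries."""
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    var = np.full(bins - 1, -1.0)
    for k in range(bins - 1):
        w0 = p[: k + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (p[k + 1:] * centers[k + 1:]).sum() / w1
        var[k] = w0 * w1 * (mu0 - mu1) ** 2
    # lowest threshold among (numerically) tied maximizers
    k = int(np.flatnonzero(var >= var.max() * (1.0 - 1e-12))[0])
    return edges[k + 1]


def test_otsu_separates_two_point_masses():
    t = otsu_threshold([0, 0, 0, 10, 10, 10])
    assert 0 < t < 10


def test_otsu_matches_brute_force_on_bimodal_mixture():
    rng = np.random.default_rng(42)
    v = np.concatenate([rng.normal(10, 2, 4000), rng.normal(30, 3, 2000)])
    assert otsu_threshold(v) == pytest.approx(_otsu_brute_force(v), abs=1e-9)


def test_otsu_close_to_skimage_reference():
    rng = np.random.default_rng(3)
    v = np.concatenate([rng.normal(0, 1, 3000), rng.normal(8, 1, 3000)])
    ours = otsu_threshold(v)
    theirs = skimage_otsu(v, nbins=256)
    bin_width = np.ptp(v) / 256
    assert abs(ours - theirs) <= 1.5 * bin_width  # edge vs center convention


@settings(max_examples=20, derandomize=True, deadline=None)
@given(shift=st.floats(-50, 50))
def test_otsu_translation_equivariance(shift):
    rng = np.random.default_rng(7)
    v = np.concatenate([rng.normal(5, 1, 500), rng.normal(20, 2, 500)])
    assert otsu_threshold(v + shift) == pytest.approx(otsu_threshold(v) + shift,
                                                      abs=1e-8)


def test_otsu_degenerate_input_raises():
    with pytest.raises(ValueError, match="degenerate"):
        otsu_threshold([5.0, 5.0, 5.0])


# ---------------------------------------------------------------- classify

def _boundary_fixture():
    """Volume whose class-boundary voxels sit exactly at mu+2sd / mu+4sd
    of the Otsu-low reference region (fixed-point construction)."""
    lows = np.array([90.0] * 120 + [110.0] * 120)
    highs = np.full(60, 260.0)
    p2, p4 = 120.0, 140.0
    for _ in range(60):
        vals = np.concatenate([lows, [p2, p4 - 1e-6, p4], highs])
        thr = otsu_threshold(vals)
        low = vals[vals < thr]
        mu, sd = low.mean(), low.std()
        p2, p4 = mu + 2 * sd, mu + 4 * sd
    vals = np.concatenate([lows, [p2, p4 - 1e-6, p4], highs])
    return vals, p2, p4


def test_classify_inclusive_sd_thresholds():
    """A voxel at exactly mu+4sd is scar, at exactly mu+2sd fibrosis."""
    vals, p2, p4 = _boundary_fixture()
    vol = ImageVolume(values=vals.reshape(1, 1, -1), spacing_mm=(1, 1, 1))
    out = classify_tissue(vol).labels.ravel()
    idx2, idx4m, idx4 = len(vals) - 63, len(vals) - 62, len(vals) - 61
    assert vals[idx2] == pytest.approx(p2)
    assert out[idx2] == FIBROSIS       # >= 2 SD inclusive
    assert out[idx4m] == FIBROSIS      # just below 4 SD stays fibrosis
    assert out[idx4] == SCAR           # >= 4 SD inclusive


def test_classify_reference_mean_voxel_is_normal():
    vals, _, _ = _boundary_fixture()
    vol = ImageVolume(values=vals.reshape(1, 1, -1), spacing_mm=(1, 1, 1))
    out = classify_tissue(vol).labels.ravel()
    assert out[0] == NORMAL and out[120] == NORMAL


def test_classify_outside_mask_is_background():
    vals, _, _ = _boundary_fixture()
    vol = ImageVolume(values=vals.reshape(1, 1, -1), spacing_mm=(1, 1, 1))
    mask = np.ones(vol.values.shape, dtype=bool)
    mask[0, 0, :10] = False
    out = classify_tissue(vol, mask).labels
    assert np.all(out[0, 0, :10] == BACKGROUND)


def test_classify_degenerate_distribution_all_normal(caplog):
    vol = ImageVolume(values=np.full((1, 4, 4), 3.0), spacing_mm=(1, 1, 1))
    with caplog.at_level("WARNING"):
        out = classify_tissue(vol)
    assert np.all(out.labels == NORMAL)


def test_classify_monotone_in_intensity():
    """Raising a voxel's intensity never demotes its tissue class."""
    vals, _, _ = _boundary_fixture()
    vol = ImageVolume(values=vals.reshape(1, 1, -1), spacing_mm=(1, 1, 1))
    base = classify_tissue(vol).labels.ravel()
    order = {NORMAL: 0, FIBROSIS: 1, SCAR: 2}
    bumped_vals = vals.copy()
    probe = 60  # a low-region voxel
    for bump in (10.0, 35.0, 60.0, 120.0):
        bumped_vals[probe] = vals[probe] + bump
        vol2 = ImageVolume(values=bumped_vals.reshape(1, 1, -1), spacing_mm=(1, 1, 1))
        lab = classify_tissue(vol2).labels.ravel()[probe]
        assert order[lab] >= order[base[probe]]


def test_classify_recovers_generator_truth(patient1):
    seg = classify_tissue(patient1.intensity)
    truth = patient1.truth_labels.labels
    for k in (NORMAL, FIBROSIS, SCAR):
        m = truth == k
        assert (seg.labels[m] == k).mean() >= 0.99


# --------------------------------------------------------------- partition

def test_partition_equal_on_divisible_grid():
    mask = np.ones((90, 90), dtype=bool)
    aha = partition_aha((90, 90), mask)
    assert np.all(aha.volumes == 900)
    assert aha.volumes.sum() == mask.sum()


def test_partition_matches_per_node_rule():
    rng = np.random.default_rng(5)
    mask = rng.random((40, 52)) > 0.3
    aha = partition_aha((40, 52), mask)
    ny, nx = mask.shape
    for iy, ix in [(0, 0), (13, 17), (39, 51), (20, 26), (7, 44)]:
        if mask[iy, ix]:
            expect = min(iy * 3 // ny, 2) * 3 + min(ix * 3 // nx, 2)
            assert aha.segment[iy, ix] == expect
        else:
            assert aha.segment[iy, ix] == -1
    assert aha.volumes.sum() == mask.sum()


def test_partition_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        partition_aha((4, 4), np.zeros((4, 4), dtype=bool))


# ------------------------------------------------------------- proportions

def test_segment_proportions_trivial_cases():
    mask = np.ones((30, 30), dtype=bool)
    aha = partition_aha((30, 30), mask)
    lab = np.full((30, 30), NORMAL, dtype=np.uint8)
    np.testing.assert_allclose(segment_proportions(lab, aha), 0.0)
    lab[aha.segment == 4] = SCAR
    props = segment_proportions(lab, aha)
    assert props[4] == 1.0
    assert np.allclose(np.delete(props, 4), 0.0)


def test_segment_proportions_uniform_fraction():
    mask = np.ones((30, 30), dtype=bool)
    aha = partition_aha((30, 30), mask)
    lab = np.full((30, 30), NORMAL, dtype=np.uint8)
    lab[::5, :] = FIBROSIS  # exactly 20% of every segment (rows 0,5,..)
    props = segment_proportions(lab, aha)
    np.testing.assert_allclose(props, 0.2, atol=1e-12)


def test_segment_proportions_weighted_sum_is_global_fraction():
    rng = np.random.default_rng(11)
    lab = rng.choice([NORMAL, FIBROSIS, SCAR], size=(33, 47)).astype(np.uint8)
    mask = np.ones(lab.shape, dtype=bool)
    aha = partition_aha(lab.shape, mask)
    props = segment_proportions(lab, aha)
    weighted = np.nansum(props * aha.volumes) / aha.volumes.sum()
    global_frac = np.isin(lab, [FIBROSIS, SCAR]).mean()
    assert weighted == pytest.approx(global_frac, abs=1e-12)


# ------------------------------------------------------------------ nifti

def test_nifti_round_trip(tmp_path, patient1):
    path = tmp_path / "img.nii.gz"
    write_nifti(path, patient1.intensity)
    back = read_nifti(path)
    np.testing.assert_allclose(back.values, patient1.intensity.values, rtol=1e-6)
    assert back.spacing_mm == pytest.approx(patient1.intensity.spacing_mm)
    lpath = tmp_path / "lab.nii.gz"
    write_nifti(lpath, patient1.truth_labels)
    lab = read_nifti(lpath, as_labels=True)
    assert np.array_equal(lab.labels, patient1.truth_labels.labels)
    assert (tmp_path / "lab_labels.json").exists()
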