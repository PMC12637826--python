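"""Evaluation operations against closed-form, brute-force and Monte-Carlo
oracles."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

from vtwin.evaluation import (
    EvalGrid,
    MetricsReport,
    RigidTransform,
    avg_cloud_distance,
    bullseye_correlation,
    eam_stats,
    make_eval_grid,
    myocardium_mask,
    overlap_metrics,
    paired_volume_test,
    project_to_surface,
    rasterize_lesions,
    read_points_csv,
    register_fiducial,
    sheet_surface_mesh,
    write_points_csv,
)
from vtwin.synthetic import generate_clinical_lesions


# ------------------------------------------------------------ registration

def test_identity_registration(rng):
    pts = rng.random((6, 3)) * 20
    t = register_fiducial(pts, pts)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)
    assert t.rms_residual == pytest.approx(0.0, abs=1e-12)


def test_known_transform_recovered_to_1e6(rng):
    src = rng.random((8, 3)) * 30
    r = Rotation.from_euler("zyx", [30, 10, -20], degrees=True).as_matrix()
    t_vec = np.array([5.0, -3.0, 12.0])
    dst = src @ r.T + t_vec
    reg = register_fiducial(src, dst)
    np.testing.assert_allclose(reg.rotation, r, atol=1e-6)
    np.testing.assert_allclose(reg.translation, t_vec, atol=1e-6)
    np.testing.assert_allclose(reg.apply(src), dst, atol=1e-6)


def test_noisy_residual_matches_procrustes_minimum(rng):
    src = rng.random((10, 3)) * 25
    r = Rotation.from_euler("xyz", [15, -25, 40], degrees=True).as_matrix()
    dst = src @ r.T + [1, 2, 3] + rng.normal(0, 0.5, (10, 3))
    reg = register_fiducial(src, dst)
    # independent oracle: orthogonal Procrustes on centered clouds
    a0 = src - src.mean(axis=0)
    b0 = dst - dst.mean(axis=0)
    r_star, _ = orthogonal_procrustes(a0, b0)
    rms_star = np.sqrt(((a0 @ r_star - b0) ** 2).sum(axis=1).mean())
    assert reg.rms_residual == pytest.approx(rms_star, abs=1e-9)


def test_collinear_landmarks_rejected():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        register_fiducial(pts, pts + 1.0)


def test_rigid_transform_invariants():
    r = Rotation.from_euler("z", 73, degrees=True).as_matrix()
    t = RigidTransform(rotation=r, translation=[1, 2, 3])
    comp = t.compose(t.inverse())
    np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(comp.translation, 0.0, atol=1e-12)
    with pytest.raises(ValueError, match="orthonormal"):
        RigidTransform(rotation=np.eye(3) * 1.1, translation=[0, 0, 0])


# -------------------------------------------------------------- projection

def test_projection_of_surface_point_is_itself(rng):
    surf = rng.random((50, 3)) * 10
    out = project_to_surface(surf[7], surf)
    np.testing.assert_allclose(out[0], surf[7])


def test_projection_matches_brute_force(rng):
    surf = rng.random((200, 3)) * 10
    pts = rng.random((40, 3)) * 12
    out = project_to_surface(pts, surf)
    for p, o in zip(pts, out):
        d = np.linalg.norm(surf - p, axis=1)
        np.testing.assert_allclose(o, surf[np.argmin(d)])


def test_projection_tie_breaks_to_lowest_index():
    surf = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    out = project_to_surface(np.array([[1.0, 0, 0]]), surf)
    np.testing.assert_allclose(out[0], surf[0])


# ------------------------------------------------------------ rasterization

def test_single_hemisphere_volume_converges_to_closed_form():
    r = 3.5  # mm
    expect = (2.0 / 3.0) * np.pi * (r / 10.0) ** 3  # cm^3
    errs = []
    for spacing in (1.0, 0.5, 0.25):
        grid = make_eval_grid(np.array([[0.0, 0, 0]]), spacing, pad_mm=r + 1)
        _, vol = rasterize_lesions(np.array([[0.0, 0, 0]]), r, grid)
        errs.append(abs(vol - expect) / expect)
    assert errs[-1] < 0.02
    assert errs[-1] <= errs[0]  # refinement reduces the error


def test_coincident_points_add_no_volume():
    grid = make_eval_grid(np.array([[0.0, 0, 0]]), 0.5, pad_mm=5)
    _, v1 = rasterize_lesions(np.array([[0.0, 0, 0]]), 3.5, grid)
    _, v2 = rasterize_lesions(np.array([[0.0, 0, 0], [0.0, 0, 0]]), 3.5, grid)
    assert v1 == v2


def test_union_volume_matches_monte_carlo(rng):
    pts = np.array([[0.0, 0, 0], [2.5, 1.0, 0.0]])
    r = 3.5
    grid = make_eval_grid(pts, 0.25, pad_mm=r + 1)
    _, vol = rasterize_lesions(pts, r, grid)
    # Monte-Carlo oracle over the bounding box
    lo = pts.min(axis=0) - r
    hi = pts.max(axis=0) + r
    n = 400_000
    samples = rng.uniform(lo, hi, (n, 3))
    inside = np.zeros(n, dtype=bool)
    for p in pts:
        rel = samples - p
        inside |= (np.linalg.norm(rel, axis=1) <= r) & (rel[:, 2] <= 0)
    mc = inside.mean() * np.prod((hi - lo) / 10.0)
    assert vol == pytest.approx(mc, rel=0.01)


def test_union_bounded_by_sum_with_equality_iff_disjoint():
    r = 3.5
    far = np.array([[0.0, 0, 0], [20.0, 0, 0]])
    near = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    grid_f = make_eval_grid(far, 0.5, pad_mm=r + 1)
    grid_n = make_eval_grid(near, 0.5, pad_mm=r + 1)
    _, v_single = rasterize_lesions(far[:1], r, grid_f)
    _, v_far = rasterize_lesions(far, r, grid_f)
    _, v_near = rasterize_lesions(near, r, grid_n)
    assert v_far == pytest.approx(2 * v_single, rel=1e-6)
    assert v_near < 2 * v_single


# ----------------------------------------------------------------- metrics

def test_perfect_and_disjoint_masks():
    myo = np.ones((4, 10, 10), dtype=bool)
    a = np.zeros_like(myo)
    a[:, :5] = True
    rep = overlap_metrics(a, a, myo)
    assert (rep.dice, rep.sensitivity, rep.specificity, rep.fdr) == (1, 1, 1, 0)
    b = np.zeros_like(myo)
    b[:, 5:] = True
    assert overlap_metrics(a, b, myo).dice == 0.0


def test_metrics_match_confusion_formulas_on_random_masks(rng):
    myo = np.ones((3, 8, 8), dtype=bool)
    for _ in range(100):
        a = rng.random(myo.shape) > 0.5
        b = rng.random(myo.shape) > 0.5
        rep = overlap_metrics(a, b, myo)
        tp = np.sum(a & b)
        fp = np.sum(a & ~b)
        fn = np.sum(~a & b)
        tn = np.sum(~a & ~b)
        assert rep.dice == pytest.approx(2 * tp / (2 * tp + fp + fn))
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        assert rep.specificity == pytest.approx(tn / (tn + fp))
        assert rep.fdr == pytest.approx(fp / (tp + fp) if tp + fp else 0.0)


def test_metrics_reject_grid_mismatch():
    with pytest.raises(ValueError, match="grid"):
        overlap_metrics(np.ones((2, 2, 2), bool), np.ones((2, 2, 3), bool),
                        np.ones((2, 2, 2), bool))


# --------------------------------------------------------------- distances

def test_identical_clouds_distance_zero(rng):
    a = rng.random((30, 3))
    assert avg_cloud_distance(a, a) == 0.0


def test_two_point_distance():
    assert avg_cloud_distance([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(5.0)


def test_avg_distance_matches_double_loop(rng):
    a = rng.random((25, 3)) * 10
    b = rng.random((40, 3)) * 10
    d_ab = np.array([min(np.linalg.norm(p - q) for q in b) for p in a])
    d_ba = np.array([min(np.linalg.norm(q - p) for p in a) for q in b])
    expect = 0.5 * (d_ab.mean() + d_ba.mean())
    assert avg_cloud_distance(a, b) == pytest.approx(expect, abs=1e-12)


def test_empty_cloud_rejected():
    with pytest.raises(ValueError, match="empty"):
        avg_cloud_distance(np.zeros((0, 3)), [[0, 0, 0]])


# --------------------------------------------------------------- eam stats

def test_flat_sheet_area_is_exact():
    mesh = sheet_surface_mesh(100.0, 100.0, 5.0)
    area, _ = eam_stats(mesh, np.zeros((0, 3)))
    assert area == pytest.approx(100.0)  # 10 cm x 10 cm


def test_single_point_density_is_zero():
    mesh = sheet_surface_mesh(20.0, 20.0, 5.0)
    _, density = eam_stats(mesh, np.array([[5.0, 5.0, 0.0]]))
    assert density == 0.0


def test_lattice_density_matches_analytic_count():
    """Points on a 5-mm grid: neighbors within 10 mm are enumerable."""
    xs = np.arange(0, 50.0, 5.0)
    pts = np.array([[x, y, 0.0] for x in xs for y in xs])
    mesh = sheet_surface_mesh(50.0, 50.0, 5.0)
    _, density = eam_stats(mesh, pts)
    counts = []
    for p in pts:
        d = np.linalg.norm(pts - p, axis=1)
        counts.append(int(((d <= 10.0) & (d > 0)).sum()))
    assert density == pytest.approx(np.mean(counts))


# ------------------------------------------------------------- correlation

def test_correlation_extremes_and_oracle(rng):
    a = rng.random(27)
    r, _ = bullseye_correlation(a, a)
    assert r == pytest.approx(1.0)
    r, _ = bullseye_correlation(a, 2 * a.mean() - a)
    assert r == pytest.approx(-1.0)
    b = rng.random(27)
    r, _ = bullseye_correlation(a, b)
    expect = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
    assert r == pytest.approx(expect, abs=1e-12)


def test_correlation_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        bullseye_correlation(np.ones(9), np.arange(9.0))


# ----------------------------------------------------------------- wilcoxon

def test_uniform_shift_gives_minimal_exact_p():
    a = np.arange(1.0, 9.0)
    b = a + 1.0
    stat, p = paired_volume_test(a, b)
    # all 8 differences share one sign: two-sided exact p = 2 / 2^8
    assert p == pytest.approx(2.0 / 2 ** 8)
    assert stat == 0.0


def test_swap_symmetry():
    rng = np.random.default_rng(5)
    a = rng.random(12)
    b = rng.random(12)
    _, p1 = paired_volume_test(a, b)
    _, p2 = paired_volume_test(b, a)
    assert p1 == pytest.approx(p2)


def test_hand_enumerated_rank_sum():
    a = np.array([10.0, 12.0, 9.0, 15.0, 11.0, 8.0])
    b = np.array([11.0, 10.0, 12.0, 11.0, 12.0, 9.0])
    # d = a-b = [-1, 2, -3, 4, -1, -1]; |d| ranks: 1s -> 2, 2 -> 4, 3 -> 5, 4 -> 6
    # W+ = ranks of positive d = 4 + 6 = 10; W- = 2+2+2+5 = 11; stat = min = 10
    stat, _ = paired_volume_test(a, b)
    assert stat == 10.0


def test_degenerate_pairs_rejected():
    with pytest.raises(ValueError, match="degenerate|equal"):
        paired_volume_test(np.ones(6), np.ones(6))


# ------------------------------------------------- end-to-end lesion chain

def test_noiseless_clinical_lesions_align_with_truth(patient1):
    """Registration + projection + rasterization of noise-free clinical
    lesions reproduces the truth-channel lesion mask (dice >= 0.95)."""
    pts_clin = generate_clinical_lesions(patient1, jitter_mm=0.0,
                                         extra_fraction=0.0, seed=3)
    reg = register_fiducial(patient1.landmarks_clinical, patient1.landmarks_twin)
    back = reg.apply(pts_clin)
    truth = np.concatenate([
        np.asarray(line) for line in patient1.channel_truth
    ])
    # densify the truth center line at the same spacing
    y = np.linspace(truth[:, 1].min(), truth[:, 1].max(), 16)
    truth_pts = np.stack([np.full_like(y, truth[0, 0]), y, np.zeros_like(y)], axis=1)
    grid = make_eval_grid(np.concatenate([back, truth_pts]), 0.5, pad_mm=4.5)
    m_clin, _ = rasterize_lesions(back, 3.5, grid)
    m_truth, _ = rasterize_lesions(truth_pts, 3.5, grid)
    myo = np.ones(grid.shape, dtype=bool)
    rep = overlap_metrics(m_clin, m_truth, myo)
    assert rep.dice >= 0.95
    assert rep.fdr <= 0.05


def test_fdr_increases_with_extra_fraction(patient1):
    """Off-target clinical points inflate the false-detection rate."""
    fdrs = []
    for extra in (0.0, 0.5, 1.0):
        vals = []
        for seed in (1, 2, 3):
            pts = generate_clinical_lesions(patient1, jitter_mm=0.0,
                                            extra_fraction=extra, seed=seed)
            reg = register_fiducial(patient1.landmarks_clinical,
                                    patient1.landmarks_twin)
            back = reg.apply(pts)
            truth = patient1.channel_truth[0]
            y = np.linspace(truth[0, 1], truth[1, 1], 16)
            tp = np.stack([np.full_like(y, truth[0, 0]), y, np.zeros_like(y)],
                          axis=1)
            grid = make_eval_grid(np.concatenate([back, tp]), 1.0, pad_mm=4.5)
            m_a, _ = rasterize_lesions(back, 3.5, grid)
            m_b, _ = rasterize_lesions(tp, 3.5, grid)
            rep = overlap_metrics(m_a, m_b, np.ones(grid.shape, dtype=bool))
            vals.append(rep.fdr)
        fdrs.append(np.mean(vals))
    assert fdrs[0] < fdrs[1] < fdrs[2]


def test_points_csv_round_trip(tmp_path, rng):
    pts = rng.random((7, 3)) * 10
    path = tmp_path / "pts.csv"
    write_points_csv(path, pts, ids=[f"p{i}" for i in range(7)])
    ids, back = read_points_csv(path)
    assert ids == [f"p{i}" for i in range(7)]
    np.testing.assert_allclose(back, pts)
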