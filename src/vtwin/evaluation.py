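"""Lesion-set evaluation: fiducial registration, surface projection,
hemispherical lesion rasterization, overlap metrics, point-cloud
distances, EAM surface statistics and the cohort-level tests.

Conventions the package fixes (the clinical literature leaves them
open): the average point-cloud distance is the symmetric mean
nearest-neighbor distance; overlap metrics are computed on a voxelized
evaluation grid restricted to the myocardium; each ablation point
contributes a semi-spherical (hemisphere) volume extending inward along
the surface normal, and overlapping hemispheres are counted once (set
union).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .synthetic import LandmarkSet

log = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "MetricsReport",
    "EvalGrid",
    "register_fiducial",
    "project_to_surface",
    "make_eval_grid",
    "myocardium_mask",
    "rasterize_lesions",
    "overlap_metrics",
    "avg_cloud_distance",
    "eam_stats",
    "bullseye_correlation",
    "paired_volume_test",
    "sheet_surface_mesh",
    "write_points_csv",
    "read_points_csv",
    "write_lesions_csv",
]


@dataclass(frozen=True)
class RigidTransform:
    """x -> R x + t with R proper orthonormal."""

    rotation: np.ndarray
    translation: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or np.abs(r @ r.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be orthonormal (3x3)")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: first apply ``other``, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(rotation=self.rotation.T,
                              translation=-self.rotation.T @ self.translation)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-matrix overlap metrics plus lesion volumes."""

    dice: float
    sensitivity: float
    specificity: float
    fdr: float
    tp: int
    fp: int
    fn: int
    tn: int


def _as_matched_points(src, dst):
    if isinstance(src, LandmarkSet) and isinstance(dst, LandmarkSet):
        if src.labels != dst.labels:
            lut = {l: i for i, l in enumerate(dst.labels)}
            if set(src.labels) != set(dst.labels):
                raise ValueError("landmark label sets do not match")
            order = [lut[l] for l in src.labels]
            return src.points, dst.points[order]
        return src.points, dst.points
    a = np.asarray(src, dtype=float)
    b = np.asarray(dst, dtype=float)
    if a.shape != b.shape:
        raise ValueError("landmark sets must have equal counts")
    return a, b


def register_fiducial(src, dst, allow_scaling: bool = False) -> RigidTransform:
    """Least-squares rigid registration of matched landmarks (Kabsch).

    Minimizes sum ||R src_i + t - dst_i||^2 over proper rotations R and
    translations t; with ``allow_scaling`` a similarity transform is
    fitted instead (the scale multiplies the rotation).  Requires >= 3
    non-collinear pairs.
    """
    a, b = _as_matched_points(src, dst)
    if len(a) < 3:
        raise ValueError("at least 3 landmark pairs are required")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("landmarks are collinear; registration is degenerate")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    scale = 1.0
    if allow_scaling:
        scale = float((s * np.diag(corr)).sum() / (a0 ** 2).sum())
    t = cb - scale * r @ ca
    resid = scale * a0 @ r.T - b0
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    if allow_scaling:
        return _ScaledTransform(r, t, scale, rms)
    return RigidTransform(rotation=r, translation=t, rms_residual=rms)


class _ScaledTransform(RigidTransform):
    """Similarity transform (optional mode); scale stored separately."""

    def __init__(self, rotation, translation, scale, rms):
        object.__setattr__(self, "rotation", np.asarray(rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(translation, dtype=float))
        object.__setattr__(self, "rms_residual", float(rms))
        object.__setattr__(self, "scale", float(scale))

    def apply(self, pts):
        return self.scale * (np.asarray(pts, dtype=float) @ self.rotation.T) + self.translation


def project_to_surface(points: np.ndarray, surface_nodes: np.ndarray) -> np.ndarray:
    """Snap each point to the nearest surface node (Euclidean).

    Exact distance ties resolve to the lowest node index (KD-tree query
    returns the smallest index among equidistant neighbors).
    """
    surface_nodes = np.asarray(surface_nodes, dtype=float)
    if surface_nodes.size == 0:
        raise ValueError("surface is empty")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(surface_nodes)
    _, idx = tree.query(pts)
    return surface_nodes[idx]


@dataclass(frozen=True)
class EvalGrid:
    """Uniform voxel grid for lesion rasterization (voxel centers)."""

    origin_mm: np.ndarray     # (3,)
    spacing_mm: float
    shape: tuple              # (nz, ny, nx)

    def centers(self) -> np.ndarray:
        nz, ny, nx = self.shape
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        return (np.stack([xx, yy, zz], axis=-1).reshape(-1, 3) * self.spacing_mm
                + self.origin_mm)

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.spacing_mm / 10.0) ** 3


def make_eval_grid(surface_nodes: np.ndarray, spacing_mm: float = 0.5,
                   pad_mm: float = 3.5) -> EvalGrid:
    """Grid covering the surface bounding box, padded on all sides.

    Voxel centers are offset by ~half a voxel from the input point
    lattice so that flat region boundaries (e.g. the hemisphere base
    plane on the surface) fall between voxel layers; the midpoint
    counting rule is then unbiased.
    """
    s = np.asarray(surface_nodes, dtype=float)
    lo = s.min(axis=0) - pad_mm - 0.497 * spacing_mm
    hi = s.max(axis=0) + pad_mm
    n = np.maximum(np.ceil((hi - lo) / spacing_mm).astype(int) + 1, 1)
    return EvalGrid(origin_mm=lo, spacing_mm=float(spacing_mm),
                    shape=(int(n[2]), int(n[1]), int(n[0])))


def myocardium_mask(grid: EvalGrid, surface_nodes: np.ndarray,
                    thickness_mm: float = 3.5,
                    inward: np.ndarray = (0.0, 0.0, -1.0)) -> np.ndarray:
    """Voxels within ``thickness_mm`` of the surface on its inward side."""
    centers = grid.centers()
    tree = cKDTree(np.asarray(surface_nodes, dtype=float))
    d, idx = tree.query(centers)
    inw = np.asarray(inward, dtype=float)
    rel = centers - np.asarray(surface_nodes, dtype=float)[idx]
    side = rel @ inw >= -1e-6
    return ((d <= thickness_mm) & side).reshape(grid.shape)


def rasterize_lesions(points: np.ndarray, radius_mm: float, grid: EvalGrid,
                      inward_normals: np.ndarray | None = None):
    """Union of inward hemispheres around each ablation point.

    Each point contributes a semi-sphere of ``radius_mm`` extending
    inward along its surface normal (default -z for a sheet); the mask
    union inherently avoids double counting overlaps.  Returns
    (mask, volume_cm3).
    """
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if inward_normals is None:
        normals = np.tile([0.0, 0.0, -1.0], (len(pts), 1))
    else:
        normals = np.atleast_2d(np.asarray(inward_normals, dtype=float))
        if len(normals) == 1:
            normals = np.tile(normals, (len(pts), 1))
    centers = grid.centers()
    mask = np.zeros(len(centers), dtype=bool)
    tree = cKDTree(centers)
    for p, n in zip(pts, normals):
        idx = np.asarray(tree.query_ball_point(p, radius_mm + 1e-9), dtype=int)
        if idx.size == 0:
            continue
        rel = centers[idx] - p
        mask[idx[rel @ n >= -1e-9]] = True
    vol = float(mask.sum()) * grid.voxel_volume_cm3
    return mask.reshape(grid.shape), vol


def overlap_metrics(pred: np.ndarray, ref: np.ndarray,
                    myocardium: np.ndarray) -> MetricsReport:
    """Confusion-matrix metrics of predicted vs reference lesion masks,
    counted over myocardial voxels (reference = ground truth)."""
    pred, ref, myo = (np.asarray(m, dtype=bool) for m in (pred, ref, myocardium))
    if not (pred.shape == ref.shape == myo.shape):
        raise ValueError("masks must share one grid")
    p, r = pred[myo], ref[myo]
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    sens = tp / (tp + fn) if (tp + fn) else 1.0
    spec = tn / (tn + fp) if (tn + fp) else 1.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return MetricsReport(dice=dice, sensitivity=sens, specificity=spec, fdr=fdr,
                         tp=tp, fp=fp, fn=fn, tn=tn)


def avg_cloud_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean nearest-neighbor distance between point clouds."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("average distance undefined for an empty cloud")
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def sheet_surface_mesh(extent_x_mm: float, extent_y_mm: float, h_mm: float):
    """Triangulated flat sheet (two triangles per grid cell)."""
    nx = int(round(extent_x_mm / h_mm)) + 1
    ny = int(round(extent_y_mm / h_mm)) + 1
    xs = np.linspace(0, extent_x_mm, nx)
    ys = np.linspace(0, extent_y_mm, ny)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)], axis=1)
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append((a, a + 1, a + nx))
            faces.append((a + 1, a + nx + 1, a + nx))
    return verts, np.asarray(faces, dtype=int)


def eam_stats(surface_mesh, map_points: np.ndarray,
              density_radius_mm: float = 10.0):
    """Surface area (cm^2) and mapping-point density (points within a
    1-cm radius of each point, self excluded, averaged over points)."""
    verts, faces = surface_mesh
    verts = np.asarray(verts, dtype=float)
    tri = verts[np.asarray(faces, dtype=int)]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    degenerate = areas <= 1e-12
    if degenerate.any():
        log.warning("skipping %d degenerate triangles", int(degenerate.sum()))
    area_cm2 = float(areas[~degenerate].sum()) / 100.0
    pts = np.atleast_2d(np.asarray(map_points, dtype=float))
    if len(pts) == 0:
        return area_cm2, 0.0
    tree = cKDTree(pts)
    counts = np.array([
        len(tree.query_ball_point(p, density_radius_mm)) - 1 for p in pts
    ])
    return area_cm2, float(counts.mean())


def bullseye_correlation(prop_a, prop_b):
    """Pearson correlation between two per-segment proportion tables
    pooled over (patient, segment) pairs; returns (r, two-sided p)."""
    a = np.asarray(prop_a, dtype=float).ravel()
    b = np.asarray(prop_b, dtype=float).ravel()
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def paired_volume_test(vol_a, vol_b):
    """Wilcoxon signed-rank test on paired volumes.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used for n <= 25 pairs (without ties), the normal
    approximation above.  Returns (statistic, two-sided p).
    """
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need >= 5 paired volumes of equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all pairs are equal; test is degenerate")
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) != len(ranks)
    if d.size <= 25 and not has_ties:
        method = "exact"
    elif d.size <= 16:  # exact sign-flip enumeration handles ties
        method = stats.PermutationMethod(n_resamples=2 ** d.size + 1)
    else:
        method = "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


def write_points_csv(path, points: np.ndarray, ids=None) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float)).reshape(-1, 3)
    if ids is None:
        ids = [str(i) for i in range(len(pts))]
    pd.DataFrame({
        "id": list(ids), "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
    }).to_csv(path, index=False)


def read_points_csv(path):
    df = pd.read_csv(path)
    return df["id"].tolist(), df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


def write_lesions_csv(path, lesion_set) -> None:
    rows = []
    for les, prov in zip(lesion_set.lesions, lesion_set.provenance):
        x2, y2, z2 = les.endpoint if les.endpoint else (np.nan, np.nan, np.nan)
        rows.append({
            "kind": les.kind,
            "x": les.center[0], "y": les.center[1], "z": les.center[2],
            "x2": x2, "y2": y2, "z2": z2,
            "radius_mm": les.radius_mm,
            "round": prov.get("round"),
            "provenance": prov.get("target_kind"),
        })
    pd.DataFrame(rows, columns=["kind", "x", "y", "z", "x2", "y2", "z2",
                                "radius_mm", "round", "provenance"]).to_csv(path, index=False)
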