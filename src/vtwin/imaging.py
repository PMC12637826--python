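"""Intensity-volume processing: resampling, thresholding, tissue
classification and AHA-style regional partitioning.

The classification follows the LGE-MRI convention for fibrotic
remodeling: the myocardium is binarized by Otsu's method, the mean and
(population) SD of the low-intensity region define the non-fibrotic
reference, and voxels >= 2 SD above the reference mean are labeled
diffuse fibrosis, >= 4 SD dense scar (both bounds inclusive).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import BACKGROUND, FIBROSIS, LABEL_NAMES, NORMAL, SCAR

log = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "TissueLabelVolume",
    "AHAMap",
    "SEGMENT_NAMES",
    "resample_isotropic",
    "otsu_threshold",
    "classify_tissue",
    "partition_aha",
    "segment_proportions",
    "read_nifti",
    "write_nifti",
]


@dataclass
class ImageVolume:
    """Scalar volume with voxel-center geometry.

    ``values`` is (nz, ny, nx); voxel (iz, iy, ix) sits at
    origin + (ix, iy, iz) * spacing (mm, x fastest).
    """

    values: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array (nz, ny, nx)")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive lengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class TissueLabelVolume:
    """Per-voxel tissue class on the same grid convention as ImageVolume."""

    labels: np.ndarray
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        valid = {BACKGROUND, NORMAL, FIBROSIS, SCAR}
        found = set(np.unique(self.labels).tolist())
        if not found <= valid:
            raise ValueError(f"invalid label codes {sorted(found - valid)}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self):
        return self.labels.shape


SEGMENT_NAMES = tuple(
    f"{long_}-{circ}"
    for long_ in ("basal", "mid", "apical")
    for circ in ("anterior", "lateral", "inferior")
)


@dataclass
class AHAMap:
    """Nine-segment regional partition (3 long-axis x 3 circumferential).

    ``segment`` holds the segment id (0..8) per node, -1 outside the
    myocardium mask.  ``volumes`` is the node count per segment.
    """

    segment: np.ndarray
    volumes: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.volumes is None:
            self.volumes = np.array([
                int((self.segment == k).sum()) for k in range(9)
            ])


def resample_isotropic(vol: ImageVolume, target_mm: float = 0.35) -> ImageVolume:
    """Trilinear resample onto an isotropic grid of ``target_mm`` spacing.

    The physical extent (voxel-center span) is preserved to within one
    voxel; singleton axes are left untouched.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be > 0, got {target_mm}")
    shape = vol.values.shape
    spacing = np.asarray(vol.spacing_mm, dtype=float)  # (sz, sy, sx) for (z, y, x)
    spacing_zyx = spacing[::-1]
    new_shape, coords = [], []
    for ax in range(3):
        if shape[ax] == 1:
            new_shape.append(1)
            coords.append(np.zeros(1))
            continue
        span = (shape[ax] - 1) * spacing_zyx[ax]
        n = int(np.floor(span / target_mm)) + 1
        new_shape.append(n)
        coords.append(np.arange(n) * target_mm / spacing_zyx[ax])
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndimage.map_coordinates(
        vol.values.astype(float), np.array([g.ravel() for g in grid]), order=1,
        mode="nearest",
    ).reshape(new_shape)
    new_spacing = tuple(
        vol.spacing_mm[i] if shape[2 - i] == 1 else target_mm for i in range(3)
    )
    return ImageVolume(values=out, spacing_mm=new_spacing, origin_mm=vol.origin_mm)


def otsu_threshold(values) -> float:
    """Otsu's threshold over a 256-bin histogram.

    Returns the bin edge maximizing the between-class variance; ties are
    broken toward the lowest threshold for determinism.  Requires at
    least two distinct values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("Otsu threshold undefined for degenerate (all-equal) input")
    hist, edges = np.histogram(v, bins=256)
    p = hist.astype(float) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)
    mu_cum = np.cumsum(p * centers)
    mu_t = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu_cum) ** 2 / (w0 * (1.0 - w0))
    between[~np.isfinite(between)] = -1.0
    k = int(np.argmax(between))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def classify_tissue(vol: ImageVolume, myocardium_mask: np.ndarray | None = None
                    ) -> TissueLabelVolume:
    """SD-threshold tissue classification against the Otsu-low reference.

    Reference mean and population SD are computed over the Otsu
    low-intensity region of the masked voxels; then
    ``scar``      iff intensity >= mean + 4 SD,
    ``fibrosis``  iff mean + 2 SD <= intensity < mean + 4 SD,
    ``normal``    otherwise; voxels outside the mask are background.

    A degenerate Otsu split (single intensity class) yields an
    all-normal myocardium with a logged warning.
    """
    if myocardium_mask is None:
        myocardium_mask = np.ones(vol.values.shape, dtype=bool)
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    if myocardium_mask.shape != vol.values.shape:
        raise ValueError("mask shape does not match volume")
    if not myocardium_mask.any():
        raise ValueError("myocardium mask is empty")
    labels = np.full(vol.values.shape, BACKGROUND, dtype=np.uint8)
    masked = vol.values[myocardium_mask]
    try:
        thr = otsu_threshold(masked)
    except ValueError:
        log.warning("degenerate intensity distribution; labeling all voxels normal")
        labels[myocardium_mask] = NORMAL
        return TissueLabelVolume(labels=labels, spacing_mm=vol.spacing_mm,
                                 origin_mm=vol.origin_mm)
    low = masked[masked < thr]
    if low.size == 0:
        log.warning("empty Otsu low region; labeling all voxels normal")
        labels[myocardium_mask] = NORMAL
        return TissueLabelVolume(labels=labels, spacing_mm=vol.spacing_mm,
                                 origin_mm=vol.origin_mm)
    mu = float(low.mean())
    sd = float(low.std())  # population SD
    cls = np.full(masked.shape, NORMAL, dtype=np.uint8)
    if sd > 0:
        cls[masked >= mu + 2.0 * sd] = FIBROSIS
        cls[masked >= mu + 4.0 * sd] = SCAR
    labels[myocardium_mask] = cls
    return TissueLabelVolume(labels=labels, spacing_mm=vol.spacing_mm,
                             origin_mm=vol.origin_mm)


def partition_aha(domain_shape, myocardium_mask: np.ndarray) -> AHAMap:
    """Partition the mask into a 3 x 3 grid of equal in-plane extent.

    The long axis (basal/mid/apical) is the slower in-plane axis (y),
    the circumferential axis (anterior/lateral/inferior) the faster (x).
    For 3-D volumes the partition is applied in-plane and shared across
    slices.
    """
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    if myocardium_mask.shape != tuple(domain_shape):
        raise ValueError("mask shape does not match domain shape")
    if not myocardium_mask.any():
        raise ValueError("myocardium mask is empty")
    ny, nx = myocardium_mask.shape[-2], myocardium_mask.shape[-1]
    iy = np.arange(ny)
    ix = np.arange(nx)
    band_y = np.minimum(iy * 3 // ny, 2)
    band_x = np.minimum(ix * 3 // nx, 2)
    seg2d = band_y[:, None] * 3 + band_x[None, :]
    seg = np.broadcast_to(seg2d, myocardium_mask.shape).astype(np.int8).copy()
    seg[~myocardium_mask] = -1
    return AHAMap(segment=seg)


def segment_proportions(labels: TissueLabelVolume | np.ndarray, aha: AHAMap,
                        classes=(FIBROSIS, SCAR)) -> np.ndarray:
    """Per-segment ratio of voxels in ``classes`` to segment volume.

    Returns a length-9 array; empty segments yield NaN (reported as
    missing rather than zero).
    """
    lab = labels.labels if isinstance(labels, TissueLabelVolume) else np.asarray(labels)
    if lab.shape != aha.segment.shape:
        raise ValueError("label and segment grids are incompatible")
    member = np.isin(lab, list(classes))
    out = np.full(9, np.nan)
    for k in range(9):
        seg_mask = aha.segment == k
        n = int(seg_mask.sum())
        if n:
            out[k] = float(member[seg_mask].sum()) / n
    return out


def write_nifti(path, vol: ImageVolume | TissueLabelVolume) -> None:
    """Write a volume as NIfTI; label volumes get a JSON code-table sidecar."""
    import nibabel as nib

    data = vol.labels if isinstance(vol, TissueLabelVolume) else vol.values
    # NIfTI is x-fastest; our arrays are (z, y, x)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(data).T, affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    if isinstance(vol, TissueLabelVolume):
        side = str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json"
        with open(side, "w") as f:
            json.dump({str(k): v for k, v in LABEL_NAMES.items()}, f, indent=1)


def read_nifti(path, as_labels: bool = False):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T  # back to (z, y, x)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if as_labels:
        return TissueLabelVolume(labels=data.astype(np.uint8), spacing_mm=spacing,
                                 origin_mm=origin)
    return ImageVolume(values=data.astype(float), spacing_mm=spacing, origin_mm=origin)
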