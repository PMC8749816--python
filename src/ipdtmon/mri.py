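"""Volumetric overlap metrics between tumor and T1-hyperintensity labels.

After iPDT, non-contrast-enhanced T1-weighted MRI frequently shows intrinsic
hyperintense lesions (associated with methemoglobin formation).  This module
quantifies their spatial relation to the contrast-enhancing tumor volume with
the Dice (DSC), Jaccard (JSC) and overlap-volume (OV) coefficients, the
normalized hyperintensity image intensity I_T1 (mean over the lesion divided
by the mean over seven 8 mm white-matter reference spheres in the unaffected
hemisphere), the lesion's maximum diameter, and a per-fiber-pair
"hyperintensity strength" combining the lesion's fractional presence in a
pair's light transmission zone with I_T1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, map_coordinates
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .geometry import TransmissionZone, zone_overlap

__all__ = [
    "LabelVolume",
    "ImageVolume",
    "OverlapReport",
    "resample_mask",
    "overlap_metrics",
    "t1_intensity_norm",
    "hyperintensity_strength",
    "max_diameter",
]


@dataclass
class LabelVolume:
    """Binary voxel mask with an index-to-world affine (NIfTI convention)."""

    mask: np.ndarray
    affine: np.ndarray
    role: str = "label"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-15:
            raise ValueError("affine must be invertible")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume

    def world_coordinates(self, indices: np.ndarray | None = None) -> np.ndarray:
        if indices is None:
            indices = np.argwhere(self.mask)
        return indices @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class ImageVolume:
    """Scalar image (e.g. a T1-weighted volume) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)


def _same_grid(a: LabelVolume, b: LabelVolume) -> bool:
    return a.mask.shape == b.mask.shape and np.allclose(a.affine, b.affine)


def resample_mask(label: LabelVolume, shape: tuple, affine: np.ndarray) -> LabelVolume:
    """Nearest-neighbor resampling of a mask onto a target grid (labels stay 0/1)."""
    affine = np.asarray(affine, dtype=float)
    idx = np.indices(shape).reshape(3, -1)
    world = affine[:3, :3] @ idx + affine[:3, 3:4]
    src = np.linalg.inv(label.affine[:3, :3]) @ (world - label.affine[:3, 3:4])
    vals = map_coordinates(label.mask.astype(np.uint8), src, order=0, mode="constant", cval=0)
    return LabelVolume(vals.reshape(shape).astype(bool), affine, role=label.role)


@dataclass
class OverlapReport:
    """Geometric relation of a tumor volume V_T and a hyperintensity V_hyp.

    Invariants: 0 <= JSC <= DSC <= 1, JSC = DSC / (2 - DSC), 0 <= OV <= 1,
    intersection <= min(V_T, V_hyp).
    """

    v_t_mm3: float
    v_hyp_mm3: float
    intersection_mm3: float
    dsc: float
    jsc: float
    ov: float
    vhyp_over_vt_percent: float
    intersection_over_vt: float
    max_diameter_hyp_mm: float | None = None
    i_t1: float | None = None
    case_id: str = ""


def overlap_metrics(vt: LabelVolume, vhyp: LabelVolume, case_id: str = "") -> OverlapReport:
    """Dice, Jaccard and overlap-volume coefficients of two label volumes.

    DSC = 2|A n B| / (|A| + |B|); JSC = |A n B| / |A u B|;
    OV = |A n B| / min(|A|, |B|).  Labels on different grids are resampled
    (nearest-neighbor) onto the tumor grid first.
    """
    if not vt.mask.any() or not vhyp.mask.any():
        raise ValueError("overlap metrics require non-empty labels")
    if not _same_grid(vt, vhyp):
        vhyp = resample_mask(vhyp, vt.mask.shape, vt.affine)
        if not vhyp.mask.any():
            raise ValueError("hyperintensity label empty after resampling to the tumor grid")
    vox = vt.voxel_volume
    a, b = vt.mask, vhyp.mask
    inter = float(np.logical_and(a, b).sum()) * vox
    union = float(np.logical_or(a, b).sum()) * vox
    va = float(a.sum()) * vox
    vb = float(b.sum()) * vox
    dsc = 2.0 * inter / (va + vb)
    jsc = inter / union
    ov = inter / min(va, vb)
    return OverlapReport(
        v_t_mm3=va,
        v_hyp_mm3=vb,
        intersection_mm3=inter,
        dsc=dsc,
        jsc=jsc,
        ov=ov,
        vhyp_over_vt_percent=100.0 * vb / va,
        intersection_over_vt=inter / va,
        case_id=case_id,
    )


def t1_intensity_norm(
    image: ImageVolume, vhyp: LabelVolume, wm_spheres: list[LabelVolume]
) -> float:
    """Normalized T1 hyperintensity intensity I_T1.

    Ratio of the mean image intensity inside the hyperintensity lesion to the
    mean over the union of the white-matter reference spheres.  Background is
    neglected (it is <1% of tissue intensity in the source data); the ratio is
    invariant under global image scaling, which removes gain differences
    between cases.
    """
    if len(wm_spheres) == 0:
        raise ValueError("at least one white-matter reference sphere is required")
    shape, affine = image.data.shape, image.affine

    def mean_in(label: LabelVolume) -> tuple[float, int]:
        if label.mask.shape != shape or not np.allclose(label.affine, affine):
            label = resample_mask(label, shape, affine)
        n = int(label.mask.sum())
        return (float(image.data[label.mask].sum()), n)

    hyp_sum, hyp_n = mean_in(vhyp)
    if hyp_n == 0:
        raise ValueError("hyperintensity mask is empty on the image grid")
    wm_sum = 0.0
    wm_n = 0
    for sphere in wm_spheres:
        s, n = mean_in(sphere)
        wm_sum += s
        wm_n += n
    if wm_n == 0 or wm_sum == 0.0:
        raise ValueError("white-matter reference mean is zero or empty")
    return (hyp_sum / hyp_n) / (wm_sum / wm_n)


def hyperintensity_strength(
    zone: TransmissionZone,
    vhyp: LabelVolume,
    i_t1: float,
    denominator: str = "zone",
) -> float:
    """Hyperintensity strength of one fiber pair.

    The fraction of the pair's light transmission zone occupied by the
    hyperintensity lesion, multiplied by the lesion's normalized intensity
    I_T1.  ``denominator="hyp"`` instead divides the overlap by the lesion
    volume (the alternative reading of "fraction of T1 hyperintensity"); the
    zone-fraction default keeps the measure on a dimensionless <= I_T1 scale.
    """
    overlap, zone_fraction, involved = zone_overlap(zone, vhyp)
    if not involved:
        return 0.0
    if denominator == "zone":
        fraction = zone_fraction
    elif denominator == "hyp":
        fraction = overlap / vhyp.volume_mm3
    else:
        raise ValueError("denominator must be 'zone' or 'hyp'")
    return float(fraction * i_t1)


def max_diameter(label: LabelVolume) -> float:
    """Maximum Feret diameter of a mask: largest pairwise distance between
    surface-voxel centers, in mm."""
    if not label.mask.any():
        raise ValueError("max_diameter requires a non-empty mask")
    surface = label.mask & ~binary_erosion(label.mask)
    pts = label.world_coordinates(np.argwhere(surface))
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (flat/collinear) point sets: brute force below
    return float(pdist(pts).max())
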