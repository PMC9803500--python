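"""Brain extraction, tissue segmentation and the supraventricular WM ROI.

These stages stand in for the skull stripping and three-class tissue
extraction that clinical pipelines delegate to dedicated tools: Otsu
thresholding plus largest-component selection for the brain mask, 1-D
k-means (k = 3) on intensities for WM / GM / CSF, and a ventricle-anchored
rule for the white matter "at and above the bilateral ventricular level"
in which visible VRs are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .types import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "TissueSegmentation",
    "SupraventricularROI",
    "extract_brain",
    "segment_tissues",
    "find_ventricles",
    "supraventricular_roi",
    "compute_tissue_volumes",
    "OUTSIDE",
    "WM",
    "GM",
    "CSF",
]

OUTSIDE, WM, GM, CSF = 0, 1, 2, 3

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TissueSegmentation:
    """Label map over the brain mask with per-class mean intensities.

    Classes are named by ascending mean intensity, which on T2-weighted
    input orders them WM < GM < CSF.
    """

    labels: np.ndarray  # uint8, values in {OUTSIDE, WM, GM, CSF}
    class_means: dict[int, float]
    spacing: tuple[float, float, float]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SupraventricularROI:
    """Binary counting region: WM at and above the ventricle top slice."""

    mask: np.ndarray
    inferior_slice: int  # z_v


def extract_brain(volume: ImageVolume) -> np.ndarray:
    """Binary brain mask: Otsu threshold, largest 3D component, per-slice
    hole filling.

    Raises if the volume is not finite/non-negative or no foreground
    survives thresholding.
    """
    data = volume.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite voxels")
    if np.any(data < 0):
        raise ValueError("magnitude image must be non-negative")
    if np.ptp(data) == 0:
        raise ValueError("no brain found: constant volume")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise ValueError("no brain found: empty foreground after thresholding")
    lab, n = ndimage.label(fg, structure=_CONN26)
    sizes = np.bincount(lab.ravel())[1:]
    mask = lab == (1 + int(np.argmax(sizes)))
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return mask


def segment_tissues(
    volume: ImageVolume,
    mask: np.ndarray,
    k: int = 3,
    seed: int = 0,
    max_fit_voxels: int = 100_000,
) -> TissueSegmentation:
    """Three-class intensity clustering inside the brain mask.

    k-means (10 restarts, seed-controlled) on the 1-D intensity
    distribution; when the mask holds more than ``max_fit_voxels`` voxels
    the centres are fitted on a deterministic subsample and all voxels are
    then assigned to the nearest centre, which leaves the result unchanged
    up to centre estimation noise but keeps the fit fast.
    """
    vals = volume.data[mask]
    if vals.size == 0:
        raise ValueError("brain mask is empty")
    if np.unique(vals).size < k:
        raise ValueError(f"fewer than {k} distinct intensities inside the mask")
    fit_vals = vals
    if vals.size > max_fit_voxels:
        sub = np.random.default_rng(seed).choice(vals.size, max_fit_voxels, replace=False)
        fit_vals = vals[sub]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(fit_vals.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)  # ascending: WM, GM, CSF on T2
    # nearest-centre assignment of every voxel
    assign = np.argmin(np.abs(vals[:, None] - centers[None, :]), axis=1)
    remap = np.empty(k, dtype=np.uint8)
    remap[order] = np.arange(1, k + 1)
    labels = np.zeros(volume.shape, dtype=np.uint8)
    labels[mask] = remap[assign]
    class_means = {
        int(remap[c]): float(vals[assign == c].mean()) if np.any(assign == c) else float(centers[c])
        for c in range(k)
    }
    return TissueSegmentation(labels=labels, class_means=class_means, spacing=volume.spacing)


def find_ventricles(
    seg: TissueSegmentation,
    min_volume_mm3: float = 500.0,
) -> tuple[np.ndarray, int]:
    """Locate the lateral ventricles and the slice index of their top.

    Ventricles are the CSF connected components (3D, 26-connectivity)
    whose in-plane centroid falls in the central third of the field and
    whose volume exceeds ``min_volume_mm3``; z_v is the superior-most slice
    the combined mask reaches.
    """
    csf = seg.labels == CSF
    if not csf.any():
        raise ValueError("ventricles not found: no CSF class present")
    lab, n = ndimage.label(csf, structure=_CONN26)
    nx, ny = seg.labels.shape[:2]
    vv = seg.voxel_volume
    keep = np.zeros_like(csf)
    found = False
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() * vv < min_volume_mm3:
            continue
        cx, cy, _ = ndimage.center_of_mass(comp)
        if nx / 3 <= cx <= 2 * nx / 3 and ny / 3 <= cy <= 2 * ny / 3:
            keep |= comp
            found = True
    if not found:
        raise ValueError("ventricles not found")
    z_v = int(np.max(np.nonzero(keep.any(axis=(0, 1)))[0]))
    return keep, z_v


def supraventricular_roi(
    seg: TissueSegmentation,
    ventricle_mask: np.ndarray,
    z_v: int,
    ventricle_margin_vox: int = 2,
) -> SupraventricularROI:
    """White matter at and above the ventricular level.

    Per slice z >= z_v the ROI is the WM mask with its in-plane holes
    filled — enclosed CSF-intensity voxels are retained because visible
    VRs are themselves CSF-bright and must not be excluded by their own
    signal — minus the ventricle mask dilated in-plane by
    ``ventricle_margin_vox`` voxels (partial-volume rims around the
    ventricle would otherwise seed spurious tubular responses).
    """
    nz = seg.labels.shape[2]
    if not 0 <= z_v < nz:
        raise ValueError(f"z_v={z_v} outside slice range [0, {nz})")
    wm = seg.labels == WM
    roi = np.zeros_like(wm)
    for z in range(z_v, nz):
        roi[:, :, z] = ndimage.binary_fill_holes(wm[:, :, z])
    excl = ventricle_mask
    if ventricle_margin_vox > 0:
        st = ndimage.generate_binary_structure(2, 2)
        excl = ventricle_mask.copy()
        for z in range(nz):
            if ventricle_mask[:, :, z].any():
                excl[:, :, z] = ndimage.binary_dilation(
                    ventricle_mask[:, :, z], st, iterations=ventricle_margin_vox
                )
    roi &= ~excl
    if not roi.any():
        raise ValueError("supraventricular ROI is empty")
    return SupraventricularROI(mask=roi, inferior_slice=z_v)


def compute_tissue_volumes(seg: TissueSegmentation) -> tuple[float, float]:
    """(brain volume, WM volume) in mm^3 — class voxel counts times the
    voxel volume."""
    vv = seg.voxel_volume
    brain = float((seg.labels > 0).sum()) * vv
    wm = float((seg.labels == WM).sum()) * vv
    return brain, wm
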