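"""Core data containers shared across the pipeline stages.

Conventions
-----------
* Volumes are 3D ``numpy`` arrays indexed ``(x, y, z)`` with the slice axis
  last; the slice index increases superiorly, so "above the ventricles"
  means larger ``z``.
* Voxel spacing is expressed in millimetres per axis; the voxel volume is
  the product of the spacings.
* All coordinates are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "ImageVolume",
    "GroundTruth",
    "VRsMetrics",
    "ComparisonResult",
    "CorrelationResult",
    "LoessFit",
    "CutoffResult",
]


@dataclass
class ImageVolume:
    """A 3D intensity volume with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensity values; the last axis is the slice (inferior-to-superior)
        axis.
    spacing : tuple of float
        Voxel spacing in mm, ``(dx, dy, dz)``. All entries must be > 0.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class GroundTruth:
    """Exact per-phantom labels, the oracle for every downstream stage.

    Attributes
    ----------
    vrs_labels : ndarray of int
        0 = background, k = id of the k-th embedded VRs structure. Where two
        structures overlap the later id wins in the map; both ids are kept
        in ``overlapping_ids``.
    tissue_labels : ndarray of uint8
        0 = outside brain, 1 = WM, 2 = GM, 3 = CSF. VRs voxels carry the WM
        label here (they are CSF-intensity channels within the WM
        compartment).
    ventricle_mask : ndarray of bool
    vrs_count : int
        Number of embedded structures.
    vrs_volume_mm3 : float
        Exactly ``(number of labelled voxels) * voxel_volume``.
    ventricle_top_slice : int
        Superior-most slice index intersecting the ventricle mask.
    overlapping_ids : list of tuple
        Provenance for structures merged in the label map.
    """

    vrs_labels: np.ndarray
    tissue_labels: np.ndarray
    ventricle_mask: np.ndarray
    vrs_count: int
    vrs_volume_mm3: float
    ventricle_top_slice: int
    overlapping_ids: list = field(default_factory=list)

    def brain_mask(self) -> np.ndarray:
        return self.tissue_labels > 0

    def wm_mask(self) -> np.ndarray:
        return self.tissue_labels == 1


@dataclass
class VRsMetrics:
    """The four per-subject quantification outputs plus provenance."""

    vrs_count: int
    vrs_volume_mm3: float
    wm_volume_mm3: float
    brain_volume_mm3: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vrs_count < 0 or self.vrs_volume_mm3 < 0:
            raise ValueError("VRs metrics must be non-negative")
        if self.wm_volume_mm3 < 0 or self.brain_volume_mm3 < 0:
            raise ValueError("tissue volumes must be non-negative")

    def as_dict(self) -> dict:
        return {
            "vrs_count": self.vrs_count,
            "vrs_volume_mm3": self.vrs_volume_mm3,
            "wm_volume_mm3": self.wm_volume_mm3,
            "brain_volume_mm3": self.brain_volume_mm3,
        }


@dataclass
class ComparisonResult:
    """Mann-Whitney comparison of one metric between two groups."""

    metric: str
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    adjusted_alpha: float
    significant: bool
    method: str = "asymptotic"


@dataclass
class CorrelationResult:
    """Pearson correlation between two cohort variables."""

    var_x: str
    var_y: str
    r: float
    p_value: float
    n: int


@dataclass
class LoessFit:
    """Locally weighted linear regression evaluated on a fixed grid."""

    grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int
    n_neighbors: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("LOESS produced non-finite fitted values")


@dataclass
class CutoffResult:
    """Changepoint detected on a smoothed duration-response curve."""

    cutoff: float
    criterion: str
    profile_grid: np.ndarray
    profile: np.ndarray
    span: float
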