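"""Synthetic MR phantoms and synthetic cohorts.

The phantom emulates the T2-weighted contrast the quantification pipeline
consumes: a bright-CSF, mid-GM, dark-WM ellipsoidal "brain" on a near-zero
background, two paramedian ventricles, and embedded bright tubular
structures standing in for visible Virchow-Robin spaces (VRs).  Every
phantom comes with exact voxel-level ground truth.

The cohort generator draws per-subject clinical covariates and VRs metrics
from a Gaussian copula whose margins are truncated normals matched to the
configured mean +/- SD *after* truncation, and whose latent correlations
reproduce the configured duration/course vs. count/volume associations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.stats import norm, truncnorm

from .types import GroundTruth, ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "VRsStructureSpec",
    "PhantomConfig",
    "generate_phantom",
    "add_rician_noise",
    "random_structure_specs",
    "MarginSpec",
    "GroupConfig",
    "CohortConfig",
    "default_cohort_config",
    "generate_cohort",
    "write_fixture_set",
    "COHORT_COLUMNS",
]

# ---------------------------------------------------------------------------
# Phantom side
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VRsStructureSpec:
    """One embedded tubular VRs structure.

    ``kind`` is ``"linear"`` (axis in the slice plane, seen as a short
    bright line) or ``"circular"`` (axis through-plane, seen as a bright
    dot/disk on consecutive slices).  ``center`` is in voxel coordinates,
    ``orientation`` a unit vector in (x, y, z) mm space, ``length_mm`` the
    full axis length and ``radius_mm`` the tube radius.
    """

    kind: str
    center: tuple[float, float, float]
    orientation: tuple[float, float, float]
    length_mm: float
    radius_mm: float = 0.75
    intensity: float | None = None  # None -> CSF mean

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "circular"):
            raise ValueError(f"unknown structure kind {self.kind!r}")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.length_mm < self.radius_mm:
            raise ValueError("length_mm must be >= radius_mm")

    def unit_orientation(self) -> np.ndarray:
        o = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(o)
        if n == 0:
            raise ValueError("orientation must be a nonzero vector")
        return o / n


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, tissue intensities and noise level of a phantom.

    The default grid is a desk-scale 160 x 160 x 24 volume at the
    acquisition spacing 0.75 x 0.75 x 4 mm (i.e. a 120 mm in-plane field of
    view); :meth:`full_resolution` gives the 320 x 320 / 240 mm preset.
    Intensities follow the T2 ordering CSF > GM > WM.
    """

    shape: tuple[int, int, int] = (160, 160, 24)
    spacing: tuple[float, float, float] = (0.75, 0.75, 4.0)
    wm_mean: float = 100.0
    gm_mean: float = 130.0
    csf_mean: float = 200.0
    noise_sigma: float = 5.0
    ventricle_top_slice: int = 12
    structures: tuple[VRsStructureSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not (self.csf_mean > self.gm_mean > self.wm_mean):
            raise ValueError("T2 ordering requires CSF mean > GM mean > WM mean")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 < self.ventricle_top_slice < self.shape[2]):
            raise ValueError("ventricle_top_slice outside the slice range")

    @classmethod
    def full_resolution(cls, **kw) -> "PhantomConfig":
        """The acquisition-scale preset: 320 x 320 matrix, 240 mm FOV."""
        kw.setdefault("shape", (320, 320, 24))
        return cls(**kw)


# Brain ellipsoid semi-axes as fractions of the grid, and the normalised
# radius at which WM gives way to the GM shell.
_BRAIN_FRAC = (0.45, 0.45, 0.46)
_WM_SHELL = 0.88
_VENT_XOFF_FRAC = 0.0875  # paramedian offset as a fraction of nx
_VENT_SEMI_FRAC = (0.05, 0.125)  # in-plane semi-axes as fractions of (nx, ny)


def _phantom_masks(config: PhantomConfig):
    """Brain / GM / WM / ventricle masks for the configured geometry."""
    nx, ny, nz = config.shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = _BRAIN_FRAC[0] * nx, _BRAIN_FRAC[1] * ny, _BRAIN_FRAC[2] * nz
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    brain = r2 <= 1.0
    gm = brain & (r2 > _WM_SHELL**2)
    wm = brain & ~gm

    # Two paramedian ventricle ellipsoids whose rasterised top slice equals
    # ventricle_top_slice exactly (the half-axis is padded by 0.3 slice so
    # the top slice carries a non-degenerate disk).
    ztop = config.ventricle_top_slice
    zbot = max(2, ztop - 8)
    zc = (ztop + zbot) / 2
    half = (ztop - zbot) / 2 + 0.3
    vent = np.zeros(config.shape, dtype=bool)
    for side in (-1.0, 1.0):
        vx = cx + side * _VENT_XOFF_FRAC * nx
        vr = (
            ((x - vx) / (_VENT_SEMI_FRAC[0] * nx)) ** 2
            + ((y - cy) / (_VENT_SEMI_FRAC[1] * ny)) ** 2
            + ((z - zc) / half) ** 2
        )
        vent |= vr <= 1.0
    vent &= wm
    return brain, gm, wm, vent


def _rasterize_structure(
    spec: VRsStructureSpec, shape: Sequence[int], spacing: Sequence[float]
) -> tuple[np.ndarray, ...]:
    """Voxel indices whose centres fall inside the cylinder.

    The test is exact: a voxel centre p (in mm) belongs to the structure iff
    its axial coordinate along the axis is within +/- length/2 and its
    radial distance from the axis is within the radius.
    """
    center = np.asarray(spec.center, dtype=float)
    o = spec.unit_orientation()
    sp = np.asarray(spacing, dtype=float)
    half = spec.length_mm / 2
    extent = (half * np.abs(o) + spec.radius_mm) / sp + 1
    lo = np.maximum(0, np.floor(center - extent)).astype(int)
    hi = np.minimum(shape, np.ceil(center + extent).astype(int) + 1)
    if np.any(lo >= hi):
        return (np.array([], int),) * 3
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    offs = np.stack([(grids[i] - center[i]) * sp[i] for i in range(3)], axis=-1)
    t = offs @ o
    radial2 = (offs**2).sum(axis=-1) - t**2
    inside = (np.abs(t) <= half) & (radial2 <= spec.radius_mm**2 + 1e-12)
    return tuple(g[inside] for g in grids)


def generate_phantom(config: PhantomConfig) -> tuple[ImageVolume, GroundTruth]:
    """Build a noiseless tissue phantom with embedded VRs structures.

    Returns the intensity volume and exact ground truth.  Structures whose
    voxels stray outside the WM compartment (including into the ventricles)
    are rejected with an error naming the structure id.  Overlapping
    structures are merged in the label map (the earlier id is kept where
    they overlap) and recorded in ``overlapping_ids``.
    """
    brain, gm, wm, vent = _phantom_masks(config)
    vol = np.zeros(config.shape, dtype=np.float64)
    vol[wm] = config.wm_mean
    vol[gm] = config.gm_mean
    vol[vent] = config.csf_mean

    tissue = np.zeros(config.shape, dtype=np.uint8)
    tissue[wm] = 1
    tissue[gm] = 2
    tissue[vent] = 3

    labels = np.zeros(config.shape, dtype=np.int32)
    overlaps: list[tuple[int, int]] = []
    for sid, spec in enumerate(config.structures, start=1):
        idx = _rasterize_structure(spec, config.shape, config.spacing)
        if idx[0].size == 0:
            raise ValueError(f"structure {sid} rasterises to zero voxels")
        inside_wm = tissue[idx] == 1
        if not np.all(inside_wm):
            raise ValueError(
                f"structure {sid} ({spec.kind}) has voxels outside the WM "
                f"compartment"
            )
        prev = labels[idx]
        for other in np.unique(prev[prev > 0]):
            overlaps.append((int(other), sid))
        fresh = prev == 0
        sel = tuple(i[fresh] for i in idx)
        labels[sel] = sid
        vol[idx] = config.csf_mean if spec.intensity is None else spec.intensity

    vv = float(np.prod(config.spacing))
    if vent.any():
        vent_top = int(np.max(np.nonzero(vent.any(axis=(0, 1)))[0]))
    else:
        vent_top = -1
    truth = GroundTruth(
        vrs_labels=labels,
        tissue_labels=tissue,
        ventricle_mask=vent,
        vrs_count=len(config.structures),
        vrs_volume_mm3=float((labels > 0).sum()) * vv,
        ventricle_top_slice=vent_top,
        overlapping_ids=overlaps,
    )
    return ImageVolume(vol, config.spacing), truth


def add_rician_noise(
    volume: ImageVolume, sigma: float, rng: np.random.Generator | int | None = None
) -> ImageVolume:
    """Corrupt a magnitude image with Rician noise.

    Each voxel v is replaced by sqrt((v + n1)^2 + n2^2) with n1, n2
    independent zero-mean Gaussians of standard deviation ``sigma`` — the
    standard magnitude-MR noise model.  ``sigma = 0`` returns the input
    unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ImageVolume(volume.data.copy(), volume.spacing)
    rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    data = np.sqrt((volume.data + n1) ** 2 + n2**2)
    return ImageVolume(data, volume.spacing)


def _segment_points(center_mm: np.ndarray, o: np.ndarray, length: float, k: int = 21):
    t = np.linspace(-0.5, 0.5, k) * length
    return center_mm[None, :] + np.outer(t, o)


def _segment_gap(a, b) -> float:
    """Surface-to-surface distance between two cylinders (sampled axes)."""
    pa = _segment_points(*a[:3])
    pb = _segment_points(*b[:3])
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)).min()
    return float(d - a[3] - b[3])


def random_structure_specs(
    rng: np.random.Generator | int,
    n: int,
    config: PhantomConfig | None = None,
    p_circular: float = 0.4,
    min_gap_mm: float = 4.5,
    linear_radius_mm: tuple[float, float] = (1.0, 1.5),
    circular_radius_mm: tuple[float, float] = (1.75, 2.5),
    linear_length_mm: tuple[float, float] = (6.0, 12.0),
    circular_length_mm: tuple[float, float] = (8.0, 16.0),
    max_tries: int = 50000,
) -> tuple[VRsStructureSpec, ...]:
    """Place ``n`` well-separated VRs structures in supraventricular WM.

    Rejection sampling against the phantom geometry: candidates must
    rasterise entirely inside WM, stay clear of a 3-voxel in-plane margin
    around the ventricles, sit on slices at or above the ventricle top, and
    keep a surface-to-surface gap of ``min_gap_mm`` from every accepted
    structure so components remain resolvable.

    Radii span visibly enlarged perivascular spaces: through-plane
    ("circular") tubes are drawn wider than in-plane ("linear") ones
    because a dot at the resolution limit is not reliably renderable on a
    0.75 mm grid.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(rng)
    _, _, wm, vent = _phantom_masks(config)
    zv = config.ventricle_top_slice
    # structures must stay clear of the ventricle rim (so CSF components
    # stay separable) and of the GM boundary (so a VRs remains an enclosed
    # hole of the WM on its slice)
    st = ndimage.generate_binary_structure(2, 2)
    vent_excl = vent.copy()
    allowed = np.zeros_like(wm)
    for z in range(config.shape[2]):
        if vent[:, :, z].any():
            vent_excl[:, :, z] = ndimage.binary_dilation(
                vent[:, :, z], st, iterations=3
            )
        allowed[:, :, z] = ndimage.binary_erosion(wm[:, :, z], st, iterations=3)
    # the margin must hold in 3D: a CSF structure 26-adjacent to the
    # ventricle roof would merge with it and shift the detected top slice
    vent_excl[:, :, 1:] |= vent_excl[:, :, :-1]
    vent_excl[:, :, :-1] |= vent_excl[:, :, 1:]
    allowed &= ~vent_excl
    allowed[:, :, :zv] = False

    nx, ny, nz = config.shape
    sp = np.asarray(config.spacing)
    specs: list[VRsStructureSpec] = []
    geo: list[tuple] = []
    tries = 0
    while len(specs) < n and tries < max_tries:
        tries += 1
        z = int(rng.integers(zv, nz - 1))
        if rng.uniform() < p_circular:
            kind = "circular"
            o = np.array([0.0, 0.0, 1.0])
            radius = float(rng.uniform(*circular_radius_mm))
            length = float(rng.uniform(*circular_length_mm))
        else:
            kind = "linear"
            th = rng.uniform(0, 2 * np.pi)
            o = np.array([np.cos(th), np.sin(th), 0.0])
            radius = float(rng.uniform(*linear_radius_mm))
            length = float(rng.uniform(*linear_length_mm))
        cx = int(rng.integers(8, nx - 8))
        cy = int(rng.integers(8, ny - 8))
        if not allowed[cx, cy, z]:
            continue
        spec = VRsStructureSpec(kind, (cx, cy, z), tuple(o), length, radius)
        idx = _rasterize_structure(spec, config.shape, config.spacing)
        if idx[0].size == 0 or not np.all(allowed[idx]):
            continue
        center_mm = np.array([cx, cy, z]) * sp
        cand = (center_mm, o, length, radius)
        if any(_segment_gap(cand, g) < min_gap_mm for g in geo):
            continue
        geo.append(cand)
        specs.append(spec)
    if len(specs) < n:
        logger.warning(
            "placed only %d of %d requested structures after %d tries",
            len(specs), n, tries,
        )
    return tuple(specs)


# ---------------------------------------------------------------------------
# Cohort side
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age_months",
    "sex",
    "ga_weeks",
    "duration_min",
    "course_days",
    "hc_cm",
    "vrs_count",
    "vrs_volume_mm3",
    "wm_volume_mm3",
    "brain_volume_mm3",
]

#: the variables that participate in the correlated joint model
_JOINT_VARS = ("duration", "course", "vrs_count", "vrs_volume")


@dataclass(frozen=True)
class MarginSpec:
    """Target mean +/- SD of one margin after truncation to (lower, upper]."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")


@dataclass(frozen=True)
class GroupConfig:
    name: str
    n: int
    male_prop: float
    vrs_count: MarginSpec
    vrs_volume: MarginSpec
    wm_volume: MarginSpec
    brain_volume: MarginSpec
    hc: MarginSpec
    age: MarginSpec
    ga: MarginSpec
    duration: MarginSpec | None = None
    course: MarginSpec | None = None
    correlations: tuple[tuple[tuple[str, str], float], ...] = ()

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group sample size must be >= 2")
        if not 0 <= self.male_prop <= 1:
            raise ValueError("male_prop must lie in [0, 1]")
        for (a, b), r in self.correlations:
            if a not in _JOINT_VARS or b not in _JOINT_VARS:
                raise ValueError(f"correlation refers to unknown variable ({a}, {b})")
            if not -1 <= r <= 1:
                raise ValueError(f"correlation ({a}, {b}) outside [-1, 1]")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupConfig, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Cohort defaults: 30 / 40 / 35 subjects with the published group
    means, SDs and within-group correlations.

    Seizure durations are truncated at the 5-minute group boundary and the
    15-minute ceiling of the simple-febrile-seizure definition (lower bound
    0.5 min); the course from seizure onset to the scan is truncated to
    (0, 15] days.
    """
    long = GroupConfig(
        name="SFS>5M",
        n=30,
        male_prop=0.70,
        duration=MarginSpec(7.16, 1.23, 5.0, 15.0),
        course=MarginSpec(9.60, 1.32, 0.0, 15.0),
        vrs_count=MarginSpec(642.70, 100.62, 0.0),
        vrs_volume=MarginSpec(8514.63, 835.33, 0.0),
        wm_volume=MarginSpec(300670.0, 155800.0, 0.0),
        brain_volume=MarginSpec(880010.0, 156410.0, 0.0),
        hc=MarginSpec(70.82, 10.18, 30.0, 120.0),
        age=MarginSpec(28.07, 15.12, 6.0, 60.0),
        ga=MarginSpec(39.73, 1.07, 37.0, 44.0),
        correlations=(
            (("duration", "vrs_count"), 0.778),
            (("duration", "vrs_volume"), 0.702),
            (("course", "vrs_count"), -0.812),
            (("course", "vrs_volume"), -0.807),
        ),
    )
    short = GroupConfig(
        name="SFS<=5M",
        n=40,
        male_prop=0.7333,
        duration=MarginSpec(2.70, 0.45, 0.5, 5.0),
        course=MarginSpec(9.40, 1.43, 0.0, 15.0),
        vrs_count=MarginSpec(445.80, 66.10, 0.0),
        vrs_volume=MarginSpec(6390.43, 692.74, 0.0),
        wm_volume=MarginSpec(321420.0, 70520.0, 0.0),
        brain_volume=MarginSpec(894290.0, 81100.0, 0.0),
        hc=MarginSpec(71.64, 11.35, 30.0, 120.0),
        age=MarginSpec(26.89, 15.92, 6.0, 60.0),
        ga=MarginSpec(39.80, 0.94, 37.0, 44.0),
        correlations=(
            (("duration", "vrs_count"), 0.563),
            (("duration", "vrs_volume"), 0.568),
            (("course", "vrs_count"), -0.628),
            (("course", "vrs_volume"), -0.562),
        ),
    )
    control = GroupConfig(
        name="control",
        n=35,
        male_prop=0.7429,
        vrs_count=MarginSpec(430.77, 182.55, 0.0),
        vrs_volume=MarginSpec(6048.37, 111.50, 0.0),
        wm_volume=MarginSpec(308510.0, 134450.0, 0.0),
        brain_volume=MarginSpec(916730.0, 181910.0, 0.0),
        hc=MarginSpec(71.26, 10.04, 30.0, 120.0),
        age=MarginSpec(27.83, 17.04, 6.0, 60.0),
        ga=MarginSpec(39.41, 1.14, 35.0, 44.0),
    )
    return CohortConfig(groups=(long, short, control), seed=seed)


@lru_cache(maxsize=32)
def _completed_correlation(
    variables: tuple[str, ...], targets: tuple[tuple[tuple[str, str], float], ...]
) -> tuple[tuple[float, ...], ...]:
    """Complete the correlation matrix over ``variables``.

    The configured entries are held exact; the unspecified entries are
    chosen to maximise the smallest eigenvalue of the matrix (a matrix
    completion, so the targets survive untouched whenever any positive
    semi-definite completion exists).  If even the best completion is
    indefinite, a clipped-eigenvalue repair is applied and an error raised
    when that moves any configured entry materially.
    """
    p = len(variables)
    index = {v: i for i, v in enumerate(variables)}
    fixed = {}
    for (a, b), r in targets:
        if a in index and b in index:
            fixed[(min(index[a], index[b]), max(index[a], index[b]))] = r
    free = [
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if (i, j) not in fixed
    ]

    def build(vals: np.ndarray) -> np.ndarray:
        R = np.eye(p)
        for (i, j), r in fixed.items():
            R[i, j] = R[j, i] = r
        for (i, j), r in zip(free, vals):
            R[i, j] = R[j, i] = r
        return R

    if not free:
        R = build(np.array([]))
    else:
        def neg_min_eig(vals):
            return -np.linalg.eigvalsh(build(vals))[0]

        best = None
        for start in np.linspace(-0.8, 0.8, 5):
            res = optimize.minimize(
                neg_min_eig,
                np.full(len(free), start),
                bounds=[(-0.99, 0.99)] * len(free),
            )
            if best is None or res.fun < best.fun:
                best = res
        R = build(best.x)

    min_eig = np.linalg.eigvalsh(R)[0]
    if min_eig < 1e-9:
        # clipped-eigenvalue repair (Higham-style single projection with
        # unit-diagonal restoration)
        for _ in range(100):
            w, V = np.linalg.eigh(R)
            R = (V * np.clip(w, 1e-8, None)) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            if np.linalg.eigvalsh(R)[0] >= 1e-9:
                break
        worst, dev = None, 0.0
        for (i, j), r in fixed.items():
            if abs(R[i, j] - r) > dev:
                worst, dev = (variables[i], variables[j]), abs(R[i, j] - r)
        if dev > 0.05:
            raise ValueError(
                f"correlation targets are infeasible: pair {worst} moved by "
                f"{dev:.3f} during PSD repair"
            )
    return tuple(tuple(row) for row in R)


@lru_cache(maxsize=256)
def _truncnorm_parent(margin: MarginSpec) -> tuple[float, float, float, float]:
    """Parent (mu, sigma) whose (lower, upper]-truncation has the target
    mean and SD, plus the standardised bounds.

    Solved as weighted least squares with the mean term dominating: for
    feasible targets both moments are matched essentially exactly, while a
    target SD beyond what the truncated-normal family can reach on the
    given interval (possible for heavily dispersed bounded covariates)
    yields the closest achievable SD at the exact mean.
    """
    mean, sd, lo, hi = margin.mean, margin.sd, margin.lower, margin.upper
    if sd == 0:
        return mean, 0.0, -np.inf, np.inf
    zlo = (lo - mean) / sd
    zhi = (hi - mean) / sd
    if zlo < -5 and zhi > 5:  # truncation effect below ~1e-5 relative
        return mean, sd, -np.inf, np.inf

    def residual(p):
        mu, s = p[0], math.exp(p[1])
        a, b = (lo - mu) / s, (hi - mu) / s
        d = truncnorm(a, b)
        return [
            50.0 * (mu + s * d.mean() - mean) / sd,
            (s * d.std() - sd) / sd,
        ]

    sol = optimize.least_squares(
        residual, [mean, math.log(sd)], method="lm", xtol=1e-14, ftol=1e-14
    )
    mu, s = float(sol.x[0]), float(math.exp(sol.x[1]))
    return mu, s, (lo - mu) / s, (hi - mu) / s


def _margin_from_latent(z: np.ndarray, margin: MarginSpec) -> np.ndarray:
    mu, s, a, b = _truncnorm_parent(margin)
    if s == 0:
        return np.full_like(z, mu)
    if not np.isfinite(a) and not np.isfinite(b):
        return mu + s * z
    u = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)
    return truncnorm.ppf(u, a, b, loc=mu, scale=s)


def _draw_group(g: GroupConfig, rng: np.random.Generator) -> pd.DataFrame:
    has_clinical = g.duration is not None
    if has_clinical and g.course is None:
        raise ValueError(f"group {g.name}: duration without course")
    joint = (
        ("duration", "course", "vrs_count", "vrs_volume")
        if has_clinical
        else ("vrs_count", "vrs_volume")
    )
    R = np.asarray(_completed_correlation(joint, g.correlations))
    w, V = np.linalg.eigh(R)
    L = V * np.sqrt(np.clip(w, 0, None))
    z = rng.standard_normal((g.n, len(joint))) @ L.T

    margins = {
        "vrs_count": g.vrs_count,
        "vrs_volume": g.vrs_volume,
    }
    if has_clinical:
        margins["duration"] = g.duration
        margins["course"] = g.course
    drawn = {
        v: _margin_from_latent(z[:, i], margins[v]) for i, v in enumerate(joint)
    }

    df = pd.DataFrame(
        {
            "group": g.name,
            "age_months": _margin_from_latent(rng.standard_normal(g.n), g.age),
            "sex": np.where(rng.uniform(size=g.n) < g.male_prop, "M", "F"),
            "ga_weeks": _margin_from_latent(rng.standard_normal(g.n), g.ga),
            "duration_min": drawn.get("duration", np.full(g.n, np.nan)),
            "course_days": drawn.get("course", np.full(g.n, np.nan)),
            "hc_cm": _margin_from_latent(rng.standard_normal(g.n), g.hc),
            "vrs_count": np.round(drawn["vrs_count"]).astype(int),
            "vrs_volume_mm3": drawn["vrs_volume"],
            "wm_volume_mm3": _margin_from_latent(rng.standard_normal(g.n), g.wm_volume),
            "brain_volume_mm3": _margin_from_latent(
                rng.standard_normal(g.n), g.brain_volume
            ),
        }
    )
    return df


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    One row per subject with the schema in :data:`COHORT_COLUMNS`.  Within
    each seizure group the four joint variables (duration, course, VRs
    count, VRs volume) follow a Gaussian copula whose margins hit the
    configured mean +/- SD after truncation and whose correlations match
    the configured targets; controls carry no duration/course.
    """
    config = config or default_cohort_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for g in config.groups:
        df = _draw_group(g, rng)
        df.insert(
            0,
            "subject_id",
            [f"{_group_key(g.name)}-{i:03d}" for i in range(1, g.n + 1)],
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]
    return out


def _group_key(name: str) -> str:
    return name.replace(">", "gt").replace("<=", "le").replace(" ", "")


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------


def write_fixture_set(
    out_dir,
    phantom_configs: Iterable[PhantomConfig],
    cohort_config: CohortConfig | None = None,
) -> dict:
    """Write phantoms (+ ground-truth labels), a cohort CSV and a manifest.

    Every file is reproducible from the seeds recorded in the manifest;
    re-running with the same configs rewrites byte-identical content.
    """
    from pathlib import Path

    from .io import write_cohort_csv, write_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"phantoms": [], "cohort": None}
    for i, pc in enumerate(phantom_configs):
        vol, truth = generate_phantom(pc)
        noisy = add_rician_noise(vol, pc.noise_sigma, np.random.default_rng(pc.seed))
        img_path = out / f"phantom_{i:02d}.nii.gz"
        lab_path = out / f"phantom_{i:02d}_labels.nii.gz"
        write_nifti(img_path, noisy)
        write_nifti(lab_path, ImageVolume(truth.vrs_labels.astype(np.float32), pc.spacing))
        manifest["phantoms"].append(
            {
                "image": img_path.name,
                "labels": lab_path.name,
                "seed": pc.seed,
                "noise_sigma": pc.noise_sigma,
                "n_structures": len(pc.structures),
                "true_count": truth.vrs_count,
                "true_volume_mm3": truth.vrs_volume_mm3,
            }
        )
    if cohort_config is not None:
        cohort = generate_cohort(cohort_config)
        cohort_path = out / "cohort.csv"
        write_cohort_csv(cohort_path, cohort)
        manifest["cohort"] = {"file": cohort_path.name, "seed": cohort_config.seed}
    import json

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
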