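"""NIfTI and CSV interchange, YAML run configuration, and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .quantify import PipelineConfig
from .synthetic import COHORT_COLUMNS, PhantomConfig
from .types import ImageVolume
from .vesselness import VesselnessParams

logger = logging.getLogger(__name__)

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_cohort_csv",
    "write_cohort_csv",
    "RunConfig",
    "load_config",
    "RunManifest",
]

VALID_GROUPS = ("SFS>5M", "SFS<=5M", "control")

_NUMERIC_COLUMNS = [
    "age_months",
    "ga_weeks",
    "duration_min",
    "course_days",
    "hc_cm",
    "vrs_count",
    "vrs_volume_mm3",
    "wm_volume_mm3",
    "brain_volume_mm3",
]


def read_nifti(path) -> ImageVolume:
    """Load a 3D NIfTI volume, reoriented to RAS+ so that the slice index
    increases superiorly."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected 3D data, got {data.ndim}D in {path}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite voxels in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data, spacing)


def write_nifti(path, volume: ImageVolume) -> None:
    """Write a volume as NIfTI-1 with an RAS+ affine built from the spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_cohort_csv(path) -> pd.DataFrame:
    """Load and validate a cohort table.

    The header must match the canonical schema; groups must be one of
    ``SFS>5M``, ``SFS<=5M``, ``control``; seizure duration and course are
    required on seizure rows and must be absent on controls; numeric
    columns must parse cleanly (no thousands separators).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "sex": str})
    if list(df.columns) != COHORT_COLUMNS:
        missing = set(COHORT_COLUMNS) - set(df.columns)
        extra = set(df.columns) - set(COHORT_COLUMNS)
        raise ValueError(
            f"cohort schema mismatch in {path}: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    bad_groups = set(df["group"]) - set(VALID_GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}")
    for col in _NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column {col!r} is not cleanly numeric: {exc}") from exc
    is_control = df["group"] == "control"
    if df.loc[is_control, ["duration_min", "course_days"]].notna().any().any():
        raise ValueError("control subjects must not carry seizure duration/course")
    sfs = df.loc[~is_control]
    if sfs[["duration_min", "course_days"]].isna().any().any():
        raise ValueError("seizure-group subjects must carry duration and course")
    return df


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    span: float = 0.5
    degree: int = 1
    criterion: str = "max_abs_curvature"
    cutoff_metric: str = "vrs_count"
    n_grid: int = 200


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one run; written next to its outputs."""

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    n_structures: int = 25
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    stats: StatsParams = field(default_factory=StatsParams)

    def to_dict(self) -> dict:
        def clean(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {
                    f.name: clean(getattr(obj, f.name))
                    for f in fields(obj)
                    if f.name != "structures"
                }
            if isinstance(obj, (list, tuple)):
                return [clean(o) for o in obj]
            return obj

        return clean(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    top_allowed = {"seed", "out_dir", "log_level", "n_structures", "phantom", "vesselness", "quantify", "stats"}
    _check_keys(raw, top_allowed, "<top-level>")

    phantom_blk = dict(raw.get("phantom", {}))
    _check_keys(
        phantom_blk,
        {f.name for f in fields(PhantomConfig)} - {"structures"},
        "phantom",
    )
    if "shape" in phantom_blk:
        phantom_blk["shape"] = tuple(phantom_blk["shape"])
    if "spacing" in phantom_blk:
        phantom_blk["spacing"] = tuple(phantom_blk["spacing"])

    vess_blk = dict(raw.get("vesselness", {}))
    _check_keys(vess_blk, {f.name for f in fields(VesselnessParams)}, "vesselness")
    if "scales_mm" in vess_blk:
        vess_blk["scales_mm"] = tuple(vess_blk["scales_mm"])

    quant_blk = dict(raw.get("quantify", {}))
    _check_keys(
        quant_blk,
        {f.name for f in fields(PipelineConfig)} - {"vesselness"},
        "quantify",
    )

    stats_blk = dict(raw.get("stats", {}))
    _check_keys(stats_blk, {f.name for f in fields(StatsParams)}, "stats")

    seed = int(raw.get("seed", 0))
    vess = VesselnessParams(**vess_blk)
    pipeline = PipelineConfig(vesselness=vess, seed=seed, **quant_blk)
    return RunConfig(
        seed=seed,
        out_dir=str(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
        n_structures=int(raw.get("n_structures", 25)),
        phantom=PhantomConfig(seed=seed, **phantom_blk),
        pipeline=pipeline,
        stats=StatsParams(**stats_blk),
    )


@dataclass
class RunManifest:
    """Reproducibility record written next to every run's outputs.

    Deterministic stages reproduce bit-for-bit from (config, seed);
    stochastic stages reproduce distributionally.  Timings are logged, not
    stored, so that identical runs write identical manifests.
    """

    tool_version: str
    config_hash: str
    seed: int
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"
        )

    @staticmethod
    def file_hash(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
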