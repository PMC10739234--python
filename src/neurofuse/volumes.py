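"""Core volume/label data model, NIfTI-1 and YAML I/O, configuration and logging.

Conventions used throughout the package:

* voxel indices are 0-based and voxel-centered,
* world axes are RAS, world coordinates are in millimetres,
* the world coordinate of voxel ``(i, j, k)`` is ``origin + spacing * (i, j, k)``,
* spacing is a single isotropic edge length (anisotropic input is rejected,
  never silently resampled),
* intensities are stored as 32-bit float, label maps as 8-bit unsigned int.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import yaml

log = logging.getLogger("neurofuse")

# ---------------------------------------------------------------------------
# label legend
# ---------------------------------------------------------------------------

REST = 0
CSF = 1
BRAINSTEM = 2
NERVE = 3
VESSEL = 4

LABEL_NAMES = {REST: "REST", CSF: "CSF", BRAINSTEM: "BRAINSTEM",
               NERVE: "NERVE", VESSEL: "VESSEL"}

#: isotropy tolerance: maximum relative spread of the three header spacings
ISOTROPY_RTOL = 0.01


def setup_logging(verbose: bool = False) -> None:
    """Configure the package logger to write structured lines to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Volume / LabelMap
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D scalar grid with isotropic spacing and a world origin (RAS, mm)."""

    values: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if any(n < 4 for n in self.values.shape):
            raise ValueError(f"every dimension must be >= 4, got {self.values.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("volume contains non-finite values")
        self.spacing = float(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def center(self) -> np.ndarray:
        """World coordinate of the grid center."""
        return self.origin + self.spacing * (np.asarray(self.shape) - 1) / 2.0

    def world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of (fractional) voxel indices, shape (..., 3)."""
        return self.origin + self.spacing * np.asarray(index, dtype=float)

    def index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world coordinates, shape (..., 3)."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def same_geometry(self, other: "Volume | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing, self.origin.copy())


@dataclass
class LabelMap(Volume):
    """Integer grid assigning each voxel to exactly one of the five labels."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.round(self.values)):
                raise ValueError("label map values must be integers")
            self.values = self.values.astype(np.uint8)
        super().__post_init__()
        bad = set(np.unique(self.values)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; legend is {LABEL_NAMES}")
        self.values = self.values.astype(np.uint8)

    def mask(self, label: int) -> np.ndarray:
        return self.values == label

    def copy(self) -> "LabelMap":
        return LabelMap(self.values.copy(), self.spacing, self.origin.copy())


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 volume.

    Spacing is taken from the header and must be isotropic (relative spread
    of the three voxel edge lengths at most 1%); files that look like label
    maps (integer dtype) come back as :class:`LabelMap`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D volume, got {img.ndim}D in {path}")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    spread = (zooms.max() - zooms.min()) / zooms.mean()
    if spread > ISOTROPY_RTOL:
        raise ValueError(
            f"anisotropic spacing {tuple(round(z, 4) for z in zooms)} in {path}; "
            "only isotropic volumes are supported"
        )
    # RAS origin from the affine; the data grid is used as stored.
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.integer):
        return LabelMap(data.astype(np.uint8), float(zooms.mean()), origin)
    return Volume(np.asarray(data, dtype=np.float32), float(zooms.mean()), origin)


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume (float32) or LabelMap (uint8) as NIfTI-1."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelMap):
        data = v.values.astype(np.uint8)
    else:
        data = v.values.astype(np.float32)
    affine = np.diag([v.spacing, v.spacing, v.spacing, 1.0])
    affine[:3, 3] = v.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((v.spacing,) * 3)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"config value {name} must be > 0, got {value}")


@dataclass
class PhantomConfig:
    """Parameters of the synthetic posterior-fossa phantom."""

    shape: int = 96                 # cubic grid edge, voxels
    spacing: float = 0.4            # mm, isotropic
    noise_sd: float = 4.0           # additive Gaussian noise, intensity units
    # CISS tissue means: bright CSF, dark flow voids, intermediate soft tissue
    ciss_csf: float = 100.0
    ciss_vessel: float = 25.0
    ciss_brainstem: float = 55.0
    ciss_nerve: float = 70.0
    ciss_rest: float = 28.0
    # TOF tissue means: bright inflowing arteries, suppressed background
    tof_vessel: float = 180.0
    tof_background: float = 25.0
    # flow artifacts: erased flow-void intervals on wide-lumen vessels
    flow_artifact_vessels: tuple[str, ...] = ("BA", "VA-le", "VA-ri")
    flow_gap_mm: tuple[float, float] = (3.0, 8.0)   # interval length range
    flow_severity: float = 1.0      # expected number of gaps per affected vessel
    # pulsation ghosts: periodic replicas of the flow-void signal
    pulsation_amplitude: float = 0.9
    pulsation_period_vox: int = 12
    pulsation_decay: float = 0.5
    pulsation_axis: int = 1
    # true TOF->CISS misalignment bounds (per axis)
    misalign_translation_mm: float = 5.0
    misalign_rotation_deg: float = 10.0
    # geometry
    wide_lumen_mm: float = 1.25     # radius at/above which a vessel is flow-artifact prone
    csf_sleeve_mm: float = 1.2      # perivascular CSF margin around vessels

    def validate(self) -> None:
        if self.shape < 64:
            raise ValueError(f"phantom shape must be >= 64, got {self.shape}")
        for name in ("spacing", "flow_severity" if False else "spacing",):
            pass
        _check_positive("phantom.spacing", self.spacing)
        if self.noise_sd < 0:
            raise ValueError("phantom.noise_sd must be >= 0")
        if self.pulsation_amplitude < 0:
            raise ValueError("phantom.pulsation_amplitude must be >= 0")
        if self.flow_severity < 0:
            raise ValueError("phantom.flow_severity must be >= 0")
        if self.pulsation_axis not in (0, 1, 2):
            raise ValueError("phantom.pulsation_axis must be 0, 1 or 2")
        lo, hi = self.flow_gap_mm
        if not (0 < lo <= hi):
            raise ValueError(f"phantom.flow_gap_mm must be 0 < lo <= hi, got {self.flow_gap_mm}")
        if self.ciss_csf <= self.ciss_vessel + 3 * self.noise_sd:
            raise ValueError("CISS CSF mean must exceed vessel mean by > 3 noise sd")
        if self.tof_vessel <= self.tof_background + 3 * self.noise_sd:
            raise ValueError("TOF vessel mean must exceed background mean by > 3 noise sd")


@dataclass
class SegmentationConfig:
    csf_tolerance: float = 25.0       # |value - seed mean| band for CSF growth
    brainstem_tolerance: float = 12.0
    tof_tolerance: float = 40.0
    connectivity: int = 6             # 6 or 26
    hole_seal_mm: float = 0.8         # leak-sealing radius for CSF hole filling

    def validate(self) -> None:
        for name in ("csf_tolerance", "brainstem_tolerance", "tof_tolerance"):
            _check_positive(f"segmentation.{name}", getattr(self, name))
        if self.hole_seal_mm < 0:
            raise ValueError("segmentation.hole_seal_mm must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError(f"segmentation.connectivity must be 6 or 26, got {self.connectivity}")


@dataclass
class RegistrationConfig:
    translation_bound_mm: float = 6.0
    rotation_bound_deg: float = 12.0
    prescan_rotation_step_deg: float = 5.0
    prescan_downsample: int = 2
    min_step_mm: float = 0.05
    min_step_deg: float = 0.05
    metric: str = "label_dice"        # or "mutual_information"

    def validate(self) -> None:
        _check_positive("registration.translation_bound_mm", self.translation_bound_mm)
        _check_positive("registration.rotation_bound_deg", self.rotation_bound_deg)
        _check_positive("registration.min_step_mm", self.min_step_mm)
        _check_positive("registration.min_step_deg", self.min_step_deg)
        if self.metric not in ("label_dice", "mutual_information"):
            raise ValueError(f"unknown registration.metric {self.metric!r}")


@dataclass
class InversionConfig:
    source_percentiles: tuple[float, float] = (5.0, 95.0)
    target_percentile: float = 10.0   # CISS CSF-area percentile defining t_hi

    def validate(self) -> None:
        lo, hi = self.source_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"inversion.source_percentiles must satisfy 0 <= lo < hi <= 100")
        if not (0 < self.target_percentile < 100):
            raise ValueError("inversion.target_percentile must be in (0, 100)")


@dataclass
class RenderingConfig:
    image_size: int = 120
    pixel_size_mm: float = 0.4
    step_fraction: float = 0.5        # ray step = step_fraction * spacing
    early_exit_alpha: float = 0.99
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        _check_positive("rendering.image_size", self.image_size)
        _check_positive("rendering.pixel_size_mm", self.pixel_size_mm)
        _check_positive("rendering.step_fraction", self.step_fraction)
        if not 0 < self.early_exit_alpha <= 1:
            raise ValueError("rendering.early_exit_alpha must be in (0, 1]")


@dataclass
class ScoringConfig:
    sample_step_mm: float = 1.0       # centerline arc-length sampling
    low_coverage: float = 0.15        # below this a vessel "can only be guessed"
    gap_threshold_mm: float = 2.0     # minimum gap counting as a flow artifact
    blob_min_voxels: int = 5          # minimum pulsation-blob size
    compression_radius_mm: float = 5.0  # extent of the compression-relevant zone
    lookup_margin_mm: float = 0.2     # radial slack when testing point coverage
    vessel_exclusion_mm: float = 1.6  # perivascular zone ignored by blob counting
    decimal_comma: bool = False       # print means with a decimal comma

    def validate(self) -> None:
        _check_positive("scoring.sample_step_mm", self.sample_step_mm)
        _check_positive("scoring.gap_threshold_mm", self.gap_threshold_mm)
        _check_positive("scoring.compression_radius_mm", self.compression_radius_mm)
        _check_positive("scoring.vessel_exclusion_mm", self.vessel_exclusion_mm)
        if not 0 < self.low_coverage < 1:
            raise ValueError("scoring.low_coverage must be in (0, 1)")
        if self.blob_min_voxels < 1:
            raise ValueError("scoring.blob_min_voxels must be >= 1")


@dataclass
class PipelineConfig:
    """Validated configuration shared by all pipeline stages."""

    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    rendering: RenderingConfig = field(default_factory=RenderingConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    def validate(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError(f"seed must be a non-negative integer, got {self.seed!r}")
        for section in fields(self):
            value = getattr(self, section.name)
            if dataclasses.is_dataclass(value):
                value.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _from_mapping(cls, data: Mapping[str, Any], prefix: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {prefix!r}")
    kwargs = {}
    for key, value in data.items():
        default = known[key].default
        if isinstance(value, list) and isinstance(default, tuple):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML, filling documented defaults.

    An empty (or missing) file yields the defaults; unknown keys and
    out-of-range values raise ``ValueError``. The effective configuration is
    echoed to the log.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    sections = {
        "phantom": PhantomConfig,
        "segmentation": SegmentationConfig,
        "registration": RegistrationConfig,
        "inversion": InversionConfig,
        "rendering": RenderingConfig,
        "scoring": ScoringConfig,
    }
    unknown = set(data) - set(sections) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "seed" in data:
        kwargs["seed"] = data["seed"]
    for name, cls in sections.items():
        if name in data:
            section = data[name] or {}
            if not isinstance(section, Mapping):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _from_mapping(cls, section, name)
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    log.info("effective config: %s", cfg.to_dict())
    return cfg
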