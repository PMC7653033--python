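"""Run configuration: YAML parsing with strict key checking and provenance.

Every pipeline stage reads its tunables from one :class:`RunConfig`;
unspecified fields take the documented defaults and unknown keys are
rejected rather than ignored.  The effective configuration is hashed and
echoed into a provenance sidecar next to every artifact a stage writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .geometry import BeamGeometry


@dataclass(frozen=True)
class ReductionConfig:
    q_bins: int = 200
    phi_bins: int = 180
    q_range_anisotropy: tuple[float, float] = (0.2, 0.5)   # nm⁻¹


@dataclass(frozen=True)
class FitBlock:
    sigma: float = 0.034
    a_bounds: tuple[float, float] = (30.0, 45.0)
    window: tuple[float, float] = (0.15, 0.60)
    poisson_weights: bool = False
    conventional_width: bool = False


@dataclass(frozen=True)
class SegmentationConfig:
    k: int = 3
    seed: int = 0
    threshold: float = 46.0
    min_region_px: int = 4


@dataclass(frozen=True)
class ShgConfig:
    angles: tuple[float, float] = (5.0, 20.0)   # (narrow, wide), degrees
    band: tuple[float, float] | None = None     # cycles/px; None = default
    window: bool = True
    crop: int = 512


@dataclass(frozen=True)
class SimulateConfig:
    grid: tuple[int, int] = (16, 16)
    scenario: str = "sham"
    ring_delta: float = 2.0
    n_empty: int = 20
    poisson: bool = True


@dataclass(frozen=True)
class RunConfig:
    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    fit: FitBlock = field(default_factory=FitBlock)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    shg: ShgConfig = field(default_factory=ShgConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)


_GEOMETRY_KEYS = {
    "energy_keV": "photon_energy",
    "flux": "flux_i0",
    "exposure_s": "exposure_tau",
    "mu_rho_cm2_g": "mass_abs_coeff",
    "distance_mm": "detector_distance",
    "pixel_um": "pixel_size",
}


def _build(cls, block: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in {context} block: {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name in block:
            v = block[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def _build_geometry(block: dict) -> BeamGeometry:
    mapped = {}
    for key, value in block.items():
        if key in _GEOMETRY_KEYS:
            mapped[_GEOMETRY_KEYS[key]] = value
        elif key == "fwhm_um":
            mapped["beam_fwhm_h"], mapped["beam_fwhm_v"] = value
        elif key == "center_px":
            mapped["beam_center"] = tuple(value)
        elif key == "shape_px":
            mapped["detector_shape"] = tuple(int(v) for v in value)
        else:
            raise ValueError(f"unknown key in geometry block: {key!r}")
    return BeamGeometry(**mapped)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; missing blocks take defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    builders = {
        "geometry": _build_geometry,
        "reduction": lambda b: _build(ReductionConfig, b, "reduction"),
        "fit": lambda b: _build(FitBlock, b, "fit"),
        "segmentation": lambda b: _build(SegmentationConfig, b, "segmentation"),
        "shg": lambda b: _build(ShgConfig, b, "shg"),
        "simulate": lambda b: _build(SimulateConfig, b, "simulate"),
    }
    unknown = set(raw) - set(builders)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {name: builder(raw[name]) for name, builder in builders.items()
              if name in raw}
    return RunConfig(**kwargs)


def config_dict(config: RunConfig) -> dict:
    """JSON-serializable view of the effective configuration."""
    return json.loads(json.dumps(dataclasses.asdict(config)))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    payload = json.dumps(config_dict(config), sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def write_provenance(artifact_path: str | Path, stage: str,
                     config: RunConfig) -> None:
    """Write ``<artifact>.provenance.json`` beside an output file."""
    path = Path(artifact_path)
    sidecar = {
        "stage": stage,
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config_dict(config),
        "peak_intensity_unit": "counts per exposure",
    }
    path.with_suffix(path.suffix + ".provenance.json").write_text(
        json.dumps(sidecar, indent=2))
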