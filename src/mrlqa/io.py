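"""File formats, configuration schema and QA reports.

Conventions stated once and used everywhere: pixel coordinates are 0-based
with (0, 0) at the image top-left; physical coordinates are millimetres
with the origin at the central pixel.  Portal images travel as 16-bit TIFF
(or DICOM) plus a YAML sidecar carrying acquisition geometry and, for
simulator output, the ground truth; dose grids travel as delimited text
with a three-line header.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .gamma import DoseGrid
from .geometry import GantryAngle, MachineGeometry, PortalImage

__all__ = [
    "QAConfig", "QAReport",
    "read_portal_image", "write_portal_image",
    "read_dose_grid", "write_dose_grid",
    "load_config",
]


# ---------------------------------------------------------------------------
# Configuration (validated YAML)
# ---------------------------------------------------------------------------

class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sad_cm: float = 143.5
    sid_cm: float = 265.0
    pixel_pitch_mm: float = 0.4
    panel_extent_cm: tuple[float, float] = (22.0, 9.5)
    central_pixel_uv: tuple[float, float] = (0.0, 0.0)

    def build(self) -> MachineGeometry:
        return MachineGeometry(
            sad_cm=self.sad_cm, sid_cm=self.sid_cm,
            pixel_pitch_mm=self.pixel_pitch_mm,
            panel_extent_cm=tuple(self.panel_extent_cm),
            central_pixel_uv=tuple(self.central_pixel_uv))


class GammaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dose_diff_pct: float = 2.0
    dta_mm: float = 2.0
    normalization: str = "local"
    suppression_pct: float = 10.0


class ChamberConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_dw: Optional[float] = None
    c_b: float = 0.995
    k_bq: Optional[float] = 0.992
    serial: Optional[str] = None


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    excluded_angles: list[float] = Field(default_factory=lambda: [10.0, 20.0, 60.0, 300.0])
    isocentre_tolerance_mm: float = 1.00
    gantry_tolerance_deg: float = 0.3


class QAConfig(BaseModel):
    """Top-level validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    gamma: GammaConfig = Field(default_factory=GammaConfig)
    chamber: ChamberConfig = Field(default_factory=ChamberConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    output_dir: str = "."
    seed: int = 0

    @field_validator("seed")
    @classmethod
    def _seed_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be >= 0")
        return v


def load_config(path: str | Path | None) -> QAConfig:
    """Load and validate a YAML configuration (defaults when path is None)."""
    if path is None:
        return QAConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return QAConfig.model_validate(data)


# ---------------------------------------------------------------------------
# QA reports
# ---------------------------------------------------------------------------

@dataclass
class QAReport:
    """A serialisable record of one analysis run."""

    test_name: str
    parameters: dict[str, Any]
    results: dict[str, Any]
    passed: Optional[bool] = None
    tolerance: Optional[dict[str, Any]] = None
    inputs_digest: Optional[str] = None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    software_version: str = ""

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__
            self.software_version = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QAReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Portal images: 16-bit TIFF / DICOM + YAML sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_portal_image(image: PortalImage, path: str | Path) -> Path:
    """Write a portal image as 16-bit TIFF with a YAML sidecar holding the
    acquisition geometry and any simulator ground truth."""
    import tifffile

    path = Path(path)
    pixels = image.pixels
    if pixels.dtype != np.uint16:
        pixels = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pixels)
    g = image.geometry
    meta = {
        "gantry_angle_deg": image.angle.degrees,
        "sad_cm": g.sad_cm,
        "sid_cm": g.sid_cm,
        "pixel_pitch_mm": g.pixel_pitch_mm,
        "panel_extent_cm": list(g.panel_extent_cm),
        "central_pixel_uv": list(image.central_pixel_uv),
        "metadata": _to_plain(image.metadata),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def _to_plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_portal_image(path: str | Path,
                      config: QAConfig | None = None) -> PortalImage:
    """Read a portal image from DICOM or 8/16-bit grayscale TIFF/PNG.

    Geometry metadata comes from DICOM tags or the YAML sidecar written
    alongside simulator output; anything missing must be supplied through
    ``config`` (an explicit error names the missing quantity).  RGB input
    is rejected — portal frames are single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    meta: dict[str, Any] = {}

    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array
        if "GantryAngle" in ds:
            meta["gantry_angle_deg"] = float(ds.GantryAngle)
        if "ImagePlanePixelSpacing" in ds:
            meta["pixel_pitch_mm"] = float(ds.ImagePlanePixelSpacing[0])
        elif "PixelSpacing" in ds:
            meta["pixel_pitch_mm"] = float(ds.PixelSpacing[0])
        if "RadiationMachineSAD" in ds:
            meta["sad_cm"] = float(ds.RadiationMachineSAD) / 10.0
        if "RTImageSID" in ds:
            meta["sid_cm"] = float(ds.RTImageSID) / 10.0
    else:
        if suffix in (".tif", ".tiff"):
            import tifffile

            pixels = tifffile.imread(path)
        elif suffix == ".png":
            from PIL import Image as PILImage

            pixels = np.asarray(PILImage.open(path))
        else:
            raise ValueError(f"unsupported portal image format: {suffix}")

    if pixels.ndim == 3:
        raise ValueError(
            "multi-channel (RGB) input is not a portal image; convert to "
            "single-channel grayscale first")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = {**meta, **(yaml.safe_load(sidecar.read_text()) or {})}

    cfg_geom = (config.geometry if config is not None else None)

    def resolve(key: str, cfg_val: Any) -> Any:
        if key in meta:
            return meta[key]
        if cfg_val is not None:
            return cfg_val
        raise ValueError(
            f"missing {key.replace('_', ' ')}: not in the image metadata/"
            f"sidecar and no configuration supplied")

    pitch = resolve("pixel_pitch_mm", cfg_geom.pixel_pitch_mm if cfg_geom else None)
    sad = resolve("sad_cm", cfg_geom.sad_cm if cfg_geom else None)
    sid = resolve("sid_cm", cfg_geom.sid_cm if cfg_geom else None)
    angle = resolve("gantry_angle_deg", None)  # angle has no config fallback
    extent = meta.get("panel_extent_cm",
                      list(cfg_geom.panel_extent_cm) if cfg_geom else [22.0, 9.5])
    nv, nu = pixels.shape
    central = meta.get("central_pixel_uv", [(nu - 1) / 2.0, (nv - 1) / 2.0])

    geom = MachineGeometry(sad_cm=sad, sid_cm=sid, pixel_pitch_mm=pitch,
                           panel_extent_cm=tuple(extent))
    return PortalImage(pixels=pixels, angle=GantryAngle(angle), geometry=geom,
                       central_pixel_uv=tuple(central),
                       metadata=meta.get("metadata", {}))


# ---------------------------------------------------------------------------
# Dose grids: delimited text with a 3-line header
# ---------------------------------------------------------------------------

def write_dose_grid(grid: DoseGrid, path: str | Path) -> Path:
    """Write a dose grid as delimited text.  Header lines:

        # nx <int> ny <int>
        # spacing_mm <sx> <sy>
        # origin_mm <ox> <oy>

    followed by ny rows of nx tab-separated doses (%.6g)."""
    path = Path(path)
    ny, nx = grid.values.shape
    lines = [
        f"# nx {nx} ny {ny}",
        f"# spacing_mm {grid.spacing_mm[0]:.6g} {grid.spacing_mm[1]:.6g}",
        f"# origin_mm {grid.origin_mm[0]:.6g} {grid.origin_mm[1]:.6g}",
    ]
    for row in grid.values:
        lines.append("\t".join(f"{v:.6g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_dose_grid(path: str | Path) -> DoseGrid:
    """Read the delimited-text dose-grid format (see :func:`write_dose_grid`).

    Malformed headers or a header/data size mismatch raise ``ValueError``
    with the offending line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 4:
        raise ValueError(f"{path}: truncated dose grid (< 4 lines)")

    def header(i: int, key: str) -> list[str]:
        parts = lines[i].split()
        if len(parts) < 2 or parts[0] != "#":
            raise ValueError(f"{path}:{i + 1}: expected '# {key} ...' header")
        if parts[1] != key:
            raise ValueError(f"{path}:{i + 1}: expected header key {key!r}, "
                             f"got {parts[1]!r}")
        return parts[2:]

    p0 = header(0, "nx")
    if len(p0) != 3 or p0[1] != "ny":
        raise ValueError(f"{path}:1: expected '# nx <int> ny <int>'")
    nx, ny = int(p0[0]), int(p0[2])
    sx, sy = (float(v) for v in header(1, "spacing_mm"))
    ox, oy = (float(v) for v in header(2, "origin_mm"))

    data = []
    for i, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        row = [float(v) for v in line.split()]
        if len(row) != nx:
            raise ValueError(f"{path}:{i}: expected {nx} values, got {len(row)}")
        data.append(row)
    if len(data) != ny:
        raise ValueError(f"{path}: header promises ny={ny} rows, found {len(data)}")
    return DoseGrid(np.array(data), (sx, sy), (ox, oy))
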