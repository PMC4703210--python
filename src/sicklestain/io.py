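"""File-format plumbing: images, CSV tables, config files, provenance.

Images are 8-bit RGB PNG/TIFF/JPEG read and written through Pillow.  Tables
are plain CSV with declared headers.  Configuration round-trips through
JSON or YAML with an explicit schema version so pinned thresholds and
calibrations stay reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .classify import CalibrationModel, Thresholds
from .errors import FormatError
from .imaging import DetectionConfig, GeometryConfig, StainImage

SCHEMA_VERSION = 1


def read_image(path: str | Path, dpi: float | None = None) -> StainImage:
    """Load a raster image as a StainImage.

    ``dpi`` overrides any resolution stored in the file; when neither is
    available a :class:`FormatError` is raised because pixel-to-mm scale is
    required for index computation.
    """
    path = Path(path)
    with Image.open(path) as im:
        file_dpi = im.info.get("dpi")
        rgb = im.convert("RGB")
        pixels = np.asarray(rgb, dtype=np.uint8)
    if dpi is None:
        if not file_dpi or not file_dpi[0]:
            raise FormatError(f"{path.name}: no DPI in file and none supplied")
        dpi = float(file_dpi[0])
    return StainImage(pixels=pixels, dpi=dpi, source_id=path.name)


def write_image(image: StainImage, path: str | Path) -> None:
    """Write a StainImage as an 8-bit RGB file with its DPI embedded."""
    Image.fromarray(image.pixels, mode="RGB").save(
        Path(path), dpi=(image.dpi, image.dpi)
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Shared configuration of a reproducible run.

    Bundles the detection/geometry parameters, optional pinned thresholds
    and calibration, the CI convention for reports, and the run seed.
    """

    dpi: float = 300.0
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)
    thresholds: Thresholds | None = None
    calibration: CalibrationModel | None = None
    ci_convention: str = "total_n"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "schema_version": SCHEMA_VERSION,
            "dpi": self.dpi,
            "detection": dataclasses.asdict(self.detection),
            "ci_convention": self.ci_convention,
            "seed": self.seed,
        }
        d["thresholds"] = (
            dataclasses.asdict(self.thresholds) if self.thresholds else None
        )
        d["calibration"] = (
            dataclasses.asdict(self.calibration) if self.calibration else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise FormatError(f"unsupported config schema version {version}")
        det = d.get("detection") or {}
        geom = det.pop("geometry_config", None)
        detection = DetectionConfig(
            **det, **({"geometry_config": GeometryConfig(**geom)} if geom else {})
        )
        thresholds = Thresholds(**d["thresholds"]) if d.get("thresholds") else None
        calibration = (
            CalibrationModel(**d["calibration"]) if d.get("calibration") else None
        )
        return cls(
            dpi=d.get("dpi", 300.0),
            detection=detection,
            thresholds=thresholds,
            calibration=calibration,
            ci_convention=d.get("ci_convention", "total_n"),
            seed=d.get("seed", 0),
        )

    def hash(self) -> str:
        """Stable short hash of the canonical JSON form, for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path.name}: config must be a mapping")
    return RunConfig.from_dict(data)


def provenance_block(config: RunConfig) -> str:
    """Plain-text provenance header written into every report."""
    from . import __version__

    return (
        f"# sicklestain {__version__}\n"
        f"# config_hash: {config.hash()}\n"
        f"# seed: {config.seed}\n"
    )


__all__ = [
    "RunConfig",
    "SCHEMA_VERSION",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "save_config",
    "load_config",
    "provenance_block",
]
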