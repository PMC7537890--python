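"""Minimal single-band raster container and TIFF I/O.

Grids are row-major numpy arrays, origin top-left, 0-based row/column
coordinates.  Every layer in one analysis shares the same shape and
resolution; reprojection is out of scope and mismatched grids are an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

NODATA = -9999.0


@dataclass
class RasterLayer:
    """One named 2-D grid with resolution (km per pixel) and nodata semantics."""

    name: str
    data: np.ndarray
    resolution_km: float = 1.0
    nodata: float = NODATA
    crs: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError(f"raster {self.name!r} must be a non-empty 2-D grid")
        if self.resolution_km <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_area_km2(self) -> float:
        return self.resolution_km**2

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return self.data != self.nodata

    def values(self) -> np.ndarray:
        """Flat array of valid cell values, row-major."""
        return self.data[self.mask()]

    def like(self, data: np.ndarray, name: str | None = None,
             resolution_km: float | None = None) -> "RasterLayer":
        return RasterLayer(
            name=name or self.name,
            data=data,
            resolution_km=resolution_km or self.resolution_km,
            nodata=self.nodata,
            crs=self.crs,
        )


def write_raster(layer: RasterLayer, path: str | Path) -> Path:
    """Write a layer as single-band float32 TIFF plus a JSON geo-sidecar.

    The sidecar (``<path>.json``) records resolution, nodata and CRS so a
    round trip preserves the full layer contract.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    res_ppkm = 1.0 / layer.resolution_km
    tifffile.imwrite(
        path,
        layer.data.astype(np.float32),
        resolution=(res_ppkm, res_ppkm),
        metadata=None,
    )
    sidecar = {
        "name": layer.name,
        "resolution_km": layer.resolution_km,
        "nodata": layer.nodata,
        "crs": layer.crs,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_raster(path: str | Path) -> RasterLayer:
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return RasterLayer(
        name=meta.get("name", path.stem),
        data=data,
        resolution_km=meta.get("resolution_km", 1.0),
        nodata=meta.get("nodata", NODATA),
        crs=meta.get("crs"),
    )


def assert_same_grid(*layers: RasterLayer) -> None:
    ref = layers[0]
    for layer in layers[1:]:
        if layer.shape != ref.shape or layer.resolution_km != ref.resolution_km:
            raise ValueError(
                f"grid mismatch: {layer.name!r} {layer.shape}@{layer.resolution_km} "
                f"vs {ref.name!r} {ref.shape}@{ref.resolution_km}"
            )
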