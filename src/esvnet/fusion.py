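"""Spatial fusion of rasters and city-level statistical totals.

City totals are spread over the grid dasymetrically: each statistical
indicator has an ancillary weighting raster (e.g. industrial land area for
industrial electricity consumption) and the allocated value in a unit is

    Af_i = As_i * wf_i / ws_i

where As_i is the city total of indicator i, wf_i the weighting value in
the unit and ws_i the city total of the weighting factor.  Allocation is
mass-conserving by construction.  1 km layers are then aggregated to the
2x2 km analysis grid (sum for extensive variables, mean for intensive
ones), land-use areas are converted to percentages of the unit area, and
every column is z-scored into a :class:`~esvnet.table.SampleTable`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .raster import RasterLayer, assert_same_grid
from .table import (FACTOR_CODES, LANDUSE_PERCENT_CODES, RESPONSE, SampleTable)
from .synth import LANDUSE_AREA_RASTERS, RASTER_FACTORS


@dataclass(frozen=True)
class AllocationSpec:
    """Pairing of one statistical indicator with its weighting raster."""

    indicator_code: str
    weighting_layer: str


#: the 13 statistical indicators and their weighting layers: industry
#: outputs follow the land-use class that hosts the activity, tourism
#: follows the nighttime-light (prosperity) surface, and total electricity /
#: water consumption follow population.
DEFAULT_ALLOCATION: tuple[AllocationSpec, ...] = (
    AllocationSpec("A4", "cultivated_area"),
    AllocationSpec("A5", "industrial_area"),
    AllocationSpec("A6", "residential_area"),
    AllocationSpec("A7", "construction_area"),
    AllocationSpec("A8", "light_index"),
    AllocationSpec("C1", "population"),
    AllocationSpec("C2", "cultivated_area"),
    AllocationSpec("C3", "industrial_area"),
    AllocationSpec("C4", "residential_area"),
    AllocationSpec("C5", "population"),
    AllocationSpec("C6", "cultivated_area"),
    AllocationSpec("C7", "industrial_area"),
    AllocationSpec("C8", "residential_area"),
)

#: intensive factors aggregated by block mean rather than sum
INTENSIVE_FACTORS = {"A3", "B1"}


class AllocationError(ValueError):
    pass


def allocate(total: float, weights: RasterLayer) -> RasterLayer:
    """Spread a city total over the grid proportionally to a weighting layer."""
    w = weights.data
    if np.any(w[weights.mask()] < 0):
        raise AllocationError(f"negative weights in {weights.name!r}")
    valid = weights.mask()
    ws = w[valid].sum()
    if ws <= 0:
        raise AllocationError(
            f"cannot allocate over {weights.name!r}: weights sum to zero")
    out = np.where(valid, total * w / ws, weights.nodata)
    return weights.like(out, name=f"allocated[{weights.name}]")


def aggregate(raster: RasterLayer, block: int, mode: str = "sum") -> RasterLayer:
    """Aggregate block x block cells into one analysis unit.

    ``mode='sum'`` for extensive variables (areas, ESV, allocated totals) —
    conserves the global total; ``mode='mean'`` for intensive ones (NDVI,
    light index).  Partial edge blocks aggregate the cells they have, so
    boundary units are kept rather than dropped.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    data = raster.data
    rows, cols = data.shape
    out_rows = -(-rows // block)
    out_cols = -(-cols // block)
    padded = np.full((out_rows * block, out_cols * block), np.nan)
    padded[:rows, :cols] = np.where(raster.mask(), data, np.nan)
    blocks = padded.reshape(out_rows, block, out_cols, block).swapaxes(1, 2)
    with np.errstate(invalid="ignore"):
        if mode == "sum":
            agg = np.nansum(blocks, axis=(2, 3))
            all_nan = np.isnan(blocks).all(axis=(2, 3))
            agg[all_nan] = raster.nodata
        else:
            agg = np.nanmean(blocks, axis=(2, 3))
            agg = np.where(np.isnan(agg), raster.nodata, agg)
    return raster.like(agg, resolution_km=raster.resolution_km * block)


def landuse_percent(area: RasterLayer, cell_area: float | None = None,
                    tol: float = 1e-6) -> RasterLayer:
    """Convert a land-use area layer to the percentage of its cell area."""
    cell_area = cell_area if cell_area is not None else area.cell_area_km2
    data = area.data
    valid = area.mask()
    if np.any(data[valid] < -tol) or np.any(data[valid] > cell_area * (1 + tol)):
        raise ValueError(f"{area.name!r} has areas outside [0, cell area]")
    pct = np.where(valid, np.clip(100.0 * data / cell_area, 0.0, 100.0),
                   area.nodata)
    return area.like(pct, name=area.name.replace("_area", "_pct"))


def build_sample_table(
    rasters: dict[str, RasterLayer],
    totals: dict[str, float],
    allocation: tuple[AllocationSpec, ...] = DEFAULT_ALLOCATION,
    block: int = 2,
    standardize_percent: bool = True,
) -> SampleTable:
    """Fuse rasters + totals into the n-units x 23-factors sample table.

    Statistical indicators are allocated at the native resolution, all
    extensive layers are block-summed to the analysis grid, land-use areas
    become percentages of the unit area, and every column is z-scored with
    the scaling parameters stored for later destandardization.
    """
    assert_same_grid(*rasters.values())
    alloc_by_code = {a.indicator_code: a for a in allocation}
    columns: dict[str, np.ndarray] = {}

    for code in FACTOR_CODES:
        if code in RASTER_FACTORS:
            layer = rasters[RASTER_FACTORS[code]]
            mode = "mean" if code in INTENSIVE_FACTORS else "sum"
            columns[code] = aggregate(layer, block, mode).values()
        elif code in LANDUSE_AREA_RASTERS:
            agg = aggregate(rasters[LANDUSE_AREA_RASTERS[code]], block, "sum")
            columns[code] = landuse_percent(agg).values()
        else:
            if code not in alloc_by_code:
                raise AllocationError(f"no weighting layer configured for {code}")
            if code not in totals:
                raise AllocationError(f"no city total provided for {code}")
            spec = alloc_by_code[code]
            if spec.weighting_layer not in rasters:
                raise AllocationError(
                    f"weighting layer {spec.weighting_layer!r} missing for {code}")
            allocated = allocate(totals[code], rasters[spec.weighting_layer])
            columns[code] = aggregate(allocated, block, "sum").values()

    columns[RESPONSE] = aggregate(rasters["esv"], block, "sum").values()
    lengths = {len(v) for v in columns.values()}
    if len(lengths) != 1:
        raise ValueError("factor columns have inconsistent unit counts")
    raw = pd.DataFrame(columns)
    return SampleTable.from_raw(raw, percent_columns=LANDUSE_PERCENT_CODES,
                                standardize_percent=standardize_percent)


# ---------------------------------------------------------------------------
# allocation-spec I/O
# ---------------------------------------------------------------------------

def save_allocation(allocation: tuple[AllocationSpec, ...],
                    path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {"indicator": a.indicator_code, "weighting_layer": a.weighting_layer}
        for a in allocation
    ]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_allocation(path: str | Path) -> tuple[AllocationSpec, ...]:
    payload = yaml.safe_load(Path(path).read_text())
    return tuple(
        AllocationSpec(item["indicator"], item["weighting_layer"])
        for item in payload
    )
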