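"""Factor/response sample table with recorded standardization parameters.

The analysis operates on n grid units x 23 socioeconomic factors plus one
ecosystem-service-value (ESV) response.  Factors follow the three-block
coding used throughout: growth quality A1-A8, ecological protection B1-B7,
resource utilization C1-C8.  Columns are z-scored (standard-deviation
standardization) and the per-column mean/SD are stored so sweeps and
extrema can be reported back in original units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical factor codes, in reporting order
FACTOR_CODES: tuple[str, ...] = (
    "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8",
    "B1", "B2", "B3", "B4", "B5", "B6", "B7",
    "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8",
)

FACTOR_NAMES: dict[str, str] = {
    "A1": "GDP (million CNY)",
    "A2": "Population (person)",
    "A3": "Light index",
    "A4": "1st industry output value (million CNY)",
    "A5": "2nd industry output value (million CNY)",
    "A6": "3rd industry output value (million CNY)",
    "A7": "Construction industry output value (million CNY)",
    "A8": "Tourism output value (million CNY)",
    "B1": "NDVI",
    "B2": "Cultivated area (%)",
    "B3": "Woodland area (%)",
    "B4": "Grassland area (%)",
    "B5": "Water area (%)",
    "B6": "Construction land area (%)",
    "B7": "Unused land area (%)",
    "C1": "Electrical consumption (kw)",
    "C2": "Agricultural electricity consumption (kw)",
    "C3": "Industrial electricity consumption (kw)",
    "C4": "Residential electricity consumption (kw)",
    "C5": "Water consumption (kt)",
    "C6": "Agricultural water consumption (kt)",
    "C7": "Industrial water consumption (kt)",
    "C8": "Residential water consumption (kt)",
}

#: land-use structure factors expressed as area proportions 0-100 %
LANDUSE_PERCENT_CODES: tuple[str, ...] = ("B2", "B3", "B4", "B5", "B6", "B7")

RESPONSE = "Y"


class StandardizationError(ValueError):
    """A column cannot be z-scored (zero spread or missing values)."""


@dataclass
class SampleTable:
    """Standardized factor matrix + ESV response with inverse-transform state.

    ``data`` holds the model-ready (standardized) columns; ``mean``/``sd``
    map every column (including ``Y``) to its original-unit center/spread so
    ``destandardize`` is an exact inverse.  Columns listed in
    ``percent_columns`` are land-use percentages; when
    ``percent_standardized`` is False they were left on the 0-100 scale and
    their mean/sd are identity parameters (0, 1).
    """

    data: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]
    percent_columns: tuple[str, ...] = LANDUSE_PERCENT_CODES
    percent_standardized: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in list(self.codes) + [RESPONSE] if c not in self.data]
        if missing:
            raise ValueError(f"table is missing columns {missing}")
        if self.data.isna().any().any():
            raise StandardizationError("table contains missing values")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_raw(
        cls,
        raw: pd.DataFrame,
        percent_columns: tuple[str, ...] = LANDUSE_PERCENT_CODES,
        standardize_percent: bool = True,
    ) -> "SampleTable":
        """Z-score every column of a raw (original-units) table.

        Percentage columns must lie in [0, 100]; with
        ``standardize_percent=False`` they are passed through unscaled.
        Constant columns raise :class:`StandardizationError` — a factor with
        zero spread cannot enter the sweep analysis.
        """
        if raw.isna().any().any():
            raise StandardizationError("raw table contains missing values")
        for code in percent_columns:
            col = raw[code].to_numpy()
            if col.min() < -1e-9 or col.max() > 100 + 1e-9:
                raise ValueError(f"percentage column {code} outside [0, 100]")
        data = {}
        mean: dict[str, float] = {}
        sd: dict[str, float] = {}
        for col in raw.columns:
            x = raw[col].to_numpy(dtype=float)
            if col in percent_columns and not standardize_percent:
                mean[col], sd[col] = 0.0, 1.0
                data[col] = x
                continue
            m, s = float(x.mean()), float(x.std())
            if s == 0.0:
                raise StandardizationError(f"column {col} is constant (zero SD)")
            mean[col], sd[col] = m, s
            data[col] = (x - m) / s
        return cls(
            data=pd.DataFrame(data, index=raw.index),
            mean=mean,
            sd=sd,
            percent_columns=tuple(percent_columns),
            percent_standardized=standardize_percent,
        )

    # -- views -------------------------------------------------------------

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c != RESPONSE)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def X(self) -> np.ndarray:
        return self.data[list(self.codes)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data[RESPONSE].to_numpy(dtype=float)

    def column(self, code: str) -> np.ndarray:
        return self.data[code].to_numpy(dtype=float)

    def factor_means(self) -> np.ndarray:
        return self.X.mean(axis=0)

    # -- transforms --------------------------------------------------------

    def destandardize(self, code: str, value):
        """Map a model-scale value of one column back to original units."""
        return np.asarray(value, dtype=float) * self.sd[code] + self.mean[code]

    def standardize_value(self, code: str, value):
        return (np.asarray(value, dtype=float) - self.mean[code]) / self.sd[code]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """CSV of the model-ready table + JSON sidecar of scaling parameters."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path, index_label="unit")
        sidecar = {
            "mean": self.mean,
            "sd": self.sd,
            "percent_columns": list(self.percent_columns),
            "percent_standardized": self.percent_standardized,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SampleTable":
        path = Path(path)
        data = pd.read_csv(path, index_col="unit")
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            mean=meta["mean"],
            sd=meta["sd"],
            percent_columns=tuple(meta["percent_columns"]),
            percent_standardized=meta["percent_standardized"],
        )
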