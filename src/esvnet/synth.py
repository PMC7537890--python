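"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Two modes:

* **landscape** — emulates the real data model: spatially autocorrelated
  land-use fraction fields on a 1 km grid, population / nighttime-light /
  NDVI / GDP surfaces, city-level statistical totals to be allocated by
  weighting layers, and a ground-truth ESV surface built from land-use
  value coefficients (equivalent-factor idea: each unit of land area
  provides services at a class-specific value density) plus Gaussian noise.

* **oracle** — a factor table whose response is a known sum of closed-form
  single-factor effects (linear / quadratic), shipped with a
  machine-readable truth record so recovery tests need no re-derivation.

All randomness flows through one integer seed; identical (config, seed)
pairs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import RasterLayer
from .table import FACTOR_CODES, LANDUSE_PERCENT_CODES, RESPONSE, SampleTable

LANDUSE_CLASSES: tuple[str, ...] = (
    "cultivated", "woodland", "grassland", "water", "construction", "unused",
)

#: value density per land class (currency per km^2, arbitrary units).
#: Ranking water > woodland > grassland > cultivated > unused > construction
#: mirrors the sign structure the analysis expects to recover.
DEFAULT_ESV_COEFFICIENTS: dict[str, float] = {
    "water": 250.0,
    "woodland": 180.0,
    "grassland": 120.0,
    "cultivated": 60.0,
    "unused": 20.0,
    "construction": 5.0,
}

#: city totals for the statistical (non-raster) indicators; magnitudes are
#: plausible for a megacity of a few thousand km^2 and are configurable.
DEFAULT_CITY_TOTALS: dict[str, float] = {
    "A4": 2.0e4,    # 1st industry output (million CNY)
    "A5": 3.0e6,    # 2nd industry output
    "A6": 9.0e5,    # 3rd industry output
    "A7": 9.0e4,    # construction industry output
    "A8": 4.0e4,    # tourism output
    "C1": 5.0e5,    # electrical consumption (kw)
    "C2": 2.0e2,    # agricultural electricity
    "C3": 4.0e5,    # industrial electricity
    "C4": 1.0e4,    # residential electricity
    "C5": 3.5e4,    # water consumption (kt)
    "C6": 1.2e3,    # agricultural water
    "C7": 2.0e4,    # industrial water
    "C8": 1.0e4,    # residential water
}

RASTER_FACTORS: dict[str, str] = {
    "A1": "gdp", "A2": "population", "A3": "light_index", "B1": "ndvi",
}

LANDUSE_AREA_RASTERS: dict[str, str] = {
    "B2": "cultivated_area", "B3": "woodland_area", "B4": "grassland_area",
    "B5": "water_area", "B6": "construction_area", "B7": "unused_area",
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic city.

    ``grid_shape`` is in 1 km cells; the default 64x64 yields 1024 analysis
    units after 2x2 km aggregation, the same order as a real mid-size city.
    ``spatial_corr_length`` (km) controls landscape patchiness;
    ``noise_sd`` is the ESV noise SD as a fraction of the ESV signal SD.
    """

    grid_shape: tuple[int, int] = (64, 64)
    seed: int = 0
    landuse_classes: tuple[str, ...] = LANDUSE_CLASSES
    spatial_corr_length: float = 6.0
    resolution_km: float = 1.0
    esv_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ESV_COEFFICIENTS))
    noise_sd: float = 0.1
    city_totals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CITY_TOTALS))
    softmax_sharpness: float = 3.0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        missing = set(self.landuse_classes) - set(self.esv_coefficients)
        if missing:
            raise ValueError(f"esv_coefficients missing classes {sorted(missing)}")
        if any(v < 0 for v in self.esv_coefficients.values()):
            raise ValueError("esv_coefficients must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spatial_corr_length <= 0:
            raise ValueError("spatial_corr_length must be positive")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  corr_km: float, resolution_km: float) -> np.ndarray:
    """Gaussian random field: white noise smoothed to the correlation length,
    rescaled to zero mean / unit SD."""
    white = rng.standard_normal(shape)
    sigma = corr_km / resolution_km
    f = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_landscape(
    config: SynthConfig,
) -> tuple[dict[str, RasterLayer], dict[str, float]]:
    """Generate the full raster stack + statistical totals of a synthetic city.

    Returns one raster per raster-type index — ESV, GDP, population, light
    index, NDVI, and each land-use area (with construction split into
    industrial and residential sub-areas, required as weighting layers) —
    plus the city-totals table for the statistical indicators.

    Per-cell land-use areas sum exactly to the cell area, and with
    ``noise_sd=0`` the ESV raster equals the coefficient expansion exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    res = config.resolution_km
    cell_area = res**2

    # land-use fractions: one smoothed field per class -> softmax
    fields = np.stack([
        _smooth_field(rng, shape, config.spatial_corr_length, res)
        for _ in config.landuse_classes
    ])
    logits = config.softmax_sharpness * fields
    logits -= logits.max(axis=0, keepdims=True)
    expf = np.exp(logits)
    fractions = expf / expf.sum(axis=0)
    frac = dict(zip(config.landuse_classes, fractions))

    def layer(name: str, data: np.ndarray) -> RasterLayer:
        return RasterLayer(name=name, data=data, resolution_km=res)

    rasters: dict[str, RasterLayer] = {}
    for cls_name in config.landuse_classes:
        rasters[f"{cls_name}_area"] = layer(f"{cls_name}_area",
                                            frac[cls_name] * cell_area)

    # construction splits into industrial / residential by a second field
    split = _sigmoid(1.5 * _smooth_field(rng, shape, config.spatial_corr_length, res))
    rasters["industrial_area"] = layer(
        "industrial_area", split * frac["construction"] * cell_area)
    rasters["residential_area"] = layer(
        "residential_area", (1.0 - split) * frac["construction"] * cell_area)

    # socioeconomic surfaces, correlated with the built-up pattern
    pop_field = _smooth_field(rng, shape, config.spatial_corr_length, res)
    population = 4.0e4 * (frac["construction"] + 0.02) * np.exp(0.5 * pop_field)
    rasters["population"] = layer("population", population)

    light_noise = _smooth_field(rng, shape, config.spatial_corr_length / 2, res)
    light = 63.0 * np.clip(
        0.85 * frac["construction"] + 0.10 * _sigmoid(light_noise) + 0.05, 0, 1)
    rasters["light_index"] = layer("light_index", light)

    vegetation = frac["cultivated"] + frac["woodland"] + frac["grassland"]
    ndvi_noise = _smooth_field(rng, shape, config.spatial_corr_length / 2, res)
    ndvi = np.clip(0.8 * vegetation + 0.05 * ndvi_noise + 0.05, -0.1, 0.95)
    rasters["ndvi"] = layer("ndvi", ndvi)

    gdp_field = _smooth_field(rng, shape, config.spatial_corr_length, res)
    gdp = 50.0 * (0.6 * light / 63.0 + 0.4 * population / population.max()
                  + 0.05 * np.exp(0.3 * gdp_field))
    rasters["gdp"] = layer("gdp", gdp)

    # ground-truth ESV = sum over classes of area x value coefficient + noise
    signal = sum(
        config.esv_coefficients[c] * frac[c] * cell_area
        for c in config.landuse_classes
    )
    signal = np.asarray(signal, dtype=float)
    if config.noise_sd > 0:
        noise = config.noise_sd * signal.std() * rng.standard_normal(shape)
    else:
        noise = 0.0
    rasters["esv"] = layer("esv", signal + noise)

    return rasters, dict(config.city_totals)


# ---------------------------------------------------------------------------
# oracle mode
# ---------------------------------------------------------------------------

SHAPE_TAGS = (
    "monotone_increasing", "monotone_decreasing", "u_shaped", "inverted_u", "null",
)


@dataclass
class Effect:
    """One planted single-factor effect on the response."""

    shape: str
    amplitude: float = 1.0
    vertex: float = 0.0  # quadratic vertex, on the standardized factor scale

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_TAGS:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        a, v = self.amplitude, self.vertex
        if self.shape == "monotone_increasing":
            return a * x
        if self.shape == "monotone_decreasing":
            return -a * x
        if self.shape == "u_shaped":
            return a * 0.5 * (x - v) ** 2
        if self.shape == "inverted_u":
            return -a * 0.5 * (x - v) ** 2
        return np.zeros_like(x)


@dataclass
class OracleSpec:
    """Ground-truth specification for recovery tests.

    ``effects`` maps factor codes to planted effects; unlisted factors are
    null.  ``correlation`` is the pairwise (equi-)correlation of the factor
    draws; values in [0, 1) keep the covariance positive definite.
    ``noise_sd`` is the SD of additive Gaussian response noise.
    """

    n: int = 2000
    effects: dict[str, Effect] = field(default_factory=dict)
    correlation: float = 0.0
    noise_sd: float = 0.1
    codes: tuple[str, ...] = FACTOR_CODES

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must lie in [0, 1)")
        unknown = set(self.effects) - set(self.codes)
        if unknown:
            raise ValueError(f"effects reference unknown factors {sorted(unknown)}")


def generate_oracle_table(
    spec: OracleSpec, seed: int,
) -> tuple[SampleTable, dict[str, dict]]:
    """Draw a factor table with known closed-form response structure.

    Y = sum_i f_i(X_i) + eps, f_i from the planted shape family.  Returns the
    standardized table plus a truth record {code: {shape, amplitude, vertex}}
    for every non-null factor.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    p = len(spec.codes)
    if spec.correlation > 0:
        # equicorrelated Gaussians via a shared latent factor
        shared = rng.standard_normal((spec.n, 1))
        own = rng.standard_normal((spec.n, p))
        rho = spec.correlation
        X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    else:
        X = rng.standard_normal((spec.n, p))

    y = np.zeros(spec.n)
    for j, code in enumerate(spec.codes):
        effect = spec.effects.get(code)
        if effect is not None:
            y += effect(X[:, j])
    if spec.noise_sd > 0:
        y = y + spec.noise_sd * rng.standard_normal(spec.n)

    raw = pd.DataFrame(X, columns=list(spec.codes))
    raw[RESPONSE] = y
    # oracle factors are already ~N(0,1); z-scoring keeps the table contract
    table = SampleTable.from_raw(raw, percent_columns=())
    truth = {
        code: {"shape": e.shape, "amplitude": e.amplitude, "vertex": e.vertex}
        for code, e in spec.effects.items()
        if e.shape != "null"
    }
    return table, truth
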