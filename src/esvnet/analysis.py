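"""Model disassembly: single-factor response curves and two-factor surfaces.

The trained surrogate is probed with control-variable sweeps: all factors
but one are held at their sample means while the target factor is sampled
continuously over its *sampling domain* (default: its observed range).
The interval of predicted ESV traced out is the *response domain*; its
width measures the factor's influence intensity and is thresholded into
extremely significant (ES, >= 0.2), significant (S, >= 0.1) and
non-significant (NS) classes.  The curve's trend is then named with a
small taxonomy (monotone increasing/decreasing, U-shaped, inverted
U-shaped, increasing/decreasing with fluctuation), and for U-type curves
the extremum is located and reported in original units.  Pairs of factors
are probed the same way on a 2-D grid to expose coupling (interaction)
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import FACTOR_NAMES, RESPONSE, SampleTable

ES_THRESHOLD = 0.2
S_THRESHOLD = 0.1

SHAPES = (
    "monotone_increasing", "monotone_decreasing", "u_shaped", "inverted_u",
    "increasing_with_fluctuation", "decreasing_with_fluctuation",
)


@dataclass
class AnalysisConfig:
    """Sweep resolution, smoothing, and intensity/shape thresholds.

    ``flat_tol`` treats first differences smaller than this fraction of the
    curve amplitude as flat when naming the shape; ``smooth_window`` is a
    centered moving average (odd width) applied before shape naming.
    """

    es_threshold: float = ES_THRESHOLD
    s_threshold: float = S_THRESHOLD
    sweep_points: int = 201
    smooth_window: int = 5
    flat_tol: float = 0.02
    pair_grid: int = 51

    def validate(self) -> None:
        if not (0 < self.s_threshold < self.es_threshold):
            raise ValueError("need 0 < s_threshold < es_threshold")
        if self.sweep_points < 11:
            raise ValueError("sweep_points must be >= 11")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 1")
        if self.pair_grid < 1:
            raise ValueError("pair_grid must be >= 1")


@dataclass
class ResponseCurve:
    """One factor's sweep: domain, predictions, intensity and shape."""

    factor: str
    sampling_domain: tuple[float, float]
    xs: np.ndarray
    ys: np.ndarray
    range: float
    intensity: str
    shape: str
    zero_range: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.factor: self.xs, RESPONSE: self.ys})


@dataclass
class CouplingSurface:
    """Predicted ESV over a 2-D factor grid, all other factors at means."""

    factors: tuple[str, str]
    xs: np.ndarray
    ys: np.ndarray
    Z: np.ndarray
    argmax: tuple[int, int]

    def max_value(self) -> float:
        return float(self.Z[self.argmax])


def classify_intensity(range_: float,
                       config: AnalysisConfig | None = None) -> str:
    """ES / S / NS by thresholding the response-domain range.

    Boundary convention: thresholds are inclusive upward (a range exactly at
    a threshold takes the stronger class).
    """
    config = config or AnalysisConfig()
    if range_ < 0:
        raise ValueError("range must be non-negative")
    if range_ >= config.es_threshold:
        return "ES"
    if range_ >= config.s_threshold:
        return "S"
    return "NS"


def _moving_average(ys: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return ys.astype(float)
    pad = window // 2
    padded = np.pad(ys.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _monotone_segments(smooth: np.ndarray, tol: float) -> list[float]:
    """Net changes of the curve's monotone runs, small runs merged away.

    The smoothed curve is cut at its turning points into monotone segments;
    any segment whose net change is below ``tol`` (an absolute threshold on
    the response scale) is folded into its neighbours, so wiggle smaller
    than the tolerance never counts as a direction change.
    """
    diffs = np.diff(smooth)
    signs = np.sign(diffs)
    segments: list[float] = []
    for d, s in zip(diffs, signs):
        if segments and np.sign(segments[-1]) == s:
            segments[-1] += d
        else:
            segments.append(float(d))
    # iteratively merge sub-tolerance segments with their neighbours
    while len(segments) > 1:
        k = int(np.argmin(np.abs(segments)))
        if abs(segments[k]) >= tol:
            break
        if k == 0:
            first = segments.pop(0)
            segments[0] += first
        elif k == len(segments) - 1:
            last = segments.pop()
            segments[-1] += last
        else:
            merged = segments[k - 1] + segments[k] + segments[k + 1]
            segments[k - 1:k + 2] = [merged]
        # merging can give adjacent same-sign segments; re-collapse
        collapsed: list[float] = []
        for d in segments:
            if collapsed and np.sign(collapsed[-1]) == np.sign(d):
                collapsed[-1] += d
            else:
                collapsed.append(d)
        segments = collapsed
    return segments


def classify_shape(xs: np.ndarray, ys: np.ndarray,
                   config: AnalysisConfig | None = None) -> str:
    """Name the trend of a response curve.

    Smooth with a centered moving average, split the curve into monotone
    runs, and discard runs whose net rise/fall is below ``flat_tol`` x
    curve amplitude (numerical wiggle).  One remaining run -> monotone by
    its direction; a fall-then-rise pair -> U-shaped; rise-then-fall ->
    inverted U; more runs -> increasing or decreasing with fluctuation by
    the sign of the net change.  An all-flat curve is reported as monotone
    increasing (callers flag zero range).
    """
    config = config or AnalysisConfig()
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 11:
        raise ValueError("need at least 11 sweep points")
    smooth = _moving_average(ys, config.smooth_window)
    amplitude = float(smooth.max() - smooth.min())
    if amplitude == 0.0:
        return "monotone_increasing"
    segments = _monotone_segments(smooth, config.flat_tol * amplitude)
    net = smooth[-1] - smooth[0]
    if len(segments) == 1:
        return ("monotone_increasing" if segments[0] > 0
                else "monotone_decreasing")
    if len(segments) == 2:
        return "u_shaped" if (segments[0] < 0 < segments[1]) else "inverted_u"
    return ("increasing_with_fluctuation" if net >= 0
            else "decreasing_with_fluctuation")


def _baseline_row(table: SampleTable) -> np.ndarray:
    return table.factor_means()


def single_factor_response(
    model, table: SampleTable, factor: str,
    config: AnalysisConfig | None = None,
    domain: tuple[float, float] | None = None,
) -> ResponseCurve:
    """Sweep one factor over its sampling domain, others at sample means.

    ``domain`` overrides the default observed [min, max] (on the sweep
    scale, i.e. the scale the factor column is stored on) to reproduce
    wider report-style domains.
    """
    config = config or AnalysisConfig()
    config.validate()
    codes = table.codes
    if factor not in codes:
        raise KeyError(f"unknown factor {factor!r}")
    j = codes.index(factor)
    col = table.column(factor)
    lo, hi = domain if domain is not None else (float(col.min()), float(col.max()))
    if not (hi > lo):
        raise ValueError(f"degenerate sampling domain for {factor}: [{lo}, {hi}]")
    xs = np.linspace(lo, hi, config.sweep_points)
    X = np.tile(_baseline_row(table), (config.sweep_points, 1))
    X[:, j] = xs
    ys = np.asarray(model.predict(X), dtype=float)
    rng_ = float(ys.max() - ys.min())
    zero_range = rng_ == 0.0
    return ResponseCurve(
        factor=factor,
        sampling_domain=(lo, hi),
        xs=xs,
        ys=ys,
        range=rng_,
        intensity=classify_intensity(rng_, config),
        shape=classify_shape(xs, ys, config),
        zero_range=zero_range,
    )


def find_extremum(curve: ResponseCurve, table: SampleTable,
                  config: AnalysisConfig | None = None
                  ) -> tuple[float, float, bool]:
    """Locate the curve's extremum and report it in original units.

    For U-type shapes returns the interior arg-extremum of the smoothed
    curve; for monotone curves returns the better endpoint with
    ``is_extremum=False``.  Factor and ESV values are destandardized with
    the table's stored scaling parameters.
    """
    config = config or AnalysisConfig()
    smooth = _moving_average(curve.ys, config.smooth_window)
    if curve.shape == "inverted_u":
        i = int(np.argmax(smooth))
        interior = True
    elif curve.shape == "u_shaped":
        i = int(np.argmin(smooth))
        interior = True
    else:
        i = int(np.argmax(smooth))
        interior = False
    x_star = float(table.destandardize(curve.factor, curve.xs[i]))
    y_star = float(table.destandardize(RESPONSE, curve.ys[i]))
    return x_star, y_star, interior


def pair_response_surface(
    model, table: SampleTable, f1: str, f2: str,
    config: AnalysisConfig | None = None,
    domains: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> CouplingSurface:
    """Predicted ESV on a 2-D grid of two factors, all others at means."""
    config = config or AnalysisConfig()
    config.validate()
    if f1 == f2:
        raise ValueError("coupling surface needs two distinct factors")
    codes = table.codes
    for f in (f1, f2):
        if f not in codes:
            raise KeyError(f"unknown factor {f!r}")
    j1, j2 = codes.index(f1), codes.index(f2)

    def axis(f, j, override):
        col = table.column(f)
        lo, hi = override if override is not None else (col.min(), col.max())
        return (np.linspace(lo, hi, config.pair_grid) if config.pair_grid > 1
                else np.array([(lo + hi) / 2.0]))

    d1, d2 = domains if domains is not None else (None, None)
    xs = axis(f1, j1, d1)
    ys = axis(f2, j2, d2)
    G1, G2 = np.meshgrid(xs, ys, indexing="ij")
    X = np.tile(_baseline_row(table), (G1.size, 1))
    X[:, j1] = G1.ravel()
    X[:, j2] = G2.ravel()
    Z = np.asarray(model.predict(X), dtype=float).reshape(G1.shape)
    argmax = np.unravel_index(int(np.argmax(Z)), Z.shape)
    return CouplingSurface(factors=(f1, f2), xs=xs, ys=ys, Z=Z,
                           argmax=(int(argmax[0]), int(argmax[1])))


def response_report(
    model, table: SampleTable,
    config: AnalysisConfig | None = None,
    domains: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Sweep all factors and assemble the influence-intensity report.

    One row per factor: sampling domain (sweep scale and original units),
    response-domain range, ES/S/NS class and function shape, sorted by
    range descending — the table a practitioner reads first.
    """
    config = config or AnalysisConfig()
    domains = domains or {}
    rows = []
    for code in table.codes:
        curve = single_factor_response(model, table, code, config,
                                       domain=domains.get(code))
        lo, hi = curve.sampling_domain
        rows.append({
            "factor": code,
            "name": FACTOR_NAMES.get(code, code),
            "domain_lo": lo,
            "domain_hi": hi,
            "original_lo": float(table.destandardize(code, lo)),
            "original_hi": float(table.destandardize(code, hi)),
            "response_range": curve.range,
            "intensity": curve.intensity,
            "shape": curve.shape,
        })
    report = pd.DataFrame(rows).sort_values(
        "response_range", ascending=False, kind="mergesort")
    return report.reset_index(drop=True)


def save_surface(surface: CouplingSurface, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(surface.Z, index=surface.xs, columns=surface.ys)
    df.index.name = surface.factors[0]
    df.columns.name = surface.factors[1]
    df.to_csv(path)
    return path
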