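"""Cognizable synergistic features from the penultimate layer, vs PCA.

Because the output layer is a single linear neuron, the prediction
decomposes exactly over the last hidden (16-unit ReLU) layer:

    y(x) = sum_j w_j h_j(x) + b

so each penultimate unit j is a candidate "synergistic feature" with
weight |w_j|.  Its per-factor contribution is the weighted range of the
response traced by unit j when that factor alone is swept (others at
sample means): |w_j| * (max - min of h_j).  Factors whose contribution
clears a threshold form the feature's contained-factor set — groups of
socioeconomic variables the network has fused into one internal quantity.
A standard PCA on the factor matrix provides the comparison
dimensionality reduction: per-component contained factors are those with
loading magnitude above a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .analysis import AnalysisConfig
from .model import TrainedSurrogate
from .table import FACTOR_NAMES, SampleTable

#: smallest contribution treated as "contained"; of order 1/10 of a typical
#: retained feature weight
DEFAULT_CONTRIB_THRESHOLD = 3e-4
DEFAULT_WEIGHT_THRESHOLD = 0.0
DEFAULT_LOADING_THRESHOLD = 0.1


@dataclass
class FeatureConfig:
    weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD
    contrib_threshold: float = DEFAULT_CONTRIB_THRESHOLD
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD
    sweep_points: int = 201


@dataclass
class SynergisticFeature:
    """One penultimate unit: output weight, per-factor contributions, set."""

    neuron: int
    weight: float
    contributions: dict[str, float]
    contained: tuple[str, ...]
    label: str = ""  # free-text interpretation slot; never auto-named

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PCAResult:
    """Loadings, explained-variance shares and thresholded factor sets."""

    loadings: np.ndarray            # n_components x n_factors
    explained_variance_ratio: np.ndarray
    contained: tuple[tuple[str, ...], ...]
    codes: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def penultimate_activations(model: TrainedSurrogate, X: np.ndarray) -> np.ndarray:
    """Last-hidden-layer activations h (n x width).

    Requires — and asserts — the linear scalar output contract:
    ``w @ h + b`` must reproduce ``predict`` to 1e-6.
    """
    if model.activations[-1] != "linear" or model.weights[-1].shape[1] != 1:
        raise ValueError("feature extraction requires a linear scalar output layer")
    h = model.penultimate(X)
    recon = h @ model.output_weights + model.output_bias
    if not np.allclose(recon, model.predict(X), atol=1e-6):
        raise AssertionError("penultimate reconstruction does not match predict")
    return h


def _factor_sweep_matrix(table: SampleTable, j: int, points: int) -> np.ndarray:
    col = table.column(table.codes[j])
    xs = np.linspace(float(col.min()), float(col.max()), points)
    X = np.tile(table.factor_means(), (points, 1))
    X[:, j] = xs
    return X


def extract_features(
    model: TrainedSurrogate, table: SampleTable,
    config: FeatureConfig | None = None,
) -> list[SynergisticFeature]:
    """One candidate feature per penultimate unit; retain the informative ones.

    For each unit j and factor i the contribution is
    |w_j| * range(h_j under factor i's single-factor sweep).  Units with
    weight >= weight_threshold and a non-empty contained set are kept,
    sorted by weight descending.  At most the penultimate width can be
    retained, and every contained set carries its numeric contributions.
    """
    config = config or FeatureConfig()
    codes = table.codes
    w = model.output_weights
    width = len(w)

    # one sweep per factor, all units' activations at once
    ranges = np.zeros((width, len(codes)))
    for i in range(len(codes)):
        X = _factor_sweep_matrix(table, i, config.sweep_points)
        h = penultimate_activations(model, X)
        ranges[:, i] = h.max(axis=0) - h.min(axis=0)

    features = []
    for j in range(width):
        weight = abs(float(w[j]))
        contribs = {codes[i]: weight * float(ranges[j, i])
                    for i in range(len(codes))}
        contained = tuple(c for c, v in contribs.items()
                          if v >= config.contrib_threshold)
        if weight >= config.weight_threshold and weight > 0 and contained:
            features.append(SynergisticFeature(
                neuron=j, weight=weight, contributions=contribs,
                contained=contained))
    features.sort(key=lambda f: f.weight, reverse=True)
    return features


def pca_compare(table: SampleTable, n_components: int = 6,
                loading_threshold: float = DEFAULT_LOADING_THRESHOLD
                ) -> PCAResult:
    """Standard PCA on the factor matrix as the comparison reduction."""
    X = table.X
    if n_components > X.shape[1]:
        raise ValueError("more components than factors")
    if n_components > X.shape[0]:
        raise ValueError("more components than samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    loadings = pca.components_
    contained = tuple(
        tuple(c for c, v in zip(table.codes, comp) if abs(v) >= loading_threshold)
        for comp in loadings
    )
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        contained=contained,
        codes=table.codes,
    )


def feature_report(features: list[SynergisticFeature],
                   pca: PCAResult) -> pd.DataFrame:
    """Side-by-side listing of network features and principal components.

    Rows pair feature k with component k (shorter side padded); the
    ``overlap`` column counts shared contained factors.
    """
    for f in features:
        unknown = set(f.contained) - set(pca.codes)
        if unknown:
            raise ValueError(f"feature factors {sorted(unknown)} not in PCA table")
    n = max(len(features), pca.n_components)
    rows = []
    for k in range(n):
        feat = features[k] if k < len(features) else None
        comp = pca.contained[k] if k < pca.n_components else None
        f_set = set(feat.contained) if feat else set()
        c_set = set(comp) if comp is not None else set()
        rows.append({
            "rank": k + 1,
            "feature_neuron": feat.neuron if feat else None,
            "feature_weight": feat.weight if feat else None,
            "feature_factors": " ".join(feat.contained) if feat else "",
            "pc_variance_share": (float(pca.explained_variance_ratio[k])
                                  if comp is not None else None),
            "pc_factors": " ".join(comp) if comp is not None else "",
            "overlap": len(f_set & c_set) if feat and comp is not None else None,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_features(features: list[SynergisticFeature], path: str | Path) -> Path:
    """CSV (one row per feature x contained factor) + JSON of full records."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in features:
        for code in f.contained:
            rows.append({
                "neuron": f.neuron,
                "weight": f.weight,
                "factor": code,
                "factor_name": FACTOR_NAMES.get(code, code),
                "weighted_range_of_Y": f.contributions[code],
                "label": f.label,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps([f.to_dict() for f in features], indent=1))
    return path


def save_pca(pca: PCAResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(pca.loadings, columns=list(pca.codes))
    df.insert(0, "component", np.arange(1, pca.n_components + 1))
    df.insert(1, "variance_share", pca.explained_variance_ratio)
    df.to_csv(path, index=False)
    return path


def report_markdown(report: pd.DataFrame) -> str:
    """Render the comparison table as Markdown."""
    lines = ["| " + " | ".join(report.columns) + " |",
             "| " + " | ".join("---" for _ in report.columns) + " |"]
    for _, row in report.iterrows():
        cells = ["" if pd.isna(v) else
                 (f"{v:.4g}" if isinstance(v, float) else str(v))
                 for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
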