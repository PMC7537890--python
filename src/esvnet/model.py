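"""MLP surrogate mapping 23 standardized factors to ESV, with NSE/RSR scoring.

The network is a multilayer feedforward dense stack: a 128-unit linear
layer, a 256-unit tanh layer, a 16-unit ReLU layer (the penultimate layer
the feature analysis decomposes) and a scalar linear output, with dropout
0.3 after every hidden layer during training.  It is trained with Adam on
mean-squared error, 70/30 train/test split, 200 epochs.

Inference is strictly deterministic (dropout off), which the downstream
response-curve and feature analyses rely on: the prediction is an exact
linear combination of penultimate activations, y = sum_j w_j h_j + b.

Fit quality is reported with the Nash-Sutcliffe efficiency
NSE = 1 - SSE/SStot and the RMSE-to-observation-SD ratio RSR = RMSE/SD(obs)
(population normalization in both, so NSE = 1 - RSR^2 holds exactly);
NSE > 0.5 with RSR <= 0.70 grades as "satisfactory".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .table import SampleTable

DEFAULT_HIDDEN: tuple[tuple[int, str], ...] = (
    (128, "linear"), (256, "tanh"), (16, "relu"),
)

_ACT = {
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
}


class TrainingDiverged(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    The hidden stack is given as (units, activation) pairs; the output layer
    is always one linear neuron (the feature decomposition requires it).
    Optimizer defaults (Adam lr 1e-3, beta1 0.9, beta2 0.999, batch 32) are
    the common framework defaults and are recorded here for reproducibility.
    """

    hidden_layers: tuple[tuple[int, str], ...] = DEFAULT_HIDDEN
    dropout: float = 0.3
    epochs: int = 200
    train_fraction: float = 0.7
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        for _, act in self.hidden_layers:
            if act not in _ACT:
                raise ValueError(f"unknown activation {act!r}")


@dataclass
class FitMetrics:
    nse: float
    rsr: float
    grade: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def evaluate(obs: np.ndarray, pred: np.ndarray) -> FitMetrics:
    """Nash-Sutcliffe efficiency and RMSE/SD(obs) ratio of a prediction."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must be equal-length vectors, n >= 2")
    sse = float(np.sum((obs - pred) ** 2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("constant observations: NSE/RSR undefined")
    nse = 1.0 - sse / sstot
    rsr = float(np.sqrt(sse / sstot))
    # boundary tolerance: 0.70 computed as sqrt(1 - 0.51) may land one ulp high
    grade = ("satisfactory" if (nse > 0.5 and rsr <= 0.70 + 1e-9)
             else "unsatisfactory")
    return FitMetrics(nse=nse, rsr=rsr, grade=grade)


@dataclass
class TrainedSurrogate:
    """Weights, biases and activations of a trained stack, plus history.

    ``weights[k]`` maps layer k-1 activations (or the input for k=0) to
    layer k pre-activations; ``activations`` has one entry per layer
    including the final 'linear'.  ``predict`` is deterministic.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: list[str]
    config: ModelConfig | None = None
    history: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.weights[-1].shape[1] != 1 or self.activations[-1] != "linear":
            raise ValueError("output layer must be one linear neuron")

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    @property
    def output_weights(self) -> np.ndarray:
        """Output-layer coefficients w_j over the penultimate units."""
        return self.weights[-1][:, 0]

    @property
    def output_bias(self) -> float:
        return float(self.biases[-1][0])

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} factor columns, got {X.shape[1]}")
        return X

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """All layer activations, dropout inactive."""
        acts = []
        a = X
        for W, b, name in zip(self.weights, self.biases, self.activations):
            z = a @ W + b
            a = _ACT[name][0](z)
            acts.append(a)
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic scalar prediction per sample."""
        return self._forward(self._check_X(X))[-1][:, 0]

    def penultimate(self, X: np.ndarray) -> np.ndarray:
        """Activations of the last hidden layer (n x width)."""
        return self._forward(self._check_X(X))[-2]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Portable weights file (npz) + JSON config + history CSV."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)
        meta = {
            "activations": self.activations,
            "config": asdict(self.config) if self.config else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        if self.history is not None:
            self.history.to_csv(path.with_suffix(".history.csv"), index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedSurrogate":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path)
        meta = json.loads(path.with_suffix(".json").read_text())
        n_layers = len(meta["activations"])
        weights = [arrays[f"W{i}"] for i in range(n_layers)]
        biases = [arrays[f"b{i}"] for i in range(n_layers)]
        cfg = meta.get("config")
        if cfg:
            cfg["hidden_layers"] = tuple(tuple(h) for h in cfg["hidden_layers"])
        hist_path = path.with_suffix(".history.csv")
        history = pd.read_csv(hist_path) if hist_path.exists() else None
        return cls(weights=weights, biases=biases,
                   activations=list(meta["activations"]),
                   config=ModelConfig(**cfg) if cfg else None,
                   history=history)


def _init_layers(rng: np.random.Generator, sizes: list[int]
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Seeded Glorot-uniform initialization."""
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def split_indices(n: int, train_fraction: float, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split into train/test index arrays."""
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return perm[:n_train], perm[n_train:]


def train(table: SampleTable, config: ModelConfig | None = None
          ) -> tuple[TrainedSurrogate, FitMetrics]:
    """Fit the surrogate on a standardized sample table.

    Uses a seeded shuffle for the train/test split, seeded weight
    initialization and seeded dropout masks, so identical (table, config)
    pairs yield bit-identical weights, history and metrics.  Returns the
    model and the held-out (test-set) fit metrics.
    """
    config = config or ModelConfig()
    config.validate()
    X, y = table.X, table.y
    n = len(y)
    if n < 50:
        raise ValueError(f"need at least 50 samples, got {n}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("table contains non-finite values")

    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = split_indices(n, config.train_fraction, rng)
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]

    sizes = [X.shape[1]] + [u for u, _ in config.hidden_layers] + [1]
    act_names = [a for _, a in config.hidden_layers] + ["linear"]
    weights, biases = _init_layers(rng, sizes)
    n_layers = len(weights)

    # Adam state
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    step = 0
    keep = 1.0 - config.dropout

    history = {"epoch": [], "train_loss": [], "test_loss": []}
    n_tr = len(y_tr)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_tr)
        epoch_sse = 0.0
        for start in range(0, n_tr, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            m = len(idx)

            # forward with inverted dropout on hidden activations
            a = xb
            zs, raw_acts, dropped, masks = [], [], [], []
            for k in range(n_layers):
                z = a @ weights[k] + biases[k]
                a_raw = _ACT[act_names[k]][0](z)
                if k < n_layers - 1 and config.dropout > 0:
                    mask = (rng.random(a_raw.shape) < keep) / keep
                    a = a_raw * mask
                else:
                    mask = None
                    a = a_raw
                zs.append(z)
                raw_acts.append(a_raw)
                dropped.append(a)
                masks.append(mask)

            resid = dropped[-1][:, 0] - yb
            epoch_sse += float(np.sum(resid**2))

            # backward
            delta = (2.0 / m) * resid[:, None]  # dL/dz_out (linear output)
            grads_W = [None] * n_layers
            grads_b = [None] * n_layers
            for k in range(n_layers - 1, -1, -1):
                a_prev = xb if k == 0 else dropped[k - 1]
                grads_W[k] = a_prev.T @ delta
                grads_b[k] = delta.sum(axis=0)
                if k > 0:
                    da = delta @ weights[k].T
                    if masks[k - 1] is not None:
                        da = da * masks[k - 1]
                    deriv = _ACT[act_names[k - 1]][1](zs[k - 1], raw_acts[k - 1])
                    delta = da * deriv

            # Adam update
            step += 1
            b1, b2 = config.beta1, config.beta2
            corr1 = 1.0 - b1**step
            corr2 = 1.0 - b2**step
            for k in range(n_layers):
                for theta, g, mm, vv in (
                    (weights[k], grads_W[k], mW, vW),
                    (biases[k], grads_b[k], mb, vb),
                ):
                    mm[k] = b1 * mm[k] + (1 - b1) * g
                    vv[k] = b2 * vv[k] + (1 - b2) * g**2
                    theta -= config.learning_rate * (mm[k] / corr1) / (
                        np.sqrt(vv[k] / corr2) + config.eps)

        train_loss = epoch_sse / n_tr
        if not np.isfinite(train_loss):
            raise TrainingDiverged(f"non-finite training loss at epoch {epoch}")
        model_now = TrainedSurrogate(weights=weights, biases=biases,
                                     activations=act_names)
        test_loss = float(np.mean((model_now.predict(X_te) - y_te) ** 2))
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["test_loss"].append(test_loss)

    model = TrainedSurrogate(
        weights=weights, biases=biases, activations=act_names,
        config=config, history=pd.DataFrame(history),
    )
    metrics = evaluate(y_te, model.predict(X_te))
    return model, metrics
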