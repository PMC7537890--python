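"""Shared fixtures: a synthetic city, its fused table, and trained surrogates.

Training fixtures are session-scoped because fitting the full 200-epoch
stack is the expensive step; every test that only probes a trained model
shares one fit.
"""

import numpy as np
import pytest

import esvnet


@pytest.fixture(scope="session")
def landscape():
    config = esvnet.SynthConfig(seed=7)
    rasters, totals = esvnet.generate_landscape(config)
    return config, rasters, totals


@pytest.fixture(scope="session")
def fused_table(landscape):
    _, rasters, totals = landscape
    return esvnet.build_sample_table(rasters, totals)


@pytest.fixture(scope="session")
def trained(fused_table):
    model, metrics = esvnet.train(fused_table, esvnet.ModelConfig(seed=7))
    return model, metrics


#: planted effects used across recovery tests: two strong monotone factors
#: and one inverted-U factor, amplitudes well above the response noise
ORACLE_EFFECTS = {
    "A5": esvnet.Effect("monotone_decreasing", 1.0),
    "B5": esvnet.Effect("monotone_increasing", 0.8),
    "C5": esvnet.Effect("inverted_u", 0.6, vertex=0.0),
}


@pytest.fixture(scope="session")
def oracle_spec():
    return esvnet.OracleSpec(effects=dict(ORACLE_EFFECTS), n=2000, noise_sd=0.1)


@pytest.fixture(scope="session")
def oracle_fit(oracle_spec):
    table, truth = esvnet.generate_oracle_table(oracle_spec, seed=3)
    model, metrics = esvnet.train(table, esvnet.ModelConfig(seed=3))
    return table, truth, model, metrics


def make_relu_probe_model(factor_index: int, scale: float, out_weight: float,
                          n_factors: int = 23) -> esvnet.TrainedSurrogate:
    """Hand-built surrogate with one penultimate unit h = ReLU(scale * x_i)
    and prediction out_weight * h: a closed-form single-neuron oracle."""
    W0 = np.zeros((n_factors, 1))
    W0[factor_index, 0] = scale
    return esvnet.TrainedSurrogate(
        weights=[W0, np.array([[out_weight]])],
        biases=[np.zeros(1), np.zeros(1)],
        activations=["relu", "linear"],
    )


def make_constant_model(value: float, n_factors: int = 23,
                        width: int = 4) -> esvnet.TrainedSurrogate:
    """Zero-weight surrogate whose output is the constant bias."""
    return esvnet.TrainedSurrogate(
        weights=[np.zeros((n_factors, width)), np.zeros((width, 1))],
        biases=[np.zeros(width), np.array([value])],
        activations=["relu", "linear"],
    )


class FunctionModel:
    """Duck-typed stand-in predicting an analytic function of the factors."""

    def __init__(self, func, n_factors: int = 23):
        self.func = func
        self.n_factors = n_factors

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        assert X.shape[1] == self.n_factors
        return self.func(X)
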