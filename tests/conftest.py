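"""Shared builders for small, analytically tractable model instances."""

import numpy as np
import pytest

from agingnet.model import ModelHyperparameters, ModelParameters


def constant_rate_params(lam: float, mort: float = 0.0) -> ModelParameters:
    """N=1, time/state-independent damage rate lam and mortality rate mort."""
    h = ModelHyperparameters(n=1, n_f=0, n_plus=0, n_d1=0, n_d2=0)
    return ModelParameters(hyper=h, w=np.zeros((1, 1)), mu=np.zeros((1, 0)),
                           gamma=np.array([[lam]]), beta=np.zeros(1),
                           alpha=np.array([mort]), eta=np.array([0.0]))


def two_node_params(lam1: float, lam2: float, w12: float = 0.0,
                    w21: float = 0.0, mort0: float = 0.0,
                    beta=(0.0, 0.0)) -> ModelParameters:
    """N=2 with constant (time-independent, state-dependent) rates.

    Node i's damage rate is lam_i + w_ij * d_j (hinged); mortality is
    mort0 + beta . d (hinged), all constant in time.
    """
    h = ModelHyperparameters(n=2, n_f=0, n_plus=1, n_d1=1, n_d2=0)
    return ModelParameters(
        hyper=h, w=np.array([[0.0, w12], [w21, 0.0]]), mu=np.zeros((2, 0)),
        gamma=np.array([[lam1, 1.0], [lam2, 1.0]]),
        beta=np.array(beta, dtype=float), alpha=np.array([mort0, 1.0]),
        eta=np.array([0.0]))


def random_valid_params(hyper: ModelHyperparameters,
                        rng: np.random.Generator,
                        scale: float = 1.0) -> ModelParameters:
    """Random parameters satisfying every sign/shape invariant."""
    n = hyper.n
    w = rng.normal(0, scale, (n, n))
    np.fill_diagonal(w, 0.0)
    return ModelParameters(
        hyper=hyper, w=w,
        mu=rng.uniform(0, 0.05 * scale, (n, hyper.n_f)),
        gamma=np.column_stack([rng.normal(0, 0.1 * scale, n),
                               rng.uniform(0, 0.2, (n, hyper.n_plus))])
        if hyper.n_plus else rng.normal(0, 0.1 * scale, (n, 1)),
        beta=rng.normal(0, scale, n),
        alpha=np.concatenate([rng.normal(0, 0.05, 1),
                              rng.uniform(0, 0.1, hyper.n_d1)]),
        eta=np.concatenate([rng.normal(0, 0.5, 1),
                            rng.uniform(0, 0.05, hyper.n_d2)]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
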