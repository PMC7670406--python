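"""Weighted network model of aging: parameters and deterministic rate functions.

The model places ``N`` binary health attributes (potential deficits) on a
weighted directed network.  Node ``i`` damages (0 -> 1, irreversibly) with a
rate driven by its *local frailty*

    f_i(t, {d_j}) = phi( sum_j w_ij d_j + mu_i(t) ),      mu_i(t) = sum_{n>=1} mu_{i,n} t^n,

where ``phi(x) = max(x, 0)`` is the hinge/rectifier and ``mu_i(t)`` is a
monotone power series absorbing the age-dependent influence of unobserved
physiology.  The damage rate is itself a hinged power series in ``f_i``:

    Gamma+_i = phi( sum_{n=0}^{n_+} gamma+_{i,n} f_i^n ).

Mortality is a separate competing process with rate

    Gamma_D = phi( sum_{n=0}^{n_D1} alpha_n x^n ),
    x(t, {d_j}) = phi( sum_j beta_j d_j + sum_{n=0}^{n_D2} eta_n t^n ).

All series coefficients of order >= 1 are constrained non-negative so that
``f_i``, ``Gamma+_i``, ``x`` and ``Gamma_D`` are monotone non-decreasing in
age at fixed deficits.  Two conventions fix otherwise-unidentifiable entries:
the diagonal of ``W`` is zero (node ``i``'s rate is only ever evaluated while
``d_i = 0``), and the constant term of ``mu_i`` is zero (redundant with the
``gamma+`` intercept).  Under these conventions the number of free parameters
is ``N (N + n_f + n_+ + 1) + n_D1 + n_D2 + 2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ModelHyperparameters",
    "ModelParameters",
    "HealthState",
    "hinge",
    "local_frailty",
    "damage_rate",
    "mortality_load",
    "mortality_rate",
    "count_parameters",
    "frailty_index",
]


# --------------------------------------------------------------------------
# hyperparameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelHyperparameters:
    """Structural sizes: node count and power-series orders.

    ``n`` nodes; ``n_f`` is the highest power in the age series mu_i(t);
    ``n_plus`` the highest power of f_i in the damage rate; ``n_d1`` the
    highest power of x in the mortality rate; ``n_d2`` the highest power of t
    in the age series of x.  Defaults are the study values used with N=10.
    """

    n: int = 10
    n_f: int = 3
    n_plus: int = 4
    n_d1: int = 3
    n_d2: int = 3

    def __post_init__(self) -> None:
        for name in ("n", "n_f", "n_plus", "n_d1", "n_d2"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n < 1:
            raise ValueError("n (node count) must be >= 1")

    @property
    def n_states(self) -> int:
        """Size of the joint deficit state space, 2**N."""
        return 1 << self.n


def count_parameters(hyper: ModelHyperparameters) -> int:
    """Total number of free fitting parameters.

    Equals ``N (N + n_f + n_plus + 1) + n_d1 + n_d2 + 2`` and, by
    construction, the length of :meth:`ModelParameters.flatten`:
    ``N(N-1)`` off-diagonal weights, ``N n_f`` mu coefficients (orders
    1..n_f), ``N (n_plus + 1)`` damage-rate coefficients, ``N`` mortality
    weights beta, ``n_d1 + 1`` alpha and ``n_d2 + 1`` eta coefficients.
    """
    h = hyper
    return h.n * (h.n + h.n_f + h.n_plus + 1) + h.n_d1 + h.n_d2 + 2


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """All fitted quantities of the weighted network model.

    Shapes (with ``N = hyper.n``):

    - ``w``: (N, N) directed connection weights, row i = receiving node,
      zero diagonal.
    - ``mu``: (N, n_f) age-series coefficients mu_{i,n}, n = 1..n_f
      (constant term fixed at 0), all >= 0.
    - ``gamma``: (N, n_plus + 1) damage-rate coefficients gamma+_{i,n},
      n = 0..n_plus; orders >= 1 are >= 0, the intercept may be negative.
    - ``beta``: (N,) mortality weights (any sign).
    - ``alpha``: (n_d1 + 1,) mortality-rate coefficients; orders >= 1 >= 0.
    - ``eta``: (n_d2 + 1,) mortality age-series coefficients; orders >= 1 >= 0.
    """

    hyper: ModelHyperparameters
    w: np.ndarray
    mu: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        h = self.hyper
        self.w = np.ascontiguousarray(np.asarray(self.w, dtype=float))
        self.mu = np.ascontiguousarray(np.asarray(self.mu, dtype=float).reshape(h.n, h.n_f))
        self.gamma = np.ascontiguousarray(np.asarray(self.gamma, dtype=float))
        self.beta = np.ascontiguousarray(np.asarray(self.beta, dtype=float))
        self.alpha = np.ascontiguousarray(np.asarray(self.alpha, dtype=float))
        self.eta = np.ascontiguousarray(np.asarray(self.eta, dtype=float))
        expected = {
            "w": (h.n, h.n),
            "gamma": (h.n, h.n_plus + 1),
            "beta": (h.n,),
            "alpha": (h.n_d1 + 1,),
            "eta": (h.n_d2 + 1,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        for name in ("w", "mu", "gamma", "beta", "alpha", "eta"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite entries")
        if np.any(np.diag(self.w) != 0.0):
            raise ValueError("diagonal of w must be identically zero")
        if np.any(self.mu < 0.0):
            raise ValueError("mu coefficients (orders >= 1) must be non-negative")
        if h.n_plus >= 1 and np.any(self.gamma[:, 1:] < 0.0):
            raise ValueError("gamma coefficients of order >= 1 must be non-negative")
        if h.n_d1 >= 1 and np.any(self.alpha[1:] < 0.0):
            raise ValueError("alpha coefficients of order >= 1 must be non-negative")
        if h.n_d2 >= 1 and np.any(self.eta[1:] < 0.0):
            raise ValueError("eta coefficients of order >= 1 must be non-negative")

    # -- flatten / unflatten ------------------------------------------------

    def flatten(self) -> np.ndarray:
        """Free parameters as one vector (length :func:`count_parameters`).

        Order: off-diagonal w (row-major), mu (row-major), gamma (row-major),
        beta, alpha, eta.
        """
        h = self.hyper
        off = ~np.eye(h.n, dtype=bool)
        return np.concatenate([
            self.w[off],
            self.mu.ravel(),
            self.gamma.ravel(),
            self.beta,
            self.alpha,
            self.eta,
        ])

    @classmethod
    def unflatten(cls, vec: np.ndarray, hyper: ModelHyperparameters) -> "ModelParameters":
        """Inverse of :meth:`flatten`."""
        h = hyper
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (count_parameters(h),):
            raise ValueError(
                f"expected vector of length {count_parameters(h)}, got {vec.shape}")
        pos = 0

        def take(k: int) -> np.ndarray:
            nonlocal pos
            out = vec[pos:pos + k]
            pos += k
            return out

        w = np.zeros((h.n, h.n))
        off = ~np.eye(h.n, dtype=bool)
        w[off] = take(h.n * (h.n - 1))
        mu = take(h.n * h.n_f).reshape(h.n, h.n_f)
        gamma = take(h.n * (h.n_plus + 1)).reshape(h.n, h.n_plus + 1)
        beta = take(h.n)
        alpha = take(h.n_d1 + 1)
        eta = take(h.n_d2 + 1)
        return cls(hyper=h, w=w, mu=mu, gamma=gamma, beta=beta, alpha=alpha, eta=eta)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "hyper": {"N": self.hyper.n, "n_f": self.hyper.n_f,
                      "n_plus": self.hyper.n_plus, "n_D1": self.hyper.n_d1,
                      "n_D2": self.hyper.n_d2},
            "W": self.w.tolist(),
            "mu": self.mu.tolist(),
            "gamma": self.gamma.tolist(),
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "eta": self.eta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        h = d["hyper"]
        hyper = ModelHyperparameters(n=h["N"], n_f=h["n_f"], n_plus=h["n_plus"],
                                     n_d1=h["n_D1"], n_d2=h["n_D2"])
        return cls(hyper=hyper, w=np.array(d["W"]), mu=np.array(d["mu"]),
                   gamma=np.array(d["gamma"]), beta=np.array(d["beta"]),
                   alpha=np.array(d["alpha"]), eta=np.array(d["eta"]))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParameters":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    # -- convenience --------------------------------------------------------

    def mu_of_t(self, node: int, t: float) -> float:
        """Age series mu_i(t) = sum_{n>=1} mu_{i,n} t^n (Horner)."""
        acc = 0.0
        for c in self.mu[node][::-1]:
            acc = acc * t + c
        return acc * t


# --------------------------------------------------------------------------
# health state
# --------------------------------------------------------------------------

@dataclass
class HealthState:
    """One individual's binary deficit vector at an age (years)."""

    deficits: np.ndarray
    age: float = 0.0

    def __post_init__(self) -> None:
        self.deficits = np.asarray(self.deficits)
        if self.deficits.ndim != 1:
            raise ValueError("deficits must be a 1-d vector")
        if not np.all(np.isin(self.deficits, (0, 1))):
            raise ValueError("deficits must be exactly 0 or 1")
        self.deficits = self.deficits.astype(np.int8)
        if not math.isfinite(self.age) or self.age < 0:
            raise ValueError(f"age must be finite and >= 0, got {self.age}")

    @property
    def n(self) -> int:
        return self.deficits.shape[0]


def frailty_index(state: HealthState) -> float:
    """Frailty Index F = sum_i d_i / N: the proportion of deficits present."""
    return float(np.mean(state.deficits))


# --------------------------------------------------------------------------
# rate functions
# --------------------------------------------------------------------------

def hinge(x: float) -> float:
    """Rectifier phi(x) = max(x, 0). Rejects non-finite input."""
    if not math.isfinite(x):
        raise ValueError(f"hinge requires finite input, got {x}")
    return x if x > 0.0 else 0.0


def _check_state(state: HealthState, params: ModelParameters) -> None:
    if state.n != params.hyper.n:
        raise ValueError(
            f"state has {state.n} deficits but the model has {params.hyper.n} nodes")


def local_frailty(node: int, state: HealthState, t: float,
                  params: ModelParameters) -> float:
    """Local frailty f_i = phi( sum_j w_ij d_j + mu_i(t) )."""
    _check_state(state, params)
    if not 0 <= node < params.hyper.n:
        raise IndexError(f"node {node} out of range for N={params.hyper.n}")
    if not math.isfinite(t) or t < 0:
        raise ValueError(f"age must be finite and >= 0, got {t}")
    s = float(params.w[node] @ state.deficits) + params.mu_of_t(node, t)
    return hinge(s)


def damage_rate(node: int, state: HealthState, t: float,
                params: ModelParameters) -> float:
    """Damage rate Gamma+_i = phi( sum_n gamma+_{i,n} f_i^n ), per year.

    Only meaningful for undamaged nodes; querying a damaged node is a
    contract violation and raises.
    """
    _check_state(state, params)
    if not 0 <= node < params.hyper.n:
        raise IndexError(f"node {node} out of range for N={params.hyper.n}")
    if state.deficits[node] != 0:
        raise ValueError(f"node {node} is already damaged; its 0->1 rate is undefined")
    f = local_frailty(node, state, t, params)
    acc = 0.0
    for c in params.gamma[node][::-1]:
        acc = acc * f + c
    return hinge(acc)


def mortality_load(state: HealthState, t: float, params: ModelParameters) -> float:
    """Mortality load x = phi( sum_j beta_j d_j + sum_n eta_n t^n )."""
    _check_state(state, params)
    if not math.isfinite(t) or t < 0:
        raise ValueError(f"age must be finite and >= 0, got {t}")
    acc = 0.0
    for c in params.eta[::-1]:
        acc = acc * t + c
    return hinge(float(params.beta @ state.deficits) + acc)


def mortality_rate(state: HealthState, t: float, params: ModelParameters) -> float:
    """Mortality rate Gamma_D = phi( sum_n alpha_n x^n ), per year."""
    x = mortality_load(state, t, params)
    acc = 0.0
    for c in params.alpha[::-1]:
        acc = acc * x + c
    return hinge(acc)
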