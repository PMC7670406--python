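"""Maximum-likelihood fitting by bounded particle swarm optimization.

The objective is the simulation-based censored log-likelihood (optionally
L1-penalized on network and mortality weights).  The objective is stochastic
in principle; a fixed likelihood random stream is used for every evaluation
(common random numbers), which makes the objective a deterministic function
of the parameters and keeps optimizer comparisons consistent.

The PSO is a standard global-best swarm with constriction-style coefficients
(inertia 0.72, cognitive = social = 1.49) and reflecting bound handling;
coordinates whose lower and upper bounds coincide are held fixed (e.g. the
zero diagonal of W).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .likelihood import LikelihoodConfig, log_likelihood
from .model import ModelHyperparameters, ModelParameters, count_parameters
from .simulate import RngSpec

__all__ = ["FitConfig", "FitResult", "default_bounds", "penalized_objective",
           "fit", "moment_start", "balanced_train_test_split"]


def default_bounds(hyper: ModelHyperparameters, box: float = 10.0):
    """Per-coefficient (lower, upper) bounds on the flattened vector.

    Monotonicity constraints: every power-series coefficient of order >= 1
    has lower bound 0.  Weights and zeroth-order coefficients live in the
    symmetric interval [-box, box].  The diagonal of W is absent from the
    flattened vector (fixed at zero by construction).
    """
    h = hyper
    lo, hi = [], []

    def add(k, lo_v, hi_v):
        lo.extend([lo_v] * k)
        hi.extend([hi_v] * k)

    add(h.n * (h.n - 1), -box, box)          # off-diagonal weights
    add(h.n * h.n_f, 0.0, box)               # mu, orders >= 1
    for _ in range(h.n):                     # gamma rows: intercept then >= 1
        add(1, -box, box)
        add(h.n_plus, 0.0, box)
    add(h.n, -box, box)                      # beta
    add(1, -box, box)                        # alpha_0
    add(h.n_d1, 0.0, box)
    add(1, -box, box)                        # eta_0
    add(h.n_d2, 0.0, box)
    lo = np.array(lo)
    hi = np.array(hi)
    assert lo.size == count_parameters(h)
    return lo, hi


@dataclass
class FitConfig:
    """Swarm and objective settings."""

    swarm_size: int = 50
    iterations: int = 200
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    bounds: tuple | None = None            # (lo, hi) on the flattened vector
    reg_lambda: float = 0.0                # L1 strength on (W, beta)
    likelihood: LikelihoodConfig = field(default_factory=LikelihoodConfig)
    seed: int = 0
    # simulation streams are shared by all particles within an iteration
    # (common random numbers for fair ranking) and reseeded every
    # ``reseed_every`` iterations so the swarm cannot climb a single noise
    # realization; 0 keeps one fixed stream for the whole run
    reseed_every: int = 1
    # selection phase: personal-best positions are re-scored once on an
    # independent stream with simulation budgets scaled by this factor, and
    # the winner is returned (undoes noise-driven selection); 0 disables
    final_selection_factor: int = 5
    # seed one particle at the method-of-moments estimate (moment_start)
    warm_start: bool = True

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm size must be >= 2")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.reg_lambda < 0:
            raise ValueError("regularization strength must be >= 0")


@dataclass
class FitResult:
    """Best parameters, their objective value, and the optimization trace.

    ``trace`` is the swarm's best-so-far value per iteration under the
    fitting streams (non-decreasing); ``best_value`` is the winning
    candidate's value under the final-selection stream when that phase is
    enabled, so it may differ from ``trace[-1]``.
    """

    params: ModelParameters
    best_value: float
    trace: np.ndarray
    n_evaluations: int


def penalized_objective(params: ModelParameters, data: list,
                        config: FitConfig, rng: RngSpec | None = None) -> float:
    """log-likelihood minus lambda * (||W||_1 + ||beta||_1)."""
    if config.bounds is not None:
        lo, hi = config.bounds
        v = params.flatten()
        if np.any(v < lo - 1e-12) or np.any(v > hi + 1e-12):
            raise ValueError("parameters violate the configured bounds")
    rng = rng if rng is not None else RngSpec(config.seed, 500_000)
    ll = log_likelihood(params, data, config.likelihood, rng)
    pen = config.reg_lambda * (np.abs(params.w).sum() + np.abs(params.beta).sum())
    return ll - pen


def moment_start(data: list, hyper: ModelHyperparameters,
                 bounds=None, bin_width: float = 5.0) -> np.ndarray:
    """Method-of-moments warm start for the swarm, computed from the data.

    Interactions are initialized at zero.  Per-deficit damage series come
    from a least-squares fit of the empirical cumulative hazard implied by
    binned baseline prevalences, -log(1 - p_i(t)) ~ gamma_0 t + s t^2/2
    (the quadratic term split between the damage slope and the background
    age slope at mid-bound magnitudes).  Mortality comes from a linear fit
    of the binned within-window death hazard.  The result is clipped into
    the bounds; it is a crude but consistent marginal estimate that anchors
    the swarm in a behaviourally sane region.
    """
    lo, hi = bounds if bounds is not None else default_bounds(hyper)
    h = hyper
    t = np.array([r.baseline_age for r in data])
    d = np.stack([r.deficits for r in data])
    a = np.array([r.survival_age for r in data])
    c = np.array([r.censored for r in data])
    edges = np.arange(np.floor(t.min() / bin_width) * bin_width,
                      t.max() + bin_width, bin_width)
    min_count = max(5, len(data) // 50)
    mids, prev, haz = [], [], []
    for k in range(len(edges) - 1):
        sel = (t >= edges[k]) & (t < edges[k + 1])
        if sel.sum() < min_count:
            continue
        mids.append(0.5 * (edges[k] + edges[k + 1]))
        prev.append(np.nanmean(d[sel], axis=0))
        py = (a[sel] - t[sel]).sum()
        haz.append((c[sel] == 0).sum() / max(py, 1e-9))
    if not mids:   # data too sparse for moments: start mid-bounds
        return 0.5 * (lo + hi)
    mids = np.array(mids)
    prev = np.clip(np.stack(prev), 1e-3, 1 - 1e-3)
    haz = np.array(haz)

    # per-field views of the bound vectors, via the flatten layout
    nw, nmu, ng = h.n * (h.n - 1), h.n * h.n_f, h.n * (h.n_plus + 1)
    i_gamma, i_alpha = nw + nmu, nw + nmu + ng + h.n
    i_eta = i_alpha + h.n_d1 + 1

    params = ModelParameters.unflatten(np.zeros(count_parameters(h)), h)
    # damage: cumulative hazard Lambda_i(t) = -log(1 - p_i(t)) ~ g0 t + q t^2
    X = np.column_stack([mids, mids ** 2])
    for i in range(h.n):
        lam = -np.log(1 - prev[:, i])
        g0, q = np.linalg.lstsq(X, lam, rcond=None)[0]
        params.gamma[i, 0] = g0
        if h.n_plus >= 1 and h.n_f >= 1:
            # Gamma_i ~ g0 + gamma_1 mu_1 t: curvature 2q = gamma_1 mu_1
            row = i_gamma + i * (h.n_plus + 1)
            g1 = max(0.5 * hi[row + 1], 1e-6)
            params.gamma[i, 1] = g1
            params.mu[i, 0] = max(2 * q / g1, 0.0)
    # mortality: additive-hazard moment fit on individuals,
    # rate ~ c0 + c1 t + sum_i b_i d_i  (exposure-weighted least squares),
    # mapped onto alpha_1 (beta . d + eta_0 + eta_1 t) with alpha_1 at
    # half-bound; marginal (age-only) fallback when deficits are all missing
    exposure = np.maximum(a - t, 1e-6)
    rate = (c == 0).astype(float) / exposure
    dmat = np.nan_to_num(d, nan=np.nanmean(d, axis=0))
    X2 = np.column_stack([np.ones_like(t), t, dmat])
    W2 = exposure
    coef = np.linalg.lstsq(X2 * np.sqrt(W2)[:, None],
                           rate * np.sqrt(W2), rcond=None)[0]
    c0, c1, b = coef[0], coef[1], coef[2:]
    if h.n_d1 >= 1 and h.n_d2 >= 1:
        a1 = max(0.5 * hi[i_alpha + 1], 1e-6)
        params.alpha[1] = a1
        params.eta[1] = max(c1 / a1, 1e-6)
        params.eta[0] = c0 / a1
        params.beta = b / a1
    else:
        params.alpha[0] = max(c0 + c1 * np.median(mids), 1e-6)
    return np.clip(params.flatten(), lo, hi)


def _reflect(x, lo, hi):
    """Reflect positions into [lo, hi] (repeated until inside)."""
    span = hi - lo
    free = span > 0
    y = x.copy()
    y[..., ~free] = lo[~free]
    z = np.mod(y[..., free] - lo[free], 2 * span[free])
    y[..., free] = lo[free] + np.where(z > span[free], 2 * span[free] - z, z)
    return y


def fit(data: list, hyper: ModelHyperparameters,
        config: FitConfig | None = None) -> FitResult:
    """Global-best PSO over the flattened parameter vector.

    Deterministic under a fixed ``config.seed``.  Raises if every particle
    of the initial swarm has a non-finite objective.
    """
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    cfg = config or FitConfig()
    lo, hi = cfg.bounds if cfg.bounds is not None else default_bounds(hyper)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    dim = count_parameters(hyper)
    if lo.shape != (dim,) or hi.shape != (dim,):
        raise ValueError(f"bounds must have shape ({dim},)")
    if np.any(lo > hi):
        raise ValueError("lower bounds exceed upper bounds")

    rng = np.random.default_rng(cfg.seed)
    lik = cfg.likelihood

    def objective(vec: np.ndarray, ll_rng: RngSpec) -> float:
        try:
            p = ModelParameters.unflatten(vec, hyper)
        except ValueError:
            return -np.inf
        val = log_likelihood(p, data, lik, ll_rng)
        if not np.isfinite(val):
            return -np.inf
        pen = cfg.reg_lambda * (np.abs(p.w).sum() + np.abs(p.beta).sum())
        return val - pen

    def iter_rng(it: int) -> RngSpec:
        if cfg.reseed_every <= 0:
            return RngSpec(cfg.seed, 500_000)
        return RngSpec(cfg.seed, 500_000 + 1000 * (it // cfg.reseed_every))

    S = cfg.swarm_size
    span = hi - lo
    pos = lo + rng.random((S, dim)) * span
    if cfg.warm_start:
        anchor = moment_start(data, hyper, (lo, hi))
        k = max(1, S // 10)
        pos[0] = anchor
        for j in range(1, k):
            pos[j] = np.clip(anchor + (rng.random(dim) - 0.5) * 0.1 * span,
                             lo, hi)
    vel = np.zeros((S, dim))
    vmax = 0.2 * span          # standard velocity clamp
    pbest = pos.copy()
    pbest_val = np.array([objective(pos[s], iter_rng(0)) for s in range(S)])
    n_eval = S
    if not np.any(np.isfinite(pbest_val)):
        raise RuntimeError(
            "all initial particles have non-finite objective; check data, "
            "bounds and simulation budgets")
    g = int(np.argmax(pbest_val))
    gbest = pbest[g].copy()
    gbest_val = float(pbest_val[g])
    trace = [gbest_val]

    for it in range(cfg.iterations):
        r1 = rng.random((S, dim))
        r2 = rng.random((S, dim))
        vel = (cfg.inertia * vel
               + cfg.cognitive * r1 * (pbest - pos)
               + cfg.social * r2 * (gbest[None, :] - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = _reflect(pos + vel, lo, hi)
        ll_rng = iter_rng(it + 1)
        for s in range(S):
            v = objective(pos[s], ll_rng)
            n_eval += 1
            if v > pbest_val[s]:
                pbest_val[s] = v
                pbest[s] = pos[s]
                if v > gbest_val:
                    gbest_val = float(v)
                    gbest = pos[s].copy()
        trace.append(gbest_val)

    if cfg.final_selection_factor > 0:
        f = cfg.final_selection_factor
        # re-score with the sharpest estimator: forward per-record death
        # densities, regardless of the (cheaper) search-time estimator
        sel_cfg = replace(lik, pool_size=lik.pool_size * f,
                          per_record=max(lik.per_record, 64) * f,
                          min_bin_count=lik.min_bin_count * f,
                          density_from_pool=False)
        sel_rng = RngSpec(cfg.seed, 499_000)
        cand = np.unique(np.vstack([pbest, gbest[None, :]]), axis=0)
        vals = np.empty(len(cand))
        for k, vec in enumerate(cand):
            p = ModelParameters.unflatten(vec, hyper)
            v = log_likelihood(p, data, sel_cfg, sel_rng)
            pen = cfg.reg_lambda * (np.abs(p.w).sum() + np.abs(p.beta).sum())
            vals[k] = v - pen if np.isfinite(v) else -np.inf
        n_eval += len(cand)
        best = int(np.argmax(vals))
        gbest = cand[best]
        gbest_val = float(vals[best])

    return FitResult(params=ModelParameters.unflatten(gbest, hyper),
                     best_value=gbest_val, trace=np.array(trace),
                     n_evaluations=n_eval)


def balanced_train_test_split(data: list, bin_width: float = 5.0,
                              per_bin: int = 150, seed: int = 0):
    """Age-balanced split: up to ``per_bin`` records per baseline-age bin
    go to training; the remainder is the test set."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rng = np.random.default_rng(seed)
    ages = np.array([r.baseline_age for r in data])
    bins = np.floor(ages / bin_width).astype(int)
    train_idx = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        take = min(per_bin, idx.size)
        train_idx.extend(rng.choice(idx, size=take, replace=False))
    train_set = set(int(i) for i in train_idx)
    train = [data[i] for i in sorted(train_set)]
    test = [data[i] for i in range(len(data)) if i not in train_set]
    return train, test
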