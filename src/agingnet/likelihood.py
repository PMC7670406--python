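"""Simulation-based likelihood for censored cross-sectional cohort data.

The observed data are rows {t, {d_i}, a, c}: baseline age, binary deficits
(missing values allowed), last known-alive age, censoring flag.  The
log-likelihood factorizes into a health term and a mortality term,

    L = sum_{c=0} log p(a | {d}, t)  +  sum_m log p({d_i} | t)
        + sum_{c=1} log S(a | {d}, t),

and every probability is estimated from simulations of the model:

- p({d_i} | t): a birth-cohort pool (all-zero deficits at t = 0) is tallied
  into an age-binned joint state distribution with additive smoothing.
- S(a | {d}, t): the fraction of pool individuals alive at t, with the
  record's observed deficits at age t, that survive to a (exact simulated
  event ages make the conditioning exact in age).
- p(a | {d}, t) for uncensored, fully observed records: forward simulations
  from (t, {d}) and a central finite difference of the empirical survival
  over a one-year window.  Records with missing deficits marginalize
  implicitly: the health term sums the state distribution over all
  completions, and mortality terms condition on pool individuals matching
  the observed sub-vector (the ``density_from_pool`` option applies this
  pool estimator to all uncensored records, which is much cheaper inside an
  optimizer loop).

Degenerate parameter vectors that leave no simulated survivors where the
data need them yield ``-inf`` rather than raising, so an optimizer can
discard them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import ModelParameters
from .simulate import DEFAULT_HORIZON, RngSpec, _run_batch

__all__ = ["CohortRecord", "StateDistribution", "LikelihoodConfig",
           "SurvivalCurve", "estimate_state_distribution", "survival_function",
           "log_likelihood", "EmptyBinError"]


class EmptyBinError(RuntimeError):
    """An age bin contains no simulated survivors."""


@dataclass
class CohortRecord:
    """One cross-sectional row: baseline age, deficits, survival age, flag.

    ``deficits`` is a float vector with entries 0.0, 1.0 or NaN (missing);
    ``survival_age`` is min(death age, censoring age); ``censored`` is 1 if
    the death age is beyond the observation window.
    """

    baseline_age: float
    deficits: np.ndarray
    survival_age: float
    censored: int

    def __post_init__(self) -> None:
        self.deficits = np.asarray(self.deficits, dtype=float)
        ok = np.isnan(self.deficits) | np.isin(self.deficits, (0.0, 1.0))
        if not ok.all():
            raise ValueError("deficits must be 0, 1 or NaN")
        if np.isnan(self.deficits).all():
            raise ValueError("at least one deficit must be observed")
        if self.censored not in (0, 1):
            raise ValueError("censored flag must be 0 or 1")
        if self.survival_age < self.baseline_age:
            raise ValueError("survival age precedes baseline age")

    @property
    def fully_observed(self) -> bool:
        return not np.isnan(self.deficits).any()


@dataclass
class LikelihoodConfig:
    """Simulation budgets and smoothing choices for likelihood estimation."""

    pool_size: int = 10_000        # birth-cohort pool per evaluation
    per_record: int = 500          # forward sims per uncensored record
    bin_width: float = 1.0         # years, health-term age bins
    pseudo_count: float = 0.5      # additive smoothing per joint state
    delta: float = 1.0             # years, death-density finite difference
    density_floor: float = 1e-10   # per year
    density_from_pool: bool = False
    min_bin_count: int = 10        # simulated survivors required per used bin
    horizon: float = DEFAULT_HORIZON


@dataclass
class StateDistribution:
    """Age-binned joint distribution over the 2^N deficit states.

    ``probs[k]`` is the smoothed probability table for bin k (sums to 1);
    ``counts[k]`` is the number of simulated survivors tallied in bin k.
    Bins with no survivors are flagged by ``counts[k] == 0`` and accessing
    them raises :class:`EmptyBinError` (distinct from a zero-probability
    state, which smoothing forbids anyway).
    """

    bin_edges: np.ndarray
    probs: np.ndarray
    counts: np.ndarray
    pseudo_count: float

    @property
    def n_states(self) -> int:
        return self.probs.shape[1]

    def bin_index(self, age: float) -> int:
        k = int(np.searchsorted(self.bin_edges, age, side="right")) - 1
        if k < 0 or k >= len(self.counts):
            raise ValueError(f"age {age} outside the binned range")
        return k

    def probability(self, state, age: float) -> float:
        """p(state | age bin); ``state`` is a 0/1 vector or an integer code."""
        k = self.bin_index(age)
        if self.counts[k] == 0:
            raise EmptyBinError(f"no simulated survivors in bin at age {age}")
        if np.ndim(state) > 0:
            state = int(np.asarray(state) @ (1 << np.arange(len(state))))
        return float(self.probs[k, state])


class SurvivalCurve:
    """Empirical step-function survival estimate S(a) from simulated deaths.

    S(a) = fraction of simulated trajectories with death age > a; equals 1
    below the baseline age by convention and is reported at the horizon even
    if positive there.
    """

    def __init__(self, start_age: float, death_ages: np.ndarray, horizon: float):
        self.start_age = float(start_age)
        self.horizon = float(horizon)
        death_ages = np.asarray(death_ages, dtype=float)
        self.n = death_ages.size
        self._deaths = np.sort(death_ages[np.isfinite(death_ages)])

    def __call__(self, a):
        a = np.asarray(a, dtype=float)
        frac = 1.0 - np.searchsorted(self._deaths, a, side="right") / self.n
        out = np.where(a < self.start_age, 1.0, frac)
        return float(out) if out.ndim == 0 else out

    @property
    def step_ages(self) -> np.ndarray:
        return self._deaths


# --------------------------------------------------------------------------
# pool machinery
# --------------------------------------------------------------------------

def birth_pool(params: ModelParameters, n_sim: int, rng: RngSpec,
               horizon: float = DEFAULT_HORIZON):
    """Simulate ``n_sim`` individuals from birth (no damage at t = 0).

    Returns ``(damage_ages, death_ages)`` arrays; see
    :func:`agingnet._ssa.simulate_batch`.
    """
    n = params.hyper.n
    t0s = np.zeros(n_sim)
    d0s = np.zeros((n_sim, n), dtype=np.int8)
    streams = rng.stream + np.arange(n_sim, dtype=np.uint64)
    return _run_batch(params, t0s, d0s, horizon, rng.seed, streams)


def pool_state_codes(dmg: np.ndarray, death: np.ndarray, age: float):
    """(codes, alive) of every pool individual at an exact age."""
    n = dmg.shape[1]
    pow2 = (1 << np.arange(n)).astype(np.int64)
    codes = (dmg <= age) @ pow2
    return codes, death > age


def estimate_state_distribution(params: ModelParameters, n_sim: int,
                                age_bins: np.ndarray, rng: RngSpec,
                                pseudo_count: float = 0.5,
                                horizon: float = DEFAULT_HORIZON
                                ) -> StateDistribution:
    """Tally a birth-cohort pool into p({d_i} | age bin) with smoothing.

    Each simulated individual alive at a bin's midpoint contributes its
    joint state there; ``pseudo_count`` is added to every state in every
    bin before normalizing.
    """
    edges = np.asarray(age_bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("age_bins must be increasing edges")
    dmg, death = birth_pool(params, n_sim, rng, horizon)
    return _tally(dmg, death, edges, params.hyper.n, pseudo_count)


def _tally(dmg, death, edges, n, pseudo_count) -> StateDistribution:
    n_bins = len(edges) - 1
    n_states = 1 << n
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(n_bins, dtype=np.int64)
    probs = np.full((n_bins, n_states), np.nan)
    for k, m in enumerate(mids):
        codes, alive = pool_state_codes(dmg, death, m)
        counts[k] = int(alive.sum())
        tab = np.bincount(codes[alive], minlength=n_states).astype(float)
        if counts[k] > 0:
            tab += pseudo_count
            probs[k] = tab / tab.sum()
    return StateDistribution(bin_edges=edges, probs=probs, counts=counts,
                             pseudo_count=pseudo_count)


def survival_function(params: ModelParameters, record: CohortRecord,
                      n_sim: int, rng: RngSpec,
                      horizon: float = DEFAULT_HORIZON) -> SurvivalCurve:
    """Individual survival S(a | t, {d}) from forward simulations.

    The record must be fully observed (marginalization over missing deficits
    is handled by :func:`log_likelihood`, not here).
    """
    if not record.fully_observed:
        raise ValueError("survival_function requires fully observed deficits")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    t0s = np.full(n_sim, record.baseline_age)
    d0s = np.tile(record.deficits.astype(np.int8), (n_sim, 1))
    streams = rng.stream + np.arange(n_sim, dtype=np.uint64)
    _, death = _run_batch(params, t0s, d0s, horizon, rng.seed, streams)
    return SurvivalCurve(record.baseline_age, death, horizon)


# --------------------------------------------------------------------------
# the full censored log-likelihood
# --------------------------------------------------------------------------

def _record_key(record: CohortRecord) -> int:
    """Stable 32-bit key of a record's content (for stream derivation)."""
    import zlib
    payload = np.concatenate([[record.baseline_age, record.survival_age,
                               float(record.censored)],
                              np.nan_to_num(record.deficits, nan=2.0)])
    return zlib.crc32(payload.tobytes())


def _as_arrays(data):
    t = np.array([r.baseline_age for r in data])
    d = np.stack([r.deficits for r in data])
    a = np.array([r.survival_age for r in data])
    c = np.array([r.censored for r in data])
    return t, d, a, c


def log_likelihood(params: ModelParameters, data: list,
                   config: LikelihoodConfig | None = None,
                   rng: RngSpec = RngSpec(0)) -> float:
    """Full censored log-likelihood, estimated from simulations.

    Uses one shared birth-cohort pool for the health terms and all
    pool-matched mortality terms, and (by default) per-record forward
    simulations for uncensored death densities.  With a fixed ``rng`` the
    value is deterministic, so repeated evaluations at different parameters
    share common random numbers.
    """
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    cfg = config or LikelihoodConfig()
    if cfg.pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    n = params.hyper.n
    n_states = 1 << n
    t, d, a, c = _as_arrays(data)

    dmg, death = birth_pool(params, cfg.pool_size, rng, cfg.horizon)

    # ---- health term: binned joint distribution -------------------------
    top = np.ceil(t.max() / cfg.bin_width + 1) * cfg.bin_width
    edges = np.arange(0.0, top + cfg.bin_width / 2, cfg.bin_width)
    dist = _tally(dmg, death, edges, n, cfg.pseudo_count)
    bins = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                   len(edges) - 2)
    # estimator-validity guard: the conditional probabilities below are
    # meaningless when almost no simulated individual survives to the ages
    # the data occupy, so such parameters are treated as invalid
    if np.any(dist.counts[bins] < max(1, cfg.min_bin_count)):
        return -np.inf

    ll = 0.0
    all_states = np.arange(n_states)
    pow2 = (1 << np.arange(n)).astype(np.int64)
    observed = ~np.isnan(d)
    obs_mask_bits = (observed @ pow2).astype(np.int64)
    obs_val_bits = (np.nan_to_num(d, nan=0.0).astype(np.int64) @ pow2)
    for m in range(len(data)):
        if observed[m].all():
            p_health = dist.probs[bins[m], obs_val_bits[m]]
        else:
            sel = (all_states & obs_mask_bits[m]) == obs_val_bits[m]
            p_health = dist.probs[bins[m], sel].sum()
        ll += np.log(p_health)

    # ---- matched pool sets at exact baseline ages ------------------------
    # match[m, p]: pool individual p alive at t_m with the observed deficits
    alive_t = death[None, :] > t[:, None]                       # (M, P)
    match = alive_t.copy()
    for i in range(n):
        dam_i = dmg[None, :, i] <= t[:, None]
        obs_i = observed[:, i]
        want = (d[:, i] == 1.0)[:, None]
        match &= ~obs_i[:, None] | (dam_i == want)
    n_match = match.sum(axis=1)

    # ---- censored survival terms ----------------------------------------
    surv_a = death[None, :] > a[:, None]
    cen = c == 1
    if cen.any():
        k_alive = (match[cen] & surv_a[cen]).sum(axis=1)
        n_m = n_match[cen]
        # fall back to the marginal (alive-at-t) pool when no state match
        none = n_m == 0
        if none.any():
            idx = np.flatnonzero(cen)[none]
            k_alive = k_alive.astype(float)
            n_m = n_m.astype(float)
            k_alive[none] = (alive_t[idx] & surv_a[idx]).sum(axis=1)
            n_m[none] = alive_t[idx].sum(axis=1)
            if np.any(n_m == 0):
                return -np.inf
        s_hat = (k_alive + 0.5) / (n_m + 1.0)
        ll += float(np.log(s_hat).sum())

    # ---- uncensored death densities --------------------------------------
    unc = np.flatnonzero(c == 0)
    if unc.size:
        fully = np.array([data[m].fully_observed for m in unc])
        pool_path = unc[~fully] if not cfg.density_from_pool else unc
        fwd_path = unc[fully] if not cfg.density_from_pool else np.array([], int)

        if pool_path.size:
            lo = (death[None, :] > a[pool_path, None] - cfg.delta / 2)
            hi = (death[None, :] > a[pool_path, None] + cfg.delta / 2)
            n_m = n_match[pool_path]
            k_lo = (match[pool_path] & lo).sum(axis=1)
            k_hi = (match[pool_path] & hi).sum(axis=1)
            none = n_m == 0
            if none.any():
                idx = pool_path[none]
                k_lo = k_lo.astype(float)
                k_hi = k_hi.astype(float)
                n_m = n_m.astype(float)
                k_lo[none] = (alive_t[idx] & lo[none]).sum(axis=1)
                k_hi[none] = (alive_t[idx] & hi[none]).sum(axis=1)
                n_m[none] = alive_t[idx].sum(axis=1)
                if np.any(n_m == 0):
                    return -np.inf
            # add-half continuity correction: a zero-death window costs
            # log(0.5 / n) rather than the hard floor
            dens = (k_lo - k_hi + 0.5) / (n_m + 1.0) / cfg.delta
            ll += float(np.log(np.maximum(dens, cfg.density_floor)).sum())

        if fwd_path.size:
            if cfg.per_record < 1:
                raise ValueError("per_record must be >= 1")
            R = cfg.per_record
            t0s = np.repeat(t[fwd_path], R)
            d0s = np.repeat(d[fwd_path].astype(np.int8), R, axis=0)
            horizons = np.repeat(a[fwd_path] + cfg.delta, R)
            # streams keyed to record content, so the likelihood is exactly
            # invariant to record order and duplicates contribute identically
            keys = np.array([_record_key(data[m]) for m in fwd_path],
                            dtype=np.uint64)
            streams = (np.uint64(cfg.pool_size) + np.uint64(rng.stream)
                       + np.uint64(R) * np.repeat(keys, R)
                       + np.tile(np.arange(R, dtype=np.uint64), fwd_path.size))
            _, fdeath = _run_batch(params, t0s, d0s, horizons, rng.seed, streams)
            fdeath = fdeath.reshape(fwd_path.size, R)
            k_lo = (fdeath > a[fwd_path, None] - cfg.delta / 2).sum(axis=1)
            k_lo = np.where(a[fwd_path] - cfg.delta / 2 < t[fwd_path], R, k_lo)
            k_hi = (fdeath > a[fwd_path, None] + cfg.delta / 2).sum(axis=1)
            dens = (k_lo - k_hi + 0.5) / (R + 1.0) / cfg.delta
            ll += float(np.log(np.maximum(dens, cfg.density_floor)).sum())

    return float(ll)
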