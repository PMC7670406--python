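"""Public simulation interface: individuals, cohorts, trajectories.

Wraps the compiled kernels in :mod:`agingnet._ssa` with validated dataclasses.
Damage is irreversible (0 -> 1 only); mortality competes with damage as one
extra event channel.  The default horizon is 120 years; individuals alive at
the horizon carry ``death_age = None`` rather than being killed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _ssa
from .model import HealthState, ModelParameters

__all__ = ["RngSpec", "Trajectory", "simulate_individual", "simulate_cohort",
           "state_at_age", "trajectories_to_frame", "DEFAULT_HORIZON"]

DEFAULT_HORIZON = 120.0


@dataclass(frozen=True)
class RngSpec:
    """Reproducible random stream: identical spec => identical trajectory."""

    seed: int
    stream: int = 0

    def child(self, offset: int) -> "RngSpec":
        return RngSpec(self.seed, self.stream + offset)


@dataclass
class Trajectory:
    """Ordered damage events and a death age for one simulated individual."""

    start_age: float
    initial_state: HealthState
    events: list  # list of (age, node) with strictly increasing ages
    death_age: float | None
    horizon: float

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.events]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise ValueError("event ages must be strictly increasing")
        if ages and ages[0] <= self.start_age:
            raise ValueError("event ages must exceed the start age")
        nodes = [i for _, i in self.events]
        if len(set(nodes)) != len(nodes):
            raise ValueError("each node may damage at most once")
        if self.death_age is not None:
            if ages and self.death_age < ages[-1]:
                raise ValueError("death age precedes the last damage event")
            if self.death_age > self.horizon:
                raise ValueError("death age exceeds the horizon")
        if ages and ages[-1] > self.horizon:
            raise ValueError("event ages exceed the horizon")


def _gl_for(params: ModelParameters):
    h = params.hyper
    deg = max(h.n_f * max(h.n_plus, 1), h.n_d2 * max(h.n_d1, 1), h.n_f, h.n_d2, 1)
    return _ssa.gauss_legendre_01(deg)


def _run_batch(params: ModelParameters, t0s, d0s, horizon, seed, streams,
               method: str = "inversion", thinning_window: float = 1.0):
    xg, wg = _gl_for(params)
    t0s = np.ascontiguousarray(t0s, dtype=float)
    d0s = np.ascontiguousarray(d0s, dtype=np.int8)
    streams = np.ascontiguousarray(streams, dtype=np.uint64)
    horizons = np.ascontiguousarray(
        np.broadcast_to(np.asarray(horizon, dtype=float), t0s.shape))
    if method == "inversion":
        return _ssa.simulate_batch(t0s, d0s, horizons, params.w,
                                   params.mu, params.gamma, params.beta,
                                   params.alpha, params.eta, xg, wg,
                                   np.uint64(seed), streams)
    if method == "thinning":
        return _ssa.simulate_batch_thinning(t0s, d0s, horizons, params.w,
                                            params.mu, params.gamma,
                                            params.beta, params.alpha,
                                            params.eta, np.uint64(seed),
                                            streams, float(thinning_window))
    raise ValueError(f"unknown method {method!r}")


def _to_trajectory(start_age, d0, dmg_row, death, horizon) -> Trajectory:
    events = [(float(dmg_row[i]), i) for i in range(len(d0))
              if d0[i] == 0 and np.isfinite(dmg_row[i])]
    events.sort()
    return Trajectory(
        start_age=float(start_age),
        initial_state=HealthState(deficits=np.array(d0, dtype=np.int8),
                                  age=float(start_age)),
        events=events,
        death_age=None if not np.isfinite(death) else float(death),
        horizon=float(horizon),
    )


def simulate_individual(params: ModelParameters, initial: HealthState,
                        horizon: float = DEFAULT_HORIZON,
                        rng: RngSpec = RngSpec(0),
                        method: str = "inversion") -> Trajectory:
    """Simulate one individual from ``initial`` until death or ``horizon``.

    Competing risks among all undamaged nodes and mortality; waiting times
    are drawn from the exact inhomogeneous-hazard distribution (see
    :mod:`agingnet._ssa`).  ``method="thinning"`` selects the rejection
    cross-check sampler.
    """
    if horizon <= initial.age:
        raise ValueError("horizon must exceed the initial age")
    if initial.n != params.hyper.n:
        raise ValueError("initial state size does not match the model")
    dmg, death = _run_batch(params, np.array([initial.age]),
                            initial.deficits[None, :], horizon,
                            rng.seed, np.array([rng.stream]), method=method)
    return _to_trajectory(initial.age, initial.deficits, dmg[0], death[0], horizon)


def simulate_cohort(params: ModelParameters, baselines: list,
                    horizon: float = DEFAULT_HORIZON,
                    rng: RngSpec = RngSpec(0),
                    replicates_per_baseline: int = 1) -> list:
    """Simulate ``replicates_per_baseline`` trajectories per baseline state.

    Stream ids are derived per (baseline, replicate), so each individual's
    trajectory is independent of batch order and of the other baselines.
    """
    if len(baselines) == 0:
        raise ValueError("baselines must be non-empty")
    if replicates_per_baseline < 0:
        raise ValueError("replicates_per_baseline must be >= 0")
    if replicates_per_baseline == 0:
        return []
    B = len(baselines)
    R = replicates_per_baseline
    t0s = np.repeat([b.age for b in baselines], R)
    d0s = np.repeat(np.stack([b.deficits for b in baselines]), R, axis=0)
    streams = rng.stream + np.arange(B * R, dtype=np.uint64)
    dmg, death = _run_batch(params, t0s, d0s, horizon, rng.seed, streams)
    return [_to_trajectory(t0s[k], d0s[k], dmg[k], death[k], horizon)
            for k in range(B * R)]


def state_at_age(traj: Trajectory, t: float) -> HealthState:
    """State at age ``t``: events at ages <= t applied (right-continuous)."""
    if t < traj.start_age:
        raise ValueError("query age precedes the trajectory start")
    if traj.death_age is not None and t >= traj.death_age:
        raise ValueError("query age is at or after death")
    if t > traj.horizon:
        raise ValueError("query age exceeds the horizon")
    d = traj.initial_state.deficits.copy()
    for age, node in traj.events:
        if age <= t:
            d[node] = 1
    return HealthState(deficits=d, age=float(t))


def trajectories_to_frame(trajectories: list) -> pd.DataFrame:
    """Long-format export: columns id, age, event_type (node index, DEATH, or
    a CENSORED summary row at the horizon)."""
    rows = []
    for k, tr in enumerate(trajectories):
        for age, node in tr.events:
            rows.append((k, age, str(node)))
        if tr.death_age is not None:
            rows.append((k, tr.death_age, "DEATH"))
        else:
            rows.append((k, tr.horizon, "CENSORED"))
    return pd.DataFrame(rows, columns=["id", "age", "event_type"])
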