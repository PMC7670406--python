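"""Ground-truth generators and cross-sectional cohort samplers.

Emulates the *structure* of the two observational aging studies the model
family is used with — an older cohort (study entry at ages 65-99, deaths
observed within a 6-year window, ~78% censored) and a broad adult cohort
(ages 20-85, 10-year window, ~88% censored), each with N = 10 binary
deficits — without reproducing their actual prevalences, which are not
bundled.  Cohorts are sampled by simulating individuals from birth,
conditioning on survival to the drawn baseline age (the left truncation a
cross-sectional study of the living implies), recording the deficit state at
baseline, and right-censoring the death age at baseline + window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import CohortRecord
from .model import ModelHyperparameters, ModelParameters
from .simulate import DEFAULT_HORIZON, RngSpec, _run_batch

__all__ = ["CohortDesign", "make_ground_truth", "sample_cross_sectional",
           "csha_preset", "nhanes_preset", "CSHA_DEFICITS"]

CSHA_DEFICITS = [
    "Walking difficulty", "Showering difficulty", "Phone difficulty",
    "Going out difficulty", "Shopping difficulty", "Preparing meal difficulty",
    "House work difficulty", "Take medicine difficulty",
    "Managing money difficulty", "Issues prevent normal activity",
]


@dataclass
class CohortDesign:
    """Shape of a synthetic cross-sectional study."""

    m: int
    age_min: float
    age_max: float
    censoring_window: float
    age_dist: str = "uniform"          # "uniform" | "truncnorm"
    age_mean: float | None = None      # truncnorm location
    age_sd: float | None = None        # truncnorm scale
    missingness: float = 0.0           # per-deficit missing probability
    seed: int = 0
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.censoring_window <= 0:
            raise ValueError("censoring window must be positive")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if self.age_dist not in ("uniform", "truncnorm"):
            raise ValueError(f"unknown age distribution {self.age_dist!r}")
        if self.age_dist == "truncnorm" and (self.age_mean is None
                                             or self.age_sd is None):
            raise ValueError("truncnorm requires age_mean and age_sd")
        if self.m < 1:
            raise ValueError("m must be >= 1")


def csha_preset(m: int = 8547, missingness: float = 0.0,
                seed: int = 0) -> CohortDesign:
    """Older-cohort preset: entry ages 65-99 (mean 76, sd 7), 6-year window."""
    return CohortDesign(m=m, age_min=65.0, age_max=99.0, censoring_window=6.0,
                        age_dist="truncnorm", age_mean=76.0, age_sd=7.0,
                        missingness=missingness, seed=seed,
                        labels=list(CSHA_DEFICITS))


def nhanes_preset(m: int = 9504, missingness: float = 0.1,
                  seed: int = 0) -> CohortDesign:
    """Broad-adult preset: entry ages 20-85 (mean 51, sd 20), 10-year window."""
    return CohortDesign(m=m, age_min=20.0, age_max=85.0,
                        censoring_window=10.0, age_dist="truncnorm",
                        age_mean=51.0, age_sd=20.0, missingness=missingness,
                        seed=seed, labels=list(CSHA_DEFICITS))


# --------------------------------------------------------------------------
# ground truth parameters
# --------------------------------------------------------------------------

def make_ground_truth(n: int, hyper: ModelHyperparameters | None = None,
                      connectivity: float = 0.4, effect_scale: float = 1.0,
                      seed: int = 0, target_median_death: float = 80.0
                      ) -> ModelParameters:
    """Random but realistically scaled parameters for synthetic studies.

    Weights are sparse (density ``connectivity``), mostly synergistic
    (damage begets damage); baseline damage rates give deficit prevalences
    that rise over adult life; mortality weights make deficits matter for
    survival.  The mortality scale is then calibrated by a short pilot
    simulation (bisection on a multiplier) so the birth-cohort median death
    age lands near ``target_median_death`` (always inside [60, 100]).
    """
    if hyper is None:
        hyper = ModelHyperparameters(n=n)
    if hyper.n != n:
        raise ValueError("hyper.n must equal n")
    rng = np.random.default_rng(seed)

    w = np.zeros((n, n))
    off_idx = np.array([(i, j) for i in range(n) for j in range(n) if i != j])
    n_edges = int(round(connectivity * len(off_idx)))
    if n_edges > 0:
        picked = off_idx[rng.choice(len(off_idx), size=n_edges, replace=False)]
        # mostly synergistic links: damage begets damage
        w[picked[:, 0], picked[:, 1]] = rng.normal(0.6, 0.3, size=n_edges) \
            * effect_scale

    mu = np.zeros((n, hyper.n_f))
    if hyper.n_f >= 1:
        mu[:, 0] = rng.uniform(0.0005, 0.002, size=n)
        for k in range(1, hyper.n_f):
            mu[:, k] = rng.uniform(0.0, 0.002, size=n) / 100.0 ** k

    gamma = np.zeros((n, hyper.n_plus + 1))
    gamma[:, 0] = rng.uniform(0.001, 0.004, size=n)
    if hyper.n_plus >= 1:
        gamma[:, 1] = rng.uniform(0.03, 0.12, size=n)
        for k in range(2, hyper.n_plus + 1):
            gamma[:, k] = rng.uniform(0.0, 0.03, size=n) / 2.0 ** k

    beta = rng.uniform(0.2, 1.0, size=n) * effect_scale
    alpha = np.zeros(hyper.n_d1 + 1)
    alpha[0] = 1e-4
    if hyper.n_d1 >= 1:
        alpha[1] = 0.05
        for k in range(2, hyper.n_d1 + 1):
            alpha[k] = 0.01 / 2.0 ** k
    eta = np.zeros(hyper.n_d2 + 1)
    if hyper.n_d2 >= 1:
        eta[1] = 0.02
        for k in range(2, hyper.n_d2 + 1):
            eta[k] = 1e-4 / 10.0 ** (k - 2)

    def with_scale(s: float) -> ModelParameters:
        al = alpha.copy()
        al[0] *= s
        if hyper.n_d1 >= 1:
            al[1:] *= s
        return ModelParameters(hyper=hyper, w=w, mu=mu, gamma=gamma,
                               beta=beta, alpha=al, eta=eta)

    def pilot_median(s: float) -> float:
        from .likelihood import birth_pool
        _, death = birth_pool(with_scale(s), 400, RngSpec(seed, 900_000))
        death = np.where(np.isfinite(death), death, DEFAULT_HORIZON)
        return float(np.median(death))

    lo, hi = 1e-3, 1e3     # median death is decreasing in the multiplier
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        if pilot_median(mid) > target_median_death:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.02:
            break
    return with_scale(np.sqrt(lo * hi))


# --------------------------------------------------------------------------
# cross-sectional sampling
# --------------------------------------------------------------------------

def _draw_baseline_ages(design: CohortDesign, rng: np.random.Generator,
                        size: int) -> np.ndarray:
    if design.age_dist == "uniform":
        return rng.uniform(design.age_min, design.age_max, size=size)
    from scipy import stats
    a = (design.age_min - design.age_mean) / design.age_sd
    b = (design.age_max - design.age_mean) / design.age_sd
    return stats.truncnorm.rvs(a, b, loc=design.age_mean, scale=design.age_sd,
                               size=size, random_state=rng)


def sample_cross_sectional(params: ModelParameters, design: CohortDesign,
                           max_attempt_factor: int = 50) -> list:
    """Sample a synthetic cross-sectional cohort from the model.

    Individuals are simulated from birth; a drawn baseline age is accepted
    only if the individual is still alive then (study entry among the
    living).  Survival age = min(death age, baseline + window); missing
    deficits are masked independently (MCAR).  Aborts with a diagnostic if
    the design is infeasible under the model (too many rejections).
    """
    n = params.hyper.n
    rng = np.random.default_rng(design.seed)
    records: list[CohortRecord] = []
    attempts = 0
    batch = max(256, design.m)
    stream0 = 0
    while len(records) < design.m:
        if attempts >= max_attempt_factor * design.m:
            raise RuntimeError(
                f"cohort design infeasible: {attempts} birth simulations "
                f"yielded only {len(records)}/{design.m} individuals alive in "
                f"[{design.age_min}, {design.age_max}]")
        k = min(batch, max_attempt_factor * design.m - attempts)
        t0s = np.zeros(k)
        d0s = np.zeros((k, n), dtype=np.int8)
        streams = stream0 + np.arange(k, dtype=np.uint64)
        stream0 += k
        attempts += k
        dmg, death = _run_batch(params, t0s, d0s, DEFAULT_HORIZON,
                                design.seed, streams)
        base = _draw_baseline_ages(design, rng, k)
        for p in range(k):
            if len(records) >= design.m:
                break
            t0 = base[p]
            if not death[p] > t0:      # dead before study entry: reject
                continue
            deficits = (dmg[p] <= t0).astype(float)
            if design.missingness > 0:
                miss = rng.random(n) < design.missingness
                if miss.all():
                    miss[rng.integers(n)] = False
                deficits[miss] = np.nan
            t_c = t0 + design.censoring_window
            if death[p] <= t_c:
                a_obs, c = float(death[p]), 0
            else:
                a_obs, c = float(t_c), 1
            records.append(CohortRecord(baseline_age=float(t0),
                                        deficits=deficits,
                                        survival_age=a_obs, censored=c))
    return records
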