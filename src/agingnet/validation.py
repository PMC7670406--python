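"""Validation battery: trajectory forecasts, imputation AUC, survival metrics.

Everything here consumes either simulated trajectories (prevalence and
frailty-index summaries) or a fitted/true model plus cohort records
(imputation AUC, survival curves, discrimination).  Survival discrimination
uses the age-dependent concordance index

    C_td = Pr( S1(a1) < S2(a1) | a1 < a2, individual 1 uncensored ),

evaluated at the earlier death age so crossing survival curves are handled;
calibration uses an R^2 built from inverse-probability-of-censoring weighted
Brier scores against the population Kaplan-Meier reference.  Confidence
intervals are percentile bootstrap over individuals (1000 resamples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from sklearn.metrics import roc_auc_score

from .likelihood import SurvivalCurve, birth_pool, survival_function
from .model import ModelParameters
from .simulate import DEFAULT_HORIZON, RngSpec

logger = logging.getLogger("agingnet")

__all__ = ["PrevalenceCurve", "MetricResult", "deficit_prevalence",
           "pairwise_prevalence", "fi_distribution", "leftout_deficit_auc",
           "kaplan_meier", "mean_survival_curve", "predict_survival_curves",
           "td_c_index", "brier_r2", "window_mortality_auc",
           "conditional_damage_rate"]

N_BOOTSTRAP = 1000


@dataclass
class PrevalenceCurve:
    """Deficit (or deficit-pair) prevalence among survivors vs age."""

    ages: np.ndarray
    values: np.ndarray
    se: np.ndarray
    index: object           # deficit index, or (i, j) pair

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age grid must be increasing")
        v = self.values[~np.isnan(self.values)]
        if np.any((v < 0) | (v > 1)):
            raise ValueError("prevalence values must lie in [0, 1]")


@dataclass
class MetricResult:
    """Point estimate with a 95% CI and the stratum it refers to."""

    estimate: float
    ci_low: float
    ci_high: float
    stratum: str = "all"
    n: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high or
                np.isnan(self.estimate)):
            raise ValueError("CI must contain the point estimate")


# --------------------------------------------------------------------------
# trajectory summaries
# --------------------------------------------------------------------------

def _traj_arrays(trajectories):
    """(start, damage_ages, death) arrays from a list of Trajectory."""
    P = len(trajectories)
    n = trajectories[0].initial_state.n
    start = np.array([tr.start_age for tr in trajectories])
    death = np.array([np.inf if tr.death_age is None else tr.death_age
                      for tr in trajectories])
    dmg = np.full((P, n), np.inf)
    for p, tr in enumerate(trajectories):
        dmg[p, tr.initial_state.deficits.astype(bool)] = tr.start_age
        for age, node in tr.events:
            dmg[p, node] = age
    return start, dmg, death


def deficit_prevalence(trajectories, ages) -> list:
    """Per-deficit prevalence among trajectories alive at each grid age."""
    ages = np.asarray(ages, dtype=float)
    start, dmg, death = _traj_arrays(trajectories)
    n = dmg.shape[1]
    curves = []
    vals = np.full((len(ages), n), np.nan)
    ses = np.full((len(ages), n), np.nan)
    for k, t in enumerate(ages):
        alive = (death > t) & (start <= t)
        m = alive.sum()
        if m == 0:
            continue
        p = (dmg[alive] <= t).mean(axis=0)
        vals[k] = p
        ses[k] = np.sqrt(p * (1 - p) / m)
    for i in range(n):
        curves.append(PrevalenceCurve(ages=ages, values=vals[:, i],
                                      se=ses[:, i], index=i))
    return curves


def pairwise_prevalence(trajectories, ages, pair) -> PrevalenceCurve:
    """Joint prevalence p(d_i = 1, d_j = 1 | alive at age)."""
    i, j = pair
    ages = np.asarray(ages, dtype=float)
    start, dmg, death = _traj_arrays(trajectories)
    vals = np.full(len(ages), np.nan)
    ses = np.full(len(ages), np.nan)
    for k, t in enumerate(ages):
        alive = (death > t) & (start <= t)
        m = alive.sum()
        if m == 0:
            continue
        both = ((dmg[alive, i] <= t) & (dmg[alive, j] <= t)).mean()
        vals[k] = both
        ses[k] = np.sqrt(both * (1 - both) / m)
    return PrevalenceCurve(ages=ages, values=vals, se=ses, index=(i, j))


def fi_distribution(trajectories, age: float):
    """Distribution of the Frailty Index among survivors at ``age``.

    Returns (support, probabilities) with support {0, 1/N, ..., 1}.
    """
    start, dmg, death = _traj_arrays(trajectories)
    n = dmg.shape[1]
    alive = (death > age) & (start <= age)
    if alive.sum() == 0:
        raise ValueError(f"no trajectories alive at age {age}")
    counts = (dmg[alive] <= age).sum(axis=1)
    hist = np.bincount(counts, minlength=n + 1).astype(float)
    return np.arange(n + 1) / n, hist / hist.sum()


# --------------------------------------------------------------------------
# imputation of left-out deficits
# --------------------------------------------------------------------------

def _bootstrap_auc(scores, labels, rng, n_boot=N_BOOTSTRAP):
    order = np.argsort(scores, kind="mergesort")
    s, y = np.asarray(scores)[order], np.asarray(labels)[order]
    m = len(s)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(m, size=m)
        yb, sb = y[idx], s[idx]
        if yb.min() == yb.max():
            vals[b] = np.nan
            continue
        vals[b] = roc_auc_score(yb, sb)
    vals = vals[~np.isnan(vals)]
    return np.percentile(vals, [2.5, 97.5]) if len(vals) else (np.nan, np.nan)


def leftout_deficit_auc(params: ModelParameters, records, leftout: int,
                        n_sim: int = 20_000, rng: RngSpec = RngSpec(0),
                        age_strata=None) -> list:
    """ROC AUC for imputing one left-out deficit from the others and age.

    For each record the score is the simulated probability
    p(d_j = 1 | {d_i, i != j}, t): among pool individuals (simulated from
    birth) alive at the record's baseline age with the record's other
    deficits, the fraction having deficit j.  Records with no alive matching
    simulated individual are dropped (count logged and reported).
    Returns overall MetricResult first, then one per age stratum if
    ``age_strata`` (bin edges) is given.
    """
    n = params.hyper.n
    records = [r for r in records if not np.isnan(r.deficits[leftout])]
    dmg, death = birth_pool(params, n_sim, rng)
    scores, labels, ages = [], [], []
    dropped = 0
    for r in records:
        t = r.baseline_age
        alive = death > t
        match = alive.copy()
        for i in range(n):
            if i == leftout or np.isnan(r.deficits[i]):
                continue
            match &= (dmg[:, i] <= t) == bool(r.deficits[i])
        k = match.sum()
        if k == 0:
            dropped += 1
            continue
        scores.append((dmg[match, leftout] <= t).mean())
        labels.append(int(r.deficits[leftout]))
        ages.append(t)
    if dropped:
        logger.info("leftout_deficit_auc: dropped %d/%d records with no "
                    "matching simulated individual", dropped, len(records))
    scores = np.array(scores)
    labels = np.array(labels)
    ages = np.array(ages)
    brng = np.random.default_rng((rng.seed, rng.stream, 77))

    def result(mask, label):
        s, y = scores[mask], labels[mask]
        if len(y) == 0 or y.min() == y.max():
            return MetricResult(np.nan, np.nan, np.nan, stratum=label,
                                n=int(mask.sum()), n_dropped=dropped)
        est = roc_auc_score(y, s)
        lo, hi = _bootstrap_auc(s, y, brng)
        return MetricResult(float(est), float(min(lo, est)),
                            float(max(hi, est)), stratum=label, n=len(y),
                            n_dropped=dropped)

    out = [result(np.ones(len(scores), bool), "all")]
    if age_strata is not None:
        edges = np.asarray(age_strata, dtype=float)
        for k in range(len(edges) - 1):
            mask = (ages >= edges[k]) & (ages < edges[k + 1])
            out.append(result(mask, f"[{edges[k]:g},{edges[k+1]:g})"))
    return out


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

def kaplan_meier(survival_ages, censor_flags, entry_ages=None):
    """Product-limit estimate of the population survival function.

    ``censor_flags`` uses the cohort convention (1 = censored).  With
    ``entry_ages`` the estimate accounts for left truncation (study entry
    among the living).  Returns a fitted
    :class:`lifelines.KaplanMeierFitter` (step function + Greenwood-type CI).
    """
    a = np.asarray(survival_ages, dtype=float)
    c = np.asarray(censor_flags, dtype=int)
    km = KaplanMeierFitter()
    km.fit(a, event_observed=1 - c, entry=entry_ages)
    return km


def predict_survival_curves(params: ModelParameters, records,
                            n_sim: int = 200, rng: RngSpec = RngSpec(0),
                            horizon: float = DEFAULT_HORIZON) -> list:
    """Per-record survival curves from forward simulations (shared seed)."""
    curves = []
    for m, r in enumerate(records):
        curves.append(survival_function(params, r, n_sim,
                                        rng.child(m * n_sim), horizon))
    return curves


def mean_survival_curve(params: ModelParameters, records,
                        n_sim: int = 200, rng: RngSpec = RngSpec(0),
                        ages=None, horizon: float = DEFAULT_HORIZON):
    """Population mean <S>_M of individual survival curves on a common grid.

    Returns (ages, values); individual curves equal 1 below their own
    baseline age by convention.
    """
    curves = predict_survival_curves(params, records, n_sim, rng, horizon)
    if ages is None:
        lo = min(r.baseline_age for r in records)
        ages = np.arange(np.floor(lo), horizon + 0.5, 0.5)
    ages = np.asarray(ages, dtype=float)
    vals = np.mean([c(ages) for c in curves], axis=0)
    return ages, vals


def _curve_matrix(curves, eval_ages):
    """S[m, k] = curve m evaluated at eval_ages[k]."""
    return np.stack([c(eval_ages) for c in curves])


def td_c_index(curves, survival_ages, censor_flags, age_strata=None,
               baseline_ages=None, n_boot: int = N_BOOTSTRAP,
               seed: int = 0) -> list:
    """Age-dependent concordance index of predicted survival curves.

    A pair (m1, m2) is comparable when m1 is uncensored and a1 < a2; it is
    concordant when S1(a1) < S2(a1) (ties count 0.5).  The stratified
    variant restricts pairs to a baseline-age bin (requires
    ``baseline_ages``).  Returns the overall MetricResult first, then one
    per stratum.
    """
    a = np.asarray(survival_ages, dtype=float)
    c = np.asarray(censor_flags, dtype=int)
    M = len(a)
    unc = np.flatnonzero(c == 0)
    rng = np.random.default_rng(seed)

    def compute(members):
        mem = np.asarray(members)
        u = mem[np.isin(mem, unc)]
        if u.size == 0:
            return MetricResult(np.nan, np.nan, np.nan, n=len(mem))
        a1 = a[u]
        # S[m, k] = S_m(a1_k) for every member m and uncensored member k
        S = _curve_matrix([curves[m] for m in mem], a1)
        own = np.searchsorted(mem, u)          # column k's owner row
        s_own = S[own, np.arange(u.size)]
        comparable = a[mem][:, None] > a1[None, :]
        # concordant when the earlier-dying individual (column owner) has the
        # lower predicted survival at its own death age
        score = np.where(comparable,
                         (S > s_own[None, :]) + 0.5 * (S == s_own[None, :]),
                         0.0)
        num = float(score.sum())
        den = float(comparable.sum())
        if den == 0:
            return MetricResult(np.nan, np.nan, np.nan, n=len(mem))
        est = num / den
        # percentile bootstrap over individuals via multiplicity vectors
        vals = np.empty(n_boot)
        comp_f = comparable.astype(float)
        for b in range(n_boot):
            cnt = np.bincount(rng.integers(len(mem), size=len(mem)),
                              minlength=len(mem)).astype(float)
            w_col = cnt[own]
            nb = float(cnt @ score @ w_col)
            db = float(cnt @ comp_f @ w_col)
            vals[b] = nb / db if db > 0 else np.nan
        vals = vals[~np.isnan(vals)]
        lo, hi = (np.percentile(vals, [2.5, 97.5]) if len(vals)
                  else (np.nan, np.nan))
        return MetricResult(float(est), float(min(lo, est)),
                            float(max(hi, est)), n=len(mem))

    out = [compute(np.arange(M))]
    out[0].stratum = "all"
    if age_strata is not None:
        if baseline_ages is None:
            raise ValueError("stratified C-index requires baseline_ages")
        t0 = np.asarray(baseline_ages, dtype=float)
        edges = np.asarray(age_strata, dtype=float)
        for k in range(len(edges) - 1):
            members = np.flatnonzero((t0 >= edges[k]) & (t0 < edges[k + 1]))
            if members.size == 0:
                continue
            r = compute(members)
            r.stratum = f"[{edges[k]:g},{edges[k+1]:g})"
            out.append(r)
    return out


def brier_r2(curves, survival_ages, censor_flags, eval_times,
             entry_ages=None, n_boot: int = N_BOOTSTRAP, seed: int = 0) -> list:
    """R^2 from IPCW Brier scores against the Kaplan-Meier reference.

    BS(t) averages (S_m(t))^2 / G(a_m) over individuals observed to die by t
    and (1 - S_m(t))^2 / G(t) over those still alive at t, where G is the
    censoring Kaplan-Meier; the reference model is the population KM curve.
    Returns one MetricResult per eval time (stratum label "t=...").
    """
    a = np.asarray(survival_ages, dtype=float)
    c = np.asarray(censor_flags, dtype=int)
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    M = len(a)
    km = kaplan_meier(a, c, entry_ages)
    cens_km = KaplanMeierFitter().fit(a, event_observed=c, entry=entry_ages)

    def G(x):
        return np.maximum(
            np.asarray(cens_km.survival_function_at_times(x)), 1e-8)

    S_model = _curve_matrix(curves, eval_times)            # (M, T)
    s_ref = np.asarray(km.survival_function_at_times(eval_times))
    rng = np.random.default_rng(seed)
    out = []
    g_am = G(np.maximum(a - 1e-9, 0.0))
    for k, t in enumerate(eval_times):
        died = (a <= t) & (c == 0)
        alive = a > t
        g_t = float(G(np.array([t]))[0])

        def contrib(s_m):
            z = np.zeros(M)
            z[died] = s_m[died] ** 2 / g_am[died]
            z[alive] = (1 - s_m[alive]) ** 2 / g_t
            return z

        z_model = contrib(S_model[:, k])
        z_ref = contrib(np.full(M, s_ref[k]))
        bs_m, bs_r = z_model.mean(), z_ref.mean()
        est = 1 - bs_m / bs_r if bs_r > 0 else np.nan
        vals = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(M, size=M)
            br = z_ref[idx].mean()
            vals[b] = 1 - z_model[idx].mean() / br if br > 0 else np.nan
        vals = vals[~np.isnan(vals)]
        lo, hi = (np.percentile(vals, [2.5, 97.5]) if len(vals)
                  else (np.nan, np.nan))
        out.append(MetricResult(float(est), float(min(lo, est)),
                                float(max(hi, est)), stratum=f"t={t:g}",
                                n=M))
    return out


def window_mortality_auc(params: ModelParameters, records, window: float,
                         n_sim: int = 200, rng: RngSpec = RngSpec(0)
                         ) -> MetricResult:
    """ROC AUC for predicting death within ``window`` years of baseline.

    Score is 1 - S(t + window); individuals censored before the window's
    end are excluded.  Degenerate labels (all died or all survived) are
    signalled with a ValueError.
    """
    labels, scores = [], []
    curves = predict_survival_curves(params, records, n_sim, rng)
    for r, curve in zip(records, curves):
        end = r.baseline_age + window
        if r.censored == 1 and r.survival_age < end:
            continue
        labels.append(int(r.censored == 0 and r.survival_age <= end))
        scores.append(1.0 - curve(end))
    labels = np.array(labels)
    scores = np.array(scores)
    if len(labels) == 0 or labels.min() == labels.max():
        raise ValueError("window mortality AUC undefined: all labels identical")
    est = roc_auc_score(labels, scores)
    lo, hi = _bootstrap_auc(scores, labels,
                            np.random.default_rng((rng.seed, rng.stream, 99)))
    return MetricResult(float(est), float(min(lo, est)), float(max(hi, est)),
                        n=len(labels))


def conditional_damage_rate(params: ModelParameters, source: int, target: int,
                            ages, n_sim: int = 20_000,
                            rng: RngSpec = RngSpec(0)) -> np.ndarray:
    """Mean damage rate of ``target`` given prior damage of ``source``.

    Gamma_{i<-j}(t) averages Gamma+_i over the simulated age-t distribution
    of states with d_i = 0 and d_j = 1.  Ages with no such simulated
    individual yield NaN.
    """
    ages = np.asarray(ages, dtype=float)
    dmg, death = birth_pool(params, n_sim, rng)
    out = np.full(len(ages), np.nan)
    gam = params.gamma[target]
    for k, t in enumerate(ages):
        states = dmg <= t
        sel = (death > t) & states[:, source] & ~states[:, target]
        if not sel.any():
            continue
        f = states[sel] @ params.w[target] + params.mu_of_t(target, t)
        f = np.maximum(f, 0.0)
        g = np.polyval(gam[::-1], f)
        out[k] = np.maximum(g, 0.0).mean()
    return out
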