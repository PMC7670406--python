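# agingnet

A weighted network model of human aging: stochastic accumulation of binary
health deficits on a weighted directed network, with competing mortality,
fitted to **cross-sectional, right-censored** cohort data by
simulation-based maximum likelihood.

## Who this is for

Researchers in quantitative aging and geriatric epidemiology who have
cohort tables of the common cross-sectional shape — one baseline
measurement of N binary health attributes (ADL/IADL difficulties, clinical
indicators) per individual, plus a survival age known only up to a short
censoring window — and who want a *generative* model: one that simulates
individual health trajectories and death ages forward from any baseline
age and deficit combination, rather than only scoring risk.

## The model

Each of N binary attributes d_i ∈ {0,1} damages irreversibly with rate

    Γ⁺_i(t, {d_j}) = φ( Σₙ γ⁺_{i,n} f_i ⁿ ),   f_i = φ( Σ_j w_ij d_j + μ_i(t) ),

where φ(x) = max(x, 0) and μ_i(t) is a monotone power series in age
standing in for unobserved physiology.  Mortality is a competing event with
rate Γ_D = φ(Σₙ αₙ xⁿ), x = φ(Σ_j β_j d_j + Σₙ ηₙ tⁿ).  The directed
weights w_ij encode how existing damage promotes further damage.  The model
is simulated exactly (event-driven SSA with time-dependent hazards) and
fitted by maximizing a censored log-likelihood

    L = Σ_{c=0} log p̂(a|{d},t) + Σ log p̂({d_i}|t) + Σ_{c=1} log Ŝ(a|{d},t)

whose every term is estimated from model simulations, using bounded
particle swarm optimization.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from agingnet import (ModelHyperparameters, make_ground_truth, csha_preset,
                      sample_cross_sectional, count_parameters)
from agingnet.likelihood import LikelihoodConfig, log_likelihood
from agingnet.simulate import RngSpec

hyper = ModelHyperparameters(n=10)          # study configuration
print(count_parameters(hyper))              # -> 188

# a small synthetic study: N=3 deficits, entry ages 65-99, 6-year window
h3 = ModelHyperparameters(n=3, n_f=1, n_plus=1, n_d1=1, n_d2=1)
truth = make_ground_truth(3, h3, seed=42)
records = sample_cross_sectional(truth, csha_preset(m=2000, seed=11))
print(np.mean([r.censored for r in records]))          # -> 0.8945
print(np.nanmean([r.deficits for r in records], 0))    # -> [0.47 0.48 0.65]

cfg = LikelihoodConfig(pool_size=30_000, per_record=1000)
print(round(log_likelihood(truth, records, cfg, RngSpec(3)), 1))  # -> -4711.2
```

The first number is the free-parameter count of the ten-deficit model with
series orders (4, 3, 3, 3).  The censored fraction (~0.89) and baseline
deficit prevalences (~0.5–0.65) show the sampler reproducing the structure
of an older-adult cross-sectional study; the last line evaluates the full
simulation-based censored log-likelihood of the generating parameters on
their own cohort.

A command-line interface mirrors the library:

```bash
agingnet synth --preset csha --n 3 --m 2000 --seed 11 \
         --out cohort.tsv --params-out truth.json
agingnet fit --data cohort.tsv --n 3 --seed 7 --out fitted.json
agingnet validate --params fitted.json --data cohort.tsv --seed 1 \
         --out metrics.json
```

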