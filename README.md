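# eggfr

Lifetime host–parasitoid functional-response modelling with explicit egg-production
dynamics: forward simulation, Bayesian (Metropolis–Hastings) fitting, DIC model
selection and averaging, and simulation-based parameter recovery.

## The problem

Classical functional-response experiments confine a parasitoid with hosts for a fixed
short period and fit Holling's type II/III curves, ignoring that a female's daily
parasitism is also limited by her physiology: how many mature eggs she carries, how
fast she matures new ones, and whether she resorbs unlaid eggs. `eggfr` implements an
integrated model family for *daily, lifelong* parasitism records — for each female, a
sequence of days with `n_offered` hosts and `n_parasitized` counted from emerged
wasps — of the kind produced by exposing encyrtid wasps (e.g. *Anagyrus* spp.
attacking *Hypogeococcus* mealybugs) to fresh host cohorts every day of their lives.

The daily expected parasitism couples behaviour and physiology by the law of the
minimum:

```
p(n, t) = f(n) ∧ e(t)        (∧ = minimum, additionally capped at n)
```

* `f(n)` — one of six functional-response equations: type I (`f = a·n`), type II
  (Holling disc, constant attack rate), and type III variants in which the attack
  rate λ rises with host density (`λ = b + a·n`, or `λ = a·n^(s−1)` so the disc
  numerator is `a·n^s`) or with the female's cumulative lifetime host exposure
  (experience variants `λ = b + a·x` and `λ = a·(x+n)^(s−1)`, `x` = hosts offered on
  all previous days). All disc variants share `f = λn / (1 + λHn)`, saturating at
  `1/H`.
* `e(t)` — the latent mature-egg stock, governed by one of eight nested equations:
  unlimited eggs; a fixed emergence load `e0` (pro-ovigenic); daily production
  `h0·g^(t−1)`; optional overnight resorption of a proportion `r` of unlaid eggs,
  possibly only of the excess over a threshold `u`; optional storage capacity `C`.

Crossing 6 functional responses with 8 egg equations gives the 48-model candidate
family. Observed counts are binomial, `k_t ~ Binomial(n_t, p_t/n_t)`; the stock is
propagated with the observed counts as eggs spent, so the likelihood is a product of
binomials. Models are fitted by component-wise random-walk Metropolis with
acceptance-rate adaptation, compared by DIC (models within 5 of the best are
averaged with `w ∝ exp(−ΔDIC/2)`), and goodness of fit is summarised by the
Cox–Snell generalized coefficient of determination.

Because this kind of study publishes point estimates rather than raw per-female
tables, the package ships a synthetic-experiment generator that mirrors the
published design — six nominal densities (10, 20, 40, 60, 80, 110 hosts/day), five
replicate females each, jittered daily offerings, gamma lifespans of a few days — so
that every pipeline stage is verifiable by generate-and-refit parameter recovery.

## Worked example

```python
from eggfr import *

# day-1 expectation at 13 offered hosts, linear type III point estimates
frp = FRParams(b=0.073, a=0.003, H=0.005)
fr_expected(FREquation.C, frp, 13)          # 1.4455  (prints as 1.45 rounded)

# simulate a full experiment under model C5 and refit it
p = PROFILES["cachamai_C5"]                 # generating values incl. e0=56, h0=8 ...
data = generate_experiment(p.model, p.frp, p.eggp, p.design, seed=1)
fit = mh_sample(p.model, data, iterations=20_000, burnin=10_000, seed=1)
dic(fit, p.model, data)                     # (597.71, 6.12)
fit.posterior_mean()["e0"]                  # 49.2  (posterior SD 2.2)
```

The numbered drivers under `analysis/` run the full narrative and write tables to
`results/`:

```bash
python analysis/01_simulate_experiments.py --seed 1   # 30-female datasets + manifests
python analysis/02_fit_candidate_models.py --seed 1   # DIC/GCD table over candidates
python analysis/03_model_selection.py                 # delta-DIC rule + averaging
python analysis/04_parameter_recovery.py              # 10-seed recovery battery
```

On the seed-1 synthetic C5 experiment the candidate table comes out as A1 869.4,
B1 871.3, B3 706.5, C1 845.5, C7 609.2, **C5 597.7, E5 595.5** — the two rising-
attack-rate type III models are selected together (ΔDIC 2.2 < 5, GCD ≈ 0.89), so no
unique model can be identified and they are averaged, reproducing the qualitative
selection outcome of this experimental design; the generating model beats the type I
/ unlimited-egg null in 10/10 recovery seeds.

The same pipeline is available from the shell: `eggfr simulate|fit|compare|recover`
(see `eggfr --help`).

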