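# Methods

## Model

One female's adult life is a sequence of days `t = 1, 2, …`. On day `t` she is
offered `n_t` fresh hosts (the previous day's hosts are removed, so there is no
prey depletion across days and the exposure window is fixed at one day — no free
exposure-time parameter). Her expected parasitism is the smaller of what searching
behaviour allows and what her egg supply allows,

    p_t = min( f(n_t), e_t, n_t ),

and the observed count is binomial per host, `k_t ~ Binomial(n_t, p_t / n_t)`.
Failed development and superparasitism are deliberately absorbed into this
observation noise rather than modelled.

### Functional-response equations (A–F)

| eq | attack rate λ | expected attacks |
|----|---------------|------------------|
| A  | —             | `min(a·n, n)` (type I; plateaus only via the cap at `n`) |
| B  | `a`           | `λn/(1+λHn)` (type II) |
| C  | `b + a·n`     | type III, attack rate linear in host number |
| D  | `b + a·x`     | type III via experience `x` |
| E  | `a·n^(s−1)`   | type III, disc numerator `a·n^s` |
| F  | `a·(x+n)^(s−1)` | E with experience added to the density |

`x` is the cumulative number of hosts *offered* on all days strictly before the
current one (a day-old female has `x = 0`; what she was shown counts whether or
not she parasitized it). Parameters: `b` ≥ 0 attack rate at emergence (day⁻¹),
`a` ≥ 0 attack-rate change, `H` ≥ 0 handling time (days, `1/H` the asymptote),
`s = 1 + q` ≥ 1 the density exponent. `f` is clamped to `[0, n]` so the per-host
probability is always a probability.

Two open reconstruction choices are worth flagging. The experience variable could
count hosts parasitized instead of offered, or include the current day; we use
prior-days offered. Equation F's experience could multiply the kernel instead of
entering the power; we use the D-analogous additive form.

### Egg-production equations (1–8)

The latent mature-egg stock `e_t` (continuous; only observations are integers)
starts at `e_1 = e0` (capped at `C` where a capacity applies; equation 1 keeps it
infinite) and is updated overnight in this order:

1. eggs laid are removed: `rem = e_t − min(k_t, e_t)`;
2. resorption: none (eq 3, 8), a proportion `r` of everything (eq 4, 6), or a
   proportion `r` of the excess over a threshold `u` — the stock is never resorbed
   below `u` (eq 5, 7);
3. production `h0·g^t` is credited (the term indexed to the day it becomes
   available; day-1 laying draws on `e0` alone);
4. the capacity cap `C` is applied (eq 6–8).

Equation 1 is unlimited supply, equation 2 a fixed load with no replenishment
(strictly pro-ovigenic); 3–7 add production, resorption, threshold and capacity in
a nested ladder, and 8 (production + capacity without resorption) completes the
2×2 of {resorption} × {capacity} on top of 3. With no laying and `g < 1` the stock
converges to `e0 + h0·g/(1−g)`.

The threshold semantics ("excess over `u`") is one of two defensible readings of
a verbal description; the alternative (resorb `r` of the whole remainder whenever
it exceeds `u`) was implemented and compared on synthetic recoveries — it
sharpens the recovery of `r` for the short-lived profile but degrades the
emergence load, and neither reading is clearly superior — so the excess rule was
kept. Both readings collapse to the same equations 4/6 as `u → 0`.

### Likelihood

Females are independent. Within a female the stock is propagated with the
*observed* counts as eggs spent, which makes `e_t` a deterministic function of
data and parameters and the likelihood a plain product of binomials — no
latent-state integration (the alternative, propagating expected layings, ignores
realized egg expenditure). Days with `n_t = 0` contribute nothing; `p_t = 0` with
`k_t > 0` yields −∞ rather than an error; a success probability of exactly 1 with
`k_t < n_t` is clamped to `1 − 10⁻¹²`.

The readable recursion lives in `lifetime.py`; sampling uses an identical flat
kernel (`_fast.py`), numba-compiled when available, asserted equal to the
reference (and to a from-first-principles enumeration oracle) in the tests.

## Inference

Component-wise random-walk Metropolis. Strictly positive parameters are proposed
multiplicatively on the log scale (with the Jacobian term in the acceptance
ratio); `r` and `s` use additive proposals with rejection outside their support.
Per-parameter step sizes are tuned every 100 burn-in iterations toward acceptance
in [0.2, 0.5] (×0.7 when below, ×1.4 when above) and frozen afterwards. The
initial point is drawn from the priors, re-drawn up to 100 times if the
likelihood starts at −∞. Chains are bit-reproducible from a seed. The reference
profile is 200,000 iterations with 100,000 burn-in; all experiments in this
repository use the desk-scale profile 20,000 / 10,000, at which a C5 fit of a
30-female dataset takes ~2 s and repeat fits from dispersed starting points agree
to well within one posterior SD.

Priors: positive parameters (`b, a, H, e0, h0, g, u, C`) get a normal(0, 100)
truncated at zero (i.e. half-normal, SD 10); `r ~ U(0, 1)`; `s ~ U(1, 5)`. Two
consequences are documented rather than hidden: a zero-centred prior shrinks a
weakly identified count-scale parameter by roughly its prior score times the
posterior variance (≈ −3 eggs on an emergence load near 56 with posterior SD ≈
2.3, more on the resorption threshold), and for a parameter the data barely
constrain the posterior is prior-dominated. A flat alternative for the egg load
was evaluated and rejected: it removes the shrinkage where the load is identified
but lets it drift arbitrarily where it is not, dragging correlated parameters
with it.

Model comparison: `DIC = D̄ + pD` with the Spiegelhalter plug-in
`pD = D̄ − D(θ̄)`, `θ̄` the posterior mean projected into the support if needed.
Negative `pD` (possible for strongly non-normal posteriors) is logged as a
warning, not an error. Models within 5 DIC of the minimum are selected; if more
than one survives, weights `w ∝ exp(−ΔDIC/2)` are used and parameter summaries
are averaged with the unconditional (between-model variance inflated) SD;
parameters absent from a model have their weight mass renormalized over the
models that carry them. Fit quality is the Cox–Snell generalized coefficient of
determination `1 − exp(2(ℓ₀ − ℓ₁)/N)` with `N` the number of female-days and the
null model a single constant per-host probability at its pooled MLE — the
minimal nested reference, since none is prescribed for this statistic.

## Synthetic experiments

The generator emulates the laboratory design the models were built for: six
nominal densities (10, 20, 40, 60, 80, 110 hosts/day) × five replicate females;
daily offered counts are the nominal ± uniform integer jitter of up to 3 (the
host supply is pulsed in reality, and published per-day ranges at low density
span about that much); lifespans are drawn from a gamma moment-matched to the
species profile (mean 4, SD 2 days for the short-lived profile; 5 and 3 for the
longer-lived one), rounded, and resampled below the 2-day minimum the design
implies. Daily counts come from the forward model itself. Two bundled species
profiles carry published point estimates as generating values: a short-lived
profile (equation C + threshold resorption, eq 5) and an experience-driven one
(equation D + eq 5 or, with capacity, eq 7).

What the generator does **not** emulate — and what passing recovery tests
therefore cannot certify about real data: overdispersion beyond binomial noise,
mortality correlated with oviposition effort, host-quality variation, and any
within-day behavioural structure. Real datasets of this kind show per-observation
deviances several times larger than the synthetic ones.

## What the design identifies, and what it does not

Ten-seed generate-and-refit batteries at the full design (30 females, ≈ 130
female-days) show three regimes:

* sharply identified: the attack-rate slope `a`, emergence attack rate `b`, the
  production ratio `g`, and the capacity `C` when late-life production makes it
  bind — posterior means typically within a few percent of the generating values;
* identified but diffuse and/or prior-shrunk: `e0`, `h0`, `H`, `u`, `r` for the
  short-lived profile — generating values sit within 2 posterior SDs in ≥ 7/10
  seeds, but posterior SDs are several-fold wider than the point precision a
  real-data analysis would print, and posterior means shift accordingly (e.g.
  egg load ~50 for a generating 56, threshold ~13 for 19);
* structurally unidentified: the emergence load under the experience equation D —
  its day-1 functional response (`λ = b` at zero experience) never probes a
  ~57-egg load at any offered density, and threshold resorption erases the
  load's memory within a day (∂e_{t+1}/∂e0 ≈ 1−r); its posterior is
  prior-dominated in every seed. This is a property of the design/model pair,
  not of the sampler, and it is asserted (as a red check, deliberately) in the
  acceptance suite.

The DIC machinery is robust to all of this: the generating model beats the type I
/ unlimited-egg null in 10/10 seeds even at a 4,000-iteration profile, and on
synthetic data from the linear type III model the two rising-attack-rate type III
variants are co-selected within ΔDIC < 5 — the same "no unique model" outcome the
published four-candidate DIC table produces when fed through the selection rule.

## Numerical choices

* Likelihood ε = 10⁻¹² for probability-1 clamping; −∞ propagates immediately.
* Binomial coefficients are precomputed per dataset (`gammaln`).
* DIC plug-in at the posterior mean, projected onto the support (clamp at 0, and
  into [0,1] / [1,∞) for `r` / `s`) with a logged warning if projection occurs.
* Lifespan discretization: round-then-resample (not truncate-and-shift), keeping
  the mean close to the target at the cost of ~2% excess SD.
* No thinning; acceptance-rate window 100; adaptation multipliers 0.7 / 1.4.
* Ties in `min(f, e, n)` need no tie-break — the minimum itself is the model.
* Degenerate inputs: empty datasets, non-consecutive days, `k > n`, negative
  stocks and invalid model names are rejected with `ValueError`s at the boundary.
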