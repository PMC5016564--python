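# Methods

## The design and the estimand

A BACIPS study samples a treatment and a control unit at the same occasions
before and after an intervention. Working with ratios rather than
differences makes effects proportional and comparable across response
variables with different scales and domains (survival on (0,1), density on
the positive reals). For a response x measured per period t,

    R_t      = x_treat,t / x_ctrl,t                     (per aligned posterior sample)
    R_BACI   = exp( mean_{t in after} log R_t  -  mean_{t in before} log R_t )

Averaging on the log scale treats the per-period ratios as log-normal and
makes the era summaries geometric means; eras weight periods equally, with
no weighting by interval length. Because every quantity is a posterior draw
vector and the division is done per sample, the posterior of R_BACI yields
direct statements such as P(increase >= 30%). The "increase >= x%" event is
the closed set {R >= 1 + x/100}; the x = 0 decrease cell is P(R < 1) so the
two x = 0 cells are complementary. A decrease of 100% or more is impossible
for a positive ratio; the table formatter reports such cells as 0.00 and
the computation refuses explicit requests for them.

## Study-design arithmetic

Occasions are calendar dates; interval lengths are exact Gregorian day
counts. Survival over an interval of d days is standardized to a base
period of 91.25 days (one quarter of a 365-day year) by giving the interval
the likelihood contribution S_t^(d/91.25); the base period is configurable.
Era labels: an interval is "after" iff it starts on or after the
installation date; an occasion inherits the era of the interval it
terminates, and an occasion terminating no interval takes its era from its
own date relative to installation. Under this rule the bundled seasonal
design (16 intervals from June 2007 to September 2012 plus one
abundance-only January 2007 session, installation December 2009) splits
into 10 before / 8 after occasions and 8 before / 8 after intervals, with
the terminal interval unusable for survival because its survival and
recapture parameters enter only through their product. The exact day of the
January 2007 session is a convention (the 15th); nothing downstream depends
on it.

## Closed-capture abundance (M0 with data augmentation)

Each site × period has two consecutive-day sessions under population
closure, summarized by (n10, n11, n01). M0 assumes one capture probability
p for all individuals and both sessions. The unknown N is recast by
augmenting the n observed individuals with z = 500 all-zero
pseudo-individuals (more than twice any plausible site abundance), each a
member of the population with probability psi ~ Uniform(0,1), which induces
N ~ DU(0, M), M = n + z; p ~ Uniform(0,1). Conditional on (psi, p) the
pseudo-individual inclusion indicators are iid Bernoulli, so the Gibbs
sweep draws their count u ~ Binomial(z, psi(1-p)^2 / (psi(1-p)^2 + 1-psi))
directly — an exact collapse of the per-indicator update — followed by
conjugate Beta draws for psi and p. Defaults are 3 chains, 1000 burn-in
sweeps, 15000 post-burn-in sweeps thinned by 3 (5000 kept per chain).

Two conducted-but-empty sessions are data under this model: integrating p
out of (1-p)^{2N} gives a posterior proportional to 1/(2N+1), not the
uniform prior. The sampler and the enumeration oracle agree on this
posterior; "no information" in the strict sense only arises when no
sessions exist.

Density is N × 100 / length_m (fish per 100 m). Watershed-level series are
per-draw geometric means across sites; N = 0 draws are floored at the
half-fish density 0.5 × 100 / length_m for their site before taking logs (a
continuity correction, configurable) so the log average stays defined.

## Open-population survival (hierarchical CJS)

Encounter histories are one 0/1 code per occasion, conditional on first
capture. Individuals detected leaving the system are right-censored
immediately after their last detection: they contribute survival and
detection terms up to that occasion and no "never seen again" term. The
likelihood is evaluated on the m-array (release cohort × first-recapture
counts plus a never-seen column), an exact sufficient reduction of the
per-individual product; equality of the two routes is tested.

Each watershed is fitted separately. Survival logits are exchangeable
within era strata: logit(S_t) ~ N(mu_g, sigma_g) for g in {before, after},
with mu_g ~ N(0, 100) (mean/sd parameterization) and 1/sigma_g^2 ~
Gamma(0.001, 0.001) (shape/rate); the two watersheds' fits together give
the four hyperdistributions of the design. The hierarchy lives on the logit
scale: a normal on the probability scale could not respect (0,1) under flat
hyperpriors. Recapture logits carry N(0, 1.75) with 1.75 read as a standard
deviation; its back-transformed 2.5th/97.5th percentiles are ~0.03/0.97,
i.e. effectively flat over the plausible range. Intervals with zero
releases are retained and their S_t is prior-dominated (drawn from the
hyperdistribution) rather than dropped.

Sampling is Metropolis-within-Gibbs, compiled with numba: adaptive
random-walk Metropolis on each logit parameter (proposal scales tuned
toward 0.44 acceptance during burn-in only, then frozen, preserving
detailed balance), and Gibbs updates for mu_g and 1/sigma_g^2 by
normal-gamma conjugacy. Defaults mirror a 10-chain protocol with 1000 kept
draws per chain, 1000 burn-in sweeps, and thinning by 6. Convergence is
the classic (non-split, non-rank-normalized) Gelman-Rubin R-hat per
parameter at the 1.1 threshold, computed on logit/log scales for bounded
parameters; a split-chain variant is available behind a flag and is
cross-checked against arviz in the tests. Identical chains make the
between-chain variance exactly zero and the statistic degenerates to
sqrt((n-1)/n); this is reported with a warning rather than clamped.

## Synthetic data

The generator emulates the study's structure: two watersheds, three
seasonal survival levels (winter low — default 0.52 — and spring/fall high
— 0.72/0.68 — on the base-period scale), staggered releases at every
occasion, Bernoulli survival per interval at S_t^exponent, Bernoulli
detection (default 0.45), detected-emigration censoring (default 0.02 per
detection), and two-day closed sessions (capture probability 0.35, site
abundances Poisson around 150). A background treatment/control difference
(odds factor 0.9) is present by default, exactly the spatial difference the
paired design must absorb. The treatment effect k_S multiplies survival
odds on treatment after-era intervals (closed in (0,1)); k_D multiplies
treatment after-era abundances. k = 1 is the null. Because the ratio
statistic lives on the probability scale, recovery targets are computed
from the realized simulated probabilities (an odds multiplier of 1.5 at
S ~ 0.5-0.7 is a probability-scale R_BACI of ~1.15), never from k itself.

What the generator does not emulate: movement between sites, detection
heterogeneity among individuals or antenna types, overdispersion, and
closure violations. Passing tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to these field
realities.

## Problem sizes and numerical choices

The replicate-level recovery experiments run at desk scale — 3 sites per
watershed, 6 before + 6 after quarterly intervals, 300 releases per
occasion, 4 chains × (500 burn + 2000 sweeps, thin 2) — chosen as the
smallest configuration at which the 95% interval for R_BACI is both
informative and calibrated; 50 replicates per condition. The M0 oracle
comparisons use fixed count configurations with z ≤ 500 and compare the
sampler to exhaustive enumeration of N with a 4001-point trapezoid
quadrature over p: means within 3 Monte-Carlo standard errors (effective
sample size by Geyer's initial positive sequence), tail percentiles within
3 asymptotic quantile standard errors plus one unit for integer-draw
discreteness. The CJS likelihood is checked exactly (1e-10) against
summation over all latent alive/dead trajectories for every detection
pattern of up to four occasions, censored and uncensored. Likelihood cells
are floored at 1e-300 before logs to keep impossible-event evaluations
finite; survival/recapture parameters are validated to lie strictly inside
(0,1).

## Known limitations

- Apparent survival only: censoring removes detected emigrants, but
  undetected permanent emigration still biases S_t downward.
- The CJS core has no continuous-resight or dead-recovery components, no
  overdispersion correction, and no model selection over nuisance
  structures; recapture is fully time-varying.
- M0 only (no behavioural, temporal, or heterogeneity responses within a
  session pair), exactly two secondary sessions.
- The terminal interval's survival is unidentified (confounded with the
  final recapture probability) and must be excluded from era means by the
  caller, as the bundled designs do.
- Era classification assumes a single installation event; phased
  installations need a user-supplied rule.
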