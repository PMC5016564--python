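# bacips

Bayesian effect sizes for **BACIPS** (before-after-control-impact paired
series) field studies built on mark-recapture data — the design used to ask
"how much did a restoration action change survival and density?" when
treatment sites cannot be randomized.

The package estimates juvenile-fish-style demographic parameters for a
treatment and a control watershed sampled at paired seasonal occasions, and
summarizes the treatment response as a posterior distribution of a ratio
statistic with a direct probabilistic reading ("the probability survival
increased by at least 30% is 0.88").

## What it computes

Three linked pieces:

1. **Seasonal survival** — a Cormack–Jolly–Seber model with time-varying
   survival `S_t` and recapture `p_t`, fitted separately per watershed.
   Unequal interval lengths are standardized to a 3-month base period (an
   interval of `d` days contributes `S_t^(d/91.25)`), and individuals
   detected emigrating are right-censored. Survival logits are drawn
   hierarchically from era strata, `logit(S_t) ~ N(μ_g, σ_g)` with flat
   hyperpriors `μ ~ N(0, 100)`, `1/σ² ~ Γ(0.001, 0.001)` — four
   hyperdistributions in all (treatment/control × before/after) — yielding
   shrinkage estimates. Nuisance logits get the weakly informative prior
   `logit(θ) ~ N(0, 1.75)`.
2. **Abundance and density** — closed-capture model M0 on two-day sessions
   via data augmentation (`M = n + z`, inclusion probability ψ, inducing
   `N ~ DU(0, M)`), a Gibbs sampler per site × period, densities as
   fish/100 m, and per-period watershed geometric means across sites.
3. **The effect statistic** — per period, the treatment:control ratio
   `R_t = x_treat / x_ctrl` per aligned MCMC sample; then

   `R_BACI = exp( mean_t log R_after,t − mean_t log R_before,t )`,

   the after-era geometric-mean ratio over the before-era one. `R_BACI = 1.28`
   means a 28% increase on the treatment watershed after the action,
   relative to the control. The posterior draw vector gives
   `P(increase ≥ x%)` and `P(decrease ≥ x%)` tables directly.

Convergence is monitored with the classic Gelman–Rubin R-hat (threshold
1.1). A synthetic-data module generates full BACIPS datasets with known
truth (seasonal survival, staggered releases, detected emigration, two-day
closed sessions, odds-scale treatment effects), so the whole pipeline is
testable without field data.

## Worked example

Simulate a desk-scale study (three sites per watershed, six quarterly
intervals per era, 300 releases per occasion) with a 1.5 odds-scale
survival effect after the action, fit both watersheds, and summarize:

```python
import warnings
import bacips as b

design = b.make_desk_design()                      # 6 before + 6 after quarterly intervals
truth = b.SimulationTruth.from_design(design, k_s=1.5, seed=3)
histories, counts, _ = b.simulate_baci_dataset(design, truth=truth,
                                               n_released_per_occasion=300, seed=3)
fits = {
    ws: b.fit_survival([h for h in histories if h.watershed == ws], design,
                       chains=4, iters_per_chain=1000, burn=500, thin=2, seed=i)
    for i, ws in enumerate(("treatment", "control"))
}
effect = b.survival_baci(fits["treatment"], fits["control"])
med, lo, hi = b.summarize_effect(effect)
print(f"R_BACI median {med:.2f} (95% CI {lo:.2f}-{hi:.2f}); "
      f"generating truth {truth.true_r_s_baci():.2f}")
print(effect.effect_table[["direction", "threshold_percent", "probability_2dp"]]
      .to_string(index=False))
```

prints

```
R_BACI median 1.13 (95% CI 1.01-1.28); generating truth 1.15
direction  threshold_percent  probability_2dp
 increase                  0             0.98
 increase                 20             0.17
 increase                 30             0.01
 increase                 50             0.00
 increase                100             0.00
 decrease                  0             0.02
 decrease                 20             0.00
 decrease                 30             0.00
 decrease                 50             0.00
```

The credible interval brackets the generating truth (1.15 — the odds-scale
multiplier 1.5 maps to a ~15% probability-scale effect at these survival
levels), and the effect table reads off the probability of any threshold of
interest: here a near-certain increase (0.98) that is very unlikely to
exceed 30%.

A `bacips` console script exposes the same workflow from a shell
(`bacips simulate`, `bacips fit-m0`, `bacips fit-survival`,
`bacips effect`); see `bacips --help`.

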