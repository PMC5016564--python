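"""Hierarchical Bayesian open-population survival (CJS with censoring).

Seasonal apparent survival S_t and recapture probability p_t are estimated
from PIT-tag encounter histories with a Cormack-Jolly-Seber likelihood,
conditional on first capture.  Intervals of unequal calendar length are
standardized to a common base period: an interval of d days contributes
S_t ** (d / base_period_days), so every S_t is interpreted on the base
(3-month) scale.  Individuals detected emigrating are right-censored after
their last detection and contribute no survival or chi term beyond it.

Survival logits are drawn hierarchically from era strata (before/after the
restoration action):  logit(S_t) ~ N(mu_g, sigma_g) with flat hyperpriors
mu_g ~ N(0, 100) and 1/sigma_g^2 ~ Gamma(0.001, 0.001); treatment and
control watersheds are fitted separately, giving the four hyperdistributions
of the BACI design.  Recapture logits carry the weakly informative nuisance
prior logit(p) ~ N(0, 1.75).  Posterior sampling is Metropolis-within-Gibbs
(see `_cjs_mcmc`); convergence is checked with the Gelman-Rubin R-hat at the
conventional 1.1 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from ._cjs_mcmc import run_cjs_chain
from .closed_capture import ConvergenceWarning
from .design import EncounterHistory, StudyDesign
from .diagnostics import RhatReport, gelman_rubin

__all__ = [
    "SurvivalParams",
    "PosteriorDraws",
    "CJSSurvival",
    "cjs_log_likelihood",
    "build_m_array",
    "fit_survival",
    "shrinkage_estimates",
]

NUISANCE_PRIOR_SD = 1.75  # logit-scale sd; back-transformed ~ flat on (0,1)


@dataclass
class SurvivalParams:
    """Per-interval survival and per-occasion recapture probabilities.

    ``s[t]`` is survival over interval t on the base-period scale (the
    interval contributes ``s[t] ** exponent_t``); ``p[t]`` is the recapture
    probability at occasion t+1 (no recapture parameter exists for the first
    occasion).  Values are held on the probability scale here; samplers work
    on logits.
    """

    s: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.s.shape != self.p.shape:
            raise ValueError("need one recapture probability per interval-terminating occasion")
        for name, arr in (("s", self.s), ("p", self.p)):
            if np.any(arr <= 0.0) or np.any(arr >= 1.0):
                raise ValueError(f"{name} must lie strictly inside (0, 1)")

    @property
    def logit_s(self) -> np.ndarray:
        return logit(self.s)

    @property
    def logit_p(self) -> np.ndarray:
        return logit(self.p)


def _effective_detections(h: EncounterHistory) -> list[int]:
    """Detection occasions, truncated at the censoring occasion."""
    occs = [i for i, d in enumerate(h.detections) if d == 1]
    if h.censored_after is not None:
        occs = [i for i in occs if i <= h.censored_after]
    return occs


def cjs_log_likelihood(
    histories: list[EncounterHistory] | EncounterHistory,
    params: SurvivalParams,
    design: StudyDesign,
) -> float:
    """Conditional-on-first-capture CJS log-likelihood of a history set.

    Reference per-individual implementation.  Each individual contributes,
    from its first capture: per-interval survival terms S_t^{e_t}, detection
    terms p / (1-p) at subsequent occasions, and — unless censored — the
    probability chi of never being seen after its last detection.  Censored
    individuals contribute nothing past their censoring occasion.
    """
    if isinstance(histories, EncounterHistory):
        histories = [histories]
    T = design.n_intervals
    K = T + 1
    e = np.array([iv.exponent for iv in design.intervals])
    se = params.s ** e
    p = params.p
    # chi[t]: never detected after occasion t given alive there
    chi = np.ones(K)
    for t in range(T - 1, -1, -1):
        chi[t] = (1.0 - se[t]) + se[t] * (1.0 - p[t]) * chi[t + 1]

    ll = 0.0
    for h in histories:
        if len(h.detections) != K:
            raise ValueError(
                f"history {h.individual_id!r} has {len(h.detections)} occasions; design has {K}"
            )
        dets = _effective_detections(h)
        first, last = dets[0], dets[-1]
        detset = set(dets)
        for t in range(first, last):
            ll += np.log(se[t])                     # survived interval t
            obs = (t + 1) in detset
            ll += np.log(p[t] if obs else 1.0 - p[t])
        if h.censored_after is None:
            ll += np.log(max(chi[last], 1e-300))
    return float(ll)


def build_m_array(histories: list[EncounterHistory], n_occasions: int) -> np.ndarray:
    """Reduce histories to the (T, T+1) m-array of cohort transition counts.

    Row i counts individuals released at occasion i; column j < T counts
    those next recaptured at occasion j+1; column T counts those never seen
    again.  A censored individual is simply not re-released after its last
    effective detection, the classical loss-on-capture treatment.
    """
    T = n_occasions - 1
    marr = np.zeros((T, T + 1))
    for h in histories:
        if len(h.detections) != n_occasions:
            raise ValueError(
                f"history {h.individual_id!r} has {len(h.detections)} occasions; "
                f"design has {n_occasions}"
            )
        dets = _effective_detections(h)
        for a, b in zip(dets, dets[1:]):
            marr[a, b - 1] += 1
        last = dets[-1]
        if h.censored_after is None and last < T:
            marr[last, T] += 1
    return marr


@dataclass
class PosteriorDraws:
    """Chain-labelled posterior draws from one watershed's survival fit.

    Arrays are shaped (chains, kept, dim): ``s`` and ``p`` with one column
    per interval / non-initial occasion, ``mu`` and ``sigma`` with one column
    per era stratum (order given by ``strata``).
    """

    s: np.ndarray
    p: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    interval_eras: list[str]
    strata: list[str]
    rhat: RhatReport
    watershed: str = "treatment"

    @property
    def n_draws(self) -> int:
        return self.s.shape[0] * self.s.shape[1]

    def s_flat(self) -> np.ndarray:
        """(total draws, T) survival draws with chains stacked."""
        return self.s.reshape(-1, self.s.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iter, parameter, value."""
        recs = []
        chains, kept, T = self.s.shape
        for c in range(chains):
            for k in range(kept):
                for t in range(T):
                    recs.append((c, k, f"S[{t}]", self.s[c, k, t]))
                    recs.append((c, k, f"p[{t + 1}]", self.p[c, k, t]))
                for g, name in enumerate(self.strata):
                    recs.append((c, k, f"mu[{name}]", self.mu[c, k, g]))
                    recs.append((c, k, f"sigma[{name}]", self.sigma[c, k, g]))
        return pd.DataFrame(recs, columns=["chain", "iter", "parameter", "value"])


class CJSSurvival(BaseEstimator):
    """Hierarchical CJS survival estimator for one watershed.

    Parameters mirror the sampling protocol: ``chains`` chains each keeping
    ``iters`` draws after ``burn`` burn-in sweeps with thinning ``thin``
    (every thin-th sweep retained).  ``mu_prior_sd``, ``gamma_a``/``gamma_b``
    and ``p_prior_sd`` set the hyperpriors mu ~ N(0, mu_prior_sd),
    1/sigma^2 ~ Gamma(a, b) and the nuisance prior logit(p) ~ N(0, p_prior_sd).

    Attributes after :meth:`fit`: ``draws_`` (:class:`PosteriorDraws`),
    ``rhat_``, ``m_array_``, ``interval_eras_``.
    """

    def __init__(self, chains: int = 10, iters: int = 1000, burn: int = 1000,
                 thin: int = 6, seed: int | None = None, mu_prior_sd: float = 100.0,
                 gamma_a: float = 0.001, gamma_b: float = 0.001,
                 p_prior_sd: float = NUISANCE_PRIOR_SD, rhat_threshold: float = 1.1):
        self.chains = chains
        self.iters = iters
        self.burn = burn
        self.thin = thin
        self.seed = seed
        self.mu_prior_sd = mu_prior_sd
        self.gamma_a = gamma_a
        self.gamma_b = gamma_b
        self.p_prior_sd = p_prior_sd
        self.rhat_threshold = rhat_threshold

    def fit(self, histories: list[EncounterHistory], design: StudyDesign, y=None) -> "CJSSurvival":
        eras = [iv.era for iv in design.intervals]
        if any(e is None for e in eras):
            raise ValueError("design intervals carry no era labels; run classify_sessions first")
        strata = sorted(set(eras), key=("before", "after").index)
        strat_idx = np.array([strata.index(e) for e in eras], dtype=np.int64)
        exponents = np.array([iv.exponent for iv in design.intervals])
        T = design.n_intervals
        K = T + 1

        watersheds = {h.watershed for h in histories}
        if len(watersheds) > 1:
            raise ValueError(
                f"histories span watersheds {sorted(watersheds)}; fit each watershed separately"
            )
        marr = build_m_array(histories, K)

        rng = np.random.default_rng(self.seed)
        chain_seeds = rng.integers(0, 2**31 - 1, size=self.chains)
        s_all = np.empty((self.chains, self.iters, T))
        p_all = np.empty((self.chains, self.iters, T))
        mu_all = np.empty((self.chains, self.iters, len(strata)))
        sig_all = np.empty((self.chains, self.iters, len(strata)))
        for c in range(self.chains):
            s, p, mu, sig = run_cjs_chain(
                marr, exponents, strat_idx, len(strata), self.iters, self.burn,
                self.thin, self.mu_prior_sd, self.gamma_a, self.gamma_b,
                self.p_prior_sd, int(chain_seeds[c]),
            )
            s_all[c], p_all[c], mu_all[c], sig_all[c] = s, p, mu, sig

        rhats: dict[str, float] = {}
        for t in range(T):
            rhats[f"S[{t}]"] = gelman_rubin(logit(np.clip(s_all[:, :, t], 1e-12, 1 - 1e-12)))
            rhats[f"p[{t + 1}]"] = gelman_rubin(logit(np.clip(p_all[:, :, t], 1e-12, 1 - 1e-12)))
        for g, name in enumerate(strata):
            rhats[f"mu[{name}]"] = gelman_rubin(mu_all[:, :, g])
            rhats[f"sigma[{name}]"] = gelman_rubin(np.log(sig_all[:, :, g]))
        report = RhatReport(rhats, threshold=self.rhat_threshold)
        if not report.passed:
            warnings.warn(f"R-hat >= {self.rhat_threshold} for: {report.failed}", ConvergenceWarning)

        self.m_array_ = marr
        self.interval_eras_ = eras
        self.rhat_ = report
        self.draws_ = PosteriorDraws(
            s=s_all, p=p_all, mu=mu_all, sigma=sig_all,
            interval_eras=eras, strata=strata, rhat=report,
            watershed=histories[0].watershed if histories else "treatment",
        )
        return self


def fit_survival(
    histories: list[EncounterHistory],
    design: StudyDesign,
    chains: int = 10,
    iters_per_chain: int = 1000,
    burn: int = 1000,
    thin: int = 6,
    seed: int | None = None,
    **prior_kwargs,
) -> PosteriorDraws:
    """Fit the hierarchical CJS model to one watershed's histories."""
    est = CJSSurvival(chains=chains, iters=iters_per_chain, burn=burn, thin=thin,
                      seed=seed, **prior_kwargs)
    return est.fit(histories, design).draws_


def shrinkage_estimates(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summaries of every S_t and of each stratum mean survival.

    Quantiles are taken per draw on the probability scale (equivalently,
    quantiles of logits back-transformed, by monotonicity).  Stratum rows
    summarize inverse-logit(mu_g), the hyperdistribution's central survival.
    """
    if draws.n_draws == 0:
        raise ValueError("no draws to summarize")
    rows = []
    s_flat = draws.s_flat()
    for t in range(s_flat.shape[1]):
        v = s_flat[:, t]
        rows.append(
            {
                "parameter": f"S[{t}]",
                "era": draws.interval_eras[t],
                "median": float(np.median(v)),
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
            }
        )
    mu_flat = draws.mu.reshape(-1, draws.mu.shape[2])
    for g, name in enumerate(draws.strata):
        v = expit(mu_flat[:, g])
        rows.append(
            {
                "parameter": f"S~[{name}]",
                "era": name,
                "median": float(np.median(v)),
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
            }
        )
    return pd.DataFrame(rows)
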