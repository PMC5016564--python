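"""Closed-capture model M0 abundance via data augmentation, and density.

Two consecutive-day capture sessions at a closed site yield capture-history
tallies n10 (first day only), n11 (both days), n01 (second day only); the
number of unique individuals is n = n10 + n11 + n01.  Model M0 assumes a
single capture probability p shared by both sessions and all individuals.

Unknown abundance N is handled by parameter-expanded data augmentation: the
n observed individuals are padded with z all-zero pseudo-individuals
(M = n + z), each included in the population with probability psi.  A
Uniform(0,1) prior on psi induces a discrete-uniform prior N ~ DU(0, M).
Conditional on (psi, p) the inclusion indicators of the pseudo-individuals
are iid Bernoulli, so the Gibbs sweep samples their *count* directly from a
Binomial — an exact collapse of the per-indicator update:

    u   | psi, p  ~  Binomial(z, psi q^2 / (psi q^2 + 1 - psi)),  q = 1 - p
    psi | u       ~  Beta(1 + n + u, 1 + z - u)
    p   | u       ~  Beta(1 + y, 1 + 2 N - y),   N = n + u,
                     y = n10 + n01 + 2 n11  (total captures)

Abundance draws convert to density as fish per 100 m by N * 100 / length_m,
and watershed-level series are per-draw geometric means across sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .diagnostics import RhatReport, gelman_rubin

__all__ = [
    "SessionCounts",
    "AbundanceDraws",
    "DensityDraws",
    "M0Abundance",
    "fit_m0",
    "abundance_to_density",
    "watershed_period_mean",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    """R-hat at or above the 1.1 threshold on one or more parameters."""


@dataclass(frozen=True)
class SessionCounts:
    """Capture-history tallies for one site and one two-session period."""

    site_id: str
    period_id: int
    n10: int
    n11: int
    n01: int

    def __post_init__(self) -> None:
        if min(self.n10, self.n11, self.n01) < 0:
            raise ValueError("capture-history counts must be nonnegative")

    @property
    def n(self) -> int:
        """Unique individuals captured."""
        return self.n10 + self.n11 + self.n01

    @property
    def total_captures(self) -> int:
        return self.n10 + self.n01 + 2 * self.n11


@dataclass
class AbundanceDraws:
    """Posterior draws of abundance N, shape (chains, draws per chain)."""

    site_id: str
    period_id: int
    draws: np.ndarray
    n_observed: int
    M: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws)
        if self.draws.ndim != 2:
            raise ValueError("draws must be (chains, kept) shaped")

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1)


@dataclass
class DensityDraws:
    """Posterior draws of density in fish per 100 m."""

    label: str  # site_id or watershed name
    period_id: int
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1)


class M0Abundance(BaseEstimator):
    """Bayesian M0 closed-capture abundance estimator with data augmentation.

    Parameters
    ----------
    z : int
        Augmentation size; M = n + z and the induced prior is N ~ DU(0, M).
    chains, iters, burn, thin : int
        Per-chain post-burn-in iteration count `iters`; `iters // thin`
        draws are retained per chain.
    seed : int or None
        Master seed; per-chain substreams are derived deterministically.

    Attributes (after :meth:`fit`)
    ------------------------------
    n_draws_ : ndarray, (chains, kept) retained draws of N
    p_draws_, psi_draws_ : matching draws of p and psi
    rhat_ : RhatReport for N, p, psi
    summary_ : pandas Series with median and 2.5/97.5 percentiles of N
    """

    def __init__(self, z: int = 500, chains: int = 3, iters: int = 15000,
                 burn: int = 1000, thin: int = 3, seed: int | None = None):
        self.z = z
        self.chains = chains
        self.iters = iters
        self.burn = burn
        self.thin = thin
        self.seed = seed

    def fit(self, counts: SessionCounts, y=None) -> "M0Abundance":
        if self.z < 1:
            raise ValueError("augmentation size z must be >= 1")
        n = counts.n
        y_cap = counts.total_captures
        z = self.z
        M = n + z
        rng_root = np.random.default_rng(self.seed)
        chain_seeds = rng_root.integers(0, 2**31 - 1, size=self.chains)

        kept = self.iters // self.thin
        n_draws = np.empty((self.chains, kept), dtype=np.int64)
        p_draws = np.empty((self.chains, kept))
        psi_draws = np.empty((self.chains, kept))

        for c in range(self.chains):
            rng = np.random.default_rng(int(chain_seeds[c]))
            psi = rng.uniform()
            p = rng.uniform()
            k = 0
            for it in range(self.burn + self.iters):
                q2 = (1.0 - p) ** 2
                r = psi * q2 / (psi * q2 + 1.0 - psi)
                u = rng.binomial(z, r)
                N = n + u
                psi = rng.beta(1 + n + u, 1 + z - u)
                p = rng.beta(1 + y_cap, 1 + 2 * N - y_cap)
                post = it - self.burn
                if post >= 0 and post % self.thin == 0 and k < kept:
                    n_draws[c, k] = N
                    p_draws[c, k] = p
                    psi_draws[c, k] = psi
                    k += 1

        self.counts_ = counts
        self.M_ = M
        self.n_draws_ = n_draws
        self.p_draws_ = p_draws
        self.psi_draws_ = psi_draws
        self.rhat_ = RhatReport(
            {
                "N": gelman_rubin(n_draws.astype(float)),
                "p": gelman_rubin(p_draws),
                "psi": gelman_rubin(psi_draws),
            }
        )
        if not self.rhat_.passed:
            warnings.warn(
                f"R-hat >= 1.1 for {self.rhat_.failed} "
                f"(site {counts.site_id}, period {counts.period_id})",
                ConvergenceWarning,
            )
        flat = n_draws.reshape(-1)
        self.summary_ = pd.Series(
            {
                "median": float(np.median(flat)),
                "q2.5": float(np.percentile(flat, 2.5)),
                "q97.5": float(np.percentile(flat, 97.5)),
                "mean": float(flat.mean()),
                "rhat_N": self.rhat_.rhats["N"],
            }
        )
        return self

    def abundance_draws_(self) -> AbundanceDraws:
        return AbundanceDraws(
            site_id=self.counts_.site_id,
            period_id=self.counts_.period_id,
            draws=self.n_draws_,
            n_observed=self.counts_.n,
            M=self.M_,
        )


def fit_m0(counts: SessionCounts, z: int = 500, chains: int = 3, iters: int = 15000,
           burn: int = 1000, thin: int = 3, seed: int | None = None) -> tuple[AbundanceDraws, np.ndarray]:
    """Fit model M0 to one site-period; returns (AbundanceDraws, p draws)."""
    est = M0Abundance(z=z, chains=chains, iters=iters, burn=burn, thin=thin, seed=seed).fit(counts)
    return est.abundance_draws_(), est.p_draws_


def abundance_to_density(draws: AbundanceDraws, length_m: float) -> DensityDraws:
    """Convert abundance draws to fish per 100 m of stream: N * 100 / length."""
    if length_m <= 0:
        raise ValueError("site length must be positive")
    return DensityDraws(
        label=draws.site_id,
        period_id=draws.period_id,
        draws=np.asarray(draws.draws, dtype=float) * 100.0 / length_m,
    )


def watershed_period_mean(
    site_density: list[DensityDraws],
    site_lengths: dict[str, float],
    label: str = "watershed",
    zero_floor: bool = True,
) -> DensityDraws:
    """Per-draw geometric mean of site densities for one watershed and period.

    Averaging is done on the log scale, per MCMC sample:
    exp(mean_site(log d)).  Zero densities (N = 0 draws) are floored at the
    half-fish density 0.5 * 100 / length_m for their site before taking logs
    (a continuity correction), so the geometric mean stays defined.
    """
    if not site_density:
        raise ValueError("at least one site is required")
    shapes = {d.draws.shape for d in site_density}
    periods = {d.period_id for d in site_density}
    if len(shapes) != 1:
        raise ValueError(f"draw-count mismatch across sites: {sorted(shapes)}")
    if len(periods) != 1:
        raise ValueError(f"sites span multiple periods: {sorted(periods)}")
    logs = []
    for d in site_density:
        arr = np.asarray(d.draws, dtype=float)
        if zero_floor:
            floor = 0.5 * 100.0 / site_lengths[d.label]
            arr = np.maximum(arr, floor)
        elif np.any(arr <= 0):
            raise ValueError(f"nonpositive density for site {d.label} with zero_floor disabled")
        logs.append(np.log(arr))
    gm = np.exp(np.mean(logs, axis=0))
    return DensityDraws(label=label, period_id=site_density[0].period_id, draws=gm)
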