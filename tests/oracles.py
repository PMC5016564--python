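"""Independent reference implementations used only to check the package.

Each oracle takes the dumbest correct route: day counting by single-day
iteration, closed-capture posteriors by exhaustive enumeration of N with a
fixed-grid quadrature over p, and the CJS likelihood by summing over every
latent alive/dead vector.  None of them shares code with the implementations
they validate.
"""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np
from scipy.special import gammaln


def count_days_by_iteration(start: dt.date, end: dt.date) -> int:
    """Walk forward one day at a time."""
    n = 0
    d = start
    while d < end:
        d += dt.timedelta(days=1)
        n += 1
    return n


def m0_grid_posterior(n10: int, n11: int, n01: int, z: int, grid: int = 4001):
    """Exhaustive posterior of N under M0 + data augmentation.

    Enumerates N in {n..M} with the induced discrete-uniform prior and
    integrates the Uniform(0,1) capture probability on a fixed grid
    (trapezoid rule).  Returns (Ns, pmf, mean, q2.5, q97.5).
    """
    n = n10 + n11 + n01
    y = n10 + n01 + 2 * n11  # total captures over the two sessions
    M = n + z
    Ns = np.arange(n, M + 1)
    p = np.linspace(1e-9, 1 - 1e-9, grid)
    log_terms = np.empty(Ns.shape)
    for i, N in enumerate(Ns):
        ll = y * np.log(p) + (2 * N - y) * np.log1p(-p)
        m = ll.max()
        log_terms[i] = m + np.log(np.trapezoid(np.exp(ll - m), p))
    logpost = gammaln(Ns + 1) - gammaln(Ns - n + 1) + log_terms
    pmf = np.exp(logpost - logpost.max())
    pmf /= pmf.sum()
    mean = float((Ns * pmf).sum())
    cdf = np.cumsum(pmf)
    q_lo = float(Ns[np.searchsorted(cdf, 0.025)])
    q_hi = float(Ns[np.searchsorted(cdf, 0.975)])
    return Ns, pmf, mean, q_lo, q_hi


def geyer_ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence, summed
    over chains (a conservative per-chain estimate)."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    ess_total = 0.0
    for x in chains:
        n = x.size
        x = x - x.mean()
        var = x.var()
        if var == 0:
            ess_total += n
            continue
        acf = np.correlate(x, x, mode="full")[n - 1:] / (var * n)
        # sum of adjacent autocorrelation pairs until it goes nonpositive
        tau = 1.0
        for k in range(1, n - 1, 2):
            pair = acf[k] + acf[k + 1]
            if pair <= 0:
                break
            tau += 2.0 * pair
        ess_total += n / tau
    return ess_total


def cjs_brute_force_likelihood(detections, s_eff, p, censored_after=None) -> float:
    """CJS history probability by summation over all latent alive vectors.

    ``s_eff[t]`` is the survival probability of interval t (exponent already
    applied); ``p[t]`` is detection at occasion t+1.  Conditioned on being
    alive at the first detection.  If censored, the history is truncated at
    the censoring occasion and no never-seen term applies.
    """
    detections = list(detections)
    K = len(detections)
    first = detections.index(1)
    end = K - 1 if censored_after is None else min(censored_after, K - 1)
    total = 0.0
    span = end - first  # latent states needed at occasions first+1..end
    for bits in itertools.product((0, 1), repeat=span):
        alive = [1] * (first + 1) + list(bits)
        prob = 1.0
        for t in range(first, end):
            a_now, a_next = alive[t], alive[t + 1]
            if a_now == 1:
                prob *= s_eff[t] if a_next == 1 else 1.0 - s_eff[t]
            elif a_next == 1:
                prob = 0.0
            if prob == 0.0:
                break
        if prob == 0.0:
            continue
        for occ in range(first + 1, end + 1):
            if detections[occ] == 1:
                prob *= p[occ - 1] if alive[occ] == 1 else 0.0
            else:
                prob *= (1.0 - p[occ - 1]) if alive[occ] == 1 else 1.0
            if prob == 0.0:
                break
        total += prob
    return total


def all_histories(n_occasions: int):
    """Every 0/1 detection pattern with at least one detection."""
    for bits in itertools.product((0, 1), repeat=n_occasions):
        if any(bits):
            yield bits
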