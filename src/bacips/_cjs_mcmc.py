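"""Numba kernels for the hierarchical CJS sampler.

The open-population likelihood is evaluated on the m-array (release cohort x
first-recapture occasion counts plus a never-seen-again column), a sufficient
reduction of the per-individual conditional-on-first-capture likelihood.
Logit survival and recapture parameters move by adaptive random-walk
Metropolis (scales tuned toward 0.44 acceptance during burn-in only, frozen
afterwards); stratum means and precisions are Gibbs-updated through
normal-gamma conjugacy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=False)
def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=False)
def cjs_marray_loglik(marr, se, p):
    """Log-likelihood of an m-array under time-varying CJS.

    marr : (T, T+1) counts; row i = released at occasion i, column j < T =
           first recaptured at occasion j+1, column T = never seen again.
    se   : (T,) per-interval survival already raised to its exponent.
    p    : (T,) recapture probability at occasions 1..T.
    """
    T = se.shape[0]
    chi = np.empty(T + 1)
    chi[T] = 1.0
    for t in range(T - 1, -1, -1):
        chi[t] = (1.0 - se[t]) + se[t] * (1.0 - p[t]) * chi[t + 1]
    ll = 0.0
    for i in range(T):
        m_never = marr[i, T]
        if m_never > 0.0:
            c = chi[i]
            if c < _TINY:
                c = _TINY
            ll += m_never * np.log(c)
        surv = 1.0
        nondet = 1.0
        for j in range(i, T):
            surv *= se[j]
            if j > i:
                nondet *= 1.0 - p[j - 1]
            m = marr[i, j]
            if m > 0.0:
                q = surv * nondet * p[j]
                if q < _TINY:
                    q = _TINY
                ll += m * np.log(q)
    return ll


@njit(cache=False)
def _loglik_from_logits(marr, e, x, y):
    T = e.shape[0]
    se = np.empty(T)
    p = np.empty(T)
    for t in range(T):
        se[t] = _expit(x[t]) ** e[t]
        p[t] = _expit(y[t])
    return cjs_marray_loglik(marr, se, p)


@njit(cache=False)
def run_cjs_chain(marr, e, strat, n_strata, kept, burn, thin,
                  mu_prior_sd, gamma_a, gamma_b, p_prior_sd, seed):
    """One MCMC chain; returns (s, p, mu, sigma) draw arrays.

    strat maps each interval to its hyperdistribution stratum (era).  The
    hierarchical prior is logit(S_t) ~ N(mu_g, 1/sqrt(tau_g)); recapture
    logits carry the fixed N(0, p_prior_sd) nuisance prior.
    """
    np.random.seed(seed)
    T = e.shape[0]
    G = n_strata

    x = np.random.normal(0.0, 1.0, T)   # logit S
    y = np.random.normal(0.0, 1.0, T)   # logit p
    mu = np.random.normal(0.0, 1.0, G)
    tau = np.ones(G)

    ls_x = np.full(T, -0.7)  # log proposal scales
    ls_y = np.full(T, -0.7)

    s_out = np.empty((kept, T))
    p_out = np.empty((kept, T))
    mu_out = np.empty((kept, G))
    sig_out = np.empty((kept, G))

    cur = _loglik_from_logits(marr, e, x, y)
    n_iter = burn + kept * thin
    k = 0
    for it in range(n_iter):
        gamma = 10.0 / (100.0 + it)
        adapting = it < burn

        for t in range(T):
            g = strat[t]
            prop = x[t] + np.exp(ls_x[t]) * np.random.normal()
            old = x[t]
            x[t] = prop
            new = _loglik_from_logits(marr, e, x, y)
            dprior = -0.5 * tau[g] * ((prop - mu[g]) ** 2 - (old - mu[g]) ** 2)
            loga = new - cur + dprior
            if np.log(np.random.random()) < loga:
                cur = new
                acc = 1.0
            else:
                x[t] = old
                acc = 0.0
            if adapting:
                ls_x[t] += gamma * (acc - 0.44)

        for t in range(T):
            prop = y[t] + np.exp(ls_y[t]) * np.random.normal()
            old = y[t]
            y[t] = prop
            new = _loglik_from_logits(marr, e, x, y)
            dprior = -0.5 * (prop * prop - old * old) / (p_prior_sd * p_prior_sd)
            loga = new - cur + dprior
            if np.log(np.random.random()) < loga:
                cur = new
                acc = 1.0
            else:
                y[t] = old
                acc = 0.0
            if adapting:
                ls_y[t] += gamma * (acc - 0.44)

        for g in range(G):
            n_g = 0.0
            sx = 0.0
            for t in range(T):
                if strat[t] == g:
                    n_g += 1.0
                    sx += x[t]
            prec0 = 1.0 / (mu_prior_sd * mu_prior_sd)
            post_prec = prec0 + n_g * tau[g]
            post_mean = tau[g] * sx / post_prec
            mu[g] = post_mean + np.random.normal() / np.sqrt(post_prec)
            ss = 0.0
            for t in range(T):
                if strat[t] == g:
                    d = x[t] - mu[g]
                    ss += d * d
            tau[g] = np.random.gamma(gamma_a + 0.5 * n_g, 1.0 / (gamma_b + 0.5 * ss))

        post = it - burn
        if post >= 0 and post % thin == 0 and k < kept:
            for t in range(T):
                s_out[k, t] = _expit(x[t])
                p_out[k, t] = _expit(y[t])
            for g in range(G):
                mu_out[k, g] = mu[g]
                sig_out[k, g] = 1.0 / np.sqrt(tau[g])
            k += 1

    return s_out, p_out, mu_out, sig_out
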