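"""Compiled inner loops of the threshold-model Gibbs sampler.

Everything here operates on flat arrays prepared by
:mod:`wssgwas.threshold_model`. The residual variance is fixed at 1
throughout, so liabilities and effects are in residual-standard-deviation
units. Random numbers come from numba's per-process RNG, seeded once at the
top of the kernel, which makes a chain reproducible from (seed, inputs).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_INF = np.inf
_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _ncdf(x):
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True)
def _tail_normal(lo):
    """Standard normal conditioned on z > lo, for lo >= 0 (Robert's
    exponential-rejection sampler; efficient far into the tail)."""
    alpha = 0.5 * (lo + np.sqrt(lo * lo + 4.0))
    while True:
        z = lo - np.log(np.random.random()) / alpha
        d = z - alpha
        if np.random.random() <= np.exp(-0.5 * d * d):
            return z


@njit(cache=True)
def truncated_normal(mu, lo, hi):
    """Draw from N(mu, 1) truncated to (lo, hi); either bound may be inf."""
    a = lo - mu
    b = hi - mu
    if b == _INF:
        if a <= 0.45:
            while True:
                z = np.random.standard_normal()
                if z > a:
                    return mu + z
        return mu + _tail_normal(a)
    if a == -_INF:
        if -b <= 0.45:
            while True:
                z = np.random.standard_normal()
                if z < b:
                    return mu + z
        return mu - _tail_normal(-b)
    # both bounds finite
    if a <= 0.0 <= b and b - a >= 1.0:
        while True:
            z = np.random.standard_normal()
            if a < z < b:
                return mu + z
    if a > 0.0:
        c = a * a
    elif b < 0.0:
        c = b * b
    else:
        c = 0.0
    while True:  # uniform rejection on the interval
        z = a + (b - a) * np.random.random()
        if np.random.random() <= np.exp(0.5 * (c - z * z)):
            return mu + z


@njit(cache=True)
def run_chain_kernel(seed, n_iterations, burn_in, thin,
                     rec_animal, rec_cg, rec_cat, y,
                     an_ptr, an_rec, cg_ptr, cg_rec, nrec_per_animal,
                     h_indptr, h_indices, h_data,
                     t1, t2_init, sample_t2,
                     prior_kind, prior_nu, prior_scale, sigma_a2_init,
                     sample_liabilities, sample_variance):
    """One Gibbs chain; returns thinned samples and posterior BV moments.

    Sweep order: liabilities (truncated normals) -> contemporary-group
    effects (flat prior) -> breeding values (single-site Gauss-Seidel over
    the sparse H^-1 system) -> additive variance (scaled-inverse-chi-square)
    -> upper threshold (uniform between the bracketing liabilities).
    """
    np.random.seed(seed)
    n_rec = rec_animal.shape[0]
    n_an = nrec_per_animal.shape[0]
    n_cg = cg_ptr.shape[0] - 1

    beta = np.zeros(n_cg)
    a = np.zeros(n_an)
    sigma_a2 = sigma_a2_init
    t2 = t2_init

    n_samples = (n_iterations - burn_in) // thin
    sig_out = np.empty(n_samples)
    t2_out = np.empty(n_samples)
    a_sum = np.zeros(n_an)
    a_sumsq = np.zeros(n_an)
    stored = 0

    t2_at_y = t2  # threshold in force when liabilities were last drawn
    for it in range(n_iterations):
        if sample_liabilities:
            t2_at_y = t2
            for r in range(n_rec):
                mu = beta[rec_cg[r]] + a[rec_animal[r]]
                c = rec_cat[r]
                lo = -_INF
                hi = _INF
                if c == 0:
                    hi = t1
                elif c == 1:
                    lo = t1
                    if sample_t2:
                        hi = t2
                else:
                    lo = t2
                y[r] = truncated_normal(mu, lo, hi)

        for k in range(n_cg):
            nk = cg_ptr[k + 1] - cg_ptr[k]
            if nk == 0:
                continue
            s = 0.0
            for jj in range(cg_ptr[k], cg_ptr[k + 1]):
                r = cg_rec[jj]
                s += y[r] - a[rec_animal[r]]
            beta[k] = s / nk + np.random.standard_normal() / np.sqrt(nk)

        lam = 1.0 / sigma_a2
        for j in range(n_an):
            rj = 0.0
            for jj in range(an_ptr[j], an_ptr[j + 1]):
                r = an_rec[jj]
                rj += y[r] - beta[rec_cg[r]]
            hjj = 0.0
            off = 0.0
            for pp in range(h_indptr[j], h_indptr[j + 1]):
                col = h_indices[pp]
                if col == j:
                    hjj += h_data[pp]
                else:
                    off += h_data[pp] * a[col]
            cjj = nrec_per_animal[j] + lam * hjj
            mean = (rj - lam * off) / cjj
            a[j] = mean + np.random.standard_normal() / np.sqrt(cjj)

        if sample_variance:
            quad = 0.0
            for j in range(n_an):
                s = 0.0
                for pp in range(h_indptr[j], h_indptr[j + 1]):
                    s += h_data[pp] * a[h_indices[pp]]
                quad += a[j] * s
            if prior_kind == 0:  # scaled-inverse-chi-square (nu, S)
                df = n_an + prior_nu
                chi = 2.0 * np.random.standard_gamma(0.5 * df)
                sigma_a2 = (quad + prior_nu * prior_scale) / chi
            else:  # uniform prior on h2: p(s2) = (1+s2)^-2, MH step
                chi = 2.0 * np.random.standard_gamma(0.5 * (n_an - 2.0))
                prop = quad / chi
                ratio = ((1.0 + sigma_a2) / (1.0 + prop)) ** 2
                if np.random.random() <= ratio:
                    sigma_a2 = prop

        if sample_t2:
            # conditional draw: uniform between the bracketing liabilities
            mx = t1
            mn = 1.0e300
            for r in range(n_rec):
                if rec_cat[r] == 1:
                    if y[r] > mx:
                        mx = y[r]
                elif rec_cat[r] == 2:
                    if y[r] < mn:
                        mn = y[r]
            t2 = mx + (mn - mx) * np.random.random()
            # Metropolis move on t2 with the liabilities marginalized
            # (Cowles-style); the bracketing interval above shrinks like
            # 1/n, so this extra move is what actually traverses the
            # posterior. Liabilities are redrawn first thing next sweep,
            # restoring category consistency before anything else uses them.
            prop = t2 + 0.05 * np.random.standard_normal()
            if prop > t1:
                logr = 0.0
                ok = True
                for r in range(n_rec):
                    c = rec_cat[r]
                    if c == 0:
                        continue
                    mu = beta[rec_cg[r]] + a[rec_animal[r]]
                    if c == 1:
                        num = _ncdf(prop - mu) - _ncdf(t1 - mu)
                        den = _ncdf(t2 - mu) - _ncdf(t1 - mu)
                    else:
                        num = 1.0 - _ncdf(prop - mu)
                        den = 1.0 - _ncdf(t2 - mu)
                    if num < 1.0e-300:
                        ok = False
                        break
                    if den < 1.0e-300:
                        den = 1.0e-300
                    logr += np.log(num) - np.log(den)
                if ok and np.log(np.random.random()) <= logr:
                    t2 = prop

        if it >= burn_in and (it - burn_in + 1) % thin == 0 and stored < n_samples:
            sig_out[stored] = sigma_a2
            t2_out[stored] = t2
            for j in range(n_an):
                a_sum[j] += a[j]
                a_sumsq[j] += a[j] * a[j]
            stored += 1

    return sig_out, t2_out, a_sum, a_sumsq, y, beta, a, stored, t2_at_y
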