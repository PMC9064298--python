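"""Compiled kinetic Monte Carlo core.

Implements the same event rules as :mod:`mtgrowth.lattice` (association,
terminal dissociation, hydrolysis of buried GTP; trans-acting nucleotide;
energy-additive lateral contacts; staggered seam) as a tight numba loop with
rate-sum (direct-method) sampling.  The statistical contract — event ``i``
with probability ``rate_i / total``, waiting times exponential in the total
rate — is identical to racing per-event exponential execution times.
"""
from __future__ import annotations

import numba
import numpy as np

GTP = 0
GDP = 1

OK = 0
OVERFLOW = 1


@numba.njit(cache=True, inline="always")
def _lat_count(heights, p, i, n_pf, seam_off):
    n = 0
    # left neighbour
    q = p - 1 if p > 0 else n_pf - 1
    j = i + seam_off if p == 0 else i
    if 0 <= j < heights[q]:
        n += 1
    # right neighbour
    q = p + 1 if p < n_pf - 1 else 0
    j = i - seam_off if p == n_pf - 1 else i
    if 0 <= j < heights[q]:
        n += 1
    return n


@numba.njit(cache=True)
def kmc_sample(heights, nuc, seed_len, sample_dt, n_samples,
               conc, k_on, kd_long, lat_ratio, gdp_x, k_gtpase,
               site_dep, kon_long_f, kon_bucket_f, seam_off, rng_seed,
               out_sub, out_gdp, out_pf, record_pf):
    """Advance the lattice, recording state on a regular time grid.

    ``out_sub[k]`` receives the total non-seed dimer count and ``out_gdp[k]``
    the number of GDP-exposed protofilament ends at time ``k * sample_dt``
    (state is piecewise constant between reactions, so the value recorded is
    the state in effect at that instant).  Returns ``OVERFLOW`` if a
    protofilament outgrows the preallocated capacity, else ``OK``.
    """
    np.random.seed(rng_seed)
    n_pf = heights.shape[0]
    cap = nuc.shape[1]

    # per-protofilament count of hydrolysis-eligible (buried, non-seed) GTP
    elig = np.zeros(n_pf, dtype=np.int64)
    elig_tot = 0
    for p in range(n_pf):
        c = 0
        for i in range(seed_len, heights[p] - 1):
            if nuc[p, i] == GTP:
                c += 1
        elig[p] = c
        elig_tot += c

    # on-rate constants by lateral-contact count of the site
    kon_site = np.empty(3, dtype=np.float64)
    if site_dep:
        kon_site[0] = k_on * kon_long_f
        kon_site[1] = k_on
        kon_site[2] = k_on / kon_bucket_f
    else:
        kon_site[0] = k_on
        kon_site[1] = k_on
        kon_site[2] = k_on
    pow_ratio = np.empty(3, dtype=np.float64)
    pow_ratio[0] = 1.0
    pow_ratio[1] = lat_ratio
    pow_ratio[2] = lat_ratio * lat_ratio

    a_rate = np.empty(n_pf, dtype=np.float64)
    d_rate = np.empty(n_pf, dtype=np.float64)

    t = 0.0
    k = 0  # next sample index
    seed_sub = n_pf * seed_len
    while k < n_samples:
        # --- rates -------------------------------------------------------
        total = 0.0
        for p in range(n_pf):
            h = heights[p]
            nl = _lat_count(heights, p, h, n_pf, seam_off)
            r = kon_site[nl] * conc
            a_rate[p] = r
            total += r
            if h > seed_len:
                nl = _lat_count(heights, p, h - 1, n_pf, seam_off)
                kd = kd_long * pow_ratio[nl]
                if nuc[p, h - 2] == GDP:
                    kd *= gdp_x
                r = kon_site[nl] * kd
            else:
                r = 0.0
            d_rate[p] = r
            total += r
        total += k_gtpase * elig_tot

        if total <= 0.0:
            # frozen: state persists for all remaining samples
            break

        dt = -np.log(np.random.random()) / total
        t_next = t + dt

        # --- record samples passed by this waiting interval ---------------
        while k < n_samples and k * sample_dt <= t_next:
            s = 0
            g = 0
            for p in range(n_pf):
                s += heights[p]
                h = heights[p]
                if h > seed_len and nuc[p, h - 1] == GDP:
                    g += 1
            out_sub[k] = s - seed_sub
            out_gdp[k] = g
            if record_pf:
                for p in range(n_pf):
                    out_pf[k, p] = heights[p]
            k += 1
        if k >= n_samples:
            break
        t = t_next

        # --- choose and apply one event -----------------------------------
        u = np.random.random() * total
        done = False
        for p in range(n_pf):
            if u < a_rate[p]:
                h = heights[p]
                if h >= cap:
                    return OVERFLOW
                nuc[p, h] = GTP
                if h - 1 >= seed_len and nuc[p, h - 1] == GTP:
                    elig[p] += 1
                    elig_tot += 1
                heights[p] = h + 1
                done = True
                break
            u -= a_rate[p]
        if not done:
            for p in range(n_pf):
                if u < d_rate[p]:
                    h = heights[p] - 1
                    heights[p] = h
                    if h - 1 >= seed_len and nuc[p, h - 1] == GTP:
                        elig[p] -= 1
                        elig_tot -= 1
                    done = True
                    break
                u -= d_rate[p]
        if not done and elig_tot > 0:
            # hydrolysis: all eligible subunits share rate k_gtpase
            target = int(u / k_gtpase)
            if target >= elig_tot:
                target = elig_tot - 1
            for p in range(n_pf):
                if target < elig[p]:
                    # pick the (target+1)-th eligible GTP scanning from the tip
                    seen = 0
                    for i in range(heights[p] - 2, seed_len - 1, -1):
                        if nuc[p, i] == GTP:
                            if seen == target:
                                nuc[p, i] = GDP
                                elig[p] -= 1
                                elig_tot -= 1
                                break
                            seen += 1
                    break
                target -= elig[p]

    # frozen system: fill out the remaining grid with the final state
    while k < n_samples:
        s = 0
        g = 0
        for p in range(n_pf):
            s += heights[p]
            h = heights[p]
            if h > seed_len and nuc[p, h - 1] == GDP:
                g += 1
        out_sub[k] = s - seed_sub
        out_gdp[k] = g
        if record_pf:
            for p in range(n_pf):
                out_pf[k, p] = heights[p]
        k += 1
    return OK
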