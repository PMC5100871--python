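"""Compiled inner loops for the simulation engines.

Everything here is a plain numerical kernel: no domain objects, no I/O.
The public modules (:mod:`gendom.engine`, :mod:`gendom.equilibrium`) wrap
these kernels and expose readable reference implementations of the same
update rules; the test suite checks the two paths against each other.

Random-number contract
----------------------
Kernels use numba's port of the legacy NumPy Mersenne Twister, which is
stream-compatible with :class:`numpy.random.RandomState` for the calls
used here (``uniform`` and ``binomial``; the multinomial draw is written
as NumPy's own conditional-binomial chain).  A reference implementation
seeded with the same integer therefore consumes an identical random
stream, which makes trajectory-level equality testable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Termination codes for equilibrium iteration.
ACTIVE = 0
FULL_POLYMORPHISM = 1
ALLELE_LOST = 2
CAP_REACHED = 3
DEGENERATE = 4


@njit(cache=True)
def iterate_batch_kernel(W, p0, conv_tol, extinct_tol, max_generations):
    """Iterate the viability-selection recurrence for a batch of fitness sets.

    Parameters
    ----------
    W : (S, n, n) float64
        Symmetric genotype fitness matrices, one per set.
    p0 : (S, n) float64
        Initial allele-frequency vectors on the simplex.
    conv_tol : float
        L1 change below which the trajectory counts as converged.
    extinct_tol : float
        Frequency below which an allele counts as lost (checked before
        the convergence test each generation, and once on ``p0``).
    max_generations : int
        Iteration cap; trajectories still active afterwards are flagged.

    Returns
    -------
    status, generations, p_final
    """
    S = p0.shape[0]
    n = p0.shape[1]
    status = np.zeros(S, dtype=np.int8)
    gens = np.zeros(S, dtype=np.int64)
    p_final = np.empty((S, n))
    for s in range(S):
        p = p0[s].copy()
        pn = np.empty(n)
        st = ACTIVE
        for i in range(n):
            if p[i] < extinct_tol:
                st = ALLELE_LOST
        g = 0
        while st == ACTIVE and g < max_generations:
            g += 1
            wbar = 0.0
            for i in range(n):
                mi = 0.0
                for j in range(n):
                    mi += W[s, i, j] * p[j]
                pn[i] = p[i] * mi
                wbar += p[i] * mi
            if wbar <= 0.0:
                st = DEGENERATE
                break
            l1 = 0.0
            lost = False
            for i in range(n):
                pn[i] /= wbar
                d = pn[i] - p[i]
                if d < 0.0:
                    d = -d
                l1 += d
                if pn[i] < extinct_tol:
                    lost = True
                p[i] = pn[i]
            if lost:
                st = ALLELE_LOST
            elif l1 < conv_tol:
                st = FULL_POLYMORPHISM
        if st == ACTIVE:
            st = CAP_REACHED
        status[s] = st
        gens[s] = g
        for i in range(n):
            p_final[s, i] = p[i]
    return status, gens, p_final


@njit(cache=True)
def constructionist_kernel(seed, generations, alpha, random_alpha,
                           mutation_frequency, extinction_threshold,
                           two_n, common_cutoff):
    """Run one constructionist replicate.

    Per generation, in order: introduce one novel mutant allele,
    apply deterministic viability selection, apply multinomial drift
    (if ``two_n > 0``), then remove alleles whose frequency fell below
    the extinction threshold (strict ``<``) and renormalize.

    Random draws per generation, in order: the mutant's primary effect
    X (U[0,1]); its interaction column Y (n+1 values, U[0,1]); in
    random-alpha mode its weighting column (n+1 values, U[0,1/2]); one
    uniform for the frequency-proportional donor choice; with drift,
    the binomial chain of the multinomial sample.

    Returns
    -------
    (n, ids, X, Y, A, W, p, series_n, series_nc, series_wbar, clamps)
    """
    np.random.seed(seed)
    cap = 32
    X = np.zeros(cap)
    Y = np.zeros((cap, cap))
    A = np.zeros((cap, cap))
    W = np.zeros((cap, cap))
    p = np.zeros(cap)
    ids = np.zeros(cap, dtype=np.int64)

    # Founder allele: X_1 = Y_11 = 1/2 makes w_11 = 1/2 for every weighting.
    X[0] = 0.5
    Y[0, 0] = 0.5
    if random_alpha:
        a0 = np.random.uniform(0.0, 0.5)
    else:
        a0 = alpha
    A[0, 0] = a0
    W[0, 0] = a0 * (X[0] + X[0]) + (1.0 - 2.0 * a0) * Y[0, 0]
    p[0] = 1.0
    ids[0] = 1
    next_id = 2
    n = 1

    ser_n = np.zeros(generations + 1, dtype=np.int64)
    ser_nc = np.zeros(generations + 1, dtype=np.int64)
    ser_w = np.zeros(generations + 1)
    ser_n[0] = 1
    ser_nc[0] = 1
    ser_w[0] = W[0, 0]
    clamps = 0

    for g in range(generations):
        if n + 1 > cap:
            cap2 = cap * 2
            Xn = np.zeros(cap2)
            pn_ = np.zeros(cap2)
            idn = np.zeros(cap2, dtype=np.int64)
            Yn = np.zeros((cap2, cap2))
            An = np.zeros((cap2, cap2))
            Wn = np.zeros((cap2, cap2))
            for i in range(n):
                Xn[i] = X[i]
                pn_[i] = p[i]
                idn[i] = ids[i]
                for j in range(n):
                    Yn[i, j] = Y[i, j]
                    An[i, j] = A[i, j]
                    Wn[i, j] = W[i, j]
            X, p, ids, Y, A, W, cap = Xn, pn_, idn, Yn, An, Wn, cap2

        # --- mutation: novel allele A_{n+1} ---
        xn = np.random.uniform(0.0, 1.0)
        X[n] = xn
        ycol = np.random.uniform(0.0, 1.0, n + 1)
        if random_alpha:
            acol = np.random.uniform(0.0, 0.5, n + 1)
        else:
            acol = np.full(n + 1, alpha)
        for i in range(n + 1):
            Y[i, n] = ycol[i]
            Y[n, i] = ycol[i]
            A[i, n] = acol[i]
            A[n, i] = acol[i]
            wv = acol[i] * (X[i] + xn) + (1.0 - 2.0 * acol[i]) * ycol[i]
            W[i, n] = wv
            W[n, i] = wv
        u = np.random.uniform(0.0, 1.0)
        tot = 0.0
        for i in range(n):
            tot += p[i]
        target = u * tot
        run = 0.0
        donor = n - 1
        for i in range(n):
            run += p[i]
            if target < run:
                donor = i
                break
        t = mutation_frequency
        if p[donor] < t:
            t = p[donor]
            clamps += 1
        p[donor] -= t
        p[n] = t
        ids[n] = next_id
        next_id += 1
        n += 1

        # --- selection ---
        wbar = 0.0
        m = np.empty(n)
        for i in range(n):
            mi = 0.0
            for j in range(n):
                mi += W[i, j] * p[j]
            m[i] = mi
            wbar += p[i] * mi
        s = 0.0
        for i in range(n):
            p[i] = p[i] * m[i] / wbar
            s += p[i]
        for i in range(n):
            p[i] /= s

        # --- drift: multinomial over 2N gene copies ---
        # Written as NumPy's conditional-binomial chain so that the random
        # stream matches RandomState.multinomial exactly.
        if two_n > 0:
            ssum = 0.0
            for i in range(n):
                ssum += p[i]
            pv = np.empty(n)
            for i in range(n):
                pv[i] = p[i] / ssum
                p[i] = 0.0
            remaining = two_n
            rest = 1.0
            for i in range(n - 1):
                pi = pv[i] / rest
                if pi > 1.0:
                    pi = 1.0
                k = np.random.binomial(remaining, pi)
                p[i] = k / two_n
                remaining -= k
                if remaining <= 0:
                    remaining = 0
                    break
                rest -= pv[i]
            if remaining > 0:
                p[n - 1] = remaining / two_n

        # --- extinction filter (strict <) + renormalization ---
        keep = 0
        for i in range(n):
            if p[i] >= extinction_threshold:
                keep += 1
        if keep == 0:
            raise ValueError("all alleles fell below the extinction threshold")
        if keep < n:
            idx = np.empty(keep, dtype=np.int64)
            k = 0
            for i in range(n):
                if p[i] >= extinction_threshold:
                    idx[k] = i
                    k += 1
            s = 0.0
            for a in range(keep):
                ia = idx[a]
                X[a] = X[ia]
                ids[a] = ids[ia]
                p[a] = p[ia]
                s += p[ia]
            for a in range(keep):
                for b in range(keep):
                    Y[a, b] = Y[idx[a], idx[b]]
                    A[a, b] = A[idx[a], idx[b]]
                    W[a, b] = W[idx[a], idx[b]]
            for a in range(keep):
                p[a] /= s
            n = keep

        nc = 0
        for i in range(n):
            if p[i] > common_cutoff:
                nc += 1
        wb = 0.0
        for i in range(n):
            mi = 0.0
            for j in range(n):
                mi += W[i, j] * p[j]
            wb += p[i] * mi
        ser_n[g + 1] = n
        ser_nc[g + 1] = nc
        ser_w[g + 1] = wb

    return (n, ids[:n].copy(), X[:n].copy(), Y[:n, :n].copy(),
            A[:n, :n].copy(), W[:n, :n].copy(), p[:n].copy(),
            ser_n, ser_nc, ser_w, clamps)
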