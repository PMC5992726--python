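"""Independent reference computations used to verify the implementation.

Everything here is deliberately written the slow, literal way (explicit
loops, exhaustive path enumeration, exact rational arithmetic) and shares
no code with the package's vectorized/scaled implementations.
"""

from fractions import Fraction
from itertools import product
from math import comb, exp, log

import numpy as np


def exact_binomial_pmf(m: int, r: int, p: Fraction) -> Fraction:
    """C(r,m) p^m (1-p)^(r-m) in exact rational arithmetic."""
    return comb(r, m) * p**m * (1 - p) ** (r - m)


def enumerate_paths(B, A, pi):
    """Posterior quantities by exhaustive enumeration of all N^T state paths.

    B : (T, N) per-site emission probabilities
    A : (T-1, N, N) per-step transition matrices
    pi : (N,) initial distribution

    Returns (loglik, gamma, xi) summed over every path's joint probability.
    """
    B = np.asarray(B, dtype=float)
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    T, N = B.shape
    total = 0.0
    gamma = np.zeros((T, N))
    xi = np.zeros((max(T - 1, 0), N, N))
    for path in product(range(N), repeat=T):
        prob = pi[path[0]] * B[0, path[0]]
        for t in range(1, T):
            prob *= A[t - 1, path[t - 1], path[t]] * B[t, path[t]]
        total += prob
        for t in range(T):
            gamma[t, path[t]] += prob
        for t in range(T - 1):
            xi[t, path[t], path[t + 1]] += prob
    return log(total), gamma / total, xi / total


def eq5_transition_update(xi, d, tc, A0, D, n_contexts):
    """Term-by-term transcription of the constrained transition update.

    For each transition context c and each entry (i, j):

        numerator   = sum_t [c == c_{t,t+1}] xi_ijt (A0_ijc / A_ij(d_t)) e^{-d_t/D_c}
        denominator = sum over j of the numerators of row i

    with A_ij(d) = A0_ij e^{-d/D} + (1/N)(1 - e^{-d/D}).  Rows with zero
    denominator keep the previous value.
    """
    N = A0.shape[1]
    TC = n_contexts * n_contexts
    new = np.array(A0, dtype=float, copy=True)
    for c in range(TC):
        for i in range(N):
            nums = []
            for j in range(N):
                s = 0.0
                for t in range(len(d)):
                    if tc[t] != c:
                        continue
                    f = exp(-d[t] / D[c])
                    a = A0[c, i, j] * f + (1.0 - f) / N
                    s += xi[t, i, j] * (A0[c, i, j] / a) * f
                nums.append(s)
            denom = sum(nums)
            if denom > 0:
                for j in range(N):
                    new[c, i, j] = nums[j] / denom
    return new


def eq6_emission_update(gamma, m, r, ctx, n_contexts, prev_p):
    """Term-by-term transcription of the emission update:
    p'_ic = sum_t [c == c_t] gamma_it m_t / sum_t [c == c_t] gamma_it r_t."""
    N = gamma.shape[1]
    new = np.array(prev_p, dtype=float, copy=True)
    for i in range(N):
        for c in range(n_contexts):
            num = den = 0.0
            for t in range(len(m)):
                if ctx[t] != c:
                    continue
                num += gamma[t, i] * m[t]
                den += gamma[t, i] * r[t]
            if den > 0:
                new[i, c] = num / den
    return new
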