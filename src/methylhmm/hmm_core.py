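"""Two-state distance-aware HMM for methylation calling and imputation.

The hidden states are U (unmethylated) and M (methylated).  At cytosine t
with sequence context c_t, the observation (m_t methylated out of r_t total
reads) is emitted from a context-specific binomial with success probability
p_{i,c_t} for state i; a zero-coverage site has emission probability 1 in
both states, so its call is driven entirely by its neighbourhood.  The
transition from cytosine t to t+1, separated by d bp and in transition
context (c_t, c_{t+1}), interpolates exponentially between a zero-distance
stochastic matrix A° and the uninformative uniform matrix:

    A_ij(d) = A°_ij * exp(-d/D) + (1/N) * (1 - exp(-d/D))

with decay length D per transition context (estimated beforehand from the
correlation decay of neighbouring methylation levels, see
:mod:`methylhmm.correlation_decay`; it is held fixed during fitting).

Parameters are estimated by Baum-Welch.  The distance dependence changes
the M-step for A°: the Lagrange-constrained stationary condition weights
each pairwise posterior xi_ijt by (A°_ij / A_ij(d_t)) * exp(-d_t/D), with
rows renormalized.  Emission updates pool posterior-weighted counts per
context; the initial distribution pi is re-estimated from chain starts
(each chromosome is an independent chain).

1 - p_{U,CG} estimates the bisulfite conversion rate; 1 - p_{M,CG} is an
upper bound on the inappropriate (methylated-cytosine) conversion rate,
biased upward by intermediate methylation from tissue heterogeneity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.stats import binom as _binom

from .genome_context import CONTEXTS_6, Methylome

logger = logging.getLogger("methylhmm")

N_STATES = 2
STATE_NAMES = ("U", "M")

#: fitting defaults: initial emission probabilities break the U/M label
#: symmetry toward their conventional meaning; transitions start sticky.
INIT_P_U = 0.05
INIT_P_M = 0.80
INIT_A0_DIAG = 0.9
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 500
DEFAULT_DECAY_BP = 30.0


class NumericalError(RuntimeError):
    """Raised when the EM violates its monotonicity/finiteness contract."""


@dataclass
class HMMParams:
    """Parameters of the distance-aware two-state HMM.

    p : (2, C) binomial success probabilities per (state, context)
    A0 : (C*C, 2, 2) zero-distance transition matrices per transition context
    D : (C*C,) decay lengths in bp per transition context
    pi : (2,) initial state distribution
    """

    p: np.ndarray
    A0: np.ndarray
    D: np.ndarray
    pi: np.ndarray
    contexts: tuple[str, ...] = CONTEXTS_6

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.A0 = np.asarray(self.A0, dtype=float)
        self.D = np.atleast_1d(np.asarray(self.D, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        C = len(self.contexts)
        if self.D.size == 1:
            self.D = np.full(C * C, float(self.D[0]))
        if self.A0.ndim == 2:
            self.A0 = np.broadcast_to(self.A0, (C * C, N_STATES, N_STATES)).copy()
        self.validate()

    def validate(self) -> None:
        C = len(self.contexts)
        if self.p.shape != (N_STATES, C):
            raise ValueError(f"p must have shape (2, {C}), got {self.p.shape}")
        if self.A0.shape != (C * C, N_STATES, N_STATES):
            raise ValueError(f"A0 must have shape ({C * C}, 2, 2)")
        if self.D.shape != (C * C,):
            raise ValueError(f"D must have shape ({C * C},)")
        if np.any(self.D <= 0):
            raise ValueError("decay lengths D must be positive")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("binomial probabilities must lie in [0, 1]")
        if not np.allclose(self.A0.sum(axis=2), 1.0, atol=1e-12):
            raise ValueError("A0 rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-12):
            raise ValueError("pi must sum to 1")

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    def transition_context_index(self, ci: int, cj: int) -> int:
        return ci * self.n_contexts + cj

    def cg_index(self) -> int:
        return self.contexts.index("CG")


def default_params(
    contexts: tuple[str, ...] = CONTEXTS_6, D=DEFAULT_DECAY_BP
) -> HMMParams:
    """Fitting start point: p_U=0.05, p_M=0.80, sticky A° (diag 0.9), uniform pi."""
    C = len(contexts)
    p = np.vstack([np.full(C, INIT_P_U), np.full(C, INIT_P_M)])
    a0 = np.array(
        [[INIT_A0_DIAG, 1 - INIT_A0_DIAG], [1 - INIT_A0_DIAG, INIT_A0_DIAG]]
    )
    return HMMParams(p=p, A0=a0, D=D, pi=np.array([0.5, 0.5]), contexts=contexts)


@dataclass
class FitResult:
    """Output of a fitted model, aligned 1:1 with the input methylome.

    Sites with undefined sequence context are excluded from fitting; their
    rows carry NaN posteriors and status "undefined".
    """

    gamma: np.ndarray  # (T, 2) posteriors
    status: np.ndarray  # "U"/"M"/"undefined"
    rc_level: np.ndarray  # recalibrated level m' per site
    loglik_trace: np.ndarray
    params: HMMParams
    conversion_rate_u: float
    conversion_rate_m_upper: float
    converged: bool = True

    @property
    def max_posterior(self) -> np.ndarray:
        return np.max(self.gamma, axis=1)


# ---------------------------------------------------------------------------
# emissions and transitions
# ---------------------------------------------------------------------------

def emission_prob(m, r, p):
    """Binomial emission C(r,m) p^m (1-p)^(r-m); exactly 1 when r = 0."""
    m = np.asarray(m)
    r = np.asarray(r)
    if np.any(m > r) or np.any(m < 0):
        raise ValueError("need 0 <= m <= r")
    out = _binom.pmf(m, r, p)
    return out if out.ndim else float(out)


def transition_matrix(A0: np.ndarray, d: float, D: float, N: int = N_STATES) -> np.ndarray:
    """Distance-d transition matrix: A°·e^{-d/D} + (1/N)(1 - e^{-d/D})."""
    if D <= 0:
        raise ValueError("decay length D must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    f = np.exp(-d / D)
    return np.asarray(A0, dtype=float) * f + (1.0 - f) / N


def _emission_matrix(m, r, ctx, p) -> np.ndarray:
    """Per-site emission probabilities, shape (T, 2)."""
    B = np.empty((len(m), N_STATES))
    for i in range(N_STATES):
        B[:, i] = _binom.pmf(m, r, p[i, ctx])
    B[r == 0] = 1.0  # imputed sites: emission 1 in every state
    return B


def _step_arrays(methylome: Methylome, params: HMMParams):
    """Per-step (t -> t+1) transition-context index, distance and within-chain mask."""
    d = methylome.step_distances()
    within = d >= 0
    C = params.n_contexts
    ctx = methylome.context.astype(np.int64)
    tc = ctx[:-1] * C + ctx[1:]
    tc[~within] = -1
    return d, tc, within


def _transition_stack(d, tc, within, params) -> tuple[np.ndarray, np.ndarray]:
    """Stack of per-step transition matrices and the decay factors e^{-d/D}."""
    f = np.ones(len(d))
    f[within] = np.exp(-d[within] / params.D[tc[within]])
    A = np.empty((len(d), N_STATES, N_STATES))
    if len(d):
        A0 = np.empty_like(A)
        A0[within] = params.A0[tc[within]]
        A0[~within] = np.eye(N_STATES)  # placeholder, never used by the kernel
        A[:] = A0 * f[:, None, None] + (1.0 - f[:, None, None]) / N_STATES
    return A, f


@njit(cache=True)
def _fb_kernel(B, A, pi, starts, ends, gamma, xi):  # pragma: no cover - numba
    N = B.shape[1]
    loglik = 0.0
    for c in range(starts.shape[0]):
        s = starts[c]
        e = ends[c]
        Tn = e - s
        alpha = np.empty((Tn, N))
        scale = np.empty(Tn)
        norm = 0.0
        for i in range(N):
            alpha[0, i] = pi[i] * B[s, i]
            norm += alpha[0, i]
        if norm <= 0.0 or not np.isfinite(norm):
            return np.nan
        scale[0] = norm
        for i in range(N):
            alpha[0, i] /= norm
        loglik += np.log(norm)
        for t in range(1, Tn):
            norm = 0.0
            for j in range(N):
                a = 0.0
                for i in range(N):
                    a += alpha[t - 1, i] * A[s + t - 1, i, j]
                a *= B[s + t, j]
                alpha[t, j] = a
                norm += a
            if norm <= 0.0 or not np.isfinite(norm):
                return np.nan
            scale[t] = norm
            for j in range(N):
                alpha[t, j] /= norm
            loglik += np.log(norm)
        beta = np.empty((Tn, N))
        for i in range(N):
            beta[Tn - 1, i] = 1.0
        for t in range(Tn - 2, -1, -1):
            for i in range(N):
                b = 0.0
                for j in range(N):
                    b += A[s + t, i, j] * B[s + t + 1, j] * beta[t + 1, j]
                # scale by the forward normalizer of step t+1
                beta[t, i] = b / scale[t + 1]
        for t in range(Tn):
            g = 0.0
            for i in range(N):
                gamma[s + t, i] = alpha[t, i] * beta[t, i]
                g += gamma[s + t, i]
            for i in range(N):
                gamma[s + t, i] /= g
        for t in range(Tn - 1):
            z = 0.0
            for i in range(N):
                for j in range(N):
                    v = (
                        alpha[t, i]
                        * A[s + t, i, j]
                        * B[s + t + 1, j]
                        * beta[t + 1, j]
                        / scale[t + 1]
                    )
                    xi[s + t, i, j] = v
                    z += v
            for i in range(N):
                for j in range(N):
                    xi[s + t, i, j] /= z
    return loglik


def _forward_backward_arrays(methylome: Methylome, params: HMMParams):
    T = len(methylome)
    B = _emission_matrix(methylome.m, methylome.r, methylome.context, params.p)
    d, tc, within = _step_arrays(methylome, params)
    A, f = _transition_stack(d, tc, within, params)
    starts = methylome.chain_starts()
    ends = np.append(starts[1:], T)
    gamma = np.zeros((T, N_STATES))
    xi = np.zeros((max(T - 1, 0), N_STATES, N_STATES))
    loglik = _fb_kernel(B, A, params.pi, starts, ends, gamma, xi)
    if not np.isfinite(loglik):
        raise NumericalError(
            "forward pass produced zero or non-finite probability; "
            "emission parameters are degenerate for the observed counts"
        )
    xi[~within] = 0.0  # chromosome-boundary steps carry no transition
    return gamma, xi, float(loglik), (d, tc, within, A, f)


def forward_backward(methylome: Methylome, params: HMMParams):
    """Scaled forward-backward over per-chromosome chains.

    Returns (gamma, xi, loglik): gamma rows sum to 1; xi[t] is the pairwise
    posterior for the step t -> t+1 and sums to 1 for within-chromosome
    steps (zero rows at chromosome boundaries); loglik is the exact data
    log-likelihood.
    """
    mv = methylome.subset(methylome.context_valid)
    if len(mv) == 0:
        raise ValueError("methylome has no sites with a defined context")
    gamma, xi, loglik, _ = _forward_backward_arrays(mv, params)
    return gamma, xi, loglik


# ---------------------------------------------------------------------------
# M-step updates
# ---------------------------------------------------------------------------

def _update_transitions_arrays(xi, tc, within, A, f, params) -> np.ndarray:
    TC = params.n_contexts ** 2
    num = np.zeros((TC, N_STATES, N_STATES))
    if len(tc):
        w = within
        # Lagrange-stationary weight: xi * A°/A(d) * dA/dA° with dA/dA° = e^{-d/D}
        W = xi[w] * params.A0[tc[w]] * f[w, None, None] / A[w]
        np.add.at(num, tc[w], W)
    denom = num.sum(axis=2, keepdims=True)
    newA0 = params.A0.copy()
    ok = denom[:, :, 0] > 0
    rows = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    for c in range(TC):
        for i in range(N_STATES):
            if ok[c, i]:
                newA0[c, i] = rows[c, i] / rows[c, i].sum()
    n_kept = int((~ok).sum())
    if n_kept:
        logger.debug("kept previous A0 rows for %d zero-weight (context,row)s", n_kept)
    return newA0


def update_transitions(xi: np.ndarray, methylome: Methylome, params: HMMParams) -> np.ndarray:
    """One constrained M-step update of the zero-distance matrices A°.

    Implements the Lagrange-multiplier stationary condition of the
    distance-dependent objective; at d = 0 it reduces to the classical
    Baum-Welch transition update.  Transition contexts with zero total
    weight keep their previous row.
    """
    mv = methylome.subset(methylome.context_valid)
    d, tc, within = _step_arrays(mv, params)
    A, f = _transition_stack(d, tc, within, params)
    return _update_transitions_arrays(xi, tc, within, A, f, params)


def update_emissions(
    gamma: np.ndarray, methylome: Methylome, prev_p: np.ndarray | None = None
) -> np.ndarray:
    """Emission M-step: p'_ic = sum(gamma_it m_t) / sum(gamma_it r_t) per context.

    Zero-coverage sites contribute nothing.  Contexts with zero denominator
    keep ``prev_p`` (NaN when no previous value is given).
    """
    mv = methylome.subset(methylome.context_valid)
    C = len(mv.contexts)
    ctx = mv.context.astype(np.int64)
    p = np.empty((N_STATES, C))
    for i in range(N_STATES):
        num = np.bincount(ctx, weights=gamma[:, i] * mv.m, minlength=C)
        den = np.bincount(ctx, weights=gamma[:, i] * mv.r, minlength=C)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        if np.any(den == 0):
            logger.debug(
                "emission update: %d contexts with zero coverage weight in state %s",
                int((den == 0).sum()),
                STATE_NAMES[i],
            )
    if prev_p is not None:
        p = np.where(np.isnan(p), prev_p, p)
    return p


def recalibrated_levels(
    gamma: np.ndarray, params: HMMParams, contexts: np.ndarray
) -> np.ndarray:
    """Recalibrated level m' = p_U,c * gamma_U + p_M,c * gamma_M per site."""
    ctx = np.asarray(contexts, dtype=np.int64)
    return params.p[0, ctx] * gamma[:, 0] + params.p[1, ctx] * gamma[:, 1]


def conversion_rates(params: HMMParams) -> tuple[float, float]:
    """(1 - p_{U,CG}, 1 - p_{M,CG}).

    The first is the bisulfite conversion rate for unmethylated cytosines;
    the second is an upper bound on the inappropriate conversion rate of
    methylated cytosines (confounded with intermediate methylation).
    """
    cg = params.cg_index()
    return float(1.0 - params.p[0, cg]), float(1.0 - params.p[1, cg])


# ---------------------------------------------------------------------------
# Baum-Welch driver
# ---------------------------------------------------------------------------

def baum_welch(
    methylome: Methylome,
    init: HMMParams | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Fit the HMM by Baum-Welch with distance-aware transition updates.

    Decay lengths D in ``init`` are treated as fixed constants (estimate
    them first with :mod:`methylhmm.correlation_decay`).  Iterates until the
    absolute log-likelihood change drops below ``tol`` or ``max_iter`` is
    reached; a log-likelihood decrease beyond 1e-8 raises
    :class:`NumericalError`.  After convergence the state labels are
    swapped if needed so that state U has the smaller mean emission
    probability.

    The returned :class:`FitResult` is aligned 1:1 with the input
    methylome: every site, including zero-coverage ones, gets posteriors,
    a status call (posterior argmax; ties go to U) and a recalibrated
    level.  Undefined-context sites are excluded from fitting and carry
    NaN/"undefined".
    """
    valid = methylome.context_valid
    mv = methylome.subset(valid)
    if len(mv) == 0:
        raise ValueError("methylome has no sites with a defined context")
    params = init if init is not None else default_params(methylome.contexts)
    if params.contexts != methylome.contexts:
        raise ValueError("params and methylome use different context sets")

    trace: list[float] = []
    converged = False
    gamma = xi = None
    starts = mv.chain_starts()
    for _ in range(max_iter):
        gamma, xi, loglik, (d, tc, within, A, f) = _forward_backward_arrays(mv, params)
        if trace:
            if loglik < trace[-1] - 1e-8:
                raise NumericalError(
                    f"log-likelihood decreased from {trace[-1]:.10f} to "
                    f"{loglik:.10f}"
                )
            if abs(loglik - trace[-1]) < tol:
                trace.append(loglik)
                converged = True
                break
        trace.append(loglik)
        newA0 = _update_transitions_arrays(xi, tc, within, A, f, params)
        newp = update_emissions(gamma, mv, prev_p=params.p)
        newpi = gamma[starts].sum(axis=0)
        newpi = newpi / newpi.sum()
        params = replace(params, p=newp, A0=newA0, pi=newpi)
        logger.debug("EM iteration %d: loglik %.6f", len(trace), loglik)
    if not converged:
        # realign posteriors with the final parameters
        gamma, xi, loglik, _ = _forward_backward_arrays(mv, params)
        trace.append(loglik)
        logger.warning("Baum-Welch stopped at max_iter=%d without converging", max_iter)

    # label convention: U is the low-emission state
    if np.nanmean(params.p[0]) > np.nanmean(params.p[1]):
        params = replace(
            params,
            p=params.p[::-1].copy(),
            A0=params.A0[:, ::-1, ::-1].copy(),
            pi=params.pi[::-1].copy(),
        )
        gamma = gamma[:, ::-1].copy()

    T = len(methylome)
    full_gamma = np.full((T, N_STATES), np.nan)
    full_gamma[valid] = gamma
    status = np.full(T, "undefined", dtype="<U9")
    status[valid] = np.where(gamma[:, 1] > gamma[:, 0], "M", "U")
    full_rc = np.full(T, np.nan)
    full_rc[valid] = recalibrated_levels(gamma, params, mv.context)
    conv_u, conv_m = conversion_rates(params)
    return FitResult(
        gamma=full_gamma,
        status=status,
        rc_level=full_rc,
        loglik_trace=np.asarray(trace),
        params=params,
        conversion_rate_u=conv_u,
        conversion_rate_m_upper=conv_m,
        converged=converged,
    )


def fit_methylome(
    methylome: Methylome,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    max_distance: int = 100,
    min_pairs: int = 100,
) -> tuple[FitResult, "DecayFit"]:
    """Full fitting pipeline: decay pre-fit for D, then Baum-Welch."""
    from .correlation_decay import estimate_decay

    decay = estimate_decay(methylome, max_distance=max_distance, min_pairs=min_pairs)
    init = default_params(methylome.contexts, D=decay.D)
    fit = baum_welch(methylome, init=init, tol=tol, max_iter=max_iter)
    return fit, decay
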