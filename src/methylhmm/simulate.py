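"""Synthetic methylome generator following the model's own generative process.

Sites are laid out with geometric inter-cytosine gaps (dense, plant-like
spacing), contexts drawn i.i.d. from a realistic composition, hidden U/M
states generated by the distance-dependent Markov chain, and read counts
drawn as r ~ Poisson(lambda) (including zero-coverage mass) with
m ~ Binomial(r, p_{state,context}).  Bisulfite conversion failure enters as
p_U > 0: an unmethylated cytosine yields a methylated read with
probability p_U = 1 - conversion rate.

Default truth parameters emulate a typical plant WGBS regime and are
synthetic: conversion failure 1% (p_U = 0.01), p_M graded from 0.8 (CG)
down to 0.3 (CHH_rest) to reflect the context ordering of methylation
levels, sticky transitions (A° diagonal 0.9) with decay length D = 30 bp,
mean coverage 6X.  All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_context import CONTEXTS_6, CytosineSites, Methylome
from .hmm_core import HMMParams, N_STATES

#: synthetic context composition, loosely plant-like (CHH-heavy genome)
DEFAULT_CONTEXT_WEIGHTS = (0.14, 0.05, 0.09, 0.17, 0.12, 0.43)
#: synthetic per-context M-state emission probabilities, CG highest
DEFAULT_P_M = {
    "CG": 0.80,
    "CCG": 0.70,
    "CWG": 0.60,
    "CAA": 0.45,
    "CTA": 0.40,
    "CHH_rest": 0.30,
    "CHG": 0.65,
    "CHH": 0.35,
}
DEFAULT_CONVERSION_FAILURE = 0.01
DEFAULT_MEAN_GAP = 3.0
DEFAULT_COVERAGE = 6.0
DEFAULT_A0_DIAG = 0.9
DEFAULT_D_BP = 30.0


@dataclass
class SimulationTruth:
    """Ground truth of a simulated methylome: hidden states + generators."""

    states: np.ndarray  # 0 = U, 1 = M per site
    params: HMMParams
    conversion_failure: float
    coverage_lambda: float
    seed: int | None


def default_truth_params(
    contexts: tuple[str, ...] = CONTEXTS_6,
    D: float = DEFAULT_D_BP,
    p_u: float = DEFAULT_CONVERSION_FAILURE,
    a0_diag: float = DEFAULT_A0_DIAG,
) -> HMMParams:
    """Generating parameters for a plant-like synthetic methylome."""
    p = np.vstack(
        [
            np.full(len(contexts), p_u),
            np.array([DEFAULT_P_M[c] for c in contexts]),
        ]
    )
    a0 = np.array([[a0_diag, 1 - a0_diag], [1 - a0_diag, a0_diag]])
    return HMMParams(p=p, A0=a0, D=D, pi=np.array([0.5, 0.5]), contexts=contexts)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_sites(
    n: int,
    context_weights=DEFAULT_CONTEXT_WEIGHTS,
    mean_gap: float = DEFAULT_MEAN_GAP,
    seed=None,
    contexts: tuple[str, ...] = CONTEXTS_6,
    chrom: str = "chr1",
) -> CytosineSites:
    """Lay out n cytosines with geometric gaps and i.i.d. contexts.

    ``mean_gap`` is the mean inter-cytosine distance in bp (gaps >= 1).
    Strands are drawn uniformly; strand plays no role in the chain model
    beyond bookkeeping, since distance is the position difference.
    """
    rng = _rng(seed)
    w = np.asarray(context_weights, dtype=float)
    if len(w) != len(contexts) or not np.isclose(w.sum(), 1.0):
        raise ValueError("context weights must match contexts and sum to 1")
    if n == 0:
        return CytosineSites(
            chrom=np.empty(0, dtype=object),
            position=np.empty(0, dtype=np.int64),
            strand=np.empty(0, dtype="<U1"),
            context=np.empty(0, dtype=np.int16),
            context_valid=np.empty(0, dtype=bool),
            contexts=contexts,
        )
    # geometric gaps with support {1, 2, ...} and the requested mean
    p_geom = min(1.0, 1.0 / max(mean_gap, 1.0))
    gaps = rng.geometric(p_geom, size=n)
    pos = np.cumsum(gaps).astype(np.int64)
    ctx = rng.choice(len(contexts), size=n, p=w).astype(np.int16)
    strand = np.where(rng.random(n) < 0.5, "+", "-").astype("<U1")
    return CytosineSites(
        chrom=np.full(n, chrom, dtype=object),
        position=pos,
        strand=strand,
        context=ctx,
        context_valid=np.ones(n, dtype=bool),
        contexts=contexts,
    )


def simulate_states(sites: CytosineSites, params: HMMParams, seed=None) -> np.ndarray:
    """Draw hidden states from the distance-dependent Markov chain.

    The first site of each chromosome follows pi; each subsequent state is
    drawn from the transition row A(A°_c, d, D_c) of the previous state,
    where c is the transition context of the adjacent pair.
    """
    rng = _rng(seed)
    n = len(sites)
    states = np.empty(n, dtype=np.int8)
    if n == 0:
        return states
    C = len(sites.contexts)
    u = rng.random(n)
    d = np.diff(sites.position)
    new_chrom = np.ones(n, dtype=bool)
    new_chrom[1:] = sites.chrom[1:] != sites.chrom[:-1]
    tc = sites.context[:-1].astype(np.int64) * C + sites.context[1:].astype(np.int64)
    f = np.exp(-d / params.D[tc])
    # per-step probability of ending in M given previous state
    pM_from = params.A0[tc, :, 1] * f[:, None] + 0.5 * (1 - f[:, None])
    states[0] = 1 if u[0] < params.pi[1] else 0
    for t in range(1, n):
        if new_chrom[t]:
            states[t] = 1 if u[t] < params.pi[1] else 0
        else:
            states[t] = 1 if u[t] < pM_from[t - 1, states[t - 1]] else 0
    return states


def simulate_counts(
    sites: CytosineSites,
    states: np.ndarray,
    params: HMMParams,
    coverage_lambda: float = DEFAULT_COVERAGE,
    seed=None,
) -> Methylome:
    """Draw read counts: r ~ Poisson(lambda), m ~ Binomial(r, p_{state,ctx})."""
    rng = _rng(seed)
    n = len(sites)
    r = rng.poisson(coverage_lambda, size=n).astype(np.int64)
    p_site = params.p[np.asarray(states, dtype=np.int64), sites.context.astype(np.int64)]
    m = rng.binomial(r, p_site).astype(np.int64)
    return Methylome(
        chrom=sites.chrom,
        position=sites.position,
        strand=sites.strand,
        context=sites.context,
        context_valid=sites.context_valid,
        m=m,
        r=r,
        contexts=sites.contexts,
    )


def simulate_methylome(
    n: int,
    params: HMMParams | None = None,
    coverage_lambda: float = DEFAULT_COVERAGE,
    mean_gap: float = DEFAULT_MEAN_GAP,
    context_weights=DEFAULT_CONTEXT_WEIGHTS,
    seed=None,
    contexts: tuple[str, ...] = CONTEXTS_6,
) -> tuple[Methylome, SimulationTruth]:
    """One-call generator: sites, states and counts from a single seed."""
    rng = _rng(seed)
    if params is None:
        params = default_truth_params(contexts)
    sites = simulate_sites(
        n, context_weights=context_weights, mean_gap=mean_gap, seed=rng,
        contexts=contexts,
    )
    states = simulate_states(sites, params, seed=rng)
    methylome = simulate_counts(
        sites, states, params, coverage_lambda=coverage_lambda, seed=rng
    )
    truth = SimulationTruth(
        states=states,
        params=params,
        conversion_failure=float(params.p[0, params.cg_index()]),
        coverage_lambda=coverage_lambda,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
    return methylome, truth
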