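"""Correlation-decay pre-fit for the HMM's transition decay lengths D.

Neighbouring cytosines have correlated methylation; the correlation decays
roughly exponentially with genomic distance.  For each transition context
(the ordered pair of the two neighbours' sequence contexts) we tabulate the
Pearson correlation y(d) of raw methylation levels m/r between adjacent
covered cytosines at each distance d, then fit

    y(d) = a0 * exp(-d / D)

by nonlinear least squares.  The fitted D feeds the HMM as a fixed
constant.  "Adjacent" means consecutive in the methylome with no other
cytosine in between, mirroring how the HMM defines transitions; chains are
per chromosome, so cross-chromosome neighbours never form a pair.

Sparse transition contexts (too few distances, or a failed fit) inherit a
pooled fit over all contexts; if even the pooled fit is impossible the
decay length falls back to 30 bp, within the 10-40 bp range over which the
spatial dependency of plant methylation is typically strong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genome_context import Methylome
from .hmm_core import DEFAULT_DECAY_BP

logger = logging.getLogger("methylhmm")

D_MIN, D_MAX = 1.0, 1000.0
MULTISTART_D = (5.0, 30.0, 100.0)
DEFAULT_MAX_DISTANCE = 100
DEFAULT_MIN_PAIRS = 100


@dataclass
class DecayFit:
    """Fitted correlation decay per transition context.

    a0, D : (C*C,) amplitude and decay length per transition context
    table : rows (transition_context, distance, correlation, n_pairs)
    pooled : (a0, D) of the all-contexts fit
    fallback : boolean mask of contexts that inherited the pooled fit
    """

    a0: np.ndarray
    D: np.ndarray
    table: pd.DataFrame
    pooled: tuple[float, float]
    fallback: np.ndarray
    contexts: tuple[str, ...]

    def transition_context_names(self) -> list[str]:
        return [f"{a}->{b}" for a in self.contexts for b in self.contexts]


def adjacent_correlations(
    methylome: Methylome,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    pooled: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of levels between adjacent covered cytosines.

    For each transition context and each distance d in [1, max_distance],
    correlates the raw levels m/r of consecutive methylome sites (both with
    r >= 1 and a defined context) separated by d bp on the same chromosome.
    Rows with fewer than ``min_pairs`` pairs are omitted.

    With ``pooled=True`` all transition contexts are merged into a single
    correlation per distance (transition_context -1).  Because gap lengths
    are independent of context composition, the pooled y(d) keeps a clean
    single-exponential shape, whereas fitting the union of per-context rows
    would mix amplitudes unevenly across distances (sparse high-amplitude
    contexts drop out at large d first, faking a faster decay).

    Returns a DataFrame (transition_context, distance, correlation, n_pairs).
    """
    mv = methylome.subset(methylome.context_valid)
    empty = pd.DataFrame(
        {
            "transition_context": pd.Series(dtype=np.int64),
            "distance": pd.Series(dtype=np.int64),
            "correlation": pd.Series(dtype=float),
            "n_pairs": pd.Series(dtype=np.int64),
        }
    )
    if len(mv) < 2:
        return empty
    C = len(mv.contexts)
    d = mv.step_distances()
    lev = mv.levels
    x, y = lev[:-1], lev[1:]
    tc = mv.context[:-1].astype(np.int64) * C + mv.context[1:].astype(np.int64)
    keep = (
        (d >= 1)
        & (d <= max_distance)
        & np.isfinite(x)
        & np.isfinite(y)
    )
    if not keep.any():
        return empty
    df = pd.DataFrame(
        {
            "transition_context": np.full(keep.sum(), -1) if pooled else tc[keep],
            "distance": d[keep],
            "x": x[keep],
            "y": y[keep],
        }
    )
    df["xx"] = df["x"] ** 2
    df["yy"] = df["y"] ** 2
    df["xy"] = df["x"] * df["y"]
    g = df.groupby(["transition_context", "distance"]).agg(
        n=("x", "size"),
        sx=("x", "sum"),
        sy=("y", "sum"),
        sxx=("xx", "sum"),
        syy=("yy", "sum"),
        sxy=("xy", "sum"),
    )
    n = g["n"].to_numpy(dtype=float)
    cov = g["sxy"] - g["sx"] * g["sy"] / n
    vx = g["sxx"] - g["sx"] ** 2 / n
    vy = g["syy"] - g["sy"] ** 2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(vx * vy)
    out = g.reset_index()[["transition_context", "distance"]].copy()
    out["correlation"] = np.asarray(corr)
    out["n_pairs"] = g["n"].to_numpy(dtype=np.int64)
    out = out[(out["n_pairs"] >= min_pairs) & np.isfinite(out["correlation"])]
    return out.reset_index(drop=True)


def _exp_decay(d, a0, D):
    return a0 * np.exp(-d / D)


def _fit_one(
    d: np.ndarray, y: np.ndarray, n_pairs: np.ndarray | None = None
) -> tuple[float, float] | None:
    """Multi-start least squares of y = a0 exp(-d/D); best by SSE, D clamped.

    Rows are weighted by sqrt(n_pairs) when pair counts are given, since
    the sampling error of a correlation scales as 1/sqrt(n).
    """
    best = None
    best_sse = np.inf
    a0_init = float(y[np.argmin(d)])
    sigma = None if n_pairs is None else 1.0 / np.sqrt(n_pairs.astype(float))
    for D_init in MULTISTART_D:
        try:
            popt, _ = curve_fit(
                _exp_decay,
                d.astype(float),
                y.astype(float),
                p0=[a0_init, D_init],
                sigma=sigma,
                bounds=([-2.0, D_MIN], [2.0, D_MAX]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = (y - _exp_decay(d, *popt)) / (sigma if sigma is not None else 1.0)
        sse = float(np.sum(resid**2))
        if sse < best_sse:
            best_sse = sse
            best = (float(popt[0]), float(np.clip(popt[1], D_MIN, D_MAX)))
    return best


def fit_decay(
    table: pd.DataFrame,
    contexts: tuple[str, ...],
    pooled_table: pd.DataFrame | None = None,
) -> DecayFit:
    """Fit (a0, D) per transition context from a correlation table.

    Contexts with fewer than 3 distinct distances, or whose optimizer fails,
    inherit the pooled all-contexts fit (from ``pooled_table`` when given,
    else from the union of per-context rows); D is clamped to [1, 1000] bp.
    """
    C = len(contexts)
    TC = C * C
    pooled = None
    src = pooled_table if pooled_table is not None and len(pooled_table) else table
    if len(src) >= 3 and src["distance"].nunique() >= 3:
        pooled = _fit_one(
            src["distance"].to_numpy(),
            src["correlation"].to_numpy(),
            src["n_pairs"].to_numpy(),
        )
    if pooled is None:
        pooled = (0.5, DEFAULT_DECAY_BP)
        if len(table) > 0:
            logger.warning("pooled decay fit failed; using default D=%g bp", pooled[1])
    a0 = np.full(TC, pooled[0])
    D = np.full(TC, pooled[1])
    fallback = np.ones(TC, dtype=bool)
    for tc_idx, sub in table.groupby("transition_context"):
        if sub["distance"].nunique() < 3:
            continue
        res = _fit_one(
            sub["distance"].to_numpy(),
            sub["correlation"].to_numpy(),
            sub["n_pairs"].to_numpy(),
        )
        if res is None:
            logger.warning(
                "decay fit did not converge for transition context %d; "
                "using pooled fit",
                tc_idx,
            )
            continue
        a0[tc_idx], D[tc_idx] = res
        fallback[tc_idx] = False
    return DecayFit(
        a0=a0, D=D, table=table, pooled=pooled, fallback=fallback, contexts=contexts
    )


def estimate_decay(
    methylome: Methylome,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> DecayFit:
    """Convenience: correlation table plus per-context exponential fits."""
    table = adjacent_correlations(methylome, max_distance, min_pairs)
    pooled_table = adjacent_correlations(methylome, max_distance, min_pairs, pooled=True)
    return fit_decay(table, methylome.contexts, pooled_table=pooled_table)
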