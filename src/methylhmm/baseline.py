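"""Binomial-test baseline caller with neighbourhood majority imputation.

The comparison method for the saturation analysis: informative cytosines
(r >= 3 reads) are tested one-sided against the sequencing/conversion error
rate (H0: methylated-read probability = error_rate, H1: greater) and called
M when significant, U otherwise.  Missing and uninformative sites (r < 3)
are imputed with the majority status of directly-called cytosines of the
same sequence context within a 200 bp neighbourhood (+-100 bp around the
focal site, any strand); sites with no informative neighbour, or a tied
vote, stay "undefined".  Undefined calls count as false negatives in
downstream F1 evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom as _binom
from statsmodels.stats.multitest import multipletests

from .genome_context import Methylome

logger = logging.getLogger("methylhmm")

MIN_INFORMATIVE_READS = 3
DEFAULT_ERROR_RATE = 0.01  # 1 - typical bisulfite conversion rate
DEFAULT_ALPHA = 0.05
DEFAULT_WINDOW_BP = 200


@dataclass
class BaselineCalls:
    """Per-site baseline status ("U"/"M"/"undefined") and test p-values.

    ``p_value`` is NaN for sites that were not directly tested (r < 3 or
    undefined context); ``direct`` marks directly tested sites.
    """

    status: np.ndarray
    p_value: np.ndarray
    direct: np.ndarray


def binomial_test_call(
    m: int,
    r: int,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Exact one-sided binomial call for a single informative site.

    Tests H0: P(methylated read) = error_rate against greater; returns "M"
    when the tail probability P(X >= m) is below alpha, else "U".  Sites
    with r < 3 must be routed to imputation instead.  (FDR correction
    applies across a collection, see :func:`baseline_calls`.)
    """
    if r < MIN_INFORMATIVE_READS:
        raise ValueError(f"binomial test requires r >= {MIN_INFORMATIVE_READS}")
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    p = float(_binom.sf(m - 1, r, error_rate))  # P(X >= m)
    return "M" if p < alpha else "U"


def baseline_calls(
    methylome: Methylome,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
    fdr: bool = True,
    window: int = DEFAULT_WINDOW_BP,
) -> BaselineCalls:
    """Run the full baseline: direct tests on r >= 3 sites, then imputation."""
    T = len(methylome)
    status = np.full(T, "undefined", dtype="<U9")
    p_value = np.full(T, np.nan)
    direct = (methylome.r >= MIN_INFORMATIVE_READS) & methylome.context_valid
    if direct.any():
        m = methylome.m[direct]
        r = methylome.r[direct]
        pvals = _binom.sf(m - 1, r, error_rate)
        if fdr:
            reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        else:
            reject = pvals < alpha
        status[direct] = np.where(reject, "M", "U")
        p_value[direct] = pvals
    return neighborhood_impute(
        methylome, BaselineCalls(status=status, p_value=p_value, direct=direct),
        window=window,
    )


def neighborhood_impute(
    methylome: Methylome,
    direct_calls: BaselineCalls,
    window: int = DEFAULT_WINDOW_BP,
) -> BaselineCalls:
    """Impute r < 3 sites by same-context majority vote within the window.

    The window spans +-window/2 bp around the focal position.  Only
    directly tested sites vote; context must match but strand need not.
    A tie or an empty electorate leaves the site "undefined".
    """
    half = window / 2.0
    status = direct_calls.status.copy()
    to_impute = np.flatnonzero(~direct_calls.direct & methylome.context_valid)
    if to_impute.size == 0:
        return BaselineCalls(status, direct_calls.p_value, direct_calls.direct)
    # per (chrom, context): positions of voters with cumulative M/U counts
    voters = np.flatnonzero(direct_calls.direct)
    chrom_all = methylome.chrom
    for key in np.unique(chrom_all[to_impute]):
        on_chrom = chrom_all == key
        for ctx in np.unique(methylome.context[to_impute[on_chrom[to_impute]]]):
            vsel = voters[
                (chrom_all[voters] == key) & (methylome.context[voters] == ctx)
            ]
            tsel = to_impute[
                (chrom_all[to_impute] == key)
                & (methylome.context[to_impute] == ctx)
            ]
            if tsel.size == 0:
                continue
            if vsel.size == 0:
                continue  # stays undefined
            vpos = methylome.position[vsel].astype(float)
            is_m = (status[vsel] == "M").astype(np.int64)
            cum_m = np.concatenate([[0], np.cumsum(is_m)])
            cum_n = np.arange(vsel.size + 1)
            fpos = methylome.position[tsel].astype(float)
            lo = np.searchsorted(vpos, fpos - half, side="left")
            hi = np.searchsorted(vpos, fpos + half, side="right")
            n_m = cum_m[hi] - cum_m[lo]
            n_tot = cum_n[hi] - cum_n[lo]
            n_u = n_tot - n_m
            call = np.where(n_m > n_u, "M", np.where(n_u > n_m, "U", "undefined"))
            call[n_tot == 0] = "undefined"
            status[tsel] = call
    return BaselineCalls(status, direct_calls.p_value, direct_calls.direct)
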