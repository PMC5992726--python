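"""Evaluation suite: saturation analysis, genome-wide summaries, profiles.

Saturation analysis thins reads per site (binomial thinning of methylated
and unmethylated counts, equivalent in distribution to Bernoulli read
sampling), refits on the reduced data, and scores status calls against the
full-data calls as ground truth with per-state precision/recall/F1.

Genome-wide summaries come in three flavours: GML (fraction of cytosines
called methylated), naive weighted GML (sum of methylated reads over total
reads) and recalibrated wGML (coverage-weighted mean of the recalibrated
level m').  Sites fall into coverage categories: imputed (r = 0),
uninformative (r = 1 or 2) and informative (r >= 3).

Meta-methylation enrichment profiles average m' over scaled feature bodies
plus fixed-width flanks, per context and coverage category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_context import Methylome

logger = logging.getLogger("methylhmm")

COVERAGE_CATEGORIES = ("imputed", "uninformative", "informative")
DEFAULT_BODY_BINS = 20
DEFAULT_FLANK_BP = 1000
DEFAULT_FLANK_BINS = 10
DEFAULT_CONFIDENCE = 0.9


def coverage_category(r: np.ndarray) -> np.ndarray:
    """0 = imputed (r=0), 1 = uninformative (r=1,2), 2 = informative (r>=3)."""
    r = np.asarray(r)
    return np.where(r == 0, 0, np.where(r < 3, 1, 2))


def downsample(methylome: Methylome, fraction: float, seed=None) -> Methylome:
    """Thin reads per site: keep each methylated and unmethylated read
    independently with probability ``fraction``; positions and contexts
    unchanged."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m_kept = rng.binomial(methylome.m, fraction)
    u_kept = rng.binomial(methylome.r - methylome.m, fraction)
    return methylome.with_counts(m_kept.astype(np.int64),
                                 (m_kept + u_kept).astype(np.int64))


@dataclass
class F1Result:
    """Per-state precision/recall/F1 plus truth-frequency-weighted overall F1."""

    per_state: pd.DataFrame  # index U/M, columns precision/recall/f1/n_truth
    overall_f1: float
    degenerate: bool  # some state had a zero denominator


def f1_scores(calls: np.ndarray, truth_calls: np.ndarray) -> F1Result:
    """Score status calls against ground-truth calls.

    Undefined predictions count as false negatives for the truth state and
    never as false positives.  Overall F1 is the mean of per-state F1
    weighted by truth-state frequency.  Zero-denominator precision/recall
    give F1 = 0 with the ``degenerate`` flag set.
    """
    calls = np.asarray(calls)
    truth = np.asarray(truth_calls)
    if len(calls) != len(truth):
        raise ValueError("calls and truth have different lengths")
    rows = []
    degenerate = False
    for s in ("U", "M"):
        tp = int(np.sum((calls == s) & (truth == s)))
        fp = int(np.sum((calls == s) & (truth != s)))
        fn = int(np.sum((truth == s) & (calls != s)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        if tp + fp == 0 or tp + fn == 0:
            degenerate = degenerate or (tp + fn > 0 or tp + fp > 0)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append((s, prec, rec, f1, tp + fn))
    per_state = pd.DataFrame(
        rows, columns=["state", "precision", "recall", "f1", "n_truth"]
    ).set_index("state")
    weights = per_state["n_truth"].to_numpy(dtype=float)
    total = weights.sum()
    overall = float((per_state["f1"].to_numpy() * weights).sum() / total) if total else 0.0
    return F1Result(per_state=per_state, overall_f1=overall, degenerate=degenerate)


def _per_context_and_total(values: dict[str, float], total: float) -> pd.Series:
    s = pd.Series(values, dtype=float)
    s["total"] = total
    return s


def gml_from_calls(status: np.ndarray, contexts: np.ndarray,
                   context_names: tuple[str, ...]) -> pd.Series:
    """Genome-wide methylation level from status calls: #M / #sites.

    Computed per context plus a "total" aggregate.  Undefined statuses stay
    in the denominator and never count as methylated, which is what makes
    this measure unstable at low coverage.
    """
    status = np.asarray(status)
    ctx = np.asarray(contexts)
    out = {}
    for i, name in enumerate(context_names):
        sel = ctx == i
        out[name] = float(np.mean(status[sel] == "M")) if sel.any() else np.nan
    return _per_context_and_total(out, float(np.mean(status == "M")) if len(status) else np.nan)


def weighted_gml(methylome: Methylome) -> pd.Series:
    """Naive weighted GML: sum(m) / sum(r) per context plus "total".

    Zero-coverage sites contribute nothing; a context with no reads at all
    is NaN.
    """
    ctx = methylome.context
    out = {}
    for i, name in enumerate(methylome.contexts):
        sel = ctx == i
        rs = int(methylome.r[sel].sum())
        out[name] = float(methylome.m[sel].sum() / rs) if rs else np.nan
        if rs == 0:
            logger.warning("weighted GML undefined for context %s (no reads)", name)
    rtot = int(methylome.r.sum())
    return _per_context_and_total(out, float(methylome.m.sum() / rtot) if rtot else np.nan)


def recalibrated_wgml(fit, methylome: Methylome) -> pd.Series:
    """Coverage-weighted recalibrated GML: sum(m'_t r_t) / sum(r_t) per context."""
    if len(fit.rc_level) != len(methylome):
        raise ValueError("fit and methylome have different lengths")
    ctx = methylome.context
    rc = fit.rc_level
    ok = np.isfinite(rc)
    out = {}
    for i, name in enumerate(methylome.contexts):
        sel = (ctx == i) & ok
        rs = int(methylome.r[sel].sum())
        out[name] = float((rc[sel] * methylome.r[sel]).sum() / rs) if rs else np.nan
    rtot = int(methylome.r[ok].sum())
    total = float((rc[ok] * methylome.r[ok]).sum() / rtot) if rtot else np.nan
    return _per_context_and_total(out, total)


def confidence_summary(
    fit, methylome: Methylome, threshold: float = DEFAULT_CONFIDENCE
) -> pd.DataFrame:
    """Fraction of sites with max posterior >= threshold, by coverage
    category and context (plus "total" rows/columns)."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    maxpost = np.nanmax(fit.gamma, axis=1)
    cat = coverage_category(methylome.r)
    ok = methylome.context_valid
    rows = []
    for ci, cname in enumerate(COVERAGE_CATEGORIES):
        in_cat = (cat == ci) & ok
        row = {}
        for i, name in enumerate(methylome.contexts):
            sel = in_cat & (methylome.context == i)
            row[name] = float(np.mean(maxpost[sel] >= threshold)) if sel.any() else np.nan
        row["total"] = float(np.mean(maxpost[in_cat] >= threshold)) if in_cat.any() else np.nan
        row["n_sites"] = int(in_cat.sum())
        rows.append(pd.Series(row, name=cname))
    return pd.DataFrame(rows)


def enrichment_profile(
    fit,
    methylome: Methylome,
    features: pd.DataFrame,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bp: int = DEFAULT_FLANK_BP,
    flank_bins: int = DEFAULT_FLANK_BINS,
) -> pd.DataFrame:
    """Meta-feature profile of mean recalibrated level.

    Feature bodies are scaled to ``body_bins`` equal fractions, flanked by
    ``flank_bins`` fixed-width bins covering ``flank_bp`` on each side.
    Minus-strand features are flipped so bins always run 5'->3'.  Sites in
    overlapping features are counted once per feature occurrence.  Returns
    tidy rows (context, category, bin, mean_rc_level, n_sites); empty bins
    are absent.
    """
    n_bins = body_bins + 2 * flank_bins
    rc = fit.rc_level
    cat = coverage_category(methylome.r)
    acc: dict[tuple[int, int, int], tuple[float, int]] = {}
    for feat in features.itertuples(index=False):
        on = np.flatnonzero(
            (methylome.chrom == feat.chrom)
            & (methylome.position >= feat.start - flank_bp)
            & (methylome.position <= feat.end + flank_bp)
            & methylome.context_valid
            & np.isfinite(rc)
        )
        if on.size == 0:
            continue
        pos = methylome.position[on].astype(float)
        length = feat.end - feat.start + 1
        bins = np.empty(on.size, dtype=np.int64)
        up = pos < feat.start
        down = pos > feat.end
        body = ~(up | down)
        bins[up] = np.minimum(
            ((pos[up] - (feat.start - flank_bp)) / flank_bp * flank_bins).astype(int),
            flank_bins - 1,
        )
        bins[body] = flank_bins + np.minimum(
            ((pos[body] - feat.start) / length * body_bins).astype(int),
            body_bins - 1,
        )
        bins[down] = flank_bins + body_bins + np.minimum(
            ((pos[down] - feat.end - 1) / flank_bp * flank_bins).astype(int),
            flank_bins - 1,
        )
        if getattr(feat, "strand", "+") == "-":
            bins = n_bins - 1 - bins
        for idx, b in zip(on, bins):
            key = (int(methylome.context[idx]), int(cat[idx]), int(b))
            tot, n = acc.get(key, (0.0, 0))
            acc[key] = (tot + rc[idx], n + 1)
    rows = [
        {
            "context": methylome.contexts[c],
            "category": COVERAGE_CATEGORIES[k],
            "bin": b,
            "mean_rc_level": tot / n,
            "n_sites": n,
        }
        for (c, k, b), (tot, n) in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows, columns=["context", "category", "bin", "mean_rc_level", "n_sites"]
    )
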