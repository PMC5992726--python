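"""Readers and writers for the formats the tool touches.

Input: per-cytosine counts in the BS-Seeker2 CGmap dialect (8 tab-separated
columns: chrom, C/G nucleotide, 1-based position, CG/CHG/CHH class,
dinucleotide, level, methylated count, total count; optionally gzipped).
The strand is encoded by column 2: C means the cytosine is on the forward
strand, G means it is the complement of a reference G, i.e. minus strand.

Output: a per-cytosine methylome TSV (one row per genomic cytosine,
including zero-coverage sites, with posteriors, status call and
recalibrated level) and bedGraph tracks for genome browsers.  Annotation
features are read from BED (0-based half-open, converted at the boundary)
or GFF3 (already 1-based inclusive).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_context import (
    CONTEXT_6_TO_3,
    CONTEXTS_3,
    CONTEXTS_6,
    FormatError,
    Methylome,
)

logger = logging.getLogger("methylhmm")

CGMAP_COLUMNS = [
    "chrom",
    "nucleotide",
    "position",
    "context_class",
    "dinucleotide",
    "level",
    "methylated",
    "total",
]


def read_cgmap(path) -> pd.DataFrame:
    """Read a CGmap file into a DataFrame with an inferred ``strand`` column.

    Raises :class:`FormatError` on a wrong column count (naming the line)
    or on records with methylated > total.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CGMAP_COLUMNS,
            dtype={
                "chrom": str,
                "nucleotide": str,
                "position": np.int64,
                "context_class": str,
                "dinucleotide": str,
                "level": float,
                "methylated": np.int64,
                "total": np.int64,
            },
            compression="infer",
            comment=None,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CGMAP_COLUMNS, [str, str, np.int64, str, str, float, np.int64, np.int64]
        )})
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed CGmap file {path}: {exc}") from exc
    bad_nuc = ~df["nucleotide"].isin(["C", "G"])
    if bad_nuc.any():
        line = int(np.flatnonzero(bad_nuc.to_numpy())[0]) + 1
        raise FormatError(f"{path}: line {line}: nucleotide column must be C or G")
    over = df["methylated"] > df["total"]
    if over.any():
        line = int(np.flatnonzero(over.to_numpy())[0]) + 1
        raise FormatError(f"{path}: line {line}: methylated count exceeds total")
    df["strand"] = np.where(df["nucleotide"] == "C", "+", "-")
    return df


def write_cgmap(methylome: Methylome, path) -> None:
    """Serialize a Methylome in CGmap layout (all sites, including r = 0)."""
    ctx_names = methylome.context_names()
    if methylome.contexts == CONTEXTS_3:
        classes = np.where(ctx_names == "", "--", ctx_names)
    else:
        collapse = np.asarray(
            [CONTEXT_6_TO_3[c] for c in methylome.contexts] + ["--"], dtype=object
        )
        classes = collapse[methylome.context]
    dinuc = np.where(classes == "CG", "CG", "--")
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(
            methylome.r > 0, methylome.m / np.maximum(methylome.r, 1), 0.0
        )
    df = pd.DataFrame(
        {
            "chrom": methylome.chrom,
            "nucleotide": np.where(methylome.strand == "+", "C", "G"),
            "position": methylome.position,
            "context_class": classes,
            "dinucleotide": dinuc,
            "level": np.round(level, 6),
            "methylated": methylome.m,
            "total": methylome.r,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def cgmap_to_methylome(counts: pd.DataFrame) -> Methylome:
    """Build a Methylome directly from CGmap records (genome-free mode).

    Contexts are taken from the 3-class column, collapsed to CG/CHG/CHH;
    only covered sites exist, so nothing is imputable beyond what the file
    lists.  Prefer genome-backed :func:`methylhmm.genome_context.merge_counts`
    when a FASTA is available.
    """
    df = counts.sort_values(
        ["chrom", "position", "strand"], kind="mergesort"
    ).reset_index(drop=True)
    ctx = np.full(len(df), -1, dtype=np.int16)
    for i, name in enumerate(CONTEXTS_3):
        ctx[(df["context_class"] == name).to_numpy()] = i
    return Methylome(
        chrom=df["chrom"].to_numpy(dtype=object),
        position=df["position"].to_numpy(dtype=np.int64),
        strand=df["strand"].to_numpy(dtype="<U1"),
        context=ctx,
        context_valid=ctx >= 0,
        m=df["methylated"].to_numpy(dtype=np.int64),
        r=df["total"].to_numpy(dtype=np.int64),
        contexts=CONTEXTS_3,
    )


METHYLOME_COLUMNS = [
    "chrom",
    "position",
    "strand",
    "context",
    "counts_methylated",
    "counts_total",
    "posterior_U",
    "posterior_M",
    "status",
    "rc_level",
]


def write_methylome(methylome: Methylome, fit, path) -> None:
    """Write the per-cytosine methylome TSV (header + one row per site).

    ``fit`` is a :class:`methylhmm.hmm_core.FitResult` aligned 1:1 with the
    methylome; floats are printed at 6 decimals.
    """
    if len(fit.gamma) != len(methylome):
        raise ValueError(
            f"fit length {len(fit.gamma)} does not match methylome length "
            f"{len(methylome)}"
        )
    df = pd.DataFrame(
        {
            "chrom": methylome.chrom,
            "position": methylome.position,
            "strand": methylome.strand,
            "context": np.where(
                methylome.context_valid, methylome.context_names(), "."
            ),
            "counts_methylated": methylome.m,
            "counts_total": methylome.r,
            "posterior_U": fit.gamma[:, 0],
            "posterior_M": fit.gamma[:, 1],
            "status": fit.status,
            "rc_level": fit.rc_level,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_methylome_table(path) -> pd.DataFrame:
    """Read back a methylome TSV written by :func:`write_methylome`."""
    df = pd.read_csv(path, sep="\t", compression="infer")
    missing = [c for c in METHYLOME_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing methylome columns {missing}")
    return df


def write_bedgraph(methylome: Methylome, rc_level: np.ndarray, path, strand=None) -> None:
    """Export recalibrated levels as bedGraph (0-based half-open intervals)."""
    mask = np.ones(len(methylome), dtype=bool)
    if strand is not None:
        mask &= methylome.strand == strand
    mask &= np.isfinite(rc_level)
    df = pd.DataFrame(
        {
            "chrom": methylome.chrom[mask],
            "start": methylome.position[mask] - 1,
            "end": methylome.position[mask],
            "value": np.round(rc_level[mask], 6),
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def read_annotation(path, format: str | None = None) -> pd.DataFrame:
    """Read genomic features from BED or GFF3.

    Returns a DataFrame (chrom, start, end, strand, type) with coordinates
    normalized to 1-based inclusive.  BED input (0-based half-open) is
    converted at this boundary; GFF3 is used as-is.  ``format`` defaults to
    a guess from the file extension.
    """
    p = str(path)
    if format is None:
        stem = p[:-3] if p.endswith(".gz") else p
        if stem.endswith((".gff", ".gff3")):
            format = "GFF3"
        elif stem.endswith(".bed"):
            format = "BED"
        else:
            raise FormatError(f"cannot guess annotation format of {path}")
    format = format.upper()
    if format == "BED":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", compression="infer")
        if df.shape[1] < 3:
            raise FormatError(f"{path}: BED needs at least 3 columns")
        out = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[1].astype(np.int64) + 1,  # 0-based -> 1-based
                "end": df[2].astype(np.int64),
                "strand": df[5].astype(str) if df.shape[1] > 5 else ".",
                "type": df[3].astype(str) if df.shape[1] > 3 else "feature",
            }
        )
    elif format == "GFF3":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", compression="infer"
        )
        if df.shape[1] < 8:
            raise FormatError(f"{path}: GFF3 needs 9 columns")
        out = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[3].astype(np.int64),
                "end": df[4].astype(np.int64),
                "strand": df[6].astype(str),
                "type": df[2].astype(str),
            }
        )
    else:
        raise FormatError(f"unknown annotation format {format!r}")
    short = out["end"] < out["start"]
    if short.any():
        line = int(np.flatnonzero(short.to_numpy())[0]) + 1
        raise FormatError(f"{path}: line {line}: feature shorter than 1 bp")
    return out
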