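"""Cytosine extraction and sequence-context assignment.

Every cytosine in a genome is assigned to one of six sequence contexts
defined by the two bases immediately 3' of the cytosine on its own strand:

    CG        second base G (any third base)
    CCG       trinucleotide CCG
    CWG       CAG or CTG            (W = A/T)
    CAA       trinucleotide CAA
    CTA       trinucleotide CTA
    CHH_rest  the remaining CHH trinucleotides, i.e. CCA plus CHY
              (H = A/C/T, Y = C/T): CCA, CAC, CAT, CCC, CCT, CTC, CTT

These six classes partition all C-initial trinucleotides without N and
subdivide the classical CG/CHG/CHH scheme, reflecting the distinct
methylation maintenance behaviour of each subcontext in plants.  A
three-class CG/CHG/CHH mode is available for genome-free workflows.

Coordinates are 1-based inclusive throughout.  Minus-strand cytosines are
reference G's; their context is read 5'->3' on the minus strand, i.e. from
the complemented reference bases at position-1, position-2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("methylhmm")

CONTEXTS_6: tuple[str, ...] = ("CG", "CCG", "CWG", "CAA", "CTA", "CHH_rest")
CONTEXTS_3: tuple[str, ...] = ("CG", "CHG", "CHH")

#: collapse map from the six subcontexts to the classical three
CONTEXT_6_TO_3: dict[str, str] = {
    "CG": "CG",
    "CCG": "CHG",
    "CWG": "CHG",
    "CAA": "CHH",
    "CTA": "CHH",
    "CHH_rest": "CHH",
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class FormatError(ValueError):
    """Raised for malformed input files or sequences."""


def assign_context(trinucleotide: str, contexts: tuple[str, ...] = CONTEXTS_6) -> str:
    """Map a C-initial trinucleotide (5'->3' on the cytosine's strand) to its context.

    Parameters
    ----------
    trinucleotide:
        Three bases starting at the cytosine, on the cytosine's own strand.
    contexts:
        ``CONTEXTS_6`` (default) or ``CONTEXTS_3``.

    Raises
    ------
    ValueError
        If the first base is not C or the trinucleotide contains a non-ACGT
        character (including N): the context is undefined.
    """
    tri = trinucleotide.upper()
    if len(tri) != 3 or tri[0] != "C":
        raise ValueError(f"not a C-initial trinucleotide: {trinucleotide!r}")
    if any(b not in "ACGT" for b in tri[1:]):
        raise ValueError(f"undefined context (ambiguous base) in {trinucleotide!r}")
    if tri[1] == "G":
        return "CG"
    if contexts == CONTEXTS_3:
        return "CHG" if tri[2] == "G" else "CHH"
    if tri[2] == "G":
        return "CCG" if tri[1] == "C" else "CWG"
    if tri == "CAA":
        return "CAA"
    if tri == "CTA":
        return "CTA"
    return "CHH_rest"


def _context_table(contexts: tuple[str, ...]) -> np.ndarray:
    """4x4 lookup: (code of base at +1, code of base at +2) -> context index."""
    table = np.empty((4, 4), dtype=np.int16)
    inv = "ACGT"
    for b1 in range(4):
        for b2 in range(4):
            name = assign_context("C" + inv[b1] + inv[b2], contexts)
            table[b1, b2] = contexts.index(name)
    return table


@dataclass
class CytosineSites:
    """All cytosines of a genome, both strands, with context annotation.

    Arrays are parallel and sorted by (chrom in genome order, position,
    strand with + before -).  ``context`` holds indices into ``contexts``;
    sites whose two downstream bases run off the chromosome or contain N
    have ``context_valid`` False and context index -1.
    """

    chrom: np.ndarray
    position: np.ndarray
    strand: np.ndarray
    context: np.ndarray
    context_valid: np.ndarray
    contexts: tuple[str, ...] = CONTEXTS_6

    def __len__(self) -> int:
        return len(self.position)

    def context_names(self) -> np.ndarray:
        names = np.asarray(self.contexts + ("",), dtype=object)
        return names[self.context]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "position": self.position,
                "strand": self.strand,
                "context": self.context_names(),
                "context_valid": self.context_valid,
            }
        )


@dataclass
class Methylome:
    """Ordered per-cytosine methylation counts: the HMM observation sequence.

    One record per genomic cytosine (both strands interleaved on one
    coordinate axis), sorted by (chrom, position, strand with + before -).
    Zero-coverage sites are ordinary records with m = r = 0.
    """

    chrom: np.ndarray
    position: np.ndarray
    strand: np.ndarray
    context: np.ndarray  # index into ``contexts``; -1 for undefined
    context_valid: np.ndarray
    m: np.ndarray  # methylated read count
    r: np.ndarray  # total read count
    contexts: tuple[str, ...] = CONTEXTS_6

    def __post_init__(self) -> None:
        if np.any(self.m > self.r) or np.any(self.m < 0):
            raise ValueError("methylated counts must satisfy 0 <= m <= r")

    def __len__(self) -> int:
        return len(self.position)

    @property
    def levels(self) -> np.ndarray:
        """Raw methylation levels m/r; NaN where r = 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.r > 0, self.m / np.maximum(self.r, 1), np.nan)

    def chain_starts(self) -> np.ndarray:
        """Indices where a new chromosome (independent HMM chain) begins."""
        if len(self) == 0:
            return np.empty(0, dtype=np.int64)
        new = np.ones(len(self), dtype=bool)
        new[1:] = self.chrom[1:] != self.chrom[:-1]
        return np.flatnonzero(new)

    def step_distances(self) -> np.ndarray:
        """Distances position[t+1]-position[t]; -1 at chromosome boundaries."""
        d = np.empty(max(len(self) - 1, 0), dtype=np.int64)
        if d.size:
            d[:] = self.position[1:] - self.position[:-1]
            boundary = self.chrom[1:] != self.chrom[:-1]
            d[boundary] = -1
        return d

    def context_names(self) -> np.ndarray:
        names = np.asarray(self.contexts + ("",), dtype=object)
        return names[self.context]

    def subset(self, mask: np.ndarray) -> "Methylome":
        return Methylome(
            chrom=self.chrom[mask],
            position=self.position[mask],
            strand=self.strand[mask],
            context=self.context[mask],
            context_valid=self.context_valid[mask],
            m=self.m[mask],
            r=self.r[mask],
            contexts=self.contexts,
        )

    def with_counts(self, m: np.ndarray, r: np.ndarray) -> "Methylome":
        return replace(self, m=np.asarray(m), r=np.asarray(r))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "position": self.position,
                "strand": self.strand,
                "context": self.context_names(),
                "context_valid": self.context_valid,
                "counts_methylated": self.m,
                "counts_total": self.r,
            }
        )


def _load_sequences(genome) -> list[tuple[str, str]]:
    """Accept a FASTA path, a mapping name->sequence, or pyfaidx.Fasta."""
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), rebuild=False)
        return [(name, str(fa[name][:])) for name in fa.keys()]
    if isinstance(genome, Mapping):
        return list(genome.items())
    # pyfaidx.Fasta or similar
    return [(name, str(genome[name][:])) for name in genome.keys()]


def extract_cytosines(
    genome, contexts: tuple[str, ...] = CONTEXTS_6
) -> CytosineSites:
    """Extract every cytosine on both strands with its sequence context.

    Plus-strand sites are reference C's; minus-strand sites are reference
    G's, with context read 5'->3' on the minus strand.  Sites whose two
    downstream bases (on their own strand) are missing or contain N get
    ``context_valid`` False.

    Raises
    ------
    FormatError
        If a sequence contains characters other than A/C/G/T/N.
    """
    table = _context_table(contexts)
    chroms, positions, strands, ctxs, valids = [], [], [], [], []
    for name, seq in _load_sequences(genome):
        s = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        code = np.full(256, -2, dtype=np.int16)
        for b, c in _BASE_CODE.items():
            code[ord(b)] = c
        code[ord("N")] = -1
        bc = code[s]
        if np.any(bc == -2):
            bad = chr(s[np.argmax(bc == -2)])
            raise FormatError(f"non-nucleotide character {bad!r} in sequence {name}")
        n = len(s)
        # plus strand: C at i (0-based); downstream bases at i+1, i+2
        plus_idx = np.flatnonzero(bc == _BASE_CODE["C"])
        pad = np.concatenate([bc, [-1, -1]])
        p1, p2 = pad[plus_idx + 1], pad[plus_idx + 2]
        plus_valid = (p1 >= 0) & (p2 >= 0)
        plus_ctx = np.full(len(plus_idx), -1, dtype=np.int16)
        plus_ctx[plus_valid] = table[p1[plus_valid], p2[plus_valid]]
        # minus strand: G at i; downstream on minus strand = complement of
        # reference bases at i-1, i-2.  Complement in code space is 3-code.
        minus_idx = np.flatnonzero(bc == _BASE_CODE["G"])
        padl = np.concatenate([[-1, -1], bc])
        m1, m2 = padl[minus_idx + 1], padl[minus_idx]  # i-1, i-2 in padded coords
        minus_valid = (m1 >= 0) & (m2 >= 0)
        m1c = np.where(m1 >= 0, 3 - m1, -1)
        m2c = np.where(m2 >= 0, 3 - m2, -1)
        minus_ctx = np.full(len(minus_idx), -1, dtype=np.int16)
        minus_ctx[minus_valid] = table[m1c[minus_valid], m2c[minus_valid]]

        pos = np.concatenate([plus_idx, minus_idx]) + 1  # 1-based
        strand = np.concatenate(
            [np.full(len(plus_idx), "+"), np.full(len(minus_idx), "-")]
        )
        ctx = np.concatenate([plus_ctx, minus_ctx])
        valid = np.concatenate([plus_valid, minus_valid])
        # sort by (position, strand with + before -); '+' < '-' in ASCII
        order = np.lexsort((strand == "-", pos))
        chroms.append(np.full(len(pos), name, dtype=object))
        positions.append(pos[order])
        strands.append(strand[order])
        ctxs.append(ctx[order])
        valids.append(valid[order])

    if not chroms:
        return CytosineSites(
            chrom=np.empty(0, dtype=object),
            position=np.empty(0, dtype=np.int64),
            strand=np.empty(0, dtype="<U1"),
            context=np.empty(0, dtype=np.int16),
            context_valid=np.empty(0, dtype=bool),
            contexts=contexts,
        )
    return CytosineSites(
        chrom=np.concatenate(chroms),
        position=np.concatenate(positions).astype(np.int64),
        strand=np.concatenate(strands).astype("<U1"),
        context=np.concatenate(ctxs).astype(np.int16),
        context_valid=np.concatenate(valids),
        contexts=contexts,
    )


def merge_counts(sites: CytosineSites, counts: pd.DataFrame) -> Methylome:
    """Join genome cytosines with CGmap read counts into a Methylome.

    Every genome cytosine appears exactly once; sites absent from
    ``counts`` get m = r = 0.  Contexts come from the genome, never from
    the CGmap context columns.  Count records at positions that are not
    genome cytosines (wrong base, off the end) are dropped with a warning.

    Parameters
    ----------
    counts:
        DataFrame as returned by :func:`methylhmm.io_formats.read_cgmap`
        (columns chrom, position, strand, methylated, total).
    """
    m = np.zeros(len(sites), dtype=np.int64)
    r = np.zeros(len(sites), dtype=np.int64)
    if len(counts):
        site_df = pd.DataFrame(
            {
                "chrom": sites.chrom,
                "position": sites.position,
                "strand": sites.strand,
                "_idx": np.arange(len(sites)),
            }
        )
        merged = counts.merge(site_df, on=["chrom", "position", "strand"], how="left")
        hit = merged["_idx"].notna()
        n_dropped = int((~hit).sum())
        if n_dropped:
            logger.warning(
                "dropped %d count records at non-cytosine reference positions",
                n_dropped,
            )
        idx = merged.loc[hit, "_idx"].to_numpy(dtype=np.int64)
        np.add.at(m, idx, merged.loc[hit, "methylated"].to_numpy(dtype=np.int64))
        np.add.at(r, idx, merged.loc[hit, "total"].to_numpy(dtype=np.int64))
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
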