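"""Deduplication, redundancy, and summary statistics of contig sets.

Emulates 100%-identity clustering (exact full-length substring
containment) and computes the standard assembly summary: contig count,
total bases, max/min/mean length and N50, after an optional minimum
length filter.  The same operations serve nucleotide contigs and
translated (amino-acid) contigs; only the length unit differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Contig

__all__ = ["SummaryStats", "dedup_contigs", "assembly_summary", "length_histogram", "n50"]


@dataclass(frozen=True)
class SummaryStats:
    """One row of a basic assembly-statistics table."""

    n_contigs: int
    total_bases: int
    max_len: int
    min_len: int
    mean_len: float
    n50: int
    redundancy: float = 0.0


def dedup_contigs(
    contigs: Sequence[Contig], mode: str = "substring"
) -> tuple[list[Contig], float]:
    """Remove redundant contigs at 100% identity; return survivors + redundancy.

    In ``substring`` mode (default) a contig is removed iff its sequence
    is an exact, full-length, case-insensitive substring of a longer (or
    equal-length, earlier-retained) contig — the behaviour of
    100%-identity clustering.  ``exact`` mode removes only exact
    duplicate sequences.

    Redundancy is ``(n_before - n_after) / n_before``; the retained list
    follows input order.  An empty input yields ``([], 0.0)``.
    """
    if mode not in ("substring", "exact"):
        raise ValueError(f"mode must be 'substring' or 'exact', got {mode!r}")
    if not contigs:
        return [], 0.0
    n_before = len(contigs)
    retained_idx: list[int] = []
    if mode == "exact":
        seen: set[str] = set()
        for i, c in enumerate(contigs):
            s = c.seq.upper()
            if s not in seen:
                seen.add(s)
                retained_idx.append(i)
    else:
        # Longest first (ties by input order) so each candidate need only
        # be checked against already-retained, never-shorter sequences.
        order = sorted(range(n_before), key=lambda i: (-len(contigs[i].seq), i))
        kept_seqs: list[str] = []
        for i in order:
            s = contigs[i].seq.upper()
            if not any(s in k for k in kept_seqs):
                kept_seqs.append(s)
                retained_idx.append(i)
        retained_idx.sort()
    retained = [contigs[i] for i in retained_idx]
    redundancy = (n_before - len(retained)) / n_before
    return retained, redundancy


def n50(lengths: Sequence[int]) -> int:
    """Largest length L whose cumulative sum from the longest down reaches
    half the total (weighted-median definition)."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def _summary_from_lengths(lengths: Sequence[int], redundancy: float) -> SummaryStats:
    arr = np.asarray(lengths, dtype=np.int64)
    return SummaryStats(
        n_contigs=int(arr.size),
        total_bases=int(arr.sum()),
        max_len=int(arr.max()),
        min_len=int(arr.min()),
        mean_len=round(float(arr.mean()), 1),
        n50=n50(lengths),
        redundancy=redundancy,
    )


def assembly_summary(
    contigs: Sequence[Contig], min_len: int = 200, redundancy: float = 0.0
) -> SummaryStats:
    """Summarise an (already deduplicated) contig set.

    Contigs shorter than ``min_len`` are discarded first — the
    conventional cutoff is 200 nt for nucleotide contigs and 50 aa for
    translated ones.  ``redundancy`` is carried through from a prior
    :func:`dedup_contigs` call for reporting.
    """
    lengths = [len(c.seq) for c in contigs if len(c.seq) >= min_len]
    if not lengths:
        raise ValueError("empty assembly after length filter")
    return _summary_from_lengths(lengths, redundancy)


def length_histogram(lengths: Iterable[int], bin_edges: Sequence[int | float]) -> list[int]:
    """Histogram of lengths over half-open bins ``[e_i, e_{i+1})``; the
    last bin is closed on the right."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with at least two edges")
    counts, _ = np.histogram(np.fromiter(lengths, dtype=float), bins=edges)
    return [int(c) for c in counts]
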