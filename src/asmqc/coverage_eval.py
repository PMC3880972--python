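"""Reference-guided coverage evaluation: contiguity, completeness, % hits.

Given tabular alignment hits of assembled contigs against a reference
transcript/protein panel, this module computes per-reference coverage
(best single contig and union of all contigs) and sweeps a coverage
threshold:

* contiguity(t)   — fraction of references covered to >= t by a single
  best contig;
* completeness(t) — fraction covered to >= t by the union of all
  aligned contigs;
* % hits          — fraction of references with at least one hit
  (constant in t).

All three use the full reference-panel size as denominator, so
completeness(t) >= contiguity(t) and both are bounded by % hits.
Multiple HSPs between one contig and one reference are merged before
any fraction is computed, so coverage never exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import AlignmentHit

__all__ = [
    "CoverageRecord",
    "EvalRow",
    "merge_intervals",
    "covered_length",
    "reference_coverage",
    "evaluate",
    "contiguity_count_at",
    "default_threshold_sweep",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class CoverageRecord:
    """Coverage summary for one reference with at least one hit."""

    ref_id: str
    ref_len: int
    best_contig_id: str
    best_single_frac: float
    union_frac: float
    n_contigs_hitting: int

    def __post_init__(self) -> None:
        if not self.best_single_frac <= self.union_frac <= 1.0 + 1e-12:
            raise ValueError(
                f"{self.ref_id}: best_single_frac {self.best_single_frac} > "
                f"union_frac {self.union_frac} or union_frac > 1"
            )


@dataclass(frozen=True)
class EvalRow:
    """One row of a threshold sweep."""

    threshold: float
    contiguity: float
    completeness: float
    pct_hits: float


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge half-open intervals into a disjoint sorted list.

    Touching intervals ([0,5) and [5,10)) are merged.  Covered length is
    preserved.
    """
    ivs = sorted(intervals)
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"invalid interval [{s},{e}): start must be < end")
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def covered_length(intervals: Iterable[Interval]) -> int:
    """Total length of the union of half-open intervals."""
    return sum(e - s for s, e in merge_intervals(intervals))


def reference_coverage(
    hits: Sequence[AlignmentHit],
    ref_lens: Mapping[str, int],
    max_evalue: Optional[float] = None,
    best_hsp_only: bool = False,
) -> list[CoverageRecord]:
    """Per-reference coverage records from a hit list.

    For each reference with at least one hit: the union fraction merges
    the subject intervals of all hits; the best-single fraction is the
    maximum per-contig merged coverage, ties broken by longer declared
    contig length (qlen) then lexicographically smaller contig id.
    References without hits are omitted.

    ``max_evalue`` optionally drops weaker hits first; ``best_hsp_only``
    keeps only the top-bitscore HSP per (contig, reference) pair instead
    of merging all HSPs.
    """
    if max_evalue is not None:
        hits = [h for h in hits if h.evalue <= max_evalue]
    if best_hsp_only:
        best: dict[tuple[str, str], AlignmentHit] = {}
        for h in hits:
            key = (h.qid, h.sid)
            prev = best.get(key)
            if prev is None or (h.bitscore, -h.evalue) > (prev.bitscore, -prev.evalue):
                best[key] = h
        hits = list(best.values())

    by_ref: dict[str, dict[str, list[Interval]]] = {}
    qlens: dict[str, int] = {}
    for h in hits:
        if h.sid not in ref_lens:
            raise ValueError(f"hit to unknown reference {h.sid!r}")
        if h.s_iv[1] > ref_lens[h.sid]:
            raise ValueError(
                f"hit {h.qid}->{h.sid}: subject interval end {h.s_iv[1]} "
                f"exceeds reference length {ref_lens[h.sid]}"
            )
        by_ref.setdefault(h.sid, {}).setdefault(h.qid, []).append(h.s_iv)
        if h.qlen is not None:
            qlens[h.qid] = h.qlen

    records = []
    for ref_id in sorted(by_ref):
        per_contig = by_ref[ref_id]
        ref_len = ref_lens[ref_id]
        union = covered_length(iv for ivs in per_contig.values() for iv in ivs)
        cov_by_contig = {qid: covered_length(ivs) for qid, ivs in per_contig.items()}
        best_qid = min(
            cov_by_contig,
            key=lambda q: (-cov_by_contig[q], -qlens.get(q, -1), q),
        )
        records.append(
            CoverageRecord(
                ref_id=ref_id,
                ref_len=ref_len,
                best_contig_id=best_qid,
                best_single_frac=cov_by_contig[best_qid] / ref_len,
                union_frac=union / ref_len,
                n_contigs_hitting=len(per_contig),
            )
        )
    return records


def evaluate(
    records: Sequence[CoverageRecord],
    n_refs: int,
    thresholds: Sequence[float],
    among_hits: bool = False,
) -> list[EvalRow]:
    """Contiguity/completeness/% hits at each threshold (closed comparison, >=).

    The denominator is the full reference-panel size ``n_refs``;
    ``among_hits=True`` renormalises by the number of references with
    hits instead (useful for comparison with tools that report that way).
    """
    if n_refs == 0:
        raise ValueError("n_refs must be positive")
    if n_refs < len(records):
        raise ValueError(f"n_refs={n_refs} smaller than number of records={len(records)}")
    denom = len(records) if among_hits else n_refs
    rows = []
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0,1]")
        if denom == 0:
            rows.append(EvalRow(t, 0.0, 0.0, 0.0))
            continue
        cont = sum(1 for r in records if r.best_single_frac >= t) / denom
        comp = sum(1 for r in records if r.union_frac >= t) / denom
        rows.append(EvalRow(t, cont, comp, len(records) / denom))
    return rows


def contiguity_count_at(records: Sequence[CoverageRecord], threshold: float) -> int:
    """Count (not fraction) of references whose best single contig covers >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0,1]")
    return sum(1 for r in records if r.best_single_frac >= threshold)


def default_threshold_sweep() -> list[float]:
    """0 plus 0.05 steps from 0.05 to 1.00."""
    return [0.0] + [round(0.05 * i, 2) for i in range(1, 21)]
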