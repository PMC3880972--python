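"""Read preprocessing, seeded pair subsampling, and library-QC fractions.

Covers three jobs around the raw paired-end data:

* :func:`filter_reads` — drop pairs with short mates or poly-A/poly-T
  homopolymer tails (a library-construction artifact of poly-A priming);
* :func:`subsample_pairs` / :func:`run_saturation_experiment` — draw
  seeded fractions of the pair set and aggregate an evaluation metric
  over replicates, producing a saturation curve (metric vs proportion
  of reads used);
* :func:`rrna_fraction` / :func:`unique_start_fraction` — ribosomal-RNA
  contamination and duplicate-marking-style library complexity.  Read
  mapping itself is out of scope: these consume counts and mapped
  fragment keys produced by any mapper (or by the fixture generator's
  truth-based placements).
"""

from __future__ import annotations

import math
import random
import re
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, TypeVar

from .coverage_eval import merge_intervals
from .io_formats import ReadPair

__all__ = [
    "SubsampleSpec",
    "FragmentKey",
    "FilterReport",
    "SaturationRow",
    "filter_reads",
    "subsample_indices",
    "subsample_pairs",
    "saturation_table",
    "rrna_fraction",
    "unique_start_fraction",
    "derive_seed",
    "placement_completeness",
    "run_saturation_experiment",
]

T = TypeVar("T")


@dataclass(frozen=True)
class SubsampleSpec:
    """Design of a saturation experiment: which proportions, how many
    replicates (proportion 1.0 is always run once), and the base seed."""

    proportions: tuple[float, ...]
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.proportions) != sorted(set(self.proportions)):
            raise ValueError("proportions must be sorted ascending and unique")
        if any(not 0.0 < p <= 1.0 for p in self.proportions):
            raise ValueError("proportions must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def n_replicates(self, proportion: float) -> int:
        return 1 if proportion == 1.0 else self.replicates


@dataclass(frozen=True)
class FragmentKey:
    """Duplicate-marking identity of a mapped pair: reference, both mate
    start coordinates, and the strand of mate 1."""

    ref_id: str
    start1: int
    strand1: str
    start2: int

    def __post_init__(self) -> None:
        if self.strand1 not in ("+", "-"):
            raise ValueError(f"strand1 must be '+' or '-', got {self.strand1!r}")
        if self.start1 < 0 or self.start2 < 0:
            raise ValueError("mate starts must be >= 0")


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_short: int
    n_polya: int
    n_retained: int


@dataclass(frozen=True)
class SaturationRow:
    proportion: float
    mean: float
    sd: float
    n: int


_RUN_RE = {base: re.compile(f"{base}+") for base in "AT"}


def _longest_run(seq: str, base: str) -> int:
    runs = _RUN_RE[base].findall(seq)
    return max((len(r) for r in runs), default=0)


def _polya_flagged(seq: str, max_frac: float, mode: str) -> bool:
    s = seq.upper()
    if mode == "run":
        worst = max(_longest_run(s, "A"), _longest_run(s, "T"))
    else:  # total content of A (or of T, for reverse-complemented tails)
        worst = max(s.count("A"), s.count("T"))
    return worst / len(s) > max_frac


def filter_reads(
    pairs: Sequence[ReadPair],
    min_len: int = 50,
    max_polya_run_frac: float = 0.06,
    polya_mode: str = "run",
) -> tuple[list[ReadPair], FilterReport]:
    """Drop pairs with a short mate or an excessive poly-A/T signal.

    A pair is discarded if either mate is shorter than ``min_len``
    (counted as "short"), or — checked second — if either mate's longest
    A or T homopolymer run exceeds ``max_polya_run_frac`` of its length
    ("polya").  ``polya_mode="total"`` uses total A (or T) content
    instead of the longest run.  Retained pairs are returned unchanged,
    in input order.
    """
    if polya_mode not in ("run", "total"):
        raise ValueError(f"polya_mode must be 'run' or 'total', got {polya_mode!r}")
    retained: list[ReadPair] = []
    n_short = n_polya = 0
    for p in pairs:
        if len(p.seq1) < min_len or len(p.seq2) < min_len:
            n_short += 1
        elif _polya_flagged(p.seq1, max_polya_run_frac, polya_mode) or _polya_flagged(
            p.seq2, max_polya_run_frac, polya_mode
        ):
            n_polya += 1
        else:
            retained.append(p)
    return retained, FilterReport(len(pairs), n_short, n_polya, len(retained))


def subsample_indices(n: int, proportion: float, seed: int) -> list[int]:
    """Sorted indices of a uniform without-replacement draw of
    ``k = round-half-up(proportion * n)`` items (clamped to [1, n])."""
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    if n < 1:
        raise ValueError("cannot subsample an empty set")
    k = min(n, max(1, math.floor(proportion * n + 0.5)))
    rng = random.Random(seed)
    return sorted(rng.sample(range(n), k))


def subsample_pairs(
    pairs: Sequence[ReadPair], proportion: float, seed: int
) -> list[ReadPair]:
    """Draw a seeded uniform subset of pairs, mates never separated,
    input relative order preserved.  Identical (input, proportion, seed)
    yields an identical selection."""
    return [pairs[i] for i in subsample_indices(len(pairs), proportion, seed)]


def saturation_table(
    metric_values: Mapping[float, Sequence[float]]
) -> list[SaturationRow]:
    """Aggregate replicate metric values per proportion into
    (mean, sample sd, n) rows, sorted by proportion.  sd is 0 for n=1."""
    if not metric_values:
        raise ValueError("empty metric map")
    rows = []
    for p in sorted(metric_values):
        vals = list(metric_values[p])
        if not vals:
            raise ValueError(f"no replicate values for proportion {p}")
        sd = statistics.stdev(vals) if len(vals) > 1 else 0.0
        rows.append(SaturationRow(p, statistics.fmean(vals), sd, len(vals)))
    return rows


def rrna_fraction(n_rrna_reads: int, n_total_reads: int) -> float:
    """Fraction of reads identified as ribosomal RNA."""
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    if not 0 <= n_rrna_reads <= n_total_reads:
        raise ValueError(
            f"n_rrna_reads must be in [0, {n_total_reads}], got {n_rrna_reads}"
        )
    return n_rrna_reads / n_total_reads


def unique_start_fraction(keys: Sequence[FragmentKey]) -> float:
    """Library-complexity proxy: distinct mapped fragment keys / all keys."""
    if not keys:
        raise ValueError("empty key list")
    return len(set(keys)) / len(keys)


def derive_seed(base_seed: int, prop_index: int, replicate: int) -> int:
    """Deterministic per-(proportion, replicate) seed below 2**31."""
    return (base_seed * 1_000_003 + prop_index * 10_007 + replicate * 101 + 7) % (2**31 - 1)


def placement_completeness(
    placements: Sequence[tuple[str, int, int]],
    orf_ivs: Mapping[str, tuple[int, int]],
    threshold: float,
    indices: Optional[Sequence[int]] = None,
) -> float:
    """Fraction of reference genes whose coding region is covered to
    >= ``threshold`` by the union of fragment placements.

    A placement is (gene_id, fragment_start, fragment_end) on the
    transcript; only the part overlapping the gene's coding interval
    counts.  ``indices`` restricts the evaluation to a subsample.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0,1]")
    chosen = placements if indices is None else [placements[i] for i in indices]
    per_gene: dict[str, list[tuple[int, int]]] = {}
    for gene, s, e in chosen:
        o_s, o_e = orf_ivs[gene]
        cs, ce = max(s, o_s), min(e, o_e)
        if cs < ce:
            per_gene.setdefault(gene, []).append((cs, ce))
    n_ok = 0
    for gene, ivs in per_gene.items():
        o_s, o_e = orf_ivs[gene]
        cov = sum(e - s for s, e in merge_intervals(ivs))
        if cov / (o_e - o_s) >= threshold:
            n_ok += 1
    return n_ok / len(orf_ivs)


def run_saturation_experiment(
    placements: Sequence[tuple[str, int, int]],
    orf_ivs: Mapping[str, tuple[int, int]],
    spec: SubsampleSpec,
    threshold: float = 0.8,
) -> tuple[dict[float, list[float]], list[SaturationRow]]:
    """Completeness-vs-proportion saturation curve from fragment placements.

    For each proportion (replicated per ``spec``), subsample the
    placements with a seed derived from (base seed, proportion index,
    replicate) and compute :func:`placement_completeness`.  A read set's
    contribution to a reference's coverage is the union of its
    exactly-known placements — a desk-scale proxy for re-assembling each
    subsample, preserving the shape of the experiment.
    """
    values: dict[float, list[float]] = {}
    for i, p in enumerate(spec.proportions):
        reps = []
        for r in range(spec.n_replicates(p)):
            idx = subsample_indices(len(placements), p, derive_seed(spec.seed, i, r))
            reps.append(placement_completeness(placements, orf_ivs, threshold, idx))
        values[p] = reps
    return values, saturation_table(values)
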