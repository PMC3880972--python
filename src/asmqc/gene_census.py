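"""Organelle-targeted gene census: PPR classification, reciprocal best
hits, pairwise identity and coding-sequence intactness.

Pentatricopeptide-repeat (PPR) proteins are called from profile-HMM
motif digests: a transcript with more than one PPR motif counts as a
PPR gene.  Class assignment follows standard PPR nomenclature priority:
any DYW motif makes the gene PLS-DYW; otherwise any E/E+ motif makes it
PLS-E; otherwise it is P class.  The PLS subclasses (E, DYW) are the
ones implicated in organellar RNA editing, so their counts are the
biologically interesting output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_formats import AlignedPair, AlignmentHit, MotifAnnotation
from .orf_translate import translate_frame

__all__ = [
    "PPRCall",
    "CensusCounts",
    "OrthologPair",
    "classify_ppr",
    "census",
    "reciprocal_best_hits",
    "pairwise_identity",
    "intactness_check",
]

PPR_CLASSES = ("P", "PLS-E", "PLS-DYW")
NOT_PPR = "not-PPR"

_NT_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class PPRCall:
    seq_id: str
    n_motifs: int
    class_label: str

    def __post_init__(self) -> None:
        if (self.class_label == NOT_PPR) != (self.n_motifs < 2):
            raise ValueError(
                f"{self.seq_id}: label {self.class_label!r} inconsistent with "
                f"{self.n_motifs} motifs"
            )


@dataclass(frozen=True)
class CensusCounts:
    """PPR census totals: overall PPR gene count and per-class counts."""

    n_ppr: int
    n_p: int
    n_pls_e: int
    n_pls_dyw: int
    n_not_ppr: int

    def __post_init__(self) -> None:
        if self.n_ppr != self.n_p + self.n_pls_e + self.n_pls_dyw:
            raise ValueError("PPR total must equal P + PLS-E + PLS-DYW")


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    bitscore_ab: float
    bitscore_ba: float


def classify_ppr(annotation: MotifAnnotation) -> PPRCall:
    """Call a transcript's PPR status and class from its motif list.

    Fewer than two motifs (of any class) -> not a PPR gene.  Otherwise
    DYW dominates, then E/E+, then P (a PPR gene with only P/L/S motifs
    is P class).
    """
    classes = {m[0] for m in annotation.motifs}
    n = len(annotation.motifs)
    if n < 2:
        label = NOT_PPR
    elif "DYW" in classes:
        label = "PLS-DYW"
    elif "E" in classes or "E+" in classes:
        label = "PLS-E"
    else:
        label = "P"
    return PPRCall(annotation.seq_id, n, label)


def census(annotations: Sequence[MotifAnnotation]) -> CensusCounts:
    """Count PPR genes and their classes across a set of transcripts."""
    seen: set[str] = set()
    counts = {c: 0 for c in PPR_CLASSES}
    n_not = 0
    for ann in annotations:
        if ann.seq_id in seen:
            raise ValueError(f"duplicate seq_id in annotations: {ann.seq_id!r}")
        seen.add(ann.seq_id)
        call = classify_ppr(ann)
        if call.class_label == NOT_PPR:
            n_not += 1
        else:
            counts[call.class_label] += 1
    return CensusCounts(
        n_ppr=sum(counts.values()),
        n_p=counts["P"],
        n_pls_e=counts["PLS-E"],
        n_pls_dyw=counts["PLS-DYW"],
        n_not_ppr=n_not,
    )


def _best_per_query(hits: Sequence[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Top hit per query: max bitscore, ties by min evalue, then
    lexicographically smallest subject id."""
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        prev = best.get(h.qid)
        if prev is None or (-h.bitscore, h.evalue, h.sid) < (-prev.bitscore, prev.evalue, prev.sid):
            best[h.qid] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[AlignmentHit], hits_ba: Sequence[AlignmentHit]
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between sets A and B.

    (a, b) is emitted iff b is a's best hit in A->B and a is b's best
    hit in B->A.  Output is sorted by ``id_a``; no id appears twice on
    either side.
    """
    best_ab = _best_per_query(hits_ab)
    best_ba = _best_per_query(hits_ba)
    pairs = []
    for a, hab in best_ab.items():
        hba = best_ba.get(hab.sid)
        if hba is not None and hba.sid == a:
            pairs.append(OrthologPair(a, hab.sid, hab.bitscore, hba.bitscore))
    return sorted(pairs, key=lambda p: p.id_a)


def pairwise_identity(pair: AlignedPair, ungapped_denominator: bool = False) -> float:
    """Identity of an aligned pair: matching columns / alignment columns.

    A column matches iff both characters are equal (case-insensitive)
    and neither is the gap character.  By default columns with a gap in
    either sequence count in the denominator; with
    ``ungapped_denominator`` the denominator is the gap-free columns
    only (0.0 if there are none).
    """
    a, b = pair.aln_a.upper(), pair.aln_b.upper()
    matches = ungapped = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            ungapped += 1
            if x == y:
                matches += 1
    denom = ungapped if ungapped_denominator else len(a)
    return matches / denom if denom else 0.0


def intactness_check(seq: str, is_nucleotide: Optional[bool] = None) -> str:
    """Classify a coding sequence or peptide as "intact",
    "internal-stop" or "no-terminus".

    Nucleotide input is translated in frame +1 and must carry a leading
    ATG and a trailing stop codon to be intact; peptide input is checked
    for internal stops only.  When ``is_nucleotide`` is None the
    alphabet decides (ACGTN-only strings are treated as nucleotide).
    """
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    if is_nucleotide is None:
        is_nucleotide = set(s) <= _NT_ALPHABET
    if is_nucleotide:
        if len(s) % 3 != 0:
            raise ValueError(f"nucleotide length {len(s)} not divisible by 3")
        pep = translate_frame(s, 1)
    else:
        pep = s
    if "*" in pep[:-1]:
        return "internal-stop"
    if is_nucleotide and not (s.startswith("ATG") and pep.endswith("*")):
        return "no-terminus"
    return "intact"
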