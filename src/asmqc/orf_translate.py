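"""Alignment-anchored translation with stop-to-stop extension.

A translated (blastx-style) hit supplies a reading frame and an aligned
region ("anchor") on a contig.  The anchor is translated in that frame
and then extended codon-by-codon in both directions until a stop codon
is reached or the contig runs out, yielding the maximal stop-free
peptide containing the anchored residues.  No start codon is required:
the peptide may begin mid-ORF, which is the right behaviour for
fragmentary transcriptome contigs.

Frames follow the blast convention: +1..+3 are offsets 0..2 on the
forward strand, -1..-3 are offsets 0..2 on the reverse complement.
Reported nucleotide intervals are always on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .asm_stats import SummaryStats, _summary_from_lengths, dedup_contigs
from .io_formats import AlignmentHit, Contig

__all__ = ["TranslatedContig", "translate_frame", "anchor_translate_extend", "translate_assembly"]

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
_CODON_TO_AA = dict(_TABLE.forward_table)
_STOPS = frozenset(_TABLE.stop_codons)

FRAMES = (-3, -2, -1, 1, 2, 3)


def _codon_aa(codon: str) -> str:
    """One codon to one residue; codons containing N (or anything outside
    ACGT) yield 'X', stop codons yield '*'."""
    aa = _CODON_TO_AA.get(codon)
    if aa is not None:
        return aa
    if codon in _STOPS:
        return "*"
    return "X"


@dataclass(frozen=True)
class TranslatedContig:
    """A stop-free peptide anchored on a contig, with its frame and the
    forward-strand nucleotide interval it back-translates to."""

    contig_id: str
    frame: int
    peptide: str
    q_start_nt: int
    q_end_nt: int

    def __post_init__(self) -> None:
        if self.q_end_nt - self.q_start_nt != 3 * len(self.peptide):
            raise ValueError(
                f"{self.contig_id}: interval length {self.q_end_nt - self.q_start_nt} "
                f"!= 3 x peptide length {len(self.peptide)}"
            )
        if "*" in self.peptide:
            raise ValueError(f"{self.contig_id}: internal stop in peptide")


def translate_frame(seq: str, frame: int) -> str:
    """Translate ``seq`` in one of the six frames (standard code).

    Negative frames operate on the reverse complement; the leading
    offset is ``|frame| - 1`` and a trailing partial codon is dropped.
    Stop codons render '*'; codons containing N render 'X'.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    s = seq.upper()
    if frame < 0:
        s = reverse_complement(s)
    off = abs(frame) - 1
    return "".join(_codon_aa(s[i : i + 3]) for i in range(off, len(s) - 2, 3))


def _snap_to_codons(start: int, end: int, offset: int, length: int) -> tuple[int, int]:
    """Snap [start, end) outward to codon boundaries of the frame phase,
    clamped to the translatable region [offset, last complete codon)."""
    last = offset + 3 * ((length - offset) // 3)
    a = max(offset, offset + 3 * ((start - offset) // 3))
    b = min(last, offset + 3 * (-((offset - end) // 3)))  # ceil division
    return a, b


def anchor_translate_extend(
    contig: Contig, hit: AlignmentHit, strict: bool = False
) -> TranslatedContig:
    """Translate a hit's aligned region in its frame and extend both ways
    to stop codons (stops excluded from the peptide).

    The anchor interval is snapped outward to the frame's codon grid, so
    no anchored residue is lost when alignment columns cross codon
    boundaries.  A stop codon inside the anchor is an error under
    ``strict``; otherwise the peptide is truncated at the first in-anchor
    stop (logged) and only upstream extension is attempted.
    """
    if hit.qframe is None:
        raise ValueError(f"hit {hit.qid}->{hit.sid}: frame required")
    frame = hit.qframe
    L = len(contig.seq)
    q_s, q_e = hit.q_iv
    if not (0 <= q_s < q_e <= L):
        raise ValueError(
            f"anchor [{q_s},{q_e}) outside contig {contig.id} of length {L}"
        )
    seq = contig.seq.upper()
    work = seq if frame > 0 else reverse_complement(seq)
    # anchor in working-strand coordinates
    ws, we = (q_s, q_e) if frame > 0 else (L - q_e, L - q_s)
    off = abs(frame) - 1
    a, b = _snap_to_codons(ws, we, off, L)
    if b <= a:
        raise ValueError(
            f"anchor [{q_s},{q_e}) of {contig.id} leaves no complete codon in frame {frame}"
        )
    if (a, b) != (ws, we):
        if strict and ((ws - off) % 3 != 0 or (we - off) % 3 != 0):
            raise ValueError(
                f"anchor [{q_s},{q_e}) of {contig.id} not congruent with frame {frame} phase"
            )
        logger.debug(
            "anchor of %s snapped from [%d,%d) to codon grid [%d,%d) in frame %+d",
            contig.id, ws, we, a, b, frame,
        )

    aa = [_codon_aa(work[i : i + 3]) for i in range(a, b, 3)]
    truncated = False
    if "*" in aa:
        if strict:
            raise ValueError(f"stop codon inside anchor of {contig.id}")
        stop_at = aa.index("*")
        logger.warning(
            "anchor of %s contains a stop codon; truncating at anchor codon %d",
            contig.id, stop_at,
        )
        aa = aa[:stop_at]
        b = a + 3 * stop_at
        truncated = True
        if not aa:
            raise ValueError(f"anchor of {contig.id} starts with a stop codon")

    # upstream: prepend codons until a stop or the translatable edge
    pos = a - 3
    while pos >= off:
        res = _codon_aa(work[pos : pos + 3])
        if res == "*":
            break
        aa.insert(0, res)
        pos -= 3
    a = pos + 3
    # downstream (skipped when the anchor was stop-truncated: the stop ends it)
    if not truncated:
        pos = b
        while pos + 3 <= L:
            res = _codon_aa(work[pos : pos + 3])
            if res == "*":
                break
            aa.append(res)
            pos += 3
        b = pos

    if frame > 0:
        nt_s, nt_e = a, b
    else:
        nt_s, nt_e = L - b, L - a
    return TranslatedContig(contig.id, frame, "".join(aa), nt_s, nt_e)


def translate_assembly(
    contigs: Sequence[Contig],
    hits: Sequence[AlignmentHit],
    min_aa: int = 50,
    strict: bool = False,
) -> tuple[list[TranslatedContig], SummaryStats]:
    """Translate every anchored contig, deduplicate and summarise.

    One hit is used per contig (best bitscore, ties by lowest evalue then
    input order).  Peptides are deduplicated at 100% identity (substring
    containment, as for nucleotide contigs), filtered at ``min_aa``
    residues, and summarised with the usual count/total/max/mean/N50
    metrics in amino acids.
    """
    by_id = {c.id: c for c in contigs}
    best_hit: dict[str, tuple[float, float, int]] = {}
    chosen: dict[str, AlignmentHit] = {}
    for i, h in enumerate(hits):
        if h.qid not in by_id:
            raise ValueError(f"hit references unknown contig {h.qid!r}")
        key = (-h.bitscore, h.evalue, i)
        if h.qid not in best_hit or key < best_hit[h.qid]:
            best_hit[h.qid] = key
            chosen[h.qid] = h

    translated = [
        anchor_translate_extend(by_id[qid], chosen[qid], strict=strict)
        for qid in (c.id for c in contigs)
        if qid in chosen
    ]
    as_contigs = [Contig(t.contig_id, t.peptide) for t in translated]
    kept, redundancy = dedup_contigs(as_contigs)
    kept_ids = {c.id for c in kept}
    result = [t for t in translated if t.contig_id in kept_ids and len(t.peptide) >= min_aa]
    lengths = [len(t.peptide) for t in result]
    if not lengths:
        raise ValueError("empty assembly after length filter")
    return result, _summary_from_lengths(lengths, redundancy)
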