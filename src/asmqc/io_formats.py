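"""Readers and writers for the external formats the toolkit consumes.

Every downstream module operates only on the domain types defined here:
:class:`Contig`, :class:`ReadPair`, :class:`AlignmentHit`,
:class:`MotifAnnotation` and :class:`AlignedPair`.

Conventions enforced at parse time, exactly once:

* all intervals are 0-based, half-open, on the forward strand;
* percent identity is stored as a fraction in ``[0, 1]`` (user-facing
  output multiplies by 100);
* parsers are strict and fail fast with a line number rather than
  skipping malformed rows — evaluation metrics silently change when
  rows are dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

__all__ = [
    "Contig",
    "ReadPair",
    "AlignmentHit",
    "MotifAnnotation",
    "AlignedPair",
    "MOTIF_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_motif_table",
    "write_motif_table",
    "read_aligned_pair",
    "read_ref_lens",
    "write_ref_lens",
    "write_tsv",
]

#: PPR motif classes accepted in motif-hit tables.  P/L/S are the repeat
#: motifs proper; E, E+ and DYW are the C-terminal domains that define
#: the editing-associated PLS subclasses.
MOTIF_CLASSES = ("P", "L", "S", "E", "E+", "DYW")


@dataclass(frozen=True)
class Contig:
    """An assembled sequence record; the unit of all assembly statistics."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"contig id must be a non-empty token, got {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for contig {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """One paired-end fragment: both mates with their quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        for mate, (s, q) in enumerate(((self.seq1, self.qual1), (self.seq2, self.qual2)), 1):
            if len(s) < 1:
                raise ValueError(f"read pair {self.id!r}: mate {mate} is empty")
            if len(q) != len(s):
                raise ValueError(
                    f"read pair {self.id!r}: mate {mate} quality length {len(q)} "
                    f"!= sequence length {len(s)}"
                )


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP row from a tabular alignment file, in internal coordinates.

    ``q_iv`` and ``s_iv`` are 0-based half-open intervals on the forward
    strand.  ``q_reversed`` records that the query coordinates were given
    in reverse orientation in the input (a negative-frame translated hit);
    when ``qframe`` is present its sign is authoritative.
    """

    qid: str
    sid: str
    pident: float
    aln_len: int
    q_iv: tuple[int, int]
    s_iv: tuple[int, int]
    evalue: float
    bitscore: float
    qframe: Optional[int] = None
    qlen: Optional[int] = None
    slen: Optional[int] = None
    q_reversed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 1.0:
            raise ValueError(f"pident must be a fraction in [0,1], got {self.pident}")
        for name, (a, b), n in (("q_iv", self.q_iv, self.qlen), ("s_iv", self.s_iv, self.slen)):
            if not a < b:
                raise ValueError(f"{name} must satisfy start < end, got [{a},{b})")
            if n is not None and b > n:
                raise ValueError(f"{name} end {b} exceeds declared length {n}")
        if self.qframe is not None and self.qframe not in (-3, -2, -1, 1, 2, 3):
            raise ValueError(f"qframe must be in ±1..±3, got {self.qframe}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")


@dataclass(frozen=True)
class MotifAnnotation:
    """Per-transcript list of profile-HMM motif hits, ordered by start."""

    seq_id: str
    motifs: tuple[tuple[str, int, int, float], ...]

    def __post_init__(self) -> None:
        starts = [m[1] for m in self.motifs]
        if starts != sorted(starts):
            raise ValueError(f"motifs of {self.seq_id!r} are not ordered by start")
        for cls, start, end, _score in self.motifs:
            if cls not in MOTIF_CLASSES:
                raise ValueError(
                    f"unknown motif class {cls!r} for {self.seq_id!r}; "
                    f"allowed: {', '.join(MOTIF_CLASSES)}"
                )
            if not 0 <= start < end:
                raise ValueError(f"bad motif interval [{start},{end}) for {self.seq_id!r}")


@dataclass(frozen=True)
class AlignedPair:
    """Two rows of a pairwise alignment (aligned FASTA), gap character '-'."""

    id_a: str
    id_b: str
    aln_a: str
    aln_b: str

    def __post_init__(self) -> None:
        if len(self.aln_a) != len(self.aln_b):
            raise ValueError(
                f"aligned lengths differ: {len(self.aln_a)} vs {len(self.aln_b)}"
            )
        if len(self.aln_a) < 1:
            raise ValueError("empty alignment")
        for i, (a, b) in enumerate(zip(self.aln_a, self.aln_b)):
            if a == "-" and b == "-":
                raise ValueError(f"double-gap column at position {i}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a FASTA file into an ordered list of :class:`Contig`.

    Sequences are uppercased; input order is preserved.  Duplicate ids,
    empty records, and text before the first header are errors.
    """
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}: malformed header: first record must start with '>'")
                break
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id: {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence record: {rec.id}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike, width: int = 60) -> None:
    """Write contigs as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (4-line records, two mate files)
# ---------------------------------------------------------------------------

_MATE_SUFFIXES = ("/1", "/2")


def _strip_mate_suffix(read_id: str) -> str:
    # Casava-style " 1:N:0:..." tails are already dropped by taking the
    # first whitespace token; legacy "/1", "/2" suffixes are stripped here.
    token = read_id.split()[0]
    for suf in _MATE_SUFFIXES:
        if token.endswith(suf):
            return token[: -len(suf)]
    return token


def read_fastq_pairs(path1: str | os.PathLike, path2: str | os.PathLike) -> list[ReadPair]:
    """Read two mate FASTQ files into positionally paired :class:`ReadPair`.

    Pair ids come from file 1 with mate suffixes ("/1", "/2" and
    Casava-style " 1:...", " 2:..." tails) stripped.
    """
    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError(f"mate count mismatch: {len(recs1)} vs {len(recs2)}")
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        pairs.append(
            ReadPair(_strip_mate_suffix(r1.id), str(r1.seq).upper(), q1, str(r2.seq).upper(), q2)
        )
    return pairs


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | os.PathLike, path2: str | os.PathLike
) -> None:
    """Write pairs as two 4-line FASTQ files with "/1" and "/2" suffixes."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# Tabular alignment hits (12-column BLAST dialect plus declared extras)
# ---------------------------------------------------------------------------

_STD_COLUMNS = 12
_KNOWN_EXTRAS = ("qframe", "qlen", "slen")


def read_tabular_hits(
    path: str | os.PathLike, extra_columns: Sequence[str] = ()
) -> list[AlignmentHit]:
    """Parse a 12-column tabular hit file with optional declared extras.

    Standard columns: qid, sid, pident, length, mismatch, gapopen,
    qstart, qend, sstart, send, evalue, bitscore.  ``extra_columns``
    names trailing columns in order; recognised names are ``qframe``,
    ``qlen`` and ``slen``.

    1-based inclusive coordinates are converted to 0-based half-open;
    reversed coordinate pairs are normalised to forward-strand intervals
    with the orientation flagged.  ``pident`` is divided by 100.
    """
    for name in extra_columns:
        if name not in _KNOWN_EXTRAS:
            raise ValueError(f"unknown extra column {name!r}; known: {', '.join(_KNOWN_EXTRAS)}")
    n_cols = _STD_COLUMNS + len(extra_columns)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}: expected {n_cols} columns, got {len(fields)} at line {lineno}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2]) / 100.0
                aln_len = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                extras = {
                    name: int(value)
                    for name, value in zip(extra_columns, fields[_STD_COLUMNS:])
                }
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric field at line {lineno}: {exc}") from None
            q_reversed = qstart > qend
            if q_reversed:
                qstart, qend = qend, qstart
            if sstart > send:
                sstart, send = send, sstart
            qframe = extras.get("qframe")
            if qframe is not None:
                q_reversed = qframe < 0
            try:
                hits.append(
                    AlignmentHit(
                        qid=qid,
                        sid=sid,
                        pident=pident,
                        aln_len=aln_len,
                        q_iv=(qstart - 1, qend),
                        s_iv=(sstart - 1, send),
                        evalue=evalue,
                        bitscore=bitscore,
                        qframe=qframe,
                        qlen=extras.get("qlen"),
                        slen=extras.get("slen"),
                        q_reversed=q_reversed,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return hits


def write_tabular_hits(
    hits: Iterable[AlignmentHit], path: str | os.PathLike, extra_columns: Sequence[str] = ()
) -> None:
    """Write hits back to the 12(+extras)-column tabular dialect.

    Inverse of :func:`read_tabular_hits`: coordinates go out 1-based
    inclusive (reversed for negative-orientation queries) and pident is
    multiplied by 100.  Mismatch/gapopen columns, which the domain type
    does not carry, are written as 0.
    """
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.q_iv[0] + 1, h.q_iv[1]
            if h.q_reversed:
                qs, qe = qe, qs
            row = [
                h.qid,
                h.sid,
                f"{h.pident * 100:.2f}",
                str(h.aln_len),
                "0",
                "0",
                str(qs),
                str(qe),
                str(h.s_iv[0] + 1),
                str(h.s_iv[1]),
                f"{h.evalue:g}",
                f"{h.bitscore:g}",
            ]
            for name in extra_columns:
                value = getattr(h, name)
                if value is None:
                    raise ValueError(f"hit {h.qid}->{h.sid} lacks extra column {name!r}")
                row.append(str(value))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Motif-hit tables (digest of a profile-HMM domain search)
# ---------------------------------------------------------------------------

def read_motif_table(path: str | os.PathLike) -> list[MotifAnnotation]:
    """Read a motif-hit TSV (seq_id, motif_class, start, end, score).

    Rows are grouped by ``seq_id`` (order of first appearance) and each
    transcript's motifs are sorted by start coordinate.
    """
    grouped: dict[str, list[tuple[str, int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}: expected 5 columns, got {len(fields)} at line {lineno}")
            seq_id, cls = fields[0], fields[1]
            if cls not in MOTIF_CLASSES:
                raise ValueError(
                    f"{path}: line {lineno}: unknown motif class {cls!r}; "
                    f"allowed: {', '.join(MOTIF_CLASSES)}"
                )
            try:
                start, end, score = int(fields[2]), int(fields[3]), float(fields[4])
            except ValueError:
                raise ValueError(f"{path}: non-numeric field at line {lineno}") from None
            grouped.setdefault(seq_id, []).append((cls, start, end, score))
    return [
        MotifAnnotation(seq_id, tuple(sorted(motifs, key=lambda m: m[1])))
        for seq_id, motifs in grouped.items()
    ]


def write_motif_table(annotations: Iterable[MotifAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#seq_id\tmotif_class\tstart\tend\tscore\n")
        for ann in annotations:
            for cls, start, end, score in ann.motifs:
                fh.write(f"{ann.seq_id}\t{cls}\t{start}\t{end}\t{score:g}\n")


# ---------------------------------------------------------------------------
# Aligned pairs, reference lengths, generic TSV
# ---------------------------------------------------------------------------

def read_aligned_pair(path: str | os.PathLike) -> AlignedPair:
    """Read an aligned FASTA file holding exactly two equal-length rows."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned records, got {len(recs)}")
    return AlignedPair(recs[0].id, recs[1].id, str(recs[0].seq).upper(), str(recs[1].seq).upper())


def read_ref_lens(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column TSV of reference id -> length (residues)."""
    lens: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: expected 2 columns, got {len(fields)} at line {lineno}")
            ref_id, raw = fields
            try:
                n = int(raw)
            except ValueError:
                raise ValueError(f"{path}: non-numeric length at line {lineno}") from None
            if n < 1:
                raise ValueError(f"{path}: non-positive length at line {lineno}")
            if ref_id in lens:
                raise ValueError(f"{path}: duplicate reference id {ref_id!r} at line {lineno}")
            lens[ref_id] = n
    return lens


def write_ref_lens(lens: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#ref_id\tlength\n")
        for ref_id, n in lens.items():
            fh.write(f"{ref_id}\t{n}\n")


def write_tsv(
    path: str | os.PathLike, header: Sequence[str], rows: Iterable[Sequence[object]]
) -> None:
    """Write a TSV with a single '#'-prefixed header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
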