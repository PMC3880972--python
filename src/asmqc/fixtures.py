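"""Synthetic fixtures with known ground truth.

Generates everything the evaluation stack consumes — reference proteins
with coding sequences, fragmented "assemblies" with exactly known
placements, error-free read pairs, perfect hit tables and motif tables —
so the whole toolkit is testable end-to-end without external data or an
aligner.  The central contract is closure: metrics computed from the
emitted hit tables equal the stored truth exactly, and anchored
translation of error-free fragments recovers the planted peptides.

Every generator is a deterministic function of its parameters and seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .gene_census import CensusCounts
from .io_formats import AlignmentHit, Contig, MotifAnnotation, ReadPair

__all__ = [
    "Fragment",
    "TruthSet",
    "make_reference",
    "fragment_assembly",
    "simulate_read_pairs",
    "make_motif_fixture",
]

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_NT_ALPHABET = "ACGT"
_RC = str.maketrans("ACGTN", "TGCAN")

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for codons in _CODONS_FOR.values():
    codons.sort()
_STOP_CODONS = sorted(_table.stop_codons)


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass(frozen=True)
class Fragment:
    """Placement of one synthetic contig on its source gene.

    ``ref_aa_iv`` is the protein-space subject interval the fragment
    covers; ``contig_iv`` is the matching forward-strand interval on the
    contig; ``frame`` is the blast-style reading frame of the coding
    region on the contig (None when the fragment misses the ORF).
    """

    contig_id: str
    ref_id: str
    cds_iv: tuple[int, int]
    ref_aa_iv: Optional[tuple[int, int]]
    contig_iv: Optional[tuple[int, int]]
    frame: Optional[int]


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for one synthetic data set."""

    proteins: dict[str, str]
    cds: dict[str, str]
    orf_iv: dict[str, tuple[int, int]]
    fragments: tuple[Fragment, ...] = ()
    true_coverage: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def ref_lens(self) -> dict[str, int]:
        return {g: len(p) for g, p in self.proteins.items()}


def make_reference(
    n_genes: int,
    min_aa: int = 80,
    max_aa: int = 400,
    utr_len: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> TruthSet:
    """Random stop-free peptides and their coding sequences.

    Each CDS is a random back-translation of its peptide with an
    in-frame stop codon planted immediately 5' and 3' of the ORF, padded
    with random-nucleotide UTRs, so full-frame translation shows the
    peptide flanked by '*'.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 1 <= min_aa <= max_aa:
        raise ValueError(f"degenerate peptide length range [{min_aa}, {max_aa}]")
    if not 0 <= utr_len[0] <= utr_len[1]:
        raise ValueError(f"degenerate UTR length range {utr_len}")
    rng = random.Random(seed)
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    orf_iv: dict[str, tuple[int, int]] = {}
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        gene = f"g{i:0{width}d}"
        pep = "".join(rng.choices(_AA_ALPHABET, k=rng.randint(min_aa, max_aa)))
        orf = "".join(rng.choice(_CODONS_FOR[aa]) for aa in pep)
        utr5 = "".join(rng.choices(_NT_ALPHABET, k=rng.randint(*utr_len)))
        utr3 = "".join(rng.choices(_NT_ALPHABET, k=rng.randint(*utr_len)))
        seq = utr5 + rng.choice(_STOP_CODONS) + orf + rng.choice(_STOP_CODONS) + utr3
        start = len(utr5) + 3
        proteins[gene] = pep
        cds[gene] = seq
        orf_iv[gene] = (start, start + len(orf))
    return TruthSet(proteins=proteins, cds=cds, orf_iv=orf_iv)


def _fragment_hit(
    truth: TruthSet, frag_id: str, gene: str, a: int, b: int, rc: bool
) -> tuple[Fragment, Optional[AlignmentHit]]:
    """Derive the protein-space hit implied by placing cds[a:b) as a contig.

    Nucleotide in-ORF offsets convert to protein coordinates by floor
    division at the start and ceiling at the end, mirroring how a
    translated search reports subject intervals for partial codons.
    """
    o_s, o_e = truth.orf_iv[gene]
    flen = b - a
    ov_s, ov_e = max(a, o_s), min(b, o_e)
    if ov_s >= ov_e:
        return Fragment(frag_id, gene, (a, b), None, None, None), None
    aa_s = (ov_s - o_s) // 3
    aa_e = -(-(ov_e - o_s) // 3)
    rel_s, rel_e = ov_s - a, ov_e - a
    q_iv = (flen - rel_e, flen - rel_s) if rc else (rel_s, rel_e)
    frame_mag = (o_s - a) % 3 + 1
    frame = -frame_mag if rc else frame_mag
    hit = AlignmentHit(
        qid=frag_id,
        sid=gene,
        pident=1.0,
        aln_len=aa_e - aa_s,
        q_iv=q_iv,
        s_iv=(aa_s, aa_e),
        evalue=1e-30,
        bitscore=2.0 * (aa_e - aa_s),
        qframe=frame,
        qlen=flen,
        slen=len(truth.proteins[gene]),
        q_reversed=rc,
    )
    return Fragment(frag_id, gene, (a, b), (aa_s, aa_e), q_iv, frame), hit


def _bitmask_coverage(
    frags: Sequence[Fragment], ref_lens: Mapping[str, int]
) -> dict[str, tuple[float, float]]:
    """Per-position bitmask truth for best-single and union coverage."""
    by_gene: dict[str, list[Fragment]] = {}
    for f in frags:
        if f.ref_aa_iv is not None:
            by_gene.setdefault(f.ref_id, []).append(f)
    out = {}
    for gene, fs in by_gene.items():
        n = ref_lens[gene]
        union = np.zeros(n, dtype=bool)
        best = 0
        for f in fs:
            s, e = f.ref_aa_iv
            union[s:e] = True
            best = max(best, e - s)
        out[gene] = (best / n, int(union.sum()) / n)
    return out


def fragment_assembly(
    truth: TruthSet,
    fragments_per_gene: int = 2,
    min_frac: float = 0.3,
    max_frac: float = 0.8,
    revcomp_prob: float = 0.5,
    full_length: bool = False,
    seed: int = 0,
) -> tuple[list[Contig], list[AlignmentHit], TruthSet]:
    """Fragment every CDS into contigs with exactly known placements.

    Each gene yields ``fragments_per_gene`` contigs, each a random
    substring of the CDS spanning a uniform fraction in
    ``[min_frac, max_frac]`` of its length, reverse-complemented with
    probability ``revcomp_prob``.  ``full_length=True`` instead emits
    one full-CDS contig per gene (a perfect assembly).

    Returns the contigs, a perfect protein-space hit table derived from
    the placements (no aligner involved), and the completed
    :class:`TruthSet` with fragments and bitmask-computed coverage truth.
    """
    if not truth.cds:
        raise ValueError("truth set has no genes")
    if not 0.0 < min_frac <= max_frac <= 1.0:
        raise ValueError(f"fragment fraction range [{min_frac}, {max_frac}] invalid")
    rng = random.Random(seed)
    contigs: list[Contig] = []
    hits: list[AlignmentHit] = []
    frags: list[Fragment] = []
    for gene in sorted(truth.cds):
        seq = truth.cds[gene]
        L = len(seq)
        n_frags = 1 if full_length else fragments_per_gene
        for i in range(n_frags):
            if full_length:
                a, b, rc = 0, L, False
            else:
                flen = min(L, max(3, round(L * rng.uniform(min_frac, max_frac))))
                if flen > L:
                    raise ValueError(f"fragment longer than source gene {gene}")
                a = rng.randint(0, L - flen)
                b = a + flen
                rc = rng.random() < revcomp_prob
            frag_id = f"{gene}_frag{i}"
            frag, hit = _fragment_hit(truth, frag_id, gene, a, b, rc)
            sub = seq[a:b]
            contigs.append(Contig(frag_id, _revcomp(sub) if rc else sub))
            frags.append(frag)
            if hit is not None:
                hits.append(hit)
    completed = replace(
        truth,
        fragments=tuple(frags),
        true_coverage=_bitmask_coverage(frags, truth.ref_lens),
    )
    return contigs, hits, completed


def simulate_read_pairs(
    truth: TruthSet,
    n_pairs: int,
    read_len: int = 101,
    insert_mean: int = 200,
    insert_sd: int = 20,
    weights: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> tuple[list[ReadPair], dict[str, int], list[tuple[str, int, int]]]:
    """Error-free paired reads from random CDS positions.

    Insert sizes are normal(``insert_mean``, ``insert_sd``) clamped to
    [read_len, template length]; fragment strand is random.  Per-gene
    abundances are uniform unless ``weights`` is given.  Returns the
    pairs, per-gene read-pair counts, and the exact fragment placements
    (gene, start, end) for truth-based downstream analyses.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    genes = sorted(truth.cds)
    lens = np.array([len(truth.cds[g]) for g in genes], dtype=np.int64)
    if read_len > int(lens.min()):
        raise ValueError(
            f"read_len {read_len} exceeds shortest CDS length {int(lens.min())}"
        )
    rng = np.random.default_rng(seed)
    if weights is None:
        p = np.full(len(genes), 1.0 / len(genes))
    else:
        w = np.array([float(weights[g]) for g in genes])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with a positive sum")
        p = w / w.sum()
    gi = rng.choice(len(genes), size=n_pairs, p=p)
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64),
        read_len,
        lens[gi],
    )
    starts = (rng.random(n_pairs) * (lens[gi] - inserts + 1)).astype(np.int64)
    flip = rng.random(n_pairs) < 0.5

    pairs: list[ReadPair] = []
    counts: dict[str, int] = {g: 0 for g in genes}
    placements: list[tuple[str, int, int]] = []
    qual = "I" * read_len
    for i in range(n_pairs):
        gene = genes[gi[i]]
        s = int(starts[i])
        e = s + int(inserts[i])
        seq = truth.cds[gene]
        r1 = seq[s : s + read_len]
        r2 = _revcomp(seq[e - read_len : e])
        if flip[i]:
            r1, r2 = r2, r1
        pairs.append(ReadPair(f"rp{i:07d}", r1, qual, r2, qual))
        counts[gene] += 1
        placements.append((gene, s, e))
    return pairs, counts, placements


def make_motif_fixture(
    n_p: int = 5,
    n_pls_e: int = 3,
    n_pls_dyw: int = 2,
    n_decoys: int = 4,
    seed: int = 0,
) -> tuple[list[MotifAnnotation], CensusCounts]:
    """Motif annotations realizing exactly the requested census.

    P-class genes carry tandem P motifs; PLS-E genes end in an E motif;
    PLS-DYW genes end in E then DYW; decoys carry a single motif and
    must be called not-PPR.  Returns the annotations (shuffled
    deterministically) and the expected census counts.
    """
    for name, n in (("n_p", n_p), ("n_pls_e", n_pls_e), ("n_pls_dyw", n_pls_dyw), ("n_decoys", n_decoys)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = random.Random(seed)
    motif_len = 35

    def run(seq_id: str, classes: Sequence[str]) -> MotifAnnotation:
        motifs = []
        pos = rng.randint(0, 40)
        for cls in classes:
            motifs.append((cls, pos, pos + motif_len, round(rng.uniform(15.0, 60.0), 1)))
            pos += motif_len
        return MotifAnnotation(seq_id, tuple(motifs))

    anns: list[MotifAnnotation] = []
    for i in range(n_p):
        anns.append(run(f"p_{i:03d}", ["P"] * rng.randint(2, 8)))
    for i in range(n_pls_e):
        anns.append(run(f"plse_{i:03d}", ["P", "L", "S"] * rng.randint(1, 3) + ["E"]))
    for i in range(n_pls_dyw):
        anns.append(run(f"plsdyw_{i:03d}", ["P", "L", "S"] * rng.randint(1, 3) + ["E", "DYW"]))
    for i in range(n_decoys):
        anns.append(run(f"decoy_{i:03d}", [rng.choice(["P", "L", "S"])]))
    rng.shuffle(anns)
    expected = CensusCounts(
        n_ppr=n_p + n_pls_e + n_pls_dyw,
        n_p=n_p,
        n_pls_e=n_pls_e,
        n_pls_dyw=n_pls_dyw,
        n_not_ppr=n_decoys,
    )
    return anns, expected
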