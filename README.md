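# asmqc — reference-guided QC for de novo transcriptome assemblies

When a transcriptome is assembled de novo — no reference genome, as for
most non-model organisms — the quality of the assembly has to be judged
against an external protein panel (conserved single-copy orthologs, a
well-annotated relative's proteome). `asmqc` implements that
evaluation as a tested Python library plus a CLI:

* **Assembly statistics** — deduplication at 100% identity (exact
  full-length substring containment, emulating CD-HIT at threshold
  1.0), redundancy, and the usual count / total bases / max / mean /
  N50 summary, for nucleotide contigs and translated peptides alike.
* **Coverage evaluation** — from tabular (blastx-style) hits of contigs
  against a reference panel, per-reference coverage by the best single
  contig and by the union of all contigs, swept over a coverage
  threshold *t*:
  - contiguity(*t*) = |{refs with best-single coverage ≥ *t*}| / *N*
  - completeness(*t*) = |{refs with union coverage ≥ *t*}| / *N*
  - % hits = |{refs with ≥ 1 hit}| / *N*

  with *N* the full panel size, so contiguity ≤ completeness ≤ % hits
  at every threshold. Multiple HSPs between a contig and a reference
  are merged before any fraction is computed.
* **Anchored translation** — translate a hit's aligned region in its
  reading frame, then extend codon-by-codon in both directions until a
  stop codon: the maximal stop-free peptide containing the anchor. No
  start codon is required (contigs are fragmentary).
* **Saturation analysis** — seeded uniform subsampling of read pairs
  (k = round-half-up(p·n), mates never separated) at a ladder of
  proportions with replicates, aggregated to a mean ± sd curve of any
  metric versus the proportion of reads used.
* **Library QC** — rRNA read fraction and the unique-start-site
  fraction (duplicate-marking-style library complexity). Read mapping
  itself is out of scope; these consume counts/keys from any mapper.
* **Gene census** — PPR protein classification from profile-HMM motif
  digests (>1 motif ⇒ PPR; DYW > E/E+ > P class priority),
  reciprocal-best-hit orthologs, pairwise identity of aligned pairs,
  and coding-sequence intactness (start/stop termini, internal stops).
* **Synthetic fixtures** — generators for reference proteins/CDS,
  fragmented assemblies with exactly known coverage, error-free read
  pairs and motif tables, so the whole stack runs and is testable with
  no external data and no aligner.

## Worked example

Simulate a fragmented assembly with known truth and evaluate it:

```sh
asmqc simulate assembly --n-genes 10 --seed 3 --out-dir sim
asmqc evaluate --hits sim/hits.tsv --ref-lens sim/ref_lens.tsv \
    --extra-cols "qframe qlen slen" --threshold 0.8 --out-dir eval
cat eval/eval.tsv
```

```
#threshold_pct	contiguity_pct	completeness_pct	pct_hits
80	50.00	90.00	100.00
```

Read: every one of the 10 reference proteins was hit by at least one
contig (% hits 100); 9 of 10 are covered to ≥ 80% of their length by
the union of their contigs (completeness 90%); for 5 of 10 a single
contig alone reaches 80% (contiguity 50%). The gap between the two
numbers measures fragmentation. `eval/coverage.tsv` holds the
per-reference records, and `eval/manifest.json` the exact
configuration and input checksums of the run.

The anchored translation on a 19-nt contig, anchor [8,14) in frame +3:

```python
>>> from asmqc import Contig, AlignmentHit, anchor_translate_extend
>>> hit = AlignmentHit(qid="c", sid="r", pident=1.0, aln_len=2, q_iv=(8, 14),
...                    s_iv=(0, 2), evalue=0.0, bitscore=10.0, qframe=3)
>>> t = anchor_translate_extend(Contig("c", "GGTAAATGGCTGCTTGAGG"), hit)
>>> t.peptide, (t.q_start_nt, t.q_end_nt)
('MAA', (5, 14))
```

The anchor codons (GCT, GCT → "AA") are extended upstream past ATG
("M") to the stop TAA and downstream to the stop TGA, giving the
stop-free window "MAA".

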