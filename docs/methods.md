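# Methods

This note records the model behind each component, the parameters that
matter, and the design choices made where more than one reasonable
convention exists. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and units

All intervals inside the package are 0-based, half-open, on the forward
strand; the only conversion happens once, at parse time, when 1-based
inclusive tabular-hit coordinates are read (reversed pairs are
normalised with the orientation recorded, and the sign of `qframe`,
when present, is authoritative). Percent identity is a fraction in
[0, 1] internally; every user-facing table multiplies by 100. This
single-convention rule is what lets the interval-merging code, the
translation code and the fixture generators share arithmetic without
off-by-one drift.

## Deduplication and redundancy

100%-identity clustering is implemented as exact, full-length,
case-insensitive substring containment: a contig is redundant iff its
sequence occurs inside a longer contig (or equals an earlier-retained
contig of the same length). This reproduces the observable behaviour
of CD-HIT-style clustering at threshold 1.0 without its word-size
heuristics, which are an implementation detail, not part of the
contract. Redundancy is (n_before − n_after) / n_before. Ties among
equal-length duplicates keep the first in input order, for determinism;
the retained *set of sequences* is permutation-invariant. A
duplicates-only mode (`--dedup exact`) is available for comparison.

N50 uses the weighted-median definition — the largest length L such
that contigs of length ≥ L sum to at least half the total — which is
the universal assembly-stats convention. Summary statistics are
computed after a minimum-length filter: 200 nt for nucleotide contigs
and 50 aa for peptides by default, the conventional cutoffs for this
kind of evaluation; both are exposed as parameters rather than
hard-coded, since published pipelines have used other values (e.g. a
150 nt post-filter).

## Coverage metrics

Per reference: each contig's HSP subject intervals are merged first, so
a contig's coverage of a reference is the length of the union of its
own aligned blocks; the union fraction merges across all contigs.
"Best single contig" is the contig achieving maximal coverage of that
reference — not the longest contig by sequence length, which the
phrase could also be read to mean — with ties broken by declared contig
length, then lexicographically by id, so results are deterministic.
Coverage can therefore never exceed 1 and best-single ≤ union always
holds.

The three sweep metrics use the full reference-panel size as the
denominator, which makes % hits an upper bound for completeness and
keeps the three curves on one scale; `--among-hits` renormalises by
the number of references with hits for comparison with tools that
report that way. Threshold comparison is closed (≥), and the default
sweep is 0 plus 0.05 steps to 1.0. HSP merging is the default;
`--best-hsp-only` keeps only the top-bitscore HSP per (contig,
reference) pair for sensitivity analysis, since either convention is
defensible for fragmented alignments.

## Anchored translation

The aligned region of a contig ("anchor") is translated in the hit's
reading frame and extended codon-by-codon both ways until a stop codon
or the end of the contig; stops are excluded from the peptide.
Choices:

* The anchor interval is snapped **outward** to the frame's codon grid
  before translation — alignment columns need not respect codon
  boundaries, and outward snapping never loses anchored residues.
  Under `--strict` a non-congruent anchor is an error instead.
* No start codon is required: extension is stop-to-stop, so peptides
  may begin mid-ORF. This is deliberate — de novo contigs routinely
  truncate the 5' end of a transcript.
* A codon containing N translates to 'X' and does **not** terminate
  extension: ambiguity is not evidence of a stop.
* A stop codon *inside* the anchor is an error under `--strict`;
  otherwise the peptide is truncated at the first in-anchor stop (the
  event is logged) and only upstream extension is attempted.
* One peptide per contig, using the best hit by bitscore (ties: lowest
  e-value, then input order); contigs with HSPs in different frames use
  only that hit's frame. Frameshift-aware translation is out of scope.
* The reported nucleotide interval is always on the forward strand,
  regardless of frame sign, and equals 3 × peptide length.

The resulting invariant — every output peptide is a stop-free substring
of the full-frame translation, flanked by '*' wherever flanks exist —
is property-tested on randomized fixtures.

## Read operations

`filter_reads` drops a pair when either mate is shorter than `min_len`
(default 50 nt) or when either mate's longest A **or T** homopolymer
run exceeds 6% of its length (T catches reverse-complemented poly-A
tails). The poly-A rule is interpreted as a *longest-run* fraction,
not total base content: total A content above 6% would discard
essentially every read, so the run reading is the biologically
plausible one. A `polya_mode="total"` variant implements the literal
total-content reading for comparison.

Subsampling draws k = round-half-up(p·n) pairs (clamped to [1, n])
uniformly without replacement with `random.Random(seed)`, preserving
input order and never separating mates. Replicate seeds derive
deterministically from (base seed, proportion index, replicate index),
all below 2³¹, so a whole saturation experiment reproduces from one
seed. Saturation aggregation reports the arithmetic mean and sample
standard deviation (sd = 0 for n = 1) per proportion; proportion 1.0
is run once, the others with the configured replicate count (default
3).

The two QC fractions are pure arithmetic on mapper output: rRNA reads
/ total reads, and distinct mapped fragment keys / all keys, where a
fragment key is (reference, mate-1 start, mate-1 strand, mate-2 start)
— the identity a paired-end duplicate-marking tool uses. Running the
mapper is explicitly out of scope.

## Gene census

A transcript with more than one PPR motif (of any class) is a PPR
gene. Class priority is DYW > E/E+ > P: any DYW motif ⇒ PLS-DYW, else
any E/E+ ⇒ PLS-E, else P. This mirrors standard PPR nomenclature, in
which the C-terminal E and DYW domains define the editing-associated
PLS subclasses; a PPR gene with only P/L/S motifs falls to the P row
(there is no separate PLS-without-E row in the census output).
Classification is per transcript, not per reading frame.

Reciprocal best hits take the best hit per query (max bitscore, ties by
min e-value then lexicographically smallest subject — bitscore first
because e-values saturate at 0.0) in each direction and emit (a, b)
iff the relation holds both ways.

Pairwise identity is matching columns / alignment columns, counting
gapped columns in the denominator; `--ungapped-denominator` offers
matches / gap-free columns since both conventions appear in the
literature. Intactness of a coding sequence requires a leading ATG, a
trailing stop, and no internal stop in the frame +1 translation.

## Synthetic fixtures

The generators emulate the *structure* of a real evaluation — reference
proteins, fragmented contigs, error-free paired reads — with exactly
known truth, and deliberately not its noise:

* `make_reference` draws stop-free peptides of 80–400 aa (uniform
  residues and lengths; typical of conserved single-copy ortholog
  panels), back-translates with uniformly chosen synonymous codons,
  plants an in-frame stop immediately 5' and 3' of the ORF, and pads
  with 10–60 nt random UTRs.
* `fragment_assembly` cuts each CDS into substrings (default 2 per
  gene, 30–80% of the CDS length, reverse-complemented with
  probability 0.5) and emits the hit table those placements imply —
  no aligner runs. Nucleotide in-ORF offsets convert to protein
  subject coordinates by floor division at the start and ceiling at
  the end, mirroring how a translated search reports partial codons.
  The stored coverage truth is computed by per-position bitmask, a
  deliberately different algorithm from the interval merging used by
  the evaluator, so their exact agreement is a meaningful check.
* `simulate_read_pairs` emits error-free 101 nt mates (the library
  read length this kind of experiment uses) with normal(200, 20)
  insert sizes clamped to the template, random fragment strand, and
  uniform or user-weighted gene abundances, plus the exact placements.

What the fixtures do **not** model: sequencing errors, quality-score
structure, chimeras, alternative isoforms, or assembler behaviour.
Passing tests therefore demonstrate that the *metrics and procedures*
are computed correctly, not that any particular assembler performs
well on real data.

## The saturation proxy

The full-scale experiment this package supports — re-assembling each
read subsample and evaluating the assembly — needs an external
assembler and is out of scope at desk scale. The `saturation`
workflow instead scores a subsample by the union of its reads' exactly
known placements over each gene's coding region: completeness at a
coverage threshold, computed directly from read placements. This
preserves the experimental shape (completeness vs proportion of reads,
replicated, mean ± sd) and the saturation behaviour, and is documented
as a proxy, not a claim of assembler equivalence.

The acceptance-scale run uses 200 genes and 200,000 pairs with a
lognormal(0, 1.5) abundance profile — the dynamic range that makes
saturation informative, since under uniform abundances every gene
saturates almost immediately — with proportions
{5, 10, 20, 40, 70, 100}% and 3 replicates (100%: one run). These
sizes keep the whole experiment to a few seconds while leaving the
plateau (gain beyond 40% of reads small compared to the gain up to
40%) clearly resolvable above replicate noise.

## Numerical and degenerate-input choices

* Parsers are strict: wrong column counts, unknown motif classes,
  duplicate ids and malformed records fail fast with a line number.
  Dropping rows silently would silently change every downstream
  metric.
* `dedup_contigs([])` returns an empty set with redundancy 0;
  a summary of an empty post-filter assembly is an error, not a row of
  zeros.
* Interval merging treats touching intervals as one; zero- or
  negative-length intervals are errors.
* Histogram bins are half-open with the last bin closed (numpy
  convention).
* All generators and subsamplers are deterministic functions of
  (parameters, seed); identical inputs yield byte-identical outputs.

## Known limitations

* Substring-containment deduplication is quadratic in the number of
  contigs and is intended for evaluation-scale sets (10⁴–10⁵ contigs),
  not read-scale data.
* Identity below 100% (approximate clustering) is out of scope.
* The evaluator trusts the hit table's e-value filtering; a
  `--max-evalue` convenience filter exists but defaults to off.
* SAM/BAM, gzip transparency and multi-line FASTQ are not supported;
  inputs are plain text.
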