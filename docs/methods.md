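# Methods

## Scope and data model

All analyses operate on `CircularGenome`: one circular DNA molecule
linearized at its record origin, coordinates 0-based and half-open, all
interval arithmetic modulo the length.  Intervals may have `end > length`
to denote wrapping across the origin.  N bases are accepted on input,
excluded from the GC denominator, and treated as mismatches in all
comparisons.  Printed percentages round half-up to two decimals.

## Repeat detection

All three detectors share one engine: k-mer seeding (default k = 31) on
the doubled sequence `S+S`, with matches whose start lies in the second
copy discarded — the standard device that makes detection circle-aware.
Seeds extend to maximal exact runs along their diagonal; a k-mer occurring
more than 500 times is dropped from seeding (extreme low-complexity
sequence belongs to the tandem detector).

* **Large repeats** (`find_large_repeats`, default ≥ 2 kb at ≥ 0.99
  identity).  Exact runs on one diagonal merge across mismatch gaps
  (≤ 200 bp) under an ungapped model; because stretches between nearby
  substitutions can be shorter than k and never seed, merged candidates
  are re-scored by exact positional comparison before the identity
  threshold is applied.  When identity 1.0 is requested, the maximal exact
  runs themselves are the result (no merging).  Inverted pairs come from
  matching the doubled forward strand against its reverse complement; each
  pair is canonicalized with the `+` occurrence at the smaller start.
  Contained duplicates of a maximal pair are suppressed, and palindromic
  self-matches are excluded.  Limitation: copies that have diverged by
  internal *indels* (not just substitutions) are reported as separate
  co-diagonal pairs rather than one gapped pair.
* **Short repeats** (30–500 bp) use exact matching only.  A family is one
  repeated sequence (canonical strand chosen as the lexicographically
  smaller of sequence and reverse complement) with all its occurrences.
  Homopolymer consensus sequences and overlapping (tandem-style)
  occurrence pairs are excluded — the tandem detector owns those — which
  prevents double counting.
* **Tandem arrays**: for each period p (2 … 100 by default) a vectorized
  scan of `S[i] == S[i+p]` on the doubled sequence yields maximal runs; an
  array is kept when its (possibly fractional) copy number reaches 2, its
  unit is primitive (no smaller divisor period), and its leftmost start
  lies in the first copy.  Spans clip at the genome length.
* **KS uniformity**: one-sample Kolmogorov–Smirnov test (scipy) of
  positions scaled by genome length against Uniform(0,1).  Positions are
  linearized at the record origin; a conservative circular variant
  (maximum D over rotations anchored at observed positions) is available
  behind `rotation_max=True` but is not the default, since the standard
  test is what the field reports.

## Synteny blocks, SNPs and indels

Block finding chains co-diagonal k-mer anchors (diagonal drift ≤ 200 bp,
gap ≤ 1 kb, both strands), scores chains by matched length, and resolves
overlaps greedily to the highest-scoring tiling.  Trims applied on one
genome are mirrored on the other so the paired segments stay in
correspondence.  Boundaries are then polished: flanking chunks (≤ 64 bp)
absorb into the block while they still align (short chunks tolerate a
couple of mismatches, so a substitution at a block edge is not stranded
outside it); extension never crosses another block's claim.  Finally,
blocks contiguous on both circles — split artifacts of either genome's
origin — merge into wrapped blocks, and blocks shorter than `min_block`
(400 bp by default; 2 kb is the conventional display threshold for
rearrangement figures) or below 0.87 identity are dropped.  Blocks are
numbered along genome A.

SNPs are substitution columns of the per-block edit-distance alignment
(edlib), counted per position in mismatch runs; gap columns never count.
Two tie-breaks favour the substitution interpretation of ambiguous
alignments: equal-length segments whose Hamming distance equals their edit
distance are scored by Hamming comparison, and an adjacent
insertion/deletion pair of equal span in the CIGAR is normalized back to
substitution columns.

An indel is any segment of one genome not covered by a syntenic block and
longer than `min_indel` (400 bp), recorded with its flanking blocks and
the counterpart gap between those blocks on the other genome.  A
replacement region therefore yields one record on each side, which keeps
the bookkeeping identity exact on each genome:
blocks + indels + residue = genome length.  Insertion matching against a
panel marks a record `matched` when any non-carrier genome aligns it at
≥ 70 % identity over ≥ 80 % of its length (screened by best-infix edit
distance against the doubled target).  Records from different pairwise
comparisons merge per carrier locus before counting physical insertions.

The rearrangement lower bound reduces blocks to a signed circular
permutation (A order = identity, read off in B order with orientation
signs) and returns ⌈breakpoints/2⌉.  This is a bound, not a distance: a
single inversion creates two breakpoints, so the estimate can never
exceed, but may undercount, the true event number.

## ORFs

ORF definition: per strand and frame on the doubled sequence, each
stop-to-stop segment contributes the ORF from its first ATG to its stop;
nested ATGs are not reported.  `n_codons` counts the start codon and
excludes the stop; the default threshold is 100 codons.  A segment that
wraps the origin is scanned without its upstream context at the
linearization start, which can emit a spurious suffix ORF sharing the true
ORF's stop; only the longest ORF per (stop position, strand) is kept,
making the output rotation-equivariant.

Grouping is single-linkage at ≥ 70 % nucleotide identity over ≥ 80 % of
the *shorter* member (the stricter, symmetric reading of the coverage
rule), computed by local alignment (match 1, mismatch −1, gap open −4,
extend −1) with a fast edit-distance screen.  Group ids are deterministic.

A group is SHARED when every genome carries the ORF in *complete* form:
length within 10 % of the representative and edit distance within 10 % of
the shorter — a truncated or chimeric remnant that still met the 70/80
grouping threshold counts as partial, not complete.  Otherwise the cause
cascade runs per affected genome with GR ≻ ID ≻ M precedence: GR when a
synteny-block boundary falls strictly inside the representative locus (a
DNA break within the ORF), ID when an indel record covers or disrupts the
locus, M otherwise.  A rearrangement that breaks an ORF typically
produces two GR calls — the lost parental ORF and the novel chimeric ORF
generated at the junction — both genuinely caused by the break.

Mutation-site typology compares each member to the representative under
global affine-gap alignment: one substitution column or one contiguous gap
run is one site.  Substitutions that create an in-frame stop on either
side before the annotated stop are `premature_stop`; other substitutions
are `frame_preserving`.  Gap runs are `triplet_indel` when their length is
a multiple of 3 and below 52 nt, `non_triplet_indel` when not a multiple
of 3; in-frame indels of ≥ 52 nt fall outside this four-class typology
and are reported as `large_indel`.  Site positions are given on the
representative, so indel positions shift if a different member is chosen
as representative (substitution counts do not).

## Dissimilarity and UPGMA

d = (2·N_SNP + L_Indel1 + L_Indel2)/(L_G1 + L_G2), with N_SNP from the
block pipeline and the L_Indel totals restricted to the > 400 bp records,
matching the block threshold.  Genome pairs with no detectable homology
take L_Indel = genome length on both sides.  UPGMA is the classic
average-linkage agglomeration, merging at height d/2 (leaf-to-leaf path
length equals d); among equal minimal distances the pair whose sorted
leaf-label sets are lexicographically smallest merges first.  The
implementation is cross-checked against scipy's average linkage in the
test suite but is not delegated to it.

## Subgenomic circles

A direct repeat pair partitions the master circle into two arcs; reversible
homologous recombination across the pair yields two subcircles, each
containing one repeat copy and one arc, so s₁ + s₂ equals the master
length exactly.  An inverted pair only inverts the intervening arc
(flip-flop isomers) and predicts no subcircles.  For near-identical copies
the crossover is taken at the occurrence midpoints; subcircle sizes are
insensitive to the crossover position inside the repeat.  A genome with
several direct pairs admits many coexisting forms; the per-pair
predictions are listed and the result is flagged combinatorially complex
with no joint prediction, mirroring how such genomes are treated in
practice.

## Simulator

`generate_ancestor` draws a uniform random background, implants identical
repeat copies and, optionally, real ORFs (ATG + sense codons + stop) at
non-overlapping positions, and labels gene-like features.  Events —
duplication, inversion, translocation, insertion, deletion, substitution
batches — apply in order; unset coordinates are drawn at application time
and the realized log replays byte-for-byte on the parent.  Duplication
insertion points are drawn outside the source segment, so the two copies
are recoverable as a repeat pair of exactly the duplicated length (up to
chance flanking matches).  Substitution positions are drawn uniformly
without replacement; the transition/transversion ratio is configurable
(default 1, since no substitution model is imposed).  Features hit by a
breakpoint are renamed with a `~trunc` suffix.  Clade simulation walks a
nested-tuple topology, drawing a fresh child seed per branch from the call
seed.

What the generator does *not* emulate: real base composition and
compositional skew, recombination hotspots, heteroplasmy or substoichiometric
forms, nuclear/horizontal insertions, and gene-dense annotation.  Passing
tests therefore demonstrate algorithmic correctness on genomes whose
divergence structure is known, not performance on real annotation-rich
sequence; the deposited-accession regression (network required) covers the
latter.

## Problem sizes and numerical choices

The analysis scripts use a 60 kb ancestral circle with six descendants;
the test-suite and acceptance-script simulations use 10–30 kb circles with
20 replicate seeds per recovery measurement, 1 000 replicates for the KS
type-I error, and 6-leaf matrices for UPGMA recovery — sizes at which the
quadratic brute-force oracles remain exact cross-checks while the full
pipeline behaves as it does at full scale (all algorithms are linear or
near-linear in genome length).  Default thresholds: blocks > 400 bp at
≥ 0.87 identity, indels > 400 bp, large repeats ≥ 2 kb at ≥ 0.99 identity,
short repeats 30–500 bp exact, ORFs ≥ 100 codons, grouping 70 %/80 %,
breakpoint association window 200 bp.  Matrix symmetry is enforced to
1e-9; UPGMA heights are exact rational arithmetic over floats with no
rounding beyond the output format.

## Known limitations

* Ungapped large-repeat model (indel-diverged copies split into
  co-diagonal pairs).
* The breakpoint bound is a lower bound, undercounting when events reuse
  breakpoints or cancel.
* Insertion matching uses edit-distance screens rather than full local
  alignment; borderline 70 %/80 % cases near the threshold may differ
  from an exhaustive aligner.
* The KS test ignores circularity by default (documented flag for a
  conservative variant).
* Trans-spliced gene accounting in gene-content tallies uses feature
  intervals as given.
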