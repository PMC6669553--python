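# Methods

`baculoscan` packages the standard desk analysis of a circular baculovirus
genome as a set of small, separately testable operations.  This note
records the models and conventions each operation implements, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical corner cases.

## Coordinate model

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates exist only at format boundaries (GenBank in, GFF3 out).  A
feature on a circular genome of length L may span the origin; it is stored
*unwrapped* with `end > L` (bounded by `2L`), so `end − start` is always
the true length and overlap arithmetic never needs a special case beyond
splitting a span into at most two in-bounds segments.  Unwrapped features
are emitted to GFF3 as two lines sharing one `ID`, and GenBank
`join(a..L,1..b)` locations are read back into the unwrapped form.
Sequences are restricted to `{A,C,G,T,N}` after case folding; anything
else is a hard error, on the view that silently coercing corrupt input is
worse than failing.  G+C content excludes `N` sites from the denominator
(the convention is not universal; it is this package's choice and is
reported to one decimal).

## ORF annotation

A candidate ORF is a maximal ATG→stop span in one of six frames with at
least `min_aa` codons (default 50, the conventional annotation floor for
these genomes; the stop codon is inside the span but outside the codon
count).  Within a stop-to-stop frame segment only the 5′-most ATG defines
a candidate — nested ATGs are internal methionines, not separate genes —
which matches standard ORF-caller behavior and keeps counts stable.
Circular genomes are scanned on a doubled sequence; because the scan start
is not a real segment boundary there, ATGs seen before the first stop
codon of a frame are ignored and such segments are picked up with their
true upstream stop in the second copy.  Candidates are deduplicated by
(start mod L, strand); ORFs with an `N` in the coding span are dropped
rather than translated through ambiguity.

Retention implements the liberal overlap criterion: candidates are sorted
longest-first (ties: smaller start, then `+` strand) and a candidate is
discarded iff its overlap with some already-retained ORF reaches 50% *of
its own length*, computed on genome coordinates irrespective of strand.
Reading the threshold against the candidate's own length is what makes
the criterion liberal — a short gene nested against the flank of a long
one survives — and the longest-first greedy order makes the rule
deterministic.  The filter is idempotent and its output pairwise satisfies
the bound by construction.

Homology labeling is pairwise: each retained protein is aligned
(Smith–Waterman, BLOSUM62, gap open 11 / extend 1) against a user-supplied
reference proteome; the best reference wins if its raw score reaches the
threshold (default 100), otherwise the ORF is called `unique`.  The
default was set from the score separation observed between unrelated
random proteins (which plateau near 50–60 for proteins of a few hundred
residues) and genuine homologs at ≤ 30% divergence (hundreds); it is a
parameter, not a constant.  A configurable name list marks core genes —
the 38 genes conserved across all sequenced baculovirus genomes — so a
genome report can state its core-gene census.

## Repeat discovery

Baculovirus genomes carry two repeat classes: tandem direct repeats (dr),
often inside coding sequences, and homologous regions (hrs) — clusters of
an imperfect ~11–13 nt core motif recurring at several loci.

**Tandem repeats** are found by k-mer seeding: exact k-mer recurrences at
spacing `d` within `[min_unit, max_unit]` nominate `(position, period)`
candidates; each candidate is extended unit-by-unit left and right while
Hamming identity to the anchor unit stays at or above `min_identity`
(default 85%), plus a fractional tail where a partial unit matches the
consensus prefix.  The consensus is per-column majority over full copies
and the reported internal identity is the mean copy-vs-consensus identity.
Overlapping reports are resolved by a matches-minus-mismatches score
(match +1, mismatch −1): this penalizes phase-shifted arrays that absorb
flanking background, and among near-equal harmonics the smallest period
wins, giving the canonical representation (a 10-nt unit repeated 12 times
is reported at period 10, not 20).  The published tandem-repeat tool's
full scoring model is deliberately not reproduced; the recovery target is
the repeat geometry (unit length, copy number, identity), which seeded
simulations show is recovered in ≥ 95% of cases for units of 10–100 nt,
3–10 copies and ≤ 5% divergence.

**hr regions** are found by projecting core-motif hits (both strands,
default ≤ 1 mismatch, overlapping occurrences, origin wrap included) onto
genome positions and single-linkage clustering with gap ≤ `window`
(default 2 kb): a gap exactly equal to the window still joins.  Clusters
with at least `min_hits` hits become regions spanning first to last hit.
Naming is positional from the origin, with regions closer than a grouping
distance (default 10 kb) sharing a number and taking letter suffixes
(`hr1a`, `hr1b`, `hr2` …), which reproduces the field's naming style
without claiming to reproduce any particular paper's unstated rule.
Motif-counting conventions (strands, mismatches, overlap, wrap) are all
exposed as flags because published counts rarely state theirs; the
defaults count both strands, exact, overlapping, wrapped.

**Pairwise identity** between repeat copies is global
(Needleman–Wunsch: match +1, mismatch −1, gap open −2, extend −1) with
identity = 100 × matches / alignment columns, so indels dilute identity
through gap columns rather than being ignored.

## Variant analysis

Input SNVs (VCF with `INFO/AF`, or a delimited table) are checked against
the reference base, mapped to the covering retained ORF with wrap-aware
arithmetic, and classified by rebuilding the codon from the genome,
substituting the alternative base at the in-codon offset (alleles are
complemented first for minus-strand ORFs), and translating both codons
with the standard code.  Synonymous means identical residues; stop gain
and loss fold into non-synonymous, since the two-way coding split is what
genome reports use.  A variant inside a stop codon is coding.  Under the
liberal overlap criterion a position can sit in two retained ORFs; every
covering ORF is classified and the primary effect is taken from the
longest, with the rest kept as secondary records.  Indel rows are rejected
with a counted warning — the populations these tables describe are
reported SNV-only, and indel effect annotation is out of scope.

The summary reports counts (total / coding / synonymous / non-synonymous /
intergenic) and the mean ± sample (n−1) standard deviation of variant
frequency in percent, both over coding variants (the headline convention)
and over all variants, because published "mean ± sd" figures do not always
say which denominator they used.

## Species demarcation

The K2P distance is computed from transition (P) and transversion (Q)
proportions under pairwise deletion: sites where either sequence carries a
gap or ambiguity are excluded per pair, which uses the most data and is
recorded in the output (complete deletion is the main alternative; the
choice matters only for ragged alignments).  When `1−2P−Q ≤ 0` or
`1−2Q ≤ 0` the estimator is saturated: the distance is reported undefined
with an infinite sentinel, and the demarcation call is "different species"
with a saturation caveat rather than an error — saturation is itself
evidence of deep divergence.  The decision thresholds are
`t_high = 0.050` substitutions/site (above: distinct species) and
`t_low = 0.015` (below: same species), with the band between — and the
exact boundary values — indeterminate.  Both thresholds are configurable.

Neighbor joining is the canonical agglomeration on the Q-criterion with
two determinism conventions: ties break by the lexicographically smallest
pair of minimum leaf labels, and negative branch lengths are clamped to
zero with the deficit moved to the sister branch (so path lengths within
the joined pair are preserved).  On additive matrices the algorithm
recovers the generating tree exactly (verified against an independent
graph-based path-length oracle and dendropy's tree distances); `n = 2`
returns a single symmetrically split edge.  NJ here is a distance-based
companion for marker-gene matrices, not a replacement for likelihood
phylogenetics, which is out of scope.

## Ortholog comparison

Orthology is strict reciprocal best hit: `(x, y)` is a pair iff each is
the other's *unique* best local-alignment hit passing score ≥ 100 and
coverage ≥ 50% of the shorter protein; ties for best yield no pair.  RBH
pairs across all genome pairs are merged by single linkage; a group that
would contain two genes from one genome is split by discarding the
lowest-scoring edge in the conflicted component and re-linking, repeated
until conflict-free.  Unpaired genes become singleton groups, so the Venn
partition over exact genome subsets always conserves the total family
count.  Locus context returns the genes strictly between two unique
anchor genes, taking the shorter arc on circular genomes and orienting the
list so the first anchor comes first; it is rotation-invariant.

## Synthetic data: what it emulates and what it does not

The generator produces inputs with the statistical structure the pipeline
assumes, with exact recorded truth.  The default design mirrors a
~122 kb group I alphabaculovirus genome: length 122,075 bp, G+C 0.509,
153 ORFs (lengths 50–1100 codons drawn from a shifted exponential, one
origin-spanning), five hr loci of 8 copies of a 12-nt core motif at 5%
per-base divergence within 1-kb windows, a 10-nt-unit × 12 direct repeat
and a 68-nt-unit × 4 direct repeat carrying one substitution.  The default
variant set mirrors a deep-sequenced field population: 203 SNVs, 180
coding of which 92 synonymous, frequencies from a normal(0.38, 0.046)
clipped to (0.01, 0.99) (a moment-matched beta is available, since only a
mean ± sd is ever published).  Divergence simulation uses the exact K2P
per-site transition functions at branch length `d` and rate ratio `κ`, so
estimator-recovery tests have a true value to recover.

Construction details that matter for interpreting tests: each planted ORF
is built from non-stop, non-ATG codons and carries an in-frame stop
immediately upstream of its ATG, so the planted ATG is provably the
5′-most of its segment and recovery can be asserted exactly.  Chance
background ORFs above the length floor are disrupted after assembly by
writing an early stop codon wherever that touches no planted feature;
the remainder — chance ORFs overlapping planted genes, which cannot be
disrupted without damaging them — are enumerated in the truth set, and
variant planting avoids their spans so every truth effect is unambiguous
under any annotation of the genome.  Determinism is exact: one integer
seed drives one `numpy` Generator per call, with no time, locale or hash
dependence.

What the generator does **not** emulate: sequencing error and read-level
artifacts (variants arrive as a clean table, as they do to the pipeline),
codon-usage and strand biases, overlapping planted genes, transcription
signals, indel evolution, and genuinely homologous hr copies (each hr is
an independent motif cluster, not a duplicated region, so inter-hr
identity statistics of real genomes are not reproduced).  Passing
planted-truth tests therefore demonstrates that the operations implement
their stated conventions correctly — not that those conventions recover
every feature of a real, biased, repeat-rich genome.

## Problem sizes

The test suite and the acceptance script run at the sizes a laptop
handles in seconds: oracle equivalence for the ORF scanner on genomes up
to 5 kb (the brute-force oracle is quadratic), planted-truth recovery on a
40 kb / 40-ORF genome in unit tests and the full 122 kb / 153-ORF design
in the acceptance script, K2P estimator recovery over 100 replicates of
10 kb, NJ recovery for 4–8 taxa, and a five-proteome gene-content design
of ~18 families (each all-vs-all RBH stage is quadratic in proteome
size).  The same code paths run unchanged on full-size real inputs.

## Known limitations

- The tandem-repeat detector reports arrays seeded by exact k-mer matches;
  arrays more divergent than ~1 mismatch per seed length within every copy
  can be missed, and reported array boundaries can be off by up to one
  unit in phase.
- hr naming is positional; it will not match a published genome's hr names
  when those encode history rather than position.
- RBH orthology collapses multi-copy families (e.g. *bro* genes) to at
  most one member per genome per group; paralog-aware clustering is out of
  scope, so gene-content counts treat extra copies as split singletons.
- The K2P estimator's small upward bias at short alignments
  (O(1/sites)) is inherited from the closed form; tests compare means
  against truth within standard-error bands rather than expecting
  unbiasedness.
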