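# Methods

## Conservation model

The toolkit consumes case-coded conservation readouts (EvoPrints): one
reference sequence in which a base is uppercase when conserved across the
compared species set and lowercase otherwise. Published relaxed readouts
additionally color-code *which* species diverge; this implementation
collapses that nuance to the two-tier conserved/non-conserved partition,
because every downstream operation (block extraction, cluster cutting,
element matching) depends only on that partition. `N`/`n` bases are
counted toward conservation totals per their case but never participate
in element matching: any 6-bp window containing an `N` is skipped on both
sides of every comparison.

Coordinates are 0-based half-open internally; human-readable reports
(per-CSB alignments, cluster catalogs) print 1-based positions.

## Blocks, clusters and cutting

A **CSB** is a maximal uppercase run. Runs shorter than the minimum
element length (default 6 bp) stay in their cluster and count toward its
conserved-base total, but are ineligible for element discovery — this
reconciles block counts quoted "of 6 bp or more" with total conserved-base
accounting. A **CSC** groups consecutive CSBs whose intervening
non-conserved gaps (counted strictly between blocks) are below the ICR
cutoff; a gap equal to or exceeding the cutoff splits clusters. Clusters
are named `<region>-<i>` with consecutive 1-based indices.

The multi-cut catalog cuts at 150, 200 and 250 bp and unions the results.
A higher-cutoff cluster with a span identical to a lower-cutoff one adds
no information and is dropped; retained higher-cutoff merges are renamed
`<base>~<cutoff>` with `duplicate_of` pointing at the base name, keeping
catalog names unique while preserving the duplicate notation.

## RPS elements

Self-alignment reports every **maximal** element: a canonical-orientation
sequence (lexicographically smaller of itself and its reverse complement)
of ≥ 6 bp that either occurs at least twice across the cluster's eligible
CSBs — both orientations, distinct starts, a palindromic hit counted once
— or is a DNA palindrome (reported even at one copy, since "repeat *or*
palindromic" admits single palindromes; flagged as an open reading of the
original tool). An element is suppressed only when a single one-base
extension that itself qualifies as an element contains *every* occurrence;
this keeps shorter repeats whose occurrence sets genuinely differ from any
extension, reproducing the observed coexistence of a 10-mer repeat with
its more numerous internal heptamer at different copy numbers.

**Sub-repeat rule.** An element is flagged a sub-repeat when at least one
occurrence lies inside a longer element's occurrence *and* fewer than two
occurrences are independent of all longer elements. The first clause is
deliberate: a standalone element with no nesting at all is never a
sub-repeat, however few copies it has (a literal "fewer than two
independent occurrences" reading would absurdly flag every standalone
single-copy palindrome).

Ordering is deterministic everywhere: length descending, then canonical
sequence; occurrences by (CSB index, offset).

## Pairwise alignment and categories

Shared elements between two clusters are the maximal exact matches ≥ 6 bp
over both CSB sets and both orientations, with the same single-extension
suppression applied jointly to both sides — so a long match broken on one
side still surfaces the surviving shorter piece. Categories are defined
with respect to the **input** cluster only: full-length non-sub-repeat RPS
elements are `repeat`; sub-repeats and pieces of longer input repeats are
`subrepeat`; sequences present once in the input are `unique` (database-
side copy numbers never demote a unique element). Matching is exact — no
mismatches, no gaps — matching the original's alignment semantics.

Percent coverage normalizes the database cluster's matched conserved bases
by its *total* conserved bases, short ineligible runs included; a
self-comparison therefore reaches exactly 100 only when every CSB is
eligible.

## Scorecard

The correlation coefficient is the Pearson r of paired copy numbers over
all shared element types, unique types entering as (1, db copies) — the
criterion names "repeat and unique matches". Equal vectors score exactly
1.0 (computed symbolically, avoiding float round-off on self rows); a
zero-variance vector otherwise scores 0.0; no shared elements leaves the
score undefined (`None`, serialized as an empty value, always ranked
last). The RPS balance index is restricted to repeat/sub-repeat types —
its definition names RPS elements only — and the length-weighted ratio
M/U is `inf` when U = 0, serialized as the token `inf` and ranked above
every finite value.

"Longest shared" defaults to the longest shared element of any category;
a `repeats_only` switch restricts it to repeat/sub-repeat types, since the
original tables are ambiguous about which convention produced the printed
self-row value.

Name sorting is natural (file stem, then numeric suffix), grouping
neighboring clusters of one region.

## Repeat balance map

Per conserved base of the database cluster: the copy-number difference of
the covering shared repeat type selects the class (0 → balanced, 1, 2,
≥ 3), computed per element type and applied to all its occurrence bases.
Overlaps resolve deterministically: repeat classes beat `unique_shared`;
among repeats the longer element wins; at equal length the smaller
copy-number difference wins; remaining ties break by lexicographic
canonical sequence, making the map independent of processing order. Pie
fractions are over aligning (non-uncovered) bases and sum to 1; the
uncovered fraction is reported over all conserved bases. Text rendering
wraps class runs in `[class]…[/class]` tags (stripping tags recovers the
EvoPrint text exactly); HTML uses the legend palette green / yellow /
purple / red / gray.

## Synthetic generator

`cscdecoder.synth` emulates EvoPrint text with a prescribed CSB/gap
layout and planted elements at exact copy numbers per side. Correctness
rests on two facts: a repeated (or shared) sequence of ≥ 6 bp necessarily
repeats one of its 6-bp windows, and an even palindrome of ≥ 6 bp
contains a palindromic central 6-mer. Backgrounds are therefore built
constructively, drawing each base so that every new canonical 6-bp window
is globally unique (across both sides of a pair) and non-palindromic —
whole-text rejection sampling would essentially never terminate, since a
few hundred random bases almost surely repeat some 6-mer. Each planted
copy's two flanking bases are fixed up front so that its junction windows
are globally unique; a per-CSB retry cap of 1,000 guards the remaining
stochastic placement, and a brute-force enumeration re-checks the
finished pair against the planted tables before anything is returned.

Planted elements must have pairwise-disjoint canonical 6-mer sets, no
internally repeated 6-mer, and no palindromic 6-bp window unless the
element is that 6-bp palindrome. A pigeonhole constraint follows from the
junction windows: each copy consumes one of at most four suffix+base and
one of at most four base+prefix options, capping an element at four clean
copies across both sides (two for a 6-bp palindrome). The randomized spec
factory draws copy numbers within these caps.

Defaults: background GC 0.43 (fly-like euchromatin; cosmetic, since
cleanliness is structural), five element types of 6–12 bp per randomized
spec, five CSBs of 35–65 bp per side with 10–60 bp gaps — cluster sizes
in the low hundreds of conserved bases, the scale at which brute-force
verification stays fast. What the generator does *not* emulate: realistic
phylogenetic divergence, indels, ICR length evolution, or the genome-wide
background repeat statistics of a real cluster database — so passing
round-trip tests demonstrate algorithmic correctness, not performance on
real genomic backgrounds, where near-ubiquitous short repeats make
element inventories far denser.

## Database and search

Storage is a single-file SQLite database (clusters with payloads, RPS
records, element catalog) plus JSON export — desk-scale, serverless. The
catalog's counts use the same both-orientation, distinct-start occurrence
rule as self-alignment. The default (unconstrained) search requires the
database cluster to contain ≥ 1 occurrence of ≥ 1 of the *input's*
multi-copy elements; whether the original required multi-copy status on
both sides is unresolved, so the input-side reading is implemented and
noted. Sequence classes (noncoding / coding / utr3 / unknown) are
user-supplied metadata, defaulting to unknown.

## Numerical and edge-case conventions

* Empty EvoPrint or non-IUPAC characters: parse error naming the 1-based
  position; an EvoPrint with zero conserved bases cuts to an empty
  catalog (success with a warning, not an error).
* Zero conserved bases make coverage fractions undefined (error), as does
  a pairwise alignment with no eligible CSB on either side (the error
  names the offending side).
* Scores on identical inputs are bit-identical; ranking is a stable sort
  and invariant under candidate-order permutation.
* CLI exit codes: 0 success, 1 usage error, 2 data error. All table
  outputs carry a `# cscdecoder v… key=value` header recording the tool
  version and resolved parameters; configuration precedence is flag >
  config file > built-in default.

## Problem sizes used in the test and acceptance suites

Oracle-equivalence runs 200 random clusters of ≤ 300 conserved bases
against a naive enumeration oracle; round-trip recovery uses 100 seeded
planted pairs; monotonicity and balance-map property suites use dozens of
randomized inputs. These sizes keep brute-force verification exact and
the full suite fast while exercising every code path; the algorithms
themselves are polynomial (window enumeration is O(total · longest CSB))
and handle larger clusters without modification.

## Known limitations

* Genome-scale published figures (database-wide element frequencies,
  scorecards against >100,000-cluster catalogs) require the original
  genome assemblies' EvoPrints and are out of scope; the toolkit builds
  databases from user-supplied readouts.
* Degenerate-base matching, mismatch tolerance and motif models (PWMs)
  are deliberately absent: the method is exact-match by design.
* Single-copy palindromes are reported as elements; whether the original
  tool did so is implied but not demonstrated, and flagged for review.
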