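# cscdecoder

Comparison of candidate enhancers through their conserved sequence
clusters, starting from phylogenetic-footprint ("EvoPrint") readouts.

## The problem

Enhancers — the cis-regulatory DNA modules that switch genes on in
particular tissues at particular times — are hard to recognize from raw
sequence. Multi-species conservation helps: an EvoPrint renders one
reference genomic region with every base conserved across the compared
species in UPPERCASE and everything else in lowercase. Maximal uppercase
runs are **conserved sequence blocks** (CSBs); groups of CSBs delimited by
long stretches of less-conserved DNA (**inter-clustal regions**, ICRs) form
**conserved sequence clusters** (CSCs), the natural candidate-enhancer
unit. The question this toolkit addresses: given one CSC that is a known
enhancer, which other CSCs in a catalog are *structurally related* to it —
sharing its repeated sequence elements, at similar copy numbers — and
therefore candidates for related regulatory activity?

## The method

1. **Cutting.** An EvoPrint is parsed and cut into named CSCs at ICR
   cutoffs of 150, 200 and 250 bp (`region-1`, `region-2`, …; clusters
   that merge only at a higher cutoff are kept with a `~cutoff` notation).
2. **Self-alignment.** Each CSC's eligible CSBs (≥ 6 bp) are aligned
   against themselves in both orientations to find every **RPS element**:
   a maximal sequence of ≥ 6 bp occurring at least twice (counting
   reverse-complement hits) or forming a DNA palindrome. Shorter repeats
   nested almost entirely inside longer ones are flagged **sub-repeats**.
3. **Database search.** CSCs, CSBs and RPS records are stored in an
   embedded database with an element catalog (total occurrences; clusters
   carrying ≥ 2 copies). A search selects clusters sharing the input's
   multi-copy elements, or satisfying user-supplied mandatory elements
   with minimum copy numbers and sequence-class filters.
4. **Pairwise alignment and scoring.** Each candidate is aligned one-on-one
   against the input: the maximal exact matches ≥ 6 bp (both orientations)
   are inventoried as repeat / sub-repeat / input-unique elements, and
   eight similarity indices are reported per candidate:

   | index | definition |
   |---|---|
   | RPS balance index | M/U, where M (U) is the summed length of shared repeat types with equal (unequal) copy numbers; `inf` when fully balanced |
   | correlation coefficient | Pearson r of the paired copy-number vectors over all shared element types |
   | shared repeats | number of shared repeat + sub-repeat types |
   | total shared elements | all shared types, uniquely shared sequences included |
   | percent coverage | 100 × (db-cluster conserved bases inside ≥ 1 shared match) / (db-cluster conserved bases) |
   | required elements | user-mandated elements present at their required copies |
   | longest shared | length of the longest shared element |
   | conserved bases | total conserved bases of the db cluster |

5. **Repeat balance map.** Every conserved base of the compared cluster is
   color-classified by the copy-number difference of the repeat covering
   it (balanced / off-by-1 / off-by-2 / off-by-3-or-more / uniquely
   shared / uncovered), with longer repeats winning overlaps and repeat
   classes beating unique ones; summarized as pie-chart fractions.

A fully testable synthetic generator (`cscdecoder.synth`) builds EvoPrint
pairs whose backgrounds provably contain no unplanned repeat or shared
match of ≥ 6 bp, so every stage can be verified against exact planted
ground truth.

## Worked example

```python
from cscdecoder import build_database, score_candidates, align_pair, \
    color_classes, balance_pie
from cscdecoder.scorecard import rank
from cscdecoder.synth import random_plant_spec, make_related_pair, pair_to_cscs

a, b, gt = make_related_pair(random_plant_spec(7))   # planted pair, seed 7
A, B = pair_to_cscs(a, b)                            # synthA-1, synthB-1
db = build_database([A, B], "example.db")
for row in rank(score_candidates(db, A, db.search(A)),
                "correlation_coefficient"):
    print(row.as_dict())
print({k: round(v, 2) for k, v in
       balance_pie(color_classes(align_pair(A, B))).items()})
```

prints (abridged):

```
{'cluster_name': 'synthA-1', 'rps_balance_index': inf,
 'correlation_coefficient': 1.0, 'shared_repeats': 4,
 'total_shared_elements': 9, 'percent_coverage': 100.0, ...}
{'cluster_name': 'synthB-1', 'rps_balance_index': 0.0,
 'correlation_coefficient': -0.80, 'shared_repeats': 4,
 'total_shared_elements': 5, 'percent_coverage': 17.37, ...}
{'balanced': 0.0, 'off_by_1': 0.32, 'off_by_2': 0.39, 'off_by_3plus': 0.0,
 'unique_shared': 0.29, 'uncovered': 0.83}
```

The input cluster's own row shows the self-comparison identities — a
correlation of 1.0, 100 % coverage and an infinite (fully balanced)
repeat balance index — while the unrelated-copy-number cluster `synthB-1`
scores low on every index, and its balance map shows mostly unbalanced or
uncovered bases.

The same pipeline is available from the shell:

```sh
cscdecoder cut --input region.txt --cutoff all --out-prefix region
cscdecoder build-db --cscs cscdir/ --out csc.db
cscdecoder score --db csc.db --input region.region-1.json \
    --require ATGCAAA:3 --sort correlation_coefficient --out scorecard.tsv
cscdecoder balance-map --input A.json --db-csc B.json --format html \
    --out map.html --pie pie.json
```

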