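# herbmine

Prescription pattern mining for ethnopharmacological surveys of traditional
Chinese medicine (TCM) pharmacies.

Field surveys of TCM pharmacies collect prescriptions — each one a set of
medicinal materials with daily doses — and ask which materials and which
*combinations* of materials carry the tradition. `herbmine` implements the
quantitative side of such a survey end to end:

- **Citation frequencies.** For each material, FC is the number of
  prescriptions containing it and RFC = FC / N (N = total prescriptions),
  the standard ethnobotanical relative frequency of citation. Materials
  with RFC ≥ 0.1 form the *frequently used* subset.
- **Catalog profiling.** Breakdowns of the frequently used materials by TCM
  property (cold / cool / neutral / warm / hot), flavor (sweet / pungent /
  bitter / sour / bland, multi-valued), flavor–property pairs, and
  traditional-effect category; plus family and plant-part composition of the
  full catalog, and per-material dose summaries (mean, sample SD, quartiles).
- **Combination mining.** Frequent itemsets by levelwise (Apriori-style)
  search with downward-closure pruning: support(S) is the count (or
  fraction) of prescriptions containing all of S. Association rules A → B
  with confidence = support(A ∪ B) / support(A). Defaults follow survey
  practice: support ≥ 0.50, confidence > 0.95, combinations of 2–5
  materials.
- **Core network.** The materials appearing in frequent multi-material
  combinations form the *core*; the co-prescription graph weights each node
  by FC and each edge by its pair count (exportable as GraphML, edge list,
  or DOT).
- **Synthetic prescriptions.** Because survey raw data is often unreleased,
  two generators make the pipeline testable against printed summaries: an
  *archetype sampler* (classical formula cores drawn by weight, independent
  add-on materials, clipped-normal doses) and an *exact constraint solver*
  that builds a transaction set matching a list of exact itemset support
  counts, via integer feasibility over the composition cells of the
  constrained items.

The packaged fixtures transcribe a dysmenorrhea prescription survey of
Taiwanese TCM pharmacies: a 22-material frequent-material catalog, the ten
printed core-combination support counts at N = 99, and an archetype model
built around the Si Wu (four-substance) decoction core (Dang Gui / Chuan
Qiong / Di Huang / Bai Shao).

## Worked example

```python
from herbmine import (fixture_core7, solve_exact_transactions,
                      mine_frequent_itemsets, generate_rules, extract_core)

ts = solve_exact_transactions(fixture_core7(), seed=0)   # 99 prescriptions
frequent = mine_frequent_itemsets(ts)                    # support >= 0.50
rules = generate_rules(ts, frequent)                     # confidence > 0.95
```

prints, when the pieces are inspected:

```
N = 99 prescriptions over 7 core materials
37 frequent combinations at support 0.50:
  AS+LiC       count=92  support=0.929
  AS+LyC       count=82  support=0.828
  LiC+LyC      count=76  support=0.768
47 rules at confidence > 0.95, e.g.:
  LiC -> AS  confidence=1.000
core materials: ['AS', 'HP', 'LiC', 'LyC', 'PL', 'RG']
```

The solver has honored every packaged constraint — the Dang Gui / Chuan
Qiong pair (AS+LiC) appears in exactly 92 of the 99 prescriptions — and
mining the solved data recovers those counts; the rule LiC → AS is certain
(confidence 1.0) because every prescription containing Chuan Qiong also
contains Dang Gui in this dataset.

The same pipeline runs from the shell:

```sh
herbmine solve --constraints fixture:core7 --seed 0 --out out/
herbmine simulate --n 99 --seed 0 --out sim/
herbmine report --catalog sim/catalog.csv --prescriptions sim/prescriptions.csv --out report/
```

`report` chains validation, citation statistics, profiling, mining, rules,
and network export, and writes a `manifest.json` recording the run
configuration. Exit codes: 0 success, 2 validation error, 3 infeasible
constraints, 4 I/O error.

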