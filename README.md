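# ericakey

A scriptable multi-access identification key engine for the genus
*Erica* — the largest genus of the Ericaceae, with 851 accepted
species concentrated in the Cape Floristic Region, where identifying
a specimen among hundreds of similar heathers is a genuine obstacle
for conservationists, surveyors and enthusiasts alike.

`ericakey` re-implements the computational core of a desktop
identification aid as an open Python library and command-line tool,
for anyone who wants to script, test or extend that workflow:

* a **coded character matrix**: 21 character groups (corolla size,
  shape and colour; hairiness of stem, leaf, pedicel, sepal, corolla
  and ovary; style and anther exsertion; anther appendages; counts of
  stamens, sepals, corolla lobes, leaves per whorl and bracts;
  sepal:corolla length ratio; resprouting after fire; flowering month;
  region), with polymorphic (OR-semantics) coding per taxon;
* **strict matching** — taxa consistent with every observed character;
* **probability ranking** — taxa ordered by summed reciprocal state
  prevalence, tolerant of minor mismatches and missing data;
* a taxonomic checklist with accepted names, synonyms, unplaced names
  and WFO identifiers, searchable with `find`;
* **quarter-degree-square (QDS)** distribution handling (the standard
  southern-African 15′ × 15′ herbarium grid, codes like `3318CD`),
  per-cell taxon lists, occurrence points, coverage-gap reports and
  **KML export** for Google Earth;
* deterministic **synthetic dataset generators**, so everything is
  testable without downloading any data.

## The scoring model

For a user selection constraining groups $g = 1 \dots k$, let $n_g$ be
the number of taxa (in the ranking population, by default all terminal
accepted taxa) whose coding for group $g$ intersects the selected
state set.  Group $g$ contributes

$$p_g = 1 / n_g$$

to each of those $n_g$ carriers and 0 to every other taxon; a taxon's
score is $\sum_g p_g \cdot [\text{taxon carries } g]$.  Rare states
are therefore worth more than common ones; selecting several states in
one group (uncertainty) enlarges $n_g$ and dilutes $p_g$; and a taxon
with missing coding merely forfeits one term instead of being
eliminated, unlike in strict matching.  Taxa are listed in descending
score order, ties broken alphabetically.  Probabilities are displayed
truncated at 7 decimal places, matching the aid's printed output.

## Worked example

A tubular-flowered *Erica* observed on the Cape Peninsula.  In the
demonstration dataset exactly 361 taxa are coded corolla shape
"tube" and exactly 115 region "Cape Peninsula", so those groups
contribute 1/361 = 0.0027700 and 1/115 = 0.0086956:

```sh
$ ericakey fixtures worked-example --out demo
wrote worked-example dataset (456 taxa) to demo

$ ericakey --data demo rank --set "corolla shape=tube" \
      --set "region=Cape Peninsula" --top 3
taxon_id  name                 score      corolla_shape  region     matched_groups
amb001    Erica ambiflora-001  0.0114656  0.0027700      0.0086956  2
amb002    Erica ambiflora-002  0.0114656  0.0027700      0.0086956  2
amb003    Erica ambiflora-003  0.0114656  0.0027700      0.0086956  2
```

The top-ranked taxa are the 20 coded with both states; each earns both
group contributions, summing to 0.0114656.  Strict matching returns
exactly those 20 taxa (`ericakey --data demo identify --set ...`) —
whenever a strict match exists it coincides with the maximum-score
set of the ranking.  The same library calls are available in Python:

```python
from ericakey import fixtures
from ericakey.keying import group_contribution, probability_rank

ds, selection = fixtures.worked_example()
print(group_contribution(ds, "corolla shape", ["tube"]).display_value)
# 0.0027700
print(probability_rank(ds, selection)[0].display_score)
# 0.0114656
```

Mapping: `ericakey --data demo map "Erica ambiflora-001" --out map.kml`
writes a KML document with one translucent polygon per coded QDS cell
and one placemark per occurrence point (capped at 5,000 by default),
coloured per taxon, ready for Google Earth.

## Data format

A data directory holds four UTF-8 CSV tables — `taxa.csv`,
`codings.csv` (states pipe-joined, e.g. `tube|urn`),
`distributions.csv` (one row per taxon–QDS pair) and `points.csv`
(WGS84 decimal degrees) — plus an optional `schema.json` overriding
the default 21-group character schema.  See `docs/methods.md` for the
full model description and design notes.
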