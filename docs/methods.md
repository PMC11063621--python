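# Methods

## The identification model

`ericakey` operates on a character-state matrix: a set of taxa, a
schema of character groups each with a controlled vocabulary of
states, and per-(taxon, group) codings that are *sets* of states.  A
multi-state coding means the taxon genuinely varies (within-species
polymorphism) and is matched with OR semantics: a taxon carries a
selection in a group iff its coded set intersects the selected set.
An empty or absent coding means the character has not been coded for
that taxon — a documented, expected condition in real key data, not
an error.

Two engines act on a user selection (one nonempty state set per
constrained group; at least one group must be constrained):

**Strict matching** returns the taxa whose coding intersects the
selection in *every* constrained group.  Missing coding in any
constrained group excludes a taxon.

**Probability ranking** assigns group *g*, with carrier count
*n_g* = |{taxa whose coding intersects the selected states of *g*}|,
the contribution 1/*n_g*.  Each carrier earns that contribution, every
other taxon earns 0, and a taxon's score is the sum over constrained
groups.  Consequences, all enforced as tested invariants:

* *normalization* — the earned contributions of one group sum to
  exactly 1 over the population (n carriers × 1/n);
* *rarity reward* — a state carried by fewer taxa contributes more;
* *uncertainty penalty* — selecting more states in a group can only
  grow the carrier set (union semantics), never raising and usually
  diluting the contribution;
* *missing-data robustness* — blanking a taxon's coding in one
  constrained group removes exactly that group's contribution from its
  score, while strict matching drops the taxon entirely;
* *strict ≡ argmax* — when the strict set is nonempty it equals the
  set of taxa attaining the maximum achievable score (the sum of all
  group contributions).

Ties are broken by case-insensitive, accent-stripped alphabetical
order of the scientific name, making the ranking a total, reproducible
order.  Zero-carrier selections (no taxon carries the chosen state)
contribute 0 to everyone and raise a `ZeroCarrierWarning` naming the
group, rather than aborting: the selection is probably a user error
and surfacing it beats dividing by zero.

### Ranking population

The population used for both the denominator *n_g* and the ranked list
is configurable and defaults to the *terminal* accepted taxa: species
without subspecific taxa plus every accepted subspecies/variety, so
each tip is counted once and the normalization invariant stays exact.
(`population="species"` restricts to species.)  Synonyms and unplaced
names are never coded or ranked; they exist for name lookup only,
each hit labelled `accepted`, `synonym-of-<name>` or `unplaced`.

### Display precision

Scores are carried at full float precision internally.  The display
layer truncates each contribution toward zero at 7 decimal places —
1/361 prints as 0.0027700, 1/115 as 0.0086956 (note: *truncated*, not
rounded; rounding would give ...701 and ...957) — and shows a ranked
score as the sum of the truncated per-group values (0.0114656 in the
worked example), i.e. exactly what summing the printed contributions
gives.  Machine-readable output (json/csv) carries full precision.

## QDS geocoding

A quarter-degree square is named by the integer degrees south and east
of its degree cell's NW origin, then two letters A–D (A=NW, B=NE,
C=SW, D=SE) selecting first a 30′ quadrant and then a 15′ quarter:
`3318CD` spans 33.75–34.00°S, 18.25–18.50°E (~25 km per side).  This
is the standard southern-African herbarium (PRECIS) convention.

Numerical choices:

* the canonical text form is exactly 4 digits + 2 letters, which
  limits the domain to 0–89° S and 0–99° E; codes in data that do not
  parse (e.g. non-African conventions) are carried as opaque labels
  with a warning, never silently dropped;
* point-in-cell assignment is half-open in degrees-south/degrees-east
  magnitude space — the low-magnitude (north and west) edges of each
  cell are inclusive — so the 16 quarters of a degree cell tile it
  exactly and every in-domain point maps to exactly one QDS;
* `point_to_qds(center(qds_bbox(c))) = c` for every code, a tested
  round-trip.

## KML export

One polygon per (taxon, QDS) cell in a "QDS" folder, one point
placemark per occurrence record in per-taxon folders, each placemark
carrying the record's source label and link in its description.  A
fixed 8-colour palette is cycled in taxon-name order with the
inclusive species first (red), so a species and its subspecies are
always distinguishable.  Point placemarks are capped at
`point_limit` (default 5,000) **per export call**, taking the first
records in input order — deterministic, unlike random subsampling.
Exports with nothing mappable produce an empty but well-formed
document plus a warning.  `check_kml` validates documents
structurally (KML 2.2 namespace, Document presence, ring closure,
coordinate arity); it does not run an XSD validator, so schema
constraints beyond those checks are not enforced.

Coverage reports compare the two evidence layers per taxon: coded
cells containing none of the taxon's points, and points falling in no
coded cell.  Either indicates a gap or error worth investigating, not
necessarily a mistake.

## Synthetic data

The generators exist so every engine is exercisable offline and
deterministically; they do **not** emulate real trait correlations,
spatial range shapes, or the aid's actual codings, so passing tests
demonstrate algorithmic correctness, not floristic accuracy.

`generate_dataset(spec)` draws, per (taxon, group) cell: missing with
probability `missing_rate` (default 0.10 — character coding of real
keys is incomplete); otherwise each prevalence-targeted state of the
group independently with probability p/(1 − missing_rate), so the
carrier fraction among *all* taxa converges to the target p (checked
at n = 10,000 within ±0.02, ≈4 binomial s.d.); then topped up from the
unconstrained states to 1 state, or 2 with probability
`polymorphism_rate` (default 0.15 — multi-state codings are common but
minority).  Targets exceeding 1 − missing_rate are infeasible and
rejected.  All randomness flows from one numpy `default_rng(seed)`;
identical seeds give byte-identical CSV serialisations.

`worked_example()` is constructed, not sampled: 341 taxa coded tube
only, 95 Cape Peninsula only, 20 both — fixing the two published
carrier counts (361 tube, 115 Peninsula) exactly.  Only those two
counts are anchored to the aid's arithmetic; the overlap of 20 and the
456-taxon total are fixture choices.  (The aid's own prose mentions
359 and 116 while computing 1/361 and 1/115; this package reproduces
the computed values.)

`generate_points` places points uniformly inside each coded cell —
exactly k per cell for integer rates, Poisson counts otherwise — and
displaces a `stray_rate` fraction into an adjacent uncoded cell to
exercise coverage reporting.

## Problem sizes in the test suite

The ranking invariants are verified against an independent brute-force
recomputation (direct O(taxa × groups) scanning, no shared code with
the engine) on 200 seeded random datasets of 20–200 taxa with random
1–4-group selections, with scores required to agree within 1e-12 and
order exactly.  Geometry round-trips cover all 16 quadrant/quarter
letter pairs over several degree cells plus derandomised
property-based sampling.  These sizes run the whole suite in well
under a minute while giving each invariant a few hundred independent
chances to fail.

## Known limitations

* The default state vocabularies are configuration (the aid publishes
  only example states such as "tube" and the three region names quoted
  in its description); real datasets should ship their own
  `schema.json`.
* The importer reads only the canonical CSV dialect documented in the
  README, not the archived desktop-application export layout.
* The geocoder is southern/eastern hemisphere only; European and
  Madagascan grids pass through as opaque labels.
* No character weighting, dependence modelling, or Bayesian
  interpretation of the scores: a "probability" here is a prevalence
  heuristic, not a posterior.
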