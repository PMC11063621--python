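"""Identification engines: strict matching and reciprocal-prevalence ranking.

Two complementary modes act on a coded character matrix:

* **Strict matching** returns exactly the taxa whose coding is
  consistent with every constrained character group — the classical
  multi-access key behaviour.  Taxa with missing coding in a
  constrained group are excluded.

* **Probability ranking** scores every taxon in the ranking population
  by summing, over the constrained groups, the reciprocal prevalence
  of the selected states: a group in which n taxa carry at least one
  selected state contributes 1/n to each of those n carriers and 0 to
  everyone else.  Rare states therefore impart a greater probability
  than common ones, selecting several states in one group (observer
  uncertainty) enlarges the carrier set and dilutes the contribution,
  and a taxon with a missing coding merely forfeits that group's
  contribution instead of being eliminated — making the ranking far
  less sensitive to incomplete coding than strict matching.

Within a group, polymorphic codings are matched with OR semantics: a
taxon carries a selection if its coded state set intersects the
selected states.

Scores are carried at full floating precision; the display layer
truncates each contribution at 7 decimal places (matching the aid's
printed presentation, which truncates rather than rounds: 1/361 is
shown as 0.0027700) and shows the sum of the truncated values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .matrix_model import (
    CharacterSchema,
    DatasetError,
    KeyDataset,
    TaxonRecord,
    collation_key,
)

__all__ = [
    "Selection",
    "GroupContribution",
    "RankedTaxon",
    "ComparisonTable",
    "ZeroCarrierWarning",
    "truncate7",
    "format_probability",
    "ranking_population",
    "state_carriers",
    "group_contribution",
    "probability_rank",
    "strict_match",
    "compare_taxa",
]

DISPLAY_PLACES = 7
_QUANTUM = Decimal(1).scaleb(-DISPLAY_PLACES)


class ZeroCarrierWarning(UserWarning):
    """A constrained group whose selected states no taxon carries.

    Usually a sign of user error (an impossible character combination
    was entered); the group contributes 0 to every taxon rather than
    aborting the ranking.
    """


def truncate7(value: float) -> float:
    """Truncate toward zero at 7 decimal places (the aid's display rule)."""
    return float(Decimal(value).quantize(_QUANTUM, rounding=ROUND_DOWN))


def format_probability(value: float) -> str:
    """Render a probability the way the aid prints it, e.g. ``0.0027700``."""
    return f"{Decimal(value).quantize(_QUANTUM, rounding=ROUND_DOWN):f}"


@dataclass(frozen=True)
class Selection:
    """The observer's chosen states, one nonempty set per constrained group.

    Built through :meth:`Selection.build` so that group and state
    tokens are resolved (case-insensitively, by id or label) against a
    schema; at least one group must be constrained — there is no
    vacuous identification.
    """

    constraints: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.constraints:
            raise DatasetError("a selection must constrain at least one group")
        for gid, states in self.constraints.items():
            if not states:
                raise DatasetError(f"empty state set for group {gid!r}")

    @classmethod
    def build(cls, schema: CharacterSchema,
              raw: Mapping[str, Iterable[str]]) -> "Selection":
        resolved: dict[str, frozenset[str]] = {}
        for token, states in raw.items():
            group = schema.group(token)
            if group.group_id in resolved:
                raise DatasetError(f"group {token!r} constrained twice")
            resolved[group.group_id] = frozenset(
                group.resolve_state(s) for s in states)
        return cls(constraints=resolved)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(self.constraints)


@dataclass(frozen=True)
class GroupContribution:
    """Reciprocal prevalence of a selected state set within one group."""

    group_id: str
    carrier_count: int
    value: float

    def __post_init__(self) -> None:
        if self.carrier_count < 0:
            raise ValueError("carrier_count must be nonnegative")

    @property
    def display_value(self) -> str:
        return format_probability(self.value)


@dataclass(frozen=True)
class RankedTaxon:
    """A taxon with its summed probability and per-group breakdown."""

    taxon_id: str
    name: str
    score: float
    contributions: Mapping[str, float]
    matched_groups: int

    @property
    def display_score(self) -> str:
        """Sum of the per-group contributions as the aid prints them
        (each truncated at 7 decimal places before summing)."""
        total = sum((Decimal(v).quantize(_QUANTUM, rounding=ROUND_DOWN)
                     for v in self.contributions.values()), Decimal(0))
        return f"{total.quantize(_QUANTUM, rounding=ROUND_DOWN):f}"


@dataclass(frozen=True)
class ComparisonTable:
    """Side-by-side coded states for two or more taxa.

    One row per character group in schema order; ``None`` marks a
    missing coding, distinct from an empty shared-state intersection
    the caller might compute.
    """

    taxa: tuple[TaxonRecord, ...]
    rows: tuple[tuple[str, tuple[Optional[frozenset[str]], ...]], ...]

    def differing_rows(self) -> list[str]:
        return [gid for gid, cells in self.rows if len(set(cells)) > 1]


# ---------------------------------------------------------------------------
# ranking population


def ranking_population(ds: KeyDataset, population: str = "terminal"
                       ) -> list[TaxonRecord]:
    """The taxa that identification operates over.

    ``terminal`` (default): accepted species without subspecific taxa
    plus every accepted subspecific taxon — each tip of the checklist
    counted once.  ``species``: accepted species only.  One population
    is used for both the contribution denominator and the ranked list,
    which keeps the per-group contributions summing to exactly 1 over
    the carriers.
    """
    if population == "terminal":
        return ds.terminal_taxa()
    if population == "species":
        return ds.species()
    raise DatasetError(f"unknown ranking population {population!r}")


def _resolve_group_states(ds: KeyDataset, group_id: str,
                          states: Iterable[str]) -> tuple[str, frozenset[str]]:
    group = ds.schema.group(group_id)
    resolved = frozenset(group.resolve_state(s) for s in states)
    if not resolved:
        raise DatasetError(f"no states selected for group {group_id!r}")
    return group.group_id, resolved


def state_carriers(ds: KeyDataset, group_id: str, states: Iterable[str],
                   population: str = "terminal") -> set[str]:
    """Taxa whose coding for the group intersects the selected states.

    Union (OR) semantics over the selected states: selecting more
    states can only enlarge the carrier set, never shrink it to the
    taxa exhibiting all of them.
    """
    gid, wanted = _resolve_group_states(ds, group_id, states)
    return {t.taxon_id for t in ranking_population(ds, population)
            if ds.coding(t.taxon_id, gid) & wanted}


def group_contribution(ds: KeyDataset, group_id: str, states: Iterable[str],
                       population: str = "terminal") -> GroupContribution:
    """1 / (number of carriers of the selected states), 0 when none.

    The reciprocal-prevalence weight every carrier earns from this
    group: a state carried by a single taxon is decisive (value 1.0),
    a near-universal state contributes almost nothing.
    """
    gid, wanted = _resolve_group_states(ds, group_id, states)
    carriers = state_carriers(ds, gid, wanted, population)
    n = len(carriers)
    if n == 0:
        warnings.warn(
            f"no taxon carries the selected state(s) in group {gid!r}; "
            f"the group contributes 0", ZeroCarrierWarning, stacklevel=2)
        return GroupContribution(group_id=gid, carrier_count=0, value=0.0)
    return GroupContribution(group_id=gid, carrier_count=n, value=1.0 / n)


def probability_rank(ds: KeyDataset, selection: Selection,
                     include_zero: bool = False,
                     population: str = "terminal") -> list[RankedTaxon]:
    """Rank the population by summed reciprocal-prevalence probability.

    Each constrained group contributes its reciprocal prevalence to
    the taxa carrying a selected state and 0 to the rest; a taxon's
    score is the sum over all constrained groups.  Taxa are ordered by
    descending score, ties broken alphabetically (case-insensitive,
    accent-stripped).  Zero-score taxa are omitted unless
    ``include_zero`` is set.
    """
    pop = ranking_population(ds, population)
    per_group: list[tuple[str, frozenset[str], float]] = []
    for token, states in selection.constraints.items():
        contrib = group_contribution(ds, token, states, population)
        gid, wanted = _resolve_group_states(ds, token, states)
        per_group.append((gid, wanted, contrib.value))

    ranked: list[RankedTaxon] = []
    for t in pop:
        earned: dict[str, float] = {}
        matched = 0
        for gid, wanted, value in per_group:
            if ds.coding(t.taxon_id, gid) & wanted:
                earned[gid] = value
                matched += 1
            else:
                earned[gid] = 0.0
        score = sum(earned.values())
        if score == 0.0 and not include_zero:
            continue
        ranked.append(RankedTaxon(taxon_id=t.taxon_id, name=t.name,
                                  score=score, contributions=earned,
                                  matched_groups=matched))
    ranked.sort(key=lambda r: (-r.score, collation_key(r.name)))
    return ranked


def strict_match(ds: KeyDataset, selection: Selection,
                 population: str = "terminal") -> set[str]:
    """Taxa consistent with every constrained group.

    A taxon passes iff its coding intersects the selected states in
    each constrained group; missing coding in any constrained group
    excludes it.  Equivalently (when nonempty): the taxa attaining the
    maximum possible probability score.
    """
    result: Optional[set[str]] = None
    for token, states in selection.constraints.items():
        carriers = state_carriers(ds, token, states, population)
        result = carriers if result is None else result & carriers
        if not result:
            return set()
    assert result is not None  # Selection guarantees >=1 group
    return result


def compare_taxa(ds: KeyDataset, taxon_ids: Sequence[str],
                 group_ids: Optional[Sequence[str]] = None) -> ComparisonTable:
    """Tabulate coded states of two or more accepted taxa side by side."""
    if len(taxon_ids) < 2:
        raise DatasetError("compare needs at least two taxa")
    records = [ds.resolve_taxon(t) for t in taxon_ids]
    ids = [t.taxon_id for t in records]
    if len(set(ids)) != len(ids):
        raise DatasetError("compare: duplicate taxa in the request")
    for t in records:
        if t.status != "accepted":
            raise DatasetError(
                f"compare: {t.name!r} is not an accepted taxon "
                f"(status={t.status})")

    if group_ids is None:
        groups = list(ds.schema)
    else:
        chosen = {ds.schema.group(g).group_id for g in group_ids}
        groups = [g for g in ds.schema if g.group_id in chosen]

    rows = []
    for g in groups:
        cells = []
        for t in records:
            coded = ds.coding(t.taxon_id, g.group_id)
            cells.append(coded if coded else None)
        rows.append((g.group_id, tuple(cells)))
    return ComparisonTable(taxa=tuple(records), rows=tuple(rows))
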