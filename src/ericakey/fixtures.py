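"""Deterministic synthetic key datasets for testing and demonstration.

Everything here is generated in memory from a seed — no download, no
binary fixtures.  Three generators are provided:

* :func:`generate_dataset` — a random coded matrix honouring target
  state prevalences, polymorphism and missing-data rates in
  expectation;
* :func:`worked_example` — the canonical "tubular flower on the Cape
  Peninsula" dataset, built so the corolla-shape group has exactly 361
  carriers of "tube" (contribution 1/361 = 0.0027700) and the region
  group exactly 115 carriers of "Cape Peninsula" (1/115 = 0.0086956),
  with 20 taxa carrying both;
* :func:`generate_points` — occurrence points placed inside (or
  deliberately just outside) each taxon's coded QDS cells, to exercise
  mapping and coverage reporting.

Only the two carrier counts of the worked example (361 and 115) are
anchored to the aid's published arithmetic; the overlap of 20 and the
total of 456 taxa are fixture choices.  The random generator makes no
attempt to simulate realistic trait correlations or spatial range
shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .geo_qds import OccurrencePoint, QdsError, parse_qds, qds_bbox
from .keying import Selection
from .matrix_model import (
    CharacterSchema,
    KeyDataset,
    TaxonRecord,
    default_schema,
)

__all__ = [
    "DatasetSpec",
    "InfeasibleSpecError",
    "generate_dataset",
    "worked_example",
    "mapping_example",
    "generate_points",
]


class InfeasibleSpecError(ValueError):
    """The requested prevalences cannot be realised under the given
    missing-data rate."""


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of a synthetic key dataset.

    ``prevalence`` maps (group_id, state) to the target carrier
    fraction among *all* taxa; ``polymorphism_rate`` is the probability
    a coded (taxon, group) cell carries at least two states;
    ``missing_rate`` the probability a cell is uncoded.  The defaults
    (15% polymorphism, 10% missing) reflect that within-species
    variation is common and character coding incomplete in real key
    data.  The seed fully determines the output.
    """

    n_taxa: int = 100
    schema: CharacterSchema = field(default_factory=default_schema)
    prevalence: Mapping[tuple[str, str], float] = field(default_factory=dict)
    polymorphism_rate: float = 0.15
    missing_rate: float = 0.10
    qds_pool: tuple[str, ...] = ("3318AA", "3318CD", "3319AB", "3418BA", "3420CA")
    points_per_taxon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        for rate in (self.polymorphism_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for (gid, state), frac in self.prevalence.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"prevalence for ({gid}, {state}) must lie in [0, 1]")
        for code in self.qds_pool:
            parse_qds(code)


def generate_dataset(spec: DatasetSpec) -> KeyDataset:
    """Generate a random coded key dataset from a spec.

    All taxa are accepted species.  For each coded cell the
    prevalence-constrained states of the group are drawn independently
    with adjusted probability p/(1-missing_rate) — so the carrier
    fraction among all taxa converges to p — and the cell is then
    topped up from the unconstrained states to one state (or two, at
    the polymorphism rate).  Identical seeds give identical datasets,
    byte-for-byte when serialised.
    """
    rng = np.random.default_rng(spec.seed)
    coded_frac = 1.0 - spec.missing_rate
    by_group: dict[str, list[tuple[str, float]]] = {}
    for (gid, state), frac in spec.prevalence.items():
        group = spec.schema.group(gid)
        canonical = group.resolve_state(state)
        if frac > 0 and coded_frac == 0:
            raise InfeasibleSpecError(
                f"prevalence {frac} for ({gid}, {state}) unreachable with "
                f"missing_rate=1")
        p_adj = frac / coded_frac if coded_frac else 0.0
        if p_adj > 1.0 + 1e-12:
            raise InfeasibleSpecError(
                f"prevalence {frac} for ({gid}, {state}) exceeds the coded "
                f"fraction {coded_frac}")
        by_group.setdefault(group.group_id, []).append((canonical, min(p_adj, 1.0)))

    width = len(str(spec.n_taxa))
    taxa: dict[str, TaxonRecord] = {}
    codings: dict[str, dict[str, frozenset[str]]] = {}
    distributions: dict[str, frozenset[str]] = {}
    pool = sorted(spec.qds_pool)

    for i in range(spec.n_taxa):
        tid = f"t{i + 1:0{width}d}"
        taxa[tid] = TaxonRecord(taxon_id=tid, name=f"Erica synthetica-{i + 1:0{width}d}")
        per_group: dict[str, frozenset[str]] = {}
        for group in spec.schema:
            if rng.random() < spec.missing_rate:
                continue
            states: set[str] = set()
            pinned = by_group.get(group.group_id, [])
            for state, p_adj in pinned:
                if rng.random() < p_adj:
                    states.add(state)
            target = 2 if rng.random() < spec.polymorphism_rate else 1
            free = [s for s in group.states
                    if s not in states and s not in {st for st, _ in pinned}]
            while len(states) < target and free:
                pick = free.pop(int(rng.integers(len(free))))
                states.add(pick)
            if not states:  # prevalence states cover the whole vocabulary
                states.add(group.states[int(rng.integers(len(group.states)))])
            per_group[group.group_id] = frozenset(states)
        if per_group:
            codings[tid] = per_group
        if pool:
            k = int(rng.integers(1, min(3, len(pool)) + 1))
            chosen = rng.choice(len(pool), size=k, replace=False)
            distributions[tid] = frozenset(pool[j] for j in sorted(chosen))

    ds = KeyDataset(schema=spec.schema, taxa=taxa, codings=codings,
                    distributions=distributions, points=[])
    if spec.points_per_taxon > 0:
        ds.points = generate_points(ds, spec.points_per_taxon, 0.0,
                                    seed=spec.seed + 1)
    return ds


def worked_example() -> tuple[KeyDataset, Selection]:
    """The "tubular flower on the Cape Peninsula" demonstration dataset.

    456 accepted species: 341 coded corolla shape "tube" only, 95
    coded region "Cape Peninsula" only, and 20 coded both — so the
    tube carrier count is exactly 361 and the Peninsula carrier count
    exactly 115.  Returns the dataset together with the selection
    {corolla shape: tube, region: Cape Peninsula}; the 20 both-state
    taxa top the ranking, each earning 1/361 + 1/115.
    """
    schema = default_schema()
    taxa: dict[str, TaxonRecord] = {}
    codings: dict[str, dict[str, frozenset[str]]] = {}
    distributions: dict[str, frozenset[str]] = {}

    def add(tid: str, name: str, coding: dict[str, frozenset[str]],
            qds: frozenset[str] = frozenset()) -> None:
        taxa[tid] = TaxonRecord(taxon_id=tid, name=name)
        codings[tid] = coding
        if qds:
            distributions[tid] = qds

    for i in range(341):
        add(f"tub{i + 1:03d}", f"Erica tubularis-{i + 1:03d}",
            {"corolla_shape": frozenset({"tube"}),
             "region": frozenset({"SW Cape"})},
            frozenset({"3418BA"}))
    for i in range(95):
        add(f"pen{i + 1:03d}", f"Erica peninsulae-{i + 1:03d}",
            {"corolla_shape": frozenset({"urn"}),
             "region": frozenset({"Cape Peninsula"})},
            frozenset({"3318CD"}))
    for i in range(20):
        add(f"amb{i + 1:03d}", f"Erica ambiflora-{i + 1:03d}",
            {"corolla_shape": frozenset({"tube"}),
             "region": frozenset({"Cape Peninsula"})},
            frozenset({"3318CD", "3418AB"}))

    ds = KeyDataset(schema=schema, taxa=taxa, codings=codings,
                    distributions=distributions, points=[])
    selection = Selection.build(schema, {
        "corolla shape": ["tube"],
        "region": ["Cape Peninsula"],
    })
    return ds, selection


def mapping_example(points_per_coded_qds: float = 2.0,
                    seed: int = 0) -> KeyDataset:
    """An inclusive species with five subspecies, coded QDS cells and
    occurrence points — the shape of a mapped polymorphic species.

    Useful for exercising KML export (six distinct colours: the
    species plus five subspecies) and coverage reporting.
    """
    schema = default_schema()
    taxa: dict[str, TaxonRecord] = {}
    distributions: dict[str, frozenset[str]] = {}
    taxa["sp"] = TaxonRecord(taxon_id="sp", name="Erica exemplaris")
    distributions["sp"] = frozenset({"3318CD", "3318AB", "3418BA"})
    cells = ["3318AA", "3318CD", "3319AB", "3418BA", "3420CA"]
    for i, epithet in enumerate(("australis", "borealis", "litoralis",
                                 "montana", "typica")):
        tid = f"ssp{i + 1}"
        taxa[tid] = TaxonRecord(
            taxon_id=tid, name=f"Erica exemplaris subsp. {epithet}",
            rank="subspecies", parent_id="sp")
        distributions[tid] = frozenset({cells[i]})
    ds = KeyDataset(schema=schema, taxa=taxa, codings={},
                    distributions=distributions, points=[])
    if points_per_coded_qds > 0:
        ds.points = generate_points(ds, points_per_coded_qds, 0.0, seed=seed)
    return ds


def _adjacent_uncoded_box(code: str, coded: frozenset[str]):
    """A neighbouring 15' box not in the taxon's coded set, for stray points."""
    from .geo_qds import point_to_qds

    box = qds_bbox(parse_qds(code))
    clat, clon = box.center
    for dlat, dlon in ((0, 0.25), (0, -0.25), (0.25, 0), (-0.25, 0),
                       (0.25, 0.25), (0.25, -0.25), (-0.25, 0.25),
                       (-0.25, -0.25)):
        lat, lon = clat + dlat, clon + dlon
        if not (lat < 0 and lon > 0):
            continue
        try:
            neighbour = point_to_qds((lat, lon))
        except QdsError:
            continue
        if neighbour.code not in coded:
            return qds_bbox(neighbour)
    return None


def generate_points(ds: KeyDataset, points_per_coded_qds: float,
                    stray_rate: float, seed: int = 0) -> list[OccurrencePoint]:
    """Sample occurrence points for every coded (taxon, QDS) cell.

    Integer rates place exactly that many points per cell; fractional
    rates draw a Poisson count.  Each point is uniform inside its
    cell, except that a ``stray_rate`` fraction is displaced into an
    adjacent cell the taxon is *not* coded for, to exercise coverage
    gap detection.  Codes outside the geocoder domain are skipped.
    Fully deterministic under the seed.
    """
    if not 0.0 <= stray_rate <= 1.0:
        raise ValueError("stray_rate must lie in [0, 1]")
    if points_per_coded_qds < 0:
        raise ValueError("points_per_coded_qds must be nonnegative")
    rng = np.random.default_rng(seed)
    points: list[OccurrencePoint] = []
    canonical_coded = {
        tid: frozenset(parse_qds(c).code for c in codes
                       if _parses(c))
        for tid, codes in ds.distributions.items()
    }
    for tid in ds.taxa:
        codes = sorted(ds.distributions.get(tid, ()))
        for code in codes:
            if not _parses(code):
                continue
            if float(points_per_coded_qds).is_integer():
                n = int(points_per_coded_qds)
            else:
                n = int(rng.poisson(points_per_coded_qds))
            for k in range(n):
                box = qds_bbox(parse_qds(code))
                if rng.random() < stray_rate:
                    stray = _adjacent_uncoded_box(code, canonical_coded[tid])
                    if stray is not None:
                        box = stray
                lat = float(rng.uniform(box.south, box.north))
                lon = float(rng.uniform(box.west, box.east))
                points.append(OccurrencePoint(
                    taxon_id=tid, latitude=lat, longitude=lon,
                    source_label=f"synthetic record {tid}/{code}/{k + 1}"))
    return points


def _parses(code: str) -> bool:
    try:
        parse_qds(code)
        return True
    except QdsError:
        return False
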