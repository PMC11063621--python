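"""Domain model for a coded multi-access identification key.

The key is a character-state matrix: each taxon is coded, per character
group (e.g. corolla shape, flowering month, region), with the set of
states it exhibits.  Polymorphic coding — several states in one group —
expresses within-species variation and is interpreted with OR semantics
by the identification engines in :mod:`ericakey.keying`.

This module owns the domain types, the canonical CSV dialect for the
four data tables (taxa, codings, distributions, points), dataset
validation, and name lookup across accepted names, synonyms, and
unplaced names.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .geo_qds import OccurrencePoint

__all__ = [
    "CharacterGroup",
    "CharacterSchema",
    "TaxonRecord",
    "StateCoding",
    "KeyDataset",
    "ValidationIssue",
    "ValidationReport",
    "DatasetError",
    "MONTHS",
    "RANKS",
    "STATUSES",
    "default_schema",
    "load_schema",
    "write_schema",
    "load_dataset",
    "write_dataset",
    "validate_dataset",
    "find_name",
    "collation_key",
]

MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
          "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")

RANKS = ("species", "subspecies", "variety")
STATUSES = ("accepted", "synonym", "unplaced")
GROUP_KINDS = ("categorical", "count", "binary", "month", "region")


class DatasetError(ValueError):
    """A key dataset could not be loaded or is structurally invalid.

    Carries a human-readable message that names the offending table,
    row and token where one is known.
    """


def collation_key(name: str) -> str:
    """Deterministic case-insensitive, accent-stripped sort key for names."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return stripped.casefold()


# ---------------------------------------------------------------------------
# schema


@dataclass(frozen=True)
class CharacterGroup:
    """One observable character with a controlled vocabulary of states."""

    group_id: str
    label: str
    kind: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_id:
            raise ValueError("group_id must be nonempty")
        if self.kind not in GROUP_KINDS:
            raise ValueError(f"unknown group kind {self.kind!r}")
        if not self.states:
            raise ValueError(f"group {self.group_id!r}: states must be nonempty")
        lowered = [s.casefold() for s in self.states]
        if len(set(lowered)) != len(lowered):
            raise ValueError(f"group {self.group_id!r}: duplicate state tokens")
        if self.kind == "month" and tuple(self.states) != MONTHS:
            raise ValueError(
                f"group {self.group_id!r}: month groups must carry exactly the "
                f"12 states Jan..Dec"
            )

    def resolve_state(self, token: str) -> str:
        """Return the canonical spelling of ``token``, matched case-insensitively.

        Raises :class:`DatasetError` naming the token when it is not in
        the vocabulary.
        """
        wanted = token.strip().casefold()
        for s in self.states:
            if s.casefold() == wanted:
                return s
        raise DatasetError(
            f"unknown state {token!r} for group {self.group_id!r} "
            f"(vocabulary: {', '.join(self.states)})"
        )

    def has_state(self, token: str) -> bool:
        try:
            self.resolve_state(token)
            return True
        except DatasetError:
            return False


@dataclass(frozen=True)
class CharacterSchema:
    """An ordered collection of character groups.

    Group order is fixed for stable display; it never affects scores.
    """

    groups: tuple[CharacterGroup, ...]

    def __post_init__(self) -> None:
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate group_ids in schema")

    def __iter__(self) -> Iterator[CharacterGroup]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.groups)

    def group(self, token: str) -> CharacterGroup:
        """Resolve a group by id or label, case-insensitively.

        An exact id match wins; otherwise label matches are tried.
        Ambiguity (a token matching several labels) is an error, never
        a guess.
        """
        wanted = token.strip().casefold()
        for g in self.groups:
            if g.group_id.casefold() == wanted:
                return g
        hits = [g for g in self.groups if g.label.casefold() == wanted]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise DatasetError(f"ambiguous group token {token!r}")
        raise DatasetError(f"unknown character group {token!r}")


def _hairiness(part: str) -> CharacterGroup:
    return CharacterGroup(
        group_id=f"{part}_hairiness",
        label=f"hairiness of {part}",
        kind="binary",
        states=("glabrous", "hairy"),
    )


def default_schema() -> CharacterSchema:
    """The canonical 21-group character schema of the identification aid.

    Groups and their order follow the aid's character list: corolla
    size, shape and colour; hairiness of stem, leaf, pedicel, sepal,
    corolla and ovary; exsertion of style and anthers; anther
    appendages; counts of stamens, sepals, corolla lobes, leaves per
    whorl and bracts; sepal:corolla length ratio; resprouting after
    fire; flowering month; and geographic region.

    The state vocabularies are configuration, not ground truth: the aid
    never publishes a normative list per group, so these defaults are a
    practical vocabulary that can be overridden via a schema config
    file (:func:`load_schema`).
    """
    groups = [
        CharacterGroup("corolla_size", "corolla size", "categorical",
                       ("minute", "small", "medium", "large")),
        CharacterGroup("corolla_shape", "corolla shape", "categorical",
                       ("tube", "urn", "cup", "bell", "globose", "funnel")),
        CharacterGroup("corolla_colour", "corolla colour", "categorical",
                       ("white", "cream", "yellow", "orange", "pink", "red",
                        "purple", "green", "brown", "multicoloured")),
        _hairiness("stem"),
        _hairiness("leaf"),
        _hairiness("pedicel"),
        _hairiness("sepal"),
        _hairiness("corolla"),
        _hairiness("ovary"),
        CharacterGroup("style_exserted", "style exserted", "binary",
                       ("exserted", "included")),
        CharacterGroup("anthers_exserted", "anthers exserted", "binary",
                       ("exserted", "included")),
        CharacterGroup("anther_appendages", "anther appendages", "binary",
                       ("present", "absent")),
        CharacterGroup("stamen_number", "number of stamens", "count",
                       ("4", "8", "other")),
        CharacterGroup("sepal_number", "number of sepals", "count",
                       ("3", "4", "5")),
        CharacterGroup("corolla_lobe_number", "number of corolla lobes", "count",
                       ("3", "4", "5")),
        CharacterGroup("leaves_per_whorl", "leaves per whorl", "count",
                       ("3", "4", "5", "6")),
        CharacterGroup("bract_number", "number of bracts", "count",
                       ("1", "2", "3")),
        CharacterGroup("sepal_corolla_ratio", "sepal:corolla length ratio",
                       "categorical",
                       ("under half", "about half", "over half",
                        "equal or longer")),
        CharacterGroup("resprouting", "resprouting", "binary",
                       ("resprouter", "reseeder")),
        CharacterGroup("flowering_month", "flowering month", "month", MONTHS),
        CharacterGroup("region", "region", "region",
                       ("Cape Peninsula", "SW Cape", "S Cape", "E Cape",
                        "Langeberg", "KZ-Natal", "North South Africa",
                        "Tropical Africa", "Madagascar", "Europe")),
    ]
    return CharacterSchema(tuple(groups))


def load_schema(path: str | Path) -> CharacterSchema:
    """Read a schema config (JSON: ``{"groups": [{group_id, label, kind, states}]}``)."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        groups = tuple(
            CharacterGroup(
                group_id=g["group_id"],
                label=g["label"],
                kind=g["kind"],
                states=tuple(g["states"]),
            )
            for g in doc["groups"]
        )
    except (KeyError, TypeError) as exc:
        raise DatasetError(f"malformed schema config {path}: {exc}") from exc
    return CharacterSchema(groups)


def write_schema(schema: CharacterSchema, path: str | Path) -> None:
    doc = {
        "groups": [
            {"group_id": g.group_id, "label": g.label, "kind": g.kind,
             "states": list(g.states)}
            for g in schema
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, ensure_ascii=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# taxa and codings


@dataclass(frozen=True)
class TaxonRecord:
    """An entry in the key's checklist.

    Accepted species and subspecific taxa carry codings and
    distributions; synonyms and unplaced names exist only so that any
    published name can be found and resolved (``find_name``).
    """

    taxon_id: str
    name: str
    rank: str = "species"
    parent_id: Optional[str] = None
    status: str = "accepted"
    accepted_id: Optional[str] = None
    wfo_id: Optional[str] = None
    iucn_category: Optional[str] = None
    sort_keys: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be nonempty")
        if self.rank not in RANKS:
            raise ValueError(f"taxon {self.taxon_id!r}: unknown rank {self.rank!r}")
        if self.status not in STATUSES:
            raise ValueError(
                f"taxon {self.taxon_id!r}: unknown status {self.status!r}")


@dataclass(frozen=True)
class StateCoding:
    """The coded state set of one taxon in one character group.

    An empty set means missing/uncoded; several states mean the taxon
    varies (OR semantics).
    """

    taxon_id: str
    group_id: str
    states: frozenset[str]


@dataclass
class KeyDataset:
    """Schema + taxa + codings + QDS distributions + occurrence points.

    The unit every identification, comparison and mapping operation
    acts on.  ``codings`` maps taxon_id -> group_id -> state set;
    ``distributions`` maps taxon_id -> set of QDS code strings.
    """

    schema: CharacterSchema
    taxa: dict[str, TaxonRecord]
    codings: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    distributions: dict[str, frozenset[str]] = field(default_factory=dict)
    points: list[OccurrencePoint] = field(default_factory=list)

    def coding(self, taxon_id: str, group_id: str) -> frozenset[str]:
        """The coded state set, empty when missing/uncoded."""
        return self.codings.get(taxon_id, {}).get(group_id, frozenset())

    def accepted(self) -> list[TaxonRecord]:
        return [t for t in self.taxa.values() if t.status == "accepted"]

    def children(self, taxon_id: str) -> list[TaxonRecord]:
        return [t for t in self.taxa.values()
                if t.parent_id == taxon_id and t.status == "accepted"]

    def terminal_taxa(self) -> list[TaxonRecord]:
        """Accepted taxa at the tips of the checklist hierarchy.

        Species without accepted subspecific taxa, plus every accepted
        subspecific taxon.  This is the default ranking population for
        the identification engines.
        """
        has_children = {t.parent_id for t in self.taxa.values()
                        if t.parent_id and t.status == "accepted"}
        out = []
        for t in self.accepted():
            if t.rank == "species" and t.taxon_id in has_children:
                continue
            out.append(t)
        return out

    def species(self) -> list[TaxonRecord]:
        return [t for t in self.accepted() if t.rank == "species"]

    def resolve_taxon(self, token: str) -> TaxonRecord:
        """Resolve a taxon by id or exact name, case-insensitively."""
        if token in self.taxa:
            return self.taxa[token]
        wanted = token.strip().casefold()
        hits = [t for t in self.taxa.values()
                if t.taxon_id.casefold() == wanted or t.name.casefold() == wanted]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise DatasetError(f"ambiguous taxon token {token!r}")
        raise DatasetError(f"unknown taxon {token!r}")


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "fatal" | "warning"
    table: str
    row: str
    message: str


@dataclass
class ValidationReport:
    """All invariant violations found in a dataset.

    Incompleteness (taxa without codings or distributions) is expected
    in real key data and reported at severity ``warning``; structural
    violations are ``fatal``.
    """

    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, severity: str, table: str, row: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity, table, row, message))

    @property
    def fatal(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "fatal"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for i in self.issues:
            counts[i.severity] = counts.get(i.severity, 0) + 1
        return counts

    def ok(self) -> bool:
        return not self.fatal


def validate_dataset(ds: KeyDataset) -> ValidationReport:
    """Check every dataset invariant, reporting rather than raising.

    Fatal: dangling ids, vocabulary violations, codings on
    non-accepted taxa, broken synonym/parent links.  Warning: accepted
    terminal taxa with no codings or no distribution, and distribution
    codes that do not parse as QDS (carried as opaque labels).
    """
    from . import geo_qds  # local import: avoid cycle at module load

    rep = ValidationReport()
    taxa = ds.taxa

    for t in taxa.values():
        row = t.taxon_id
        if t.status == "synonym":
            if not t.accepted_id:
                rep.add("fatal", "taxa", row, "synonym without accepted_id")
            elif t.accepted_id not in taxa:
                rep.add("fatal", "taxa", row,
                        f"accepted_id {t.accepted_id!r} does not resolve")
            elif taxa[t.accepted_id].status != "accepted":
                rep.add("fatal", "taxa", row,
                        f"accepted_id {t.accepted_id!r} is not an accepted taxon")
        elif t.status == "accepted" and t.accepted_id:
            rep.add("fatal", "taxa", row, "accepted taxon carries accepted_id")
        if t.rank in ("subspecies", "variety") and t.status == "accepted":
            if not t.parent_id:
                rep.add("fatal", "taxa", row, f"{t.rank} without parent_id")
            elif t.parent_id not in taxa:
                rep.add("fatal", "taxa", row,
                        f"parent_id {t.parent_id!r} does not resolve")
            elif taxa[t.parent_id].rank != "species":
                rep.add("fatal", "taxa", row,
                        f"parent {t.parent_id!r} is not of rank species")

    known_groups = {g.group_id: g for g in ds.schema}
    for taxon_id, per_group in ds.codings.items():
        if taxon_id not in taxa:
            rep.add("fatal", "codings", taxon_id, "coding for unknown taxon")
            continue
        if taxa[taxon_id].status != "accepted":
            rep.add("fatal", "codings", taxon_id,
                    f"coding on non-accepted taxon (status={taxa[taxon_id].status})")
        for group_id, states in per_group.items():
            row = f"{taxon_id}/{group_id}"
            group = known_groups.get(group_id)
            if group is None:
                rep.add("fatal", "codings", row,
                        f"unknown character group {group_id!r}")
                continue
            for s in states:
                if not group.has_state(s):
                    rep.add("fatal", "codings", row,
                            f"state {s!r} not in vocabulary of group {group_id!r}")

    for taxon_id, codes in ds.distributions.items():
        if taxon_id not in taxa:
            rep.add("fatal", "distributions", taxon_id,
                    "distribution for unknown taxon")
            continue
        for code in codes:
            try:
                geo_qds.parse_qds(code)
            except geo_qds.QdsError:
                rep.add("warning", "distributions", f"{taxon_id}/{code}",
                        f"QDS code {code!r} outside the geocoder domain; "
                        f"carried as an opaque label")

    for idx, p in enumerate(ds.points):
        if p.taxon_id not in taxa:
            rep.add("fatal", "points", f"row {idx + 1}",
                    f"point for unknown taxon {p.taxon_id!r}")

    for t in ds.terminal_taxa():
        if not any(ds.coding(t.taxon_id, g.group_id) for g in ds.schema):
            rep.add("warning", "taxa", t.taxon_id,
                    "accepted taxon with no codings in any group")
        if not ds.distributions.get(t.taxon_id):
            rep.add("warning", "taxa", t.taxon_id,
                    "accepted taxon with no QDS distribution")

    return rep


# ---------------------------------------------------------------------------
# CSV input/output

TAXA_COLUMNS = ("taxon_id", "name", "rank", "parent_id", "status",
                "accepted_id", "wfo_id", "iucn", "sort_schumann", "sort_idno")
CODINGS_COLUMNS = ("taxon_id", "group_id", "states")
DISTRIBUTIONS_COLUMNS = ("taxon_id", "qds")
POINTS_COLUMNS = ("taxon_id", "latitude", "longitude", "source_label",
                  "source_url")

STATE_SEPARATOR = "|"


def _read_rows(path: str | Path, columns: Sequence[str]) -> Iterator[tuple[int, dict[str, str]]]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return
        if tuple(reader.fieldnames) != tuple(columns):
            raise DatasetError(
                f"{path.name}: header {reader.fieldnames} does not match the "
                f"canonical columns {list(columns)}")
        for record in reader:
            if None in record or any(v is None for v in record.values()):
                raise DatasetError(
                    f"{path.name}, line {reader.line_num}: wrong field count")
            yield reader.line_num, record


def load_dataset(
    taxa_path: str | Path,
    codings_path: str | Path,
    distributions_path: str | Path,
    points_path: str | Path,
    schema: Optional[CharacterSchema] = None,
) -> KeyDataset:
    """Read the four canonical CSV tables into a validated dataset.

    Unknown state tokens, dangling ids and duplicate (taxon, group)
    codings are fatal and raise :class:`DatasetError` with a file/line
    locator.  Validation warnings (incompleteness) do not block
    loading.
    """
    schema = schema or default_schema()
    taxa: dict[str, TaxonRecord] = {}
    for line, rec in _read_rows(taxa_path, TAXA_COLUMNS):
        tid = rec["taxon_id"].strip()
        if tid in taxa:
            raise DatasetError(f"taxa.csv, line {line}: duplicate taxon_id {tid!r}")
        sort_keys = {}
        if rec["sort_schumann"]:
            sort_keys["schumann"] = rec["sort_schumann"]
        if rec["sort_idno"]:
            sort_keys["idno"] = rec["sort_idno"]
        try:
            taxa[tid] = TaxonRecord(
                taxon_id=tid,
                name=rec["name"],
                rank=rec["rank"] or "species",
                parent_id=rec["parent_id"] or None,
                status=rec["status"] or "accepted",
                accepted_id=rec["accepted_id"] or None,
                wfo_id=rec["wfo_id"] or None,
                iucn_category=rec["iucn"] or None,
                sort_keys=sort_keys,
            )
        except ValueError as exc:
            raise DatasetError(f"taxa.csv, line {line}: {exc}") from exc

    codings: dict[str, dict[str, frozenset[str]]] = {}
    for line, rec in _read_rows(codings_path, CODINGS_COLUMNS):
        tid = rec["taxon_id"].strip()
        try:
            group = schema.group(rec["group_id"])
        except DatasetError as exc:
            raise DatasetError(f"codings.csv, line {line}: {exc}") from exc
        per_taxon = codings.setdefault(tid, {})
        if group.group_id in per_taxon:
            raise DatasetError(
                f"codings.csv, line {line}: duplicate coding for "
                f"({tid!r}, {group.group_id!r})")
        raw = rec["states"].strip()
        tokens = [t for t in raw.split(STATE_SEPARATOR) if t.strip()] if raw else []
        try:
            states = frozenset(group.resolve_state(t) for t in tokens)
        except DatasetError as exc:
            raise DatasetError(f"codings.csv, line {line}: {exc}") from exc
        if states:
            per_taxon[group.group_id] = states
        # an explicitly empty cell is simply a missing coding

    distributions: dict[str, set[str]] = {}
    for line, rec in _read_rows(distributions_path, DISTRIBUTIONS_COLUMNS):
        tid = rec["taxon_id"].strip()
        code = rec["qds"].strip()
        if not code:
            raise DatasetError(f"distributions.csv, line {line}: empty QDS code")
        distributions.setdefault(tid, set()).add(code)

    points: list[OccurrencePoint] = []
    for line, rec in _read_rows(points_path, POINTS_COLUMNS):
        try:
            points.append(OccurrencePoint(
                taxon_id=rec["taxon_id"].strip(),
                latitude=float(rec["latitude"]),
                longitude=float(rec["longitude"]),
                source_label=rec["source_label"],
                source_url=rec["source_url"] or None,
            ))
        except ValueError as exc:
            raise DatasetError(f"points.csv, line {line}: {exc}") from exc

    ds = KeyDataset(
        schema=schema,
        taxa=taxa,
        codings={t: dict(g) for t, g in codings.items()},
        distributions={t: frozenset(c) for t, c in distributions.items()},
        points=points,
    )
    report = validate_dataset(ds)
    if not report.ok():
        first = report.fatal[0]
        raise DatasetError(
            f"dataset fails validation with {len(report.fatal)} fatal "
            f"error(s); first: [{first.table} {first.row}] {first.message}")
    return ds


def write_dataset(ds: KeyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four canonical CSVs; inverse of :func:`load_dataset`.

    Rows are emitted in deterministic order (taxa in insertion order,
    codings in schema order, states and codes sorted) so identical
    datasets serialise byte-for-byte identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv"
             for name in ("taxa", "codings", "distributions", "points")}

    with open(paths["taxa"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TAXA_COLUMNS)
        for t in ds.taxa.values():
            w.writerow([
                t.taxon_id, t.name, t.rank, t.parent_id or "", t.status,
                t.accepted_id or "", t.wfo_id or "", t.iucn_category or "",
                t.sort_keys.get("schumann", ""), t.sort_keys.get("idno", ""),
            ])

    group_order = {g.group_id: i for i, g in enumerate(ds.schema)}
    with open(paths["codings"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CODINGS_COLUMNS)
        for tid in ds.taxa:
            per_group = ds.codings.get(tid, {})
            for gid in sorted(per_group, key=lambda g: group_order.get(g, 99)):
                w.writerow([tid, gid, STATE_SEPARATOR.join(sorted(per_group[gid]))])

    with open(paths["distributions"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DISTRIBUTIONS_COLUMNS)
        for tid in ds.taxa:
            for code in sorted(ds.distributions.get(tid, ())):
                w.writerow([tid, code])

    with open(paths["points"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(POINTS_COLUMNS)
        for p in ds.points:
            w.writerow([p.taxon_id, repr(p.latitude), repr(p.longitude),
                        p.source_label, p.source_url or ""])

    return paths


# ---------------------------------------------------------------------------
# name lookup


def find_name(ds: KeyDataset, query: str) -> list[tuple[TaxonRecord, str]]:
    """Case-insensitive substring search over all names in the checklist.

    Every hit is labelled ``accepted``, ``synonym-of-<accepted name>``
    or ``unplaced``, so that any published name — including synonyms
    and names that cannot be attributed to a known taxon — leads back
    to something the key can act on.  Returns an empty list on no
    match.
    """
    needle = collation_key(query)
    if not needle:
        return []
    hits: list[tuple[TaxonRecord, str]] = []
    for t in ds.taxa.values():
        if needle not in collation_key(t.name):
            continue
        if t.status == "accepted":
            kind = "accepted"
        elif t.status == "synonym":
            target = ds.taxa.get(t.accepted_id or "")
            kind = f"synonym-of-{target.name}" if target else "synonym-of-?"
        else:
            kind = "unplaced"
        hits.append((t, kind))
    hits.sort(key=lambda pair: collation_key(pair[0].name))
    return hits
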