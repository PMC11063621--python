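"""Quarter-degree-square (QDS) geocoding and KML distribution mapping.

The southern-African herbarium convention grids the map into degree
cells named by integer degrees south then east (e.g. ``3318`` = 33°S,
18°E, measured from the cell's NW origin), subdivided twice by letters
A–D read row-major from the NW corner (A=NW, B=NE, C=SW, D=SE): first
into 30′ quadrants, then into 15′ quarters of roughly 25 km per side.
``3318CD`` is therefore the 15′ cell spanning 33.75–34.00°S,
18.25–18.50°E.

Distribution summaries live at QDS resolution; occurrence points are
individual georeferenced records.  Both are exported together to KML
(grid polygons plus point placemarks) for display in Google Earth, and
compared against each other to flag gaps (cells without points, points
outside coded cells).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from .matrix_model import KeyDataset, TaxonRecord

__all__ = [
    "QdsCode",
    "BBox",
    "OccurrencePoint",
    "KmlExportOptions",
    "CoverageReport",
    "QdsError",
    "GeoWarning",
    "parse_qds",
    "qds_bbox",
    "point_to_qds",
    "taxa_per_qds",
    "export_kml",
    "coverage_report",
    "check_kml",
    "KML_NS",
]

KML_NS = "http://www.opengis.net/kml/2.2"

_LETTERS = "ABCD"


class QdsError(ValueError):
    """A QDS code is malformed or a point lies outside the S/E domain."""


class GeoWarning(UserWarning):
    """Non-fatal mapping diagnostics (empty exports, opaque codes)."""


@dataclass(frozen=True)
class QdsCode:
    """A quarter-degree square, e.g. ``3318CD``.

    ``lat_deg``/``lon_deg`` are the positive magnitudes of the degree
    cell's NW origin (degrees south, degrees east); ``quadrant`` picks
    the 30′ sub-cell and ``quarter`` the 15′ cell within it.
    """

    lat_deg: int
    lon_deg: int
    quadrant: str
    quarter: str

    def __post_init__(self) -> None:
        if not (0 <= self.lat_deg <= 89):
            raise QdsError(f"lat_deg {self.lat_deg} out of range 0..89")
        # the 4-digit canonical form cannot express longitudes >= 100 E
        if not (0 <= self.lon_deg <= 99):
            raise QdsError(f"lon_deg {self.lon_deg} out of range 0..99")
        for letter in (self.quadrant, self.quarter):
            if letter not in _LETTERS:
                raise QdsError(f"subdivision letter {letter!r} not in A-D")

    @property
    def code(self) -> str:
        return f"{self.lat_deg:02d}{self.lon_deg:02d}{self.quadrant}{self.quarter}"

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class BBox:
    """The 15′ × 15′ geographic box of a QDS (degrees, negative = south)."""

    south: float
    north: float
    west: float
    east: float

    def __post_init__(self) -> None:
        if not (self.south < self.north and self.west < self.east):
            raise ValueError("degenerate bbox")
        if not (math.isclose(self.north - self.south, 0.25)
                and math.isclose(self.east - self.west, 0.25)):
            raise ValueError("QDS bbox must be exactly 0.25 degrees per side")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.south + self.north) / 2, (self.west + self.east) / 2)

    def contains(self, latitude: float, longitude: float) -> bool:
        """Half-open containment: the low-magnitude (north/west) edges
        are inclusive so every point falls in exactly one QDS."""
        return (self.north >= latitude > self.south
                and self.west <= longitude < self.east)


@dataclass(frozen=True)
class OccurrencePoint:
    """One georeferenced occurrence record (WGS84 decimal degrees)."""

    taxon_id: str
    latitude: float
    longitude: float
    source_label: str = ""
    source_url: Optional[str] = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError(f"longitude {self.longitude} out of range")


def parse_qds(text: str) -> QdsCode:
    """Parse a QDS code like ``"3318CD"``; whitespace and case tolerated."""
    token = str(text).strip().upper()
    if len(token) != 6:
        raise QdsError(f"QDS code {text!r}: expected 4 digits + 2 letters")
    digits, letters = token[:4], token[4:]
    if not digits.isdigit():
        raise QdsError(f"QDS code {text!r}: degrees must be numeric")
    for letter in letters:
        if letter not in _LETTERS:
            raise QdsError(f"QDS code {text!r}: letter {letter!r} not in A-D")
    return QdsCode(int(digits[:2]), int(digits[2:]), letters[0], letters[1])


def _letter_offsets(letter: str) -> tuple[int, int]:
    # row counted southwards from the NW corner, column eastwards
    idx = _LETTERS.index(letter)
    return idx // 2, idx % 2


def qds_bbox(qds: QdsCode | str) -> BBox:
    """The 15′ box of a QDS, by successive NW-origin subdivision."""
    if isinstance(qds, str):
        qds = parse_qds(qds)
    north = -float(qds.lat_deg)
    west = float(qds.lon_deg)
    row, col = _letter_offsets(qds.quadrant)
    north -= 0.5 * row
    west += 0.5 * col
    row, col = _letter_offsets(qds.quarter)
    north -= 0.25 * row
    west += 0.25 * col
    return BBox(south=north - 0.25, north=north, west=west, east=west + 0.25)


def point_to_qds(point: OccurrencePoint | tuple[float, float]) -> QdsCode:
    """The unique QDS containing a point in the southern/eastern domain.

    Containment is half-open in degrees-south/degrees-east magnitude
    space (the low-magnitude edges of each cell are inclusive), so the
    16 quarters of a degree cell tile it without overlap or gap.
    Points outside the domain raise :class:`QdsError` rather than
    being silently dropped.
    """
    if isinstance(point, OccurrencePoint):
        lat, lon = point.latitude, point.longitude
    else:
        lat, lon = point
    if not (lat < 0 and lon > 0):
        raise QdsError(
            f"point ({lat}, {lon}) outside the southern/eastern QDS domain")
    lat_s, lon_e = -lat, lon
    lat_deg, lon_deg = int(lat_s // 1), int(lon_e // 1)
    if lat_deg > 89 or lon_deg > 99:
        raise QdsError(f"point ({lat}, {lon}) outside the QDS grid")
    lat_q = min(3, int((lat_s - lat_deg) * 4))
    lon_q = min(3, int((lon_e - lon_deg) * 4))
    quadrant = _LETTERS[(lat_q // 2) * 2 + (lon_q // 2)]
    quarter = _LETTERS[(lat_q % 2) * 2 + (lon_q % 2)]
    return QdsCode(lat_deg, lon_deg, quadrant, quarter)


def taxa_per_qds(ds: "KeyDataset", qds: QdsCode | str) -> list["TaxonRecord"]:
    """All taxa whose QDS distribution contains the code, name-sorted.

    An inclusive species and its subspecies are separate records: both
    are listed when both are coded for the cell.
    """
    from .matrix_model import collation_key

    wanted = str(qds).strip().upper() if isinstance(qds, str) else qds.code
    parse_qds(wanted)  # reject malformed queries early
    hits = [ds.taxa[tid] for tid, codes in ds.distributions.items()
            if any(c.strip().upper() == wanted for c in codes)]
    hits.sort(key=lambda t: collation_key(t.name))
    return hits


# ---------------------------------------------------------------------------
# KML export


@dataclass(frozen=True)
class KmlExportOptions:
    """Options for a KML export.

    ``point_limit`` caps the number of point placemarks per export
    call (default 5000, keeping documents manageable for the most
    densely recorded taxa); the first ``point_limit`` records in input
    order are kept, deterministically.
    """

    point_limit: int = 5000
    include_grid: bool = True
    include_points: bool = True
    palette: tuple[str, ...] = (
        # KML aabbggrr; red first for the inclusive species, then the
        # subspecies colours in name order
        "ff0000ff",  # red
        "ff00a5ff",  # orange
        "ff00b400",  # green
        "ff8b0000",  # dark blue
        "ff800080",  # purple
        "ffe6d8ad",  # light blue
        "ff00ffff",  # yellow
        "ffff00ff",  # magenta
    )

    def __post_init__(self) -> None:
        if self.point_limit < 1:
            raise ValueError("point_limit must be >= 1")


def _taxon_colour_order(ds: "KeyDataset", taxon_ids: Sequence[str]) -> list[str]:
    """Colour assignment order: inclusive species first (red), then the
    remaining taxa in name order."""
    from .matrix_model import collation_key

    records = [ds.taxa[t] for t in taxon_ids]
    species = sorted((t for t in records if t.rank == "species"),
                     key=lambda t: collation_key(t.name))
    infra = sorted((t for t in records if t.rank != "species"),
                   key=lambda t: collation_key(t.name))
    return [t.taxon_id for t in species + infra]


def _ring_coordinates(box: BBox) -> str:
    corners = [
        (box.west, box.south), (box.east, box.south),
        (box.east, box.north), (box.west, box.north),
        (box.west, box.south),  # ring closure
    ]
    return " ".join(f"{lon:.6f},{lat:.6f},0" for lon, lat in corners)


def export_kml(
    ds: "KeyDataset",
    taxon_ids: Sequence[str],
    options: KmlExportOptions | None = None,
) -> str:
    """Build a KML 2.2 document mapping the given taxa.

    One polygon per (taxon, QDS) grid square inside a "QDS" folder,
    one point placemark per occurrence record (up to
    ``options.point_limit``, in input order) in per-taxon folders, with
    source label and link in each placemark description.  Each taxon
    gets a distinct style colour, the inclusive species red.

    Distribution codes that do not parse as QDS are skipped with a
    :class:`GeoWarning`; an export with no mappable data yields an
    empty but well-formed document, also with a warning.
    """
    options = options or KmlExportOptions()
    if not taxon_ids:
        raise ValueError("export_kml needs at least one taxon")
    resolved = [ds.resolve_taxon(t).taxon_id for t in taxon_ids]
    if len(set(resolved)) != len(resolved):
        raise ValueError("duplicate taxa in export list")

    nsmap = {None: KML_NS}
    kml = etree.Element(f"{{{KML_NS}}}kml", nsmap=nsmap)
    doc = etree.SubElement(kml, f"{{{KML_NS}}}Document")
    etree.SubElement(doc, f"{{{KML_NS}}}name").text = "Erica distribution map"

    ordered = _taxon_colour_order(ds, resolved)
    colour = {tid: options.palette[i % len(options.palette)]
              for i, tid in enumerate(ordered)}
    for tid in ordered:
        style = etree.SubElement(doc, f"{{{KML_NS}}}Style", id=f"taxon-{tid}")
        line = etree.SubElement(style, f"{{{KML_NS}}}LineStyle")
        etree.SubElement(line, f"{{{KML_NS}}}color").text = colour[tid]
        etree.SubElement(line, f"{{{KML_NS}}}width").text = "2"
        poly = etree.SubElement(style, f"{{{KML_NS}}}PolyStyle")
        # translucent fill in the taxon colour
        etree.SubElement(poly, f"{{{KML_NS}}}color").text = "66" + colour[tid][2:]
        icon = etree.SubElement(style, f"{{{KML_NS}}}IconStyle")
        etree.SubElement(icon, f"{{{KML_NS}}}color").text = colour[tid]

    mapped_anything = False

    if options.include_grid:
        grid_folder = etree.SubElement(doc, f"{{{KML_NS}}}Folder")
        etree.SubElement(grid_folder, f"{{{KML_NS}}}name").text = "QDS"
        for tid in ordered:
            for code in sorted(ds.distributions.get(tid, ())):
                try:
                    box = qds_bbox(parse_qds(code))
                except QdsError:
                    warnings.warn(
                        f"taxon {tid}: QDS code {code!r} outside the geocoder "
                        f"domain; not mapped", GeoWarning, stacklevel=2)
                    continue
                pm = etree.SubElement(grid_folder, f"{{{KML_NS}}}Placemark")
                etree.SubElement(pm, f"{{{KML_NS}}}name").text = (
                    f"{ds.taxa[tid].name} {code}")
                etree.SubElement(pm, f"{{{KML_NS}}}styleUrl").text = f"#taxon-{tid}"
                polygon = etree.SubElement(pm, f"{{{KML_NS}}}Polygon")
                outer = etree.SubElement(polygon, f"{{{KML_NS}}}outerBoundaryIs")
                ring = etree.SubElement(outer, f"{{{KML_NS}}}LinearRing")
                etree.SubElement(ring, f"{{{KML_NS}}}coordinates").text = (
                    _ring_coordinates(box))
                mapped_anything = True

    if options.include_points:
        budget = options.point_limit
        selected = set(ordered)
        per_taxon: dict[str, list[OccurrencePoint]] = {t: [] for t in ordered}
        for p in ds.points:  # input order, truncated deterministically
            if p.taxon_id in selected and budget > 0:
                per_taxon[p.taxon_id].append(p)
                budget -= 1
        for tid in ordered:
            pts = per_taxon[tid]
            if not pts:
                continue
            folder = etree.SubElement(doc, f"{{{KML_NS}}}Folder")
            etree.SubElement(folder, f"{{{KML_NS}}}name").text = ds.taxa[tid].name
            for p in pts:
                pm = etree.SubElement(folder, f"{{{KML_NS}}}Placemark")
                etree.SubElement(pm, f"{{{KML_NS}}}name").text = ds.taxa[tid].name
                etree.SubElement(pm, f"{{{KML_NS}}}styleUrl").text = f"#taxon-{tid}"
                desc = p.source_label or "occurrence record"
                if p.source_url:
                    desc += f' — <a href="{p.source_url}">{p.source_url}</a>'
                etree.SubElement(pm, f"{{{KML_NS}}}description").text = desc
                pt = etree.SubElement(pm, f"{{{KML_NS}}}Point")
                etree.SubElement(pt, f"{{{KML_NS}}}coordinates").text = (
                    f"{p.longitude:.6f},{p.latitude:.6f},0")
                mapped_anything = True

    if not mapped_anything:
        warnings.warn("no mappable data for the requested taxa",
                      GeoWarning, stacklevel=2)

    return etree.tostring(kml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


def check_kml(kml_text: str | bytes) -> list[str]:
    """Structural validation of a KML 2.2 document.

    Checks well-formedness, the KML 2.2 namespace, Document presence,
    polygon ring closure (first vertex equals last, at least four
    vertices) and point coordinate arity.  Returns a list of problems;
    empty means the document passed.
    """
    problems: list[str] = []
    data = kml_text.encode("utf-8") if isinstance(kml_text, str) else kml_text
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != f"{{{KML_NS}}}kml":
        problems.append(f"root element {root.tag!r} is not KML 2.2 <kml>")
        return problems
    if root.find(f"{{{KML_NS}}}Document") is None:
        problems.append("missing <Document>")
    for ring in root.iter(f"{{{KML_NS}}}LinearRing"):
        coords = ring.findtext(f"{{{KML_NS}}}coordinates", "").split()
        if len(coords) < 4:
            problems.append("LinearRing with fewer than 4 vertices")
        elif coords[0] != coords[-1]:
            problems.append("LinearRing not closed (first vertex != last)")
    for pt in root.iter(f"{{{KML_NS}}}Point"):
        coords = pt.findtext(f"{{{KML_NS}}}coordinates", "").split()
        if len(coords) != 1:
            problems.append("Point with other than one coordinate tuple")
        else:
            parts = coords[0].split(",")
            if len(parts) not in (2, 3):
                problems.append(f"Point coordinate {coords[0]!r} malformed")
    for pm in root.iter(f"{{{KML_NS}}}Placemark"):
        if (pm.find(f"{{{KML_NS}}}Point") is None
                and pm.find(f"{{{KML_NS}}}Polygon") is None):
            problems.append("Placemark with no geometry")
    return problems


# ---------------------------------------------------------------------------
# coverage


@dataclass(frozen=True)
class CoverageReport:
    """Grid-vs-point coverage gaps for one taxon.

    ``qds_without_points``: coded cells containing none of the taxon's
    points — possible recording gaps.  ``points_outside_coded_qds``:
    points falling in no coded cell — possible distribution-table gaps
    or georeferencing errors.  Either side being nonempty flags data
    worth further investigation, not necessarily an error.
    """

    qds_without_points: frozenset[str]
    points_outside_coded_qds: tuple[OccurrencePoint, ...]


def coverage_report(ds: "KeyDataset", taxon_id: str) -> CoverageReport:
    """Compare a taxon's QDS distribution against its occurrence points."""
    taxon = ds.resolve_taxon(taxon_id)
    coded: dict[str, str] = {}  # canonical -> as-stored
    for code in ds.distributions.get(taxon.taxon_id, ()):
        try:
            coded[parse_qds(code).code] = code
        except QdsError:
            warnings.warn(
                f"taxon {taxon.taxon_id}: QDS code {code!r} outside the "
                f"geocoder domain; excluded from coverage", GeoWarning,
                stacklevel=2)
    hit: set[str] = set()
    outside: list[OccurrencePoint] = []
    for p in ds.points:
        if p.taxon_id != taxon.taxon_id:
            continue
        try:
            cell = point_to_qds(p).code
        except QdsError:
            outside.append(p)
            continue
        if cell in coded:
            hit.add(cell)
        else:
            outside.append(p)
    without = frozenset(coded[c] for c in coded if c not in hit)
    return CoverageReport(qds_without_points=without,
                          points_outside_coded_qds=tuple(outside))
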