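"""Sequence-quality, translation, and geographic record filters.

All filters are pure predicates over a harmonized record, so their keep/drop
outcome is independent of application order.  The translation check uses the
invertebrate mitochondrial genetic code (NCBI table 5) by default, which is
the appropriate code for animal CO1 barcodes; a record passes when at least
one of the three forward reading frames is free of stop codons (barcodes are
deposited in coding orientation, so reverse frames are not checked).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from shapely.geometry import Point, Polygon, shape

from .harmonize import HarmonizedRecord
from .taxonomy import RANK_INDEX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Quality-filter thresholds.

    max_n bounds the count of 'N' bases (other ambiguity codes are counted
    separately via max_ambiguous, unbounded by default); lengths are in base
    pairs; min_rank requires identification at least that fine (None
    disables the rank filter); translation_check is off | warn | drop.
    """

    max_n: int = 5
    min_length: int = 400
    max_length: int = 2000
    min_rank: Optional[str] = None
    max_ambiguous: Optional[int] = None
    translation_check: str = "warn"
    genetic_code_table: int = 5

    def __post_init__(self):
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")
        if self.max_n < 0:
            raise ValueError("max_n must be non-negative")
        if self.min_rank is not None and self.min_rank not in RANK_INDEX:
            raise ValueError(f"unknown rank {self.min_rank!r}")
        if self.translation_check not in ("off", "warn", "drop"):
            raise ValueError("translation_check must be off|warn|drop")


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: Optional[str] = None  # first failing rule, None when kept


_AMBIGUOUS = frozenset("RYSWKMBDHVN")


def quality_filter(record: HarmonizedRecord, config: FilterConfig) -> FilterDecision:
    """Drop on too many Ns, length out of bounds, or too-coarse resolution."""
    seq = record.sequence
    if seq.count("N") > config.max_n:
        return FilterDecision(False, "max_n")
    if not (config.min_length <= len(seq) <= config.max_length):
        return FilterDecision(False, "length")
    if config.max_ambiguous is not None:
        if sum(seq.count(c) for c in _AMBIGUOUS) > config.max_ambiguous:
            return FilterDecision(False, "max_ambiguous")
    if config.min_rank is not None:
        if record.lineage.resolution_index() < RANK_INDEX[config.min_rank]:
            return FilterDecision(False, "rank")
    return FilterDecision(True)


def translates_in_any_frame(sequence: str, code_table: int = 5) -> bool:
    """True if any of the 3 forward frames is stop-free (trailing partial
    codon ignored) under the given genetic code."""
    for frame in range(3):
        sub = sequence[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        if "*" not in str(Seq(sub).translate(table=code_table)):
            return True
    return False


def translation_filter(record: HarmonizedRecord, config: FilterConfig) -> str:
    """Return "keep", "warn", or "drop" per the configured policy."""
    if config.translation_check == "off" or len(record.sequence) < 6:
        return "keep"
    if translates_in_any_frame(record.sequence, config.genetic_code_table):
        return "keep"
    if config.translation_check == "drop":
        return "drop"
    logger.warning(
        "record %s does not translate in any forward frame", record.record_id
    )
    return "warn"


# -- geography ----------------------------------------------------------------


class Gazetteer:
    """Country -> (continent, biogeographic realm) lookup table."""

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        self._rows = {c.lower(): (c, cont, realm) for c, cont, realm in rows}

    @classmethod
    def from_tsv(cls, path) -> "Gazetteer":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    rows.append((parts[0], parts[1], parts[2]))
        return cls(rows)

    @classmethod
    def default(cls) -> "Gazetteer":
        """Built-in country -> continent / realm table."""
        text = (
            resources.files("barcodedb.data")
            .joinpath("gazetteer.tsv")
            .read_text(encoding="utf-8")
        )
        rows = []
        for line in text.splitlines()[1:]:
            parts = line.split("\t")
            if len(parts) >= 3:
                rows.append((parts[0], parts[1], parts[2]))
        return cls(rows)

    def labels(self, country: str) -> set[str]:
        hit = self._rows.get(country.strip().lower())
        if hit is None:
            logger.warning("unknown country %r", country)
            return set()
        return set(hit)

    def countries(self) -> list[str]:
        return [c for c, _, _ in self._rows.values()]


def load_geojson_polygons(path) -> list[tuple[str, Polygon]]:
    """Read named polygons/multipolygons from a GeoJSON file.

    The region name is taken from the feature's "name" property (falling
    back to "Name" or the feature index).
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    features = data.get("features", [data] if data.get("geometry") else [])
    out = []
    for i, feat in enumerate(features):
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            logger.warning("skipping non-polygon geometry %s", geom.geom_type)
            continue
        props = feat.get("properties") or {}
        name = props.get("name") or props.get("Name") or f"region_{i}"
        out.append((name, geom))
    return out


def polygons_from_rings(
    named_rings: Iterable[tuple[str, Sequence[tuple[float, float]]]]
) -> list[tuple[str, Polygon]]:
    """Build named polygons from (lon, lat) WGS84 closed rings."""
    return [(name, Polygon(ring)) for name, ring in named_rings]


@dataclass(frozen=True)
class RegionSpec:
    """Geographic scope: countries, continents, realms, or custom polygons."""

    kind: str  # country | continent | biogeographic_realm | custom_polygon
    names: tuple[str, ...] = ()
    polygons: tuple[tuple[str, Polygon], ...] = ()

    def __post_init__(self):
        if self.kind == "custom_polygon":
            if not self.polygons:
                raise ValueError("custom_polygon spec needs at least one polygon")
        elif not self.names:
            raise ValueError(f"{self.kind} spec needs at least one name")

    def target_labels(self) -> set[str]:
        if self.kind == "custom_polygon":
            return {name for name, _ in self.polygons}
        return set(self.names)


def assign_region(
    record: HarmonizedRecord,
    gazetteer: Gazetteer,
    polygons: Sequence[tuple[str, Polygon]] = (),
) -> set[str]:
    """Region labels from country text unioned with point-in-polygon labels.

    Polygon membership is boundary-inclusive; coordinates are (lon, lat)
    WGS84 as is shapefile practice.
    """
    labels: set[str] = set()
    src = record.record
    if src.country:
        labels |= gazetteer.labels(src.country)
    if src.latitude is not None and src.longitude is not None and polygons:
        pt = Point(src.longitude, src.latitude)
        for name, poly in polygons:
            if poly.covers(pt):
                labels.add(name)
    return labels


def region_filter(
    record: HarmonizedRecord, spec: RegionSpec, gazetteer: Gazetteer
) -> bool:
    """Keep iff the record's region labels intersect the spec.

    Records with no usable location information are dropped whenever a
    region filter is active.
    """
    labels = assign_region(record, gazetteer, spec.polygons)
    return bool(labels & spec.target_labels())
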