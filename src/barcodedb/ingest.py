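"""Parsers for the three barcode source dialects.

Three snapshot formats are consumed, all from local files (never the
network): NCBI GenBank flat files (GBFF), BOLD data-package TSV (one record
per row with rank columns and a nucleotide column), and GBOL release CSV.
Each parser yields :class:`SourceRecord` streams; ``repair_ranks`` fixes the
rank inconsistencies of GBOL-style lineages and ``merge_sources``
concatenates streams with provenance-tagged record ids.

All inputs are transparently accepted gzip-compressed (".gz" suffix).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

from .taxonomy import RANKS, _open_text

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted after gap stripping.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: Qualifier values recognized as the CO1 barcode marker in GenBank entries.
CO1_SYNONYMS = frozenset(
    {"cox1", "coi", "co1", "cytochrome c oxidase subunit i"}
)

#: Default BOLD/GBOL marker codes retained.
DEFAULT_MARKER_CODES = frozenset({"COI-5P"})

#: Positional rank labels assumed for unlabelled GBFF ORGANISM lineages.
GENBANK_LINEAGE_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class SourceRecord:
    """One specimen record from any source database.

    ``raw_lineage`` is an ordered tuple of (rank-label, name) pairs with
    unrestricted labels; ``raw_name`` is the lowest identification as given.
    Coordinates are decimal degrees WGS84.
    """

    source_db: str  # BOLD | GenBank | GBOL
    record_id: str
    raw_name: str
    raw_lineage: tuple[tuple[str, str], ...]
    sequence: str
    country: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    marker: str = "COI-5P"


@dataclass
class IngestStats:
    """Per-file skip counters updated by the readers."""

    n_read: int = 0
    n_no_marker: int = 0
    n_no_sequence: int = 0
    n_bad_row: int = 0


def _clean_sequence(raw: str) -> Optional[str]:
    """Uppercase, strip gaps and whitespace; None if empty or non-IUPAC."""
    seq = re.sub(r"[\s\-\.]", "", raw or "").upper()
    if not seq or set(seq) - IUPAC_DNA:
        return None
    return seq


def _parse_float(text: Optional[str], lo: float, hi: float) -> Optional[float]:
    if text is None or text.strip() == "":
        return None
    try:
        val = float(text)
    except ValueError:
        return None
    return val if lo <= val <= hi else None


def parse_lat_lon(text: str) -> tuple[Optional[float], Optional[float]]:
    """Parse a GenBank lat_lon qualifier like ``"52.52 N 13.40 E"``."""
    m = re.match(
        r"^\s*([0-9.]+)\s*([NS])\s+([0-9.]+)\s*([EW])\s*$", text or ""
    )
    if not m:
        return None, None
    lat = float(m.group(1)) * (1 if m.group(2) == "N" else -1)
    lon = float(m.group(3)) * (1 if m.group(4) == "E" else -1)
    if not (-90 <= lat <= 90 and -180 <= lon <= 180):
        return None, None
    return lat, lon


def split_country(text: Optional[str]) -> Optional[str]:
    """GenBank country qualifiers read "Country: locality"; keep the country."""
    if not text:
        return None
    return text.split(":", 1)[0].strip() or None


def _co1_feature(record) -> bool:
    for feat in record.features:
        if feat.type not in ("CDS", "gene", "misc_feature"):
            continue
        for key in ("gene", "product"):
            for val in feat.qualifiers.get(key, []):
                if val.strip().lower() in CO1_SYNONYMS:
                    return True
    return False


def read_genbank_flatfile(
    path, stats: Optional[IngestStats] = None
) -> Iterator[SourceRecord]:
    """Stream SourceRecords from a GenBank flat file (optionally gzipped).

    Entries without a CO1-annotated feature are skipped and counted.  The
    ORGANISM lineage is unlabelled in GBFF; standard rank labels are assigned
    positionally (kingdom, phylum, class, order, family, genus) so unmapped
    projection has something to work with; mapped harmonization only walks
    the names and ignores these labels.
    """
    stats = stats if stats is not None else IngestStats()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "genbank"):
            if not _co1_feature(rec):
                stats.n_no_marker += 1
                continue
            seq = _clean_sequence(str(rec.seq))
            if seq is None:
                stats.n_no_sequence += 1
                logger.warning("GBFF %s: empty or invalid sequence, skipped", rec.id)
                continue
            organism = rec.annotations.get("organism", "") or rec.id
            taxonomy = rec.annotations.get("taxonomy", [])
            labels = list(GENBANK_LINEAGE_RANKS) + ["clade"] * max(
                0, len(taxonomy) - len(GENBANK_LINEAGE_RANKS)
            )
            lineage = tuple(
                (lab, name) for lab, name in zip(labels, taxonomy) if name
            )
            country = None
            lat = lon = None
            for feat in rec.features:
                if feat.type != "source":
                    continue
                quals = feat.qualifiers
                raw_country = (quals.get("country") or quals.get("geo_loc_name") or [None])[0]
                country = split_country(raw_country)
                if "lat_lon" in quals:
                    lat, lon = parse_lat_lon(quals["lat_lon"][0])
            stats.n_read += 1
            yield SourceRecord(
                source_db="GenBank",
                record_id=rec.name or rec.id,
                raw_name=organism,
                raw_lineage=lineage,
                sequence=seq,
                country=country,
                latitude=lat,
                longitude=lon,
                marker="COI-5P",
            )


#: BOLD data-package rank columns, most inclusive first (no kingdom column).
BOLD_RANK_COLUMNS = (
    ("phylum", "phylum_name"),
    ("class", "class_name"),
    ("order", "order_name"),
    ("family", "family_name"),
    ("genus", "genus_name"),
    ("species", "species_name"),
)


def read_bold_tsv(
    path,
    marker_codes: Iterable[str] = DEFAULT_MARKER_CODES,
    stats: Optional[IngestStats] = None,
) -> Iterator[SourceRecord]:
    """Stream SourceRecords from a BOLD data-package TSV.

    Rows whose markercode is not in *marker_codes* are skipped and counted;
    rows without a nucleotide cell likewise.  A missing header is fatal.
    """
    stats = stats if stats is not None else IngestStats()
    markers = frozenset(marker_codes)
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"processid", "nucleotides"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValueError(f"BOLD TSV {path}: missing required header")
        for row in reader:
            marker = (row.get("markercode") or "").strip()
            if markers and marker not in markers:
                stats.n_no_marker += 1
                continue
            seq = _clean_sequence(row.get("nucleotides") or "")
            if seq is None:
                stats.n_no_sequence += 1
                continue
            lineage = tuple(
                (rank, row[col].strip())
                for rank, col in BOLD_RANK_COLUMNS
                if row.get(col, "").strip()
            )
            raw_name = lineage[-1][1] if lineage else ""
            stats.n_read += 1
            yield SourceRecord(
                source_db="BOLD",
                record_id=row["processid"].strip(),
                raw_name=raw_name,
                raw_lineage=lineage,
                sequence=seq,
                country=(row.get("country") or "").strip() or None,
                latitude=_parse_float(row.get("lat"), -90, 90),
                longitude=_parse_float(row.get("lon"), -180, 180),
                marker=marker,
            )


#: One concrete GBOL release CSV layout (fixed by the fixture generator).
GBOL_COLUMNS = {
    "id": "specimen_id",
    "ranks": (
        ("kingdom", "kingdom"),
        ("phylum", "phylum"),
        ("class", "class"),
        ("order", "order"),
        ("family", "family"),
        ("genus", "genus"),
        ("species", "species"),
    ),
    "sequence": "sequence",
    "marker": "marker",
    "country": "country",
    "latitude": "latitude",
    "longitude": "longitude",
}


def read_gbol_csv(
    path,
    marker_codes: Iterable[str] = DEFAULT_MARKER_CODES,
    columns: Optional[dict] = None,
    stats: Optional[IngestStats] = None,
) -> Iterator[SourceRecord]:
    """Stream SourceRecords from a GBOL release CSV (quoted fields honoured)."""
    stats = stats if stats is not None else IngestStats()
    cols = columns or GBOL_COLUMNS
    markers = frozenset(marker_codes)
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or cols["id"] not in reader.fieldnames:
            raise ValueError(f"GBOL CSV {path}: missing required header")
        for row in reader:
            marker = (row.get(cols["marker"]) or "").strip()
            if markers and marker and marker not in markers:
                stats.n_no_marker += 1
                continue
            seq = _clean_sequence(row.get(cols["sequence"]) or "")
            if seq is None:
                stats.n_no_sequence += 1
                continue
            lineage = tuple(
                (rank, row[col].strip())
                for rank, col in cols["ranks"]
                if row.get(col, "").strip()
            )
            raw_name = lineage[-1][1] if lineage else ""
            stats.n_read += 1
            yield SourceRecord(
                source_db="GBOL",
                record_id=row[cols["id"]].strip(),
                raw_name=raw_name,
                raw_lineage=lineage,
                sequence=seq,
                country=(row.get(cols["country"]) or "").strip() or None,
                latitude=_parse_float(row.get(cols["latitude"]), -90, 90),
                longitude=_parse_float(row.get(cols["longitude"]), -180, 180),
                marker=marker or "COI-5P",
            )


def repair_ranks(
    records: Iterable[SourceRecord],
    expected_ranks: Sequence[str] = RANKS,
) -> Iterator[SourceRecord]:
    """Insert missing rank labels so every lineage covers *expected_ranks*.

    Inserted ranks get an empty name; existing names are never altered.
    Labels outside *expected_ranks* are preserved after the canonical block.
    """
    expected = list(expected_ranks)
    for rec in records:
        have = {lab.lower(): name for lab, name in rec.raw_lineage}
        canonical = [(r, have.get(r, "")) for r in expected]
        extras = [
            (lab, name)
            for lab, name in rec.raw_lineage
            if lab.lower() not in expected
        ]
        yield replace(rec, raw_lineage=tuple(canonical + extras))


def merge_sources(*streams: Iterable[SourceRecord]) -> Iterator[SourceRecord]:
    """Concatenate source streams, prefixing ids with the source tag.

    Duplicate (source_db, record_id) pairs keep the first occurrence with a
    logged warning; the same plain id under different sources is legal.
    """
    seen: set[tuple[str, str]] = set()
    for stream in streams:
        for rec in stream:
            key = (rec.source_db, rec.record_id)
            if key in seen:
                logger.warning("duplicate record %s:%s dropped", *key)
                continue
            seen.add(key)
            yield replace(rec, record_id=f"{rec.source_db}:{rec.record_id}")
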