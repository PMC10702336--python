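"""Scope a reference database geographically.

Records carry country text and/or WGS84 coordinates.  Country names expand
to continent and biogeographic-realm labels via the gazetteer; coordinates
are tested against named polygons (boundary-inclusive).  A record passes a
region filter when any of its labels intersects the requested scope.
"""

from barcodedb import Gazetteer, RegionSpec, assign_region, region_filter
from barcodedb.filters import polygons_from_rings
from barcodedb.harmonize import HarmonizedRecord
from barcodedb.ingest import SourceRecord
from barcodedb.taxonomy import Lineage


def record(rid, country=None, lat=None, lon=None):
    src = SourceRecord(
        source_db="BOLD", record_id=rid, raw_name="Apis mellifera",
        raw_lineage=(("species", "Apis mellifera"),), sequence="ACGT" * 120,
        country=country, latitude=lat, longitude=lon,
    )
    return HarmonizedRecord(src, Lineage(species="Apis mellifera"),
                            "exact", "Apis mellifera", "Apis mellifera")


gazetteer = Gazetteer.default()
alps = polygons_from_rings(
    [("AlpineBox", [(5.9, 45.8), (13.8, 45.8), (13.8, 47.8), (5.9, 47.8),
                    (5.9, 45.8)])]
)

records = [
    record("R1", country="Germany"),
    record("R2", country="Canada"),
    record("R3", lat=46.5, lon=9.8),   # coordinates only, inside the box
    record("R4"),                       # no location information at all
]

for rec in records:
    labels = assign_region(rec, gazetteer, alps)
    print(f"{rec.record_id}: labels = {sorted(labels) or '(none)'}")

europe = RegionSpec("continent", ("Europe",))
box = RegionSpec("custom_polygon", polygons=tuple(alps))
print("kept by continent=Europe:",
      [r.record_id for r in records if region_filter(r, europe, gazetteer)])
print("kept by custom polygon:  ",
      [r.record_id for r in records if region_filter(r, box, gazetteer)])
# records without any location are always dropped while a region filter is on
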