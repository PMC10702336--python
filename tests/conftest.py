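"""Shared fixtures: a small synthetic dataset plus toy backbone stores."""

from __future__ import annotations

import pytest

from barcodedb import FixtureSpec, import_backbone
from barcodedb.fixtures import generate
from barcodedb.harmonize import HarmonizedRecord
from barcodedb.ingest import SourceRecord
from barcodedb.taxonomy import Lineage

SMALL_SPEC = FixtureSpec(
    seed=11,
    n_species=40,
    sequence_length=120,
    n_bold=15,
    n_genbank=10,
    n_gbol=10,
    n_queries=14,
    mutation_ks=(0, 1, 3, 5, 10, 30, 35),
)


@pytest.fixture(scope="session")
def small_truth(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_small")
    return generate(SMALL_SPEC, outdir)


@pytest.fixture(scope="session")
def small_backbone(small_truth):
    store, report = import_backbone(
        small_truth.backbone_dump, "gbif", homonym_list=small_truth.homonym_list
    )
    return store, report


TOY_GBIF_DUMP = """taxonID\tparentNameUsageID\tacceptedNameUsageID\tcanonicalName\ttaxonRank\ttaxonomicStatus
1\t\t\tAnimalia\tkingdom\taccepted
2\t1\t\tHymenoptera\torder\taccepted
3\t2\t\tApis\tgenus\taccepted
4\t3\t\tApis mellifera\tspecies\taccepted
5\t3\t4\tApis mellifica\tspecies\tsynonym
"""


@pytest.fixture()
def toy_store(tmp_path):
    dump = tmp_path / "toy_gbif.tsv"
    dump.write_text(TOY_GBIF_DUMP)
    store, report = import_backbone(dump, "gbif")
    return store, report


def make_record(record_id="BOLD:X1", sequence="ACGT" * 30, **kw) -> SourceRecord:
    defaults = dict(
        source_db="BOLD",
        record_id=record_id,
        raw_name="Apis mellifera",
        raw_lineage=(("genus", "Apis"), ("species", "Apis mellifera")),
        sequence=sequence,
    )
    defaults.update(kw)
    return SourceRecord(**defaults)


def make_harmonized(
    record_id: str,
    lineage: Lineage,
    sequence: str = "ACGT" * 30,
    action: str = "exact",
    **record_kw,
) -> HarmonizedRecord:
    rec = make_record(record_id=record_id, sequence=sequence, **record_kw)
    return HarmonizedRecord(
        record=rec,
        lineage=lineage,
        action=action,
        matched_name=lineage.resolution() and lineage.get(lineage.resolution()),
        original_name=rec.raw_name,
    )
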