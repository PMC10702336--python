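"""Deterministic synthetic fixtures with recorded ground truth.

The generator emulates, at toy scale, everything the pipeline consumes from
the real world: a GBIF-style backbone dump with synonyms and cross-kingdom
homonyms, a homonym list, source snapshots in the three dialects (GenBank
flat file, BOLD TSV, GBOL CSV) sharing sequences and species, a gazetteer,
custom GeoJSON regions, and a query FASTA of planted-mutation copies of
reference sequences.  Truth tables record per record the provided name, the
expected cleaned name, the expected harmonization action and lineage, the
expected quality-filter outcome, and the dereplication cluster key; per
query the planted substitution count and the expected identity bin.

Same seed, same spec -> byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .taxonomy import RANKS, Lineage
from .thid import round_half_up

_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "la", "me", "ni", "po", "ra",
    "su", "to", "ve", "xa", "zo", "chi", "dra", "phe", "lon", "mir",
)

_BASES = np.array(list("ACGT"))

_FIXTURE_COUNTRIES = (
    "Germany", "Canada", "Brazil", "Australia", "China",
    "Portugal", "Honduras", "Costa Rica",
)

_GAZETTEER_ROWS = {
    "Germany": ("Europe", "Palearctic"),
    "Canada": ("North America", "Nearctic"),
    "Brazil": ("South America", "Neotropic"),
    "Australia": ("Oceania", "Australasian"),
    "China": ("Asia", "Palearctic"),
    "Portugal": ("Europe", "Palearctic"),
    "Honduras": ("North America", "Neotropic"),
    "Costa Rica": ("North America", "Neotropic"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic study system; proportions are in [0, 1]."""

    seed: int = 0
    n_species: int = 100
    synonym_fraction: float = 0.10
    homonym_count: int = 2
    unmatched_fraction: float = 0.05
    open_nomenclature_fraction: float = 0.10
    missing_rank_fraction: float = 0.30
    duplicate_sequence_fraction: float = 0.20
    n_fraction: float = 0.05
    sequence_length: int = 658
    n_bold: int = 40
    n_genbank: int = 30
    n_gbol: int = 30
    n_orphans: int = 1
    n_queries: int = 30
    mutation_ks: tuple[int, ...] = (0, 1, 3, 5, 10, 30)
    coord_fraction: float = 0.6
    country_fraction: float = 0.85

    def __post_init__(self):
        for name in (
            "synonym_fraction", "unmatched_fraction", "open_nomenclature_fraction",
            "missing_rank_fraction", "duplicate_sequence_fraction", "n_fraction",
            "coord_fraction", "country_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        n_genera = max(6, self.n_species // 4)
        if self.homonym_count > n_genera:
            raise ValueError(
                f"homonym_count {self.homonym_count} exceeds the "
                f"{n_genera} genera the taxonomy will contain"
            )
        if max(self.mutation_ks, default=0) > self.sequence_length:
            raise ValueError("mutation count exceeds sequence length")

    @property
    def n_records(self) -> int:
        return self.n_bold + self.n_genbank + self.n_gbol


@dataclass
class FixtureTruth:
    """Paths of every generated file plus in-memory truth tables."""

    directory: Path
    backbone_dump: Path
    homonym_list: Path
    genbank_file: Path
    bold_file: Path
    gbol_file: Path
    gazetteer: Path
    regions: Path
    query_fasta: Path
    records: pd.DataFrame
    queries: pd.DataFrame
    summary: dict


class _Names:
    def __init__(self, rng):
        self._rng = rng
        self._used: set[str] = set()

    def fresh(self, capital: bool, n_syl: int = 3) -> str:
        while True:
            word = "".join(
                _SYLLABLES[self._rng.integers(len(_SYLLABLES))]
                for _ in range(n_syl)
            )
            if capital:
                word = word.capitalize()
            if word not in self._used:
                self._used.add(word)
                return word


@dataclass
class _Entity:
    """One true species of the synthetic world."""

    name: str  # accepted binomial (or fake binomial)
    genus: str
    lineage: Lineage  # full 7-rank true lineage
    sequence: str
    synonym_name: Optional[str] = None
    kind: str = "accepted"  # accepted | fake_genus


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(4, size=length)])


def _mutate(rng, seq: str, k: int) -> str:
    """Plant exactly k substitutions at distinct positions."""
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=k, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def _build_taxonomy(spec: FixtureSpec, rng, names: _Names):
    """Return (backbone rows, entities, homonym genera, plant rows)."""
    rows = []  # (taxonID, parentID, acceptedID, name, rank, status)
    by_id: dict[str, tuple] = {}
    next_id = [0]

    def add(name, rank, parent, status="accepted", accepted=""):
        next_id[0] += 1
        tid = str(next_id[0])
        row = (tid, parent or "", accepted, name, rank, status)
        rows.append(row)
        by_id[tid] = row
        return tid

    kingdom_id = add("Animalia", "kingdom", None)
    n_phyla, n_classes, n_orders = 2, 3, 4
    n_families = max(4, spec.n_species // 10)
    n_genera = max(6, spec.n_species // 4)

    phyla = [(add(names.fresh(True), "phylum", kingdom_id), None) for _ in range(n_phyla)]
    classes = []
    for _ in range(n_classes):
        pid = phyla[rng.integers(n_phyla)][0]
        classes.append(add(names.fresh(True), "class", pid))
    orders = [
        add(names.fresh(True), "order", classes[rng.integers(n_classes)])
        for _ in range(n_orders)
    ]
    families = [
        add(names.fresh(True), "family", orders[rng.integers(n_orders)])
        for _ in range(n_families)
    ]
    genera = []
    for _ in range(n_genera):
        fid = families[rng.integers(n_families)]
        gname = names.fresh(True)
        genera.append((add(gname, "genus", fid), gname, fid))

    def lineage_of(tid: str) -> Lineage:
        lin = Lineage()
        cur = tid
        while cur:
            row = by_id[cur]
            if row[4] in RANKS and lin.get(row[4]) is None:
                lin = lin.with_rank(row[4], row[3])
            cur = row[1]
        return lin

    entities: list[_Entity] = []
    for _ in range(spec.n_species):
        gid, gname, _fid = genera[rng.integers(n_genera)]
        binomial = f"{gname} {names.fresh(False)}"
        sid = add(binomial, "species", gid)
        entities.append(
            _Entity(
                name=binomial,
                genus=gname,
                lineage=lineage_of(sid),
                sequence=_random_seq(rng, spec.sequence_length),
            )
        )

    # synonyms: extra species-rank names pointing at accepted species
    n_syn = round(spec.synonym_fraction * spec.n_species)
    syn_targets = rng.permutation(spec.n_species)[:n_syn]
    by_name = {r[3]: r for r in rows}
    for i in syn_targets:
        ent = entities[i]
        syn_name = f"{ent.genus} {names.fresh(False)}"
        srow = by_name[ent.name]
        add(
            syn_name, "species", by_name[ent.genus][0],
            status="synonym", accepted=srow[0],
        )
        ent.synonym_name = syn_name

    # homonyms: the same genus name under a second (plant) kingdom
    homonym_genera: list[str] = []
    if spec.homonym_count:
        plant_kid = add("Plantae", "kingdom", None)
        plant_phy = add(names.fresh(True), "phylum", plant_kid)
        plant_cls = add(names.fresh(True), "class", plant_phy)
        plant_ord = add(names.fresh(True), "order", plant_cls)
        plant_fam = add(names.fresh(True), "family", plant_ord)
        picks = rng.permutation(n_genera)[: spec.homonym_count]
        for gi in picks:
            gname = genera[gi][1]
            add(gname, "genus", plant_fam)
            homonym_genera.append(gname)

    # fake genera: names absent from the backbone, real family
    n_fake = round(spec.unmatched_fraction * spec.n_species)
    for _ in range(n_fake):
        fid = families[rng.integers(n_families)]
        gname = names.fresh(True)
        binomial = f"{gname} {names.fresh(False)}"
        lin = lineage_of(fid).with_rank("genus", gname).with_rank("species", binomial)
        entities.append(
            _Entity(
                name=binomial,
                genus=gname,
                lineage=lin,
                sequence=_random_seq(rng, spec.sequence_length),
                kind="fake_genus",
            )
        )

    return rows, entities, homonym_genera


def _expected_lineage(ent: _Entity, story: str) -> Lineage:
    if story in ("exact", "synonym"):
        return ent.lineage
    if story in ("open_nom", "homonym_genus"):
        return ent.lineage.truncate_below("genus").with_rank("genus", ent.genus)
    if story == "fallback":
        return ent.lineage.truncate_below("family")
    return Lineage()  # orphan


def generate(spec: FixtureSpec, outdir) -> FixtureTruth:
    """Write all fixture files into *outdir* and return truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    names = _Names(rng)

    backbone_rows, entities, homonym_genera = _build_taxonomy(spec, rng, names)
    accepted = [e for e in entities if e.kind == "accepted"]
    fakes = [e for e in entities if e.kind == "fake_genus"]
    with_synonym = [e for e in accepted if e.synonym_name]
    ent_by_genus = {e.genus: e for e in accepted}

    # -- backbone dump + homonym list ------------------------------------
    backbone_path = outdir / "backbone_gbif.tsv"
    with open(backbone_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "taxonID\tparentNameUsageID\tacceptedNameUsageID\t"
            "canonicalName\ttaxonRank\ttaxonomicStatus\n"
        )
        for tid, parent, acc, name, rank, status in backbone_rows:
            fh.write(f"{tid}\t{parent}\t{acc}\t{name}\t{rank}\t{status}\n")
    homonym_path = outdir / "homonyms.tsv"
    with open(homonym_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# name\trank\tresolving_kingdom\n")
        for g in homonym_genera:
            fh.write(f"{g}\tgenus\tAnimalia\n")

    # -- record plan ------------------------------------------------------
    stories: list[tuple[str, Optional[_Entity]]] = []
    for e in fakes:
        stories.append(("fallback", e))
    for e in with_synonym:
        stories.append(("synonym", e))
    for g in homonym_genera:
        ent = ent_by_genus.get(g)
        if ent is not None:
            stories.append(("homonym_genus", ent))
    for _ in range(spec.n_orphans):
        stories.append(("orphan", None))
    if len(stories) > spec.n_records:
        raise ValueError(
            f"spec inconsistent: {len(stories)} mandatory stories exceed "
            f"{spec.n_records} records"
        )
    used_entities: list[_Entity] = []
    while len(stories) < spec.n_records:
        if used_entities and rng.random() < spec.duplicate_sequence_fraction:
            ent = used_entities[rng.integers(len(used_entities))]
        else:
            ent = accepted[rng.integers(len(accepted))]
        used_entities.append(ent)
        story = "open_nom" if rng.random() < spec.open_nomenclature_fraction else "exact"
        stories.append((story, ent))
    order = rng.permutation(len(stories))
    stories = [stories[i] for i in order]
    sources = (
        ["BOLD"] * spec.n_bold + ["GenBank"] * spec.n_genbank + ["GBOL"] * spec.n_gbol
    )

    n_planted_n = round(spec.n_fraction * spec.n_records)

    truth_rows = []
    per_source: dict[str, list[dict]] = {"BOLD": [], "GenBank": [], "GBOL": []}
    counters = {"BOLD": 0, "GenBank": 0, "GBOL": 0}
    for (story, ent), source in zip(stories, sources):
        counters[source] += 1
        i = counters[source]
        plain_id = {
            "BOLD": f"BOLD{i:04d}-22",
            "GenBank": f"GB{i:06d}",
            "GBOL": f"GBOL{i:05d}",
        }[source]
        record_id = f"{source}:{plain_id}"

        if story == "orphan":
            gname = names.fresh(True)
            binomial = f"{gname} {names.fresh(False)}"
            ent = _Entity(
                name=binomial,
                genus=gname,
                lineage=Lineage(
                    kingdom=names.fresh(True),
                    phylum=names.fresh(True),
                    class_=names.fresh(True),
                    order=names.fresh(True),
                    family=names.fresh(True),
                    genus=gname,
                    species=binomial,
                ),
                sequence=_random_seq(rng, spec.sequence_length),
                kind="orphan",
            )

        if story == "synonym":
            provided = ent.synonym_name
            expected_cleaned = ent.synonym_name
            expected_matched = ent.name
        elif story == "open_nom":
            epithet = ent.name.split()[1]
            form = rng.integers(3)
            if form == 0:
                provided = f"{ent.genus} cf. {epithet}"
            elif form == 1:
                provided = f"{ent.genus} sp. {rng.integers(1, 99)}"
            else:
                provided = f"{ent.genus} aff. {epithet}"
            expected_cleaned = ent.genus
            expected_matched = ent.genus
        elif story == "homonym_genus":
            provided = ent.genus
            expected_cleaned = ent.genus
            expected_matched = ent.genus
        elif story == "fallback":
            provided = ent.name
            expected_cleaned = ent.name
            expected_matched = ent.lineage.family
        elif story == "orphan":
            provided = ent.lineage.species
            expected_cleaned = provided
            expected_matched = ""
        else:  # exact
            provided = ent.name
            expected_cleaned = ent.name
            expected_matched = ent.name

        expected_action = {
            "exact": "exact",
            "open_nom": "exact",
            "homonym_genus": "exact",
            "synonym": "synonym_replaced",
            "fallback": "rank_fallback",
            "orphan": "unmatched",
        }[story]
        expected_lin = _expected_lineage(ent, story)

        sequence = ent.sequence
        expected_quality = "keep"
        if n_planted_n > 0 and story == "exact":
            arr = np.array(list(sequence))
            pos = rng.choice(len(arr), size=8, replace=False)
            arr[pos] = "N"
            sequence = "".join(arr)
            expected_quality = "drop:max_n"
            n_planted_n -= 1

        country = None
        lat = lon = None
        if rng.random() < spec.country_fraction:
            country = _FIXTURE_COUNTRIES[rng.integers(len(_FIXTURE_COUNTRIES))]
        in_box = False
        if rng.random() < spec.coord_fraction:
            if rng.random() < 0.5:
                lat = float(f"{rng.uniform(1, 9):.4f}")
                lon = float(f"{rng.uniform(1, 9):.4f}")
                in_box = True
            else:
                lat = float(f"{rng.uniform(41, 49):.4f}")
                lon = float(f"{rng.uniform(41, 49):.4f}")

        lin = ent.lineage
        row = {
            "record_id": record_id,
            "plain_id": plain_id,
            "source_db": source,
            "story": story,
            "provided_name": provided,
            "expected_cleaned": expected_cleaned,
            "expected_action": expected_action,
            "expected_matched": expected_matched or "",
            "expected_quality": expected_quality,
            "sequence": sequence,
            "cluster_key": sequence,
            "country": country or "",
            "latitude": lat,
            "longitude": lon,
            "in_box": in_box,
            "true_lineage": lin,
            "expected_lineage": expected_lin,
        }
        truth_rows.append(row)
        per_source[source].append(row)

    # -- write the three source snapshots ---------------------------------
    bold_path = outdir / "bold.tsv"
    _write_bold(bold_path, per_source["BOLD"], rng)
    genbank_path = outdir / "genbank.gbff"
    _write_genbank(genbank_path, per_source["GenBank"], rng, names, spec)
    gbol_path = outdir / "gbol.csv"
    _write_gbol(gbol_path, per_source["GBOL"], rng, spec)

    # -- gazetteer and regions -------------------------------------------
    gaz_path = outdir / "gazetteer.tsv"
    with open(gaz_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("country\tcontinent\trealm\n")
        for c in _FIXTURE_COUNTRIES:
            cont, realm = _GAZETTEER_ROWS[c]
            fh.write(f"{c}\t{cont}\t{realm}\n")
    regions_path = outdir / "regions.geojson"
    _write_regions(regions_path)

    # -- queries ----------------------------------------------------------
    keepable = [
        r for r in truth_rows
        if r["expected_quality"] == "keep" and r["story"] != "orphan"
    ]
    query_rows = []
    qfasta = outdir / "queries.fasta"
    with open(qfasta, "w", encoding="utf-8", newline="\n") as fh:
        for qi in range(spec.n_queries):
            src = keepable[rng.integers(len(keepable))]
            k = spec.mutation_ks[qi % len(spec.mutation_ks)]
            qseq = _mutate(rng, src["sequence"], k)
            qid = f"Q{qi:04d}"
            ident = 100.0 * (spec.sequence_length - k) / spec.sequence_length
            query_rows.append(
                {
                    "query_id": qid,
                    "source_record": src["record_id"],
                    "k": k,
                    "expected_identity": ident,
                    "expected_bin": round_half_up(ident),
                    "expected_hit": ident >= 70.0,
                }
            )
            fh.write(f">{qid}\n{qseq}\n")

    # -- truth tables ------------------------------------------------------
    records_df = pd.DataFrame(
        [
            {
                **{k: v for k, v in r.items() if k not in ("true_lineage", "expected_lineage")},
                **{f"true_{rk}": r["true_lineage"].get(rk) or "" for rk in RANKS},
                **{f"expected_{rk}": r["expected_lineage"].get(rk) or "" for rk in RANKS},
            }
            for r in truth_rows
        ]
    )
    queries_df = pd.DataFrame(query_rows)
    records_df.to_csv(outdir / "records_truth.tsv", sep="\t", index=False)
    queries_df.to_csv(outdir / "queries_truth.tsv", sep="\t", index=False)

    n_synonym_nodes = sum(1 for r in backbone_rows if r[5] == "synonym")
    summary = {
        "seed": spec.seed,
        "n_backbone_nodes": len(backbone_rows),
        "n_synonym_nodes": n_synonym_nodes,
        "n_records": spec.n_records,
        "per_source": {k: len(v) for k, v in per_source.items()},
        "n_queries": spec.n_queries,
        "sequence_length": spec.sequence_length,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return FixtureTruth(
        directory=outdir,
        backbone_dump=backbone_path,
        homonym_list=homonym_path,
        genbank_file=genbank_path,
        bold_file=bold_path,
        gbol_file=gbol_path,
        gazetteer=gaz_path,
        regions=regions_path,
        query_fasta=qfasta,
        records=records_df,
        queries=queries_df,
        summary=summary,
    )


def _lineage_cell(row: dict, rank: str) -> str:
    lin: Lineage = row["true_lineage"]
    return lin.get(rank) or ""


def _write_bold(path, rows, rng) -> None:
    cols = (
        "processid\tphylum_name\tclass_name\torder_name\tfamily_name\t"
        "genus_name\tspecies_name\tnucleotides\tcountry\tlat\tlon\tmarkercode"
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(cols + "\n")
        for row in rows:
            species_cell = row["provided_name"] if row["story"] != "homonym_genus" else ""
            genus_cell = _lineage_cell(row, "genus")
            fh.write(
                "\t".join(
                    [
                        row["plain_id"],
                        _lineage_cell(row, "phylum"),
                        _lineage_cell(row, "class"),
                        _lineage_cell(row, "order"),
                        _lineage_cell(row, "family"),
                        genus_cell,
                        species_cell,
                        row["sequence"],
                        row["country"],
                        "" if row["latitude"] is None else f"{row['latitude']:.4f}",
                        "" if row["longitude"] is None else f"{row['longitude']:.4f}",
                        "COI-5P",
                    ]
                )
                + "\n"
            )
        # one decoy row with a different marker, always skipped
        fh.write(
            "\t".join(
                ["DECOY0001-22", "", "", "", "", "", "Decoyus generis",
                 "ACGTACGTACGT", "", "", "", "16S"]
            )
            + "\n"
        )


def _write_genbank(path, rows, rng, names: _Names, spec: FixtureSpec) -> None:
    records = []
    for row in rows:
        lin: Lineage = row["true_lineage"]
        organism = row["provided_name"]
        kingdom = "Metazoa" if lin.kingdom == "Animalia" else (lin.kingdom or "")
        taxonomy = [
            n
            for n in (
                kingdom, lin.phylum, lin.class_, lin.order, lin.family, lin.genus,
            )
            if n
        ]
        rec = SeqRecord(
            Seq(row["sequence"]),
            id=row["plain_id"],
            name=row["plain_id"],
            description=f"{organism} cytochrome c oxidase subunit I (COX1) gene",
        )
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["data_file_division"] = "INV"
        rec.annotations["date"] = "01-JAN-2022"
        rec.annotations["organism"] = organism
        rec.annotations["source"] = organism
        rec.annotations["taxonomy"] = taxonomy
        src_quals = {"organism": [organism], "mol_type": ["genomic DNA"]}
        if row["country"]:
            src_quals["country"] = [f"{row['country']}: sampling site"]
        if row["latitude"] is not None:
            lat, lon = row["latitude"], row["longitude"]
            src_quals["lat_lon"] = [
                f"{abs(lat):.4f} {'N' if lat >= 0 else 'S'} "
                f"{abs(lon):.4f} {'E' if lon >= 0 else 'W'}"
            ]
        n = len(row["sequence"])
        rec.features = [
            SeqFeature(SimpleLocation(0, n), type="source", qualifiers=src_quals),
            SeqFeature(
                SimpleLocation(0, n),
                type="CDS",
                qualifiers={
                    "gene": ["COX1"],
                    "product": ["cytochrome c oxidase subunit I"],
                },
            ),
        ]
        records.append(rec)
    # one decoy rRNA entry, always skipped by the CO1 filter
    decoy = SeqRecord(
        Seq(_random_seq(rng, 200)),
        id="GBDECOY1",
        name="GBDECOY1",
        description="Decoyus generis 16S ribosomal RNA gene",
    )
    decoy.annotations["molecule_type"] = "DNA"
    decoy.annotations["data_file_division"] = "INV"
    decoy.annotations["date"] = "01-JAN-2022"
    decoy.annotations["organism"] = "Decoyus generis"
    decoy.annotations["taxonomy"] = ["Metazoa"]
    decoy.features = [
        SeqFeature(
            SimpleLocation(0, 200),
            type="rRNA",
            qualifiers={"product": ["16S ribosomal RNA"]},
        )
    ]
    records.append(decoy)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(records, fh, "genbank")


def _write_gbol(path, rows, rng, spec: FixtureSpec) -> None:
    cols = (
        "specimen_id,kingdom,phylum,class,order,family,genus,species,"
        "marker,sequence,country,latitude,longitude,locality"
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(cols + "\n")
        for row in rows:
            deficient = rng.random() < spec.missing_rank_fraction
            order_cell = "" if deficient else _lineage_cell(row, "order")
            species_cell = row["provided_name"] if row["story"] != "homonym_genus" else ""
            locality = f'"{row["country"] or "unknown"}, near site {row["plain_id"]}"'
            fh.write(
                ",".join(
                    [
                        row["plain_id"],
                        _lineage_cell(row, "kingdom"),
                        _lineage_cell(row, "phylum"),
                        _lineage_cell(row, "class"),
                        order_cell,
                        _lineage_cell(row, "family"),
                        _lineage_cell(row, "genus"),
                        species_cell,
                        "COI-5P",
                        row["sequence"],
                        row["country"],
                        "" if row["latitude"] is None else f"{row['latitude']:.4f}",
                        "" if row["longitude"] is None else f"{row['longitude']:.4f}",
                        locality,
                    ]
                )
                + "\n"
            )


def _write_regions(path) -> None:
    def square(name, x0, y0, x1, y1):
        return {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                ],
            },
        }

    data = {
        "type": "FeatureCollection",
        "features": [square("Box", 0, 0, 10, 10), square("FarBox", 20, 20, 30, 30)],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")
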