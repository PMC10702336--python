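"""Writers for the reference-database output formats.

The table (TSV with location metadata), FASTA, and comparison files are
always produced; classifier-specific dialects (SINTAX, QIIME 2, kraken2,
DADA2) are opt-in.  Header grammars are frozen here — the downstream tools
document their expected layouts, and each dialect has its own empty-rank
policy (SINTAX omits empty ranks, QIIME 2 keeps bare prefixes).
"""

from __future__ import annotations

import json
import logging
import textwrap
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .derep import DerepCluster
from .harmonize import HarmonizedRecord
from .taxonomy import RANKS, BackboneStore, Lineage

logger = logging.getLogger(__name__)

ALL_FORMATS = (
    "table",
    "fasta",
    "comparison",
    "dada2_taxonomy",
    "dada2_species",
    "sintax",
    "qiime2",
    "kraken2",
)

DEFAULT_FORMATS = ("table", "fasta", "comparison")

TABLE_COLUMNS = (
    ("record_id", "source_db")
    + RANKS
    + ("action", "country", "latitude", "longitude", "sequence")
)


@dataclass(frozen=True)
class OutputRecord:
    """One row of the final reference database."""

    record_id: str
    source_db: str
    lineage: Lineage
    action: str
    country: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    sequence: str = ""

    @classmethod
    def from_harmonized(cls, h: HarmonizedRecord) -> "OutputRecord":
        r = h.record
        return cls(
            record_id=r.record_id,
            source_db=r.source_db,
            lineage=h.lineage,
            action=h.action,
            country=r.country,
            latitude=r.latitude,
            longitude=r.longitude,
            sequence=r.sequence,
        )

    @classmethod
    def from_cluster(
        cls, c: DerepCluster, by_id: dict[str, HarmonizedRecord]
    ) -> "OutputRecord":
        """Cluster row: the winning lineage with the representative's
        provenance and location metadata."""
        rep = by_id[c.representative_id]
        r = rep.record
        return cls(
            record_id=c.representative_id,
            source_db=r.source_db,
            lineage=c.lineage,
            action=rep.action,
            country=r.country,
            latitude=r.latitude,
            longitude=r.longitude,
            sequence=c.sequence,
        )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_table(records: Sequence[OutputRecord], path) -> None:
    """Tab-separated reference table, one row per record; UTF-8, LF."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for rec in records:
            row = (
                [rec.record_id, rec.source_db]
                + [_fmt(rec.lineage.get(r)) for r in RANKS]
                + [
                    rec.action,
                    _fmt(rec.country),
                    _fmt(rec.latitude),
                    _fmt(rec.longitude),
                    rec.sequence,
                ]
            )
            fh.write("\t".join(row) + "\n")


def read_table(path) -> list[OutputRecord]:
    """Strict reader for the table format (round-trips write_table)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TABLE_COLUMNS:
            raise ValueError(f"unexpected table header in {path}")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(TABLE_COLUMNS, vals))
            out.append(
                OutputRecord(
                    record_id=row["record_id"],
                    source_db=row["source_db"],
                    lineage=Lineage.from_names([row[r] or None for r in RANKS]),
                    action=row["action"],
                    country=row["country"] or None,
                    latitude=float(row["latitude"]) if row["latitude"] else None,
                    longitude=float(row["longitude"]) if row["longitude"] else None,
                    sequence=row["sequence"],
                )
            )
    return out


def _wrap(seq: str, width: int = 80) -> str:
    return "\n".join(textwrap.wrap(seq, width)) if seq else ""


_FASTA_PREFIX = dict(zip(RANKS, "kpcofgs"))


def write_fasta(records: Sequence[OutputRecord], path) -> None:
    """Default FASTA: ``>id|k__K;p__P;...;s__S``, sequence wrapped at 80."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            tax = ";".join(
                f"{_FASTA_PREFIX[r]}__{rec.lineage.get(r) or ''}" for r in RANKS
            )
            fh.write(f">{rec.record_id}|{tax}\n{_wrap(rec.sequence)}\n")


def write_comparison(df, path) -> None:
    """Comparison TSV: accepted_name, provided_name, action, n_records."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_sintax(records: Sequence[OutputRecord], path) -> None:
    """SINTAX FASTA: ``>id;tax=k:K,p:P,...;`` with empty ranks omitted and
    spaces replaced by underscores."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fields = [
                f"{_FASTA_PREFIX[r]}:{rec.lineage.get(r).replace(' ', '_')}"
                for r in RANKS
                if rec.lineage.get(r)
            ]
            fh.write(f">{rec.record_id};tax={','.join(fields)};\n{_wrap(rec.sequence)}\n")


def write_qiime2(records: Sequence[OutputRecord], fasta_path, taxonomy_path) -> None:
    """QIIME 2 pair: FASTA with bare ids + greengenes-style taxonomy TSV
    (empty ranks kept as bare ``x__`` prefixes)."""
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n{_wrap(rec.sequence)}\n")
    with open(taxonomy_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Feature ID\tTaxon\n")
        for rec in records:
            taxon = "; ".join(
                f"{_FASTA_PREFIX[r]}__{rec.lineage.get(r) or ''}" for r in RANKS
            )
            fh.write(f"{rec.record_id}\t{taxon}\n")


def write_dada2(
    records: Sequence[OutputRecord], taxonomy_path, species_path
) -> dict[str, int]:
    """DADA2 pair: genus-level taxonomy FASTA (``>K;P;C;O;F;G;``) and a
    species FASTA (``>id Genus species``; genus- or species-empty records
    are excluded from the species file)."""
    n_species = 0
    with open(taxonomy_path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = ";".join(rec.lineage.get(r) or "" for r in RANKS[:-1]) + ";"
            fh.write(f">{header}\n{_wrap(rec.sequence)}\n")
    with open(species_path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            if not rec.lineage.genus or not rec.lineage.species:
                continue
            fh.write(f">{rec.record_id} {rec.lineage.species}\n{_wrap(rec.sequence)}\n")
            n_species += 1
    return {"species_entries": n_species}


def write_kraken2(
    records: Sequence[OutputRecord],
    backbone: BackboneStore,
    fasta_path,
    nodes_path,
    names_path,
) -> dict[str, int]:
    """kraken2 trio: FASTA with ``>id|kraken:taxid|T`` headers plus
    taxdump-style nodes/names stubs restricted to the used taxa and closed
    under parents.  Records whose lowest resolved name has no backbone
    taxon id are excluded and counted.
    """
    used: dict[str, object] = {}
    n_excluded = 0
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            rank = rec.lineage.resolution()
            node = None
            if rank is not None:
                hits = backbone.lookup(rec.lineage.get(rank), rank_hint=rank)
                if len(hits) > 1:
                    ctx = rec.lineage.kingdom
                    hits = backbone.lookup(
                        rec.lineage.get(rank), rank_hint=rank, context=ctx
                    )
                if len(hits) == 1:
                    node = backbone.accepted_of(hits[0])
            if node is None:
                n_excluded += 1
                continue
            fh.write(f">{rec.record_id}|kraken:taxid|{node.taxon_id}\n")
            fh.write(f"{_wrap(rec.sequence)}\n")
            for anc in backbone._walk_up(node):
                used[anc.taxon_id] = anc
    if n_excluded:
        logger.info("kraken2 output: %d records without taxon id excluded", n_excluded)
    with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
        for tid in sorted(used):
            node = used[tid]
            parent = node.parent_id if node.parent_id is not None else node.taxon_id
            fh.write(f"{tid}\t|\t{parent}\t|\t{node.rank}\t|\n")
    with open(names_path, "w", encoding="utf-8", newline="\n") as fh:
        for tid in sorted(used):
            node = used[tid]
            fh.write(f"{tid}\t|\t{node.canonical_name}\t|\t\t|\tscientific name\t|\n")
    return {"excluded": n_excluded, "taxa": len(used)}


@dataclass
class OutputBundle:
    """Paths of everything written for one run."""

    directory: Path
    files: dict[str, Path]
    manifest: dict


def write_outputs(
    records: Sequence[OutputRecord],
    outdir,
    comparison=None,
    formats: Iterable[str] = DEFAULT_FORMATS,
    backbone: Optional[BackboneStore] = None,
    parameters: Optional[dict] = None,
) -> OutputBundle:
    """Write the requested formats plus a JSON run manifest.

    Table, FASTA, and comparison are always included.  kraken2 requires a
    backbone store for taxon ids.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = set(formats) | set(DEFAULT_FORMATS)
    unknown = requested - set(ALL_FORMATS)
    if unknown:
        raise ValueError(f"unknown output formats: {sorted(unknown)}")
    files: dict[str, Path] = {}
    counts: dict[str, int] = {"records": len(records)}

    write_table(records, outdir / "reference.tsv")
    files["table"] = outdir / "reference.tsv"
    write_fasta(records, outdir / "reference.fasta")
    files["fasta"] = outdir / "reference.fasta"
    if comparison is not None:
        write_comparison(comparison, outdir / "comparison.tsv")
        files["comparison"] = outdir / "comparison.tsv"
    if "sintax" in requested:
        write_sintax(records, outdir / "sintax.fasta")
        files["sintax"] = outdir / "sintax.fasta"
    if "qiime2" in requested:
        write_qiime2(records, outdir / "qiime2.fasta", outdir / "qiime2_taxonomy.tsv")
        files["qiime2_fasta"] = outdir / "qiime2.fasta"
        files["qiime2_taxonomy"] = outdir / "qiime2_taxonomy.tsv"
    if "dada2_taxonomy" in requested or "dada2_species" in requested:
        info = write_dada2(
            records, outdir / "dada2_taxonomy.fasta", outdir / "dada2_species.fasta"
        )
        counts.update({f"dada2_{k}": v for k, v in info.items()})
        files["dada2_taxonomy"] = outdir / "dada2_taxonomy.fasta"
        files["dada2_species"] = outdir / "dada2_species.fasta"
    if "kraken2" in requested:
        if backbone is None:
            raise ValueError("kraken2 output requires a backbone store")
        info = write_kraken2(
            records,
            backbone,
            outdir / "kraken2.fasta",
            outdir / "kraken2_nodes.dmp",
            outdir / "kraken2_names.dmp",
        )
        counts.update({f"kraken2_{k}": v for k, v in info.items()})
        files["kraken2_fasta"] = outdir / "kraken2.fasta"
        files["kraken2_nodes"] = outdir / "kraken2_nodes.dmp"
        files["kraken2_names"] = outdir / "kraken2_names.dmp"

    from . import __version__

    manifest = {
        "version": __version__,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "parameters": parameters or {},
        "formats": sorted(requested),
        "counts": counts,
        "files": {k: str(v.name) for k, v in files.items()},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest"] = outdir / "manifest.json"
    return OutputBundle(directory=outdir, files=files, manifest=manifest)
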