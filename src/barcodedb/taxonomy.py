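"""Backbone-taxonomy store and lineage algebra.

A *backbone taxonomy* is a unitary, resolved hierarchy (GBIF Backbone or the
NCBI Taxonomy) used as the authority when harmonizing taxon names from
heterogeneous barcode sources.  This module imports backbone dumps into an
indexed SQLite store and answers name -> node queries with synonym, homonym
and ancestry resolution.

Only the seven standard ranks (kingdom, phylum, class, order, family, genus,
species) are ever projected into a :class:`Lineage`; intermediate ranks such
as subfamily are retained in the store but skipped during projection.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import sqlite3
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

#: Standard Linnean ranks, most inclusive first.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: Maximum synonym-chain length followed by :meth:`BackboneStore.accepted_of`.
MAX_SYNONYM_DEPTH = 10


class TaxonomyError(Exception):
    """Structural problem in the backbone store (cycle, dangling synonym)."""


@dataclass(frozen=True)
class TaxonNode:
    """One backbone-taxonomy entry (accepted name, synonym, or homonym)."""

    taxon_id: str
    canonical_name: str
    rank: str  # one of RANKS or "other"
    status: str  # accepted | synonym | doubtful
    parent_id: Optional[str]
    accepted_id: str
    source: str  # gbif | ncbi


@dataclass(frozen=True)
class Lineage:
    """Names at the seven standard ranks; empty slots are ``None``.

    The *resolution* of a lineage is its lowest (finest) non-empty rank.  An
    entirely empty lineage is legal only before harmonization.
    """

    kingdom: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    _FIELD_BY_RANK = {
        "kingdom": "kingdom",
        "phylum": "phylum",
        "class": "class_",
        "order": "order",
        "family": "family",
        "genus": "genus",
        "species": "species",
    }

    def get(self, rank: str) -> Optional[str]:
        return getattr(self, self._FIELD_BY_RANK[rank])

    def names(self) -> tuple[Optional[str], ...]:
        """Slot values ordered kingdom -> species."""
        return tuple(self.get(r) for r in RANKS)

    @classmethod
    def from_names(cls, names: Sequence[Optional[str]]) -> "Lineage":
        vals = [n if n else None for n in names]
        vals += [None] * (len(RANKS) - len(vals))
        return cls(**{cls._FIELD_BY_RANK[r]: v for r, v in zip(RANKS, vals)})

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Lineage":
        """Project (rank-label, name) pairs; non-standard labels are skipped.

        The first occurrence of each standard rank wins.
        """
        slots: dict[str, str] = {}
        for label, name in pairs:
            key = label.strip().lower()
            if key in RANK_INDEX and name and key not in slots:
                slots[key] = name
        return cls.from_names([slots.get(r) for r in RANKS])

    def with_rank(self, rank: str, name: Optional[str]) -> "Lineage":
        return replace(self, **{self._FIELD_BY_RANK[rank]: name})

    def resolution(self) -> Optional[str]:
        """Lowest non-empty rank, or None for an empty lineage."""
        for r in reversed(RANKS):
            if self.get(r):
                return r
        return None

    def resolution_index(self) -> int:
        """Index of the resolution in RANKS; -1 for an empty lineage."""
        r = self.resolution()
        return -1 if r is None else RANK_INDEX[r]

    def is_empty(self) -> bool:
        return self.resolution() is None

    def truncate_below(self, rank: str) -> "Lineage":
        """Empty every slot finer than *rank*."""
        cut = RANK_INDEX[rank]
        return Lineage.from_names(
            [n if i <= cut else None for i, n in enumerate(self.names())]
        )


def lca(a: Lineage, b: Lineage) -> Lineage:
    """Lowest common ancestor: longest common rank prefix of two lineages.

    Slots at and below the first disagreement are emptied; two empty slots at
    the same rank agree.
    """
    out: list[Optional[str]] = []
    for x, y in zip(a.names(), b.names()):
        if x == y:
            out.append(x)
        else:
            break
    return Lineage.from_names(out)


def lca_many(lineages: Iterable[Lineage]) -> Lineage:
    it = iter(lineages)
    try:
        acc = next(it)
    except StopIteration:
        return Lineage()
    for lin in it:
        acc = lca(acc, lin)
    return acc


def is_prefix(a: Lineage, b: Lineage) -> bool:
    """True if *a* carries no information that contradicts or exceeds *b*."""
    return all(x is None or x == y for x, y in zip(a.names(), b.names()))


@dataclass
class ImportReport:
    n_nodes: int = 0
    n_synonyms: int = 0
    n_skipped: int = 0


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


_GBIF_REQUIRED = {
    "taxonID",
    "parentNameUsageID",
    "acceptedNameUsageID",
    "canonicalName",
    "taxonRank",
    "taxonomicStatus",
}


class BackboneStore:
    """Indexed local store of one backbone taxonomy.

    Contract: query latency independent of dump order (name and (name, rank)
    indexes), acyclic parent chains, and synonym resolution via accepted_id.
    A store with no rows doubles as the "no backbone" option: every lookup
    returns an empty list.
    """

    def __init__(self, db_path: str | Path = ":memory:"):
        self._con = sqlite3.connect(str(db_path))
        self._con.executescript(
            """
            CREATE TABLE IF NOT EXISTS taxa (
                taxon_id TEXT PRIMARY KEY,
                canonical_name TEXT NOT NULL,
                name_lower TEXT NOT NULL,
                rank TEXT NOT NULL,
                status TEXT NOT NULL,
                parent_id TEXT,
                accepted_id TEXT NOT NULL,
                source TEXT NOT NULL
            );
            CREATE INDEX IF NOT EXISTS idx_taxa_name ON taxa(name_lower);
            CREATE INDEX IF NOT EXISTS idx_taxa_name_rank ON taxa(name_lower, rank);
            CREATE TABLE IF NOT EXISTS homonyms (
                name_lower TEXT NOT NULL,
                rank TEXT NOT NULL,
                resolving_kingdom TEXT NOT NULL,
                PRIMARY KEY (name_lower, rank)
            );
            """
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def null(cls) -> "BackboneStore":
        """Empty store standing in for the 'no backbone' option."""
        return cls(":memory:")

    def close(self) -> None:
        self._con.close()

    def add_node(self, node: TaxonNode) -> None:
        self._con.execute(
            "INSERT OR REPLACE INTO taxa VALUES (?,?,?,?,?,?,?,?)",
            (
                node.taxon_id,
                node.canonical_name,
                node.canonical_name.lower(),
                node.rank,
                node.status,
                node.parent_id,
                node.accepted_id,
                node.source,
            ),
        )

    def load_homonym_list(self, path) -> int:
        """Load a 3-column TSV (name, rank, resolving_kingdom); '#' comments."""
        n = 0
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    logger.warning("homonym list: malformed line %r", line)
                    continue
                name, rank, kingdom = parts[0], parts[1], parts[2]
                self._con.execute(
                    "INSERT OR REPLACE INTO homonyms VALUES (?,?,?)",
                    (name.lower(), rank.lower(), kingdom),
                )
                n += 1
        self._con.commit()
        return n

    # -- queries ----------------------------------------------------------

    @staticmethod
    def _row_to_node(row) -> TaxonNode:
        return TaxonNode(
            taxon_id=row[0],
            canonical_name=row[1],
            rank=row[3],
            status=row[4],
            parent_id=row[5],
            accepted_id=row[6],
            source=row[7],
        )

    def node(self, taxon_id: str) -> Optional[TaxonNode]:
        cur = self._con.execute("SELECT * FROM taxa WHERE taxon_id=?", (taxon_id,))
        row = cur.fetchone()
        return self._row_to_node(row) if row else None

    def __len__(self) -> int:
        return self._con.execute("SELECT COUNT(*) FROM taxa").fetchone()[0]

    def is_null(self) -> bool:
        return len(self) == 0

    def lookup(
        self,
        name: str,
        rank_hint: Optional[str] = None,
        context: Optional[str] = None,
    ) -> list[TaxonNode]:
        """Exact (case-insensitive) name match with homonym disambiguation.

        Candidates sharing the name are narrowed first by *rank_hint*, then by
        *context* (a candidate whose ancestry contains the context name wins),
        then by the imported homonym list.  If still ambiguous, all candidates
        are returned; an empty list means not found.
        """
        cur = self._con.execute(
            "SELECT * FROM taxa WHERE name_lower=? ORDER BY taxon_id",
            (name.strip().lower(),),
        )
        nodes = [self._row_to_node(r) for r in cur.fetchall()]
        if rank_hint:
            narrowed = [n for n in nodes if n.rank == rank_hint]
            if narrowed:
                nodes = narrowed
        if len(nodes) > 1 and context:
            ctx = context.strip().lower()
            narrowed = [
                n for n in nodes if ctx in (a.lower() for a in self.ancestry_names(n))
            ]
            if narrowed:
                nodes = narrowed
        if len(nodes) > 1:
            nodes = self._resolve_homonym(name, nodes)
        return nodes

    def _resolve_homonym(self, name: str, nodes: list[TaxonNode]) -> list[TaxonNode]:
        cur = self._con.execute(
            "SELECT rank, resolving_kingdom FROM homonyms WHERE name_lower=?",
            (name.strip().lower(),),
        )
        rules = dict(cur.fetchall())
        if not rules:
            return nodes
        kept = []
        for n in nodes:
            kingdom = rules.get(n.rank)
            if kingdom is None:
                kept.append(n)
                continue
            lin = self.lineage_of(n)
            if lin.kingdom and lin.kingdom.lower() == kingdom.lower():
                kept.append(n)
        return kept or nodes

    def accepted_of(self, node: TaxonNode) -> TaxonNode:
        """Resolve a synonym to its accepted partner (transitively).

        Accepted and doubtful nodes resolve to themselves.  Chains longer than
        MAX_SYNONYM_DEPTH, cycles, and dangling accepted_id references raise
        :class:`TaxonomyError`.
        """
        current = node
        for _ in range(MAX_SYNONYM_DEPTH):
            if current.status != "synonym" or current.accepted_id == current.taxon_id:
                return current
            nxt = self.node(current.accepted_id)
            if nxt is None:
                raise TaxonomyError(
                    f"dangling accepted_id {current.accepted_id!r} "
                    f"on node {current.taxon_id!r} ({current.canonical_name!r})"
                )
            current = nxt
        raise TaxonomyError(
            f"synonym chain from {node.taxon_id!r} exceeds depth "
            f"{MAX_SYNONYM_DEPTH} (cycle?)"
        )

    def _walk_up(self, node: TaxonNode) -> Iterator[TaxonNode]:
        seen = {node.taxon_id}
        current: Optional[TaxonNode] = node
        while current is not None:
            yield current
            pid = current.parent_id
            if pid is None:
                return
            if pid in seen:
                raise TaxonomyError(f"cycle in parent chain at node {pid!r}")
            seen.add(pid)
            current = self.node(pid)

    def ancestry_names(self, node: TaxonNode) -> list[str]:
        """Canonical names from the node up to the root (node included)."""
        return [n.canonical_name for n in self._walk_up(node)]

    def lineage_of(self, node: TaxonNode) -> Lineage:
        """Project the parent chain onto the seven standard ranks."""
        lin = Lineage()
        for n in self._walk_up(node):
            if n.rank in RANK_INDEX and lin.get(n.rank) is None:
                lin = lin.with_rank(n.rank, n.canonical_name)
        return lin

    def accepted_names(self) -> list[str]:
        cur = self._con.execute(
            "SELECT canonical_name FROM taxa WHERE status='accepted'"
        )
        return [r[0] for r in cur.fetchall()]

    def iter_nodes(self) -> Iterator[TaxonNode]:
        cur = self._con.execute("SELECT * FROM taxa ORDER BY taxon_id")
        for row in cur.fetchall():
            yield self._row_to_node(row)


def _norm_rank(label: str) -> str:
    label = label.strip().lower()
    return label if label in RANK_INDEX else "other"


def _import_gbif(store: BackboneStore, path) -> ImportReport:
    report = ImportReport()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return report  # empty file -> empty store
        missing = _GBIF_REQUIRED - set(reader.fieldnames)
        if missing:
            raise ValueError(f"GBIF dump missing columns: {sorted(missing)}")
        for row in reader:
            tid = (row.get("taxonID") or "").strip()
            name = (row.get("canonicalName") or "").strip()
            if not tid or not name:
                report.n_skipped += 1
                logger.warning("GBIF dump: skipping malformed row %r", row)
                continue
            status_raw = (row.get("taxonomicStatus") or "accepted").strip().lower()
            if "synonym" in status_raw:
                status = "synonym"
            elif status_raw == "doubtful":
                status = "doubtful"
            else:
                status = "accepted"
            accepted = (row.get("acceptedNameUsageID") or "").strip()
            parent = (row.get("parentNameUsageID") or "").strip() or None
            store.add_node(
                TaxonNode(
                    taxon_id=tid,
                    canonical_name=name,
                    rank=_norm_rank(row.get("taxonRank") or ""),
                    status=status,
                    parent_id=parent,
                    accepted_id=accepted if status == "synonym" and accepted else tid,
                    source="gbif",
                )
            )
            report.n_nodes += 1
            if status == "synonym":
                report.n_synonyms += 1
    return report


def _split_dmp(line: str) -> list[str]:
    # taxdump lines look like:  tax_id\t|\tvalue\t|\t...\t|
    return [f.strip() for f in line.rstrip("\n").rstrip("|").split("\t|")]


def _import_ncbi(store: BackboneStore, nodes_path, names_path) -> ImportReport:
    report = ImportReport()
    parents: dict[str, tuple[Optional[str], str]] = {}
    with _open_text(nodes_path) as fh:
        for line in fh:
            parts = _split_dmp(line)
            if len(parts) < 3:
                report.n_skipped += 1
                continue
            tid, parent, rank = parts[0], parts[1], parts[2]
            parents[tid] = (None if parent == tid else parent, _norm_rank(rank))
    syn_counter: dict[str, int] = {}
    with _open_text(names_path) as fh:
        for line in fh:
            parts = _split_dmp(line)
            if len(parts) < 4:
                report.n_skipped += 1
                continue
            tid, name, _unique, name_class = parts[0], parts[1], parts[2], parts[3]
            if tid not in parents or not name:
                report.n_skipped += 1
                continue
            parent, rank = parents[tid]
            if name_class == "scientific name":
                store.add_node(
                    TaxonNode(tid, name, rank, "accepted", parent, tid, "ncbi")
                )
                report.n_nodes += 1
            elif name_class == "synonym":
                k = syn_counter.get(tid, 0) + 1
                syn_counter[tid] = k
                store.add_node(
                    TaxonNode(f"{tid}/s{k}", name, rank, "synonym", parent, tid, "ncbi")
                )
                report.n_nodes += 1
                report.n_synonyms += 1
    return report


def import_backbone(
    dump_path,
    dialect: str,
    db_path: str | Path = ":memory:",
    names_path=None,
    homonym_list=None,
) -> tuple[BackboneStore, ImportReport]:
    """Import a backbone dump and return (store, import report).

    dialect "gbif": *dump_path* is a TSV with header taxonID,
    parentNameUsageID, acceptedNameUsageID, canonicalName, taxonRank,
    taxonomicStatus.  dialect "ncbi": *dump_path* is the nodes file and
    *names_path* the names file, pipe-delimited as in a taxdump.  Malformed
    rows are skipped with a logged warning and counted in the report.
    """
    store = BackboneStore(db_path)
    if dialect == "gbif":
        report = _import_gbif(store, dump_path)
    elif dialect == "ncbi":
        if names_path is None:
            raise ValueError("NCBI dialect requires names_path")
        report = _import_ncbi(store, dump_path, names_path)
    else:
        raise ValueError(f"unknown backbone dialect: {dialect!r}")
    if homonym_list is not None:
        store.load_homonym_list(homonym_list)
    store._con.commit()
    return store, report
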