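"""Mapping record taxonomies onto a backbone (or passing them through).

Mapped mode looks up each record's cleaned lowest-rank name in the backbone:
an accepted match keeps the name (action ``exact``); a synonym match is
replaced with the accepted name (``synonym_replaced``) unless synonyms are
allowed, in which case the synonym stays as the displayed name but the
higher ranks are still taken from the accepted node's ancestry; with no
match, the record's own higher taxa are tried upward until one matches
(``rank_fallback``); if nothing matches the record is ``unmatched`` (kept,
not dropped — a later minimal-rank filter may remove it).

Unmapped mode projects the raw lineage verbatim onto the seven standard
slots (``passthrough``); source-specific kingdom labels (Animalia vs
Metazoa, or none at all for BOLD) are left as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .ingest import SourceRecord
from .names import clean_name
from .taxonomy import RANK_INDEX, BackboneStore, Lineage, TaxonNode

logger = logging.getLogger(__name__)

ACTIONS = ("exact", "synonym_replaced", "rank_fallback", "unmatched", "passthrough")


@dataclass(frozen=True)
class HarmonizedRecord:
    record: SourceRecord
    lineage: Lineage
    action: str
    matched_name: Optional[str]
    original_name: str

    @property
    def resolution(self) -> Optional[str]:
        return self.lineage.resolution()

    @property
    def record_id(self) -> str:
        return self.record.record_id

    @property
    def sequence(self) -> str:
        return self.record.sequence


def clean_record(record: SourceRecord, token_list=None) -> SourceRecord:
    """Return a copy with cleaned raw_name and cleaned lineage names.

    Lineage entries whose name cleans to empty keep their label with an
    empty name (the rank slot stays, the uncertain name goes).
    """
    cleaned_lineage = tuple(
        (label, clean_name(name, token_list).cleaned if name else "")
        for label, name in record.raw_lineage
    )
    return replace(
        record,
        raw_name=clean_name(record.raw_name, token_list).cleaned,
        raw_lineage=cleaned_lineage,
    )


def _rank_hint(record: SourceRecord, name: str) -> Optional[str]:
    """Best-guess standard rank of the record's cleaned lowest name."""
    if len(name.split()) >= 2:
        return "species"
    labels = [
        lab.lower()
        for lab, nm in record.raw_lineage
        if nm and nm.lower() == name.lower() and lab.lower() in RANK_INDEX
    ]
    if labels:
        label = labels[-1]
        return label if label != "species" else "genus"
    # a one-token name whose raw label was species: the epithet was cleaned
    # away, what is left is a genus-level identification
    return "genus"


def _lookup_level(
    backbone: BackboneStore,
    name: str,
    rank_hint: Optional[str],
    higher_names: list[str],
) -> Optional[TaxonNode]:
    """Resolve one name against the backbone, using the record's own higher
    lineage as homonym context; None if absent or irreducibly ambiguous."""
    nodes = backbone.lookup(name, rank_hint=rank_hint)
    if not nodes:
        return None
    if len(nodes) == 1:
        return nodes[0]
    for ctx in higher_names:
        narrowed = backbone.lookup(name, rank_hint=rank_hint, context=ctx)
        if len(narrowed) == 1:
            return narrowed[0]
    logger.info("ambiguous homonym %r left unresolved at this rank", name)
    return None


def harmonize_record(
    record: SourceRecord,
    backbone: BackboneStore,
    allow_synonyms: bool = False,
) -> HarmonizedRecord:
    """Map one cleaned record onto the backbone taxonomy.

    The record's names are expected to be already cleaned (see
    :func:`clean_record`).  ``unmatched`` is a result, never an error.
    """
    # candidate names finest-first: the lowest identification, then the
    # record's own higher taxa walking upward
    levels: list[tuple[Optional[str], str]] = []
    if record.raw_name:
        levels.append((_rank_hint(record, record.raw_name), record.raw_name))
    for label, nm in reversed(record.raw_lineage):
        if not nm or (levels and nm == levels[-1][1]):
            continue
        lab = label.lower()
        levels.append((lab if lab in RANK_INDEX else None, nm))

    all_names = [nm for _, nm in levels]
    for depth, (hint, nm) in enumerate(levels):
        higher = all_names[depth + 1 :]
        node = _lookup_level(backbone, nm, hint, higher)
        if node is None:
            continue
        accepted = backbone.accepted_of(node)
        lineage = backbone.lineage_of(accepted)
        if node.status == "synonym":
            action = "synonym_replaced" if depth == 0 else "rank_fallback"
            if allow_synonyms and depth == 0 and accepted.rank in RANK_INDEX:
                lineage = lineage.with_rank(accepted.rank, node.canonical_name)
        else:
            action = "exact" if depth == 0 else "rank_fallback"
        return HarmonizedRecord(
            record=record,
            lineage=lineage,
            action=action,
            matched_name=accepted.canonical_name,
            original_name=record.raw_name,
        )
    return HarmonizedRecord(
        record=record,
        lineage=Lineage(),
        action="unmatched",
        matched_name=None,
        original_name=record.raw_name,
    )


def unmapped_merge(record: SourceRecord) -> HarmonizedRecord:
    """Project the raw lineage verbatim onto the seven standard slots.

    Kingdom labels stay source-specific (GBOL says Animalia, GenBank
    Metazoa, BOLD has none); divergence between sources is expected and is
    the user's trade-off in unmapped mode.
    """
    lineage = Lineage.from_pairs(record.raw_lineage)
    name = record.raw_name
    if name:
        known = {nm for _, nm in record.raw_lineage if nm}
        if name not in known:
            if len(name.split()) >= 2:
                if lineage.species is None:
                    lineage = lineage.with_rank("species", name)
            elif lineage.genus is None:
                lineage = lineage.with_rank("genus", name)
    return HarmonizedRecord(
        record=record,
        lineage=lineage,
        action="passthrough",
        matched_name=None,
        original_name=record.raw_name,
    )


def harmonize(
    records: Iterable[SourceRecord],
    backbone: Optional[BackboneStore] = None,
    unmapped: bool = False,
    allow_synonyms: bool = False,
    token_list=None,
) -> list[HarmonizedRecord]:
    """Clean and harmonize a record stream; record count is conserved."""
    out = []
    for rec in records:
        rec = clean_record(rec, token_list)
        if unmapped or backbone is None or backbone.is_null():
            out.append(unmapped_merge(rec))
        else:
            out.append(harmonize_record(rec, backbone, allow_synonyms))
    return out


def build_comparison(records: Iterable[HarmonizedRecord]) -> pd.DataFrame:
    """Aggregate the name mapping into the comparison table.

    One row per distinct (accepted_name, provided_name, action) with its
    occurrence count, sorted by accepted name: the reconciliation view of
    which provided names were kept, replaced, or left unmatched.
    """
    rows = [
        {
            "accepted_name": h.matched_name or "",
            "provided_name": h.original_name,
            "action": h.action,
        }
        for h in records
    ]
    if not rows:
        return pd.DataFrame(
            columns=["accepted_name", "provided_name", "action", "n_records"]
        )
    df = (
        pd.DataFrame(rows)
        .groupby(["accepted_name", "provided_name", "action"], as_index=False)
        .size()
        .rename(columns={"size": "n_records"})
        .sort_values(["accepted_name", "provided_name", "action"], kind="mergesort")
        .reset_index(drop=True)
    )
    return df
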