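"""Taxonomy-aware dereplication of identical sequences.

Records sharing the exact same sequence string collapse into one cluster.
When member taxonomies conflict, the cluster lineage is decided by a rule
cascade: (a) if the distinct lineages differ only in resolution (they form
a prefix chain), the most resolved one wins; (b) otherwise records are
counted per distinct lineage and a unique maximum wins; (c) a tie on the
maximum falls back to the lowest common ancestor of the tied lineages.

The majority is computed over full lineages, never per rank, so no chimeric
lineage can be fabricated from mixed members.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from .harmonize import HarmonizedRecord
from .taxonomy import Lineage, is_prefix, lca_many


@dataclass(frozen=True)
class DerepCluster:
    sequence: str
    lineage: Lineage
    member_count: int
    member_ids: tuple[str, ...]
    representative_id: str


def resolve_lineages(groups: dict[Lineage, list[str]]) -> tuple[Lineage, list[str]]:
    """Apply the resolution / majority / LCA cascade to one cluster.

    *groups* maps each distinct member lineage to its member record ids.
    Returns the winning lineage and the ids of the winning group (for the
    LCA case, the union of the tied groups).
    """
    lineages = list(groups)
    if len(lineages) == 1:
        return lineages[0], groups[lineages[0]]

    # (a) pure resolution differences: total prefix chain -> most resolved
    chain = sorted(lineages, key=lambda l: sum(n is not None for n in l.names()))
    if all(is_prefix(a, b) for a, b in zip(chain, chain[1:])):
        return chain[-1], groups[chain[-1]]

    # (b) majority over full lineages
    top = max(len(ids) for ids in groups.values())
    tied = [lin for lin, ids in groups.items() if len(ids) == top]
    if len(tied) == 1:
        return tied[0], groups[tied[0]]

    # (c) tie -> lowest common ancestor of the tied lineages
    winner = lca_many(sorted(tied, key=lambda l: l.names().__str__()))
    members = [rid for lin in tied for rid in groups[lin]]
    return winner, members


def dereplicate(records: Iterable[HarmonizedRecord]) -> list[DerepCluster]:
    """Collapse identical sequences; one cluster per distinct sequence.

    The representative is the lexicographically smallest member id of the
    winning lineage group, making the output independent of input order.
    Clusters are returned sorted by sequence.
    """
    by_seq: dict[str, list[HarmonizedRecord]] = defaultdict(list)
    for rec in records:
        by_seq[rec.sequence].append(rec)

    clusters = []
    for seq in sorted(by_seq):
        members = by_seq[seq]
        groups: dict[Lineage, list[str]] = defaultdict(list)
        for m in members:
            groups[m.lineage].append(m.record_id)
        lineage, winning_ids = resolve_lineages(dict(groups))
        clusters.append(
            DerepCluster(
                sequence=seq,
                lineage=lineage,
                member_count=len(members),
                member_ids=tuple(sorted(m.record_id for m in members)),
                representative_id=min(winning_ids),
            )
        )
    return clusters
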