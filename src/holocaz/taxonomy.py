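"""Taxonomic attribution of CAZyme-encoding ORFs by naive lowest common
ancestor (LCA) over the retained top-k database hits.

The LCA of a hit set is the deepest taxon shared by all hits: lineages are
compared rank by rank from domain downward and the assignment stops at the
first disagreement. A single hit keeps its full lineage; an ORF whose hits
disagree already at the domain level is left unassigned (root). No
min-support or top-percent weighting is applied — the rule is the plain
intersection of the retained hits; weighting hooks are config stubs.

Lineages are aligned by rank name; a rank missing from some hits is a
wildcard that never breaks the common prefix (the hits that do name the
rank must still agree).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from holocaz.consensus import CazymeCall
from holocaz.model import CANONICAL_RANKS, TaxonLineage, cazy_class


@dataclass(frozen=True)
class TaxonAssignment:
    """LCA result for one ORF.

    ``assigned_lineage`` may be empty (root/unassigned); it is a rank-wise
    prefix of every contributing hit's lineage. ``support`` is the number
    of hits used.
    """

    orf_id: str
    assigned_lineage: tuple[tuple[str, str], ...]
    support: int

    def name_at(self, rank: str) -> Optional[str]:
        for r, name in self.assigned_lineage:
            if r == rank:
                return name
        return None


def lca(
    lineages: Sequence[TaxonLineage],
    min_support: int = 1,  # config stub: naive LCA uses every retained hit
) -> TaxonAssignment:
    """Lowest common ancestor of one ORF's retained lineages.

    Empty input yields an unassigned (root) result; a single lineage is
    returned whole. The result is order-invariant and idempotent.
    """
    lineages = list(lineages)
    if not lineages:
        return TaxonAssignment("", (), 0)
    orf_ids = {lin.orf_id for lin in lineages}
    if len(orf_ids) != 1:
        raise ValueError(f"lca() expects hits of a single ORF, got {sorted(orf_ids)}")
    orf_id = lineages[0].orf_id
    ranks = _rank_order(lineages)
    common: list[tuple[str, str]] = []
    for rank in ranks:
        names = {lin.name_at(rank) for lin in lineages} - {None}
        if len(names) > 1:
            break
        if len(names) == 1:
            common.append((rank, names.pop()))
    return TaxonAssignment(orf_id, tuple(common), len(lineages))


def _rank_order(lineages: Iterable[TaxonLineage]) -> list[str]:
    """Canonical ranks first, then any extra ranks in first-seen order."""
    extra: list[str] = []
    for lin in lineages:
        for rank, _ in lin.lineage:
            if rank not in CANONICAL_RANKS and rank not in extra:
                extra.append(rank)
    return list(CANONICAL_RANKS) + extra


def assign_orfs(lineages: Iterable[TaxonLineage]) -> dict[str, TaxonAssignment]:
    """Group hits per ORF and LCA each group."""
    per_orf: dict[str, list[TaxonLineage]] = {}
    for lin in lineages:
        per_orf.setdefault(lin.orf_id, []).append(lin)
    return {orf: lca(hits) for orf, hits in per_orf.items()}


UNKNOWN = "unknown"


def profile_community(
    assignments: dict[str, TaxonAssignment],
    calls: Iterable[CazymeCall],
    level: str = "phylum",
) -> pd.DataFrame:
    """Taxon x CAZy-class module counts at the requested rank.

    Each call contributes its ``module_count`` to the row of the taxon its
    ORF resolves to at ``level``; ORFs unassigned or unresolved at that
    rank fall into the ``unknown`` row, so column sums conserve the total
    modules of all profiled calls.
    """
    if level not in CANONICAL_RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {CANONICAL_RANKS}")
    tallies: dict[tuple[str, str], int] = {}
    for call in calls:
        assignment = assignments.get(call.orf_id)
        taxon = assignment.name_at(level) if assignment is not None else None
        if taxon is None:
            taxon = UNKNOWN
        key = (taxon, cazy_class(call.family))
        tallies[key] = tallies.get(key, 0) + call.module_count
    if not tallies:
        return pd.DataFrame()
    taxa = sorted({t for t, _ in tallies}, key=lambda t: (t == UNKNOWN, t))
    classes = sorted({c for _, c in tallies})
    table = pd.DataFrame(0, index=pd.Index(taxa, name=level), columns=classes)
    for (taxon, cls), count in tallies.items():
        table.loc[taxon, cls] = count
    return table
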