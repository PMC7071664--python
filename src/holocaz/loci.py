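"""Gene-cluster screens on assembled contigs.

Two lignocellulose-relevant systems are screened from gene order and
conserved-domain content:

* **Polysaccharide utilization loci (PULs)** — Bacteroidetes clusters
  organized around a susC-susD transporter/binding-protein gene pair. A
  candidate requires one *sequential* pair: a susC-bearing and a
  susD-bearing gene at adjacent positions along the contig. Contigs
  carrying susC and/or susD without an adjacent pair are tallied as
  orphan-bearing (fragmented loci are common in metagenome assemblies).

* **Cellulosomes** — multi-enzyme scaffolds assembled through
  cohesin-dockerin interactions and anchored by S-layer homology (SLH)
  domains. Any contig bearing one of the three marker domains becomes a
  candidate; genes carrying both a dockerin domain and at least one CAZy
  family are the strongest evidence (enzyme-dockerin fusions destined for
  a scaffoldin) and are reported separately.

Marker defaults: susC = PF00593 (TonB-dependent receptor), susD = PF07980,
cohesin = PF00963, SLH = PF00395. The study text prints PF00963 for both
cohesin and dockerin, an apparent duplication; the shipped dockerin default
is the standard Pfam dockerin family PF00404 and both accessions are plain
config fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from holocaz.model import GeneOnContig, SampleMeta


@dataclass(frozen=True)
class LocusMarkers:
    """Pfam accessions used as locus markers (all user-configurable)."""

    susC: str = "PF00593"
    susD: str = "PF07980"
    cohesin: str = "PF00963"
    dockerin: str = "PF00404"
    slh: str = "PF00395"


DEFAULT_MARKERS = LocusMarkers()


@dataclass
class PulCandidate:
    """One sequential susC-susD pair and its co-localized CAZyme genes."""

    contig_id: str
    susC_gene: GeneOnContig
    susD_gene: GeneOnContig
    colocalized_cazymes: list[tuple[GeneOnContig, frozenset[str]]] = field(
        default_factory=list
    )
    taxon: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        genes = [self.susC_gene, self.susD_gene] + [g for g, _ in self.colocalized_cazymes]
        return (min(g.start for g in genes), max(g.end for g in genes))


@dataclass
class PulScreenResult:
    candidates: list[PulCandidate]
    orphan_contigs: list[str]  # marker-bearing contigs without a sequential pair

    @property
    def n_marker_contigs(self) -> int:
        return len(self.orphan_contigs) + len({c.contig_id for c in self.candidates})


@dataclass
class CellulosomeCandidate:
    """Marker-bearing contig: cohesin/dockerin/SLH genes and fusions."""

    contig_id: str
    dockerin_genes: list[GeneOnContig] = field(default_factory=list)
    cohesin_genes: list[GeneOnContig] = field(default_factory=list)
    slh_genes: list[GeneOnContig] = field(default_factory=list)
    taxon: Optional[str] = None

    @property
    def cazyme_dockerin_fusions(self) -> list[tuple[GeneOnContig, frozenset[str]]]:
        return [
            (g, g.cazy_families) for g in self.dockerin_genes if g.cazy_families
        ]


def attach_domains(
    genes: Sequence[GeneOnContig], hits: Iterable
) -> list[GeneOnContig]:
    """Return genes with conserved-domain hits attached by orf_id."""
    per_orf: dict[str, set] = {}
    for hit in hits:
        per_orf.setdefault(hit.orf_id, set()).add(hit)
    return [
        GeneOnContig(
            g.contig_id, g.gene_index, g.start, g.end, g.strand, g.orf_id,
            frozenset(g.domains | per_orf.get(g.orf_id, set())), g.cazy_families,
        )
        for g in genes
    ]


def attach_cazymes(
    genes: Sequence[GeneOnContig], calls: Iterable
) -> list[GeneOnContig]:
    """Return genes with consensus CAZy families attached by orf_id."""
    per_orf: dict[str, set[str]] = {}
    for call in calls:
        per_orf.setdefault(call.orf_id, set()).add(call.family)
    return [
        GeneOnContig(
            g.contig_id, g.gene_index, g.start, g.end, g.strand, g.orf_id,
            g.domains, frozenset(g.cazy_families | per_orf.get(g.orf_id, set())),
        )
        for g in genes
    ]


def _by_contig(genes: Iterable[GeneOnContig]) -> dict[str, list[GeneOnContig]]:
    """Group by contig and recompute gene order from coordinates, so the
    screens are invariant to input list order."""
    grouped: dict[str, list[GeneOnContig]] = {}
    for g in genes:
        grouped.setdefault(g.contig_id, []).append(g)
    out: dict[str, list[GeneOnContig]] = {}
    for contig, members in grouped.items():
        members = sorted(members, key=lambda g: (g.start, g.end, g.orf_id))
        out[contig] = [
            GeneOnContig(g.contig_id, idx, g.start, g.end, g.strand, g.orf_id,
                         g.domains, g.cazy_families)
            for idx, g in enumerate(members, start=1)
        ]
    return out


def screen_pul(
    genes: Iterable[GeneOnContig],
    markers: LocusMarkers = DEFAULT_MARKERS,
    max_gene_gap: int = 1,
    require_susC_upstream: bool = False,
    require_same_strand: bool = False,
    cazyme_window_bp: Optional[int] = None,
    contig_taxa: Optional[dict[str, str]] = None,
) -> PulScreenResult:
    """Screen contigs for sequential susC-susD pairs.

    "Sequential" means gene_index difference of exactly ``max_gene_gap``
    (default 1 — immediately adjacent), in either order and regardless of
    strand. Canonical Bacteroidetes PULs are tandem susC-then-susD on one
    strand; ``require_susC_upstream`` and ``require_same_strand`` enable
    that strict mode. Co-localized CAZymes are all CAZy-family genes on the
    candidate's contig, optionally limited to ``cazyme_window_bp`` around
    the pair (default: the whole contig, appropriate for short metagenome
    contigs).
    """
    contig_taxa = contig_taxa or {}
    candidates: list[PulCandidate] = []
    orphans: list[str] = []
    for contig, members in sorted(_by_contig(genes).items()):
        susC = [g for g in members if markers.susC in g.domain_accessions]
        susD = [g for g in members if markers.susD in g.domain_accessions]
        if not susC and not susD:
            continue
        pairs: list[tuple[GeneOnContig, GeneOnContig]] = []
        for gc in susC:
            for gd in susD:
                if abs(gc.gene_index - gd.gene_index) != max_gene_gap:
                    continue
                if require_susC_upstream and gc.gene_index > gd.gene_index:
                    continue
                if require_same_strand and gc.strand != gd.strand:
                    continue
                pairs.append((gc, gd))
        if not pairs:
            orphans.append(contig)
            continue
        for gc, gd in pairs:
            lo, hi = min(gc.start, gd.start), max(gc.end, gd.end)
            coloc = []
            for g in members:
                if not g.cazy_families or g.orf_id in (gc.orf_id, gd.orf_id):
                    continue
                if cazyme_window_bp is not None:
                    if g.end < lo - cazyme_window_bp or g.start > hi + cazyme_window_bp:
                        continue
                coloc.append((g, g.cazy_families))
            candidates.append(
                PulCandidate(contig, gc, gd, coloc, taxon=contig_taxa.get(contig))
            )
    return PulScreenResult(candidates=candidates, orphan_contigs=orphans)


def screen_cellulosome(
    genes: Iterable[GeneOnContig],
    markers: LocusMarkers = DEFAULT_MARKERS,
    contig_taxa: Optional[dict[str, str]] = None,
) -> list[CellulosomeCandidate]:
    """Screen contigs for cohesin, dockerin and SLH marker genes.

    One candidate per contig bearing at least one marker; dockerin genes
    that also carry a CAZy family surface as enzyme-dockerin fusions.
    """
    contig_taxa = contig_taxa or {}
    out: list[CellulosomeCandidate] = []
    for contig, members in sorted(_by_contig(genes).items()):
        dock = [g for g in members if markers.dockerin in g.domain_accessions]
        coh = [g for g in members if markers.cohesin in g.domain_accessions]
        slh = [g for g in members if markers.slh in g.domain_accessions]
        if not (dock or coh or slh):
            continue
        out.append(
            CellulosomeCandidate(contig, dock, coh, slh, taxon=contig_taxa.get(contig))
        )
    return out


def fusion_report(
    candidates: Sequence[CellulosomeCandidate],
    meta: Optional[SampleMeta] = None,
    sample_of_contig: Optional[dict[str, SampleMeta]] = None,
) -> pd.DataFrame:
    """Tabulate enzyme-dockerin fusion genes, one row per fusion.

    Columns mirror a per-gene evidence table: host, origin, sex, tissue,
    assignation (contig taxon) and the gene's CAZy families joined as
    ``"GH26 + CBM35"``.
    """
    rows = []
    for cand in candidates:
        for gene, families in cand.cazyme_dockerin_fusions:
            m = (sample_of_contig or {}).get(cand.contig_id, meta)
            rows.append(
                {
                    "host": m.host_species if m else "",
                    "origin": m.origin if m else "",
                    "sex": m.sex if m else "",
                    "tissue": m.tissue if m else "",
                    "assignation": cand.taxon or "",
                    "contig_id": cand.contig_id,
                    "orf_id": gene.orf_id,
                    "cazymes": " + ".join(sorted(families)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["host", "origin", "sex", "tissue", "assignation", "contig_id",
                 "orf_id", "cazymes"],
    )


def render_pul_map(
    candidate: PulCandidate,
    genes: Optional[Sequence[GeneOnContig]] = None,
    markers: LocusMarkers = DEFAULT_MARKERS,
) -> str:
    """Render a PUL's gene organization as an ordered label string.

    CAZyme genes show their families, marker genes show susC/susD, and
    genes with neither are ``unk``, e.g. ``unk - susC - susD - GH43``.
    """
    if genes is None:
        members = sorted(
            {id(g): g for g in
             [candidate.susC_gene, candidate.susD_gene]
             + [g for g, _ in candidate.colocalized_cazymes]}.values(),
            key=lambda g: g.start,
        )
    else:
        members = sorted(
            (g for g in genes if g.contig_id == candidate.contig_id),
            key=lambda g: (g.start, g.end, g.orf_id),
        )
    labels = []
    for g in members:
        if markers.susC in g.domain_accessions:
            labels.append("susC")
        elif markers.susD in g.domain_accessions:
            labels.append("susD")
        elif g.cazy_families:
            labels.append("+".join(sorted(g.cazy_families)))
        else:
            labels.append("unk")
    return " - ".join(labels)


def brute_force_fusion_count(genes: Iterable[GeneOnContig],
                             markers: LocusMarkers = DEFAULT_MARKERS) -> int:
    """Independent recount of enzyme-dockerin fusion genes."""
    return sum(
        1
        for g in genes
        if markers.dockerin in g.domain_accessions and g.cazy_families
    )
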