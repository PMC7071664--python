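"""End-to-end orchestration: annotate -> quantify -> classify -> taxonomy
-> locus screens, with a provenance manifest.

The pipeline consumes a dataset directory with a ``samples.tsv`` metadata
table and one subdirectory per sample holding ``genes.gff3``,
``hits_hmm.tsv``, ``hits_sim.tsv``, ``hits_pep.tsv``, ``pfam_hits.tsv``,
``lineages.tsv`` and optionally ``activities.tsv`` (orf_id, family,
predicted_activity) — exactly the layout the synthetic generator emits.
Runs are deterministic given inputs and config; every filtered record
increments a named counter surfaced in the run manifest, and input files
are checksummed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

import holocaz
from holocaz import domain_io
from holocaz.consensus import (
    CazymeCall,
    call_consensus,
    count_families,
    partition_families,
)
from holocaz.ligno import (
    ActivityPrediction,
    ClassSummary,
    breakdown_table,
    classify_calls,
    load_class_map,
    summarize_classes,
)
from holocaz.loci import (
    DEFAULT_MARKERS,
    LocusMarkers,
    attach_cazymes,
    attach_domains,
    fusion_report,
    render_pul_map,
    screen_cellulosome,
    screen_pul,
)
from holocaz.model import TaxonLineage
from holocaz.quantify import FamilyCountMatrix, normalize_counts
from holocaz.simulate import PipelineOutputs
from holocaz.taxonomy import assign_orfs, lca, profile_community

PathLike = Union[str, Path]


class PipelineError(RuntimeError):
    """A stage-tagged fatal pipeline error."""


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run.

    ``class_map_path`` None loads the packaged lignocellulose class map;
    ``groups`` None groups normalization by dataset kind.
    """

    input_dir: PathLike
    out_dir: PathLike
    similarity_evalue_max: float = 1e-50
    lineage_evalue_cutoff: float = 1e-4
    lineage_top_k: int = 5
    markers: LocusMarkers = DEFAULT_MARKERS
    class_map_path: Optional[PathLike] = None
    groups: Optional[dict[str, list[str]]] = None
    subfamily: bool = False
    strict: bool = False

    def validate(self) -> None:
        if self.similarity_evalue_max <= 0 or self.lineage_evalue_cutoff <= 0:
            raise PipelineError("config: thresholds must be positive")
        if self.lineage_top_k <= 0:
            raise PipelineError("config: lineage_top_k must be positive")
        if not Path(self.input_dir).is_dir():
            raise PipelineError(f"config: input directory not found: {self.input_dir}")


@dataclass
class RunBundle:
    """In-memory results of a pipeline run (also written to out_dir)."""

    config: RunConfig
    samples: list
    calls: list[CazymeCall]
    partial_calls: list
    matrix: FamilyCountMatrix
    annotated: list
    class_summary: ClassSummary
    assignments: dict
    community_phylum: pd.DataFrame
    community_order: pd.DataFrame
    pul_result: object
    cellulosome_candidates: list
    fusion_table: pd.DataFrame
    manifest: dict

    def as_outputs(self) -> PipelineOutputs:
        return PipelineOutputs(
            calls=self.calls,
            pul_result=self.pul_result,
            cellulosome_candidates=self.cellulosome_candidates,
            scenario_id=self.manifest.get("scenario_id"),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"[{stage}] missing input: {path}")
    return path


def run_pipeline(config: RunConfig) -> RunBundle:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    config.validate()
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    checksums: dict[str, str] = {}

    def read(stage: str, fn, path: Path, *args, **kwargs):
        _require(path, stage)
        checksums[str(path.relative_to(in_dir))] = _sha256(path)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", domain_io.ParserWarning)
            result = fn(path, *args, **kwargs)
        skipped = sum(1 for w in caught
                      if issubclass(w.category, domain_io.ParserWarning))
        if skipped:
            counters[f"{stage}.rows_skipped"] = (
                counters.get(f"{stage}.rows_skipped", 0) + skipped
            )
        return result

    samples = read("metadata", domain_io.read_sample_meta, in_dir / "samples.tsv")
    all_calls: list[CazymeCall] = []
    all_partial: list = []
    all_annotated: list = []
    all_genes_by_sample: dict[str, list] = {}
    all_lineages: list[TaxonLineage] = []
    activities_by_sample: dict[str, list[ActivityPrediction]] = {}
    class_map = load_class_map(config.class_map_path)

    for sample in samples:
        sdir = in_dir / sample.sample_id
        hits = []
        for fname, dialect in (
            ("hits_hmm.tsv", "hmm_domtbl"),
            ("hits_sim.tsv", "similarity_tab"),
            ("hits_pep.tsv", "peptide_tab"),
        ):
            hits.extend(
                read("annotate", domain_io.read_domain_hits, sdir / fname,
                     dialect, strict=config.strict)
            )
        result = call_consensus(
            hits,
            similarity_evalue_max=config.similarity_evalue_max,
            subfamily=config.subfamily,
            sample_id=sample.sample_id,
        )
        all_calls.extend(result.calls)
        all_partial.extend(result.partial)
        counters[f"consensus.partial.{sample.sample_id}"] = len(result.partial)

        genes = read("screens", domain_io.read_gene_table, sdir / "genes.gff3",
                     strict=config.strict)
        pfam_hits = read("screens", domain_io.read_domain_hits,
                         sdir / "pfam_hits.tsv", "hmm_domtbl",
                         strict=config.strict)
        genes = attach_domains(genes, pfam_hits)
        genes = attach_cazymes(genes, result.calls)
        all_genes_by_sample[sample.sample_id] = genes

        all_lineages.extend(
            read("taxonomy", domain_io.read_lineages, sdir / "lineages.tsv",
                 top_k=config.lineage_top_k,
                 evalue_cutoff=config.lineage_evalue_cutoff,
                 strict=config.strict)
        )

        act_path = sdir / "activities.tsv"
        acts: list[ActivityPrediction] = []
        if act_path.exists():
            checksums[str(act_path.relative_to(in_dir))] = _sha256(act_path)
            for line in act_path.read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) >= 3:
                    acts.append(ActivityPrediction(cols[0], cols[1], cols[2]))
        activities_by_sample[sample.sample_id] = acts
        all_annotated.extend(
            classify_calls(result.calls, acts, class_map)
        )

    # quantify
    matrix = count_families(all_calls, samples)
    matrix = normalize_counts(matrix, samples, groups=config.groups)

    # taxonomy
    assignments = assign_orfs(all_lineages)
    community_phylum = profile_community(assignments, all_calls, "phylum")
    community_order = profile_community(assignments, all_calls, "order")

    # contig taxa: LCA over the contig's assigned ORFs, deepest name kept
    contig_taxa: dict[str, str] = {}
    for sample_id, genes in all_genes_by_sample.items():
        per_contig: dict[str, list] = {}
        for g in genes:
            a = assignments.get(g.orf_id)
            if a is not None and a.assigned_lineage:
                per_contig.setdefault(g.contig_id, []).append(
                    TaxonLineage(g.contig_id, 1, a.assigned_lineage)
                )
        for contig, lins in per_contig.items():
            merged = lca(lins)
            if merged.assigned_lineage:
                contig_taxa[contig] = merged.assigned_lineage[-1][1]

    # screens
    all_genes = [g for genes in all_genes_by_sample.values() for g in genes]
    pul_result = screen_pul(all_genes, markers=config.markers,
                            contig_taxa=contig_taxa)
    cell_cands = screen_cellulosome(all_genes, markers=config.markers,
                                    contig_taxa=contig_taxa)
    meta_by_id = {s.sample_id: s for s in samples}
    contig_sample = {
        g.contig_id: meta_by_id[sid]
        for sid, genes in all_genes_by_sample.items()
        for g in genes
    }
    fusion_table = fusion_report(cell_cands, sample_of_contig=contig_sample)

    class_summary = summarize_classes(all_annotated)

    # scenario id passthrough for synthetic datasets
    scenario_id = None
    sim_manifest = in_dir / "manifest.json"
    if sim_manifest.exists():
        try:
            scenario_id = json.loads(sim_manifest.read_text()).get("scenario_id")
        except json.JSONDecodeError:
            scenario_id = None

    manifest = {
        "tool": "holocaz",
        "version": holocaz.__version__,
        "config": {
            "similarity_evalue_max": config.similarity_evalue_max,
            "lineage_evalue_cutoff": config.lineage_evalue_cutoff,
            "lineage_top_k": config.lineage_top_k,
            "subfamily": config.subfamily,
            "markers": vars(config.markers).copy(),
        },
        "input_checksums": dict(sorted(checksums.items())),
        "counters": dict(sorted(counters.items())),
        "scenario_id": scenario_id,
    }

    bundle = RunBundle(
        config=config, samples=samples, calls=all_calls,
        partial_calls=all_partial, matrix=matrix, annotated=all_annotated,
        class_summary=class_summary, assignments=assignments,
        community_phylum=community_phylum, community_order=community_order,
        pul_result=pul_result, cellulosome_candidates=cell_cands,
        fusion_table=fusion_table, manifest=manifest,
    )
    _write_bundle(bundle, out_dir, meta_by_id)
    return bundle


def _write_bundle(bundle: RunBundle, out_dir: Path, meta_by_id: dict) -> None:
    calls_df = pd.DataFrame(
        [{"orf_id": c.orf_id, "family": c.family,
          "evidence": ",".join(sorted(t.value for t in c.evidence)),
          "module_count": c.module_count, "sample_id": c.sample_id}
         for c in bundle.calls]
    )
    calls_df.to_csv(out_dir / "calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"orf_id": p.orf_id, "family": p.family,
          "evidence": ",".join(sorted(t.value for t in p.evidence)),
          "sample_id": p.sample_id}
         for p in bundle.partial_calls]
    ).to_csv(out_dir / "partial_calls.tsv", sep="\t", index=False)
    bundle.matrix.to_tsv(out_dir / "matrix_raw.tsv", normalized=False)
    bundle.matrix.to_tsv(out_dir / "matrix_normalized.tsv", normalized=True)
    breakdown_table(bundle.annotated, bundle.samples).to_csv(
        out_dir / "class_breakdown.tsv", sep="\t", index=False
    )
    bundle.community_phylum.to_csv(out_dir / "community_phylum.tsv", sep="\t")
    bundle.community_order.to_csv(out_dir / "community_order.tsv", sep="\t")
    pd.DataFrame(
        [{"contig_id": c.contig_id, "susC": c.susC_gene.orf_id,
          "susD": c.susD_gene.orf_id,
          "cazymes": ";".join(sorted(
              fam for _, fams in c.colocalized_cazymes for fam in fams)),
          "taxon": c.taxon or "", "span_start": c.span[0],
          "span_end": c.span[1]}
         for c in bundle.pul_result.candidates]
    ).to_csv(out_dir / "pul_report.tsv", sep="\t", index=False)
    pd.DataFrame({"contig_id": bundle.pul_result.orphan_contigs}).to_csv(
        out_dir / "pul_orphans.tsv", sep="\t", index=False
    )
    with (out_dir / "pul_maps.txt").open("w") as fh:
        for cand in bundle.pul_result.candidates:
            fh.write(f"{cand.contig_id}\t{render_pul_map(cand)}\n")
    pd.DataFrame(
        [{"contig_id": c.contig_id,
          "dockerin_genes": len(c.dockerin_genes),
          "cohesin_genes": len(c.cohesin_genes),
          "slh_genes": len(c.slh_genes),
          "fusions": len(c.cazyme_dockerin_fusions),
          "taxon": c.taxon or ""}
         for c in bundle.cellulosome_candidates]
    ).to_csv(out_dir / "cellulosome_report.tsv", sep="\t", index=False)
    bundle.fusion_table.to_csv(out_dir / "fusion_report.tsv", sep="\t",
                               index=False)
    (out_dir / "run_manifest.json").write_text(
        json.dumps(bundle.manifest, indent=1, sort_keys=True) + "\n"
    )
    (out_dir / "summary.json").write_text(
        json.dumps(headline_summary(bundle), indent=1, sort_keys=True) + "\n"
    )


def headline_summary(bundle: RunBundle) -> dict:
    """Headline numbers in the report's mixed precision.

    Totals and splits are plain module sums; percentages are shown to one
    decimal; ratios to one decimal. Undefined percentages (no predicted
    modules) are reported as None, never 0.
    """
    kinds = {s.sample_id: s.dataset_kind for s in bundle.samples}
    modules_by_kind: dict[str, int] = {}
    families_by_kind: dict[str, set] = {}
    for c in bundle.calls:
        kind = kinds.get(c.sample_id, "unknown")
        modules_by_kind[kind] = modules_by_kind.get(kind, 0) + c.module_count
        families_by_kind.setdefault(kind, set()).add(c.family)
    part = partition_families(
        families_by_kind.get("metagenome", set()),
        families_by_kind.get("transcriptome", set()),
    )
    cs = bundle.class_summary
    watch_fams_by_kind: dict[str, set] = {}
    for a in bundle.annotated:
        if a.status == "not_applicable":
            continue
        kind = kinds.get(a.call.sample_id, "unknown")
        watch_fams_by_kind.setdefault(kind, set()).add(a.call.family)
    n_meta_watch = len(watch_fams_by_kind.get("metagenome", set()))
    n_host_watch = len(watch_fams_by_kind.get("transcriptome", set()))
    ratio = round(n_meta_watch / n_host_watch, 1) if n_host_watch else None
    return {
        "total_modules": sum(modules_by_kind.values()),
        "modules_by_kind": dict(sorted(modules_by_kind.items())),
        "family_union": part.union_size,
        "host_only_families": len(part.host_only),
        "microbiota_only_families": len(part.microbiota_only),
        "shared_families": len(part.shared),
        "watchlist_modules": cs.n_watchlist_modules,
        "watchlist_families": cs.n_families,
        "watchlist_families_by_class": dict(sorted(cs.families_by_class.items())),
        "pct_modules_with_prediction": _round1(cs.pct_predicted),
        "pct_lignocellulolytic_of_predicted": _round1(cs.pct_ligno_predicted),
        "pct_other_substrate_of_predicted": _round1(cs.pct_other_predicted),
        "watchlist_family_ratio_microbiota_to_host": ratio,
        "pul_candidates": len(bundle.pul_result.candidates),
        "pul_orphan_contigs": len(bundle.pul_result.orphan_contigs),
        "cellulosome_contigs": len(bundle.cellulosome_candidates),
        "dockerin_cazyme_fusions": int(len(bundle.fusion_table)),
    }


def _round1(value: Optional[float]) -> Optional[float]:
    return None if value is None else round(value, 1)
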