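"""Synthetic holobiont datasets with known ground truth.

The generator emulates the statistical structure the pipeline consumes —
assembled-contig gene models, per-ORF three-tool CAZyme evidence,
conserved-domain (Pfam) marker hits, top-k taxonomy lineages and sample
metadata — not sequence content (no reads, no realistic HMM score
distributions). Planted truth:

* CAZyme ORFs, each with a true family; every tool independently reports
  the true family with probability ``tool_agreement_q``, otherwise it is
  silent or (at ``confusion_rate``) reports a wrong family. Consensus
  recall on these ORFs converges to q^3.
* PUL loci: contigs with an adjacent susC-susD gene pair plus a
  co-localized CAZyme gene; decoy contigs carry orphan susC/susD genes or
  a non-adjacent pair.
* Cellulosome loci: contigs with a cohesin+SLH scaffoldin gene and
  dockerin-bearing CAZyme (fusion) genes.

Outputs are written in exactly the formats ``holocaz.domain_io`` reads,
one subdirectory per sample, with a JSON manifest listing every planted
item. Generation is a pure function of the scenario: a fixed seed gives
byte-identical outputs, with all randomness drawn from one
``numpy.random.default_rng`` stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from holocaz.loci import DEFAULT_MARKERS, LocusMarkers
from holocaz.model import SampleMeta

PathLike = Union[str, Path]

#: CAZy families planted by default: watchlist hemicellulases/cellulases
#: plus abundant non-watchlist families (GH13, GT2, GH18) as they dominate
#: real CAZomes.
DEFAULT_FAMILY_POOL = (
    "GH13", "GT2", "GH18", "GH23", "GT4", "CBM50",
    "GH5", "GH3", "GH1", "GH9", "GH43", "GH16", "GH26", "GH10", "GH35",
    "CE1", "CE4", "AA1", "AA3", "AA10", "CBM35", "PL9", "GH2", "GH130",
)

#: Lineages drawn for CAZyme ORFs (domain;phylum;class;order).
DEFAULT_TAXA_POOL = (
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales",
    "Bacteria;Bacteroidetes;Cytophagia;Cytophagales",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Vibrionales",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales",
    "Bacteria;Actinobacteria;Actinomycetia;Micrococcales",
    "Bacteria;Planctomycetes;Planctomycetia;Planctomycetales",
)

#: Bacteroidetes-only lineages for PUL contigs (PULs are a Bacteroidetes
#: system).
BACTEROIDETES_TAXA = (
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales",
    "Bacteria;Bacteroidetes;Cytophagia;Cytophagales",
)

#: Activity emitted by the simulated peptide predictor, per family. CBMs
#: and GTs have no hydrolytic activity and get none.
DEFAULT_ACTIVITY_BY_FAMILY = {
    "GH13": "alpha-amylase",
    "GH18": "chitinase",
    "GH23": "lysozyme",
    "GH1": "beta-glucosidase",
    "GH2": "beta-galactosidase",
    "GH3": "beta-glucosidase",
    "GH5": "endoglucanase",
    "GH9": "endoglucanase",
    "GH10": "xylanase",
    "GH16": "licheninase",
    "GH26": "beta-mannanase",
    "GH35": "beta-galactosidase",
    "GH43": "xylanase",
    "GH130": "beta-mannoside phosphorylase",
    "CE1": "acetyl xylan esterase",
    "CE4": "acetyl xylan esterase",
    "PL9": "pectate lyase",
    "AA1": "laccase",
    "AA3": "cellobiose dehydrogenase",
    "AA10": "lytic polysaccharide monooxygenase",
}

_PFAM_NAMES = {
    "PF00593": "TonB_dep_Rec",
    "PF07980": "SusD",
    "PF00963": "Cohesin",
    "PF00404": "Dockerin_1",
    "PF00395": "SLH",
}


@dataclass(frozen=True)
class SampleSpec:
    """Declared identity of one synthetic sample; its ``n_orfs`` is the
    number of genes the generator actually places on its contigs."""

    sample_id: str
    host_species: str = "A. aquaticus"
    origin: str = "laboratory"
    sex: str = "male"
    tissue: str = "hindgut"
    dataset_kind: str = "metagenome"


DEFAULT_SAMPLES = (
    SampleSpec("mg_lab_male_hindgut", "A. aquaticus", "laboratory", "male", "hindgut"),
    SampleSpec("mg_field_female_caeca", "P. pruinosus", "field", "female", "caeca"),
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of one synthetic dataset.

    Defaults: 5 planted PUL pairs and 50 orphan/non-adjacent decoys (the
    planted-locus validation design), 6 cellulosome contigs carrying 30
    enzyme-dockerin fusion genes in total (the scale reported for
    dockerin-bearing CAZyme genes in isopod metagenomes), 300 background
    CAZyme ORFs, and inter-tool agreement q = 0.8 with a 10% confusion
    rate for non-agreeing tools.
    """

    seed: int = 0
    n_contigs: int = 120
    planted_puls: int = 5
    planted_cellulosomes: int = 6
    planted_fusions: int = 30
    decoy_orphans: int = 50
    n_cazyme_orfs: int = 300
    tool_agreement_q: float = 0.8
    confusion_rate: float = 0.1
    multi_domain_rate: float = 0.1
    activity_rate: float = 0.418
    family_pool: tuple[str, ...] = DEFAULT_FAMILY_POOL
    taxa_pool: tuple[str, ...] = DEFAULT_TAXA_POOL
    samples: tuple[SampleSpec, ...] = DEFAULT_SAMPLES
    markers: LocusMarkers = DEFAULT_MARKERS
    lineage_top_k: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.tool_agreement_q <= 1.0:
            raise ValueError("tool_agreement_q must be in [0, 1]")
        if not 0.0 <= self.confusion_rate <= 1.0:
            raise ValueError("confusion_rate must be in [0, 1]")
        reserved = self.planted_puls + self.planted_cellulosomes + self.decoy_orphans
        if reserved > self.n_contigs:
            raise ValueError(
                f"impossible layout: {reserved} planted/decoy contigs exceed "
                f"n_contigs={self.n_contigs}"
            )

    @property
    def scenario_id(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def generate(scenario: SyntheticScenario, out_dir: PathLike) -> dict:
    """Write the synthetic dataset and return its ground-truth manifest.

    Layout under ``out_dir``: one subdirectory per sample with
    ``genes.gff3``, ``hits_hmm.tsv`` (HMMER3 domtblout), ``hits_sim.tsv``
    (outfmt-6), ``hits_pep.tsv``, ``pfam_hits.tsv`` (domtblout) and
    ``lineages.tsv``; plus top-level ``samples.tsv`` and
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(scenario.seed)
    mk = scenario.markers

    # --- contig layout ------------------------------------------------
    roles = (
        ["pul"] * scenario.planted_puls
        + ["decoy"] * scenario.decoy_orphans
        + ["cellulosome"] * scenario.planted_cellulosomes
        + ["background"] * (
            scenario.n_contigs
            - scenario.planted_puls
            - scenario.decoy_orphans
            - scenario.planted_cellulosomes
        )
    )
    rng.shuffle(roles)

    n_samples = len(scenario.samples)
    contigs = []  # (contig_id, sample_idx, role, genes)
    orf_serial = 0
    for ci, role in enumerate(roles):
        sample_idx = ci % n_samples
        contig_id = f"s{sample_idx}_c{ci:05d}"
        # cellulosome contigs need room for their fusion-gene quota
        min_genes = {"pul": 4, "decoy": 4, "cellulosome": 7}.get(role, 3)
        n_genes = int(rng.integers(min_genes, 9))
        genes = []
        cursor = int(rng.integers(1, 200))
        for gi in range(n_genes):
            length = int(rng.integers(300, 1501))
            strand = "+" if rng.random() < 0.5 else "-"
            orf_serial += 1
            orf_id = f"orf_{orf_serial:06d}"
            genes.append(
                {"orf_id": orf_id, "start": cursor, "end": cursor + length - 1,
                 "strand": strand, "pfam": [], "true_families": []}
            )
            cursor += length + int(rng.integers(20, 201))
        contigs.append({"contig_id": contig_id, "sample_idx": sample_idx,
                        "role": role, "genes": genes})

    # --- plant marker loci --------------------------------------------
    truth_puls = []
    truth_decoys = []
    truth_cellulosomes = []
    fusion_genes: dict[str, list[str]] = {}
    cazyme_truth: dict[str, list[str]] = {}  # orf_id -> true families
    background_cazymes: dict[str, list[str]] = {}  # subset under the agreement model
    contig_taxa: dict[str, str] = {}
    watch_pool = [f for f in scenario.family_pool if f not in ("GH13", "GT2", "GH18")]

    decoy_kinds = ["susC_only", "susD_only", "nonadjacent"]
    decoy_counter = 0
    fusion_quota = _split_evenly(
        scenario.planted_fusions, scenario.planted_cellulosomes, rng
    )
    cellulosome_seen = 0
    for contig in contigs:
        genes = contig["genes"]
        role = contig["role"]
        if role == "pul":
            pos = int(rng.integers(0, len(genes) - 1))
            first_is_c = bool(rng.random() < 0.5)
            genes[pos]["pfam"].append(mk.susC if first_is_c else mk.susD)
            genes[pos + 1]["pfam"].append(mk.susD if first_is_c else mk.susC)
            free = [g for g in genes if not g["pfam"]]
            coloc_orfs = []
            if free:
                g = free[int(rng.integers(0, len(free)))]
                fam = str(rng.choice(["GH3", "GH16", "GH43"]))
                g["true_families"].append(fam)
                cazyme_truth[g["orf_id"]] = [fam]
                coloc_orfs.append(g["orf_id"])
            taxon = str(rng.choice(BACTEROIDETES_TAXA))
            contig_taxa[contig["contig_id"]] = taxon
            truth_puls.append(
                {"contig_id": contig["contig_id"],
                 "susC_orf": genes[pos]["orf_id"] if first_is_c else genes[pos + 1]["orf_id"],
                 "susD_orf": genes[pos + 1]["orf_id"] if first_is_c else genes[pos]["orf_id"],
                 "colocalized_cazymes": coloc_orfs,
                 "taxon": taxon}
            )
        elif role == "decoy":
            kind = decoy_kinds[decoy_counter % len(decoy_kinds)]
            decoy_counter += 1
            if kind == "susC_only":
                genes[int(rng.integers(0, len(genes)))]["pfam"].append(mk.susC)
            elif kind == "susD_only":
                genes[int(rng.integers(0, len(genes)))]["pfam"].append(mk.susD)
            else:  # non-adjacent pair: separated by >= 2 positions
                i = 0
                j = int(rng.integers(2, len(genes)))
                genes[i]["pfam"].append(mk.susC)
                genes[j]["pfam"].append(mk.susD)
            truth_decoys.append({"contig_id": contig["contig_id"], "kind": kind})
        elif role == "cellulosome":
            scaffoldin = genes[0]
            scaffoldin["pfam"].extend([mk.cohesin, mk.slh])
            n_fusions = min(fusion_quota[cellulosome_seen], len(genes) - 1)
            cellulosome_seen += 1
            fusion_members = []
            for g in genes[1 : 1 + n_fusions]:
                g["pfam"].append(mk.dockerin)
                fams = [str(rng.choice(watch_pool))]
                if rng.random() < 0.2:  # occasional CAZyme + CBM fusion
                    fams.append("CBM35")
                g["true_families"].extend(fams)
                # multi-family ORFs yield one call per family
                cazyme_truth[g["orf_id"]] = sorted(set(fams))
                fusion_genes[g["orf_id"]] = sorted(set(fams))
                fusion_members.append(g["orf_id"])
            taxon = str(rng.choice(scenario.taxa_pool))
            contig_taxa[contig["contig_id"]] = taxon
            truth_cellulosomes.append(
                {"contig_id": contig["contig_id"],
                 "scaffoldin_orf": scaffoldin["orf_id"],
                 "fusion_orfs": fusion_members,
                 "taxon": taxon}
            )

    # --- plant background CAZyme ORFs ---------------------------------
    free_slots = [
        g for contig in contigs for g in contig["genes"]
        if not g["pfam"] and not g["true_families"]
    ]
    if scenario.n_cazyme_orfs > len(free_slots):
        raise ValueError(
            f"impossible layout: {scenario.n_cazyme_orfs} CAZyme ORFs requested "
            f"but only {len(free_slots)} free gene slots; raise n_contigs"
        )
    chosen = rng.choice(len(free_slots), size=scenario.n_cazyme_orfs, replace=False)
    for idx in sorted(int(i) for i in chosen):
        g = free_slots[idx]
        fam = str(rng.choice(scenario.family_pool))
        g["true_families"].append(fam)
        cazyme_truth[g["orf_id"]] = [fam]
        background_cazymes[g["orf_id"]] = [fam]

    # --- per-ORF evidence ---------------------------------------------
    # Fusion and PUL-colocalized CAZymes get deterministic three-tool
    # evidence (planted loci must be re-derivable from the files);
    # background CAZymes are subject to the agreement model.
    deterministic_orfs = set(fusion_genes) | {
        o for p in truth_puls for o in p["colocalized_cazymes"]
    }
    per_sample_rows: dict[int, dict[str, list[str]]] = {
        i: {"hmm": [], "sim": [], "pep": [], "pfam": [], "lin": [], "act": []}
        for i in range(n_samples)
    }
    q = scenario.tool_agreement_q
    for contig in contigs:
        rows = per_sample_rows[contig["sample_idx"]]
        for g in contig["genes"]:
            aa_len = max((g["end"] - g["start"] + 1) // 3, 60)
            for acc in g["pfam"]:
                rows["pfam"].append(_domtbl_row(
                    _PFAM_NAMES.get(acc, acc), f"{acc}.21", g["orf_id"], aa_len,
                    1e-12, 5, min(120, aa_len)))
            for fam in g["true_families"]:
                reports = {}
                for tool in ("hmm", "sim", "pep"):
                    if g["orf_id"] in deterministic_orfs or rng.random() < q:
                        reports[tool] = fam
                    elif rng.random() < scenario.confusion_rate:
                        wrong = str(rng.choice(scenario.family_pool))
                        if wrong != fam:
                            reports[tool] = wrong
                if "hmm" in reports:
                    n_dom = 2 if rng.random() < scenario.multi_domain_rate else 1
                    for d in range(n_dom):
                        lo = 5 + d * (aa_len // 2)
                        rows["hmm"].append(_domtbl_row(
                            f"{reports['hmm']}.hmm", "-", g["orf_id"], aa_len,
                            1e-60, lo, min(lo + 90, aa_len)))
                if "sim" in reports:
                    rows["sim"].append(
                        f"{g['orf_id']}\tcazydb|{reports['sim']}\t92.5\t{aa_len}"
                        f"\t8\t0\t1\t{aa_len}\t1\t{aa_len}\t1e-80\t350.1"
                    )
                if "pep" in reports:
                    rows["pep"].append(f"{g['orf_id']}\t{reports['pep']}\t12")
                activity = DEFAULT_ACTIVITY_BY_FAMILY.get(fam)
                if activity is not None and rng.random() < scenario.activity_rate:
                    rows["act"].append(f"{g['orf_id']}\t{fam}\t{activity}")
            if g["true_families"]:
                base = contig_taxa.get(
                    contig["contig_id"], str(rng.choice(scenario.taxa_pool))
                )
                n_hits = int(rng.integers(2, scenario.lineage_top_k + 1))
                names = base.split(";")
                for h in range(n_hits):
                    if h == 0 or rng.random() < 0.6:
                        lineage = names
                    else:  # sibling order within the same class
                        lineage = names[:3] + [names[3] + "_sibling"]
                    evalue = 10.0 ** -float(rng.integers(20, 80))
                    rows["lin"].append(
                        f"{g['orf_id']}\t{h + 1}\t{evalue:.2e}\t{';'.join(lineage)}"
                    )

    # --- write files ----------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_meta = []
    for i, spec in enumerate(scenario.samples):
        sdir = out_dir / spec.sample_id
        sdir.mkdir(exist_ok=True)
        my_contigs = [c for c in contigs if c["sample_idx"] == i]
        with (sdir / "genes.gff3").open("w") as fh:
            fh.write("##gff-version 3\n")
            for c in my_contigs:
                for g in c["genes"]:
                    fh.write(
                        f"{c['contig_id']}\tholocaz_sim\tCDS\t{g['start']}\t"
                        f"{g['end']}\t.\t{g['strand']}\t0\tID={g['orf_id']}\n"
                    )
        rows = per_sample_rows[i]
        (sdir / "hits_hmm.tsv").write_text("".join(r + "\n" for r in rows["hmm"]))
        (sdir / "hits_sim.tsv").write_text("".join(r + "\n" for r in rows["sim"]))
        (sdir / "hits_pep.tsv").write_text("".join(r + "\n" for r in rows["pep"]))
        (sdir / "pfam_hits.tsv").write_text("".join(r + "\n" for r in rows["pfam"]))
        (sdir / "lineages.tsv").write_text("".join(r + "\n" for r in rows["lin"]))
        (sdir / "activities.tsv").write_text("".join(r + "\n" for r in rows["act"]))
        n_orfs = sum(len(c["genes"]) for c in my_contigs)
        sample_meta.append(SampleMeta(
            sample_id=spec.sample_id, host_species=spec.host_species,
            origin=spec.origin, sex=spec.sex, tissue=spec.tissue,
            dataset_kind=spec.dataset_kind, n_orfs=max(n_orfs, 1),
        ))
    from holocaz.domain_io import write_sample_meta

    write_sample_meta(sample_meta, out_dir / "samples.tsv")

    manifest = {
        "scenario_id": scenario.scenario_id,
        "scenario": dataclasses.asdict(scenario),
        "samples": [m.sample_id for m in sample_meta],
        "sample_of_contig": {
            c["contig_id"]: scenario.samples[c["sample_idx"]].sample_id
            for c in contigs
        },
        "cazyme_truth": cazyme_truth,
        "background_cazymes": background_cazymes,
        "pul_loci": truth_puls,
        "decoy_contigs": truth_decoys,
        "cellulosome_loci": truth_cellulosomes,
        "fusion_genes": fusion_genes,
        "contig_taxa": contig_taxa,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def _split_evenly(total: int, parts: int, rng) -> list[int]:
    if parts == 0:
        return []
    base = total // parts
    quota = [base] * parts
    for i in range(total - base * parts):
        quota[i] += 1
    return quota


def _domtbl_row(target: str, t_acc: str, orf: str, qlen: int, evalue: float,
                ali_from: int, ali_to: int) -> str:
    # 22 whitespace-delimited columns + description, HMMER3 domtblout order
    return (
        f"{target} {t_acc} 200 {orf} - {qlen} {evalue:.1e} 250.0 0.1 1 1 "
        f"{evalue:.1e} {evalue:.1e} 249.0 0.1 1 190 {ali_from} {ali_to} "
        f"{max(ali_from - 2, 1)} {min(ali_to + 2, qlen)} 0.98 synthetic"
    )


# ---------------------------------------------------------------------------
# scoring pipeline outputs against the manifest


@dataclass
class PipelineOutputs:
    """The stage outputs score_against_truth evaluates."""

    calls: list = field(default_factory=list)  # CazymeCall
    pul_result: Optional[object] = None  # PulScreenResult
    cellulosome_candidates: list = field(default_factory=list)
    scenario_id: Optional[str] = None


@dataclass(frozen=True)
class StageScores:
    """Precision/recall of one stage; None where undefined (no positives)."""

    precision: Optional[float]
    recall: Optional[float]
    exact: bool


def _pr(predicted: set, truth: set) -> StageScores:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(truth) if truth else None
    return StageScores(precision, recall, predicted == truth)


def score_against_truth(
    outputs: PipelineOutputs, manifest: dict
) -> dict[str, StageScores]:
    """Per-stage precision/recall of pipeline outputs vs planted truth.

    Stages: ``consensus`` on (orf, family) pairs; ``pul`` on pair-bearing
    contigs; ``pul_orphans`` on decoy contigs; ``fusions`` on
    enzyme-dockerin fusion ORFs. Outputs and manifest must come from the
    same scenario when both carry a scenario id.
    """
    mid = manifest.get("scenario_id")
    if outputs.scenario_id is not None and mid is not None and outputs.scenario_id != mid:
        raise ValueError(
            f"scenario mismatch: outputs {outputs.scenario_id} vs manifest {mid}"
        )
    scores: dict[str, StageScores] = {}
    truth_calls = {
        (orf, fam)
        for orf, fams in manifest["cazyme_truth"].items()
        for fam in fams
    }
    pred_calls = {(c.orf_id, c.family) for c in outputs.calls}
    scores["consensus"] = _pr(pred_calls, truth_calls)
    if outputs.pul_result is not None:
        truth_contigs = {p["contig_id"] for p in manifest["pul_loci"]}
        pred_contigs = {c.contig_id for c in outputs.pul_result.candidates}
        scores["pul"] = _pr(pred_contigs, truth_contigs)
        truth_orphans = {d["contig_id"] for d in manifest["decoy_contigs"]}
        scores["pul_orphans"] = _pr(set(outputs.pul_result.orphan_contigs),
                                    truth_orphans)
    if outputs.cellulosome_candidates:
        pred_fusions = {
            g.orf_id
            for cand in outputs.cellulosome_candidates
            for g, _ in cand.cazyme_dockerin_fusions
        }
        scores["fusions"] = _pr(pred_fusions, set(manifest["fusion_genes"]))
    return scores
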