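"""Synthetic generator: determinism, limit cases, manifest consistency,
truth scoring."""

import hashlib
import json
from pathlib import Path

import pytest

from holocaz import domain_io
from holocaz.consensus import call_consensus
from holocaz.loci import LocusMarkers, screen_pul
from holocaz.simulate import (
    PipelineOutputs,
    StageScores,
    SyntheticScenario,
    generate,
    score_against_truth,
)


def consensus_calls(scenario_dir):
    calls = []
    for sdir in sorted(p for p in Path(scenario_dir).iterdir() if p.is_dir()):
        hits = (
            domain_io.read_domain_hits(sdir / "hits_hmm.tsv", "hmm_domtbl")
            + domain_io.read_domain_hits(sdir / "hits_sim.tsv", "similarity_tab")
            + domain_io.read_domain_hits(sdir / "hits_pep.tsv", "peptide_tab")
        )
        calls.extend(call_consensus(hits, sample_id=sdir.name).calls)
    return calls


def tree_digest(root):
    digest = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            digest.update(str(p.relative_to(root)).encode())
            digest.update(p.read_bytes())
    return digest.hexdigest()


class TestGenerate:
    def test_fixed_seed_byte_identical(self, tmp_path):
        scenario = SyntheticScenario(seed=3, n_contigs=60, planted_puls=2,
                                     planted_cellulosomes=2, planted_fusions=6,
                                     decoy_orphans=10, n_cazyme_orfs=50)
        generate(scenario, tmp_path / "a")
        generate(scenario, tmp_path / "b")
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_full_agreement_gives_full_recall(self, tmp_path):
        scenario = SyntheticScenario(
            seed=5, n_contigs=80, planted_puls=0, planted_cellulosomes=0,
            planted_fusions=0, decoy_orphans=0, n_cazyme_orfs=120,
            tool_agreement_q=1.0, confusion_rate=0.0,
        )
        manifest = generate(scenario, tmp_path / "d")
        calls = consensus_calls(tmp_path / "d")
        truth = {(o, f) for o, fams in manifest["cazyme_truth"].items()
                 for f in fams}
        assert {(c.orf_id, c.family) for c in calls} == truth

    def test_zero_agreement_gives_zero_calls(self, tmp_path):
        scenario = SyntheticScenario(
            seed=5, n_contigs=80, planted_puls=0, planted_cellulosomes=0,
            planted_fusions=0, decoy_orphans=0, n_cazyme_orfs=120,
            tool_agreement_q=0.0, confusion_rate=0.0,
        )
        generate(scenario, tmp_path / "d")
        assert consensus_calls(tmp_path / "d") == []

    def test_impossible_layout_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="impossible layout"):
            SyntheticScenario(n_contigs=10, planted_puls=8, decoy_orphans=8)
        scenario = SyntheticScenario(n_contigs=30, planted_puls=0,
                                     planted_cellulosomes=0, decoy_orphans=0,
                                     n_cazyme_orfs=10**5)
        with pytest.raises(ValueError, match="impossible layout"):
            generate(scenario, tmp_path / "d")

    def test_manifest_rederivable_from_files(self, default_scenario_dir):
        """Every planted locus is recoverable by an independent scan of the
        emitted files."""
        out, scenario, manifest = default_scenario_dir
        genes_by_contig = {}
        pfam_by_orf = {}
        for sample_id in manifest["samples"]:
            sdir = Path(out) / sample_id
            for g in domain_io.read_gene_table(sdir / "genes.gff3"):
                genes_by_contig.setdefault(g.contig_id, []).append(g)
            for h in domain_io.read_domain_hits(sdir / "pfam_hits.tsv",
                                                "hmm_domtbl"):
                pfam_by_orf.setdefault(h.orf_id, set()).add(h.label)
        mk = scenario.markers
        for locus in manifest["pul_loci"]:
            members = sorted(genes_by_contig[locus["contig_id"]],
                             key=lambda g: g.gene_index)
            idx = {g.orf_id: g.gene_index for g in members}
            assert mk.susC in pfam_by_orf[locus["susC_orf"]]
            assert mk.susD in pfam_by_orf[locus["susD_orf"]]
            assert abs(idx[locus["susC_orf"]] - idx[locus["susD_orf"]]) == 1
        for decoy in manifest["decoy_contigs"]:
            members = genes_by_contig[decoy["contig_id"]]
            markers = [(g.gene_index, acc) for g in members
                       for acc in pfam_by_orf.get(g.orf_id, set())
                       if acc in (mk.susC, mk.susD)]
            c_pos = sorted(i for i, a in markers if a == mk.susC)
            d_pos = sorted(i for i, a in markers if a == mk.susD)
            adjacent = any(abs(c - d) == 1 for c in c_pos for d in d_pos)
            assert not adjacent and (c_pos or d_pos)
        for orf, fams in manifest["fusion_genes"].items():
            assert mk.dockerin in pfam_by_orf[orf]
            assert set(manifest["cazyme_truth"][orf]) == set(fams)

    def test_sample_n_orfs_match_gene_tables(self, default_scenario_dir):
        out, _, manifest = default_scenario_dir
        meta = {m.sample_id: m.n_orfs
                for m in domain_io.read_sample_meta(Path(out) / "samples.tsv")}
        for sample_id in manifest["samples"]:
            genes = domain_io.read_gene_table(Path(out) / sample_id / "genes.gff3")
            assert meta[sample_id] == len(genes)


class TestScoreAgainstTruth:
    def _manifest(self):
        return {
            "scenario_id": "abc",
            "cazyme_truth": {"o1": ["GH5"], "o2": ["GH13"]},
            "background_cazymes": {"o1": ["GH5"], "o2": ["GH13"]},
            "pul_loci": [{"contig_id": f"c{i}"} for i in range(5)],
            "decoy_contigs": [{"contig_id": "d1"}],
            "fusion_genes": {},
        }

    def test_perfect_detector_scores_one(self, default_scenario_dir):
        out, scenario, manifest = default_scenario_dir
        calls = consensus_calls(out)
        genes = []
        for sample_id in manifest["samples"]:
            sdir = Path(out) / sample_id
            from holocaz.loci import attach_cazymes, attach_domains

            g = domain_io.read_gene_table(sdir / "genes.gff3")
            g = attach_domains(g, domain_io.read_domain_hits(
                sdir / "pfam_hits.tsv", "hmm_domtbl"))
            g = attach_cazymes(g, calls)
            genes.extend(g)
        from holocaz.loci import screen_cellulosome

        outputs = PipelineOutputs(
            calls=calls,
            pul_result=screen_pul(genes, markers=scenario.markers),
            cellulosome_candidates=screen_cellulosome(genes,
                                                      markers=scenario.markers),
            scenario_id=manifest["scenario_id"],
        )
        scores = score_against_truth(outputs, manifest)
        assert scores["pul"] == StageScores(1.0, 1.0, True)
        assert scores["pul_orphans"] == StageScores(1.0, 1.0, True)
        assert scores["fusions"] == StageScores(1.0, 1.0, True)
        assert scores["consensus"].precision == 1.0

    def test_empty_detector_recall_zero_precision_na(self):
        scores = score_against_truth(PipelineOutputs(calls=[]),
                                     self._manifest())
        assert scores["consensus"].recall == 0.0
        assert scores["consensus"].precision is None

    def test_one_spurious_among_five_true(self):
        from holocaz.loci import PulScreenResult
        from conftest import make_gene

        cands = []
        for contig in [f"c{i}" for i in range(5)] + ["spurious"]:
            g1 = make_gene(contig, 1, f"{contig}_a", pfam=["PF00593"])
            g2 = make_gene(contig, 2, f"{contig}_b", pfam=["PF07980"])
            from holocaz.loci import PulCandidate

            cands.append(PulCandidate(contig, g1, g2))
        outputs = PipelineOutputs(
            calls=[], pul_result=PulScreenResult(cands, []), scenario_id="abc"
        )
        scores = score_against_truth(outputs, self._manifest())
        assert scores["pul"].precision == pytest.approx(5 / 6)
        assert scores["pul"].recall == 1.0

    def test_scenario_mismatch_fatal(self):
        with pytest.raises(ValueError, match="scenario mismatch"):
            score_against_truth(PipelineOutputs(scenario_id="zzz"),
                                self._manifest())
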