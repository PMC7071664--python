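"""Evidence-table, gene-table and lineage readers."""

import random

import pytest

from holocaz import domain_io
from holocaz.domain_io import (
    ParserError,
    ParserWarning,
    read_domain_hits,
    read_gene_table,
    read_lineages,
    write_gene_table,
)
from holocaz.model import GeneOnContig, Tool, canonicalize_label, family_of

DOMTBL_ROW = (
    "GH13.hmm - 200 orf_001 - 300 1e-60 250.0 0.1 1 1 "
    "1e-60 1e-60 249.0 0.1 1 190 12 180 10 182 0.98 alpha-amylase domain\n"
)


class TestDomainHitDialects:
    def test_domtbl_row_is_canonicalized(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("# comment\n" + DOMTBL_ROW)
        (hit,) = read_domain_hits(p, "hmm_domtbl")
        assert hit.orf_id == "orf_001"
        assert hit.source_tool is Tool.HMM
        assert hit.label == "GH13"  # trailing .hmm stripped
        assert hit.evalue == pytest.approx(1e-60)
        assert hit.coords == (12, 180)

    def test_domtbl_pfam_accession_side_detected(self, tmp_path):
        # hmmsearch direction: profile is the query, ORF the target
        row = ("orf_9 - 300 SusD PF07980.24 200 1e-30 90.0 0.1 1 1 "
               "1e-30 1e-30 89.0 0.1 1 190 5 120 3 122 0.95 -\n")
        p = tmp_path / "h.tsv"
        p.write_text(row)
        (hit,) = read_domain_hits(p, "hmm_domtbl")
        assert hit.orf_id == "orf_9"
        assert hit.label == "PF07980"  # version suffix stripped

    def test_outfmt6_subject_pipe_label(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("orf_2\tcazydb|GH5_13\t95.0\t250\t10\t0\t1\t250\t1\t250"
                     "\t1e-80\t350\n")
        (hit,) = read_domain_hits(p, "similarity_tab")
        assert hit.label == "GH5_13"  # subfamily suffix preserved
        assert hit.source_tool is Tool.SIMILARITY
        assert hit.coords == (1, 250)

    def test_peptide_row(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("orf_3\tCE1\t14\n")
        (hit,) = read_domain_hits(p, "peptide_tab")
        assert (hit.orf_id, hit.label, hit.evalue) == ("orf_3", "CE1", 14.0)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert read_domain_hits(p, "peptide_tab") == []

    def test_invalid_label_skipped_with_warning(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("orf_1\tXY99\t3\norf_2\tGH13\t5\n")
        with pytest.warns(ParserWarning, match="line 1"):
            hits = read_domain_hits(p, "peptide_tab")
        assert [h.label for h in hits] == ["GH13"]

    def test_strict_mode_raises(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("orf_1\tXY99\t3\n")
        with pytest.raises(ParserError):
            read_domain_hits(p, "peptide_tab", strict=True)

    def test_unknown_dialect_and_missing_file_fatal(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(DOMTBL_ROW)
        with pytest.raises(ParserError):
            read_domain_hits(p, "nope")
        with pytest.raises(ParserError):
            read_domain_hits(tmp_path / "absent.tsv", "peptide_tab")

    def test_warnings_plus_accepted_rows_equal_total(self, tmp_path):
        rows = ["orf_1\tGH5\t3", "orf_2\tBAD\t1", "orf_3\tCE1\t2",
                "orf_4\tZZ\t9"]
        p = tmp_path / "mix.tsv"
        p.write_text("".join(r + "\n" for r in rows))
        with pytest.warns(ParserWarning) as caught:
            hits = read_domain_hits(p, "peptide_tab")
        assert len(hits) + len(caught) == len(rows)


class TestLabels:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("GH13.hmm", "GH13"),
            ("GH5_13", "GH5_13"),
            ("PF00593.25", "PF00593"),
            ("XY99", None),
            ("", None),
        ],
    )
    def test_canonicalize(self, raw, expected):
        assert canonicalize_label(raw) == expected

    def test_family_collapse(self):
        assert family_of("GH5_13") == "GH5"
        assert family_of("CBM35") == "CBM35"


class TestGeneTable:
    def _write(self, tmp_path, rows):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n" + "".join(rows))
        return p

    def test_index_assigned_by_start(self, tmp_path):
        rows = [
            "c1\tx\tCDS\t500\t900\t.\t-\t.\tID=b\n",
            "c1\tx\tCDS\t100\t400\t.\t+\t.\tID=a\n",
        ]
        genes = read_gene_table(self._write(tmp_path, rows))
        assert [(g.orf_id, g.gene_index) for g in genes] == [("a", 1), ("b", 2)]

    def test_independent_index_per_contig(self, tmp_path):
        rows = [
            "c1\tx\tCDS\t100\t400\t.\t+\t.\tID=a\n",
            "c2\tx\tCDS\t50\t80\t.\t+\t.\tID=b\n",
            "c2\tx\tCDS\t100\t200\t.\t+\t.\tID=c\n",
        ]
        genes = read_gene_table(self._write(tmp_path, rows))
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g.gene_index)
        assert by_contig == {"c1": [1], "c2": [1, 2]}

    def test_duplicate_orf_id_warns_and_keeps_both(self, tmp_path):
        rows = [
            "c1\tx\tCDS\t100\t400\t.\t+\t.\tID=a\n",
            "c1\tx\tCDS\t500\t900\t.\t+\t.\tID=a\n",
        ]
        with pytest.warns(ParserWarning, match="duplicate"):
            genes = read_gene_table(self._write(tmp_path, rows))
        assert len(genes) == 2

    def test_start_after_end_fatal_in_strict(self, tmp_path):
        rows = ["c1\tx\tCDS\t400\t100\t.\t+\t.\tID=a\n"]
        p = self._write(tmp_path, rows)
        with pytest.warns(ParserWarning):
            assert read_gene_table(p) == []
        with pytest.raises(ParserError):
            read_gene_table(p, strict=True)

    def test_round_trip(self, tmp_path):
        rng = random.Random(11)
        genes = []
        for c in range(3):
            cursor = 1
            for i in range(rng.randint(1, 6)):
                length = rng.randint(100, 900)
                genes.append(GeneOnContig(
                    f"c{c}", i + 1, cursor, cursor + length,
                    rng.choice("+-"), f"orf_{c}_{i}"))
                cursor += length + rng.randint(10, 100)
        p = tmp_path / "rt.gff3"
        write_gene_table(genes, p)
        back = read_gene_table(p)
        assert [(g.contig_id, g.gene_index, g.start, g.end, g.strand, g.orf_id)
                for g in back] == [
            (g.contig_id, g.gene_index, g.start, g.end, g.strand, g.orf_id)
            for g in genes
        ]
        p2 = tmp_path / "rt2.gff3"
        write_gene_table(back, p2)
        assert p.read_text() == p2.read_text()


class TestLineages:
    def _write(self, tmp_path, rows):
        p = tmp_path / "lin.tsv"
        p.write_text("".join(r + "\n" for r in rows))
        return p

    def test_top_five_retained(self, tmp_path):
        rows = [f"orf_1\t{i}\t1e-{30 + i}\tBacteria;Proteobacteria"
                for i in range(1, 8)]
        lins = read_lineages(self._write(tmp_path, rows))
        assert len(lins) == 5
        # best score (smallest E-value) first
        assert [l.hit_rank for l in lins] == [1, 2, 3, 4, 5]
        assert lins[0].bitscore_or_evalue == pytest.approx(1e-37)

    def test_evalue_cutoff_drops_hit(self, tmp_path):
        rows = ["orf_1\t1\t1e-3\tBacteria;Proteobacteria"]
        assert read_lineages(self._write(tmp_path, rows),
                             evalue_cutoff=1e-4) == []

    def test_single_valid_hit(self, tmp_path):
        rows = ["orf_1\t1\t1e-20\tdomain:Bacteria;phylum:Bacteroidetes"]
        (lin,) = read_lineages(self._write(tmp_path, rows))
        assert lin.lineage == (("domain", "Bacteria"),
                               ("phylum", "Bacteroidetes"))

    def test_positional_ranks_assigned(self, tmp_path):
        rows = ["orf_1\t1\t1e-20\tBacteria;Bacteroidetes;Flavobacteriia"]
        (lin,) = read_lineages(self._write(tmp_path, rows))
        assert lin.lineage == (("domain", "Bacteria"),
                               ("phylum", "Bacteroidetes"),
                               ("class", "Flavobacteriia"))

    def test_empty_lineage_dropped_with_warning(self, tmp_path):
        rows = ["orf_1\t1\t1e-20\t"]
        with pytest.warns(ParserWarning, match="empty lineage"):
            assert read_lineages(self._write(tmp_path, rows)) == []
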