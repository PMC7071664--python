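"""Three-tool consensus semantics, family counting and set partition."""

import pytest

from conftest import ALL_TOOLS, make_call, make_sample
from holocaz.consensus import call_consensus, count_families, partition_families
from holocaz.model import DomainHit, Tool


def hit(orf, tool, label, evalue=1e-60):
    return DomainHit(orf, tool, label, evalue)


class TestCallConsensus:
    def test_three_tool_agreement_yields_call(self):
        hits = [hit("o1", Tool.HMM, "GH13"),
                hit("o1", Tool.SIMILARITY, "GH13"),
                hit("o1", Tool.PEPTIDE, "GH13")]
        result = call_consensus(hits)
        (call,) = result.calls
        assert call.family == "GH13"
        assert call.evidence == ALL_TOOLS
        assert call.module_count == 1
        assert result.partial == []

    def test_two_tool_agreement_goes_to_side_channel(self):
        hits = [hit("o1", Tool.HMM, "GH13"),
                hit("o1", Tool.SIMILARITY, "GH13")]
        result = call_consensus(hits)
        assert result.calls == []
        (partial,) = result.partial
        assert partial.family == "GH13"
        assert partial.evidence == frozenset({Tool.HMM, Tool.SIMILARITY})

    def test_module_count_is_number_of_hmm_domains(self):
        hits = [hit("o1", Tool.HMM, "GH13"),
                hit("o1", Tool.HMM, "GH13"),
                hit("o1", Tool.SIMILARITY, "GH13"),
                hit("o1", Tool.PEPTIDE, "GH13")]
        (call,) = call_consensus(hits).calls
        assert call.module_count == 2

    def test_subfamily_labels_agree_at_family_level(self):
        hits = [hit("o1", Tool.HMM, "GH5_13"),
                hit("o1", Tool.SIMILARITY, "GH5_4"),
                hit("o1", Tool.PEPTIDE, "GH5")]
        (call,) = call_consensus(hits).calls
        assert call.family == "GH5"
        # exact-label mode: no agreement
        assert call_consensus(hits, subfamily=True).calls == []

    def test_similarity_evalue_gate(self):
        hits = [hit("o1", Tool.HMM, "GH13"),
                hit("o1", Tool.SIMILARITY, "GH13", evalue=1e-20),  # above gate
                hit("o1", Tool.PEPTIDE, "GH13")]
        result = call_consensus(hits, similarity_evalue_max=1e-50)
        assert result.calls == []
        assert call_consensus(hits, similarity_evalue_max=1e-10).calls != []

    def test_multi_family_orf_yields_one_call_per_family(self):
        hits = []
        for fam in ("GH26", "CBM35"):
            hits += [hit("o1", t, fam) for t in Tool]
        calls = call_consensus(hits).calls
        assert sorted(c.family for c in calls) == ["CBM35", "GH26"]

    def test_pfam_hits_ignored(self):
        hits = [hit("o1", t, "PF00593") for t in Tool]
        result = call_consensus(hits)
        assert result.calls == [] and result.partial == []

    def test_empty_input(self):
        result = call_consensus([])
        assert result.calls == [] and result.partial == []


class TestCountFamilies:
    def test_module_counts_sum_per_cell(self):
        calls = [make_call("o1", "GH13", 1), make_call("o2", "GH13", 1),
                 make_call("o3", "GH13", 2)]
        matrix = count_families(calls, ["s1"])
        assert matrix.raw.loc["GH13", "s1"] == 4

    def test_empty_calls_give_zero_matrix(self):
        matrix = count_families([], ["s1", "s2"])
        assert matrix.samples == ["s1", "s2"]
        assert matrix.raw.to_numpy().sum() == 0

    def test_disjoint_families_block_diagonal(self):
        calls = [make_call("o1", "GH13", 1, "s1"),
                 make_call("o2", "CE1", 3, "s2")]
        matrix = count_families(calls, ["s1", "s2"])
        assert matrix.raw.loc["GH13", "s2"] == 0
        assert matrix.raw.loc["CE1", "s1"] == 0
        assert matrix.raw.loc["CE1", "s2"] == 3

    def test_total_modules_conserved(self):
        calls = [make_call(f"o{i}", fam, (i % 3) + 1, "s1")
                 for i, fam in enumerate(["GH13", "GH5", "CE1", "GH13", "AA3"])]
        matrix = count_families(calls, [make_sample("s1")])
        assert matrix.raw.to_numpy().sum() == sum(c.module_count for c in calls)

    def test_unknown_sample_fatal(self):
        with pytest.raises(ValueError, match="unknown sample"):
            count_families([make_call("o1", "GH13", 1, "ghost")], ["s1"])

    def test_class_marginals(self):
        calls = [make_call("o1", "GH13", 2), make_call("o2", "GH5", 1),
                 make_call("o3", "CE1", 3)]
        marg = count_families(calls, ["s1"]).class_marginals()
        assert marg.loc["GH", "s1"] == 3
        assert marg.loc["CE", "s1"] == 3


class TestPartitionFamilies:
    def test_printed_partition_arithmetic(self):
        # |meta| = 174, |host| = 63, overlap 36 -> union 201, host-only 27
        shared = {f"GH{i}" for i in range(1, 37)}
        meta = shared | {f"GT{i}" for i in range(1, 139)}
        host = shared | {f"CE{i}" for i in range(1, 28)}
        assert len(meta) == 174 and len(host) == 63
        part = partition_families(meta, host)
        assert len(part.host_only) == 27
        assert len(part.microbiota_only) == 138
        assert len(part.shared) == 36
        assert part.union_size == 201

    def test_identical_sets(self):
        part = partition_families({"GH1", "GH2"}, {"GH1", "GH2"})
        assert part.host_only == frozenset() == part.microbiota_only
        assert part.union_size == 2

    def test_disjoint_sets(self):
        part = partition_families({"GH1", "GH2"}, {"CE1", "CE2", "CE3"})
        assert part.union_size == 5

    def test_partition_identity_random_sets(self):
        import random

        rng = random.Random(3)
        pool = [f"GH{i}" for i in range(1, 120)]
        for _ in range(50):
            meta = set(rng.sample(pool, rng.randint(0, 60)))
            host = set(rng.sample(pool, rng.randint(0, 60)))
            part = partition_families(meta, host)
            assert (len(part.host_only) + len(part.microbiota_only)
                    + len(part.shared)) == part.union_size == len(meta | host)
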