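import pytest

from holocaz.consensus import CazymeCall
from holocaz.model import DomainHit, GeneOnContig, SampleMeta, Tool
from holocaz.simulate import SyntheticScenario, generate

ALL_TOOLS = frozenset({Tool.HMM, Tool.SIMILARITY, Tool.PEPTIDE})


def make_call(orf_id, family, module_count=1, sample_id="s1"):
    return CazymeCall(orf_id, family, ALL_TOOLS, module_count, sample_id)


def make_gene(contig, index, orf_id, pfam=(), families=(), start=None,
              strand="+", length=900):
    start = start if start is not None else index * 1000
    domains = frozenset(
        DomainHit(orf_id, Tool.HMM, acc, 1e-10) for acc in pfam
    )
    return GeneOnContig(contig, index, start, start + length, strand, orf_id,
                        domains, frozenset(families))


def make_sample(sample_id="s1", n_orfs=1000, kind="metagenome", **kw):
    defaults = dict(host_species="A. aquaticus", origin="laboratory",
                    sex="male", tissue="hindgut")
    defaults.update(kw)
    return SampleMeta(sample_id=sample_id, dataset_kind=kind, n_orfs=n_orfs,
                      **defaults)


@pytest.fixture(scope="session")
def default_scenario_dir(tmp_path_factory):
    """One generated default scenario shared across tests."""
    out = tmp_path_factory.mktemp("scenario") / "data"
    scenario = SyntheticScenario(seed=7)
    manifest = generate(scenario, out)
    return out, scenario, manifest
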