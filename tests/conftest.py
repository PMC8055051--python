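import pytest

from kegg2net.fixtures import EntrySpec, KGMLScenario, RelationSpec


@pytest.fixture
def two_gene_scenario() -> KGMLScenario:
    """Two gene entries linked by one activation relation."""
    return KGMLScenario(
        pathway_id="path:syn00001",
        title="two genes",
        entries=[
            EntrySpec("1", "gene", ["hsa:10"]),
            EntrySpec("2", "gene", ["hsa:20"]),
        ],
        relations=[RelationSpec("1", "2", [("activation", "-->")])],
    )
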