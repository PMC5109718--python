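import pytest

from florapheno import fixtures as fx
from florapheno.mining import Miner
from florapheno.patterns import build_ontology
from florapheno.pipeline import build_lexicons, relational_quality_ids


@pytest.fixture(scope="session")
def structure_ont():
    return fx.make_mini_structure_ontology()


@pytest.fixture(scope="session")
def quality_ont():
    return fx.make_mini_quality_ontology()


@pytest.fixture(scope="session")
def glossary():
    return fx.make_glossary()


@pytest.fixture(scope="session")
def pattern_cfg():
    return fx.fixture_pattern_config()


@pytest.fixture(scope="session")
def lexicons(structure_ont, quality_ont, glossary):
    return build_lexicons(structure_ont, quality_ont, glossary)


@pytest.fixture(scope="session")
def miner(lexicons, quality_ont, pattern_cfg):
    return Miner(lexicons, relational_quality_ids(quality_ont, pattern_cfg))


@pytest.fixture(scope="session")
def default_corpus(structure_ont, quality_ont, glossary):
    return fx.make_corpus(fx.FixtureSpec(), structure_ont, quality_ont,
                          glossary)


@pytest.fixture(scope="session")
def default_records(default_corpus, miner):
    records, summary = miner.mine_corpus(default_corpus[0])
    return records


@pytest.fixture(scope="session")
def default_build(default_records, structure_ont, quality_ont, pattern_cfg):
    return build_ontology(default_records, structure_ont, quality_ont,
                          pattern_cfg)


@pytest.fixture(scope="session")
def label_to_id(default_build):
    out = {gc.label: gc.flopo_id for gc in default_build.generated}
    out.update({gc.label: gc.flopo_id for gc in default_build.excluded})
    return out
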