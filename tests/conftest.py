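import pytest

import ppiscore as pp
from ppiscore.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def config():
    return pp.default_config()


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """One synthetic corpus shared across the suite (seed fixed)."""
    out = tmp_path_factory.mktemp("corpus")
    return generate_corpus(SynthConfig(seed=11), out)


@pytest.fixture(scope="session")
def sidecars(corpus):
    return pp.load_sidecar_tables(corpus.sidecar_dir)


@pytest.fixture(scope="session")
def corpus_records(corpus):
    records = []
    for p in corpus.mitab_paths:
        records.extend(pp.read_mitab(p).records)
    for p in corpus.xml_paths:
        records.extend(pp.read_psimi_xml(p))
    return records


@pytest.fixture(scope="session")
def integrated(corpus_records, sidecars):
    return pp.integrate_records(
        corpus_records,
        sidecars.id_mapping,
        pubmed_scales=sidecars.pubmed_scales,
    )
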