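import pytest

from litnet import fixtures as fx
from litnet.pipeline import PipelineConfig, run_pipeline
from litnet.syntax import FixtureAnalyzer


@pytest.fixture(scope="session")
def micro_corpus():
    return fx.worked_example_corpus()


@pytest.fixture(scope="session")
def worked_doc():
    return fx.worked_example_document()


@pytest.fixture(scope="session")
def worked_parse():
    return fx.worked_example_parse()


@pytest.fixture(scope="session")
def worked_result(micro_corpus, worked_doc, worked_parse):
    analyzer = FixtureAnalyzer({worked_doc.doc_id: worked_parse})
    config = PipelineConfig(
        documents=[worked_doc], corpus=micro_corpus, analyzer=analyzer
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """20-document no-noise study: corpus, documents, analyzer, gold."""
    spec = fx.FixtureSpec(seed=11)
    corpus, gold_map = fx.make_mini_corpus(spec)
    docs = fx.make_documents(spec, corpus)
    analyzer = FixtureAnalyzer({d.document.doc_id: d.sentences for d in docs})
    return spec, corpus, docs, analyzer
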