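import pytest

from adpop import CorpusConfig, generate
from adpop.reporting import prepare_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 200-worker corpus with ground truth, shared across tests."""
    cfg = CorpusConfig(n_workers=200, seed=42)
    records, truth = generate(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_extracted(small_corpus):
    cfg, records, truth = small_corpus
    extracted, lexicon = prepare_corpus(records)
    return extracted, lexicon
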