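import pytest

from radlabel.corpus import GeneratorConfig, generate_corpus, to_frame
from radlabel.model import EncoderConfig, ReportClassifier
from radlabel.preprocess import build_vocabulary


@pytest.fixture(scope="session")
def corpus_frame():
    """Mid-sized synthetic corpus shared across test modules."""
    return to_frame(*generate_corpus(GeneratorConfig(n_reports=400, seed=5)))


@pytest.fixture(scope="session")
def vocabulary(corpus_frame):
    return build_vocabulary(corpus_frame["text"].tolist())


def make_tiny_config(vocab_size, **overrides):
    defaults = dict(d_model=16, n_layers=1, n_heads=2, d_ff=32,
                    max_len=96, d_attention=12, d_hidden=16, seed=0)
    defaults.update(overrides)
    return EncoderConfig(vocab_size=vocab_size, **defaults)


@pytest.fixture()
def tiny_model(vocabulary):
    return ReportClassifier(vocabulary, config=make_tiny_config(len(vocabulary)))
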