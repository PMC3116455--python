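import numpy as np
import pytest

from ppisem.corpus import LabeledSentence, Vocabulary


@pytest.fixture
def toy_vocab():
    return Vocabulary({"w": 0, "x": 1, "y": 2, "z": 3})


@pytest.fixture
def two_protein_sentence():
    text = "ProtA binds strongly to ProtB today"
    return LabeledSentence(
        sentence_id="a1.0",
        abstract_id="a1",
        raw_text=text,
        protein_spans=((0, 5), (text.index("ProtB"), text.index("ProtB") + 5)),
        label=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_token_corpus(rng, n_tokens=120, vocab_size=8, max_sentence=12):
    """Random toy corpus as sentence token lists over letters a, b, c..."""
    words = [chr(ord("a") + i) for i in range(vocab_size)]
    corpus = []
    remaining = n_tokens
    while remaining > 0:
        ln = int(rng.integers(1, max_sentence + 1))
        ln = min(ln, remaining)
        corpus.append([words[i] for i in rng.integers(0, vocab_size, ln)])
        remaining -= ln
    return corpus, words
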