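import numpy as np
import pytest

from protembed.corpus import Corpus, NGramSentence, ProteinSequence
from protembed.embedding import (EmbeddingModel, TrainingConfig, Vocabulary,
                                 initialize_model)


@pytest.fixture
def tiny_corpus() -> Corpus:
    sents = [
        NGramSentence(["MAK", "QRS", "MAK"], "p1", 0),
        NGramSentence(["AKQ", "MAK"], "p1", 1),
        NGramSentence(["QRS", "AKQ"], "p2", 0),
    ]
    return Corpus(sents, n=3)


@pytest.fixture
def random_model() -> EmbeddingModel:
    """Small model with random vectors in both tables (seeded)."""
    rng = np.random.default_rng(42)
    tokens = [f"T{i:02d}" for i in range(12)]
    vocab = Vocabulary(tokens=tokens, counts={t: i + 1 for i, t in enumerate(tokens)})
    d = 5
    return EmbeddingModel(
        vocab=vocab, dim=d,
        input_vectors=rng.normal(size=(12, d)),
        output_vectors=rng.normal(size=(12, d)),
    )


def random_protein(rng: np.random.Generator, length: int,
                   alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> ProteinSequence:
    residues = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))
    return ProteinSequence(id=f"r{rng.integers(1 << 30)}", residues=residues)
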