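"""Skip-gram negative-sampling (SGNS) embeddings of sequence n-grams.

The model learns, for every n-gram token w, an input vector v_w and an
output vector v'_w of dimension d.  A (center, context) token pair drawn
from a sliding window of c tokens on each side is scored with

    p(pair observed) = sigmoid(v'_context . v_center)

and training ascends the log objective

    sum_{(w,c) in D} log sigma(v'_c . v_w)
      + sum_{(w,c) in D'} log(1 - sigma(v'_c . v_w)),

where D are the observed pairs and D' are noise pairs with the context
drawn from the unigram distribution raised to ``noise_exponent``.  The
defaults follow the protein-space setting: vectors of size 100 and a
context of 25 tokens on each side.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal

import numpy as np

from . import _kernel
from .corpus import Corpus, NGramSentence

__all__ = [
    "Vocabulary",
    "TrainingConfig",
    "TrainingPair",
    "EmbeddingModel",
    "build_vocabulary",
    "generate_pairs",
    "noise_distribution",
    "sample_noise_tokens",
    "pair_probability",
    "sgns_objective",
    "sgns_gradients",
    "initialize_model",
    "train",
    "nearest_neighbors",
    "save_model",
    "load_model",
]


@dataclass
class Vocabulary:
    """Ordered token set with corpus counts and a token -> row index map."""

    tokens: list[str]
    counts: dict[str, int]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index


@dataclass
class TrainingConfig:
    """Hyperparameters of SGNS training.

    ``window`` is the number of context tokens taken on *each side* of the
    center token.  The learning rate decays linearly from
    ``initial_learning_rate`` to ``final_learning_rate`` over all pair
    presentations (positives, across epochs).
    """

    dim: int = 100
    window: int = 25
    negatives: int = 5
    epochs: int = 5
    initial_learning_rate: float = 0.025
    final_learning_rate: float = 1e-4
    min_count: int = 1
    noise_exponent: float = 0.75
    seed: int = 1

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1 or self.negatives < 0:
            raise ValueError("dim >= 1, window >= 1, negatives >= 0 required")
        if not (self.initial_learning_rate >= self.final_learning_rate > 0):
            raise ValueError("learning rates must satisfy initial >= final > 0")


@dataclass(frozen=True)
class TrainingPair:
    center: int
    context: int
    label: Literal["positive", "negative"] = "positive"


@dataclass
class EmbeddingModel:
    """Trained token space: vocabulary plus paired W x d vector tables."""

    vocab: Vocabulary
    dim: int
    input_vectors: np.ndarray
    output_vectors: np.ndarray
    config: TrainingConfig | None = None

    def __post_init__(self) -> None:
        if self.input_vectors.shape != self.output_vectors.shape:
            raise ValueError("input and output tables must have equal shape")
        if self.input_vectors.shape != (len(self.vocab), self.dim):
            raise ValueError("vector tables must be W x d")

    def __contains__(self, token: str) -> bool:
        return token in self.vocab

    def vector(self, token: str) -> np.ndarray:
        """Input vector v_w of ``token`` (the downstream representation)."""
        try:
            return self.input_vectors[self.vocab.index[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None


def build_vocabulary(corpus: Corpus, min_count: int = 1) -> Vocabulary:
    """Count tokens over the corpus and retain those with count >= min_count.

    Ordering is deterministic: descending count, ties lexicographic.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for sent in corpus.sentences:
        counts.update(sent.tokens)
    kept = {t: c for t, c in counts.items() if c >= min_count}
    if not kept:
        raise ValueError(f"min_count={min_count} removed every token")
    tokens = sorted(kept, key=lambda t: (-kept[t], t))
    return Vocabulary(tokens=tokens, counts=kept)


def generate_pairs(sentence: NGramSentence | list[str], c: int,
                   vocab: Vocabulary) -> Iterator[TrainingPair]:
    """Positive (center, context) pairs within a window of c tokens per side.

    Out-of-vocabulary tokens keep their position (they occupy window slots)
    but never appear in a pair.  Order: center position ascending, context
    offset ascending.
    """
    tokens = sentence.tokens if isinstance(sentence, NGramSentence) else sentence
    idx = [vocab.index.get(t, -1) for t in tokens]
    for i, w in enumerate(idx):
        if w < 0:
            continue
        for j in range(max(0, i - c), min(len(idx), i + c + 1)):
            if j == i or idx[j] < 0:
                continue
            yield TrainingPair(center=w, context=idx[j], label="positive")


def noise_distribution(vocab: Vocabulary, noise_exponent: float = 0.75) -> np.ndarray:
    """Noise probabilities proportional to count(t)**noise_exponent."""
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    weights = np.array([vocab.counts[t] for t in vocab.tokens], dtype=np.float64)
    weights **= noise_exponent
    return weights / weights.sum()


def sample_noise_tokens(probs: np.ndarray, size: int, seed: int) -> np.ndarray:
    """Draw token indices i.i.d. from ``probs`` by inverse-CDF sampling."""
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    rng = np.random.default_rng(seed)
    return np.searchsorted(cum, rng.random(size), side="right").astype(np.int64)


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return -np.logaddexp(0.0, -np.asarray(x, dtype=np.float64))


def pair_probability(model: EmbeddingModel, w: str, ctx: str) -> float:
    """sigmoid(v'_ctx . v_w): probability the pair came from the data."""
    if ctx not in model.vocab:
        raise KeyError(f"token {ctx!r} not in vocabulary")
    x = float(np.dot(model.vector(w), model.output_vectors[model.vocab.index[ctx]]))
    return float(np.exp(_log_sigmoid(x)))


def sgns_objective(model: EmbeddingModel, positives: Iterable[TrainingPair],
                   negatives: Iterable[TrainingPair]) -> float:
    """Log objective: sum log sigma(x) over D plus sum log(1-sigma(x)) over D'."""
    total = 0.0
    for pair in positives:
        x = float(np.dot(model.input_vectors[pair.center],
                         model.output_vectors[pair.context]))
        total += float(_log_sigmoid(x))
    for pair in negatives:
        x = float(np.dot(model.input_vectors[pair.center],
                         model.output_vectors[pair.context]))
        total += float(_log_sigmoid(-x))
    return total


def sgns_gradients(model: EmbeddingModel, positives: Iterable[TrainingPair],
                   negatives: Iterable[TrainingPair]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of :func:`sgns_objective` w.r.t. both vector tables.

    For a pair with label y in {1, 0} and x = v'_c . v_w the per-pair
    gradient is (y - sigma(x)) v'_c for the input row and (y - sigma(x)) v_w
    for the output row — the same update the training kernel applies.
    """
    grad_in = np.zeros_like(model.input_vectors)
    grad_out = np.zeros_like(model.output_vectors)
    for label, pairs in ((1.0, positives), (0.0, negatives)):
        for pair in pairs:
            vw = model.input_vectors[pair.center]
            vc = model.output_vectors[pair.context]
            coef = label - 1.0 / (1.0 + math.exp(-float(np.dot(vw, vc))))
            grad_in[pair.center] += coef * vc
            grad_out[pair.context] += coef * vw
    return grad_in, grad_out


def initialize_model(vocab: Vocabulary, config: TrainingConfig) -> EmbeddingModel:
    """Seeded initialization: input rows uniform on [-0.5/d, 0.5/d), output zero."""
    rng = np.random.default_rng(config.seed)
    d = config.dim
    inp = rng.uniform(-0.5 / d, 0.5 / d, size=(len(vocab), d))
    out = np.zeros((len(vocab), d), dtype=np.float64)
    return EmbeddingModel(vocab=vocab, dim=d, input_vectors=inp,
                          output_vectors=out, config=config)


def _encode_corpus(corpus: Corpus, vocab: Vocabulary
                   ) -> tuple[np.ndarray, np.ndarray]:
    tokens: list[int] = []
    offsets = [0]
    for sent in corpus.sentences:
        tokens.extend(vocab.index.get(t, -1) for t in sent.tokens)
        offsets.append(len(tokens))
    return (np.asarray(tokens, dtype=np.int32),
            np.asarray(offsets, dtype=np.int64))


def train(corpus: Corpus, config: TrainingConfig | None = None) -> EmbeddingModel:
    """Train an :class:`EmbeddingModel` on ``corpus`` by SGNS gradient ascent.

    Single-threaded and bit-reproducible for a fixed ``config.seed``:
    identical seeds give identical models.  ``epochs=0`` returns the seeded
    initialization unchanged.
    """
    config = config or TrainingConfig()
    vocab = build_vocabulary(corpus, config.min_count)
    model = initialize_model(vocab, config)
    if config.epochs == 0:
        return model
    tokens, offsets = _encode_corpus(corpus, vocab)
    per_epoch = int(_kernel.count_pairs(tokens, offsets, config.window))
    if per_epoch == 0:
        return model
    probs = noise_distribution(vocab, config.noise_exponent)
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    _kernel.train_epochs(
        tokens, offsets, model.input_vectors, model.output_vectors, cum,
        config.window, config.negatives, config.epochs,
        config.initial_learning_rate, config.final_learning_rate,
        config.seed, per_epoch * config.epochs,
    )
    return model


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = float(np.linalg.norm(a)), float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def nearest_neighbors(model: EmbeddingModel, token: str, k: int
                      ) -> list[tuple[str, float]]:
    """Top-k tokens by cosine similarity of input vectors (query excluded).

    Deterministic: ties broken lexicographically.
    """
    if token not in model.vocab:
        raise KeyError(f"token {token!r} not in vocabulary")
    if k >= len(model.vocab):
        raise ValueError("k must be smaller than the vocabulary size")
    q = model.vector(token)
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(model.input_vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = model.input_vectors @ q / (norms * qn)
    sims = np.nan_to_num(sims, nan=0.0, posinf=0.0, neginf=0.0)
    order = sorted(
        (i for i in range(len(model.vocab)) if model.vocab.tokens[i] != token),
        key=lambda i: (-sims[i], model.vocab.tokens[i]),
    )
    return [(model.vocab.tokens[i], float(sims[i])) for i in order[:k]]


def save_model(model: EmbeddingModel, path) -> None:
    """Persist in the word2vec text format: "W d" header, one token row each.

    Only input vectors (the downstream representation) are stored.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.vocab)} {model.dim}\n")
        for i, token in enumerate(model.vocab.tokens):
            row = " ".join(f"{x:.8g}" for x in model.input_vectors[i])
            fh.write(f"{token} {row}\n")


def load_model(path) -> EmbeddingModel:
    """Load a word2vec-format text model written by :func:`save_model`.

    Token counts are not stored in this format; the loaded vocabulary
    carries a count of 1 for every token.  Output vectors are zero.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header {header!r}")
        W, d = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows = np.empty((W, d), dtype=np.float64)
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            if i >= W:
                raise ValueError(f"{path}: more rows than header claims (W={W})")
            if len(parts) != d + 1:
                raise ValueError(
                    f"{path}: row {i} has {len(parts) - 1} values, expected {d}"
                )
            tokens.append(parts[0])
            rows[i] = [float(x) for x in parts[1:]]
    if len(tokens) != W:
        raise ValueError(f"{path}: header claims W={W} but found {len(tokens)} rows")
    vocab = Vocabulary(tokens=tokens, counts={t: 1 for t in tokens})
    return EmbeddingModel(vocab=vocab, dim=d, input_vectors=rows,
                          output_vectors=np.zeros_like(rows))
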