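"""Whole-sequence representation: sum of overlapping n-gram input vectors."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import ProteinSequence, extract_overlapping
from .embedding import EmbeddingModel

logger = logging.getLogger(__name__)


@dataclass
class SequenceVector:
    """d-dimensional representation of one sequence.

    ``n_known`` counts in-vocabulary n-grams that contributed to the sum;
    ``n_unknown`` counts skipped out-of-vocabulary n-grams.  Their total is
    L - n + 1 for a source of length L.
    """

    id: str
    vector: np.ndarray
    n_known: int
    n_unknown: int

    @property
    def source_length(self) -> int:
        """Length of the originating sequence (for n inferred from the model)."""
        return self.n_known + self.n_unknown  # + n - 1, resolved by callers


def embed_sequence(seq: ProteinSequence, model: EmbeddingModel, n: int = 3,
                   mean: bool = False) -> SequenceVector:
    """Sum (or average, with ``mean=True``) the input vectors of all
    overlapping n-grams of ``seq``.

    Out-of-vocabulary n-grams contribute nothing and are counted in
    ``n_unknown``.  A sequence shorter than ``n`` raises; a sequence whose
    every n-gram is unknown yields the zero vector with a warning.
    """
    if len(seq) < n:
        raise ValueError(f"sequence {seq.id!r} shorter than n-gram length {n}")
    vec = np.zeros(model.dim, dtype=np.float64)
    known = unknown = 0
    index = model.vocab.index
    for token in extract_overlapping(seq, n):
        i = index.get(token)
        if i is None:
            unknown += 1
        else:
            vec += model.input_vectors[i]
            known += 1
    if known == 0:
        logger.warning("sequence %s: every n-gram out of vocabulary", seq.id)
    elif mean:
        vec /= known
    return SequenceVector(id=seq.id, vector=vec, n_known=known, n_unknown=unknown)


def embed_set(seqs: Sequence[ProteinSequence], model: EmbeddingModel,
              n: int = 3, mean: bool = False,
              strict: bool = True) -> list[SequenceVector]:
    """Embed a list of sequences, preserving order.

    With ``strict=False`` sequences shorter than ``n`` are skipped with a
    warning.  Logs the aggregate unknown-token fraction.
    """
    out: list[SequenceVector] = []
    for seq in seqs:
        if len(seq) < n and not strict:
            logger.warning("skipping %s: shorter than n=%d", seq.id, n)
            continue
        out.append(embed_sequence(seq, model, n=n, mean=mean))
    total_known = sum(v.n_known for v in out)
    total_unknown = sum(v.n_unknown for v in out)
    if total_known + total_unknown:
        frac = total_unknown / (total_known + total_unknown)
        logger.info("embedded %d sequences, unknown-token fraction %.4f",
                    len(out), frac)
    return out


def write_vectors(vectors: Sequence[SequenceVector], path) -> None:
    """TSV: id column then one column per dimension, with a header row."""
    if not vectors:
        raise ValueError("no vectors to write")
    d = vectors[0].vector.shape[0]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(f"d{i}" for i in range(d)) + "\n")
        for v in vectors:
            row = "\t".join(f"{x:.8g}" for x in v.vector)
            fh.write(f"{v.id}\t{row}\n")


def read_vectors(path) -> list[SequenceVector]:
    """Read a TSV written by :func:`write_vectors` (counts are not stored)."""
    out: list[SequenceVector] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        d = len(header) - 1
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != d + 1:
                raise ValueError(f"{path}: row with {len(parts) - 1} values, expected {d}")
            vec = np.array([float(x) for x in parts[1:]], dtype=np.float64)
            out.append(SequenceVector(id=parts[0], vector=vec,
                                      n_known=0, n_unknown=0))
    return out
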