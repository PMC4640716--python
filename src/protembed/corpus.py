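"""Protein sequence I/O and n-gram tokenization.

A protein sequence is tokenized two ways:

* **overlapping** n-grams (stride 1) — used to represent a whole sequence as
  the sum of its n-gram vectors;
* **shifted non-overlapping frames** — the sequence is segmented into
  consecutive n-grams starting at each offset 0..n-1, giving n token lists
  ("biological sentences") per sequence.  These sentences are the skip-gram
  training units: together the n frames cover exactly the multiset of
  overlapping n-grams, so every co-occurrence context is seen without
  training on redundant overlapping windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Non-standard codes that occur in curated protein databases:
#: X (unknown), B (Asx), Z (Glx), U (selenocysteine), O (pyrrolysine).
EXTENDED_AMINO_ACIDS = "XBZUO"

ALPHABET_POLICIES = ("strict", "extended", "skip-record")


@dataclass(frozen=True)
class ProteinSequence:
    """A named residue string over a declared alphabet."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class NGramSentence:
    """One frame of non-overlapping n-grams from a single sequence.

    ``tokens`` concatenated after the first ``frame`` residues of the source
    reconstruct a contiguous substring of it.
    """

    tokens: list[str]
    source_id: str
    frame: int

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """A list of n-gram sentences ready for embedding training."""

    sentences: list[NGramSentence]
    n: int
    alphabet: str = STANDARD_AMINO_ACIDS

    def __len__(self) -> int:
        return len(self.sentences)

    def save(self, path) -> None:
        """Write one sentence per line, tokens space-separated (UTF-8)."""
        with open(path, "w", encoding="utf-8") as fh:
            for sent in self.sentences:
                fh.write(" ".join(sent.tokens))
                fh.write("\n")

    @classmethod
    def load(cls, path, n: int | None = None,
             alphabet: str = STANDARD_AMINO_ACIDS) -> "Corpus":
        """Read a one-sentence-per-line token file.

        ``n`` is inferred from the first token when not given.  Source ids
        and frames are not stored in this format; loaded sentences carry a
        line-number id and frame 0.
        """
        sentences = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                tokens = line.split()
                if not tokens:
                    continue
                if n is None:
                    n = len(tokens[0])
                sentences.append(NGramSentence(tokens, source_id=f"line{i}", frame=0))
        if n is None:
            raise ValueError(f"corpus file {path!r} contains no sentences")
        return cls(sentences, n=n, alphabet=alphabet)


def _validate_residues(rec_id: str, residues: str, policy: str,
                       alphabet: str) -> str | None:
    """Return validated residues, or None when the record is to be skipped."""
    allowed = set(alphabet)
    if policy == "extended":
        allowed |= set(EXTENDED_AMINO_ACIDS)
    bad = next((ch for ch in residues if ch not in allowed), None)
    if bad is None:
        return residues
    if policy == "skip-record":
        logger.warning("skipping record %s: residue %r outside alphabet", rec_id, bad)
        return None
    raise ValueError(
        f"record {rec_id!r} contains residue {bad!r} outside the declared alphabet"
    )


def read_fasta(path, alphabet_policy: str = "extended",
               alphabet: str = STANDARD_AMINO_ACIDS) -> list[ProteinSequence]:
    """Read FASTA records into :class:`ProteinSequence` objects.

    Residues are uppercased and line wraps removed.  ``alphabet_policy``:

    * ``strict`` — any residue outside ``alphabet`` raises;
    * ``extended`` (default) — X/B/Z/U/O are additionally accepted;
    * ``skip-record`` — offending records are dropped with a warning.

    An empty file yields an empty list; sequence data before the first
    header raises.
    """
    if alphabet_policy not in ALPHABET_POLICIES:
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: sequence data before first FASTA header"
                    )
                break
        else:
            return []
    out: list[ProteinSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(" ", "")
        residues = _validate_residues(rec.id, residues, alphabet_policy, alphabet)
        if residues is not None:
            out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width])
                fh.write("\n")


def extract_overlapping(seq: ProteinSequence | str, n: int) -> list[str]:
    """All width-``n`` windows at stride 1, in order; empty when L < n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s = seq.residues if isinstance(seq, ProteinSequence) else seq
    return [s[i:i + n] for i in range(len(s) - n + 1)]


def split_nonoverlapping(seq: ProteinSequence, n: int) -> list[NGramSentence]:
    """Segment ``seq`` into ``n`` shifted non-overlapping n-gram sentences.

    Frame f holds seq[f:f+n], seq[f+n:f+2n], ... dropping any incomplete
    trailing window.  The token multisets of the n frames together equal the
    overlapping n-grams of the sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = seq.residues
    L = len(s)
    if L < n:
        raise ValueError(f"sequence {seq.id!r} shorter than n-gram length {n}")
    frames = []
    for f in range(n):
        stop = L - n + 1
        tokens = [s[i:i + n] for i in range(f, stop, n)]
        frames.append(NGramSentence(tokens, source_id=seq.id, frame=f))
    return frames


def build_training_corpus(seqs: Sequence[ProteinSequence], n: int = 3,
                          strict: bool = True,
                          alphabet: str = STANDARD_AMINO_ACIDS) -> Corpus:
    """Concatenate every sequence's ``n`` frames into one training corpus.

    With every retained sequence of length >= 2n-1 no frame is empty and the
    sentence count is exactly n times the sequence count.  Under
    ``strict=False`` sequences shorter than ``n`` are skipped with a warning
    instead of raising.
    """
    sentences: list[NGramSentence] = []
    skipped = 0
    for seq in seqs:
        if len(seq) < n:
            if strict:
                raise ValueError(
                    f"sequence {seq.id!r} shorter than n-gram length {n}"
                )
            skipped += 1
            continue
        sentences.extend(split_nonoverlapping(seq, n))
    if skipped:
        logger.warning("skipped %d sequences shorter than n=%d", skipped, n)
    return Corpus(sentences, n=n, alphabet=alphabet)
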