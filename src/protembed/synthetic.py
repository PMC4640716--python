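"""Synthetic sequence generators for every pipeline stage.

Three generators cover the testing needs of the method without any
database download:

* :func:`random_proteome` — i.i.d. sequences over the residue alphabet, a
  null proteome with no co-occurrence structure;
* :func:`motif_families` — protein families defined by shared implanted
  motifs over random background, a stand-in for evolutionarily related
  families with a tunable mutation rate;
* :func:`property_corpus` — a token corpus whose co-occurrence is aligned
  with a residue property, so that a trained space being smooth in that
  property (continuity ratio < 1) is the expected, testable outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, NGramSentence, ProteinSequence, STANDARD_AMINO_ACIDS
from .properties import PropertyScale


@dataclass
class FixtureConfig:
    """Parameters of the synthetic generators (all seeded)."""

    seed: int = 0
    alphabet: str = STANDARD_AMINO_ACIDS
    length_range: tuple[int, int] = (50, 200)
    n_sequences: int = 100
    # family parameters
    n_families: int = 3
    members_per_family: int = 50
    motif_length: int = 9
    motifs_per_family: int = 3
    mutation_rate: float = 0.1
    # property-corpus parameters
    property_name: str = "hydrophobicity"
    mixing: float = 0.9
    n_sentences: int = 5000
    tokens_per_sentence: int = 10
    ngram: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.mixing <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.n_sequences, self.n_families, self.members_per_family,
               self.motif_length, self.motifs_per_family, self.n_sentences,
               self.tokens_per_sentence) < 1:
            raise ValueError("all counts must be positive")


def _random_strings(rng: np.random.Generator, lengths: np.ndarray,
                    alphabet: str) -> list[str]:
    """Vectorized generation of random strings with the given lengths."""
    letters = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    total = int(lengths.sum())
    codes = rng.integers(0, len(letters), size=total)
    blob = letters[codes].tobytes().decode("ascii")
    out = []
    pos = 0
    for L in lengths:
        out.append(blob[pos:pos + int(L)])
        pos += int(L)
    return out


def random_proteome(config: FixtureConfig) -> list[ProteinSequence]:
    """i.i.d. uniform residues; lengths uniform on ``config.length_range``."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_sequences)
    strings = _random_strings(rng, lengths, config.alphabet)
    return [ProteinSequence(id=f"rnd{i}", residues=s)
            for i, s in enumerate(strings)]


def motif_families(config: FixtureConfig
                   ) -> tuple[list[ProteinSequence], dict[str, str]]:
    """Families of random-background sequences sharing implanted motifs.

    Each family owns ``motifs_per_family`` random motifs, disjoint across
    families.  A member is uniform background with every family motif
    implanted at a random non-overlapping position; every position of the
    finished sequence is then mutated independently with probability
    ``mutation_rate`` (to a uniformly random residue, which may coincide
    with the original).  Returns the sequences and an id -> family map.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = config.alphabet
    lo, hi = config.length_range
    need = config.motifs_per_family * config.motif_length
    if lo < need:
        raise ValueError(
            f"background length {lo} too short for {config.motifs_per_family} "
            f"motifs of length {config.motif_length}"
        )
    # draw globally distinct motifs, then assign per family
    motifs: list[str] = []
    seen: set[str] = set()
    while len(motifs) < config.n_families * config.motifs_per_family:
        m = _random_strings(rng, np.array([config.motif_length]), alphabet)[0]
        if m not in seen:
            seen.add(m)
            motifs.append(m)
    letters = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)
    seqs: list[ProteinSequence] = []
    labels: dict[str, str] = {}
    for fam in range(config.n_families):
        fam_name = f"fam{fam}"
        fam_motifs = motifs[fam * config.motifs_per_family:
                            (fam + 1) * config.motifs_per_family]
        for member in range(config.members_per_family):
            L = int(rng.integers(lo, hi + 1))
            arr = letters[rng.integers(0, len(letters), size=L)].copy()
            placed: list[tuple[int, int]] = []
            for motif in fam_motifs:
                for _ in range(1000):
                    start = int(rng.integers(0, L - config.motif_length + 1))
                    span = (start, start + config.motif_length)
                    if all(span[1] <= a or span[0] >= b for a, b in placed):
                        placed.append(span)
                        arr[span[0]:span[1]] = np.frombuffer(
                            motif.encode("ascii"), dtype=np.uint8)
                        break
                else:
                    raise ValueError("could not place motifs without overlap")
            if config.mutation_rate > 0:
                mask = rng.random(L) < config.mutation_rate
                arr[mask] = letters[rng.integers(0, len(letters),
                                                 size=int(mask.sum()))]
            sid = f"{fam_name}_m{member}"
            seqs.append(ProteinSequence(id=sid, residues=arr.tobytes().decode("ascii")))
            labels[sid] = fam_name
    return seqs, labels


def property_corpus(config: FixtureConfig,
                    scale: PropertyScale) -> Corpus:
    """Token corpus whose co-occurrence tracks a residue property.

    The alphabet is split at the median of ``scale`` into a low and a high
    half.  Each sentence picks a dominant half; each of its tokens is built
    from the dominant half with probability ``mixing`` and from the other
    half otherwise.  At mixing 1.0 sentences are pure; at 0.5 the halves
    mix at chance and the corpus carries no property signal.
    """
    rng = np.random.default_rng(config.seed)
    residues = sorted(config.alphabet)
    vals = np.array([scale.values[r] for r in residues])
    order = np.argsort(vals, kind="stable")
    half = len(residues) // 2
    low = [residues[i] for i in order[:half]]
    high = [residues[i] for i in order[half:]]
    halves = (low, high)
    n = config.ngram
    sentences: list[NGramSentence] = []
    for s in range(config.n_sentences):
        dominant = int(rng.integers(0, 2))
        tokens = []
        for _ in range(config.tokens_per_sentence):
            use = dominant if rng.random() < config.mixing else 1 - dominant
            pool = halves[use]
            idx = rng.integers(0, len(pool), size=n)
            tokens.append("".join(pool[i] for i in idx))
        sentences.append(NGramSentence(tokens, source_id=f"syn{s}", frame=0))
    return Corpus(sentences, n=n, alphabet=config.alphabet)


def cooccurrence_toy_corpus(seed: int = 0, n_sentences: int = 500,
                            fillers_per_pool: int = 6,
                            sentence_length: int = 6) -> Corpus:
    """Positive control for embedding geometry: A and B always co-occur.

    Half the sentences contain tokens AAA and BBB plus fillers from a
    private pool; the other half contain ZZZ plus fillers from a disjoint
    pool, so ZZZ never co-occurs with AAA and shares no context with it.
    After training, AAA and BBB should be closer (cosine of input vectors)
    than AAA and ZZZ.
    """
    rng = np.random.default_rng(seed)
    pool_ab = [f"P{i}A" for i in range(fillers_per_pool)]
    pool_z = [f"Q{i}Z" for i in range(fillers_per_pool)]
    sentences = []
    for i in range(n_sentences):
        if i % 2 == 0:
            toks = ["AAA", "BBB"] + [pool_ab[rng.integers(0, fillers_per_pool)]
                                     for _ in range(sentence_length - 2)]
        else:
            toks = ["ZZZ"] + [pool_z[rng.integers(0, fillers_per_pool)]
                              for _ in range(sentence_length - 1)]
        rng.shuffle(toks)
        sentences.append(NGramSentence(list(toks), source_id=f"toy{i}", frame=0))
    return Corpus(sentences, n=3)


def write_labels(labels: dict[str, str], path) -> None:
    """Two-column TSV: sequence id, family label."""
    with open(path, "w", encoding="utf-8") as fh:
        for sid, fam in labels.items():
            fh.write(f"{sid}\t{fam}\n")


def read_labels(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sid, fam = line.split("\t")
            labels[sid] = fam
    return labels
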