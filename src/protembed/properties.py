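"""Biophysical continuity of the n-gram space via Lipschitz constants.

An n-gram is scored on a per-residue property scale (mean of its residues'
values).  The smoothness of the embedding with respect to that property is
the best (smallest) Lipschitz constant k satisfying

    |f(w1) - f(w2)| <= k * ||v(w1) - v(w2)||

over all token pairs — i.e. the maximum ratio of property-score distance to
Euclidean embedding distance.  A smaller k means the property varies more
smoothly over the space.  The null reference is the "scrambled space": the
same vectors with the token labels randomly permuted, which preserves the
vector geometry but destroys any alignment with the property.  The ratio
k_trained / k_scrambled below 1 indicates the trained space is smoother
than chance.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .corpus import STANDARD_AMINO_ACIDS
from .embedding import EmbeddingModel

logger = logging.getLogger(__name__)

#: Names of the bundled residue scales.
BUILTIN_SCALES = ("mass", "volume", "van_der_waals_volume", "polarity",
                  "hydrophobicity", "charge")


@dataclass
class PropertyScale:
    """Per-residue numeric scale, e.g. hydrophobicity."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [a for a in STANDARD_AMINO_ACIDS if a not in self.values]
        if missing:
            raise ValueError(
                f"scale {self.name!r} lacks values for residues {missing}"
            )
        if not all(np.isfinite(list(self.values.values()))):
            raise ValueError(f"scale {self.name!r} contains non-finite values")


@dataclass
class LipschitzReport:
    property_name: str
    k_trained: float
    k_scrambled: float
    ratio: float
    n_points: int
    seed: int


def load_scale(path, name: str | None = None) -> PropertyScale:
    """Read a residue<TAB>value scale file ('#'-comment lines allowed)."""
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            residue, value = line.split("\t")
            values[residue] = float(value)
    return PropertyScale(name=name or str(path), values=values)


def builtin_scale(name: str) -> PropertyScale:
    """One of the bundled standard scales (see :data:`BUILTIN_SCALES`)."""
    if name not in BUILTIN_SCALES:
        raise KeyError(f"unknown scale {name!r}; available: {BUILTIN_SCALES}")
    ref = resources.files("protembed") / "data" / "scales" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return load_scale(path, name=name)


def builtin_scales() -> list[PropertyScale]:
    return [builtin_scale(name) for name in BUILTIN_SCALES]


def ngram_property_score(token: str, scale: PropertyScale,
                         aggregate: str = "mean") -> float:
    """Mean (default) or sum of per-residue scale values over the token."""
    try:
        vals = [scale.values[ch] for ch in token]
    except KeyError as exc:
        raise KeyError(
            f"residue {exc.args[0]!r} of token {token!r} absent from scale "
            f"{scale.name!r}"
        ) from None
    return float(np.sum(vals) if aggregate == "sum" else np.mean(vals))


def _as_arrays(points, scores) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, Mapping):
        keys = list(points)
        vecs = np.asarray([points[k] for k in keys], dtype=np.float64)
        svals = np.asarray([scores[k] for k in keys], dtype=np.float64)
    else:
        vecs = np.asarray(points, dtype=np.float64)
        svals = np.asarray(scores, dtype=np.float64)
    return vecs, svals


def lipschitz_constant(points, scores, return_skipped: bool = False):
    """Smallest k with |score_i - score_j| <= k * ||v_i - v_j|| for all pairs.

    ``points`` is a token -> vector mapping (or an array of vectors) and
    ``scores`` the matching token -> value mapping (or array).  Pairs at
    zero vector distance are excluded (and counted): the supremum would be
    infinite whenever their scores differ.  Raises when fewer than two
    points or every pair is degenerate.
    """
    vecs, svals = _as_arrays(points, scores)
    m = vecs.shape[0]
    if m < 2:
        raise ValueError("need at least 2 points")
    best = 0.0
    skipped = 0
    block = 512  # bounds the pairwise-distance workspace
    for start in range(0, m - 1, block):
        stop = min(start + block, m - 1)
        dw = cdist(vecs[start:stop], vecs)  # (b, m)
        df = np.abs(svals[start:stop, None] - svals[None, :])
        cols = np.arange(m)[None, :]
        rows = np.arange(start, stop)[:, None]
        upper = cols > rows  # each unordered pair once
        zero = (dw == 0.0) & upper
        skipped += int(zero.sum())
        valid = upper & ~zero
        if valid.any():
            best = max(best, float((df[valid] / dw[valid]).max()))
    if skipped == m * (m - 1) // 2:
        raise ValueError("all pairs are at zero vector distance")
    if return_skipped:
        return best, skipped
    return best


def scrambled_baseline(points, scores, n_shuffles: int = 1,
                       seed: int = 0) -> float:
    """Mean Lipschitz constant over seeded random relabelings of the space.

    Each shuffle permutes the assignment of scores to vectors uniformly at
    random, then recomputes the constant; the mean over ``n_shuffles``
    permutations is returned.
    """
    vecs, svals = _as_arrays(points, scores)
    rng = np.random.default_rng(seed)
    ks = []
    for _ in range(n_shuffles):
        perm = rng.permutation(svals.shape[0])
        ks.append(lipschitz_constant(vecs, svals[perm]))
    return float(np.mean(ks))


def continuity_report(model: EmbeddingModel, scales: Sequence[PropertyScale],
                      n_shuffles: int = 1, seed: int = 0
                      ) -> tuple[list[LipschitzReport], float]:
    """Per-scale trained vs. scrambled Lipschitz constants, plus mean ratio.

    Vocabulary tokens containing residues outside the 20-letter alphabet
    are excluded (with a logged count).  Returns one report per scale and
    the unweighted mean of the ratios.
    """
    standard = set(STANDARD_AMINO_ACIDS)
    tokens = [t for t in model.vocab.tokens if set(t) <= standard]
    excluded = len(model.vocab) - len(tokens)
    if excluded:
        logger.info("excluded %d tokens with non-standard residues", excluded)
    if len(tokens) < 2:
        raise ValueError("fewer than 2 scoreable vocabulary tokens")
    vecs = model.input_vectors[[model.vocab.index[t] for t in tokens]]
    reports = []
    for scale in scales:
        svals = np.array([ngram_property_score(t, scale) for t in tokens])
        k_tr = lipschitz_constant(vecs, svals)
        k_sc = scrambled_baseline(vecs, svals, n_shuffles=n_shuffles, seed=seed)
        if k_sc <= 0:
            raise ValueError(f"scrambled constant is 0 for scale {scale.name!r}")
        reports.append(LipschitzReport(
            property_name=scale.name, k_trained=k_tr, k_scrambled=k_sc,
            ratio=k_tr / k_sc, n_points=len(tokens), seed=seed,
        ))
    mean_ratio = float(np.mean([r.ratio for r in reports]))
    return reports, mean_ratio


def write_report_csv(reports: Sequence[LipschitzReport], mean_ratio: float,
                     path) -> None:
    """CSV with columns property, k_trained, k_scrambled, ratio + Average row."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["property", "k_trained", "k_scrambled", "ratio"])
        for r in reports:
            writer.writerow([r.property_name, f"{r.k_trained:.6g}",
                             f"{r.k_scrambled:.6g}", f"{r.ratio:.6g}"])
        k_tr = np.mean([r.k_trained for r in reports])
        k_sc = np.mean([r.k_scrambled for r in reports])
        writer.writerow(["Average", f"{k_tr:.6g}", f"{k_sc:.6g}",
                         f"{mean_ratio:.6g}"])
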