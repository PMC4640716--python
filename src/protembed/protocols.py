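"""Reference validation protocols on synthetic study conditions.

Each function runs one self-contained experiment of the method's
validation suite — corpus-construction identities, gradient verification,
continuity controls, the motif-family classification benchmark — at fixed
synthetic study conditions, and returns the measured quantities.  They are
used by the package's acceptance checks and are convenient entry points
for reproducing those numbers interactively.

Problem sizes are chosen so every protocol runs in seconds to a few
minutes on one CPU; the corpus-size identity alone runs at full scale
(546,790 sequences) because it is an exact count, not an estimate.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .classify import BinaryDataset, cross_validate, run_family_benchmark
from .corpus import build_training_corpus, extract_overlapping, split_nonoverlapping
from .embedding import (EmbeddingModel, TrainingConfig, TrainingPair, Vocabulary,
                        cosine_similarity, sgns_gradients, sgns_objective, train)
from .properties import builtin_scale, continuity_report, lipschitz_constant
from .sequence import SequenceVector, embed_set
from .synthetic import (FixtureConfig, cooccurrence_toy_corpus, motif_families,
                        property_corpus, random_proteome)

#: Number of sequences in the full-scale corpus-size identity (the size of
#: the curated protein database the method is designed to train on).
FULL_SCALE_SEQUENCES = 546_790


def corpus_size_identity(n_sequences: int = FULL_SCALE_SEQUENCES,
                         seed: int = 1, n: int = 3) -> dict:
    """Split ``n_sequences`` random sequences (length >= 5) into shifted
    non-overlapping frames and count the resulting sentences.

    With every sequence of length >= 2n-1 the count is exactly
    n * n_sequences (3 x 546,790 = 1,640,370 at full scale).
    """
    cfg = FixtureConfig(seed=seed, n_sequences=n_sequences, length_range=(5, 30))
    seqs = random_proteome(cfg)
    corpus = build_training_corpus(seqs, n=n)
    return {"n_sequences": n_sequences, "n_sentences": len(corpus)}


def sgns_gradient_max_error(n_instances: int = 100, seed: int = 11) -> float:
    """Max relative deviation of analytic SGNS gradients from fourth-order
    central finite differences over random small (model, pair-set) instances.

    Per instance the deviation is measured in the max norm, relative to the
    largest gradient entry of the table.
    """
    rng = np.random.default_rng(seed)
    h = 1e-4
    worst = 0.0
    for _ in range(n_instances):
        W, d = 5, 3
        tokens = [f"t{i}" for i in range(W)]
        vocab = Vocabulary(tokens=tokens, counts={t: 1 for t in tokens})
        model = EmbeddingModel(
            vocab=vocab, dim=d,
            input_vectors=rng.normal(scale=0.8, size=(W, d)),
            output_vectors=rng.normal(scale=0.8, size=(W, d)))
        pos = [TrainingPair(int(rng.integers(W)), int(rng.integers(W)))
               for _ in range(4)]
        neg = [TrainingPair(int(rng.integers(W)), int(rng.integers(W)), "negative")
               for _ in range(4)]
        g_in, g_out = sgns_gradients(model, pos, neg)
        for table, grad in ((model.input_vectors, g_in),
                            (model.output_vectors, g_out)):
            fd = np.zeros_like(grad)
            for i in range(W):
                for k in range(d):
                    orig = table[i, k]
                    vals = []
                    for step in (-2 * h, -h, h, 2 * h):
                        table[i, k] = orig + step
                        vals.append(sgns_objective(model, pos, neg))
                    table[i, k] = orig
                    fd[i, k] = (vals[0] - 8 * vals[1] + 8 * vals[2]
                                - vals[3]) / (12 * h)
            scale = max(np.abs(grad).max(), 1e-8)
            worst = max(worst, float(np.abs(fd - grad).max() / scale))
    return worst


def frame_union_check(n_sequences: int = 1000, seed: int = 2,
                      n: int = 3) -> dict:
    """Frame-union identity on random sequences.

    Counts sequences whose non-overlapping frames' token multiset differs
    from the overlapping token multiset, or whose total token count is not
    L - n + 1.  Both counts are 0 when the splitting rule is correct.
    """
    cfg = FixtureConfig(seed=seed, n_sequences=n_sequences, length_range=(5, 120))
    mismatches = 0
    for seq in random_proteome(cfg):
        frames = split_nonoverlapping(seq, n)
        union = Counter(t for f in frames for t in f.tokens)
        overlapping = Counter(extract_overlapping(seq, n))
        if union != overlapping or sum(union.values()) != len(seq) - n + 1:
            mismatches += 1
    return {"n_checked": n_sequences, "n_mismatches": mismatches}


def geometry_recovery(n_seeds: int = 5, base_seed: int = 1) -> dict:
    """Always-co-occurring tokens end closer than never-co-occurring ones.

    Trains on the toy co-occurrence corpus for ``n_seeds`` seeds and counts
    seeds with cosine(A, B) > cosine(A, Z).
    """
    successes = 0
    for seed in range(base_seed, base_seed + n_seeds):
        corpus = cooccurrence_toy_corpus(seed=seed)
        m = train(corpus, TrainingConfig(dim=10, window=5, epochs=5, seed=seed))
        if (cosine_similarity(m.vector("AAA"), m.vector("BBB"))
                > cosine_similarity(m.vector("AAA"), m.vector("ZZZ"))):
            successes += 1
    return {"n_seeds": n_seeds, "n_success": successes}


def lipschitz_oracle_deviation(sizes: tuple[int, ...] = (100, 500),
                               seed: int = 3) -> float:
    """Max absolute deviation of the blocked Lipschitz computation from an
    exhaustive all-pairs evaluation on random point sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for m in sizes:
        vecs = rng.normal(size=(m, 5))
        scores = rng.normal(size=m)
        fast = lipschitz_constant(vecs, scores)
        brute = 0.0
        for i in range(m):
            dw = np.linalg.norm(vecs[i + 1:] - vecs[i], axis=1)
            df = np.abs(scores[i + 1:] - scores[i])
            ok = dw > 0
            if ok.any():
                brute = max(brute, float((df[ok] / dw[ok]).max()))
        worst = max(worst, abs(fast - brute))
    return worst


#: Training configuration of the small continuity-control embeddings:
#: d=20 over 5,000 sentences needs ~10 corpus passes to converge.
CONTINUITY_TRAINING = dict(dim=20, window=5, epochs=10)


def continuity_ratios(mixing: float, n_seeds: int = 10,
                      property_name: str = "hydrophobicity",
                      base_seed: int = 0) -> list[float]:
    """Trained/scrambled Lipschitz ratios over seeds at one mixing level.

    Mixing 0.9 is the positive control (co-occurrence aligned with the
    property; ratios expected < 1); mixing 0.5 is the null (no signal;
    ratios expected near 1).
    """
    scale = builtin_scale(property_name)
    ratios = []
    for seed in range(base_seed, base_seed + n_seeds):
        cfg = FixtureConfig(seed=seed, mixing=mixing, n_sentences=5000)
        corpus = property_corpus(cfg, scale)
        model = train(corpus, TrainingConfig(seed=seed, **CONTINUITY_TRAINING))
        reports, _ = continuity_report(model, [scale], n_shuffles=1, seed=seed)
        ratios.append(reports[0].ratio)
    return ratios


#: Study conditions of the motif-family classification benchmark: 5
#: families of 100 members, each family defined by three 9-residue motifs
#: (~27 conserved positions, a short-domain stand-in), mutation rate 0.1.
FAMILY_BENCHMARK = dict(n_families=5, members_per_family=100, motif_length=9,
                        motifs_per_family=3, mutation_rate=0.1,
                        length_range=(50, 200))

#: Embedding trained for the benchmark: the standard 100-dimensional space;
#: window 10 suits the ~40-token sentences of these short synthetic proteins.
FAMILY_TRAINING = dict(dim=100, window=10, epochs=5)


def family_benchmark(seed: int = 7, folds: int = 10, **overrides) -> dict:
    """End-to-end motif-family benchmark: generate families and background,
    train an embedding on all sequences, embed, cross-validate one balanced
    task per family, and aggregate with instance weighting."""
    params = {**FAMILY_BENCHMARK, **overrides}
    fam_cfg = FixtureConfig(seed=seed, **params)
    fam_seqs, labels = motif_families(fam_cfg)
    bg_cfg = FixtureConfig(seed=seed + 1, n_sequences=120 + fam_cfg.members_per_family,
                           length_range=params["length_range"])
    bg_seqs = random_proteome(bg_cfg)
    corpus = build_training_corpus(list(fam_seqs) + list(bg_seqs), n=3)
    model = train(corpus, TrainingConfig(seed=seed, **FAMILY_TRAINING))
    vectors = {v.id: v for v in embed_set(fam_seqs, model)}
    bg_vecs = embed_set(bg_seqs, model)
    families: dict[str, list[str]] = {}
    for sid, fam in labels.items():
        families.setdefault(fam, []).append(sid)
    results, (sens, spec, acc) = run_family_benchmark(
        families, vectors, bg_vecs, folds=folds, seed=seed)
    return {"results": results, "weighted_sensitivity": sens,
            "weighted_specificity": spec, "weighted_accuracy": acc,
            "n_instances": sum(r.n_instances for r in results)}


def chance_level_accuracy(seed: int = 8, n_per_class: int = 100,
                          dim: int = 5, folds: int = 10) -> float:
    """Cross-validated accuracy when both classes share one distribution.

    The labels carry no information, so accuracy should sit at chance
    (0.5) up to binomial noise.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, dim))
    pos = [SequenceVector(id=f"p{i}", vector=X[i], n_known=dim, n_unknown=0)
           for i in range(n_per_class)]
    neg = [SequenceVector(id=f"n{i}", vector=X[n_per_class + i], n_known=dim,
                          n_unknown=0) for i in range(n_per_class)]
    res = cross_validate(BinaryDataset("null", pos, neg), folds=folds, seed=seed)
    return res.accuracy
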