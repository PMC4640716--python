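"""Sequential skip-gram negative-sampling (SGNS) inner loop.

Compiled with numba and run single-threaded so that training is
bit-reproducible for a fixed seed.  Randomness (negative draws) comes from a
64-bit linear congruential generator stepped inline; negatives are drawn by
binary search on the cumulative noise distribution, so the sampling law is
exactly the unigram^alpha distribution with no table quantization.
"""

from __future__ import annotations

import numba
import numpy as np

_LCG_MULT = np.uint64(25214903917)
_LCG_ADD = np.uint64(11)
_TWO53 = 9007199254740992.0  # 2**53


@numba.njit(cache=True)
def count_pairs(tokens, offsets, window):
    """Number of (center, context) positive pairs the kernel will visit."""
    total = 0
    n_sent = offsets.shape[0] - 1
    for s in range(n_sent):
        start = offsets[s]
        end = offsets[s + 1]
        for i in range(start, end):
            if tokens[i] < 0:
                continue
            lo = max(start, i - window)
            hi = min(end, i + window + 1)
            for j in range(lo, hi):
                if j != i and tokens[j] >= 0:
                    total += 1
    return total


@numba.njit(cache=True)
def train_epochs(tokens, offsets, inp, out, cum, window, k_neg, epochs,
                 alpha0, alpha_min, seed, total_pairs):
    """Run SGNS gradient ascent in place over ``epochs`` corpus passes.

    ``tokens`` is the int32 concatenation of all sentences (-1 marks an
    out-of-vocabulary position, which keeps its slot in the window but never
    forms a pair); ``offsets`` delimits sentences.  For each positive pair
    the update targets the context's output vector plus ``k_neg`` noise
    tokens' output vectors, then the center's input vector, with a learning
    rate decayed linearly from ``alpha0`` to ``alpha_min`` over
    ``total_pairs`` pair presentations.
    """
    W, d = inp.shape
    state = np.uint64(seed) * _LCG_MULT + np.uint64(1)
    neu1e = np.zeros(d)
    pairs_done = 0
    n_sent = offsets.shape[0] - 1
    for _ep in range(epochs):
        for s in range(n_sent):
            start = offsets[s]
            end = offsets[s + 1]
            for i in range(start, end):
                w = tokens[i]
                if w < 0:
                    continue
                lo = max(start, i - window)
                hi = min(end, i + window + 1)
                for j in range(lo, hi):
                    if j == i:
                        continue
                    c = tokens[j]
                    if c < 0:
                        continue
                    lr = alpha0 + (alpha_min - alpha0) * (pairs_done / total_pairs)
                    if lr < alpha_min:
                        lr = alpha_min
                    for k in range(d):
                        neu1e[k] = 0.0
                    for neg in range(k_neg + 1):
                        if neg == 0:
                            t = c
                            label = 1.0
                        else:
                            state = state * _LCG_MULT + _LCG_ADD
                            u = float(state >> np.uint64(11)) / _TWO53
                            t = np.searchsorted(cum, u, side="right")
                            if t >= W:
                                t = W - 1
                            label = 0.0
                        f = 0.0
                        for k in range(d):
                            f += inp[w, k] * out[t, k]
                        if f > 30.0:
                            sig = 1.0
                        elif f < -30.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-f))
                        g = (label - sig) * lr
                        for k in range(d):
                            neu1e[k] += g * out[t, k]
                            out[t, k] += g * inp[w, k]
                    for k in range(d):
                        inp[w, k] += neu1e[k]
                    pairs_done += 1
    return pairs_done
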