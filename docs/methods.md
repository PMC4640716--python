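# Methods

## Model

`protembed` learns a distributed representation of protein 3-grams with
the skip-gram model trained by negative sampling (SGNS). Every vocabulary
token *w* carries two vectors: an input vector `v_w` (the representation
used downstream) and an output vector `v′_w` (the context role). A
(center, context) pair drawn from a symmetric window is scored
`p(observed) = σ(v′_c · v_w)`, and stochastic gradient ascent maximizes
the log-likelihood of observed pairs against `k_neg` noise pairs per
positive, with noise contexts drawn from the unigram distribution raised
to an exponent. The full-softmax skip-gram likelihood is never optimized
directly; SGNS is the trained objective.

Assumptions worth stating: co-occurrence of 3-grams within a window is
taken as the only training signal; sequences are treated as i.i.d.
sentences (no position or strand information); and the input vector table
alone is used for all downstream representations.

## Tokenization

Each sequence of length L ≥ 3 is segmented into three sentences of
non-overlapping 3-grams starting at offsets 0, 1 and 2, dropping any
incomplete trailing window. The three frames together contain exactly the
multiset of all L − 2 overlapping 3-grams — an identity the test suite
asserts on random sequences — so the trainer sees every 3-gram in context
once per epoch without training on redundant overlapping windows.
Sequences shorter than 3 raise in strict mode and are skipped with a
warning otherwise. Non-standard residue codes (X, B, Z, U, O) are by
default ordinary token characters, matching what a word-level trainer run
on a raw curated database would do; `strict` and `skip-record` policies
are available.

## Training parameters

| parameter | default | meaning |
|---|---|---|
| `dim` | 100 | vector dimension d |
| `window` | 25 | context tokens on each side of the center |
| `negatives` | 5 | noise pairs per positive pair |
| `epochs` | 5 | corpus passes |
| `initial/final_learning_rate` | 0.025 → 1e-4 | linear decay over all pair presentations |
| `min_count` | 1 | vocabulary threshold (protein 3-grams are dense: ≤ 8000 standard tokens) |
| `noise_exponent` | 0.75 | unigram distortion of the noise law |

"Window 25" is interpreted as 25 tokens per side (the convention of the
word2vec `window` parameter). Input vectors initialize i.i.d. uniform on
[−0.5/d, 0.5/d), output vectors at zero — which makes `epochs=0` an
exactly testable identity. Frequent-token subsampling is not implemented.
A noise draw that happens to equal the true context is kept as a negative
rather than resampled, so the sampling law is exactly the stated
distribution.

The inner loop is a sequential numba kernel with its own 64-bit LCG for
negative draws (inverse-CDF on the exact cumulative noise distribution,
no table quantization). Single-threaded execution plus an explicit seed
makes training bit-reproducible; the pure-Python objective and gradient
functions in `embedding.py` are the oracle surface against which the
kernel's update rule is verified by fourth-order central finite
differences (step 1e-4; entries untouched by any pair have exact zero
gradient and are compared under a 1e-10 absolute floor, since the
numerical oracle itself carries ~1e-12 roundoff).

## Sequence representation

A sequence vector is the plain sum of its overlapping 3-grams' input
vectors — no averaging or length normalization by default (a `mean`
option exists), so sequence length is partially encoded in the norm.
Out-of-vocabulary 3-grams contribute nothing and are counted; an
all-unknown sequence yields the zero vector with a warning. The
representation depends only on the 3-gram multiset, is linear in the
model's vectors, and always has the model's dimension — all asserted as
properties.

## Continuity statistic

For a per-residue scale, a 3-gram's score is the mean of its residues'
values (sum available behind a flag; it changes k by exactly the factor
n). The Lipschitz constant is the maximum over unordered token pairs of
|score difference| / Euclidean distance in the full d-dimensional space
(never in a 2D projection). Pairs at zero vector distance are excluded
and counted — the supremum would otherwise be infinite. The scrambled
baseline permutes the score-to-vector assignment uniformly at random;
`n_shuffles` defaults to 1 (one scrambled space), configurable upward for
variance estimates. All scoreable vocabulary tokens enter the statistic;
tokens containing non-standard residues are excluded with a logged count.

Bundled scales are standard published values: average residue mass,
Zamyatnin residue volumes, Bondi-derived van der Waals volumes, Grantham
polarity, Kyte-Doolittle hydropathy, and integer side-chain charge at
pH 7 (His 0.1). Reported continuity ratios therefore characterize this
package's spaces, not any externally published constant.

## Classification protocol

Balanced binary datasets (negatives sampled uniformly without replacement
from a background pool excluding positives, seeded) are evaluated with
stratified seeded 10-fold cross-validation of a linear-kernel SVM at
C = 1.0, with per-dimension standardization fit on each training split
only — summed vectors have length-dependent norms that a margin
classifier would otherwise penalize arbitrarily. Headline metrics are
computed from confusion counts pooled over folds (micro); per-fold
metrics are retained on the result for fold-averaged (macro) analyses.
Families smaller than the fold count cannot be cross-validated and are
skipped with a warning, excluded from the instance-weighted summary. A
helper samples a negative pool to match a target mean sequence length
within ±5%, for disorder-style tasks where length is a confound.

## Synthetic study conditions

The generators emulate three data regimes:

* **random proteome** — i.i.d. uniform residues, lengths uniform on a
  range; the structureless null. Uniform composition rather than
  database composition keeps the null simple.
* **motif families** — each family owns three 9-residue motifs (disjoint
  across families by construction, guaranteeing a learnable signal at
  small scale), implanted at random non-overlapping positions in uniform
  background of length 50–200, with every position then mutated to a
  uniform residue at rate 0.1 by default. Three short motifs (~27
  conserved positions) stand in for a family-defining domain; a single
  9-mer is a weaker signal than real family conservation.
* **property corpus** — the alphabet is split at the median of a residue
  scale; each sentence draws tokens mostly (probability = mixing) from
  one half. At mixing 0.9 co-occurrence is strongly aligned with the
  property; at 0.5 it is chance, giving a matched null.

What these do *not* emulate: real residue composition, repeats, indels,
phylogenetic correlation between family members, or disorder-specific
composition bias. Passing tests therefore demonstrate that the
implementation recovers structure that is present and reports chance when
it is absent — not that any particular accuracy transfers to real
proteomes.

## Validation protocols and problem sizes

`protembed.protocols` fixes the study conditions used by the acceptance
checks. The corpus-size identity runs at full scale (546,790 sequences,
an exact count). Continuity controls train d = 20 embeddings on 5,000
sentences for 10 corpus passes — the passes chosen so this small corpus
reaches convergence — over 10 seeds per mixing level. The family
benchmark trains the standard d = 100 space with window 10 (suited to
the ~40-token sentences of these short synthetic proteins) for 5 passes.
Chance-level calibration uses 200 instances against the 99% binomial
band around 0.5.

## Numerical choices

* Vocabulary order, neighbor ranking and all other ties break
  lexicographically, for determinism.
* Sigmoid inputs are clamped at ±30 in the kernel; the Python objective
  uses a stabilized log-sigmoid (`-logaddexp(0, -x)`).
* Model persistence uses the word2vec text format (`W d` header, one
  token row each) with 8 significant digits; only input vectors are
  stored, so token counts and output vectors do not survive a round
  trip.
* Cosine similarity of a zero vector is defined as 0.
* The Lipschitz computation blocks the pairwise-distance workspace at
  512 rows to bound memory on vocabularies of thousands of tokens.

## Known limitations

* The trainer is deliberately single-threaded; there is no parallel or
  GPU path.
* Hierarchical softmax and frequent-token subsampling are not
  implemented.
* The `window` semantics count tokens, not residues; with 3-gram tokens
  a window of 25 spans 75 residues per side.
* Loaded models carry placeholder token counts (the text format does not
  store them), so noise distributions cannot be rebuilt from a loaded
  model alone.
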