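"""Represent whole sequences as summed 3-gram vectors.

Embeds a handful of sequences with a small trained model and shows the
bookkeeping: each sequence of length L contributes L - 2 overlapping
3-grams, each in-vocabulary 3-gram adds its input vector to the sum, and
unknown 3-grams are skipped but counted.
"""

import numpy as np

from protembed import build_training_corpus, embed_set, train
from protembed.embedding import TrainingConfig
from protembed.synthetic import FixtureConfig, random_proteome

seqs = random_proteome(FixtureConfig(seed=1, n_sequences=100,
                                     length_range=(60, 120)))
model = train(build_training_corpus(seqs, n=3),
              TrainingConfig(dim=16, window=5, epochs=2, seed=1))

vectors = embed_set(seqs[:5], model)
for v in vectors:
    print(f"{v.id}: |v| = {np.linalg.norm(v.vector):.3f}, "
          f"{v.n_known} known + {v.n_unknown} unknown 3-grams")
print("\nthe norm grows with sequence length because the representation "
      "is a plain sum; n_known + n_unknown always equals L - 2.")
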