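"""2D projection and plotting of the n-gram space.

The high-dimensional token vectors are projected to 2D with t-distributed
stochastic neighbor embedding (t-SNE) for visual inspection — colored by a
property score, the projection shows whether biophysically similar n-grams
cluster.  Per-dataset 2D histograms bin every overlapping n-gram occurrence
of a sequence set into the shared projected coordinate frame, making token
usage across datasets visually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE

from .corpus import ProteinSequence, extract_overlapping


@dataclass
class Projection2D:
    ids: list[str]
    coords: np.ndarray  # (n, 2)
    perplexity: float
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.ids), 2):
            raise ValueError("coords must be (len(ids), 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite projected coordinates")

    def mapping(self) -> dict[str, np.ndarray]:
        return {i: self.coords[k] for k, i in enumerate(self.ids)}


def project_2d(vectors: Mapping[str, np.ndarray], perplexity: float = 30.0,
               seed: int = 0) -> Projection2D:
    """t-SNE projection of an id -> vector mapping to 2D.

    Deterministic for a fixed seed (PCA initialization, fixed random
    state).  Requires at least 3 points and perplexity < point count.
    """
    ids = list(vectors)
    if len(ids) < 3:
        raise ValueError("need at least 3 points to project")
    if perplexity >= len(ids):
        raise ValueError(f"perplexity {perplexity} must be < n points {len(ids)}")
    X = np.asarray([vectors[i] for i in ids], dtype=np.float64)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca", learning_rate="auto")
    coords = tsne.fit_transform(X)
    return Projection2D(ids=ids, coords=coords, perplexity=perplexity, seed=seed)


def ngram_histogram2d(dataset: Sequence[ProteinSequence],
                      projection: Projection2D, bins: int = 100,
                      n: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin every overlapping n-gram occurrence at its projected coordinate.

    The grid covers the bounding box of the full projection, so histograms
    of different datasets share one coordinate frame.  Returns (grid,
    x_edges, y_edges); the grid total equals the number of in-vocabulary
    n-gram occurrences in the dataset.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if n is None:
        n = len(projection.ids[0])
    coord_of = projection.mapping()
    xs, ys = [], []
    for seq in dataset:
        for token in extract_overlapping(seq, n):
            c = coord_of.get(token)
            if c is not None:
                xs.append(c[0])
                ys.append(c[1])
    x_range = (projection.coords[:, 0].min(), projection.coords[:, 0].max())
    y_range = (projection.coords[:, 1].min(), projection.coords[:, 1].max())
    grid, x_edges, y_edges = np.histogram2d(
        xs, ys, bins=bins, range=(x_range, y_range))
    return grid, x_edges, y_edges


def render(obj, out_path, color_by: Mapping[str, float] | None = None,
           title: str | None = None) -> None:
    """Write a raster image of a projection (scatter) or a histogram grid.

    For a :class:`Projection2D`, points are colored by the optional
    ``color_by`` id -> scalar mapping, min-max normalized, with a colorbar
    legend.  For a (grid, x_edges, y_edges) triple a heatmap is drawn.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    if isinstance(obj, Projection2D):
        if color_by is not None:
            c = np.array([color_by[i] for i in obj.ids], dtype=np.float64)
            lo, hi = c.min(), c.max()
            norm = (c - lo) / (hi - lo) if hi > lo else np.zeros_like(c)
            sc = ax.scatter(obj.coords[:, 0], obj.coords[:, 1], c=norm,
                            s=8, cmap="viridis")
            fig.colorbar(sc, ax=ax, label="normalized property score")
        else:
            ax.scatter(obj.coords[:, 0], obj.coords[:, 1], s=8)
    else:
        grid, x_edges, y_edges = obj
        im = ax.imshow(grid.T, origin="lower", aspect="auto",
                       extent=(x_edges[0], x_edges[-1], y_edges[0], y_edges[-1]),
                       cmap="viridis")
        fig.colorbar(im, ax=ax, label="n-gram occurrences")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
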