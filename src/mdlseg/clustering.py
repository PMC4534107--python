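"""Methylome comparison by MDL pixel vectors: Spearman + Ward clustering.

Each methylome is reduced to its 400-pixel MDL count vector; similarity
between two methylomes is the Spearman rank-order correlation of their
vectors (average ranks for ties — pixel counts are heavily tied at zero).
Samples are clustered with Ward's method on the dissimilarity d = 1 - rho,
the convention that lets Ward linkage operate on an arbitrary precomputed
dissimilarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric Spearman rho matrix with unit diagonal."""

    names: tuple[str, ...]
    rho: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.names)
        if self.rho.shape != (n, n):
            raise ValueError("similarity matrix shape does not match sample names")
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.all(np.diag(self.rho) == 1.0):
            raise ValueError("similarity matrix diagonal must be exactly 1")
        if np.any(self.rho < -1 - 1e-12) or np.any(self.rho > 1 + 1e-12):
            raise ValueError("Spearman rho outside [-1, 1]")


def spearman_matrix(vectors: Mapping[str, np.ndarray]) -> SimilarityMatrix:
    """Pairwise Spearman rho of per-sample pixel vectors.

    Computed as the Pearson correlation of average-ranked values, the
    defining identity under ties. A constant vector has no ranks to
    correlate; it is reported as an error naming the offending sample.
    """
    names = tuple(vectors)
    if len(names) < 2:
        raise ValueError("need at least 2 samples")
    lengths = {len(np.asarray(v).reshape(-1)) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError("all samples must share one grid (vector lengths differ)")
    ranks = []
    for name in names:
        v = np.asarray(vectors[name], dtype=float).reshape(-1)
        if np.all(v == v[0]):
            raise ValueError(f"sample {name!r} has a zero-variance pixel vector")
        ranks.append(rankdata(v, method="average"))
    rho = np.corrcoef(np.vstack(ranks))
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return SimilarityMatrix(names=names, rho=np.clip(rho, -1.0, 1.0))


@dataclass(frozen=True)
class ClusterResult:
    """Ward merge tree over samples: scipy linkage records + leaf order."""

    names: tuple[str, ...]
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix on d = 1 - rho
    leaf_order: tuple[int, ...]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.leaf_order)


def ward_cluster(similarity: SimilarityMatrix) -> ClusterResult:
    """Ward linkage on the precomputed dissimilarity d = 1 - rho."""
    if len(similarity.names) < 2:
        raise ValueError("need at least 2 samples to cluster")
    dist = 1.0 - similarity.rho
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        names=similarity.names,
        linkage=z,
        leaf_order=tuple(int(i) for i in order),
    )


def cut_into(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat partition into k clusters (cluster ids are arbitrary labels)."""
    labels = hierarchy.fcluster(result.linkage, t=k, criterion="maxclust")
    return {name: int(lab) for name, lab in zip(result.names, labels)}


def to_newick(result: ClusterResult) -> str:
    """Newick string; branch lengths are merge-height differences."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{result.names[node.id]}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    root = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
    return root


def write_similarity(sim: SimilarityMatrix, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample\t" + "\t".join(sim.names) + "\n")
        for name, row in zip(sim.names, sim.rho):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def render_similarity(sim: SimilarityMatrix, result: ClusterResult, path) -> None:
    """Heatmap of rho with rows/columns in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(result.leaf_order)
    mat = sim.rho[np.ix_(order, order)]
    labels = [sim.names[i] for i in order]
    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * len(labels), 0.8 + 0.5 * len(labels)))
    im = ax.imshow(mat, cmap="Reds", vmin=min(0.0, mat.min()), vmax=1.0)
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=8)
    ax.set_yticks(range(len(labels)), labels, fontsize=8)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
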