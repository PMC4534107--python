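"""Methylated domain landscape (MDL): the 2-D domain-density fingerprint.

Every domain of a segmented methylome is a point in the plane
(log10 size in bp, mean methylation level). Binning those points on a
fixed 20 x 20 grid — 400 pixels — gives a compact summary of how the
methylome is partitioned: how many domains of which size and level exist.
The grid is fixed across samples (default log10 size over [100 bp, 10^7 bp],
level over [0, 1]) so pixel vectors from different methylomes are directly
comparable; domains falling outside the grid are counted separately rather
than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .domains import Domain

DEFAULT_GRID_BINS = 20
DEFAULT_SIZE_RANGE_LOG10 = (2.0, 7.0)  # 100 bp .. 10 Mb
DEFAULT_METH_RANGE = (0.0, 1.0)


def default_size_edges(bins: int = DEFAULT_GRID_BINS) -> np.ndarray:
    return np.linspace(*DEFAULT_SIZE_RANGE_LOG10, bins + 1)


def default_meth_edges(bins: int = DEFAULT_GRID_BINS) -> np.ndarray:
    return np.linspace(*DEFAULT_METH_RANGE, bins + 1)


@dataclass(frozen=True)
class MDLMatrix:
    """Domain counts on the (methylation level) x (log10 size) grid.

    Rows are methylation bins (ascending level), columns are size bins
    (ascending log10 size). Bin intervals are half-open [low, high) with
    the final bin closed, the numpy histogram convention.
    """

    counts: np.ndarray  # (n_meth_bins, n_size_bins) non-negative ints
    size_edges: np.ndarray  # length n_size_bins + 1, on log10(bp)
    meth_edges: np.ndarray  # length n_meth_bins + 1, on [0, 1]
    total: int  # domains binned on the grid
    out_of_range: int  # domains outside the grid

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.meth_edges) - 1, len(self.size_edges) - 1):
            raise ValueError("counts shape inconsistent with edges")
        for edges in (self.size_edges, self.meth_edges):
            if not np.all(np.diff(edges) > 0):
                raise ValueError("bin edges must be strictly increasing")
        if int(self.counts.sum()) != self.total:
            raise ValueError("total does not match counts")

    @property
    def n_pixels(self) -> int:
        return self.counts.size

    def same_grid(self, other: "MDLMatrix") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and np.array_equal(self.size_edges, other.size_edges)
            and np.array_equal(self.meth_edges, other.meth_edges)
        )


def compute_mdl(
    domains: Sequence[Domain],
    size_edges: np.ndarray | None = None,
    meth_edges: np.ndarray | None = None,
) -> MDLMatrix:
    """Bin domains by (log10 size, mean methylation level).

    Order-independent; count conservation holds by construction:
    ``counts.sum() + out_of_range == len(domains)``.
    """
    size_edges = default_size_edges() if size_edges is None else np.asarray(size_edges, float)
    meth_edges = default_meth_edges() if meth_edges is None else np.asarray(meth_edges, float)
    sizes = np.array([d.size for d in domains], dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("all domains must have positive size")
    meths = np.array([d.mean_meth for d in domains], dtype=float)
    if len(domains) == 0:
        counts = np.zeros((len(meth_edges) - 1, len(size_edges) - 1), dtype=np.int64)
        return MDLMatrix(counts, size_edges, meth_edges, 0, 0)
    counts, _, _ = np.histogram2d(meths, np.log10(sizes), bins=(meth_edges, size_edges))
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    return MDLMatrix(counts, size_edges, meth_edges, total, len(domains) - total)


def mdl_vector(matrix: MDLMatrix) -> np.ndarray:
    """Row-major flattening of the pixel counts (the clustering vector)."""
    return matrix.counts.reshape(-1).copy()


def mdl_vectors(matrices: Mapping[str, MDLMatrix]) -> dict[str, np.ndarray]:
    """Pixel vectors for several samples; grids must be identical."""
    items = list(matrices.items())
    if not items:
        return {}
    ref_name, ref = items[0]
    for name, m in items[1:]:
        if not m.same_grid(ref):
            raise ValueError(f"MDL grids differ between samples {ref_name!r} and {name!r}")
    return {name: mdl_vector(m) for name, m in items}


# ---------------------------------------------------------------------------
# Serialization and rendering
# ---------------------------------------------------------------------------


def write_mdl(matrix: MDLMatrix, path, header_lines: Iterable[str] = ()) -> None:
    """TSV: '#'-header block with the grid edges and counts metadata,
    then the integer grid, one methylation bin per row."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# size_edges_log10\t" + "\t".join(f"{e:.10g}" for e in matrix.size_edges) + "\n")
        fh.write("# meth_edges\t" + "\t".join(f"{e:.10g}" for e in matrix.meth_edges) + "\n")
        fh.write(f"# total\t{matrix.total}\n")
        fh.write(f"# out_of_range\t{matrix.out_of_range}\n")
        for row in matrix.counts:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_mdl(path) -> MDLMatrix:
    size_edges = meth_edges = None
    total = out_of_range = 0
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                fields = line[1:].strip().split("\t")
                key = fields[0]
                if key == "size_edges_log10":
                    size_edges = np.array([float(v) for v in fields[1:]])
                elif key == "meth_edges":
                    meth_edges = np.array([float(v) for v in fields[1:]])
                elif key == "total":
                    total = int(fields[1])
                elif key == "out_of_range":
                    out_of_range = int(fields[1])
                continue
            rows.append([int(v) for v in line.split("\t")])
    if size_edges is None or meth_edges is None:
        raise ValueError(f"{path}: missing grid edge headers")
    return MDLMatrix(np.asarray(rows, dtype=np.int64), size_edges, meth_edges, total, out_of_range)


def render_mdl(matrix: MDLMatrix, path, title: str | None = None) -> None:
    """Pseudocolor density plot: x = domain size (log scale), y = mean
    methylation level, colour = log-scaled domain count per pixel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    fig, ax = plt.subplots(figsize=(5, 4.2))
    x = 10.0 ** matrix.size_edges
    with np.errstate(all="ignore"):
        norm = LogNorm(vmin=1, vmax=max(1, int(matrix.counts.max())))
        masked = np.ma.masked_equal(matrix.counts, 0)
        mesh = ax.pcolormesh(x, matrix.meth_edges, masked, norm=norm, cmap="viridis")
    ax.set_xscale("log")
    ax.set_xlabel("domain size (bp)")
    ax.set_ylabel("mean methylation level")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="domains per pixel")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
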