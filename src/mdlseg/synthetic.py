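"""Seeded synthetic methylomes with known domain structure.

The generator realizes the piecewise-constant-mean model that the
segmentation assumes: a chromosome is a sequence of domains, each with a
true methylation probability pi; CpG positions are laid down with
geometric inter-CpG spacing (mean 100 bp by default, optionally 10x denser
inside designated "island" domains to mimic the CpG-density contrast
between unmethylated islands and CpG-poor low-methylated regions); per-site
coverage is Poisson (default mean 30, a typical deep WGBS depth after
strand merging) and the methylated count is Binomial(coverage, pi).
Zero-coverage sites are dropped before any filtering, as in real call
files. Everything is reproducible from the spec's seed.

What this emulates — and what it does not: levels are binomial around a
constant domain mean, so there is no residual autocorrelation within
domains, no bisulfite non-conversion error, no copy-number or mapping
artefacts, and no biological replicate variance. Tests passing on these
tracks demonstrate the estimator under its own model assumptions, not
performance on real tissue data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .domains import Domain
from .io_methylome import ChromSites, MethylomeTrack, RegionSet
import pandas as pd

DEFAULT_SPACING = 100.0  # mean inter-CpG interval, bp
DEFAULT_ISLAND_DENSITY = 10.0  # density multiplier inside island domains
DEFAULT_DEPTH = 30.0  # Poisson mean coverage


@dataclass(frozen=True)
class DomainSpec:
    """One true domain: genomic length, methylation probability, island flag."""

    length: int  # bp
    pi: float
    island: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("domain length must be positive")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")


@dataclass
class SimSpec:
    """Full description of a synthetic methylome."""

    chroms: Mapping[str, Sequence[DomainSpec]]
    spacing: float = DEFAULT_SPACING
    island_density: float = DEFAULT_ISLAND_DENSITY
    depth: float = DEFAULT_DEPTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 1.0:
            raise ValueError("mean spacing must exceed 1 bp")
        if self.island_density < 1.0:
            raise ValueError("island density multiplier must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.chroms or any(len(v) == 0 for v in self.chroms.values()):
            raise ValueError("every chromosome needs at least one domain")


@dataclass
class SimTruth:
    """True domain boundaries (genomic starts of 2nd..last domains) and pi."""

    boundaries: dict[str, np.ndarray] = field(default_factory=dict)
    domains: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def n_boundaries(self) -> int:
        return sum(len(b) for b in self.boundaries.values())


def simulate_methylome(spec: SimSpec) -> tuple[MethylomeTrack, SimTruth]:
    """Draw one methylome and its ground truth from the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    chroms: dict[str, ChromSites] = {}
    truth = SimTruth()
    for chrom in sorted(spec.chroms):
        doms = spec.chroms[chrom]
        positions: list[np.ndarray] = []
        pis: list[np.ndarray] = []
        offset = 0
        intervals: list[tuple[int, int, float]] = []
        bounds: list[int] = []
        for j, d in enumerate(doms):
            if j > 0:
                bounds.append(offset)
            spacing = spec.spacing / (spec.island_density if d.island else 1.0)
            # geometric gaps with mean `spacing`; expected count ~ length/spacing
            n_draw = int(d.length / spacing * 1.6 + 20)
            p = min(1.0, 1.0 / spacing)
            gaps = rng.geometric(p, size=n_draw)
            pos = np.cumsum(gaps) - 1
            while pos[-1] < d.length:  # pragma: no cover - rare top-up
                extra = rng.geometric(p, size=n_draw)
                pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
            pos = pos[pos < d.length]
            positions.append(pos + offset)
            pis.append(np.full(len(pos), d.pi))
            intervals.append((offset, offset + d.length, d.pi))
            offset += d.length
        pos = np.concatenate(positions)
        pi = np.concatenate(pis)
        total = rng.poisson(spec.depth, size=len(pos))
        meth = rng.binomial(np.maximum(total, 1), pi)
        meth = np.where(total > 0, meth, 0)
        keep = total > 0
        if keep.any():
            chroms[chrom] = ChromSites(pos[keep], meth[keep], total[keep])
        truth.boundaries[chrom] = np.asarray(bounds, dtype=np.int64)
        truth.domains[chrom] = intervals
    track = MethylomeTrack(chroms=chroms, sample=f"sim-seed{spec.seed}")
    return track, truth


def truth_region_set(truth: SimTruth) -> RegionSet:
    rows = [
        (chrom, s, e, f"pi={pi:.3f}")
        for chrom, doms in truth.domains.items()
        for s, e, pi in doms
    ]
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def random_simspec(
    seed: int,
    n_domains: int = 20,
    min_cpgs: int = 50,
    max_cpgs: int = 200,
    min_delta_pi: float = 0.3,
    spacing: float = DEFAULT_SPACING,
    depth: float = DEFAULT_DEPTH,
    chrom: str = "chrSim",
) -> SimSpec:
    """A random piecewise-constant genome with well-separated neighbours.

    Consecutive domains differ in pi by at least ``min_delta_pi`` and each
    domain spans between ``min_cpgs`` and ``max_cpgs`` expected CpGs.
    """
    rng = np.random.default_rng(seed)
    pis: list[float] = []
    while len(pis) < n_domains:
        cand = float(rng.uniform(0, 1))
        if not pis or abs(cand - pis[-1]) >= min_delta_pi:
            pis.append(cand)
    lengths = rng.integers(min_cpgs, max_cpgs + 1, size=n_domains) * spacing
    doms = [DomainSpec(length=int(l), pi=p) for l, p in zip(lengths, pis)]
    return SimSpec(
        chroms={chrom: doms},
        spacing=spacing,
        depth=depth,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def methylome_simspec(
    seed: int,
    n_domains: int = 500,
    pmd_fraction: float = 0.0,
    spacing: float = DEFAULT_SPACING,
    depth: float = DEFAULT_DEPTH,
    chrom: str = "chrSim",
) -> SimSpec:
    """A methylome-shaped genome: methylated background punctuated by
    small unmethylated and low-methylated regions.

    Domain classes mirror the recurring features of mammalian methylomes:
    a fully methylated background (2-50 kb, level 0.70-0.95), CpG-dense
    unmethylated islands (1-3 kb, level < 0.10), short CpG-poor
    low-methylated regions (0.3-1.5 kb, level 0.15-0.45) and, when
    ``pmd_fraction`` > 0, large partially methylated domains (10-100 kb,
    level 0.40-0.65). Level differences between some neighbours are
    subtle, so detection genuinely depends on coverage and penalty.
    """
    if not 0.0 <= pmd_fraction < 1.0:
        raise ValueError("pmd_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    doms: list[DomainSpec] = []
    for _ in range(n_domains):
        u = rng.uniform()
        if u < pmd_fraction:
            length = 10.0 ** rng.uniform(4.0, 5.0)  # 10-100 kb
            doms.append(DomainSpec(int(length), float(rng.uniform(0.40, 0.65))))
        elif u < pmd_fraction + 0.30:
            length = rng.uniform(1_000, 3_000)  # CpG island / UMR
            doms.append(DomainSpec(int(length), float(rng.uniform(0.0, 0.10)), island=True))
        elif u < pmd_fraction + 0.45:
            length = rng.uniform(300, 1_500)  # LMR
            doms.append(DomainSpec(int(length), float(rng.uniform(0.15, 0.45))))
        else:
            length = 10.0 ** rng.uniform(3.3, 4.7)  # FMR background, 2-50 kb
            doms.append(DomainSpec(int(length), float(rng.uniform(0.70, 0.95))))
    return SimSpec(
        chroms={chrom: doms},
        spacing=spacing,
        depth=depth,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Boundary recovery scoring
# ---------------------------------------------------------------------------


def _boundary_indices(
    coords: np.ndarray, sites_pos: np.ndarray
) -> np.ndarray:
    """Map genomic boundary coordinates to retained-CpG ordinals (index of
    the first retained site at/after the boundary)."""
    return np.searchsorted(sites_pos, coords, side="left")


def boundary_recovery(
    truth: SimTruth,
    domains: Sequence[Domain],
    track: MethylomeTrack,
    tolerance_cpg: int = 2,
) -> tuple[float, float]:
    """(recall, precision) of predicted vs true boundaries.

    Distances are measured in retained-CpG ordinals on the track the
    segmentation actually saw. A true boundary counts as recovered when a
    predicted boundary lies within ``tolerance_cpg`` sites of it, under a
    one-to-one maximum-cardinality matching (so one prediction cannot
    claim two truths). With no predicted boundaries, precision is reported
    as 1.0 by convention (no prediction is wrong).
    """
    n_true = n_pred = n_matched = 0
    for chrom in sorted(set(truth.boundaries) | {d.chrom for d in domains}):
        if chrom not in track.chroms:
            continue
        pos = track.chroms[chrom].pos
        coords = truth.boundaries.get(chrom, np.empty(0, dtype=np.int64))
        t_idx = _boundary_indices(coords, pos)
        doms = sorted((d for d in domains if d.chrom == chrom), key=lambda d: d.start)
        starts = np.array([d.start for d in doms[1:]], dtype=np.int64)
        p_idx = _boundary_indices(starts, pos)
        n_true += len(t_idx)
        n_pred += len(p_idx)
        if len(t_idx) and len(p_idx):
            adj = np.abs(t_idx[:, None] - p_idx[None, :]) <= tolerance_cpg
            if adj.any():
                # matching decomposes per chromosome: no cross-chromosome edges
                matching = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
                n_matched += int((matching >= 0).sum())
    if n_true == 0:
        return 1.0, 1.0 if n_pred == 0 else 0.0
    if n_pred == 0:
        return 0.0, 1.0
    return n_matched / n_true, n_matched / n_pred
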