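"""Genomic methylated domains: construction, classification, overlap, DMRs.

A domain is the genomic footprint of one segment of the per-chromosome CpG
series: it runs from the position of its first CpG to the position of its
last CpG + 2 (half-open, covering the terminal CpG dinucleotide), carries
the number of member CpGs and their mean methylation level, and optionally
the maximum penalty at which its left boundary is still detected.

Classification rules follow the field's descriptive region classes:
PMD-like (partially methylated domain: > 10 kb, mean level < 70 %),
DMV-like (methylation valley: > 5 kb, mean level < 15 %), and the three
recurring clusters of the methylated-domain landscape — fully methylated
(FMR-like), short low-methylated (LMR-like) and unmethylated (UMR-like)
domains. Labels may co-occur; every rule is configurable.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .changepoint import Segmentation, max_penalty_scan, pelt_segment
from .io_methylome import MethylomeTrack, RegionSet

# last CpG position + CPG_END_PAD = half-open domain end (covers the CG dinucleotide)
CPG_END_PAD = 2


@dataclass(frozen=True)
class Domain:
    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_meth: float
    max_penalty: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"domain start >= end: {self.chrom}:{self.start}-{self.end}")
        if self.n_cpg < 1:
            raise ValueError("domain must contain at least one CpG")
        if not 0.0 <= self.mean_meth <= 1.0:
            raise ValueError(f"mean_meth {self.mean_meth} outside [0, 1]")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LabelRule:
    """Size/methylation predicate; any bound left as None is not enforced.

    ``size_gt``/``size_ge``/``size_lt``/``size_le`` bound the domain size
    in bp, ``meth_*`` the mean methylation level.
    """

    size_gt: float | None = None
    size_ge: float | None = None
    size_lt: float | None = None
    size_le: float | None = None
    meth_gt: float | None = None
    meth_ge: float | None = None
    meth_lt: float | None = None
    meth_le: float | None = None

    def matches(self, domain: Domain) -> bool:
        s, m = domain.size, domain.mean_meth
        checks = (
            self.size_gt is None or s > self.size_gt,
            self.size_ge is None or s >= self.size_ge,
            self.size_lt is None or s < self.size_lt,
            self.size_le is None or s <= self.size_le,
            self.meth_gt is None or m > self.meth_gt,
            self.meth_ge is None or m >= self.meth_ge,
            self.meth_lt is None or m < self.meth_lt,
            self.meth_le is None or m <= self.meth_le,
        )
        return all(checks)


def default_label_rules() -> dict[str, LabelRule]:
    return {
        "PMD-like": LabelRule(size_gt=10_000, meth_lt=0.70),
        "DMV-like": LabelRule(size_gt=5_000, meth_lt=0.15),
        "FMR-like": LabelRule(size_ge=1_000, meth_ge=0.70),
        "LMR-like": LabelRule(size_ge=100, size_le=1_500, meth_ge=0.10, meth_lt=0.50),
        "UMR-like": LabelRule(size_ge=1_000, size_le=3_000, meth_lt=0.10),
    }


def rules_from_mapping(mapping: Mapping[str, Mapping[str, float]]) -> dict[str, LabelRule]:
    """Build rules from a plain mapping (e.g. parsed YAML)."""
    return {name: LabelRule(**dict(params)) for name, params in mapping.items()}


def build_domains(
    track: MethylomeTrack,
    segmentations: Mapping[str, Segmentation],
    boundary_penalties: Mapping[str, Mapping[int, float]] | None = None,
) -> list[Domain]:
    """Back-map per-chromosome segmentations to genomic domains.

    One domain per segment; its genomic extent runs from the first member
    CpG to the last member CpG + 2. Domains partition the retained CpGs
    exactly (sum of n_cpg equals the retained site count).
    """
    domains: list[Domain] = []
    for chrom in sorted(segmentations):
        seg = segmentations[chrom]
        sites = track.chroms[chrom]
        if seg.n != len(sites):
            raise ValueError(
                f"{chrom}: segmentation over {seg.n} points but chromosome has "
                f"{len(sites)} retained sites"
            )
        penalties = (boundary_penalties or {}).get(chrom, {})
        levels = sites.levels
        for a, b in seg.segments:
            domains.append(
                Domain(
                    chrom=chrom,
                    start=int(sites.pos[a]),
                    end=int(sites.pos[b - 1]) + CPG_END_PAD,
                    n_cpg=b - a,
                    mean_meth=float(levels[a:b].mean()),
                    max_penalty=penalties.get(a) if a > 0 else None,
                )
            )
    return domains


def segment_track(
    track: MethylomeTrack,
    penalty: float = 1.0,
    scan_grid: np.ndarray | None = None,
) -> list[Domain]:
    """Segment every chromosome independently and back-map to domains.

    Chromosomes are independent work units, so the result does not depend
    on processing order. With ``scan_grid`` set, each internal boundary
    additionally gets its maximum detectable penalty from a scan over the
    grid.
    """
    segs: dict[str, Segmentation] = {}
    penalties: dict[str, dict[int, float]] = {}
    for chrom in track.chrom_names():
        levels = track.chroms[chrom].levels
        segs[chrom] = pelt_segment(levels, penalty)
        if scan_grid is not None:
            penalties[chrom] = max_penalty_scan(levels, scan_grid)
    return build_domains(track, segs, penalties if scan_grid is not None else None)


def classify(domain: Domain, rules: Mapping[str, LabelRule] | None = None) -> set[str]:
    """All labels whose predicates hold for this domain (may be empty)."""
    if rules is None:
        rules = default_label_rules()
    return {name for name, rule in rules.items() if rule.matches(domain)}


# ---------------------------------------------------------------------------
# Interval arithmetic against reference region sets
# ---------------------------------------------------------------------------


def _covered_bp(start: int, end: int, intervals: np.ndarray) -> int:
    """Bases of [start, end) covered by merged sorted half-open intervals."""
    if len(intervals) == 0:
        return 0
    lo = np.minimum(np.maximum(intervals[:, 0], start), end)
    hi = np.minimum(np.maximum(intervals[:, 1], start), end)
    return int((hi - lo).sum())


def overlap_fraction(domain: Domain, regions: RegionSet, label: str | None = None) -> float:
    """Fraction of the domain's bases covered by the region set."""
    iv = regions.by_chrom(label).get(domain.chrom)
    if iv is None:
        return 0.0
    return _covered_bp(domain.start, domain.end, iv) / domain.size


def select_overlapping(
    domains: Iterable[Domain],
    regions: RegionSet,
    min_fraction: float = 0.8,
    label: str | None = None,
) -> list[Domain]:
    """Domains more than ``min_fraction`` of which is covered by the regions."""
    by_chrom = regions.by_chrom(label)
    out = []
    for d in domains:
        iv = by_chrom.get(d.chrom)
        if iv is not None and _covered_bp(d.start, d.end, iv) / d.size > min_fraction:
            out.append(d)
    return out


def domains_to_region_set(domains: Iterable[Domain], label: str = ".") -> RegionSet:
    rows = [(d.chrom, d.start, d.end, label) for d in domains]
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def region_coverage(a: RegionSet, b: RegionSet) -> tuple[float, float]:
    """Reciprocal base-pair coverage: (fraction of A covered by B, of B by A)."""

    def one_way(x: RegionSet, y: RegionSet) -> float:
        total = x.total_bp
        if total == 0:
            return 0.0
        y_by = y.by_chrom()
        covered = 0
        for chrom, iv in x.by_chrom().items():
            yiv = y_by.get(chrom)
            if yiv is None:
                continue
            for s, e in iv:
                covered += _covered_bp(int(s), int(e), yiv)
        return covered / total

    return one_way(a, b), one_way(b, a)


# ---------------------------------------------------------------------------
# Minimal DMR calling between two segmented samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int
    end: int
    mean_a: float
    mean_b: float

    @property
    def diff(self) -> float:
        return self.mean_a - self.mean_b


def _atomize(bounds_a: list[int], bounds_b: list[int]) -> list[int]:
    return sorted(set(bounds_a) | set(bounds_b))


def detect_dmrs(
    domains_a: Sequence[Domain],
    domains_b: Sequence[Domain],
    min_level_diff: float = 0.3,
) -> list[DMR]:
    """Differential domains from two segmentations of the same genome.

    The two domain sets are intersected into atomic intervals (every
    boundary of either sample cuts); atoms covered by both samples whose
    level difference reaches ``min_level_diff`` are merged into maximal
    abutting runs. Run-level means are recomputed per sample as
    CpG-weighted means, apportioning each domain's CpG count to an atom by
    its base-pair share of the domain.
    """
    by_chrom_a: dict[str, list[Domain]] = {}
    by_chrom_b: dict[str, list[Domain]] = {}
    for d in domains_a:
        by_chrom_a.setdefault(d.chrom, []).append(d)
    for d in domains_b:
        by_chrom_b.setdefault(d.chrom, []).append(d)

    out: list[DMR] = []
    for chrom in sorted(set(by_chrom_a) & set(by_chrom_b)):
        da = sorted(by_chrom_a[chrom], key=lambda d: d.start)
        db = sorted(by_chrom_b[chrom], key=lambda d: d.start)
        starts_a = [d.start for d in da]
        starts_b = [d.start for d in db]

        def locate(doms: list[Domain], starts: list[int], pos: int) -> Domain | None:
            i = bisect.bisect_right(starts, pos) - 1
            if i >= 0 and doms[i].start <= pos < doms[i].end:
                return doms[i]
            return None

        cuts = _atomize(
            [d.start for d in da] + [d.end for d in da],
            [d.start for d in db] + [d.end for d in db],
        )
        run: list[tuple[int, int, Domain, Domain]] = []

        def flush() -> None:
            if not run:
                return
            start, end = run[0][0], run[-1][1]
            wa = wb = sa = sb = 0.0
            for s, e, xa, xb in run:
                fa = xa.n_cpg * (e - s) / xa.size
                fb = xb.n_cpg * (e - s) / xb.size
                wa += fa
                wb += fb
                sa += fa * xa.mean_meth
                sb += fb * xb.mean_meth
            out.append(DMR(chrom, start, end, sa / wa, sb / wb))
            run.clear()

        for s, e in zip(cuts[:-1], cuts[1:]):
            xa = locate(da, starts_a, s)
            xb = locate(db, starts_b, s)
            hit = (
                xa is not None
                and xb is not None
                and abs(xa.mean_meth - xb.mean_meth) >= min_level_diff
            )
            if hit and run and run[-1][1] != s:
                flush()
            if hit:
                run.append((s, e, xa, xb))
            else:
                flush()
        flush()
    return out


# ---------------------------------------------------------------------------
# Domain file I/O (BED6-like TSV with extended columns)
# ---------------------------------------------------------------------------

DOMAIN_COLUMNS = (
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "n_cpg",
    "mean_meth",
    "max_penalty",
)


def write_domains(
    domains: Iterable[Domain],
    path,
    rules: Mapping[str, LabelRule] | None = None,
    header_lines: Iterable[str] = (),
) -> None:
    """BED6-like TSV: chrom, start, end, name (comma-joined labels or "."),
    score (mean_meth * 1000, integer), strand ".", then n_cpg, mean_meth,
    max_penalty ("." when absent). Pass ``rules`` to fill the name column."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for d in domains:
            labels = sorted(classify(d, rules)) if rules is not None else []
            name = ",".join(labels) if labels else "."
            mp = "." if d.max_penalty is None else f"{d.max_penalty:.6g}"
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{round(d.mean_meth * 1000)}\t.\t"
                f"{d.n_cpg}\t{d.mean_meth:.6f}\t{mp}\n"
            )


def read_domains(path) -> list[Domain]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}: malformed line {lineno}: need >= 8 columns")
            mp = None if len(f) < 9 or f[8] == "." else float(f[8])
            out.append(
                Domain(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    n_cpg=int(f[6]),
                    mean_meth=float(f[7]),
                    max_penalty=mp,
                )
            )
    return out


def write_dmrs(dmrs: Iterable[DMR], path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("#chrom\tstart\tend\tmean_a\tmean_b\tdiff\n")
        for d in dmrs:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.mean_a:.6f}\t{d.mean_b:.6f}\t{d.diff:.6f}\n"
            )
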