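"""Reading, writing and filtering per-CpG methylation call files.

A methylome is held as a :class:`MethylomeTrack`: per chromosome, parallel
numpy arrays of CpG position, methylated read count and total read count.
Positions are 0-based coordinates of the C of the CpG on the plus strand;
the two strands of one CpG are merged additively at read time. Genomic
intervals (reference UMR/LMR/FMR/PMD sets, domain output) use 0-based
half-open coordinates throughout.

Two input dialects are supported:

``bismark_report``
    The CpG cytosine-report layout: chrom, 1-based position, strand,
    count methylated, count unmethylated, context, trinucleotide. Only
    rows whose context is ``CpG``/``CG`` are used.
``bedgraph_counts``
    bedGraph-with-counts: chrom, 0-based start, end, methylation percent,
    count methylated, count unmethylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

DIALECTS = ("bismark_report", "bedgraph_counts")

_CPG_CONTEXTS = frozenset({"CpG", "CG", "cpg", "cg"})


@dataclass(frozen=True)
class CpGSite:
    """One CpG with read counts; ``pos`` is the plus-strand C, 0-based."""

    chrom: str
    pos: int
    meth_count: int
    total_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.meth_count <= self.total_count:
            raise ValueError(
                f"invalid counts at {self.chrom}:{self.pos}: "
                f"meth={self.meth_count}, total={self.total_count}"
            )

    @property
    def level(self) -> float:
        """Methylation level meth/total in [0, 1]; total must be > 0."""
        if self.total_count == 0:
            raise ValueError("level undefined for total_count == 0")
        return self.meth_count / self.total_count


@dataclass
class ChromSites:
    """Sorted per-chromosome CpG arrays (positions strictly increasing)."""

    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if not (len(self.pos) == len(self.meth) == len(self.total)):
            raise ValueError("pos/meth/total length mismatch")
        if len(self.pos) > 1 and not np.all(np.diff(self.pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.meth > self.total) or np.any(self.meth < 0):
            raise ValueError("need 0 <= meth <= total at every site")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def levels(self) -> np.ndarray:
        """Per-site methylation level; sites with total == 0 are excluded upstream."""
        return self.meth / self.total


@dataclass
class MethylomeTrack:
    """Ordered per-chromosome collection of CpG sites — the measurement series."""

    chroms: dict[str, ChromSites] = field(default_factory=dict)
    sample: str = ""
    min_depth: int | None = None

    @property
    def n_sites(self) -> int:
        return sum(len(c) for c in self.chroms.values())

    def chrom_names(self) -> list[str]:
        return sorted(self.chroms)

    def sites(self) -> Iterator[CpGSite]:
        for chrom in self.chrom_names():
            c = self.chroms[chrom]
            for p, m, t in zip(c.pos, c.meth, c.total):
                yield CpGSite(chrom, int(p), int(m), int(t))


def _parse_bismark_line(fields: list[str]) -> tuple[str, int, int, int, str] | None:
    # chrom, 1-based pos, strand, n_meth, n_unmeth, context, trinucleotide
    if len(fields) < 6:
        raise ValueError("expected >= 6 tab-separated fields")
    context = fields[5]
    if context not in _CPG_CONTEXTS:
        return None
    chrom, pos1, strand = fields[0], int(fields[1]), fields[2]
    meth, unmeth = int(fields[3]), int(fields[4])
    if strand == "+":
        pos0 = pos1 - 1
    elif strand == "-":
        # minus-strand C sits on the G of the plus-strand CpG
        pos0 = pos1 - 2
    else:
        raise ValueError(f"bad strand {strand!r}")
    if pos0 < 0:
        raise ValueError("position underflows after strand adjustment")
    return chrom, pos0, meth, meth + unmeth, strand


def _parse_bedgraph_line(fields: list[str]) -> tuple[str, int, int, int, str] | None:
    # chrom, start(0-based), end, percent, n_meth, n_unmeth
    if len(fields) < 6:
        raise ValueError("expected >= 6 tab-separated fields")
    chrom, start = fields[0], int(fields[1])
    meth, unmeth = int(fields[4]), int(fields[5])
    return chrom, start, meth, meth + unmeth, "."


def read_methylome(path, dialect: str = "bismark_report", sample: str = "") -> MethylomeTrack:
    """Read per-CpG calls into a :class:`MethylomeTrack`.

    Counts of the two strands of one CpG are summed onto the plus-strand C
    coordinate. Sites with zero total coverage are dropped (their level is
    undefined). A duplicate position remaining after strand merging, or a
    malformed line, raises ``ValueError`` with the offending line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    parse = _parse_bismark_line if dialect == "bismark_report" else _parse_bedgraph_line
    per_chrom: dict[str, dict[int, list]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            try:
                rec = parse(line.split("\t"))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from None
            if rec is None:
                continue
            chrom, pos, meth, total, strand = rec
            bucket = per_chrom.setdefault(chrom, {})
            if pos in bucket:
                prev = bucket[pos]
                if strand == "." or strand in prev[2]:
                    raise ValueError(f"{path}: duplicate position {chrom}:{pos} at line {lineno}")
                prev[0] += meth
                prev[1] += total
                prev[2] += strand
            else:
                bucket[pos] = [meth, total, strand]
    chroms: dict[str, ChromSites] = {}
    for chrom, bucket in per_chrom.items():
        pos = np.fromiter(bucket.keys(), dtype=np.int64, count=len(bucket))
        meth = np.fromiter((v[0] for v in bucket.values()), dtype=np.int64, count=len(bucket))
        total = np.fromiter((v[1] for v in bucket.values()), dtype=np.int64, count=len(bucket))
        order = np.argsort(pos, kind="stable")
        pos, meth, total = pos[order], meth[order], total[order]
        keep = total > 0
        if keep.any():
            chroms[chrom] = ChromSites(pos[keep], meth[keep], total[keep])
    return MethylomeTrack(chroms=chroms, sample=sample)


def write_methylome(
    track: MethylomeTrack,
    path,
    dialect: str = "bismark_report",
    header_lines: Iterable[str] = (),
) -> None:
    """Write a track in either dialect (strand-merged, one row per CpG)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for chrom in track.chrom_names():
            c = track.chroms[chrom]
            for p, m, t in zip(c.pos, c.meth, c.total):
                if dialect == "bismark_report":
                    fh.write(f"{chrom}\t{p + 1}\t+\t{m}\t{t - m}\tCpG\tCGN\n")
                else:
                    pct = 100.0 * m / t
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{pct:.6g}\t{m}\t{t - m}\n")


def filter_by_coverage(track: MethylomeTrack, min_depth: int = 5) -> MethylomeTrack:
    """Retain sites covered by at least ``min_depth`` reads.

    Order is preserved; the operation is idempotent and monotone in
    ``min_depth``. Returns a new track (input is not modified).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    chroms = {}
    for chrom, c in track.chroms.items():
        keep = c.total >= min_depth
        if keep.any():
            chroms[chrom] = ChromSites(c.pos[keep], c.meth[keep], c.total[keep])
    return MethylomeTrack(chroms=chroms, sample=track.sample, min_depth=min_depth)


# ---------------------------------------------------------------------------
# Reference region sets (BED intervals)
# ---------------------------------------------------------------------------


def _merge_sorted(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping or abutting sorted half-open intervals (Nx2 int)."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    out: list[list[int]] = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, dtype=np.int64)


@dataclass
class RegionSet:
    """Labelled genomic intervals, 0-based half-open, merged per label."""

    df: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "label" not in df.columns:
            df["label"] = "."
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"interval start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
        merged = []
        for (chrom, label), grp in df.groupby(["chrom", "label"], sort=True):
            iv = grp[["start", "end"]].to_numpy(dtype=np.int64)
            iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
            for s, e in _merge_sorted(iv):
                merged.append((chrom, int(s), int(e), label))
        out = pd.DataFrame(merged, columns=["chrom", "start", "end", "label"])
        self.df = out.sort_values(["chrom", "start", "end", "label"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_bp(self) -> int:
        """Total bases covered, counting overlap between labels once."""
        return sum(iv[:, 1].sum() - iv[:, 0].sum() for iv in self.by_chrom().values())

    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())

    def by_chrom(self, label: str | None = None) -> dict[str, np.ndarray]:
        """Per-chromosome merged Nx2 interval arrays, pooled across labels
        (or restricted to one label)."""
        df = self.df if label is None else self.df[self.df["label"] == label]
        out = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            iv = grp[["start", "end"]].to_numpy(dtype=np.int64)
            iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
            out[chrom] = _merge_sorted(iv)
        return out


def read_region_set(path) -> RegionSet:
    """Read a BED3/BED4 file into a normalized :class:`RegionSet`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed line {lineno}: need >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}: malformed line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            label = fields[3] if len(fields) > 3 else "."
            rows.append((fields[0], start, end, label))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def write_region_set(regions: RegionSet, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for row in regions.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")
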