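"""Readers, writers and segment assembly for read-level methylation data.

On-disk formats
---------------
* Read haplotype table: tab-separated ``chrom, read_id, positions, calls``
  where ``positions`` is a comma-separated list of 1-based CpG coordinates
  (the forward-strand C of each CpG dyad) and ``calls`` is a string over
  ``{1, 0, ?}`` parallel to the position list (``?`` = missing call).
  One file per tissue per channel.
* Per-site counts: tab-separated ``chrom, pos, N_C, N_T`` with ``pos``
  1-based, matching Bismark CpG-report ordering.
* Intervals (annotations, blocks): BED, 0-based half-open.

Internally all interval arithmetic is 0-based half-open; haplotype
positions stay 1-based as in the table format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

MISSING = "?"
CHANNELS = ("5mC", "5hmC")


class ParseError(ValueError):
    """A malformed record in an on-disk table, with its line number."""


@dataclass(frozen=True)
class MethylationHaplotype:
    """Ordered binary CpG modification states carried by one sequencing read.

    ``calls[i]`` is the state read out at 1-based position ``positions[i]``:
    ``"1"`` modified, ``"0"`` unmodified, ``"?"`` missing.
    """

    chrom: str
    positions: tuple[int, ...]
    calls: str
    read_id: str = ""
    tissue: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.positions):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.positions)} positions "
                f"but {len(self.calls)} calls"
            )
        if any(b - a <= 0 for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError(f"read {self.read_id!r}: positions not strictly increasing")
        if not set(self.calls) <= {"0", "1", MISSING}:
            raise ValueError(f"read {self.read_id!r}: calls must be over {{0,1,?}}")
        if set(self.calls) <= {MISSING}:
            raise ValueError(f"read {self.read_id!r}: no non-missing call")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class Segment:
    """A contiguous sequenceable-and-mappable region assembled from reads."""

    chrom: str
    start: int  # 0-based
    end: int    # half-open
    cpg_positions: tuple[int, ...] = ()  # 1-based, sorted

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end} is empty")


@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."


class GenomicElementSet:
    """A labeled collection of genomic intervals with fast overlap queries."""

    def __init__(self, label: str, records: Iterable[BedRecord] = ()) -> None:
        self.label = label
        self.records: list[BedRecord] = []
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            self.add(rec)

    @classmethod
    def from_tuples(cls, label: str, intervals: Iterable[tuple]) -> "GenomicElementSet":
        return cls(label, (BedRecord(*t) for t in intervals))

    def add(self, rec: BedRecord) -> None:
        if rec.start >= rec.end:
            raise ValueError(
                f"invalid interval {rec.chrom}:{rec.start}-{rec.end} (start >= end)"
            )
        self.records.append(rec)
        self._trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def overlapping(self, chrom: str, start: int, end: int) -> list[BedRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree.overlap(start, end))]

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """Overlap query for a single 0-based base position."""
        return self.overlaps(chrom, pos0, pos0 + 1)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(r.chrom, r.start, r.end) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BedRecord]:
        return iter(self.records)


# ---------------------------------------------------------------------------
# parsers


def parse_read_haplotypes(
    path: str | Path, tissue: str = "", channel: str = ""
) -> list[MethylationHaplotype]:
    """Parse a read haplotype table, validating every record.

    Malformed lines raise :class:`ParseError` naming the line number.
    An empty file yields an empty list with a warning.
    """
    path = Path(path)
    out: list[MethylationHaplotype] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, read_id, pos_str, calls = fields
            try:
                positions = tuple(int(p) for p in pos_str.split(","))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position list {pos_str!r}") from exc
            try:
                out.append(
                    MethylationHaplotype(chrom, positions, calls, read_id, tissue, channel)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not out:
        logger.warning("no haplotype records parsed from %s", path)
    logger.info("parsed %d haplotypes from %s", len(out), path)
    return out


def write_read_haplotypes(haplotypes: Iterable[MethylationHaplotype], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for hap in haplotypes:
            pos = ",".join(str(p) for p in hap.positions)
            fh.write(f"{hap.chrom}\t{hap.read_id}\t{pos}\t{hap.calls}\n")


def parse_site_counts(path: str | Path) -> pd.DataFrame:
    """Parse a per-site count table into columns chrom, pos, n_c, n_t.

    Counts must be non-negative integers; duplicate (chrom, pos) rows are an
    error because they would silently double-count coverage downstream.
    """
    path = Path(path)
    rows = []
    seen: set[tuple[str, int]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, pos_s, nc_s, nt_s = fields
            try:
                pos, n_c, n_t = int(pos_s), int(nc_s), int(nt_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if n_c < 0 or n_t < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            key = (chrom, pos)
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate site {chrom}:{pos}")
            seen.add(key)
            rows.append(key + (n_c, n_t))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_c", "n_t"])
    logger.info("parsed %d count rows from %s", len(df), path)
    return df


def write_site_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[["chrom", "pos", "n_c", "n_t"]].to_csv(path, sep="\t", header=False, index=False)


def parse_bed(path: str | Path, label: str = "") -> GenomicElementSet:
    """Parse a BED file (>= 3 columns) into a :class:`GenomicElementSet`.

    Coordinates are kept 0-based half-open exactly as stored; BED6 name,
    score and strand columns are retained when present.
    """
    path = Path(path)
    out = GenomicElementSet(label or path.stem)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            out.add(BedRecord(chrom, start, end, name, score, strand))
    logger.info("parsed %d intervals from %s", len(out), path)
    return out


def write_bed(records: Iterable[BedRecord], path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for rec in records:
            score = "." if rec.score is None else f"{rec.score:g}"
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{score}\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# segment assembly


def derive_segments(
    haplotypes: Sequence[MethylationHaplotype], max_gap: int = 500
) -> list[Segment]:
    """Assemble sequenceable-and-mappable segments from read footprints.

    Read footprints (first to last covered CpG) on each chromosome are
    merged whenever the gap between consecutive footprints is at most
    ``max_gap`` bp.  Every covered CpG lands in exactly one segment.  The
    result is independent of input read order.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    cpgs_by_chrom: dict[str, set[int]] = {}
    for hap in haplotypes:
        lo = hap.positions[0] - 1          # 0-based start of first CpG
        hi = hap.positions[-1]             # half-open end of last CpG
        by_chrom.setdefault(hap.chrom, []).append((lo, hi))
        cpgs_by_chrom.setdefault(hap.chrom, set()).update(hap.positions)

    segments: list[Segment] = []
    for chrom in sorted(by_chrom):
        merged: list[list[int]] = []
        for lo, hi in sorted(by_chrom[chrom]):
            if merged and lo - merged[-1][1] <= max_gap:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        cpgs = sorted(cpgs_by_chrom[chrom])
        for lo, hi in merged:
            members = tuple(p for p in cpgs if lo < p <= hi)
            segments.append(Segment(chrom, lo, hi, members))
    return segments
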