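"""Methylation linkage disequilibrium and haplotype-block partitioning.

Two CpGs covered by the same reads carry correlated binary states when the
underlying cell population is a mixture of epialleles.  The coupling is
quantified exactly as allelic linkage disequilibrium:

    r2 = (P_AB - P_A * P_B)^2 / (P_A (1 - P_A) P_B (1 - P_B))

estimated over the reads that cover both sites with non-missing calls.
A segment is partitioned into blocks — MHBs (5mC channel, cutoff 0.5) or
hMHBs (5hmC channel, cutoff 0.2, gene bodies only) — as maximal runs of
consecutive CpGs whose every adjacent pair has a defined r2 at or above
the cutoff; runs with fewer than ``min_cpgs`` CpGs are discarded.  Pairs
with undefined r2 (monomorphic marginal or insufficient joint coverage)
break a run: a block never spans a gap with no co-coverage evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GenomicElementSet, MethylationHaplotype, Segment, derive_segments

DEFAULT_MIN_PAIR_READS = 5
DEFAULT_MIN_CPGS = 4
MHB_R2_CUTOFF = 0.5
HMHB_R2_CUTOFF = 0.2


@dataclass(frozen=True)
class LdEstimate:
    """Pairwise methylation LD between two CpG sites."""

    pos_i: int
    pos_j: int
    p_a: float
    p_b: float
    p_ab: float
    r2: float          # nan when undefined
    n_pairs: int
    defined: bool


@dataclass(frozen=True)
class Block:
    """A run of tightly coupled CpGs (an MHB or hMHB).

    ``start``/``end`` are 0-based half-open: start = first member CpG - 1
    (its 0-based coordinate), end = last member CpG position.
    """

    chrom: str
    positions: tuple[int, ...]       # 1-based member CpGs
    adjacent_r2: tuple[float, ...]
    kind: str = "MHB"
    block_id: str = ""

    @property
    def start(self) -> int:
        return self.positions[0] - 1

    @property
    def end(self) -> int:
        return self.positions[-1]

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def mean_r2(self) -> float:
        return float(np.mean(self.adjacent_r2))


def haplotype_matrix(
    haplotypes: Sequence[MethylationHaplotype], sites: Sequence[int]
) -> np.ndarray:
    """Reads x sites int8 matrix of calls (1, 0, or -1 for missing/uncovered)."""
    index = {pos: j for j, pos in enumerate(sites)}
    mat = np.full((len(haplotypes), len(sites)), -1, dtype=np.int8)
    for i, hap in enumerate(haplotypes):
        for pos, call in zip(hap.positions, hap.calls):
            j = index.get(pos)
            if j is not None and call != "?":
                mat[i, j] = int(call)
    return mat


def _r2_from_columns(
    a: np.ndarray, b: np.ndarray, min_pair_reads: int
) -> tuple[float, float, float, float, int, bool]:
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    if n < min_pair_reads:
        return math.nan, math.nan, math.nan, math.nan, n, False
    x = a[both].astype(float)
    y = b[both].astype(float)
    p_a = x.mean()
    p_b = y.mean()
    p_ab = (x * y).mean()
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0.0:
        return p_a, p_b, p_ab, math.nan, n, False
    r2 = (p_ab - p_a * p_b) ** 2 / denom
    return p_a, p_b, p_ab, float(min(max(r2, 0.0), 1.0)), n, True


def ld_r2(
    haplotypes: Sequence[MethylationHaplotype],
    site_i: int,
    site_j: int,
    min_pair_reads: int = DEFAULT_MIN_PAIR_READS,
) -> LdEstimate:
    """LD r2 between two CpGs over the reads covering both.

    Undefined estimates (monomorphic marginal, or fewer than
    ``min_pair_reads`` doubly covering reads) are flagged, not raised.
    """
    mat = haplotype_matrix(haplotypes, [site_i, site_j])
    p_a, p_b, p_ab, r2, n, defined = _r2_from_columns(mat[:, 0], mat[:, 1], min_pair_reads)
    return LdEstimate(site_i, site_j, p_a, p_b, p_ab, r2, n, defined)


def ld_matrix(
    haplotypes: Sequence[MethylationHaplotype],
    sites: Sequence[int],
    min_pair_reads: int = DEFAULT_MIN_PAIR_READS,
) -> np.ndarray:
    """Symmetric matrix of pairwise r2 over the given sites (nan = undefined)."""
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    mat = haplotype_matrix(haplotypes, sites)
    k = len(sites)
    out = np.full((k, k), np.nan)
    for i in range(k):
        covered = mat[:, i] >= 0
        if covered.any() and 0 < mat[covered, i].mean() < 1:
            out[i, i] = 1.0
        for j in range(i + 1, k):
            *_, r2, _, defined = _r2_from_columns(mat[:, i], mat[:, j], min_pair_reads)
            if defined:
                out[i, j] = out[j, i] = r2
    return out


def partition_segment(
    haplotypes: Sequence[MethylationHaplotype],
    sites: Sequence[int],
    chrom: str,
    r2_cutoff: float,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_pair_reads: int = DEFAULT_MIN_PAIR_READS,
    kind: str = "MHB",
) -> list[Block]:
    """Partition one segment's CpGs into blocks by the adjacent-pair scan.

    The candidate-and-extend description collapses to maximal runs under a
    single cutoff: every maximal run of consecutive CpGs whose adjacent
    pairs all have defined r2 >= cutoff becomes one block.
    """
    sites = sorted(sites)
    if len(sites) < 2:
        return []
    mat = haplotype_matrix(haplotypes, sites)
    adj: list[float] = []
    for j in range(len(sites) - 1):
        *_, r2, _, defined = _r2_from_columns(mat[:, j], mat[:, j + 1], min_pair_reads)
        adj.append(r2 if defined else math.nan)

    blocks: list[Block] = []
    run_start: int | None = None
    for j, r2 in enumerate(adj + [math.nan]):  # sentinel closes the last run
        passing = not math.isnan(r2) and r2 >= r2_cutoff
        if passing and run_start is None:
            run_start = j
        elif not passing and run_start is not None:
            lo, hi = run_start, j  # pairs lo..hi-1 pass -> sites lo..hi
            if hi - lo + 1 >= min_cpgs:
                blocks.append(
                    Block(
                        chrom,
                        tuple(sites[lo : hi + 1]),
                        tuple(adj[lo:hi]),
                        kind=kind,
                    )
                )
            run_start = None
    return blocks


def call_blocks(
    haplotypes: Sequence[MethylationHaplotype],
    r2_cutoff: float = MHB_R2_CUTOFF,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_pair_reads: int = DEFAULT_MIN_PAIR_READS,
    restrict_to: GenomicElementSet | None = None,
    max_gap: int = 500,
    kind: str | None = None,
) -> list[Block]:
    """Full block discovery: assemble segments, partition each into blocks.

    ``haplotypes`` should come from one channel, pooled across tissues
    (the LD signal is computed on the combined haplotypes; per-tissue MHL
    is taken afterwards on the shared block set).  With ``restrict_to``
    set — e.g. gene bodies for hMHB discovery — CpGs outside the element
    set are masked before partitioning.
    """
    if not haplotypes:
        return []
    if kind is None:
        channel = haplotypes[0].channel
        kind = "hMHB" if channel == "5hmC" else "MHB"
    blocks: list[Block] = []
    for seg in derive_segments(haplotypes, max_gap=max_gap):
        sites = list(seg.cpg_positions)
        if restrict_to is not None:
            sites = [p for p in sites if restrict_to.contains_point(seg.chrom, p - 1)]
        if len(sites) < min_cpgs:
            continue
        seg_haps = [
            h
            for h in haplotypes
            if h.chrom == seg.chrom
            and h.positions[0] <= seg.end
            and h.positions[-1] > seg.start
        ]
        blocks.extend(
            partition_segment(
                seg_haps, sites, seg.chrom, r2_cutoff, min_cpgs, min_pair_reads, kind
            )
        )
    for i, blk in enumerate(blocks):
        object.__setattr__(blk, "block_id", f"{kind}_{i:05d}")
    return blocks
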