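"""Methylation haplotype load, average levels, and tissue specificity.

MHL is the length-weighted mean of the fraction of fully modified
contiguous substrings over all observed haplotype substrings:

    MHL = sum_i w_i * f_i / sum_i w_i,   w_i = i,
    f_i = (# all-"1" substrings of length i) / (# substrings of length i)

taken over every read clipped to the block, with lengths that contribute
no substrings dropped from both sums.  MHL rewards *coordinated* loads:
a block where half the molecules are fully modified scores higher than a
block where every molecule is half modified, although both have the same
average methylation level (AML = fraction of "1" calls).

The tissue-specificity index over a block's per-tissue MHL values is

    TSI = sum_j (1 - 10^MHL(j) / 10^MHL(max)) / (n - 1)

where the maximal tissue contributes zero; TSI > 0.6 marks a
tissue-specific block, and the remaining (shared) blocks split into
low/high-MHL groups by their cross-tissue mean.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import Block
from .io import MethylationHaplotype

DEFAULT_MIN_READS = 5
DEFAULT_TSI_THRESHOLD = 0.6
DEFAULT_SHARED_SPLIT = 0.5

TISSUE_SPECIFIC = "tissue-specific"
SHARED_LOW = "shared-low-MHL"
SHARED_HIGH = "shared-high-MHL"
UNCLASSIFIED = "unclassified"


def _clip_to_block(hap: MethylationHaplotype, block_positions: Sequence[int]) -> list[str]:
    """Calls at the block's CpGs, split into runs at missing/uncovered sites.

    Substrings never span a missing call, so each contiguous run of
    observed in-block calls is counted independently.
    """
    members = set(block_positions)
    runs: list[str] = []
    current: list[str] = []
    for pos in sorted(members):
        call = None
        # positions are sorted in both hap and block; dict lookup keeps it simple
        try:
            idx = hap.positions.index(pos)
            call = hap.calls[idx]
        except ValueError:
            call = None
        if call in ("0", "1"):
            current.append(call)
        else:
            if current:
                runs.append("".join(current))
            current = []
    if current:
        runs.append("".join(current))
    return runs


def mhl_from_strings(
    strings: Iterable[str], weight: Callable[[int], float] = float
) -> float:
    """MHL of a collection of gap-free call strings over {0, 1}.

    ``weight`` maps substring length to its weight (default w_i = i).
    Returns nan when no substrings are observed.
    """
    meth: dict[int, int] = {}
    total: dict[int, int] = {}
    for s in strings:
        if not s:
            continue
        if not set(s) <= {"0", "1"}:
            raise ValueError(f"call string {s!r} not over {{0,1}}")
        length = len(s)
        # run-lengths of consecutive "1"s give the all-modified window counts
        ones_runs = [len(r) for r in s.split("0") if r]
        for i in range(1, length + 1):
            total[i] = total.get(i, 0) + (length - i + 1)
            meth[i] = meth.get(i, 0) + sum(max(0, k - i + 1) for k in ones_runs)
    if not total:
        return math.nan
    num = sum(weight(i) * meth.get(i, 0) / total[i] for i in total if total[i] > 0)
    den = sum(weight(i) for i in total if total[i] > 0)
    return num / den


def aml_from_strings(strings: Iterable[str]) -> float:
    """Average modification level: fraction of "1" calls."""
    ones = n = 0
    for s in strings:
        ones += s.count("1")
        n += len(s)
    return ones / n if n else math.nan


def compute_mhl(
    haplotypes: Sequence[MethylationHaplotype],
    block: Block | Sequence[int],
    min_reads: int = DEFAULT_MIN_READS,
    weight: Callable[[int], float] = float,
) -> float:
    """MHL of a block from the reads overlapping it (nan if under-covered)."""
    positions = block.positions if isinstance(block, Block) else tuple(block)
    runs: list[str] = []
    n_informative = 0
    for hap in haplotypes:
        r = _clip_to_block(hap, positions)
        if r:
            n_informative += 1
            runs.extend(r)
    if n_informative < min_reads:
        return math.nan
    return mhl_from_strings(runs, weight=weight)


def compute_aml(
    haplotypes: Sequence[MethylationHaplotype],
    block: Block | Sequence[int],
    min_reads: int = DEFAULT_MIN_READS,
) -> float:
    """Average modification level of a block (nan if under-covered)."""
    positions = block.positions if isinstance(block, Block) else tuple(block)
    runs: list[str] = []
    n_informative = 0
    for hap in haplotypes:
        r = _clip_to_block(hap, positions)
        if r:
            n_informative += 1
            runs.extend(r)
    if n_informative < min_reads:
        return math.nan
    return aml_from_strings(runs)


def mhl_matrix(
    blocks: Sequence[Block],
    haplotypes_by_tissue: Mapping[str, Sequence[MethylationHaplotype]],
    min_reads: int = DEFAULT_MIN_READS,
    metric: str = "mhl",
) -> pd.DataFrame:
    """Blocks x tissues table of MHL (or AML with metric="aml").

    Under-covered entries are NaN — missingness is flagged, never zero.
    Haplotypes are pre-bucketed per block by overlap for speed.
    """
    fn = compute_mhl if metric == "mhl" else compute_aml
    data = {}
    for tissue, haps in haplotypes_by_tissue.items():
        by_chrom: dict[str, list[MethylationHaplotype]] = {}
        for h in haps:
            by_chrom.setdefault(h.chrom, []).append(h)
        col = []
        for blk in blocks:
            cand = [
                h
                for h in by_chrom.get(blk.chrom, [])
                if h.positions[0] <= blk.positions[-1] and h.positions[-1] >= blk.positions[0]
            ]
            col.append(fn(cand, blk, min_reads=min_reads))
        data[tissue] = col
    index = [blk.block_id or f"block_{i}" for i, blk in enumerate(blocks)]
    return pd.DataFrame(data, index=index)


def compute_tsi(mhl_row: Sequence[float]) -> float:
    """Tissue-specificity index of one block's per-tissue MHL values.

    TSI = sum_j (1 - 10^MHL(j)/10^MHL(max)) / (n - 1); the maximal tissue
    contributes 0, equal loads give 0, and TSI -> 1 as the non-maximal
    loads fall toward the floor.  Requires >= 2 non-missing values.
    """
    vals = np.asarray([v for v in mhl_row if not (v is None or math.isnan(v))], dtype=float)
    if vals.size < 2:
        return math.nan
    mhl_max = vals.max()
    terms = 1.0 - 10.0 ** (vals - mhl_max)
    return float(terms.sum() / (vals.size - 1))


def classify_blocks(
    mhl: pd.DataFrame,
    tsi_threshold: float = DEFAULT_TSI_THRESHOLD,
    shared_split: float = DEFAULT_SHARED_SPLIT,
) -> pd.DataFrame:
    """Three-way classification of blocks from their MHL matrix.

    TSI > threshold -> tissue-specific; otherwise shared, split into
    low/high by the cross-tissue mean MHL against ``shared_split``.
    Rows with any missing tissue are reported unclassified (strict mode).
    """
    if mhl.shape[1] < 2:
        raise ValueError("need at least two tissues to classify")
    rows = []
    for block_id, row in mhl.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.any(np.isnan(vals)):
            rows.append((block_id, math.nan, UNCLASSIFIED, None, math.nan))
            continue
        tsi = compute_tsi(vals)
        max_tissue = row.idxmax()
        mean_mhl = float(vals.mean())
        if tsi > tsi_threshold:
            cls = TISSUE_SPECIFIC
        elif mean_mhl > shared_split:
            cls = SHARED_HIGH
        else:
            cls = SHARED_LOW
        rows.append((block_id, tsi, cls, max_tissue, mean_mhl))
    return pd.DataFrame(
        rows, columns=["block_id", "tsi", "class", "max_tissue", "mean_mhl"]
    ).set_index("block_id")
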