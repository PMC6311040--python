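"""Synthetic read-level oxBS/TAB data with planted co-modification structure.

The generator emulates the epiallele picture behind haplotype-block
analysis: within a planted block, every DNA molecule in a tissue is either
fully modified (with per-tissue probability ``pi``) or fully unmodified —
a two-component cell-subpopulation mixture that makes neighboring CpG
states tightly coupled on single reads.  Outside blocks, sites are
independent Bernoulli draws at a background rate.  Bisulfite-chemistry
conversion errors are applied independently per call: a truly modified
cytosine reads out "0" with probability ``eps_fn`` and an unmodified one
reads out "1" with probability ``eps_fp``.

Under zero conversion error every haplotype restricted to a planted block
is all-1 or all-0, so the fraction of fully modified substrings at every
length equals ``pi`` — the expected methylation haplotype load of the
block is exactly ``pi``, which is what :func:`truth` records.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MethylationHaplotype

DEFAULT_EPS_FP = 0.005  # unmodified base read out as "C"
DEFAULT_EPS_FN = 0.02   # modified base read out as "T"


@dataclass
class CpGLandscape:
    """Simulated genome scaffold: segments, CpG positions and annotations.

    ``cpg_positions[i]`` are 1-based coordinates strictly inside segment
    ``segments[i]``; segments are disjoint.  ``element_labels`` maps an
    annotation class (gene_body / intergenic / ...) to its intervals
    (0-based half-open).
    """

    segments: list[tuple[str, int, int]]
    cpg_positions: list[np.ndarray]
    gene_bodies: list[tuple[str, int, int]] = field(default_factory=list)
    element_labels: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    @property
    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.cpg_positions)

    def all_positions(self) -> list[tuple[str, int]]:
        out = []
        for (chrom, _, _), pos in zip(self.segments, self.cpg_positions):
            out.extend((chrom, int(p)) for p in pos)
        return out


@dataclass(frozen=True)
class BlockSpec:
    """A planted co-modified block: CpG index range within a segment plus
    the per-tissue epiallele (fully-modified molecule) fraction."""

    segment: int
    cpg_lo: int           # index into the segment's CpG list, inclusive
    cpg_hi: int           # exclusive
    pi: Mapping[str, float]
    channel: str = "5mC"

    def __post_init__(self) -> None:
        if not 0 <= self.cpg_lo < self.cpg_hi:
            raise ValueError(f"bad CpG index range [{self.cpg_lo}, {self.cpg_hi})")
        for tissue, p in self.pi.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pi[{tissue!r}] = {p} outside [0, 1]")


def _validate_specs(landscape: CpGLandscape, specs: Sequence[BlockSpec]) -> None:
    # overlap is forbidden only within one channel: a 5mC and a 5hmC block
    # may share a segment (that is what co-modification looks like)
    per_key: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for spec in specs:
        if not 0 <= spec.segment < len(landscape.segments):
            raise ValueError(f"spec references segment {spec.segment} of {len(landscape.segments)}")
        n = len(landscape.cpg_positions[spec.segment])
        if spec.cpg_hi > n:
            raise ValueError(f"spec range [{spec.cpg_lo},{spec.cpg_hi}) exceeds {n} CpGs")
        per_key.setdefault((spec.segment, spec.channel), []).append((spec.cpg_lo, spec.cpg_hi))
    for (seg, channel), ranges in per_key.items():
        ranges.sort()
        for (a0, a1), (b0, _) in zip(ranges, ranges[1:]):
            if b0 < a1:
                raise ValueError(f"overlapping planted {channel} blocks in segment {seg}")


def _stream_seed(master_seed: int, tissue: str, channel: str) -> np.random.Generator:
    # one independent stream per (tissue, channel): adding a tissue to a run
    # does not perturb the reads simulated for the others
    key = (zlib.crc32(tissue.encode()), zlib.crc32(channel.encode()))
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def simulate_landscape(
    n_segments: int,
    cpgs_per_segment: int,
    spacing: float,
    seed: int,
    chrom: str = "chr1",
    segment_gap: int = 10_000,
    gene_body_every: int = 2,
) -> CpGLandscape:
    """Lay out ``n_segments`` disjoint segments of CpGs on one chromosome.

    Inter-CpG gaps are geometric with the given mean and a 2 bp minimum.
    Every ``gene_body_every``-th segment (starting with the first) is
    annotated as a gene body; the rest are intergenic.
    """
    if n_segments < 1 or cpgs_per_segment < 4:
        raise ValueError("need n_segments >= 1 and cpgs_per_segment >= 4")
    if spacing < 2:
        raise ValueError("mean spacing must be >= 2 bp")
    rng = np.random.default_rng(seed)
    segments: list[tuple[str, int, int]] = []
    cpg_positions: list[np.ndarray] = []
    gene_bodies: list[tuple[str, int, int]] = []
    intergenic: list[tuple[str, int, int]] = []
    cursor = 1_000
    for i in range(n_segments):
        p = 1.0 if spacing == 2 else 1.0 / (spacing - 1.0)
        gaps = 1 + rng.geometric(p, size=cpgs_per_segment - 1)
        positions = cursor + np.concatenate([[0], np.cumsum(gaps)])
        start, end = int(positions[0] - 1), int(positions[-1])
        segments.append((chrom, start, end))
        cpg_positions.append(positions.astype(np.int64))
        if i % gene_body_every == 0:
            gene_bodies.append((chrom, start, end))
        else:
            intergenic.append((chrom, start, end))
        cursor = int(positions[-1]) + segment_gap
    return CpGLandscape(
        segments,
        cpg_positions,
        gene_bodies,
        {"gene_body": gene_bodies, "intergenic": intergenic},
    )


def simulate_reads(
    landscape: CpGLandscape,
    specs: Sequence[BlockSpec],
    n_reads: int,
    span: int,
    tissues: Sequence[str],
    channel: str,
    seed: int,
    background: float = 0.05,
    eps_fp: float = DEFAULT_EPS_FP,
    eps_fn: float = DEFAULT_EPS_FN,
) -> dict[str, tuple[list[MethylationHaplotype], pd.DataFrame]]:
    """Simulate ``n_reads`` reads per segment per tissue for one channel.

    Returns ``{tissue: (haplotypes, counts)}`` where ``counts`` has columns
    chrom, pos, n_c, n_t and is exactly consistent with the emitted reads.
    """
    if span < 2:
        raise ValueError("span must be >= 2 CpGs")
    if not tissues:
        raise ValueError("at least one tissue required")
    if not (0.0 <= background <= 1.0 and 0.0 <= eps_fp <= 1.0 and 0.0 <= eps_fn <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    _validate_specs(landscape, specs)
    specs = [s for s in specs if s.channel == channel]
    for seg_idx, pos in enumerate(landscape.cpg_positions):
        if span > len(pos):
            raise ValueError(f"span {span} exceeds {len(pos)} CpGs in segment {seg_idx}")

    out: dict[str, tuple[list[MethylationHaplotype], pd.DataFrame]] = {}
    for tissue in tissues:
        rng = _stream_seed(seed, tissue, channel)
        haps: list[MethylationHaplotype] = []
        count_rows: dict[tuple[str, int], list[int]] = {}
        for seg_idx, ((chrom, _, _), positions) in enumerate(
            zip(landscape.segments, landscape.cpg_positions)
        ):
            m = len(positions)
            block_of_site = np.full(m, -1, dtype=np.int64)
            seg_specs = [s for s in specs if s.segment == seg_idx]
            for b, spec in enumerate(seg_specs):
                block_of_site[spec.cpg_lo : spec.cpg_hi] = b

            starts = rng.integers(0, m - span + 1, size=n_reads)
            site_idx = starts[:, None] + np.arange(span)[None, :]     # reads x span
            blocks = block_of_site[site_idx]

            # one epiallele draw per read per planted block (fully modified
            # with probability pi), independent background elsewhere
            state = rng.random((n_reads, span)) < background
            for b, spec in enumerate(seg_specs):
                pi_t = float(spec.pi.get(tissue, 0.0))
                epiallele = rng.random(n_reads) < pi_t
                in_block = blocks == b
                state = np.where(in_block, epiallele[:, None], state)

            flips = rng.random((n_reads, span))
            observed = np.where(state, flips >= eps_fn, flips < eps_fp)

            seg_positions = positions[site_idx]
            for r in range(n_reads):
                calls = "".join("1" if c else "0" for c in observed[r])
                haps.append(
                    MethylationHaplotype(
                        chrom,
                        tuple(int(p) for p in seg_positions[r]),
                        calls,
                        read_id=f"{tissue}_{channel}_s{seg_idx}_r{r}",
                        tissue=tissue,
                        channel=channel,
                    )
                )
            for j in range(span):
                for r in range(n_reads):
                    key = (chrom, int(seg_positions[r, j]))
                    cell = count_rows.setdefault(key, [0, 0])
                    cell[0 if observed[r, j] else 1] += 1
        counts = pd.DataFrame(
            [(c, p, v[0], v[1]) for (c, p), v in sorted(count_rows.items())],
            columns=["chrom", "pos", "n_c", "n_t"],
        )
        out[tissue] = (haps, counts)
    return out


def truth(
    specs: Sequence[BlockSpec],
    landscape: CpGLandscape,
    tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Truth table for planted blocks: one row per block per tissue.

    ``expected_mhl`` is the zero-error closed form: with a two-component
    epiallele mixture every in-block haplotype is all-1 or all-0, so the
    fully-modified fraction at every substring length — hence the MHL —
    equals the mixture weight ``pi``.
    """
    _validate_specs(landscape, specs)
    rows = []
    for i, spec in enumerate(specs):
        chrom, _, _ = landscape.segments[spec.segment]
        pos = landscape.cpg_positions[spec.segment]
        start = int(pos[spec.cpg_lo] - 1)
        end = int(pos[spec.cpg_hi - 1])
        tset = tissues if tissues is not None else sorted(spec.pi)
        for tissue in tset:
            rows.append(
                {
                    "block_id": f"planted_{i}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "segment": spec.segment,
                    "channel": spec.channel,
                    "tissue": tissue,
                    "expected_mhl": float(spec.pi.get(tissue, 0.0)),
                }
            )
    return pd.DataFrame(rows)
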