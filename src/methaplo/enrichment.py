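"""Enrichment, overlap and co-localization statistics for called sites
and haplotype blocks.

All score-style statistics share one form: log2(observed / expected) with
the expectation proportional to the CpG content of the element —
expected = (# calls genome-wide) x (# CpGs in element) / (# CpGs genome-wide).
Overlap significance comes from two routes that are kept distinct: a
matched random-sampling null (regions re-placed uniformly in a universe,
matched on length or on CpG count, 10,000 reps by default) giving an
empirical p with the +1/(n+1) correction, and the exact hypergeometric
upper tail for count tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import Block
from .io import GenomicElementSet

NEG_INF = float("-inf")


@dataclass
class OverlapSampling:
    """Observed overlap vs a matched random-sampling null distribution."""

    observed: int
    expected_mean: float
    expected_sd: float
    n_reps: int
    p_value: float
    counts: np.ndarray  # per-rep overlap counts


@dataclass(frozen=True)
class EnhancerCall:
    chrom: str
    start: int
    end: int
    klass: str            # "active" | "poised"
    marks: tuple[str, ...]


def enrichment_score(
    observed_in_element: int,
    called_genome: int,
    cpg_in_element: int,
    cpg_genome: int,
) -> float:
    """log2(observed / expected) with expected = called * cpg_in/cpg_total.

    Returns nan when the expectation is zero (undefined, flagged rather
    than infinite) and -inf when the element holds no calls but a positive
    expectation.
    """
    if min(observed_in_element, called_genome, cpg_in_element) < 0 or cpg_genome <= 0:
        raise ValueError("counts must be non-negative with cpg_genome > 0")
    if called_genome <= 0:
        raise ValueError("called_genome must be positive")
    expected = called_genome * cpg_in_element / cpg_genome
    if expected == 0:
        return math.nan
    if observed_in_element == 0:
        return NEG_INF
    return math.log2(observed_in_element / expected)


def _count_in(positions: Iterable[tuple[str, int]], chrom: str, start: int, end: int) -> int:
    """Count 1-based site positions falling in a 0-based half-open interval."""
    return sum(1 for c, p in positions if c == chrom and start < p <= end)


def gene_comod_enrichment(
    genes: Sequence[tuple[str, int, int, str]],
    co_sites: set[tuple[str, int]],
    cpg_positions: Sequence[tuple[str, int]],
) -> pd.DataFrame:
    """Per-gene enrichment of co-modified CpGs, ranked by score.

    A gene is "enriched" when its score exceeds 0 (more co-modified sites
    than its CpG content predicts).  Genes with no CpGs are flagged
    undefined (nan score).
    """
    n_co = len(co_sites)
    n_cpg = len(cpg_positions)
    rows = []
    for chrom, start, end, name in genes:
        g_cpg = _count_in(cpg_positions, chrom, start, end)
        g_co = _count_in(co_sites, chrom, start, end)
        if g_cpg == 0 or n_co == 0:
            score = math.nan
        else:
            score = enrichment_score(g_co, n_co, g_cpg, n_cpg)
        rows.append((name, chrom, start, end, g_cpg, g_co, score))
    df = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "n_cpg", "n_co", "score"]
    )
    df["enriched"] = df["score"] > 0
    return df.sort_values("score", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# matched random sampling


def _sample_matched_regions(
    lengths: Sequence[int],
    universe: Sequence[tuple[str, int, int]],
    rng: np.random.Generator,
    cpg_counts: Sequence[int] | None = None,
    cpg_index: dict[str, np.ndarray] | None = None,
    max_attempts: int = 1000,
) -> list[tuple[str, int, int]]:
    """Place one matched region per template, non-overlapping within a rep.

    Length matching: a start is drawn uniformly over every valid placement
    of that length across the universe.  CpG matching: a window of the same
    CpG count is drawn uniformly over every all-inside-one-interval window.
    """
    placed: list[tuple[str, int, int]] = []
    if cpg_counts is not None:
        if cpg_index is None:
            raise ValueError("cpg matching requires a cpg_index")
        windows: dict[int, list[tuple[str, np.ndarray]]] = {}
        for k in set(cpg_counts):
            opts = []
            for chrom, start, end in universe:
                pos = cpg_index.get(chrom)
                if pos is None:
                    continue
                inside = pos[(pos > start) & (pos <= end)]
                if len(inside) >= k:
                    opts.append((chrom, inside))
            windows[k] = opts
        for k in cpg_counts:
            opts = windows[k]
            weights = np.array([len(p) - k + 1 for _, p in opts], dtype=float)
            if not opts or weights.sum() <= 0:
                raise ValueError(f"no universe window holds {k} CpGs")
            prob = weights / weights.sum()
            for _ in range(max_attempts):
                i = rng.choice(len(opts), p=prob)
                chrom, pos = opts[i]
                j = rng.integers(0, len(pos) - k + 1)
                region = (chrom, int(pos[j] - 1), int(pos[j + k - 1]))
                if not any(
                    c == region[0] and region[1] < e and s < region[2] for c, s, e in placed
                ):
                    placed.append(region)
                    break
            else:
                raise ValueError("could not place a non-overlapping matched region")
        return placed

    for length in lengths:
        weights = np.array(
            [max(0, (end - start) - length + 1) for _, start, end in universe], dtype=float
        )
        if weights.sum() <= 0:
            raise ValueError(f"no universe interval can hold a template of length {length}")
        prob = weights / weights.sum()
        for _ in range(max_attempts):
            i = rng.choice(len(universe), p=prob)
            chrom, ustart, uend = universe[i]
            s = int(rng.integers(ustart, uend - length + 1))
            region = (chrom, s, s + length)
            if not any(c == chrom and s < e and st < s + length for c, st, e in placed):
                placed.append(region)
                break
        else:
            raise ValueError("could not place a non-overlapping matched region")
    return placed


def sampled_expected_overlap(
    template_blocks: Sequence[Block] | Sequence[tuple[str, int, int]],
    universe: GenomicElementSet | Sequence[tuple[str, int, int]],
    target_set: GenomicElementSet,
    n_reps: int = 10_000,
    matching: str = "length",
    seed: int = 0,
    cpg_index: dict[str, np.ndarray] | None = None,
    cpg_counts: Sequence[int] | None = None,
) -> OverlapSampling:
    """Observed overlap of the templates with a target set, against a null
    of matched regions randomly re-placed within the universe.

    Each rep re-places |templates| regions (matched on length, or on CpG
    count with ``matching="cpg"``) uniformly and without mutual overlap in
    the universe and records how many overlap the target set.  The
    empirical p-value is (1 + #{reps >= observed}) / (n_reps + 1).
    """
    if matching not in ("length", "cpg"):
        raise ValueError("matching must be 'length' or 'cpg'")
    uni = universe.intervals() if isinstance(universe, GenomicElementSet) else list(universe)
    if not uni:
        raise ValueError("universe is empty")

    def _triplet(b):
        return (b.chrom, b.start, b.end) if isinstance(b, Block) else (b[0], b[1], b[2])

    templates = [_triplet(b) for b in template_blocks]
    lengths = [e - s for _, s, e in templates]
    if matching == "cpg":
        if cpg_counts is None:
            counts = []
            for b in template_blocks:
                if isinstance(b, Block):
                    counts.append(b.n_cpgs)
                else:
                    raise ValueError("cpg matching needs Block templates or cpg_counts")
            cpg_counts = counts
    else:
        cpg_counts = None

    observed = sum(1 for c, s, e in templates if target_set.overlaps(c, s, e))
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=np.int64)
    for rep in range(n_reps):
        placed = _sample_matched_regions(lengths, uni, rng, cpg_counts, cpg_index)
        counts[rep] = sum(1 for c, s, e in placed if target_set.overlaps(c, s, e))
    p = (1 + int((counts >= observed).sum())) / (n_reps + 1)
    return OverlapSampling(
        observed=observed,
        expected_mean=float(counts.mean()),
        expected_sd=float(counts.std(ddof=1)) if n_reps > 1 else 0.0,
        n_reps=n_reps,
        p_value=p,
        counts=counts,
    )


def hypergeometric_overlap_test(
    population: int, successes: int, draws: int, observed: int
) -> float:
    """Exact upper-tail P(X >= observed), X ~ Hypergeom(population, successes, draws)."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("inconsistent hypergeometric counts")
    if not 0 <= observed <= min(successes, draws):
        raise ValueError(
            f"observed {observed} exceeds min(successes, draws) = {min(successes, draws)}"
        )
    return float(stats.hypergeom.sf(observed - 1, population, successes, draws))


def midpoint_distance_histogram(
    blocks_a: Sequence[Block] | Sequence[tuple[str, int, int]],
    blocks_b: Sequence[Block] | Sequence[tuple[str, int, int]],
    max_dist: int = 5000,
    bin_width: int = 100,
) -> tuple[np.ndarray, int]:
    """For each block in A, distance to the nearest midpoint in B, binned.

    Returns (counts per [0,bin), [bin,2*bin) ... bin up to max_dist,
    n_excluded) where excluded blocks lie beyond max_dist or on a
    chromosome with no B block; histogram total + excluded == |A|.
    """

    def _mid(b):
        if isinstance(b, Block):
            return b.chrom, b.midpoint
        chrom, s, e = b
        return chrom, (s + e) / 2.0

    b_mids: dict[str, np.ndarray] = {}
    for b in blocks_b:
        chrom, m = _mid(b)
        b_mids.setdefault(chrom, []).append(m)  # type: ignore[arg-type]
    b_mids = {c: np.sort(np.asarray(v, dtype=float)) for c, v in b_mids.items()}

    n_bins = max_dist // bin_width
    hist = np.zeros(n_bins, dtype=np.int64)
    excluded = 0
    for a in blocks_a:
        chrom, m = _mid(a)
        mids = b_mids.get(chrom)
        if mids is None or len(mids) == 0:
            excluded += 1
            continue
        d = float(np.min(np.abs(mids - m)))
        if d >= max_dist:
            excluded += 1
        else:
            hist[int(d // bin_width)] += 1
    return hist, excluded


def classify_enhancers(
    h3k4me1: GenomicElementSet,
    h3k27ac: GenomicElementSet,
    tss: Sequence[tuple[str, int]],
    distal_bp: int = 2000,
) -> list[EnhancerCall]:
    """Active/poised enhancer calls from histone-mark peaks.

    Distal H3K4me1 peaks (farther than ``distal_bp`` from every TSS) are
    enhancers: active when also overlapping an H3K27ac peak, else poised.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss:
        tss_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v, dtype=float)) for c, v in tss_by_chrom.items()}

    calls: list[EnhancerCall] = []
    for rec in h3k4me1:
        sites = tss_by_chrom.get(rec.chrom)
        if sites is not None and len(sites):
            # distance from interval to nearest TSS point (0 if inside)
            d = np.where(
                sites < rec.start, rec.start - sites, np.maximum(sites - rec.end + 1, 0)
            )
            if float(d.min()) <= distal_bp:
                continue
        active = h3k27ac.overlaps(rec.chrom, rec.start, rec.end)
        calls.append(
            EnhancerCall(
                rec.chrom,
                rec.start,
                rec.end,
                "active" if active else "poised",
                ("H3K4me1", "H3K27ac") if active else ("H3K4me1",),
            )
        )
    return calls


def block_comod_enrichment(
    blocks: Sequence[Block],
    classes: pd.Series | dict[str, str],
    co_sites: set[tuple[str, int]],
    n_cpg_genome: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-block co-modification enrichment plus per-class summary.

    A block is enriched when its score (same log2(obs/expected) form with
    the block's CpG count as the element size) exceeds 0.  Classes are
    compared by the exact hypergeometric test on the enriched/total count
    table: population = all classified blocks, successes = enriched
    blocks, draws = class size, observed = enriched blocks in the class.
    """
    if isinstance(classes, pd.Series):
        classes = classes.to_dict()
    n_co = len(co_sites)
    rows = []
    for blk in blocks:
        n_in = _count_in(co_sites, blk.chrom, blk.start, blk.end)
        if n_co == 0:
            score = math.nan
        else:
            score = enrichment_score(n_in, n_co, blk.n_cpgs, n_cpg_genome)
        rows.append(
            (
                blk.block_id,
                blk.chrom,
                blk.start,
                blk.end,
                blk.n_cpgs,
                n_in,
                score,
                classes.get(blk.block_id, "unclassified"),
            )
        )
    per_block = pd.DataFrame(
        rows,
        columns=["block_id", "chrom", "start", "end", "n_cpg", "n_co", "score", "class"],
    )
    per_block["enriched"] = per_block["score"] > 0

    known = per_block[per_block["class"] != "unclassified"]
    population = len(known)
    successes = int(known["enriched"].sum())
    summary_rows = []
    for cls, grp in known.groupby("class"):
        draws = len(grp)
        obs = int(grp["enriched"].sum())
        p = hypergeometric_overlap_test(population, successes, draws, obs)
        summary_rows.append((cls, draws, obs, obs / draws if draws else math.nan, p))
    summary = pd.DataFrame(
        summary_rows, columns=["class", "n_blocks", "n_enriched", "fraction_enriched", "p_value"]
    )
    return per_block, summary
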