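"""End-to-end orchestration: simulate or load reads, call sites, discover
blocks, compute MHL/TSI, classify, and run the enrichment statistics.

A run is driven by a single :class:`RunConfig` (YAML on disk).  Defaults
mirror the analysis thresholds used throughout: LD r2 cutoff 0.5 for MHBs
and 0.2 for hMHBs, minimum 4 CpGs per block, binomial calling at
BH-corrected q <= 0.05 with coverage >= 5, TSI > 0.6 for tissue-specific
blocks, and 10,000 resampling reps.  Every stage writes its outputs as it
completes, records a sha256 in the manifest, and appends to a state
marker, so a partial failure leaves completed results behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import blocks as blocks_mod
from . import enrichment as enrich_mod
from . import mhl as mhl_mod
from . import simulate as sim_mod
from . import sites as sites_mod
from .io import (
    BedRecord,
    GenomicElementSet,
    MethylationHaplotype,
    parse_read_haplotypes,
    parse_site_counts,
    write_bed,
    write_read_haplotypes,
    write_site_counts,
)

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ("cerebellum", "cortex", "olfactory_bulb")


@dataclass
class RunConfig:
    """All thresholds and inputs for one pipeline run."""

    outdir: str = "methaplo_run"
    seed: int = 0
    tissues: tuple[str, ...] = DEFAULT_TISSUES

    # simulation (demo mode); ignored when `inputs` is provided
    n_segments: int = 12
    cpgs_per_segment: int = 24
    spacing: float = 40.0
    n_reads: int = 200
    span: int = 6
    background_mc: float = 0.45
    background_hmc: float = 0.03
    eps_fp: float = sim_mod.DEFAULT_EPS_FP
    eps_fn: float = sim_mod.DEFAULT_EPS_FN
    pi_high: float = 0.85
    pi_low: float = 0.15
    pi_hmc: float = 0.5

    # optional real inputs: {tissue: {channel: {"reads": path, "counts": path}}}
    inputs: dict[str, Any] | None = None
    gene_bodies_bed: str | None = None

    # thresholds
    r2_mhb: float = blocks_mod.MHB_R2_CUTOFF
    r2_hmhb: float = blocks_mod.HMHB_R2_CUTOFF
    min_cpgs: int = blocks_mod.DEFAULT_MIN_CPGS
    min_pair_reads: int = blocks_mod.DEFAULT_MIN_PAIR_READS
    max_gap: int = 500
    alpha: float = sites_mod.DEFAULT_ALPHA
    min_cov: int = sites_mod.DEFAULT_MIN_COV
    min_reads_mhl: int = mhl_mod.DEFAULT_MIN_READS
    tsi_threshold: float = mhl_mod.DEFAULT_TSI_THRESHOLD
    shared_split: float = mhl_mod.DEFAULT_SHARED_SPLIT
    n_reps: int = 10_000

    def validate(self) -> None:
        for name, lo, hi in (
            ("r2_mhb", 0.0, 1.0),
            ("r2_hmhb", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
            ("tsi_threshold", 0.0, 1.0),
            ("shared_split", 0.0, 1.0),
            ("eps_fp", 0.0, 1.0),
            ("eps_fn", 0.0, 1.0),
            ("background_mc", 0.0, 1.0),
            ("background_hmc", 0.0, 1.0),
            ("pi_high", 0.0, 1.0),
            ("pi_low", 0.0, 1.0),
            ("pi_hmc", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"config: {name} = {v} outside [{lo}, {hi}]")
        for name in ("min_cpgs", "min_pair_reads", "min_cov", "min_reads_mhl", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"config: {name} must be >= 1")
        if len(self.tissues) < 2:
            raise ValueError("config: need at least two tissues")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**known)
        cfg.tissues = tuple(cfg.tissues)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["tissues"] = list(self.tissues)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class RunResult:
    """In-memory bundle of one pipeline run's stage outputs."""

    outdir: Path
    landscape: Any = None
    truth: pd.DataFrame | None = None
    site_calls: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    co_sites: dict[str, set] = field(default_factory=dict)
    mhbs: list = field(default_factory=list)
    hmhbs: list = field(default_factory=list)
    mhl: pd.DataFrame | None = None
    aml: pd.DataFrame | None = None
    classification: pd.DataFrame | None = None
    coordination: enrich_mod.OverlapSampling | None = None
    midpoint_hist: tuple | None = None
    comod_per_block: pd.DataFrame | None = None
    comod_summary: pd.DataFrame | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Provenance:
    """Stage-completion state marker plus per-file checksum manifest."""

    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.state_path = outdir / "state.json"
        self.manifest_path = outdir / "manifest.json"
        self.stages: list[str] = []
        self.files: dict[str, str] = {}

    def done(self, stage: str, *paths: Path) -> None:
        self.stages.append(stage)
        for p in paths:
            self.files[p.name] = _sha256(p)
        self.state_path.write_text(json.dumps({"completed": self.stages}, indent=1))
        self.manifest_path.write_text(json.dumps(self.files, indent=1, sort_keys=True))
        logger.info("stage complete: %s", stage)


def _demo_specs(cfg: RunConfig, landscape) -> tuple[list, list]:
    """Planted blocks for the bundled demo cohort.

    Segments rotate through four designs per channel cycle: tissue-specific
    (high pi in one rotating tissue), shared-high, shared-low, and — for
    the 5hmC channel — blocks only in gene-body segments.
    """
    tissues = list(cfg.tissues)
    mc_specs, hmc_specs = [], []
    lo = cfg.cpgs_per_segment // 4
    hi = cfg.cpgs_per_segment - lo
    designs = ["tissue-specific", "shared-high", "shared-low"]
    for seg in range(cfg.n_segments):
        design = designs[seg % 3]
        if design == "tissue-specific":
            top = tissues[(seg // 3) % len(tissues)]
            pi = {t: (cfg.pi_high if t == top else cfg.pi_low) for t in tissues}
        elif design == "shared-high":
            pi = {t: cfg.pi_high for t in tissues}
        else:
            pi = {t: cfg.pi_low for t in tissues}
        mc_specs.append(sim_mod.BlockSpec(seg, lo, hi, pi, channel="5mC"))
        if seg % 2 == 0:  # gene-body segments carry a co-hydroxymethylated block
            hmc_specs.append(
                sim_mod.BlockSpec(seg, lo, hi, {t: cfg.pi_hmc for t in tissues}, channel="5hmC")
            )
    return mc_specs, hmc_specs


def _load_inputs(cfg: RunConfig):
    haps: dict[tuple[str, str], list[MethylationHaplotype]] = {}
    counts: dict[tuple[str, str], pd.DataFrame] = {}
    for tissue, per_channel in (cfg.inputs or {}).items():
        for channel, paths in per_channel.items():
            haps[(tissue, channel)] = parse_read_haplotypes(
                paths["reads"], tissue=tissue, channel=channel
            )
            counts[(tissue, channel)] = parse_site_counts(paths["counts"])
    return haps, counts


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full analysis and write the result bundle under cfg.outdir."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _Provenance(outdir)
    result = RunResult(outdir=outdir)
    t0 = time.time()
    cfg.to_yaml(outdir / "config.yaml")

    # ---- stage: inputs (simulate the demo cohort, or load real tables)
    haps: dict[tuple[str, str], list[MethylationHaplotype]] = {}
    counts: dict[tuple[str, str], pd.DataFrame] = {}
    gene_bodies: GenomicElementSet
    if cfg.inputs:
        haps, counts = _load_inputs(cfg)
        if cfg.gene_bodies_bed is None:
            raise ValueError("gene_bodies_bed required when loading real inputs")
        from .io import parse_bed

        gene_bodies = parse_bed(cfg.gene_bodies_bed, "gene_body")
        n_cpg_genome = len(
            {(c, p) for hs in haps.values() for h in hs for c in [h.chrom] for p in h.positions}
        )
        cpg_index = None
        result.truth = None
        written: list[Path] = []
    else:
        landscape = sim_mod.simulate_landscape(
            cfg.n_segments, cfg.cpgs_per_segment, cfg.spacing, seed=cfg.seed
        )
        result.landscape = landscape
        mc_specs, hmc_specs = _demo_specs(cfg, landscape)
        for channel, specs, background in (
            ("5mC", mc_specs, cfg.background_mc),
            ("5hmC", hmc_specs, cfg.background_hmc),
        ):
            per_tissue = sim_mod.simulate_reads(
                landscape,
                specs,
                n_reads=cfg.n_reads,
                span=cfg.span,
                tissues=list(cfg.tissues),
                channel=channel,
                seed=cfg.seed,
                background=background,
                eps_fp=cfg.eps_fp,
                eps_fn=cfg.eps_fn,
            )
            for tissue, (h, c) in per_tissue.items():
                haps[(tissue, channel)] = h
                counts[(tissue, channel)] = c
        gene_bodies = GenomicElementSet.from_tuples("gene_body", landscape.gene_bodies)
        result.truth = sim_mod.truth(mc_specs + hmc_specs, landscape, list(cfg.tissues))
        n_cpg_genome = landscape.n_cpgs
        cpg_index = {
            chrom: np.sort(
                np.concatenate(
                    [
                        pos
                        for (c, _, _), pos in zip(landscape.segments, landscape.cpg_positions)
                        if c == chrom
                    ]
                )
            )
            for chrom in {c for c, _, _ in landscape.segments}
        }
        written = []
        for (tissue, channel), h in haps.items():
            p = outdir / f"reads_{tissue}_{channel}.tsv"
            write_read_haplotypes(h, p)
            written.append(p)
            p = outdir / f"counts_{tissue}_{channel}.tsv"
            write_site_counts(counts[(tissue, channel)], p)
            written.append(p)
        truth_path = outdir / "truth.tsv"
        result.truth.to_csv(truth_path, sep="\t", index=False)
        written.append(truth_path)
    prov.done("inputs", *written)

    # ---- stage: site calling and co-modified sites
    for (tissue, channel), c in counts.items():
        error_rate = cfg.eps_fp
        calls = sites_mod.call_modified_sites(
            c, error_rate, alpha=cfg.alpha, min_cov=cfg.min_cov, channel=channel
        )
        result.site_calls[(tissue, channel)] = calls
        p = outdir / f"site_calls_{tissue}_{channel}.tsv"
        calls.to_csv(p, sep="\t", index=False)
        prov.done(f"site_calls:{tissue}:{channel}", p)
    for tissue in cfg.tissues:
        mc = result.site_calls.get((tissue, "5mC"))
        hmc = result.site_calls.get((tissue, "5hmC"))
        if mc is not None and hmc is not None:
            result.co_sites[tissue] = sites_mod.co_modified_sites(mc, hmc)
    co_union: set[tuple[str, int]] = set().union(*result.co_sites.values()) if result.co_sites else set()

    # ---- stage: block discovery (pooled haplotypes per channel)
    pooled_mc = [h for (t, ch), hs in haps.items() if ch == "5mC" for h in hs]
    pooled_hmc = [h for (t, ch), hs in haps.items() if ch == "5hmC" for h in hs]
    result.mhbs = blocks_mod.call_blocks(
        pooled_mc,
        r2_cutoff=cfg.r2_mhb,
        min_cpgs=cfg.min_cpgs,
        min_pair_reads=cfg.min_pair_reads,
        max_gap=cfg.max_gap,
        kind="MHB",
    )
    result.hmhbs = blocks_mod.call_blocks(
        pooled_hmc,
        r2_cutoff=cfg.r2_hmhb,
        min_cpgs=cfg.min_cpgs,
        min_pair_reads=cfg.min_pair_reads,
        restrict_to=gene_bodies,
        max_gap=cfg.max_gap,
        kind="hMHB",
    )
    mhb_path = outdir / "blocks_mhb.bed"
    hmhb_path = outdir / "blocks_hmhb.bed"
    for path, blks in ((mhb_path, result.mhbs), (hmhb_path, result.hmhbs)):
        write_bed(
            (
                BedRecord(b.chrom, b.start, b.end, b.block_id, round(b.mean_r2() * 1000))
                for b in blks
            ),
            path,
            header="methaplo blocks: name=block_id score=mean_adjacent_r2*1000",
        )
    prov.done("blocks", mhb_path, hmhb_path)

    # ---- stage: MHL / AML matrices and classification
    by_tissue_mc = {t: haps.get((t, "5mC"), []) for t in cfg.tissues}
    result.mhl = mhl_mod.mhl_matrix(result.mhbs, by_tissue_mc, min_reads=cfg.min_reads_mhl)
    result.aml = mhl_mod.mhl_matrix(
        result.mhbs, by_tissue_mc, min_reads=cfg.min_reads_mhl, metric="aml"
    )
    result.classification = mhl_mod.classify_blocks(
        result.mhl, tsi_threshold=cfg.tsi_threshold, shared_split=cfg.shared_split
    )
    mhl_path = outdir / "mhl_matrix.tsv"
    cls_path = outdir / "classification.tsv"
    result.mhl.to_csv(mhl_path, sep="\t")
    result.aml.to_csv(outdir / "aml_matrix.tsv", sep="\t")
    result.classification.to_csv(cls_path, sep="\t")
    prov.done("mhl", mhl_path, cls_path)

    # ---- stage: coordination of hMHBs and MHBs in gene bodies
    gb_mhbs = [b for b in result.mhbs if gene_bodies.overlaps(b.chrom, b.start, b.end)]
    if gb_mhbs and result.hmhbs:
        target = GenomicElementSet.from_tuples(
            "hMHB", [(b.chrom, b.start, b.end) for b in result.hmhbs]
        )
        result.coordination = enrich_mod.sampled_expected_overlap(
            gb_mhbs,
            gene_bodies,
            target,
            n_reps=cfg.n_reps,
            matching="length",
            seed=cfg.seed + 1,
        )
        coord_path = outdir / "coordination.json"
        coord_path.write_text(
            json.dumps(
                {
                    "observed": result.coordination.observed,
                    "expected_mean": result.coordination.expected_mean,
                    "expected_sd": result.coordination.expected_sd,
                    "n_reps": result.coordination.n_reps,
                    "empirical_p": result.coordination.p_value,
                },
                indent=1,
            )
        )
        result.midpoint_hist = enrich_mod.midpoint_distance_histogram(
            result.hmhbs, result.mhbs
        )
        hist_path = outdir / "midpoint_histogram.tsv"
        hist, excluded = result.midpoint_hist
        pd.DataFrame(
            {"bin_start": np.arange(len(hist)) * 100, "count": hist}
        ).to_csv(hist_path, sep="\t", index=False)
        prov.done("coordination", coord_path, hist_path)

    # ---- stage: co-modification enrichment across block classes
    if result.classification is not None and result.mhbs:
        per_block, summary = enrich_mod.block_comod_enrichment(
            result.mhbs, result.classification["class"], co_union, n_cpg_genome
        )
        result.comod_per_block = per_block
        result.comod_summary = summary
        p1 = outdir / "comod_per_block.tsv"
        p2 = outdir / "comod_by_class.tsv"
        per_block.to_csv(p1, sep="\t", index=False)
        summary.to_csv(p2, sep="\t", index=False)
        prov.done("comod_enrichment", p1, p2)

    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "seed": cfg.seed,
                "elapsed_s": round(time.time() - t0, 2),
                "n_mhbs": len(result.mhbs),
                "n_hmhbs": len(result.hmhbs),
                "stages": prov.stages,
            },
            indent=1,
        )
    )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return result
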