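"""Discover a methylation haplotype block from read-level LD r2.

Adjacent CpGs whose states travel together across reads have r2 near 1;
independent background sites have r2 near 0.  A block is a maximal run
of adjacent pairs with r2 >= 0.5 and at least 4 CpGs.
"""

from methaplo import BlockSpec, call_blocks, ld_r2, simulate_landscape, simulate_reads

landscape = simulate_landscape(n_segments=1, cpgs_per_segment=16, spacing=40, seed=5)
spec = BlockSpec(segment=0, cpg_lo=4, cpg_hi=12, pi={"t": 0.5})
haps, _ = simulate_reads(
    landscape, [spec], n_reads=300, span=6, tissues=["t"], channel="5mC",
    seed=6, background=0.5, eps_fp=0.002, eps_fn=0.01,
)["t"]

positions = [int(p) for p in landscape.cpg_positions[0]]
inside = ld_r2(haps, positions[6], positions[7])
outside = ld_r2(haps, positions[1], positions[2])
print(f"adjacent r2 inside planted block:  {inside.r2:.3f} ({inside.n_pairs} read pairs)")
print(f"adjacent r2 in background:         {outside.r2:.3f} ({outside.n_pairs} read pairs)")

blocks = call_blocks(haps, r2_cutoff=0.5, min_cpgs=4)
planted = set(positions[4:12])
for b in blocks:
    jac = len(set(b.positions) & planted) / len(set(b.positions) | planted)
    print(
        f"called {b.kind} {b.chrom}:{b.start}-{b.end} with {b.n_cpgs} CpGs, "
        f"mean adjacent r2 {b.mean_r2():.2f}, Jaccard vs planted truth {jac:.2f}"
    )
# The planted 8-CpG block is recovered essentially exactly; the coupled
# epiallele mixture drives in-block r2 toward 1 while background pairs
# stay near 0 and break the run.
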