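"""Binomial site calling on the two channels and co-modified CpGs.

Each CpG's "C" count is tested against the conversion-error null; sites
with BH-corrected q <= 0.05 and coverage >= 5 are called modified.  A CpG
called in both the oxBS (5mC) and TAB (5hmC) channel is co-modified:
different molecules at the same position carry different marks.
"""

import pandas as pd

from methaplo import call_modified_sites, co_modified_sites

# three illustrative sites: clean signal / pure noise / under-covered
counts_mc = pd.DataFrame(
    {"chrom": "chr1", "pos": [100, 200, 300], "n_c": [18, 1, 4], "n_t": [2, 19, 0]}
)
counts_hmc = pd.DataFrame(
    {"chrom": "chr1", "pos": [100, 200, 300], "n_c": [9, 0, 4], "n_t": [11, 20, 0]}
)

mc = call_modified_sites(counts_mc, error_rate=0.005, channel="5mC")
hmc = call_modified_sites(counts_hmc, error_rate=0.005, channel="5hmC")

for name, calls in (("5mC", mc), ("5hmC", hmc)):
    print(f"-- {name} --")
    print(calls[["pos", "coverage", "level", "q_value", "called"]].to_string(index=False))

co = co_modified_sites(mc, hmc)
print("co-modified sites:", sorted(co))
# pos 100 is called in both channels (co-modified); pos 200 is noise in
# both; pos 300 has a tiny p-value but fails the coverage >= 5 filter.
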