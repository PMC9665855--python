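"""PBWT basics: build the index, map an interval, find set-maximal matches.

Builds a tiny random haplotype panel, shows how a pattern interval splits
when extended by one site, and lists the set-maximal matches of a query
haplotype against the panel.
"""

import numpy as np

from phasebeam import (
    HaplotypePanel,
    build_pbwt,
    interval_frequency,
    map_interval,
    set_maximal_matches,
)

rng = np.random.default_rng(0)
panel = HaplotypePanel(rng.integers(0, 2, size=(12, 20)))
index = build_pbwt(panel)

# the whole-panel interval at site 0 represents the empty pattern; mapping
# it forward splits it into the carriers of allele 0 and allele 1
iv = index.full_interval(0)
iv0, iv1 = map_interval(index, iv)
print(f"site 0: {iv0.size} haplotypes carry allele 0, {iv1.size} carry allele 1")
print(f"allele-1 pattern frequency: {interval_frequency(index, iv1):.3f}")

# a query copied from panel haplotype 4 with two mismatches and one no-call
query = panel.matrix[4].astype(np.int16)
query[7] ^= 1
query[15] ^= 1
query[10] = -1  # missing: matches either allele
matches = set_maximal_matches(index, panel, query)
print(f"\n{len(matches)} set-maximal matches (start, end, haplotype):")
for m in matches:
    print(f"  [{m.start:2d}, {m.end:2d})  hap {m.hap}  length {m.length}")
# haplotype 4 should reappear as the longest segments flanking the mismatches
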