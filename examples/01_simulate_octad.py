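"""Simulate one octad: the 8 DNA strands of a single hybrid meiosis.

Builds a genome-scale SNP map, runs the meiosis simulator at wild-type-like
conditions (interfering crossovers, Poisson noncrossovers, retained
heteroduplex DNA), and summarises what the ground-truth log records.
"""

from collections import Counter

import octarec as oc

snp_map = oc.build_snp_map(oc.SACCER_CHROM_LENGTHS, seed=1)
octad, truth = oc.simulate_meiosis(snp_map, oc.SimParams(), seed=7)

print(f"markers: {snp_map.n_markers} over {len(snp_map.chroms)} chromosomes")
print(f"true events: {len(truth.events)}")
print("by type:", dict(Counter(e.kind for e in truth.events)))
print("by category:", dict(Counter(e.category for e in truth.events)))

profile = oc.segregation_profile(octad)
aberrant = (~profile["mendelian"]).sum()
print(f"markers with non-Mendelian segregation: {aberrant} "
      f"({100 * aberrant / len(profile):.2f}%)")
# Each event converts or heteroduplexes a tract of markers on 1-2 chromatids,
# so a small fraction of the ~75k markers deviates from clean 4:4.
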