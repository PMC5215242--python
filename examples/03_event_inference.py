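"""Infer recombination events from an octad genotype matrix.

Per spore, the chromosome is segmented into parental phase blocks; phase
switches mark crossover junctions (validated by reciprocity between two
spores) and runs of markers deviating from the background are conversion
or heteroduplex tracts.  Tracts and junctions closer than 1.5 kb are merged
into one DSB event, then typed and measured.
"""

from collections import Counter

import octarec as oc

snp_map = oc.build_snp_map(oc.SACCER_CHROM_LENGTHS, seed=1)
octad, truth = oc.simulate_meiosis(snp_map, oc.SimParams(), seed=7)
records = oc.infer_events(octad, snp_map, chrom_lengths=oc.SACCER_CHROM_LENGTHS)

print(f"inferred events: {len(records)} "
      f"(ground truth holds {sum(e.detectable for e in truth.events)} "
      "detectable events)")
print("by type:", dict(Counter(r.kind for r in records)))
print("by category:", dict(Counter(r.category for r in records)))

frame = oc.events_to_frame(records)
with_len = frame[frame["n_markers"] > 0]
print("\nfirst events (BED-flavoured coordinates):")
print(frame.head(5).to_string(index=False))
print(f"\nmedian tract length (mid convention): "
      f"{with_len['len_mid'].median():.0f} bp over {len(with_len)} events")
# len_min/len_mid/len_max bracket the true tract: min spans the affected
# markers, max reaches the flanking unaffected ones, mid takes the midpoints.
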