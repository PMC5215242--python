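# octarec

Meiotic recombination analysis from **octad sequencing** — the 8 DNA strands
of one meiosis, recovered by letting each of the four spores of a polymorphic
hybrid yeast (S288C × SK1-like, mismatch-repair deficient) divide once and
sequencing both daughter cells. Because *msh2* cells cannot correct
heteroduplex DNA (hDNA), every interhomolog strand transfer remains visible:
a spore whose two daughters disagree at a marker carries hDNA (5:3
segregation), a spore whose both daughters switched carries a full conversion
(6:2), and a reciprocal exchange of flanking parental phase between two
spores marks a crossover (CO).

The package is written for researchers analysing tetrad/octad sequencing of
hybrid meioses. It takes per-SNP read-count tables (or pre-called 8-strand
genotype matrices) and produces:

- genotype calls under the read-count validity rule (single-type reads
  accepted in [15, 150]; two-type reads accepted when the majority lies in
  [40, 150] and the minority below 5);
- recombination events: per-spore parental phase blocks, CO junctions
  validated by reciprocity between two spores, conversion/hDNA tracts, and
  single-DSB events merged at < 1.5 kb separation;
- event classification — CO vs noncrossover (NCO), and the strand-transfer
  pattern: full conversion (6:2), SDSA-like hDNA (one contiguous
  single-strand tract), trans hDNA (donor strand switches sides once),
  symmetric hDNA (complementary tracts on two chromatids, net 4:4 but
  aberrant), or complex;
- tract lengths under three conventions (`min` ≤ `mid` ≤ `max`, bracketing
  the true tract);
- summary statistics: per-meiosis CO/NCO counts, tract-length medians with
  Wilcoxon rank-sum comparisons, and **crossover interference** estimated by
  maximum-likelihood fitting of a gamma distribution to inter-CO distances
  (shape γ = 1: no interference; γ > 1: positive interference), with
  two-sample Kolmogorov–Smirnov comparisons between strains.

A strand-resolved meiosis simulator (`simulate_meiosis`) provides exact
ground truth — interference-distributed COs from a stationary gamma-renewal
process, Poisson NCOs, configurable tract-length and hDNA-category models,
and Poisson 70× read-count emission — so every pipeline stage is testable
without any sequencing data.

## Worked example

```python
import octarec as oc

snp_map = oc.build_snp_map(oc.SACCER_CHROM_LENGTHS, seed=1)   # ~75k markers
octad, truth = oc.simulate_meiosis(snp_map, oc.SimParams(), seed=7)
counts = oc.emit_read_counts(octad, depth=70.0, seed=8)
called = oc.call_matrix(counts)
records = oc.infer_events(called, snp_map, chrom_lengths=oc.SACCER_CHROM_LENGTHS)
```

Running `python examples/03_event_inference.py` (which does the above on the
error-free octad) prints:

```
inferred events: 162 (ground truth holds 164 detectable events)
by type: {'CO': 91, 'NCO': 71}
by category: {'none': 20, 'SDSA_like_hDNA': 114, 'trans_hDNA': 17, 'complex': 3,
              'full_conversion': 5, 'symmetric_hDNA': 3}
median tract length (mid convention): 1043 bp over 152 events
```

i.e. ~92 interfering crossovers and ~70 noncrossovers per meiosis, nearly all
recovered, with hDNA retained as SDSA-like or trans tracts and a median
conversion tract around 1 kb. `examples/04_interference_and_tracts.py`
contrasts a wild-type-like strain with an *mlh2*-like mutant:

```
WT: gamma shape 2.2 (scale 52 kb, 323 gaps)
mlh2: gamma shape 2.4 (scale 52 kb, 149 gaps)
tract medians: WT 1022 bp vs mlh2 2269 bp
Wilcoxon rank-sum p = 5.81e-18
KS on inter-CO distances: D = 0.098, p = 0.26
```

— the mutant roughly doubles conversion-tract length without changing
crossover interference, the signature the analysis is designed to resolve.

The `octarec` command exposes the same pipeline from the shell:
`octarec simulate|call|infer|stats|run` (see `octarec run --help`); input and
output formats are plain TSV (SNP map, octad matrix, read counts,
BED-flavoured events) plus a JSON summary.

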