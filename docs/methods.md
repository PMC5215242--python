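# Methods

## The measurement

One meiosis of a polymorphic hybrid diploid produces four spores; allowing
each spore one mitotic division and sequencing both daughter cells recovers
all eight DNA strands of the meiosis. At every SNP distinguishing the two
parental genomes, each strand reads as parent 1 (P1), parent 2 (P2) or
missing. In a mismatch-repair-deficient (*msh2*) background heteroduplex DNA
is not corrected, so recombination intermediates survive to sequencing:

- 4:4 segregation, all spores homoduplex — no event;
- 5:3 (one spore's two strands disagree) — retained hDNA;
- 6:2 (both strands of one spore converted) — full gene conversion;
- a reciprocal switch of flanking parental phase between two spores — a
  crossover (CO), with any adjacent tract its associated conversion.

## Genotype calling

Per (marker, strand library), with `n_p1`/`n_p2` reads supporting each
parental allele: the call is the single observed allele if its count lies in
`[mono_min, mono_max] = [15, 150]`; with both alleles observed, the majority
allele if the majority count lies in `[duo_major_min, duo_major_max] =
[40, 150]` and the minority is strictly below `duo_minor_lt = 5`; otherwise
missing. Interval bounds are inclusive ("between 15 and 150") and the
minority bound strict ("below 5"), the plain reading of the rule; ties have
no majority allele and are missing. All five thresholds are configurable in
`GenotypeCallConfig`.

## Event inference

The deduction algorithm is our own concrete realization (the tetrad/octad
literature describes the idea but not an exact procedure). Per chromosome:

1. **Homoduplex runs.** For each spore, markers where both strands agree
   form runs of constant parental phase (run-length encoding). Heteroduplex
   and half-called markers are excluded from this sequence.
2. **Anchors.** Terminal runs and interior runs spanning at least
   `phase_block_min_bp` (default 20 kb, several times the largest plausible
   conversion tract yet well below typical inter-CO distances) are accepted
   as phase blocks outright. Terminal runs are always anchors so a junction
   near a telomere is not mistaken for a tract.
3. **Confirmed-junction walk.** Within each anchor gap, a boundary between
   runs is accepted as a phase switch when a reciprocal-direction boundary
   exists on another spore within `co_pair_max_bp` (default 20 kb) *and* the
   markers between the two junctions are ≥ 90% "aberrant" (heteroduplex,
   half-called, missing, or non-4:4). The zone test is what separates a true
   CO whose junction is displaced across its own conversion tract (the zone
   is the tract: ~100% aberrant) from two unrelated events whose boundaries
   mirror by coincidence (the zone is mostly clean 4:4). If the walk ends on
   the wrong phase for the right anchor, exactly one unconfirmed switch
   remains and is placed at the cut minimising phase-inconsistent markers.
   Runs that disagree with the walking phase become candidate tracts.
4. **Tract detection.** Per spore, maximal runs of markers deviating from
   the background phase (heteroduplex; opposite homoduplex; half-call
   discordant with the background), bridging up to `max_missing_run = 2`
   uninformative markers. Each affected marker records which strand carries
   the donor allele.
5. **CO pairing.** Reciprocal-direction switches on different spores are
   paired greedily nearest-first (same tolerance and transferred-zone
   validation as step 3). A pair's two junctions delimit the transferred
   zone; its markers count as affected.
6. **Merging.** Tracts, CO pairs and leftover lone switches are clustered by
   single linkage: neighbours whose nearest affected markers are separated
   by **less than `merge_gap_bp` = 1500 bp** join one event (one initiating
   DSB). The rule is strict: a 1,499 bp gap merges, a 1,500 bp gap does not.
7. **Classification.** An event is a CO iff its cluster contains a
   reciprocal switch pair; otherwise NCO. The strand-transfer pattern is
   full conversion (all affected markers 6:2 on one spore), SDSA-like hDNA
   (one contiguous single-strand tract, constant donor strand), trans hDNA
   (donor strand switches sides exactly once), symmetric hDNA (two spores
   heteroduplex over overlapping markers with complementary donor alleles),
   or complex for anything else — including clusters with a non-reciprocal
   lone switch, which typically indicates signal truncated at a chromosome
   end or an uncallable spore.
8. **Tract lengths**, three conventions per event:
   `min` = span of affected markers (single marker → 1 bp);
   `mid` = distance between the midpoints of the two flanking
   affected↔unaffected marker intervals;
   `max` = distance between the flanking unaffected markers, exclusive.
   Always `min ≤ mid ≤ max`, and for a well-separated event the true tract
   length lies in `[min, max]`. Flanks with no concordant marker clamp to
   the chromosome end and are flagged. `mid` is the headline statistic.

Coordinates: SNP maps and octad matrices are 1-based; event tables are
written BED-flavoured (0-based, half-open). CO positions are the midpoint of
the switch interval, averaged over the reciprocal pair.

## Crossover interference

Inter-CO distances are successive CO midpoint differences per chromosome per
meiosis (chromosomes with fewer than two COs contribute nothing), pooled per
genotype; per-chromosome fits are available by grouping the events manually.
The gamma MLE solves the shape score equation
`log k − ψ(k) = log(mean x) − mean(log x)` by safeguarded Newton iteration
(Minka-style initialisation, bisection fallback, tolerance 1e−12), with
`scale = mean/k`; shape 1 is a memoryless (non-interfering) process.
Chromosome-end censoring is ignored, matching a plain gamma fit to observed
gaps; this slightly deflates the pooled gap coefficient of variation because
terminal gaps are truncated. Degenerate inputs (fewer than two gaps,
non-positive gaps, zero variance) raise instead of returning a fit. Strain
comparisons use the two-sample Kolmogorov–Smirnov test on gap distributions
and the Wilcoxon rank-sum test (mid-ranks, tie-corrected normal
approximation; exact enumeration for small untied samples) on tract lengths,
both reported raw with no multiple-testing correction.

## The simulator

`simulate_meiosis` emulates the study conditions; none of the generative
choices below are claims about mechanism, only about what the data look
like. Defaults:

| parameter | default | meaning |
|---|---|---|
| `chrom_lengths` | 16 R64 chromosomes, 12.07 Mb | genome scale |
| marker density | 74,911 / 12,071,326 bp | hybrid SNP map scale (~161 bp spacing) |
| `gamma_shape_sim` | 2.3 | CO interference (wild type); mutant presets 2.5 / 1.9 |
| `mean_inter_co` | 130 kb | ≈ 93 COs per meiosis genome-wide |
| `nco_rate` | 5.8e−6 /bp | ≈ 70 NCOs per meiosis |
| `tract_len_dist_co` | geometric, median 1.0 kb | CO-associated tract length (mutant presets 2.1 / 2.3 kb) |
| `tract_len_dist_nco` | geometric, median 0.8 kb | NCO tract length (mutant presets 2.3 / 1.7 kb) |
| `tract_len_dist_sym` | geometric, median 280 bp | symmetric-hDNA tracts; yields the observed ~560 bp mean |
| `p_full_conversion` / `p_trans_hdna` / `p_sym_hdna` | 0.15 / 0.25 / 0.04 | tract-category mix; remainder SDSA-like |
| `mmr_active` | False | *msh2* background: hDNA persists |
| `p_conversion_vs_restoration` | 0.5 | only with repair active |
| depth / error | 70× Poisson, 0 | sequencing emulation |

COs follow a stationary gamma renewal process per chromosome (first event
from the equilibrium forward-recurrence distribution — a uniform fraction of
a length-biased gap — then i.i.d. gamma gaps), so gap statistics are
unbiased along the chromosome; the per-meiosis CO count is not conditioned.
Each CO exchanges flanking phase between one chromatid of each local
parental phase and writes a tract on one partner; NCOs are uniform, on a
uniform chromatid. Symmetric hDNA is drawn only for NCO tracts (a CO's
flank exchange cannot present the net-4:4 pattern) and writes complementary
single-strand tracts on two opposite-background chromatids. Events that
would overlap on a chromatid are redrawn up to `max_redraws`, and collisions
are counted in the ground truth. One root seed spawns per-chromosome
streams, so results are reproducible and chromosome-order independent.

The tract-length *family* is a configurable stand-in (only medians are known
for the real data); geometric was chosen as the simplest strictly positive
integer-valued choice. Mean CO/NCO counts per meiosis are our own
genome-scale choices in the range typical of msh2-deficient hybrid octad
studies.

**What passing tests do and do not show.** The simulator produces clean,
separable events on a fixed marker map: round-trip precision/recall near 1
demonstrates the caller's correctness on the modelled event geometry, not
robustness to alignment artifacts, segmental aneuploidy, marker-dense or
marker-desert regions, or complex multi-chromatid events beyond the modelled
categories — real octads contain all of these. Two observability effects the
simulator *does* reproduce are worth keeping in mind when reading summaries:
tracts covering no marker are invisible (so observed tract-length samples
are length-biased upward relative to the underlying process), and a CO whose
conversion tract runs past a chromosome's terminal marker is observationally
identical to a terminal NCO (the caller reports an NCO/complex event, and no
method could do otherwise).

## Numerical and degenerate-input choices

- Genotype thresholds are integers; negative counts are rejected.
- Tied two-type counts are missing (no majority exists).
- A spore with no homoduplex marker on a chromosome is uncallable there;
  events involving it are classified complex.
- Incomplete octads (≠ 8 strand libraries) are rejected at the container
  level.
- `fit_gamma_mle` converges to the global optimum of the unimodal profile
  likelihood; tests verify the log-likelihood against a grid-search oracle
  to 1e−6 nats.
- Determinism: all randomness flows from explicit seeds; repeated runs are
  byte-identical, and the run log records every threshold applied.

## Known limitations

- The event taxonomy covers the categories above; rarer 4:4-aberrant
  patterns are reported as complex rather than sub-classified.
- Phase segmentation assumes double COs closer than ~1.5 kb on one spore
  pair are indistinguishable from a single event (they merge, as in the
  distance rule).
- The censored-likelihood interference fit is not implemented; the plain
  fit ignores chromosome-end truncation of gaps.
- The VCF import shim reads plain-text single-sample VCFs with AD fields
  only; it is a convenience for real-data import, not a full VCF parser.
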