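import numpy as np
import pytest

import octarec as oc
from octarec.events import (InferenceConfig, detect_raw_tracts, infer_events,
                            infer_phase_background, merge_events,
                            pair_crossover_switches, _phase_one_chrom)

from conftest import make_octad, map_from_positions


def het(octad, snp_map, spore, lo, hi, donor, strand=0):
    """Write a single-strand hDNA tract (donor allele) on one spore."""
    pos = snp_map.positions(octad.index["chrom"].iloc[0])
    mask = (pos >= lo) & (pos <= hi)
    octad.calls[mask, 2 * spore + strand] = donor


def full_conv(octad, snp_map, spore, lo, hi, donor):
    het(octad, snp_map, spore, lo, hi, donor, 0)
    het(octad, snp_map, spore, lo, hi, donor, 1)


def crossover(octad, snp_map, sa, sb, x):
    """Reciprocal flank exchange between two spores beyond position x."""
    pos = snp_map.positions(octad.index["chrom"].iloc[0])
    mask = pos > x
    for strand in (0, 1):
        tmp = octad.calls[mask, 2 * sa + strand].copy()
        octad.calls[mask, 2 * sa + strand] = octad.calls[mask, 2 * sb + strand]
        octad.calls[mask, 2 * sb + strand] = tmp


class TestSegregationProfile:
    def test_counts_and_mendelian_flag(self, small_map):
        octad = make_octad(small_map)
        octad.calls[0, 1] = 2      # 5:3 at first marker
        octad.calls[1, 7] = 0      # 4:3 + 1 missing at second
        prof = oc.segregation_profile(octad)
        assert tuple(prof.loc[0, ["n_p1", "n_p2", "n_missing"]]) == (3, 5, 0)
        assert tuple(prof.loc[1, ["n_p1", "n_p2", "n_missing"]]) == (4, 3, 1)
        assert not prof.loc[0, "mendelian"] and not prof.loc[1, "mendelian"]
        assert prof.loc[2:, "mendelian"].all()


class TestPhaseBackground:
    def test_mendelian_octad_is_one_block_per_spore(self, small_map):
        octad = make_octad(small_map)
        phase = infer_phase_background(octad)["chr1"]
        assert phase.switches == []
        assert (phase.background == np.array([1, 1, 2, 2], dtype=np.int8)).all()

    def test_single_crossover_splits_partner_spores_in_two_blocks(self, small_map):
        octad = make_octad(small_map)
        crossover(octad, small_map, 0, 2, 5050)
        phase = infer_phase_background(octad)["chr1"]
        assert len(phase.switches) == 2
        assert sorted(s.spore for s in phase.switches) == [0, 2]
        for s in phase.switches:
            assert s.pos_left == 5000 and s.pos_right == 5100

    def test_conversion_run_is_not_a_phase_switch(self, small_map):
        octad = make_octad(small_map)
        full_conv(octad, small_map, 1, 4000, 4500, donor=2)  # 6:2 deviation
        phase = infer_phase_background(octad)["chr1"]
        assert phase.switches == []
        assert (phase.background[:, 1] == 1).all()

    def test_spore_without_homoduplex_markers_is_uncallable(self, small_map):
        # one whole strand library missing leaves no homoduplex marker
        octad = make_octad(small_map)
        octad.calls[:, 6] = 0
        phase = infer_phase_background(octad)["chr1"]
        assert phase.uncallable == [3]
        assert (phase.background[:, :3] > 0).all()

    def test_close_double_crossover_promoted_by_reciprocity(self):
        # two COs 4 kb apart on the same spore pair: the sandwiched opposite
        # run is shorter than a phase block but both its boundaries have
        # reciprocal partners, so it must yield two switches, not a tract
        snp = oc.build_snp_map({"chr1": 50_000}, mode="fixed", pitch=100)
        octad = make_octad(snp)
        crossover(octad, snp, 0, 2, 20_050)
        crossover(octad, snp, 0, 2, 24_050)
        recs = infer_events(octad, snp)
        assert [r.kind for r in recs] == ["CO", "CO"]


class TestDetectRawTracts:
    def cfg(self):
        return InferenceConfig()

    def run(self, octad, snp_map):
        chrom, pos, calls = next(octad.by_chrom())
        phase = _phase_one_chrom(pos, calls, self.cfg())
        return detect_raw_tracts(calls, pos, phase, self.cfg()), pos

    def test_no_deviations_no_tracts(self, small_map):
        tracts, _ = self.run(make_octad(small_map), small_map)
        assert tracts == []

    def test_het_run_becomes_one_single_strand_tract(self, small_map):
        octad = make_octad(small_map)
        het(octad, small_map, 0, 1200, 1900, donor=2)  # markers 12..19
        tracts, pos = self.run(octad, small_map)
        assert len(tracts) == 1
        t = tracts[0]
        assert t.spore == 0
        assert pos[t.marker_idx[0]] == 1200 and pos[t.marker_idx[-1]] == 1900
        assert (t.donor_strand == 0).all() and (t.donor_allele == 2).all()

    def test_missing_marker_inside_run_is_bridged(self, small_map):
        octad = make_octad(small_map)
        het(octad, small_map, 0, 1200, 1900, donor=2)
        octad.calls[15, 0] = 0
        octad.calls[15, 1] = 0  # fully missing marker inside the tract
        tracts, _ = self.run(octad, small_map)
        assert len(tracts) == 1
        assert len(tracts[0].marker_idx) == 7

    def test_long_uninformative_gap_splits_runs(self, small_map):
        octad = make_octad(small_map)
        het(octad, small_map, 0, 1200, 1400, donor=2)
        het(octad, small_map, 0, 1800, 2000, donor=2)
        octad.calls[14:17, 0] = 0
        octad.calls[14:17, 1] = 0  # 3 missing > max_missing_run
        tracts, _ = self.run(octad, small_map)
        assert len(tracts) == 2


class TestMergeEvents:
    def make_two_tracts(self, gap_bp):
        positions = [100, 500, 1000, 1100, 1200, 1600, 2100,
                     1200 + gap_bp, 3200, 3600, 4000, 4500]
        snp = map_from_positions(sorted(set(positions)))
        octad = make_octad(snp)
        het(octad, snp, 0, 1000, 1200, donor=2)
        het(octad, snp, 0, 1200 + gap_bp, 1200 + gap_bp, donor=2)
        return octad, snp

    def test_gap_below_merge_threshold_joins_one_event(self):
        octad, snp = self.make_two_tracts(1499)
        recs = infer_events(octad, snp)
        assert len(recs) == 1

    def test_gap_at_merge_threshold_stays_two_events(self):
        octad, snp = self.make_two_tracts(1500)
        recs = infer_events(octad, snp)
        assert len(recs) == 2

    def test_single_tract_unchanged_and_order_independent(self, small_map):
        octad = make_octad(small_map)
        het(octad, small_map, 0, 1200, 1900, donor=2)
        chrom, pos, calls = next(octad.by_chrom())
        cfg = InferenceConfig()
        phase = _phase_one_chrom(pos, calls, cfg)
        tracts = detect_raw_tracts(calls, pos, phase, cfg)
        once = merge_events(tracts, pos, cfg)
        assert len(once) == 1 and once[0] == tracts
        # idempotence: merging the merged cluster's items changes nothing
        again = merge_events(once[0], pos, cfg)
        assert again == once
        # order independence
        rev = merge_events(list(reversed(tracts)), pos, cfg)
        assert rev == once


class TestClassification:
    def test_full_conversion_without_switch_is_nco(self, small_map):
        octad = make_octad(small_map)
        full_conv(octad, small_map, 1, 4000, 4500, donor=2)
        recs = infer_events(octad, small_map)
        assert [(r.kind, r.category) for r in recs] == [("NCO", "full_conversion")]

    def test_single_strand_het_is_sdsa_like(self, small_map):
        octad = make_octad(small_map)
        het(octad, small_map, 2, 3000, 3800, donor=1)
        recs = infer_events(octad, small_map)
        assert [(r.kind, r.category) for r in recs] == [("NCO", "SDSA_like_hDNA")]

    def test_donor_strand_side_switch_is_trans(self, small_map):
        octad = make_octad(small_map)
        het(octad, small_map, 0, 3000, 3400, donor=2, strand=0)
        het(octad, small_map, 0, 3500, 3900, donor=2, strand=1)
        recs = infer_events(octad, small_map)
        assert [(r.kind, r.category) for r in recs] == [("NCO", "trans_hDNA")]

    def test_complementary_tracts_on_two_spores_are_symmetric(self, small_map):
        # two chromatids heteroduplex over the same five markers with
        # complementary donors: net 4:4 but aberrant
        octad = make_octad(small_map)
        het(octad, small_map, 0, 3000, 3400, donor=2)  # P1-background spore
        het(octad, small_map, 2, 3000, 3400, donor=1)  # P2-background spore
        recs = infer_events(octad, small_map)
        assert [(r.kind, r.category) for r in recs] == [("NCO", "symmetric_hDNA")]

    def test_reciprocal_exchange_with_adjacent_tract_is_co(self, small_map):
        octad = make_octad(small_map)
        crossover(octad, small_map, 0, 2, 5050)
        het(octad, small_map, 0, 5100, 5600, donor=1)  # hDNA on the recipient
        recs = infer_events(octad, small_map)
        assert len(recs) == 1
        assert recs[0].kind == "CO" and recs[0].category == "SDSA_like_hDNA"
        # junction estimate lies within the exchange zone (the recipient's
        # switch is displaced across its hDNA tract)
        assert 5000 <= recs[0].co_pos <= 5700

    def test_mendelian_octad_yields_no_events(self, small_map):
        assert infer_events(make_octad(small_map), small_map) == []


class TestTractLength:
    def build(self, affected, flanks_and_others, chrom_length=None):
        positions = sorted(set(affected) | set(flanks_and_others))
        snp = map_from_positions(positions)
        octad = make_octad(snp)
        for p in affected:
            het(octad, snp, 0, p, p, donor=2)
        recs = infer_events(octad, snp,
                            chrom_lengths={"chr1": chrom_length} if chrom_length else None)
        assert len(recs) == 1
        return recs[0]

    def test_worked_min_mid_max_example(self):
        r = self.build([10_000, 11_000], [9000, 9800, 11_300, 12_000, 15_000])
        assert r.len_min == 1001
        assert r.len_mid == 1250      # midpoint 9,900 to midpoint 11,150
        assert r.len_max == 1499      # 11,300 - 9,800 - 1

    def test_single_marker_tract_has_min_one(self):
        r = self.build([10_000], [9000, 9800, 11_300, 12_000, 15_000])
        assert r.len_min == 1

    def test_conventions_are_ordered(self, roundtrip_cohort):
        for _, _, records in roundtrip_cohort[:3]:
            for r in records:
                if r.n_markers:
                    assert r.len_min <= r.len_mid <= r.len_max

    def test_missing_flank_clamps_to_chromosome_end(self):
        r = self.build([100, 500], [1000, 2000, 3000], chrom_length=5000)
        assert r.clamped
        assert r.len_max == 1000 - 0 - 1


class TestInferDeterminism:
    def test_repeated_inference_is_identical(self, genome_map):
        octad, _ = oc.simulate_meiosis(genome_map, oc.SimParams(), seed=77)
        a = oc.events_to_frame(infer_events(octad, genome_map))
        b = oc.events_to_frame(infer_events(octad, genome_map))
        assert a.equals(b)

    def test_low_depth_missingness_creates_no_phantom_crossovers(self, small_map):
        params = oc.SimParams(chrom_lengths={"chr1": 10_000},
                              nco_rate=0.0, mean_inter_co=1e12)
        octad, _ = oc.simulate_meiosis(small_map, params, seed=5)
        counts = oc.emit_read_counts(octad, depth=18.0, error_rate=0.0, seed=6)
        called = oc.call_matrix(counts)
        assert (called.calls == 0).mean() > 0.05  # depth low enough to matter
        recs = infer_events(called, small_map)
        assert all(r.kind != "CO" for r in recs)
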