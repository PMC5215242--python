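import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import octarec as oc

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome_map():
    """Full-genome marker map at the default hybrid density."""
    return oc.build_snp_map(oc.SACCER_CHROM_LENGTHS, seed=1)


@pytest.fixture
def small_map():
    """One 10 kb chromosome with a marker every 100 bp."""
    return oc.build_snp_map({"chr1": 10_000}, mode="fixed", pitch=100)


def make_octad(snp_map, backgrounds=(1, 1, 2, 2)):
    """Octad whose every spore is a clean homoduplex of its background."""
    n = snp_map.n_markers
    calls = np.empty((n, 8), dtype=np.int8)
    for s, bg in enumerate(backgrounds):
        calls[:, 2 * s] = bg
        calls[:, 2 * s + 1] = bg
    return oc.OctadMatrix(snp_map.frame[["chrom", "pos"]].reset_index(drop=True),
                          calls)


def map_from_positions(positions, chrom="chr1"):
    return oc.SNPMap(pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "allele_p1": "A", "allele_p2": "G"}))


def interval_gap(a, b):
    """bp gap between two true events' intervals (0 when they overlap)."""
    if a.chrom != b.chrom:
        return float("inf")
    return max(b.start_bp - a.end_bp, a.start_bp - b.end_bp, 0)


def overlaps(rec, ev):
    return (rec.chrom == ev.chrom and rec.start_bp <= ev.end_bp
            and ev.start_bp <= rec.end_bp)


@pytest.fixture(scope="session")
def roundtrip_cohort(genome_map):
    """20 simulated meioses at default study conditions, sequenced at 70X
    with no errors, genotyped and event-called — with their ground truths."""
    cohort = []
    for k in range(20):
        octad, truth = oc.simulate_meiosis(genome_map, oc.SimParams(),
                                           seed=100 + k)
        counts = oc.emit_read_counts(octad, depth=70.0, error_rate=0.0,
                                     seed=5000 + k)
        called = oc.call_matrix(counts)
        records = oc.infer_events(called, genome_map,
                                  chrom_lengths=oc.SACCER_CHROM_LENGTHS)
        cohort.append((called, truth, records))
    return cohort
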