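"""Recombination event inference from an 8-strand genotype matrix.

Pipeline per chromosome:

1. ``segregation_profile`` — per-marker P1:P2 segregation bookkeeping.
2. ``infer_phase_background`` — per spore, segment the chromosome into
   parental phase blocks from runs of concordant homoduplex markers.  Block
   boundaries are candidate crossover (CO) points; short interior runs are
   candidate conversion tracts, not phase switches.  A demoted run whose two
   boundaries both find reciprocal-direction switches on other spores is
   re-promoted to a genuine double switch (close double CO).
3. ``detect_raw_tracts`` — maximal runs of markers deviating from the
   background phase (heteroduplex, opposite homoduplex, or discordant
   half-calls), bridging short uninformative stretches.
4. ``merge_events`` — single-linkage clustering of tracts and CO points
   separated by less than ``merge_gap_bp``; each cluster is attributed to one
   initiating double-strand break.
5. ``classify_event`` / ``tract_length`` — CO/NCO typing, heteroduplex
   sub-classification, and tract lengths under min/mid/max conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .octad import CALL_MISSING, OctadMatrix
from .snpmap import SNPMap

__all__ = [
    "InferenceConfig", "PhaseSwitch", "COPair", "Tract", "EventRecord",
    "ChromPhase", "segregation_profile", "infer_phase_background",
    "detect_raw_tracts", "pair_crossover_switches", "merge_events",
    "classify_event", "tract_length", "infer_events", "events_to_frame",
]

EVENT_COLUMNS = ["chrom", "start", "end", "event_id", "type", "category",
                 "spores", "len_min", "len_mid", "len_max", "n_markers", "co_pos"]


@dataclass(frozen=True)
class InferenceConfig:
    merge_gap_bp: int = 1500          # events closer than this share one DSB
    max_missing_run: int = 2          # uninformative markers bridged inside a tract
    min_markers_per_tract: int = 1
    phase_block_min_bp: int = 20_000  # interior homoduplex runs shorter than this
                                      # are candidate tracts, not phase switches
    co_pair_max_bp: int = 20_000      # max separation of the two reciprocal
                                      # switches of one CO (conversion tract scale)

    def __post_init__(self) -> None:
        if self.merge_gap_bp <= 0:
            raise ValueError("merge_gap_bp must be > 0")
        if self.max_missing_run < 0 or self.min_markers_per_tract < 1:
            raise ValueError("invalid bridging/tract-size configuration")


@dataclass
class PhaseSwitch:
    """A parental phase switch of one spore between two flanking markers."""

    spore: int
    left_idx: int      # marker index of last homoduplex marker before the switch
    right_idx: int     # marker index of first homoduplex marker after it
    phase_from: int
    phase_to: int
    pos_left: int
    pos_right: int

    @property
    def mid(self) -> float:
        return 0.5 * (self.pos_left + self.pos_right)


@dataclass
class COPair:
    """Two reciprocal phase switches forming one crossover.

    The two junctions may sit apart by the length of the CO-associated
    conversion tract; the markers between them are the transferred zone.
    """

    a: "PhaseSwitch"
    b: "PhaseSwitch"

    @property
    def mid(self) -> float:
        return 0.5 * (self.a.mid + self.b.mid)


@dataclass
class Tract:
    """A candidate strand-transfer tract on one spore."""

    spore: int
    marker_idx: np.ndarray          # affected (deviating) marker indices
    donor_strand: np.ndarray        # per affected marker: 0 = strand a, 1 = b,
                                    # 2 = both strands carry the donor allele
    donor_allele: np.ndarray        # per affected marker: donated parental allele


@dataclass
class ChromPhase:
    """Phase backgrounds of all four spores along one chromosome."""

    background: np.ndarray          # (M, 4) int8: 1/2 phase, 0 ambiguous
    switches: list[PhaseSwitch]
    uncallable: list[int]           # spores with no informative homoduplex marker
    concordant: np.ndarray          # (M, 4) bool: homoduplex matching background


@dataclass
class EventRecord:
    chrom: str
    start_bp: int                   # first affected position (1-based, inclusive)
    end_bp: int
    kind: str                       # "CO" | "NCO"
    category: str
    spores: tuple[int, ...]
    n_markers: int
    len_min: float
    len_mid: float
    len_max: float
    co_pos: float | None = None
    first_idx: int = -1
    last_idx: int = -1
    tracts: list[Tract] = field(default_factory=list, repr=False)
    switches: list[PhaseSwitch] = field(default_factory=list, repr=False)
    clamped: bool = False           # a flank ran off the callable chromosome


# ---------------------------------------------------------------------------


def _rle(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values: (start, end inclusive, value)."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(values) - 1]))
    return [(int(s), int(e), int(values[s])) for s, e in zip(starts, ends)]


def segregation_profile(octad: OctadMatrix) -> pd.DataFrame:
    """Per-marker segregation counts over called strands.

    A marker is Mendelian when it segregates exactly 4 P1 : 4 P2 with no
    missing strand; any deviation or missingness marks it as a candidate.
    """
    calls = octad.calls
    n_p1 = (calls == 1).sum(axis=1)
    n_p2 = (calls == 2).sum(axis=1)
    n_missing = (calls == CALL_MISSING).sum(axis=1)
    out = octad.index[["chrom", "pos"]].copy()
    out["n_p1"] = n_p1
    out["n_p2"] = n_p2
    out["n_missing"] = n_missing
    out["mendelian"] = (n_p1 == 4) & (n_p2 == 4) & (n_missing == 0)
    return out


# -- phase background -------------------------------------------------------


def _spore_runs(calls: np.ndarray, spore: int):
    """Homoduplex marker indices and phases for one spore."""
    a = calls[:, 2 * spore]
    b = calls[:, 2 * spore + 1]
    homo = (a == b) & (a > 0)
    idx = np.flatnonzero(homo)
    return idx, a[idx]


def _phase_one_chrom(pos: np.ndarray, calls: np.ndarray,
                     cfg: InferenceConfig) -> ChromPhase:
    m = len(pos)
    background = np.zeros((m, 4), dtype=np.int8)
    concordant = np.zeros((m, 4), dtype=bool)
    uncallable: list[int] = []

    # per spore: homoduplex runs.  Anchors are terminal runs (a boundary at
    # the telomere is a genuine switch candidate) and interior runs spanning
    # at least phase_block_min_bp; everything between anchors starts as a
    # candidate tract and is resolved by the confirmed-junction walk below.
    spore_runs: list[list[dict]] = []
    spore_anchors: list[list[int]] = []
    for s in range(4):
        idx, phases = _spore_runs(calls, s)
        if len(idx) == 0:
            uncallable.append(s)
            spore_runs.append([])
            spore_anchors.append([])
            continue
        runs = []
        for r0, r1, ph in _rle(phases):
            i0, i1 = int(idx[r0]), int(idx[r1])
            runs.append({"i0": i0, "i1": i1, "phase": ph,
                         "span": int(pos[i1] - pos[i0]),
                         "n_mk": r1 - r0 + 1, "block": False})
        anchors = [k for k in range(len(runs))
                   if k in (0, len(runs) - 1)
                   or runs[k]["span"] >= cfg.phase_block_min_bp]
        for k in anchors:
            runs[k]["block"] = True
        spore_runs.append(runs)
        spore_anchors.append(anchors)

    # candidate boundaries for the reciprocity pass: block boundaries plus
    # the would-be boundaries of demoted runs
    def boundaries(s: int) -> list[dict]:
        out = []
        runs = spore_runs[s]
        prev_run = None
        for r in runs:
            if prev_run is not None:
                out.append({
                    "spore": s,
                    "from": prev_run["phase"], "to": r["phase"],
                    "lo": int(pos[prev_run["i1"]]), "hi": int(pos[r["i0"]]),
                    "l_idx": prev_run["i1"], "r_idx": r["i0"],
                })
            prev_run = r
        return out

    all_bounds = [b for s in range(4) for b in boundaries(s)]
    aberrant = _aberrant_markers(calls)

    def has_reciprocal(s: int, ph_from: int, ph_to: int,
                       lo: int, hi: int, l_idx: int, r_idx: int) -> bool:
        # partner junctions can be displaced by their own conversion tract,
        # so the match tolerance is the CO-pairing scale, not the merge gap;
        # but every marker between the two junctions must then lie in the
        # transferred zone, otherwise the boundaries mirror by coincidence
        tol = cfg.co_pair_max_bp
        for b in all_bounds:
            if b["spore"] == s:
                continue
            if b["from"] == ph_to and b["to"] == ph_from:
                if b["lo"] - tol <= hi and lo <= b["hi"] + tol:
                    z_lo = min(r_idx, b["r_idx"])
                    z_hi = max(l_idx, b["l_idx"])
                    if z_lo > z_hi or aberrant[z_lo:z_hi + 1].mean() >= 0.9:
                        return True
        return False

    # confirmed-junction walk: within each anchor gap, accept boundaries as
    # phase switches when a reciprocal-direction boundary exists on another
    # spore (tolerance co_pair_max_bp, transferred-zone validated).  Runs
    # between accepted junctions are blocks when they match the walking
    # phase, candidate tracts otherwise.  If the walk ends on the wrong
    # phase for the right anchor, one unconfirmed switch remains: place it
    # at the cut minimising phase-inconsistent markers.
    for s in range(4):
        runs = spore_runs[s]
        for ai, aj in zip(spore_anchors[s][:-1], spore_anchors[s][1:]):
            if aj - ai < 2:
                continue
            walk = runs[ai]["phase"]
            seg_start = ai + 1
            for k in range(ai + 1, aj + 1):
                prev, cur = runs[k - 1], runs[k]
                if (k != aj and prev["phase"] == walk
                        and cur["phase"] == 3 - walk
                        and has_reciprocal(s, walk, 3 - walk,
                                           int(pos[prev["i1"]]),
                                           int(pos[cur["i0"]]),
                                           prev["i1"], cur["i0"])):
                    for r in range(seg_start, k):
                        runs[r]["block"] = runs[r]["phase"] == walk
                    walk = 3 - walk
                    seg_start = k
            # final segment: one more (unconfirmed) switch iff the right
            # anchor's phase differs from the walking phase
            interior = list(range(seg_start, aj))
            p_right = runs[aj]["phase"]
            if walk == p_right:
                for r in interior:
                    runs[r]["block"] = runs[r]["phase"] == walk
            else:
                best_c, best_cost = 0, None
                for c in range(len(interior) + 1):
                    cost = sum(runs[k]["n_mk"] for k in interior[:c]
                               if runs[k]["phase"] != walk)
                    cost += sum(runs[k]["n_mk"] for k in interior[c:]
                                if runs[k]["phase"] != p_right)
                    if best_cost is None or cost < best_cost:
                        best_c, best_cost = c, cost
                for pos_k, k in enumerate(interior):
                    side = walk if pos_k < best_c else p_right
                    runs[k]["block"] = runs[k]["phase"] == side

    # final blocks: consecutive block-runs of the same phase merge, absorbing
    # demoted deviations in between; switches sit between blocks of differing phase
    switches: list[PhaseSwitch] = []
    for s in range(4):
        runs = [r for r in spore_runs[s] if r["block"]]
        if not runs:
            continue
        merged: list[dict] = []
        for r in runs:
            if merged and merged[-1]["phase"] == r["phase"]:
                merged[-1]["i1"] = r["i1"]
            else:
                merged.append({"i0": r["i0"], "i1": r["i1"], "phase": r["phase"]})
        # background: block phase, extended to chromosome ends; ambiguous
        # (phase 0) strictly between blocks of different phase
        for j, blk in enumerate(merged):
            lo = 0 if j == 0 else blk["i0"]
            hi = m - 1 if j == len(merged) - 1 else blk["i1"]
            background[lo:hi + 1, s] = blk["phase"]
            if j > 0:
                prev = merged[j - 1]
                switches.append(PhaseSwitch(
                    spore=s, left_idx=prev["i1"], right_idx=blk["i0"],
                    phase_from=prev["phase"], phase_to=blk["phase"],
                    pos_left=int(pos[prev["i1"]]), pos_right=int(pos[blk["i0"]])))
        a = calls[:, 2 * s]
        b = calls[:, 2 * s + 1]
        concordant[:, s] = (a == b) & (a > 0) & (a == background[:, s])
    return ChromPhase(background=background, switches=switches,
                      uncallable=uncallable, concordant=concordant)


def infer_phase_background(octad: OctadMatrix,
                           cfg: InferenceConfig | None = None) -> dict[str, ChromPhase]:
    """Per-chromosome parental phase backgrounds for all four spores."""
    cfg = cfg or InferenceConfig()
    return {chrom: _phase_one_chrom(pos, calls, cfg)
            for chrom, pos, calls in octad.by_chrom()}


# -- tract detection --------------------------------------------------------


def _marker_classes(calls: np.ndarray, phase: ChromPhase, spore: int):
    """Classify each marker for one spore: deviating / concordant / uninformative.

    Deviating: heteroduplex, opposite homoduplex, or a half-call discordant
    with the background.  Uninformative (bridgeable): fully missing, or a
    half-call consistent with the background, or any non-homoduplex marker in
    an ambiguous-background zone.
    """
    a = calls[:, 2 * spore]
    b = calls[:, 2 * spore + 1]
    bg = phase.background[:, spore]
    het = (a > 0) & (b > 0) & (a != b)
    homo = (a == b) & (a > 0)
    partial = (a > 0) ^ (b > 0)
    called = np.where(a > 0, a, b)
    dev = het | (homo & (bg > 0) & (a != bg)) | (partial & (bg > 0) & (called != bg))
    conc = homo & (bg > 0) & (a == bg)
    return dev, conc, a, b, bg


def detect_raw_tracts(octad_calls: np.ndarray, pos: np.ndarray,
                      phase: ChromPhase, cfg: InferenceConfig) -> list[Tract]:
    """Maximal deviating runs per spore, bridging short uninformative stretches."""
    tracts: list[Tract] = []
    for s in range(4):
        if s in phase.uncallable:
            continue
        dev, conc, a, b, bg = _marker_classes(octad_calls, phase, s)
        dev_idx = np.flatnonzero(dev)
        if len(dev_idx) == 0:
            continue
        # reference phase where the background is ambiguous: nearest block
        # phase to the left (fallback right) so a donor strand is defined
        ref = bg.astype(np.int16).copy()
        for i in range(1, len(ref)):
            if ref[i] == 0:
                ref[i] = ref[i - 1]
        for i in range(len(ref) - 2, -1, -1):
            if ref[i] == 0:
                ref[i] = ref[i + 1]

        runs: list[list[int]] = [[int(dev_idx[0])]]
        for prev, cur in zip(dev_idx[:-1], dev_idx[1:]):
            between = slice(prev + 1, cur)
            n_between = cur - prev - 1
            if n_between <= cfg.max_missing_run and not conc[between].any():
                runs[-1].append(int(cur))
            else:
                runs.append([int(cur)])
        for run in runs:
            idx = np.asarray(run, dtype=np.int64)
            if len(idx) < cfg.min_markers_per_tract:
                continue
            donor_strand = np.empty(len(idx), dtype=np.int8)
            donor_allele = np.empty(len(idx), dtype=np.int8)
            for j, i in enumerate(idx):
                ref_ph = ref[i] if ref[i] > 0 else 1
                if a[i] > 0 and b[i] > 0 and a[i] != b[i]:          # heteroduplex
                    donor_strand[j] = 0 if a[i] != ref_ph else 1
                    donor_allele[j] = a[i] if a[i] != ref_ph else b[i]
                elif a[i] == b[i] and a[i] > 0:                     # opposite homo
                    donor_strand[j] = 2
                    donor_allele[j] = a[i]
                else:                                               # discordant half-call
                    donor_strand[j] = 0 if a[i] > 0 else 1
                    donor_allele[j] = a[i] if a[i] > 0 else b[i]
            tracts.append(Tract(spore=s, marker_idx=idx,
                                donor_strand=donor_strand,
                                donor_allele=donor_allele))
    return tracts


# -- merging and classification ---------------------------------------------


def _aberrant_markers(calls: np.ndarray) -> np.ndarray:
    """Markers that are not a clean 4:4 homoduplex octad (any heteroduplex,
    half-call, missing strand or non-Mendelian segregation)."""
    a = calls[:, 0::2]
    b = calls[:, 1::2]
    homo = (a == b) & (a > 0)
    n_p1 = ((calls == 1).sum(axis=1))
    return ~(homo.all(axis=1) & (n_p1 == 4))


def pair_crossover_switches(switches: Sequence[PhaseSwitch], max_gap_bp: int,
                            calls: np.ndarray | None = None,
                            ) -> tuple[list[COPair], list[PhaseSwitch]]:
    """Greedy nearest-first pairing of reciprocal-direction switches.

    Two switches pair when they sit on different spores, have opposite
    directions and their midpoints are within ``max_gap_bp`` (one CO's two
    junctions straddle at most its conversion tract).  When the junctions do
    not coincide, every marker between them must lie in the transferred zone
    (aberrant segregation or heteroduplex); two unrelated events whose
    boundaries happen to mirror each other leave Mendelian markers in between
    and are rejected.  Returns the pairs and the leftover lone switches.
    """
    aberrant = _aberrant_markers(calls) if calls is not None else None

    def valid(si: PhaseSwitch, sj: PhaseSwitch) -> bool:
        if aberrant is None:
            return True
        lo = min(si.right_idx, sj.right_idx)
        hi = max(si.left_idx, sj.left_idx)
        if lo > hi:
            return True
        inner = aberrant[lo:hi + 1]
        return inner.mean() >= 0.9

    cands = []
    for i, si in enumerate(switches):
        for j in range(i + 1, len(switches)):
            sj = switches[j]
            if (si.spore != sj.spore and si.phase_from == sj.phase_to
                    and si.phase_to == sj.phase_from
                    and abs(si.mid - sj.mid) <= max_gap_bp
                    and valid(si, sj)):
                cands.append((abs(si.mid - sj.mid), i, j))
    cands.sort()
    used: set[int] = set()
    pairs: list[COPair] = []
    for _, i, j in cands:
        if i in used or j in used:
            continue
        pairs.append(COPair(switches[i], switches[j]))
        used.update((i, j))
    lone = [s for k, s in enumerate(switches) if k not in used]
    return pairs, lone


def _item_interval(item, pos: np.ndarray) -> tuple[int, int]:
    if isinstance(item, Tract):
        return int(pos[item.marker_idx[0]]), int(pos[item.marker_idx[-1]])
    if isinstance(item, COPair):
        return (int(min(item.a.mid, item.b.mid)), int(max(item.a.mid, item.b.mid)))
    return int(item.pos_left), int(item.pos_right)


def merge_events(items: Sequence[Tract | PhaseSwitch], pos: np.ndarray,
                 cfg: InferenceConfig) -> list[list[Tract | PhaseSwitch]]:
    """Single-linkage clustering of tracts and CO points along one chromosome.

    Items whose bp gap (between nearest affected markers) is strictly less
    than ``merge_gap_bp`` join the same cluster — one initiating DSB.
    Idempotent and independent of input order.
    """
    if not items:
        return []
    ordered = sorted(items, key=lambda it: _item_interval(it, pos))
    clusters: list[list] = [[ordered[0]]]
    cur_end = _item_interval(ordered[0], pos)[1]
    for it in ordered[1:]:
        lo, hi = _item_interval(it, pos)
        if lo - cur_end < cfg.merge_gap_bp:
            clusters[-1].append(it)
        else:
            clusters.append([it])
        cur_end = max(cur_end, hi)
    return clusters


def _reciprocal_pairs(switches: list[PhaseSwitch]) -> list[tuple[PhaseSwitch, PhaseSwitch]]:
    pairs = []
    used: set[int] = set()
    for i, si in enumerate(switches):
        if i in used:
            continue
        for j in range(i + 1, len(switches)):
            sj = switches[j]
            if j in used or sj.spore == si.spore:
                continue
            if si.phase_from == sj.phase_to and si.phase_to == sj.phase_from:
                pairs.append((si, sj))
                used.update((i, j))
                break
    return pairs


def classify_event(cluster: Sequence[Tract | PhaseSwitch], octad_calls: np.ndarray,
                   phase: ChromPhase) -> tuple[str, str]:
    """(type, category) of one merged cluster.

    Type is CO iff the cluster contains a reciprocal phase switch between two
    spores.  Category describes the strand-transfer pattern: 6:2 full
    conversion, single-strand SDSA-like hDNA, trans hDNA (donor strand
    switches sides once), symmetric hDNA (complementary tracts on two
    spores), else complex.
    """
    tracts = [t for t in cluster if isinstance(t, Tract)]
    pairs = [p for p in cluster if isinstance(p, COPair)]
    switches = [s for s in cluster if isinstance(s, PhaseSwitch)]
    kind = "CO" if pairs or _reciprocal_pairs(switches) else "NCO"

    if not tracts:
        category = "none" if not switches or kind == "CO" else "complex"
        return kind, category
    spores = sorted({t.spore for t in tracts})
    if len(spores) == 1:
        strands = np.concatenate([t.donor_strand for t in tracts])
        if (strands == 2).all():
            return kind, "full_conversion"
        if (strands == 2).any():
            return kind, "complex"
        changes = int((np.diff(strands) != 0).sum())
        if changes == 0:
            return kind, "SDSA_like_hDNA"
        if changes == 1:
            return kind, "trans_hDNA"
        return kind, "complex"
    if len(spores) == 2:
        by_spore = {s: [t for t in tracts if t.spore == s] for s in spores}
        if all(len(v) == 1 for v in by_spore.values()):
            t1, t2 = by_spore[spores[0]][0], by_spore[spores[1]][0]
            het = ((t1.donor_strand != 2).all() and (t2.donor_strand != 2).all())
            overlap = (t1.marker_idx[0] <= t2.marker_idx[-1]
                       and t2.marker_idx[0] <= t1.marker_idx[-1])
            complementary = (len(set(t1.donor_allele)) == 1
                             and len(set(t2.donor_allele)) == 1
                             and t1.donor_allele[0] != t2.donor_allele[0])
            if het and overlap and complementary:
                return kind, "symmetric_hDNA"
        return kind, "complex"
    return kind, "complex"


def _affected_markers(cluster, pos: np.ndarray) -> np.ndarray:
    """Union of tract markers plus markers inside reciprocal switch intervals
    (the transferred zone of a CO whose conversion tract matches the flanking
    phase and is therefore absorbed into a block)."""
    idx: set[int] = set()
    for t in cluster:
        if isinstance(t, Tract):
            idx.update(int(i) for i in t.marker_idx)
    lone = [s for s in cluster if isinstance(s, PhaseSwitch)]
    pairs = [(p.a, p.b) for p in cluster if isinstance(p, COPair)]
    pairs += _reciprocal_pairs(lone)
    for sa, sb in pairs:
        lo = min(sa.right_idx, sb.right_idx)
        hi = max(sa.left_idx, sb.left_idx)
        idx.update(range(lo, hi + 1))
    return np.asarray(sorted(idx), dtype=np.int64)


def tract_length(first_idx: int, last_idx: int, pos: np.ndarray,
                 involved: Iterable[int], phase: ChromPhase,
                 convention: str = "mid",
                 chrom_length: int | None = None) -> tuple[float, bool]:
    """Tract length in bp under one convention.

    min: span of affected markers.  mid: distance between midpoints of the
    two flanking affected<->unaffected marker intervals.  max: distance
    between flanking unaffected markers, exclusive.  Flanks with no
    concordant marker clamp to the chromosome end (flagged).
    """
    if convention not in ("min", "mid", "max"):
        raise ValueError(f"unknown length convention {convention!r}")
    involved = [s for s in involved if s not in phase.uncallable]
    conc_all = (phase.concordant[:, involved].all(axis=1) if involved
                else np.ones(len(pos), dtype=bool))
    clamped = False
    left = next((i for i in range(first_idx - 1, -1, -1) if conc_all[i]), None)
    right = next((i for i in range(last_idx + 1, len(pos)) if conc_all[i]), None)
    p_first, p_last = float(pos[first_idx]), float(pos[last_idx])
    if left is None:
        prev_pos, clamped = 0.0, True
    else:
        prev_pos = float(pos[left])
    if right is None:
        clamped = True
        next_pos = float(chrom_length + 1 if chrom_length else pos[-1] + 1)
    else:
        next_pos = float(pos[right])
    if convention == "min":
        return p_last - p_first + 1.0, clamped
    if convention == "max":
        return next_pos - prev_pos - 1.0, clamped
    return 0.5 * (p_last + next_pos) - 0.5 * (p_first + prev_pos), clamped


def _build_record(chrom: str, cluster, pos: np.ndarray, phase: ChromPhase,
                  octad_calls: np.ndarray,
                  chrom_length: int | None) -> EventRecord:
    kind, category = classify_event(cluster, octad_calls, phase)
    tracts = [t for t in cluster if isinstance(t, Tract)]
    lone = [s for s in cluster if isinstance(s, PhaseSwitch)]
    switches = lone + [s for p in cluster if isinstance(p, COPair)
                       for s in (p.a, p.b)]
    spores = tuple(sorted({t.spore for t in tracts} | {s.spore for s in switches}))
    affected = _affected_markers(cluster, pos)
    pairs = [(p.a, p.b) for p in cluster if isinstance(p, COPair)]
    pairs += _reciprocal_pairs(lone)
    co_pos = float(np.mean([0.5 * (a.mid + b.mid) for a, b in pairs])) if pairs else None

    if len(affected):
        first_idx, last_idx = int(affected[0]), int(affected[-1])
        lens = {}
        clamped = False
        for conv in ("min", "mid", "max"):
            lens[conv], cl = tract_length(first_idx, last_idx, pos, spores,
                                          phase, conv, chrom_length)
            clamped |= cl
        start_bp, end_bp = int(pos[first_idx]), int(pos[last_idx])
    else:
        first_idx = last_idx = -1
        lens = {"min": float("nan"), "mid": float("nan"), "max": float("nan")}
        clamped = False
        if switches:
            # a CO between two markers: localized to the flanking-marker interval
            start_bp = int(min(s.pos_left for s in switches))
            end_bp = int(max(s.pos_right for s in switches))
        else:
            start_bp = end_bp = int(pos[0]) if len(pos) else 0
    return EventRecord(
        chrom=chrom, start_bp=start_bp, end_bp=end_bp, kind=kind,
        category=category, spores=spores, n_markers=len(affected),
        len_min=lens["min"], len_mid=lens["mid"], len_max=lens["max"],
        co_pos=co_pos, first_idx=first_idx, last_idx=last_idx,
        tracts=tracts, switches=switches, clamped=clamped)


def infer_events(octad: OctadMatrix, snp_map: SNPMap | None = None,
                 cfg: InferenceConfig | None = None,
                 chrom_lengths: Mapping[str, int] | None = None) -> list[EventRecord]:
    """Full deterministic composition: profile -> phase -> tracts -> merge ->
    classify -> lengths.  Output sorted by (chrom, start)."""
    cfg = cfg or InferenceConfig()
    records: list[EventRecord] = []
    for chrom, pos, calls in octad.by_chrom():
        phase = _phase_one_chrom(pos, calls, cfg)
        tracts = detect_raw_tracts(calls, pos, phase, cfg)
        pairs, lone = pair_crossover_switches(phase.switches, cfg.co_pair_max_bp,
                                              calls)
        clusters = merge_events([*tracts, *pairs, *lone], pos, cfg)
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        for cluster in clusters:
            records.append(_build_record(chrom, cluster, pos, phase, calls, length))
    chrom_order = {c: i for i, c in enumerate(octad.chroms)}
    records.sort(key=lambda r: (chrom_order[r.chrom], r.start_bp))
    return records


def events_to_frame(records: Sequence[EventRecord]) -> pd.DataFrame:
    """BED-flavoured events table: 0-based half-open intervals."""
    rows = [{
        "chrom": r.chrom, "start": r.start_bp - 1, "end": r.end_bp,
        "event_id": i, "type": r.kind, "category": r.category,
        "spores": ",".join(str(s + 1) for s in r.spores),
        "len_min": r.len_min, "len_mid": r.len_mid, "len_max": r.len_max,
        "n_markers": r.n_markers,
        "co_pos": -1.0 if r.co_pos is None else r.co_pos,
    } for i, r in enumerate(records)]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
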