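"""Strand-resolved simulation of a polymorphic hybrid meiosis.

The generator emulates the experimental design of octad sequencing in an
msh2-deficient S288C x SK1-like hybrid: crossovers (COs) are placed by a
stationary gamma-renewal process (shape > 1 = positive interference),
noncrossovers (NCOs) by a Poisson process, and every event writes a strand
transfer tract onto the recipient chromatid.  With mismatch repair inactive
(msh2, the study condition) heteroduplex DNA persists and is visible as 5:3
segregation between the two daughter strands of a spore; with repair active
tracts resolve to full conversion (6:2) or silent restoration.

Ground truth is recorded event by event so downstream genotype calling and
event inference can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .octad import CALL_P1, CALL_P2, OctadMatrix, ReadCountTable, STRANDS
from .snpmap import SACCER_CHROM_LENGTHS, SNPMap

__all__ = [
    "TractLengthModel", "SimParams", "StrandSegment", "TrueEvent",
    "GroundTruth", "place_crossovers", "simulate_meiosis",
    "emit_read_counts", "octad_calls_from_truth", "STRAIN_PRESETS",
]


@dataclass(frozen=True)
class TractLengthModel:
    """Distribution of conversion/hDNA tract lengths in bp.

    Families: ``geometric`` (params: median_bp), ``constant`` (length_bp),
    ``lognormal`` (median_bp, sigma).  The paper-scale anchor is a median
    around 1 kb for wild type; the family itself is a configurable stand-in
    since only medians are known.
    """

    name: str = "geometric"
    params: Mapping[str, float] = field(default_factory=lambda: {"median_bp": 1000.0})

    def __post_init__(self) -> None:
        if self.name == "geometric":
            if self.params.get("median_bp", 0) <= 0:
                raise ValueError("geometric tract model requires median_bp > 0")
        elif self.name == "constant":
            if self.params.get("length_bp", 0) <= 0:
                raise ValueError("constant tract model requires length_bp > 0")
        elif self.name == "lognormal":
            if self.params.get("median_bp", 0) <= 0 or self.params.get("sigma", 0) <= 0:
                raise ValueError("lognormal tract model requires median_bp, sigma > 0")
        else:
            raise ValueError(f"unknown tract length model {self.name!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name == "geometric":
            p = 1.0 - 0.5 ** (1.0 / float(self.params["median_bp"]))
            return rng.geometric(p, size=n).astype(np.int64)
        if self.name == "constant":
            return np.full(n, int(self.params["length_bp"]), dtype=np.int64)
        mu = np.log(float(self.params["median_bp"]))
        out = rng.lognormal(mu, float(self.params["sigma"]), size=n)
        return np.maximum(1, np.round(out)).astype(np.int64)


@dataclass(frozen=True)
class SimParams:
    """Generative conditions of one simulated meiosis (one genotype).

    Defaults emulate the wild-type msh2 hybrid study conditions: ~75k markers
    at R64 genome scale, CO interference shape 2.3, CO tract median 1.0 kb and
    NCO tract median 0.8 kb, mismatch repair inactive so hDNA persists.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(SACCER_CHROM_LENGTHS))
    gamma_shape_sim: float = 2.3
    mean_inter_co: float = 130_000.0
    nco_rate: float = 5.8e-6
    tract_len_dist_co: TractLengthModel = field(
        default_factory=lambda: TractLengthModel("geometric", {"median_bp": 1000.0}))
    tract_len_dist_nco: TractLengthModel = field(
        default_factory=lambda: TractLengthModel("geometric", {"median_bp": 800.0}))
    # symmetric heteroduplexes are rare and short; this default reproduces
    # their observed mean length of ~560 bp at the default marker density
    tract_len_dist_sym: TractLengthModel = field(
        default_factory=lambda: TractLengthModel("geometric", {"median_bp": 280.0}))
    p_full_conversion: float = 0.15
    p_trans_hdna: float = 0.25
    # drawn per NCO tract; targets the ~2.8 symmetric events per wild-type
    # meiosis observed genome-wide (11 events over 4 meioses)
    p_sym_hdna: float = 0.04
    mmr_active: bool = False
    p_conversion_vs_restoration: float = 0.5
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.gamma_shape_sim <= 0:
            raise ValueError("gamma_shape_sim must be > 0")
        if self.mean_inter_co <= 0:
            raise ValueError("mean_inter_co must be > 0")
        if self.nco_rate < 0:
            raise ValueError("nco_rate must be >= 0")
        for p in (self.p_full_conversion, self.p_trans_hdna, self.p_sym_hdna,
                  self.p_conversion_vs_restoration):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.p_full_conversion + self.p_trans_hdna + self.p_sym_hdna > 1.0:
            raise ValueError("category probabilities sum above 1")


#: Study-condition presets per strain: interference shape and tract medians
#: (CO / NCO, bp) as reported genome-wide, and how many meioses were sequenced.
STRAIN_PRESETS: dict[str, dict] = {
    "WT": {"gamma_shape_sim": 2.3, "co_median_bp": 1000.0,
           "nco_median_bp": 800.0, "n_meioses": 4},
    "mlh2": {"gamma_shape_sim": 2.5, "co_median_bp": 2100.0,
             "nco_median_bp": 2300.0, "n_meioses": 2},
    "mer3R893E": {"gamma_shape_sim": 1.9, "co_median_bp": 2300.0,
                  "nco_median_bp": 1700.0, "n_meioses": 2},
}


def params_for_strain(name: str, **overrides) -> SimParams:
    """SimParams preset for a named strain (WT, mlh2, mer3R893E)."""
    preset = STRAIN_PRESETS[name]
    base = SimParams(
        gamma_shape_sim=preset["gamma_shape_sim"],
        tract_len_dist_co=TractLengthModel("geometric",
                                           {"median_bp": preset["co_median_bp"]}),
        tract_len_dist_nco=TractLengthModel("geometric",
                                            {"median_bp": preset["nco_median_bp"]}),
    )
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class StrandSegment:
    """One written strand transfer: strand label, bp interval, donor allele."""

    strand: str
    start_bp: int
    end_bp: int
    allele: int  # CALL_P1 or CALL_P2


@dataclass
class TrueEvent:
    chrom: str
    start_bp: int
    end_bp: int
    kind: str              # "CO" | "NCO"
    category: str          # full_conversion | SDSA_like_hDNA | trans_hDNA |
                           # symmetric_hDNA | restoration | none
    spores: tuple[int, ...]
    co_pos: int | None
    segments: list[StrandSegment]
    n_markers: int

    @property
    def detectable(self) -> bool:
        """Visible to a marker-based caller: any CO, or an NCO covering >=1 marker."""
        return self.kind == "CO" or self.n_markers >= 1


@dataclass
class GroundTruth:
    """Complete event log of one simulated meiosis.

    ``backgrounds`` maps chrom -> parental origin (1/2) of each spore's
    chromatid before any exchange; ``co_exchanges`` maps chrom -> ordered
    list of (pos, spore_a, spore_b) reciprocal flank exchanges.  Together
    with ``events`` these reproduce the emitted octad exactly
    (see :func:`octad_calls_from_truth`).
    """

    events: list[TrueEvent]
    backgrounds: dict[str, np.ndarray]
    co_exchanges: dict[str, list[tuple[int, int, int]]]
    collisions: int = 0

    def events_frame(self) -> pd.DataFrame:
        rows = [{
            "chrom": e.chrom, "start": e.start_bp - 1, "end": e.end_bp,
            "type": e.kind, "category": e.category,
            "spores": ",".join(str(s + 1) for s in e.spores),
            "co_pos": -1 if e.co_pos is None else e.co_pos,
            "n_markers": e.n_markers,
        } for e in self.events]
        cols = ["chrom", "start", "end", "type", "category", "spores",
                "co_pos", "n_markers"]
        return pd.DataFrame(rows, columns=cols)


def place_crossovers(
    chrom_length: float,
    gamma_shape_sim: float,
    mean_inter_co: float,
    seed_or_rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """CO positions from a stationary gamma-renewal process on (0, L).

    The first event is drawn from the equilibrium forward-recurrence
    distribution (uniform fraction of a length-biased gap, i.e.
    gamma(shape+1, scale)); subsequent gaps are i.i.d. gamma(shape,
    scale=mean/shape).  shape = 1 reduces to a Poisson process (no
    interference); shape > 1 gives more evenly spaced COs.
    """
    if gamma_shape_sim <= 0 or mean_inter_co <= 0:
        raise ValueError("shape and mean inter-CO distance must be > 0")
    if chrom_length < 0:
        raise ValueError("chromosome length must be >= 0")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    scale = mean_inter_co / gamma_shape_sim
    out: list[float] = []
    t = rng.uniform() * rng.gamma(gamma_shape_sim + 1.0, scale)
    while t < chrom_length:
        out.append(t)
        t += rng.gamma(gamma_shape_sim, scale)
    return np.asarray(out, dtype=float)


def _draw_category(rng: np.random.Generator, params: SimParams, allow_sym: bool) -> str:
    u = rng.uniform()
    p_sym = params.p_sym_hdna if allow_sym else 0.0
    if u < p_sym:
        return "symmetric_hDNA"
    u -= p_sym
    if u < params.p_full_conversion:
        return "full_conversion"
    u -= params.p_full_conversion
    if u < params.p_trans_hdna:
        return "trans_hDNA"
    return "SDSA_like_hDNA"


class _ChromSim:
    """Builds one chromosome of the octad: background phases, exchanges, tracts."""

    def __init__(self, chrom: str, length: int, pos: np.ndarray,
                 params: SimParams, rng: np.random.Generator):
        self.chrom = chrom
        self.length = length
        self.pos = pos
        self.params = params
        self.rng = rng
        # chromatid backgrounds: a random 2:2 assignment of parents to spores
        parents = np.array([1, 1, 2, 2], dtype=np.int8)
        rng.shuffle(parents)
        self.background0 = parents
        self.bg = np.repeat(parents[None, :], len(pos), axis=0)  # (M, 4)
        self.calls = None  # built after exchanges
        self.exchanges: list[tuple[int, int, int]] = []
        # per-spore blocked bp intervals (tracts + switch points)
        self.blocked: list[list[tuple[int, int]]] = [[] for _ in range(4)]
        self.events: list[TrueEvent] = []
        self.collisions = 0

    # -- crossover flank exchange ------------------------------------------
    def apply_exchanges(self, co_positions: np.ndarray) -> list[tuple[int, int, int]]:
        for x in np.sort(co_positions):
            x = int(x)
            if not 1 <= x < self.length:
                continue
            # interhomolog: pick one chromatid of each local parental phase
            loc = np.searchsorted(self.pos, x, side="right")
            col = self.bg[loc] if loc < len(self.pos) else self.background0
            if loc >= len(self.pos):
                col = self.bg[-1] if len(self.pos) else self.background0
            p1_spores = np.flatnonzero(col == 1)
            p2_spores = np.flatnonzero(col == 2)
            if len(p1_spores) == 0 or len(p2_spores) == 0:
                continue
            sa = int(self.rng.choice(p1_spores))
            sb = int(self.rng.choice(p2_spores))
            mask = self.pos > x
            tmp = self.bg[mask, sa].copy()
            self.bg[mask, sa] = self.bg[mask, sb]
            self.bg[mask, sb] = tmp
            self.exchanges.append((x, sa, sb))
            self.blocked[sa].append((x, x))
            self.blocked[sb].append((x, x))
        return self.exchanges

    def init_calls(self) -> None:
        m = len(self.pos)
        self.calls = np.empty((m, 8), dtype=np.int8)
        for s in range(4):
            self.calls[:, 2 * s] = self.bg[:, s]
            self.calls[:, 2 * s + 1] = self.bg[:, s]

    # -- helpers -----------------------------------------------------------
    def _overlaps_blocked(self, spore: int, start: int, end: int) -> bool:
        return any(not (end < a or start > b) for a, b in self.blocked[spore])

    def _local_bg_constant(self, spore: int, start: int, end: int) -> int | None:
        """Background parent of `spore` over [start, end] bp, or None if it varies."""
        lo = np.searchsorted(self.pos, start, side="left")
        hi = np.searchsorted(self.pos, end, side="right")
        vals = self.bg[lo:hi, spore]
        if len(vals) == 0:
            # no markers inside: take phase at nearest position
            ref = self.bg[min(lo, len(self.pos) - 1), spore] if len(self.pos) else \
                self.background0[spore]
            return int(ref)
        u = np.unique(vals)
        return int(u[0]) if len(u) == 1 else None

    def _markers_in(self, start: int, end: int) -> np.ndarray:
        lo = np.searchsorted(self.pos, start, side="left")
        hi = np.searchsorted(self.pos, end, side="right")
        return np.arange(lo, hi)

    def _write(self, strand_col: int, start: int, end: int, allele: int) -> StrandSegment:
        idx = self._markers_in(start, end)
        self.calls[idx, strand_col] = allele
        return StrandSegment(STRANDS[strand_col], start, end, allele)

    # -- tract placement ---------------------------------------------------
    def _build_segments(self, spore: int, start: int, end: int, donor: int,
                        category: str) -> tuple[str, list[StrandSegment], tuple[int, ...]]:
        """Write a tract of the drawn category; returns realized category,
        segments and involved spores (category degrades when geometry cannot
        realize it, e.g. a trans tract with markers on one side only)."""
        rng = self.rng
        base = 2 * spore
        markers = self._markers_in(start, end)
        if category == "full_conversion":
            segs = [self._write(base, start, end, donor),
                    self._write(base + 1, start, end, donor)]
            return "full_conversion", segs, (spore,)
        if category == "trans_hDNA" and end > start and len(markers) >= 2:
            split = int(rng.integers(start, end))  # in [start, end)
            left_m = self._markers_in(start, split)
            right_m = self._markers_in(split + 1, end)
            if len(left_m) >= 1 and len(right_m) >= 1:
                first = int(rng.integers(0, 2))
                segs = [self._write(base + first, start, split, donor),
                        self._write(base + 1 - first, split + 1, end, donor)]
                return "trans_hDNA", segs, (spore,)
        if category == "symmetric_hDNA":
            partner = self._pick_symmetric_partner(spore, start, end, donor)
            if partner is not None:
                pbase = 2 * partner
                recip_allele = 3 - donor  # this spore's own background allele
                segs = [
                    self._write(base + int(rng.integers(0, 2)), start, end, donor),
                    self._write(pbase + int(rng.integers(0, 2)), start, end,
                                recip_allele),
                ]
                self.blocked[partner].append((start, end))
                return "symmetric_hDNA", segs, tuple(sorted((spore, partner)))
        # default / fallback: SDSA-like single-strand hDNA
        strand = base + int(rng.integers(0, 2))
        segs = [self._write(strand, start, end, donor)]
        return "SDSA_like_hDNA", segs, (spore,)

    def _pick_symmetric_partner(self, spore: int, start: int, end: int,
                                donor: int) -> int | None:
        candidates = []
        for t in range(4):
            if t == spore:
                continue
            bg_t = self._local_bg_constant(t, start, end)
            if bg_t == donor and not self._overlaps_blocked(t, start, end):
                candidates.append(t)
        if not candidates:
            return None
        return int(self.rng.choice(candidates))

    def place_tract(self, kind: str, anchor: int,
                    co_partners: tuple[int, int] | None) -> None:
        """Place one event's tract with redraw-on-collision.

        COs keep their renewal position; only the tract category, length and
        strand choices are redrawn.  NCOs redraw position as well.
        """
        params, rng = self.params, self.rng
        for _ in range(params.max_redraws):
            # mismatch-repair branch: hDNA corrected to conversion or restoration
            if params.mmr_active:
                if rng.uniform() < params.p_conversion_vs_restoration:
                    category = "full_conversion"
                else:
                    category = "restoration"
            else:
                # symmetric hDNA is a net-4:4 pattern: only NCO tracts can
                # present it; CO tracts draw among the asymmetric categories
                category = _draw_category(rng, params, allow_sym=(kind == "NCO"))
            if category == "symmetric_hDNA":
                model = params.tract_len_dist_sym
            elif kind == "CO":
                model = params.tract_len_dist_co
            else:
                model = params.tract_len_dist_nco
            length = int(model.sample(rng, 1)[0])
            if kind == "CO":
                x = anchor
                recipient = int(rng.choice(co_partners))
                start, end = x + 1, min(x + length, self.length)
            else:
                x = int(rng.integers(1, self.length + 1))
                recipient = int(rng.integers(0, 4))
                start, end = x, min(x + length - 1, self.length)
            if start > end:
                self.collisions += 1
                continue
            bg_local = self._local_bg_constant(recipient, start, end)
            if bg_local is None or self._overlaps_blocked(recipient, start, end):
                self.collisions += 1
                continue
            donor = 3 - bg_local
            if category == "restoration":
                self._record(kind, x, start, end, "restoration", (recipient,),
                             co_partners, [])
                return
            realized, segs, spores = self._build_segments(
                recipient, start, end, donor, category)
            self.blocked[recipient].append((start, end))
            self._record(kind, x, start, end, realized, spores, co_partners, segs)
            return
        # retry cap exhausted: CO keeps its exchange without a tract, NCO dropped
        self.collisions += 1
        if kind == "CO":
            self._record("CO", anchor, anchor + 1, anchor,
                         "none", (), co_partners, [])

    def _record(self, kind: str, x: int, start: int, end: int, category: str,
                spores: tuple[int, ...], co_partners: tuple[int, int] | None,
                segs: list[StrandSegment]) -> None:
        n_markers = sum(len(self._markers_in(s.start_bp, s.end_bp)) for s in segs)
        if segs:
            seg_lo = min(s.start_bp for s in segs)
            seg_hi = max(s.end_bp for s in segs)
        else:
            seg_lo, seg_hi = start, max(start, end)
        if kind == "CO":
            ev_start, ev_end = min(x, seg_lo), max(x, seg_hi)
            all_spores = tuple(sorted(set(spores) | set(co_partners or ())))
            co_pos = x
        else:
            ev_start, ev_end = seg_lo, seg_hi
            all_spores, co_pos = spores, None
        self.events.append(TrueEvent(
            chrom=self.chrom, start_bp=ev_start, end_bp=ev_end, kind=kind,
            category=category, spores=all_spores, co_pos=co_pos,
            segments=segs, n_markers=n_markers))


def simulate_meiosis(
    snp_map: SNPMap,
    params: SimParams,
    seed: int | None = None,
) -> tuple[OctadMatrix, GroundTruth]:
    """Simulate one meiosis over `snp_map` and return the octad plus its log.

    One root seed; per-chromosome child streams are derived deterministically
    so chromosome order does not couple random streams.
    """
    root = np.random.SeedSequence(seed)
    chroms = [c for c in params.chrom_lengths if c in set(snp_map.frame["chrom"])] \
        or list(params.chrom_lengths)
    children = root.spawn(len(params.chrom_lengths))
    child_by_chrom = dict(zip(params.chrom_lengths, children))

    frames: list[pd.DataFrame] = []
    call_blocks: list[np.ndarray] = []
    events: list[TrueEvent] = []
    backgrounds: dict[str, np.ndarray] = {}
    exchanges: dict[str, list[tuple[int, int, int]]] = {}
    collisions = 0

    for chrom in params.chrom_lengths:
        length = int(params.chrom_lengths[chrom])
        sub = snp_map.frame[snp_map.frame["chrom"] == chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        rng = np.random.default_rng(child_by_chrom[chrom])
        sim = _ChromSim(chrom, length, pos, params, rng)

        co_pos = place_crossovers(length, params.gamma_shape_sim,
                                  params.mean_inter_co, rng)
        co_pos = np.unique(co_pos.astype(np.int64))
        co_pos = co_pos[(co_pos >= 1) & (co_pos < length)]
        applied = sim.apply_exchanges(co_pos)
        sim.init_calls()

        for x, sa, sb in applied:
            sim.place_tract("CO", x, (sa, sb))

        n_nco = int(rng.poisson(params.nco_rate * length))
        for _ in range(n_nco):
            sim.place_tract("NCO", 0, None)

        frames.append(sub[["chrom", "pos"]])
        call_blocks.append(sim.calls)
        events.extend(sorted(sim.events, key=lambda e: e.start_bp))
        backgrounds[chrom] = sim.background0
        exchanges[chrom] = sim.exchanges
        collisions += sim.collisions

    index = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["chrom", "pos"]))
    calls = (np.vstack(call_blocks) if call_blocks
             else np.empty((0, 8), dtype=np.int8))
    octad = OctadMatrix(index, calls)
    truth = GroundTruth(events=events, backgrounds=backgrounds,
                        co_exchanges=exchanges, collisions=collisions)
    return octad, truth


def octad_calls_from_truth(truth: GroundTruth, snp_map: SNPMap) -> np.ndarray:
    """Re-derive the (M, 8) call matrix from the ground-truth log alone.

    Independent replay used to check simulator bookkeeping: initial 2:2
    backgrounds, then reciprocal flank exchanges left to right, then every
    recorded strand segment.
    """
    strand_col = {name: j for j, name in enumerate(STRANDS)}
    blocks: list[np.ndarray] = []
    for chrom in truth.backgrounds:
        pos = snp_map.positions(chrom)
        bg = np.repeat(truth.backgrounds[chrom][None, :], len(pos), axis=0).copy()
        for x, sa, sb in truth.co_exchanges[chrom]:
            mask = pos > x
            tmp = bg[mask, sa].copy()
            bg[mask, sa] = bg[mask, sb]
            bg[mask, sb] = tmp
        calls = np.empty((len(pos), 8), dtype=np.int8)
        for s in range(4):
            calls[:, 2 * s] = bg[:, s]
            calls[:, 2 * s + 1] = bg[:, s]
        for ev in truth.events:
            if ev.chrom != chrom:
                continue
            for seg in ev.segments:
                lo = np.searchsorted(pos, seg.start_bp, side="left")
                hi = np.searchsorted(pos, seg.end_bp, side="right")
                calls[lo:hi, strand_col[seg.strand]] = seg.allele
        blocks.append(calls)
    return np.vstack(blocks) if blocks else np.empty((0, 8), dtype=np.int8)


def emit_read_counts(
    octad: OctadMatrix,
    depth: float = 70.0,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> ReadCountTable:
    """Poisson sequencing of each strand library at the given mean depth.

    Each read reports the strand's true allele with probability
    1 - error_rate; markers with a missing genotype yield zero reads.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    calls = octad.calls
    total = rng.poisson(depth, size=calls.shape).astype(np.int64)
    total[calls == 0] = 0
    correct = rng.binomial(total, 1.0 - error_rate)
    n_p1 = np.where(calls == CALL_P1, correct, total - correct)
    n_p1[calls == 0] = 0
    n_p2 = total - n_p1
    n_p2[calls == 0] = 0
    return ReadCountTable(octad.index.copy(), n_p1, n_p2)
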