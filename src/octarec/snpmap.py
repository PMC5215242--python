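"""Biallelic SNP maps of a polymorphic hybrid genome.

A :class:`SNPMap` holds the ordered list of markers that distinguish the two
parental genomes of a hybrid (e.g. S288C x SK1 in budding yeast).  Every
downstream stage — genotype calling, strand-transfer detection, tract-length
measurement — is expressed in the coordinates of this map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SNPMap",
    "build_snp_map",
    "SACCER_CHROM_LENGTHS",
    "DEFAULT_SNP_DENSITY",
]

#: R64-1-1 S. cerevisiae nuclear chromosome lengths (bp), chrI..chrXVI.
SACCER_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218,
    "chrII": 813184,
    "chrIII": 316620,
    "chrIV": 1531933,
    "chrV": 576874,
    "chrVI": 270161,
    "chrVII": 1090940,
    "chrVIII": 562643,
    "chrIX": 439888,
    "chrX": 745751,
    "chrXI": 666816,
    "chrXII": 1078177,
    "chrXIII": 924431,
    "chrXIV": 784333,
    "chrXV": 1091291,
    "chrXVI": 948066,
}

_GENOME_BP = sum(SACCER_CHROM_LENGTHS.values())  # 12,071,326 bp

#: Default marker density (markers/bp): the 74,911-SNP S288C x SK1 map spread
#: over the 12.07 Mb nuclear genome.
DEFAULT_SNP_DENSITY: float = 74911 / _GENOME_BP

_ALLELE_PAIRS = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                          ("A", "C"), ("G", "T")], dtype=object)


@dataclass(frozen=True)
class SNPMap:
    """Ordered biallelic markers: chrom, 1-based pos, parental alleles.

    Invariants (checked on construction): positions strictly increasing
    within each chromosome; the two parental alleles differ at every marker.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "allele_p1", "allele_p2"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"SNP map missing columns: {missing}")
        df = self.frame
        if len(df):
            if (df["allele_p1"].astype(str) == df["allele_p2"].astype(str)).any():
                raise ValueError("parental alleles must differ at every marker")
            for chrom, sub in df.groupby("chrom", sort=False):
                pos = sub["pos"].to_numpy()
                if len(pos) > 1 and not (np.diff(pos) > 0).all():
                    raise ValueError(
                        f"positions not strictly increasing on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.frame[self.frame["chrom"] == chrom]
        return sub["pos"].to_numpy(dtype=np.int64)

    def subset(self, chrom: str) -> "SNPMap":
        return SNPMap(self.frame[self.frame["chrom"] == chrom].reset_index(drop=True))


def build_snp_map(
    chrom_lengths: Mapping[str, int],
    snp_density: float = DEFAULT_SNP_DENSITY,
    seed: int | None = None,
    mode: str = "uniform",
    pitch: int | None = None,
) -> SNPMap:
    """Sample a marker map over a genome.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp.
    snp_density
        Expected markers per bp (``uniform`` mode).  The default reproduces
        the genome-wide scale of the 74,911-marker hybrid map.
    mode
        ``"uniform"``: marker count per chromosome ~ Poisson(L * density),
        positions uniform without replacement.  ``"fixed"``: markers at
        ``pitch, 2*pitch, ...`` (requires ``pitch``).
    """
    if snp_density < 0:
        raise ValueError("snp_density must be >= 0")
    for chrom, length in chrom_lengths.items():
        if length < 0:
            raise ValueError(f"negative length for {chrom}")
    rng = np.random.default_rng(seed)
    rows: list[pd.DataFrame] = []
    for chrom, length in chrom_lengths.items():
        if mode == "fixed":
            if pitch is None or pitch <= 0:
                raise ValueError("fixed mode requires positive pitch")
            pos = np.arange(pitch, length + 1, pitch, dtype=np.int64)
        elif mode == "uniform":
            n = min(int(rng.poisson(length * snp_density)), length)
            pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if len(pos) == 0:
            continue
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=len(pos))
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "allele_p1": _ALLELE_PAIRS[pair_idx, 0],
            "allele_p2": _ALLELE_PAIRS[pair_idx, 1],
        }))
    if rows:
        frame = pd.concat(rows, ignore_index=True)
    else:
        frame = pd.DataFrame(columns=["chrom", "pos", "allele_p1", "allele_p2"])
    return SNPMap(frame)
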