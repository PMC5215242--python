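"""Core containers: 8-strand genotype matrices and per-strand read counts.

An octad is the set of 8 DNA strands of one meiosis: each of the 4 spores is
allowed one mitotic division and both daughter cells are sequenced, so the
two strands of every spore's chromatid are recovered separately.  Heteroduplex
DNA (hDNA) is visible as the two daughters of one spore carrying different
parental alleles (5:3 marker segregation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .snpmap import SNPMap

__all__ = [
    "CALL_MISSING", "CALL_P1", "CALL_P2",
    "STRANDS", "OctadMatrix", "ReadCountTable",
]

CALL_MISSING: int = 0
CALL_P1: int = 1
CALL_P2: int = 2

#: Strand library labels: spore i, daughter cell a/b.
STRANDS: tuple[str, ...] = ("s1a", "s1b", "s2a", "s2b", "s3a", "s3b", "s4a", "s4b")

_CALL_TO_STR = {CALL_MISSING: "NA", CALL_P1: "P1", CALL_P2: "P2"}
_STR_TO_CALL = {v: k for k, v in _CALL_TO_STR.items()}


@dataclass
class OctadMatrix:
    """Per-marker genotype calls for the 8 strands of one meiosis.

    ``index`` holds (chrom, pos) per marker; ``calls`` is an int8 array of
    shape (n_markers, 8) with values in {0 missing, 1 P1, 2 P2}, columns in
    :data:`STRANDS` order (spore i = columns 2i, 2i+1).
    """

    index: pd.DataFrame = field(repr=False)
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.calls.ndim != 2 or self.calls.shape[1] != 8:
            raise ValueError("octad requires exactly 8 strand columns")
        if len(self.index) != self.calls.shape[0]:
            raise ValueError("index/calls length mismatch")
        bad = ~np.isin(self.calls, [CALL_MISSING, CALL_P1, CALL_P2])
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2} (NA, P1, P2)")
        self.calls = self.calls.astype(np.int8)

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.index["chrom"]))

    def by_chrom(self):
        """Yield (chrom, positions, calls-slice) per chromosome."""
        chrom_arr = self.index["chrom"].to_numpy()
        pos_arr = self.index["pos"].to_numpy(dtype=np.int64)
        for chrom in self.chroms:
            mask = chrom_arr == chrom
            yield chrom, pos_arr[mask], self.calls[mask]

    def to_frame(self) -> pd.DataFrame:
        df = self.index[["chrom", "pos"]].copy()
        for j, name in enumerate(STRANDS):
            df[name] = [_CALL_TO_STR[int(v)] for v in self.calls[:, j]]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OctadMatrix":
        missing = [c for c in ("chrom", "pos", *STRANDS) if c not in df.columns]
        if missing:
            raise ValueError(f"octad frame missing columns: {missing}")
        calls = np.empty((len(df), 8), dtype=np.int8)
        for j, name in enumerate(STRANDS):
            col = df[name].astype(str)
            unknown = ~col.isin(_STR_TO_CALL)
            if unknown.any():
                row = int(np.flatnonzero(unknown.to_numpy())[0])
                raise ValueError(
                    f"invalid call {col.iloc[row]!r} in column {name}, data row {row + 1}")
            calls[:, j] = col.map(_STR_TO_CALL).to_numpy()
        return cls(df[["chrom", "pos"]].reset_index(drop=True), calls)


@dataclass
class ReadCountTable:
    """Per-marker, per-strand-library counts of reads supporting each allele.

    Array-backed: ``n_p1`` and ``n_p2`` have shape (n_markers, 8).
    """

    index: pd.DataFrame = field(repr=False)
    n_p1: np.ndarray = field(repr=False)
    n_p2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for arr in (self.n_p1, self.n_p2):
            if arr.shape != (len(self.index), 8):
                raise ValueError("count arrays must be (n_markers, 8)")
            if (arr < 0).any():
                raise ValueError("read counts must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.index)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (marker, strand library)."""
        n = len(self.index)
        return pd.DataFrame({
            "chrom": np.repeat(self.index["chrom"].to_numpy(), 8),
            "pos": np.repeat(self.index["pos"].to_numpy(), 8),
            "strand": np.tile(np.array(STRANDS), n),
            "n_p1": self.n_p1.reshape(-1),
            "n_p2": self.n_p2.reshape(-1),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, snp_map: SNPMap | None = None) -> "ReadCountTable":
        required = ["chrom", "pos", "strand", "n_p1", "n_p2"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"read-count frame missing columns: {missing}")
        strands = set(df["strand"].unique())
        if strands != set(STRANDS):
            raise ValueError(
                f"expected exactly 8 strand libraries {STRANDS}, got {sorted(strands)}")
        wide = df.pivot_table(index=["chrom", "pos"], columns="strand",
                              values=["n_p1", "n_p2"], sort=False)
        index = wide.index.to_frame(index=False)
        n_p1 = wide["n_p1"][list(STRANDS)].to_numpy(dtype=np.int64)
        n_p2 = wide["n_p2"][list(STRANDS)].to_numpy(dtype=np.int64)
        return cls(index, n_p1, n_p2)


def spore_of(strand_col: int) -> int:
    """Spore id (0..3) owning strand column 0..7."""
    return strand_col // 2
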