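"""Read-count genotype calling for octad strand libraries.

A SNP genotype for one strand library is accepted only under the read-count
validity rule used for the hybrid octad data: either all reads support a
single parental allele and their count lies within [mono_min, mono_max], or
reads of both types are present but the majority count lies within
[duo_major_min, duo_major_max] while the minority count is below
duo_minor_lt.  Anything else — including ties — is treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .octad import CALL_MISSING, CALL_P1, CALL_P2, OctadMatrix, ReadCountTable, STRANDS

__all__ = ["GenotypeCallConfig", "call_genotype", "call_matrix"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeCallConfig:
    """Validity thresholds, all in read counts.

    Defaults: single-type reads valid in [15, 150]; two-type reads valid when
    the majority lies in [40, 150] and the minority is strictly below 5.
    Bounds are inclusive ("between") and the minority bound strict ("below"),
    both read plainly; flip them here if an alternative reading is wanted.
    """

    mono_min: int = 15
    mono_max: int = 150
    duo_major_min: int = 40
    duo_major_max: int = 150
    duo_minor_lt: int = 5

    def __post_init__(self) -> None:
        if self.mono_min > self.mono_max:
            raise ValueError("mono_min must be <= mono_max")
        if self.duo_major_min > self.duo_major_max:
            raise ValueError("duo_major_min must be <= duo_major_max")
        if self.duo_minor_lt < 1:
            raise ValueError("duo_minor_lt must be >= 1")


_DEFAULT = GenotypeCallConfig()


def call_genotype(n_p1: int, n_p2: int,
                  cfg: GenotypeCallConfig = _DEFAULT) -> int:
    """Call one (marker, strand library) from its two allele counts.

    Returns CALL_P1, CALL_P2 or CALL_MISSING.  Ties with reads of both types
    have no majority allele and are missing.
    """
    if n_p1 < 0 or n_p2 < 0:
        raise ValueError("read counts must be non-negative")
    if n_p1 > 0 and n_p2 == 0:
        return CALL_P1 if cfg.mono_min <= n_p1 <= cfg.mono_max else CALL_MISSING
    if n_p2 > 0 and n_p1 == 0:
        return CALL_P2 if cfg.mono_min <= n_p2 <= cfg.mono_max else CALL_MISSING
    if n_p1 > 0 and n_p2 > 0 and n_p1 != n_p2:
        major, minor = (n_p1, n_p2) if n_p1 > n_p2 else (n_p2, n_p1)
        if cfg.duo_major_min <= major <= cfg.duo_major_max and minor < cfg.duo_minor_lt:
            return CALL_P1 if n_p1 > n_p2 else CALL_P2
    return CALL_MISSING


def call_matrix(table: ReadCountTable,
                cfg: GenotypeCallConfig = _DEFAULT) -> OctadMatrix:
    """Vectorised element-wise genotype calling over all 8 strand libraries."""
    n1 = np.asarray(table.n_p1, dtype=np.int64)
    n2 = np.asarray(table.n_p2, dtype=np.int64)
    if n1.shape[1] != 8:
        raise ValueError("read-count table must cover exactly 8 strand libraries")
    if (n1 < 0).any() or (n2 < 0).any():
        raise ValueError("read counts must be non-negative")

    calls = np.full(n1.shape, CALL_MISSING, dtype=np.int8)

    mono1 = (n1 > 0) & (n2 == 0) & (n1 >= cfg.mono_min) & (n1 <= cfg.mono_max)
    mono2 = (n2 > 0) & (n1 == 0) & (n2 >= cfg.mono_min) & (n2 <= cfg.mono_max)
    both = (n1 > 0) & (n2 > 0) & (n1 != n2)
    major = np.maximum(n1, n2)
    minor = np.minimum(n1, n2)
    duo = both & (major >= cfg.duo_major_min) & (major <= cfg.duo_major_max) \
        & (minor < cfg.duo_minor_lt)
    calls[mono1 | (duo & (n1 > n2))] = CALL_P1
    calls[mono2 | (duo & (n2 > n1))] = CALL_P2

    miss_rate = (calls == CALL_MISSING).mean(axis=0) if len(calls) else np.zeros(8)
    for name, r in zip(STRANDS, miss_rate):
        logger.info("strand %s: %.4f missing", name, r)
    return OctadMatrix(table.index.copy(), calls)
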