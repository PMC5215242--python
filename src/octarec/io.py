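"""TSV/JSON/YAML formats for maps, octads, counts, events and summaries.

All tables are tab-separated with a header row.  SNP map and octad positions
are 1-based; event intervals are written BED-flavoured (0-based, half-open).
Malformed rows are reported with their 1-based data line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .events import EVENT_COLUMNS, EventRecord, events_to_frame
from .octad import OctadMatrix, ReadCountTable, STRANDS
from .snpmap import SNPMap

__all__ = [
    "read_snp_map", "write_snp_map", "read_octad", "write_octad",
    "read_counts", "write_counts", "read_events", "write_events",
    "write_summary", "read_config", "read_counts_from_vcfs",
]


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _check_sorted_unique(df: pd.DataFrame, path) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if len(pos) > 1:
            d = np.diff(pos)
            if (d <= 0).any():
                row = int(sub.index[int(np.flatnonzero(d <= 0)[0]) + 1]) + 1
                raise ValueError(
                    f"{path}: duplicate or unsorted position on {chrom}, data line {row}")


def read_snp_map(path) -> SNPMap:
    df = _read_tsv(path, ["chrom", "pos", "allele_p1", "allele_p2"])
    _check_sorted_unique(df, path)
    return SNPMap(df)


def write_snp_map(path, snp_map: SNPMap) -> None:
    snp_map.frame.to_csv(path, sep="\t", index=False)


def read_octad(path) -> OctadMatrix:
    df = _read_tsv(path, ["chrom", "pos", *STRANDS])
    extra = [c for c in df.columns if c.startswith("s") and c not in STRANDS]
    if extra:
        raise ValueError(f"{path}: unexpected strand columns {extra}")
    _check_sorted_unique(df, path)
    try:
        return OctadMatrix.from_frame(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_octad(path, octad: OctadMatrix) -> None:
    octad.to_frame().to_csv(path, sep="\t", index=False)


def read_counts(path) -> ReadCountTable:
    df = _read_tsv(path, ["chrom", "pos", "strand", "n_p1", "n_p2"])
    if (df[["n_p1", "n_p2"]] < 0).to_numpy().any():
        bad = df[(df["n_p1"] < 0) | (df["n_p2"] < 0)].index[0] + 1
        raise ValueError(f"{path}: negative count, data line {bad}")
    try:
        return ReadCountTable.from_frame(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_counts(path, table: ReadCountTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    return _read_tsv(path, EVENT_COLUMNS)


def write_events(path, events: Sequence[EventRecord] | pd.DataFrame,
                 extra_cols: dict | None = None) -> None:
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if extra_cols:
        df = df.assign(**extra_cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.1f")


def write_summary(path, summary: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(summary, indent=2, default=_default,
                                     sort_keys=True) + "\n")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def read_counts_from_vcfs(paths: Sequence, snp_map: SNPMap) -> ReadCountTable:
    """Import shim: 8 single-sample VCFs (one per strand library, in
    :data:`STRANDS` order) with AD allele-depth fields -> ReadCountTable.

    Only records at SNP-map positions whose REF/ALT match the parental
    alleles are used; others contribute zero counts (missing).
    Plain-text VCF only.
    """
    if len(paths) != 8:
        raise ValueError("expected exactly 8 single-sample VCFs")
    key = {(c, int(p)): i for i, (c, p) in
           enumerate(zip(snp_map.frame["chrom"], snp_map.frame["pos"]))}
    a1 = snp_map.frame["allele_p1"].astype(str).to_numpy()
    a2 = snp_map.frame["allele_p2"].astype(str).to_numpy()
    n = snp_map.n_markers
    n_p1 = np.zeros((n, 8), dtype=np.int64)
    n_p2 = np.zeros((n, 8), dtype=np.int64)
    for j, path in enumerate(paths):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 10:
                    continue
                chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], \
                    fields[3], fields[4].split(",")[0]
                i = key.get((chrom, pos))
                if i is None:
                    continue
                fmt = fields[8].split(":")
                if "AD" not in fmt:
                    continue
                ad = fields[9].split(":")[fmt.index("AD")].split(",")
                try:
                    d_ref, d_alt = int(ad[0]), int(ad[1])
                except (ValueError, IndexError):
                    continue
                if ref == a1[i] and alt == a2[i]:
                    n_p1[i, j], n_p2[i, j] = d_ref, d_alt
                elif ref == a2[i] and alt == a1[i]:
                    n_p1[i, j], n_p2[i, j] = d_alt, d_ref
    return ReadCountTable(snp_map.frame[["chrom", "pos"]].reset_index(drop=True),
                          n_p1, n_p2)
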