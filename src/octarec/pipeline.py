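"""End-to-end pipeline: simulate -> sequence -> call -> infer -> summarise.

Every run is deterministic given its root seed and records all thresholds
actually applied in a machine-readable run log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .events import InferenceConfig, events_to_frame, infer_events
from .genotyping import GenotypeCallConfig, call_matrix
from .io import (read_counts, read_octad, read_snp_map, write_events,
                 write_octad, write_snp_map, write_summary)
from .simulate import (SimParams, TractLengthModel, emit_read_counts,
                       params_for_strain, simulate_meiosis)
from .snpmap import SACCER_CHROM_LENGTHS, SNPMap, build_snp_map
from .stats import fit_gamma_by_genotype, summarize

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "sim_params_from_dict"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass
class RunConfig:
    out_dir: str = "octarec_out"
    seed: int = 0
    # simulate mode: genotype name -> {n_meioses, sim params overrides}
    genotypes: dict = field(default_factory=lambda: {"WT": {"n_meioses": 1}})
    snp_map_path: str | None = None      # reuse an existing map instead of sampling
    depth: float = 70.0
    error_rate: float = 0.0
    call: GenotypeCallConfig = field(default_factory=GenotypeCallConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    convention: str = "mid"
    write_octads: bool = True


def sim_params_from_dict(d: dict) -> SimParams:
    """Build SimParams from a plain config mapping (YAML-friendly)."""
    d = dict(d)
    d.pop("n_meioses", None)
    strain = d.pop("strain", None)
    for key in ("tract_len_dist_co", "tract_len_dist_nco"):
        if key in d and isinstance(d[key], dict):
            d[key] = TractLengthModel(**d[key])
    if strain:
        return params_for_strain(strain, **d)
    return SimParams(**d)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write artifacts under ``config.out_dir``.

    Returns a dict with the events table, summary, gamma fits and paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed) % (2 ** 31)

    # -- snp map -----------------------------------------------------------
    if config.snp_map_path:
        snp_map = _stage("read_snp_map")(read_snp_map, config.snp_map_path)
    else:
        snp_map = _stage("build_snp_map")(
            build_snp_map, SACCER_CHROM_LENGTHS, seed=rng_seed)
        write_snp_map(out / "snp_map.tsv", snp_map)

    all_events: list[pd.DataFrame] = []
    truths = {}
    meiosis_counter = 0
    for gt_name, gt_cfg in config.genotypes.items():
        params = _stage("sim_params")(sim_params_from_dict,
                                      {"strain": gt_name, **gt_cfg}
                                      if gt_name in ("WT", "mlh2", "mer3R893E")
                                      else gt_cfg)
        n_meioses = int(gt_cfg.get("n_meioses", 1))
        for k in range(n_meioses):
            meiosis_id = f"{gt_name}_m{k + 1}"
            seed_k = (rng_seed + 1000003 * (meiosis_counter + 1)) % (2 ** 31)
            meiosis_counter += 1
            octad, truth = _stage("simulate")(
                simulate_meiosis, snp_map, params, seed=seed_k)
            counts = _stage("emit_read_counts")(
                emit_read_counts, octad, config.depth, config.error_rate,
                seed=seed_k + 1)
            called = _stage("call")(call_matrix, counts, config.call)
            records = _stage("infer")(
                infer_events, called, snp_map, config.inference,
                dict(params.chrom_lengths))
            df = events_to_frame(records)
            df["genotype"] = gt_name
            df["meiosis"] = meiosis_id
            all_events.append(df)
            truths[meiosis_id] = truth
            if config.write_octads:
                write_octad(out / f"octad_{meiosis_id}.tsv", called)

    events = (pd.concat(all_events, ignore_index=True) if all_events
              else events_to_frame([]))
    write_events(out / "events.tsv", events)

    summary = _stage("stats")(summarize, events, config.convention)
    gamma = fit_gamma_by_genotype(events)
    summary_dict = {
        "convention": config.convention,
        "tract_lengths": summary.tract_table,
        "event_counts": summary.count_table,
        "symmetric_hdna": summary.symmetric_table,
        "gamma_fits": {gt: {"shape": round(f.shape, 1), "scale": f.scale,
                            "loglik": f.loglik, "n_gaps": f.n_gaps}
                       for gt, f in gamma.items()},
    }
    write_summary(out / "summary.json", summary_dict)

    log = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "depth": config.depth,
        "error_rate": config.error_rate,
        "genotype_call": asdict(config.call),
        "inference": asdict(config.inference),
        "convention": config.convention,
        "n_markers": snp_map.n_markers,
        "genotypes": {k: {kk: vv for kk, vv in v.items()}
                      for k, v in config.genotypes.items()},
        "collisions": {m: t.collisions for m, t in truths.items()},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    return {"snp_map": snp_map, "events": events, "summary": summary_dict,
            "gamma": gamma, "truths": truths, "out_dir": str(out)}


def call_pipeline(counts_path: str, snp_map_path: str, out_path: str,
                  cfg: GenotypeCallConfig | None = None) -> None:
    """`call` subcommand body: counts TSV -> octad TSV."""
    read_snp_map(snp_map_path)  # validates the map the counts refer to
    table = _stage("read_counts")(read_counts, counts_path)
    octad = _stage("call")(call_matrix, table, cfg or GenotypeCallConfig())
    write_octad(out_path, octad)


def infer_pipeline(octad_path: str, snp_map_path: str | None, out_path: str,
                   cfg: InferenceConfig | None = None) -> None:
    """`infer` subcommand body: octad TSV -> events TSV."""
    octad = _stage("read_octad")(read_octad, octad_path)
    snp_map = read_snp_map(snp_map_path) if snp_map_path else None
    records = _stage("infer")(infer_events, octad, snp_map,
                              cfg or InferenceConfig())
    write_events(out_path, records)
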