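"""Progressive ensemble-docking analysis over (program x frame x monomer)
score pools.

Three stages of increasing scope, each an EFO consensus search:

  1. per (program, frame, chain): models restricted to one monomer's
     columns — the best single score and the best consensus per cell,
     plus per-chain / per-frame / per-program / global mean EF 1% values;
  2. per (program, frame): models over the union of the frame's four
     monomers, admissible only if they span at least two different
     monomers (otherwise they duplicate stage 1);
  3. per program: models over all frames and monomers, admissible only if
     they span at least two different frames; the best model per size
     (2, 3, 4) is reported together with the best single column.

Programs are analyzed as separate pools and never mixed within one model.
All stage results are pure functions of (pools, config, seed): rerunning
with the same inputs reproduces byte-identical JSON reports.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .efo import (
    ConsensusModel,
    SearchConstraint,
    best_per_size,
    search_combinations,
)
from .enrichment import ef_of_values
from .score_data import ScoreTable, orient_scores, read_score_table

__all__ = ["CampaignConfig", "StageResult", "run_stage1", "run_stage2",
           "run_stage3", "load_campaign", "report_json"]

_SEED_MOD = 2**31


def _derive_seed(seed: int, *tokens) -> int:
    crc = zlib.crc32("|".join(map(str, tokens)).encode())
    return (seed * 1_000_003 + crc) % _SEED_MOD


@dataclass
class CampaignConfig:
    """One screening campaign: oriented score pools plus search settings."""

    pools: dict[str, ScoreTable]
    frames: list[str]
    chains: list[str]
    fraction: float = 0.01
    seed: int = 0
    beam_width: int = 50
    stage1_max_vars: int = 2
    stage2_max_vars: int = 4
    stage3_max_vars: int = 4
    opt_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pools:
            raise ValueError("campaign needs at least one score pool")
        ref = next(iter(self.pools.values()))
        for name, pool in self.pools.items():
            if set(pool.ligand_ids) != set(ref.ligand_ids):
                raise ValueError(f"pool {name!r} has a different ligand set")


def _cell_key(program: str, frame: str | None, chain: str | None) -> str:
    return f"{program}|{frame or '*'}|{chain or '*'}"


def _single_column_efs(
    table: ScoreTable, keys: Sequence[str], fraction: float
) -> dict[str, float]:
    X = table.matrix(keys)
    labels = table.labels
    out = {}
    for j, key in enumerate(keys):
        sd = np.nanstd(X[:, j])
        if not np.isfinite(sd) or sd == 0:
            continue
        out[key] = float(ef_of_values(X[:, j], labels, fraction))
    return out


@dataclass
class StageResult:
    """Cells plus the unweighted means recomputable from them."""

    stage: str
    fraction: float
    seed: int
    cells: dict[str, dict] = field(default_factory=dict)
    means: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def enc(obj):
            if isinstance(obj, ConsensusModel):
                return obj.to_dict()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "stage": self.stage,
            "fraction": self.fraction,
            "seed": self.seed,
            "cells": enc(self.cells),
            "means": enc(self.means),
        }


def compute_means(cells: Mapping[str, dict]) -> dict[str, dict]:
    """Unweighted arithmetic means of cell EFs, grouped four ways.

    Absent cells (no usable columns) are simply excluded.  Means are kept
    recomputable from the cells so reports can always be audited.
    """
    groups: dict[str, dict[str, dict[str, list[float]]]] = {
        "by_program": {}, "by_frame": {}, "by_chain": {}, "global": {}
    }

    def add(group: dict, key: str, kind: str, value: float | None) -> None:
        if value is None:
            return
        group.setdefault(key, {}).setdefault(kind, []).append(value)

    for cell_key, cell in cells.items():
        program, frame, chain = cell_key.split("|")
        for kind in ("best_single_ef", "best_efo_ef"):
            value = cell.get(kind)
            add(groups["by_program"], program, kind, value)
            if frame != "*":
                add(groups["by_frame"], frame, kind, value)
            if chain != "*":
                add(groups["by_chain"], chain, kind, value)
            add(groups["global"], "all", kind, value)

    return {
        gname: {
            key: {kind: float(np.mean(vals)) for kind, vals in kinds.items()}
            for key, kinds in sorted(group.items())
        }
        for gname, group in groups.items()
    }


def run_stage1(config: CampaignConfig) -> StageResult:
    """Best single score and best EFO model per (program, frame, chain)."""
    result = StageResult("per_monomer", config.fraction, config.seed)
    for program in sorted(config.pools):
        pool = config.pools[program]
        for frame in config.frames:
            for chain in config.chains:
                keys = [
                    m.key
                    for m in pool.columns
                    if m.frame == frame and m.chain == chain
                ]
                cell_key = _cell_key(program, frame, chain)
                if not keys:
                    result.cells[cell_key] = {"absent": True}
                    continue
                singles = _single_column_efs(pool, keys, config.fraction)
                if not singles:
                    result.cells[cell_key] = {"absent": True}
                    continue
                best_single = max(sorted(singles), key=lambda k: singles[k])
                constraint = SearchConstraint(
                    max_vars=min(config.stage1_max_vars, len(singles)),
                    allowed_columns=sorted(singles),
                )
                models = search_combinations(
                    pool,
                    constraint,
                    config.fraction,
                    _derive_seed(config.seed, "stage1", program, frame, chain),
                    config.beam_width,
                    **config.opt_kwargs,
                )
                best = models[0]
                result.cells[cell_key] = {
                    "best_single_column": best_single,
                    "best_single_ef": singles[best_single],
                    "best_efo_ef": best.ef_train,
                    "best_efo_model": best,
                }
    result.means = compute_means(result.cells)
    return result


def run_stage2(config: CampaignConfig) -> StageResult:
    """Per (program, frame) consensus over all chains, spanning >= 2 chains."""
    result = StageResult("per_frame", config.fraction, config.seed)
    for program in sorted(config.pools):
        pool = config.pools[program]
        for frame in config.frames:
            keys = [m.key for m in pool.columns if m.frame == frame]
            chains_here = {m.chain for m in pool.columns
                           if m.frame == frame and m.chain is not None}
            if len(chains_here) < 2:
                raise ValueError(
                    f"frame {frame!r} of pool {program!r} has "
                    f"{len(chains_here)} chain(s); stage 2 needs >= 2"
                )
            constraint = SearchConstraint(
                max_vars=config.stage2_max_vars,
                min_distinct_chains=2,
                allowed_columns=keys,
            )
            models = search_combinations(
                pool,
                constraint,
                config.fraction,
                _derive_seed(config.seed, "stage2", program, frame),
                config.beam_width,
                **config.opt_kwargs,
            )
            singles = _single_column_efs(pool, keys, config.fraction)
            best_single = max(sorted(singles), key=lambda k: singles[k])
            best = models[0]
            result.cells[_cell_key(program, frame, None)] = {
                "best_single_column": best_single,
                "best_single_ef": singles[best_single],
                "best_efo_ef": best.ef_train,
                "best_efo_model": best,
            }
    result.means = compute_means(result.cells)
    return result


def run_stage3(config: CampaignConfig) -> StageResult:
    """Per program consensus over all frames and chains, spanning >= 2 frames.

    Reports the best model per size in {2, 3, 4} plus the best single
    column for reference.
    """
    if len(config.frames) < 2:
        raise ValueError("stage 3 needs at least 2 configured frames")
    result = StageResult("all_frames", config.fraction, config.seed)
    for program in sorted(config.pools):
        pool = config.pools[program]
        keys = [m.key for m in pool.columns
                if m.frame in config.frames and m.chain in config.chains]
        constraint = SearchConstraint(
            max_vars=config.stage3_max_vars,
            min_distinct_frames=2,
            allowed_columns=keys,
        )
        models = search_combinations(
            pool,
            constraint,
            config.fraction,
            _derive_seed(config.seed, "stage3", program),
            config.beam_width,
            **config.opt_kwargs,
        )
        per_size = best_per_size(models)
        singles = _single_column_efs(pool, keys, config.fraction)
        best_single = max(sorted(singles), key=lambda k: singles[k])
        best = models[0]
        result.cells[_cell_key(program, None, None)] = {
            "best_single_column": best_single,
            "best_single_ef": singles[best_single],
            "best_efo_ef": best.ef_train,
            "best_efo_model": best,
            "best_by_size": {str(s): m for s, m in per_size.items()},
        }
    result.means = compute_means(result.cells)
    return result


def report_json(results: Sequence[StageResult]) -> str:
    """Canonical (sorted-keys) JSON for a sequence of stage results."""
    return json.dumps([r.to_dict() for r in results], sort_keys=True, indent=2)


def load_campaign(path: str | Path) -> CampaignConfig:
    """Load a YAML/JSON campaign config.

    Expected keys: ``pools`` (program -> CSV path), ``frames``, ``chains``,
    and optionally ``fraction``, ``seed``, ``beam_width``,
    ``stage1_max_vars`` .. ``stage3_max_vars``, and ``directions``
    (function -> higher_better/lower_better overrides).  Score tables are
    oriented on load.
    """
    import yaml

    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    directions = cfg.get("directions")
    pools = {}
    for name, csv_path in cfg["pools"].items():
        csv_path = Path(csv_path)
        if not csv_path.is_absolute():
            csv_path = path.parent / csv_path
        pools[name] = orient_scores(read_score_table(csv_path, directions))
    kwargs = {
        k: cfg[k]
        for k in (
            "fraction", "seed", "beam_width",
            "stage1_max_vars", "stage2_max_vars", "stage3_max_vars",
        )
        if k in cfg
    }
    return CampaignConfig(
        pools=pools,
        frames=[str(f) for f in cfg["frames"]],
        chains=[str(c) for c in cfg["chains"]],
        **kwargs,
    )
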