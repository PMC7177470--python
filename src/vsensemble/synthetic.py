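"""Synthetic screening campaigns with the statistical structure the
consensus analysis assumes.

The real campaign (a 5300-molecule library with 53 known binders, docked
against the four monomers of three MD frames with several scoring
functions) is not publicly deposited, so this module generates emulated
campaigns: every (function, chain, frame) column scores inactives as
N(0, 1) and actives as N(delta, 1), with

    delta = delta_max * s_function * q_chain * q_frame

so per-monomer and per-frame quality differences translate into column
separability.  A shared per-ligand latent factor with loading sqrt(rho)
induces the inter-column correlation real docking scores show.  An optional
"complementary pair" (u+v, u-v with v a high-variance nuisance) plants a
signal recoverable only by combining two columns — the mechanism by which
multi-monomer consensus beats any single column.

Toy coordinate assemblies (spheres with known analytic surface areas,
chains separated beyond contact, exact-copy frames) back the structural
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import structure as struct_mod
from .score_data import (
    HIGHER,
    LOWER,
    ScoreColumnMeta,
    ScoreTable,
)

__all__ = [
    "FunctionSpec",
    "PlantedPairSpec",
    "SyntheticSpec",
    "generate_campaign",
    "plant_complementary_pair",
    "generate_toy_assembly",
    "complementary_pair_campaign",
    "study_campaign",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class FunctionSpec:
    """One scoring function: signal strength in [0, 1] and direction."""

    signal: float
    direction: str = HIGHER

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"invalid direction {self.direction!r}")


@dataclass(frozen=True)
class PlantedPairSpec:
    """Complementary-pair plant: (u+v, u-v) into two named columns."""

    program: str
    column_a: str
    column_b: str
    delta_u: float = 2.0
    sigma_v: float = 3.0
    seed: int = 0


def _default_programs() -> dict[str, dict[str, FunctionSpec]]:
    # One geometry-driven engine with strong primary scores and one
    # energy-score engine; signals chosen so the best single column's
    # EF 1% lands in the 10-30 range typical of single-score screening.
    return {
        "ligen": {
            "PS": FunctionSpec(0.8, HIGHER),
            "CS": FunctionSpec(0.6, HIGHER),
            "Contacts": FunctionSpec(0.45, HIGHER),
        },
        "plants": {
            "CHEMPLP": FunctionSpec(0.6, LOWER),
            "MLPINS": FunctionSpec(0.5, LOWER),
        },
    }


@dataclass
class SyntheticSpec:
    """Generative parameters of an emulated screening campaign.

    Defaults reproduce the study conditions: a 5300-ligand library with 53
    actives (1%), four monomer chains with quality A=1.0, B=0.3, C=D=0.6
    (chain A best, chain B worst), and three frames of increasing quality
    with 1049 the most productive.  delta_max = 3.0 keeps the best single
    column's EF 1% in the 10-30 range; rho = 0.3 is a moderate inter-score
    correlation typical of docking functions sharing pose geometry.
    """

    n_ligands: int = 5300
    n_actives: int = 53
    chains: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 0.3, "C": 0.6, "D": 0.6}
    )
    frames: dict[str, float] = field(
        default_factory=lambda: {"562": 0.7, "990": 0.85, "1049": 1.0}
    )
    programs: dict[str, dict[str, FunctionSpec]] = field(
        default_factory=_default_programs
    )
    delta_max: float = 3.0
    rho: float = 0.3
    planted_pair: PlantedPairSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_actives < self.n_ligands:
            raise ValueError("need 0 < n_actives < n_ligands")
        for q in list(self.chains.values()) + list(self.frames.values()):
            if not 0.0 <= q <= 1.0:
                raise ValueError("chain/frame qualities must lie in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


def generate_campaign(spec: SyntheticSpec) -> dict[str, ScoreTable]:
    """Generate one score table per docking program (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed % _SEED_MOD)
    n = spec.n_ligands
    width = len(str(n))
    ids = np.array([f"lig{i:0{width}d}" for i in range(1, n + 1)])
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=spec.n_actives, replace=False)] = 1
    heavy = rng.integers(10, 61, size=n)
    mol_weight = np.maximum(50.0, 13.5 * heavy + rng.normal(0.0, 15.0, size=n))
    ligands = pd.DataFrame(
        {"label": labels, "heavy_atoms": heavy, "mol_weight": np.round(mol_weight, 2)},
        index=pd.Index(ids, name="ligand_id"),
    )
    latent = rng.normal(0.0, 1.0, size=n)
    a, b = np.sqrt(spec.rho), np.sqrt(1.0 - spec.rho)

    pools: dict[str, ScoreTable] = {}
    for program in sorted(spec.programs):
        metas: list[ScoreColumnMeta] = []
        cols: dict[str, np.ndarray] = {}
        for func in sorted(spec.programs[program]):
            fs = spec.programs[program][func]
            for chain in sorted(spec.chains):
                for frame in sorted(spec.frames):
                    delta = (
                        spec.delta_max
                        * fs.signal
                        * spec.chains[chain]
                        * spec.frames[frame]
                    )
                    score = (
                        delta * labels
                        + a * latent
                        + b * rng.normal(0.0, 1.0, size=n)
                    )
                    meta = ScoreColumnMeta(func, chain, frame, fs.direction)
                    metas.append(meta)
                    cols[meta.key] = -score if fs.direction == LOWER else score
        values = pd.DataFrame(cols, index=ligands.index)
        pools[program] = ScoreTable(ligands.copy(), metas, values)

    if spec.planted_pair is not None:
        pools = plant_complementary_pair(pools, spec.planted_pair)
    return pools


def plant_complementary_pair(
    pools: Mapping[str, ScoreTable], pair: PlantedPairSpec
) -> dict[str, ScoreTable]:
    """Replace two columns by (u+v, u-v): individually weak, jointly strong.

    u carries the activity signal (delta_u on actives, unit noise); v is
    zero-mean nuisance noise of scale sigma_v.  Each column alone has its
    signal drowned by v, while the equal-weight sum reconstructs 2u exactly.
    Deterministic (and hence idempotent) given the pair's seed.
    """
    if pair.program not in pools:
        raise KeyError(f"unknown program {pair.program!r}")
    table = pools[pair.program]
    for key in (pair.column_a, pair.column_b):
        if key not in table.column_keys:
            raise KeyError(f"unknown column {key!r} in program {pair.program!r}")
    if pair.sigma_v <= 0:
        raise ValueError("sigma_v must be positive")
    rng = np.random.default_rng(pair.seed % _SEED_MOD)
    labels = table.labels
    u = pair.delta_u * labels + rng.normal(0.0, 1.0, size=len(labels))
    v = rng.normal(0.0, pair.sigma_v, size=len(labels))
    values = table.values.copy()
    metas = []
    for m in table.columns:
        if m.key == pair.column_a:
            new = replace(m, direction=HIGHER)
            values[m.key] = u + v
        elif m.key == pair.column_b:
            new = replace(m, direction=HIGHER)
            values[m.key] = u - v
        else:
            new = m
        metas.append(new)
    values.columns = [m.key for m in metas]
    out = dict(pools)
    out[pair.program] = ScoreTable(table.ligands.copy(), metas, values)
    return out


# -- canonical study conditions -----------------------------------------


def complementary_pair_campaign(
    seed: int, n_ligands: int = 2000, n_actives: int = 20
) -> tuple[ScoreTable, tuple[str, str]]:
    """Campaign for consensus-recovery studies: one scoring function over
    the four chains of one frame, with the complementary pair (delta_u = 2,
    sigma_v = 3) planted across chains A and C.

    Returns the oriented score table and the two planted column keys.
    Every non-planted column keeps its chain-quality signal, so the planted
    combination (EF around 30-40) clearly dominates the clean columns
    (EF below ~20) while each planted half alone stays weak.
    """
    from .score_data import orient_scores

    pair = ("PS__A__990", "PS__C__990")
    spec = SyntheticSpec(
        n_ligands=n_ligands,
        n_actives=n_actives,
        programs={"prog": {"PS": FunctionSpec(0.6)}},
        frames={"990": 1.0},
        seed=seed,
        planted_pair=PlantedPairSpec(
            "prog", pair[0], pair[1], delta_u=2.0, sigma_v=3.0, seed=seed + 1000
        ),
    )
    pools = generate_campaign(spec)
    return orient_scores(pools["prog"]), pair


def study_campaign(seed: int):
    """Canonical progressive-protocol study campaign (returns CampaignConfig).

    5300 ligands / 53 actives, the four chains at their default qualities
    (A best, B worst), two frames (990, 1049), and one program with a
    primary plus a rescoring function whose signals put the best single
    column's EF 1% in the 10-30 range.  A complementary signal split
    across chains C and D is planted in each frame (delta_u = 2.5, the
    strongest signal in the campaign) so that multi-monomer combination —
    the cross-talk effect the protocol is designed to expose — is the best
    available model, while single-monomer cells see only its weak halves.
    """
    from .protocol import CampaignConfig
    from .score_data import orient_scores

    frames = {"990": 0.85, "1049": 1.0}
    spec = SyntheticSpec(
        programs={
            "prog": {
                "PS": FunctionSpec(0.6, HIGHER),
                "MLPINS": FunctionSpec(0.4, LOWER),
            }
        },
        frames=frames,
        seed=seed,
    )
    pools = generate_campaign(spec)
    for frame in frames:
        pools = plant_complementary_pair(
            pools,
            PlantedPairSpec(
                "prog",
                f"MLPINS__C__{frame}",
                f"MLPINS__D__{frame}",
                delta_u=2.5,
                sigma_v=3.0,
                seed=seed * 7 + int(frame),
            ),
        )
    return CampaignConfig(
        pools={k: orient_scores(v) for k, v in pools.items()},
        frames=sorted(frames),
        chains=["A", "B", "C", "D"],
        seed=seed,
        beam_width=8,
        stage1_max_vars=2,
        stage2_max_vars=2,
    )


# -- toy coordinate assemblies ------------------------------------------


def generate_toy_assembly(kind: str, **params):
    """Minimal coordinate fixtures with known analytic properties.

    Kinds:
      - ``two_spheres(r1, r2, d)`` -> (CoordinateSet, radii override dict);
        two single-atom chains whose buried contact surface has a closed
        form (spherical caps).
      - ``separated_chains(gap)`` -> CoordinateSet; two 5-atom chains a
        ``gap`` apart along x, zero contact surface for large gaps.
      - ``copied_reference_frame(n_frames, noise, seed)`` ->
        (frames, reference); synthetic peptide-like coordinates where the
        last frame is an exact copy of the reference.
    """
    if kind == "two_spheres":
        r1 = float(params.get("r1", 2.0))
        r2 = float(params.get("r2", 2.0))
        d = float(params.get("d", 3.0))
        if r1 <= 0 or r2 <= 0 or d <= 0:
            raise ValueError("degenerate geometry: radii and distance must be > 0")
        coords = struct_mod.CoordinateSet(
            chain=np.array(["A", "B"]),
            resnum=np.array([1, 1]),
            resname=np.array(["SPH", "SPH"]),
            atom_name=np.array(["S1", "S2"]),
            element=np.array(["C", "N"]),
            xyz=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
            frame_id="0",
        )
        return coords, {"C": r1, "N": r2}
    if kind == "separated_chains":
        gap = float(params.get("gap", 100.0))
        if gap <= 0:
            raise ValueError("degenerate geometry: gap must be > 0")
        rng = np.random.default_rng(int(params.get("seed", 0)))
        xyz_a = rng.normal(0.0, 1.5, size=(5, 3))
        xyz_b = rng.normal(0.0, 1.5, size=(5, 3)) + np.array([gap, 0.0, 0.0])
        return struct_mod.CoordinateSet(
            chain=np.array(["A"] * 5 + ["B"] * 5),
            resnum=np.array([1, 1, 1, 2, 2] * 2),
            resname=np.array(["GLY"] * 10),
            atom_name=np.array(["N", "CA", "C", "N", "CA"] * 2),
            element=np.array(["N", "C", "C", "N", "C"] * 2),
            xyz=np.vstack([xyz_a, xyz_b]),
            frame_id="0",
        )
    if kind == "copied_reference_frame":
        n_frames = int(params.get("n_frames", 4))
        noise = float(params.get("noise", 0.8))
        seed = int(params.get("seed", 0))
        rng = np.random.default_rng(seed)
        n_res = int(params.get("n_res", 8))
        names = ["N", "CA", "C", "O"]
        chain = np.array(["A"] * (4 * n_res))
        resnum = np.repeat(np.arange(1, n_res + 1), 4)
        resname = np.array(["ALA"] * (4 * n_res))
        atom_name = np.array(names * n_res)
        element = np.array([nm[0] for nm in atom_name])
        ref_xyz = rng.normal(0.0, 4.0, size=(4 * n_res, 3))
        reference = struct_mod.CoordinateSet(
            chain, resnum, resname, atom_name, element, ref_xyz, frame_id="ref"
        )
        frames = []
        for i in range(n_frames - 1):
            xyz = ref_xyz + rng.normal(0.0, noise, size=ref_xyz.shape)
            frames.append(
                struct_mod.CoordinateSet(
                    chain, resnum, resname, atom_name, element, xyz, frame_id=str(i)
                )
            )
        frames.append(
            struct_mod.CoordinateSet(
                chain,
                resnum,
                resname,
                atom_name,
                element,
                ref_xyz.copy(),
                frame_id=str(n_frames - 1),
            )
        )
        return frames, reference
    raise ValueError(f"unknown toy assembly kind {kind!r}")
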