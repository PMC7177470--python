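"""Data model and I/O for docking-score tables.

A screening campaign against a homotetrameric target produces one score per
(ligand, scoring function, monomer chain, MD frame).  This module holds those
scores in a :class:`ScoreTable` — a ligand x column matrix with per-column
metadata — and provides the plumbing every downstream consensus step relies
on: parsing the ``<func>__<chain>__<frame>`` header convention, orienting all
columns so that larger is better, deriving size-normalized score variants,
and merging tables from separate campaigns over the same ligand set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HIGHER = "higher_better"
LOWER = "lower_better"

RAW = "raw"
PER_HEAVY_ATOM = "per_heavy_atom"
PER_WEIGHT = "per_weight"

#: suffix used in column headers for each normalization mode
_NORM_SUFFIX = {PER_HEAVY_ATOM: "_NORM_HEVATMS", PER_WEIGHT: "_NORM_WEIGHT"}
_SUFFIX_NORM = {v: k for k, v in _NORM_SUFFIX.items()}

#: Default score direction per scoring function (case-insensitive base name).
#: Energy-like scores are lower-better, fit/contact counts higher-better.
#: This registry is a convenience only and can always be overridden.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "CHEMPLP": LOWER,
    "PLP": LOWER,
    "PLP95": LOWER,
    "XSCORE": LOWER,
    "XSCORE_HM": LOWER,
    "MLPINS": LOWER,
    "GOLDSCORE": HIGHER,
    "ASP": HIGHER,
    "PS": HIGHER,
    "CS": HIGHER,
    "CSOPT": HIGHER,
    "CONTACTS": HIGHER,
    "GSCORE": LOWER,
}

DEFAULT_CHAINS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class LigandRecord:
    """One screened molecule: id, activity label and size descriptors."""

    ligand_id: str
    label: int
    heavy_atoms: int | None = None
    mol_weight: float | None = None


@dataclass(frozen=True)
class ScoreColumnMeta:
    """Identity of one score column: function, chain, frame, direction."""

    function_name: str
    chain: str | None = None
    frame: str | None = None
    direction: str | None = None
    normalization: str = RAW

    @property
    def key(self) -> str:
        """Canonical header token, e.g. ``Contacts_NORM_HEVATMS__A__990``."""
        func = self.function_name + _NORM_SUFFIX.get(self.normalization, "")
        parts = [func]
        if self.chain is not None or self.frame is not None:
            parts.append(self.chain or "")
        if self.frame is not None:
            parts.append(self.frame)
        return "__".join(parts)

    @classmethod
    def from_header(
        cls,
        token: str,
        directions: Mapping[str, str] | None = None,
        chain_alphabet: Sequence[str] = DEFAULT_CHAINS,
    ) -> "ScoreColumnMeta":
        """Decode a ``<func>[__<chain>[__<frame>]]`` header token."""
        parts = token.split("__")
        if not parts[0] or len(parts) > 3:
            raise ValueError(f"unparseable score column header: {token!r}")
        func, chain, frame = parts[0], None, None
        if len(parts) >= 2 and parts[1]:
            if parts[1] not in chain_alphabet:
                raise ValueError(
                    f"unparseable score column header: {token!r} "
                    f"(chain token {parts[1]!r} not in {list(chain_alphabet)})"
                )
            chain = parts[1]
        if len(parts) == 3:
            if not parts[2]:
                raise ValueError(f"unparseable score column header: {token!r}")
            frame = parts[2]
        normalization = RAW
        for suffix, norm in _SUFFIX_NORM.items():
            if func.endswith(suffix):
                func = func[: -len(suffix)]
                normalization = norm
                break
        lookup = dict(DEFAULT_DIRECTIONS)
        if directions:
            lookup.update({k.upper(): v for k, v in directions.items()})
        direction = lookup.get(func.upper())
        return cls(func, chain, frame, direction, normalization)


@dataclass
class ScoreTable:
    """Ligand x score-column matrix with per-column metadata.

    ``ligands`` is indexed by ligand_id with columns ``label`` and optionally
    ``heavy_atoms`` / ``mol_weight``; ``values`` shares that index and has one
    column per :class:`ScoreColumnMeta` key.  Missing scores are NaN (docking
    failures happen in practice; such ligands are ranked last by any model
    that uses the affected column).
    """

    ligands: pd.DataFrame
    columns: list[ScoreColumnMeta] = field(default_factory=list)
    values: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def ligand_ids(self) -> np.ndarray:
        return self.ligands.index.to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.ligands["label"].to_numpy(dtype=int)

    @property
    def column_keys(self) -> list[str]:
        return [m.key for m in self.columns]

    def meta(self, key: str) -> ScoreColumnMeta:
        for m in self.columns:
            if m.key == key:
                return m
        raise KeyError(f"no score column {key!r}")

    def matrix(self, keys: Sequence[str] | None = None) -> np.ndarray:
        """Score values as a float matrix (NaN for missing)."""
        cols = list(keys) if keys is not None else self.column_keys
        return self.values[cols].to_numpy(dtype=float)

    def subset_columns(self, keys: Sequence[str]) -> "ScoreTable":
        metas = [self.meta(k) for k in keys]
        return ScoreTable(self.ligands.copy(), metas, self.values[list(keys)].copy())

    def subset_ligands(self, ids: Sequence[str]) -> "ScoreTable":
        ids = list(ids)
        return ScoreTable(
            self.ligands.loc[ids].copy(), list(self.columns), self.values.loc[ids].copy()
        )

    def validate(self) -> None:
        if "label" not in self.ligands.columns:
            raise ValueError("ligand table lacks a 'label' column")
        if self.ligands.index.has_duplicates:
            dup = self.ligands.index[self.ligands.index.duplicated()][0]
            raise ValueError(f"duplicate ligand_id: {dup!r}")
        labels = self.ligands["label"]
        if not labels.isin([0, 1]).all():
            bad = labels[~labels.isin([0, 1])].iloc[0]
            raise ValueError(f"non-binary activity label: {bad!r}")
        keys = self.column_keys
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate score column: {dup!r}")
        if list(self.values.columns) != keys:
            raise ValueError("score matrix columns do not match column metadata")
        if not self.values.index.equals(self.ligands.index):
            raise ValueError("score matrix rows do not match ligand table")


# -- I/O -----------------------------------------------------------------

_LIGAND_COLS = ("ligand_id", "label", "heavy_atoms", "mol_weight")


def read_score_table(
    path: str | Path,
    directions: Mapping[str, str] | None = None,
    chain_alphabet: Sequence[str] = DEFAULT_CHAINS,
    sep: str | None = None,
) -> ScoreTable:
    """Read a CSV/TSV score table.

    Expected header: ``ligand_id,label[,heavy_atoms,mol_weight],<score>...``
    where each score header follows ``<func>[__<chain>[__<frame>]]``.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"ligand_id": str})
    for required in ("ligand_id", "label"):
        if required not in df.columns:
            raise ValueError(f"score table lacks required column {required!r}")
    score_cols = [c for c in df.columns if c not in _LIGAND_COLS]
    metas = [
        ScoreColumnMeta.from_header(c, directions, chain_alphabet) for c in score_cols
    ]
    ligands = df.set_index("ligand_id")[
        [c for c in ("label", "heavy_atoms", "mol_weight") if c in df.columns]
    ]
    values = df.set_index("ligand_id")[score_cols].astype(float)
    values.columns = [m.key for m in metas]
    return ScoreTable(ligands, metas, values)


def write_score_table(table: ScoreTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    out = pd.concat([table.ligands, table.values], axis=1)
    out.index.name = "ligand_id"
    out.to_csv(path, sep=sep)


def read_ligand_properties(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a ``ligand_id,label,heavy_atoms,mol_weight`` property table."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"ligand_id": str}).set_index("ligand_id")
    return df


def attach_properties(table: ScoreTable, props: pd.DataFrame) -> ScoreTable:
    """Attach heavy_atoms / mol_weight columns from a property table."""
    missing = table.ligands.index.difference(props.index)
    if len(missing):
        raise ValueError(f"property table lacks ligands: {list(missing[:5])}")
    ligands = table.ligands.copy()
    for col in ("heavy_atoms", "mol_weight"):
        if col in props.columns:
            ligands[col] = props.loc[ligands.index, col]
    return ScoreTable(ligands, list(table.columns), table.values.copy())


# -- transformations -----------------------------------------------------


def orient_scores(table: ScoreTable) -> ScoreTable:
    """Flip lower-better columns so every column ranks actives high when large.

    Idempotent: already-oriented (higher_better) columns pass unchanged.
    """
    values = table.values.copy()
    metas: list[ScoreColumnMeta] = []
    rename: dict[str, str] = {}
    for m in table.columns:
        if m.direction is None:
            raise ValueError(f"column {m.key!r} has no declared direction")
        if m.direction == LOWER:
            new = replace(m, direction=HIGHER)
            values[m.key] = -values[m.key]
            rename[m.key] = new.key
            metas.append(new)
        elif m.direction == HIGHER:
            metas.append(m)
        else:
            raise ValueError(f"column {m.key!r} has invalid direction {m.direction!r}")
    values = values.rename(columns=rename)
    return ScoreTable(table.ligands.copy(), metas, values)


def derive_normalized_scores(
    table: ScoreTable, modes: Iterable[str] = (PER_HEAVY_ATOM, PER_WEIGHT)
) -> ScoreTable:
    """Append per-heavy-atom and/or per-weight variants of every raw column.

    Size normalization is a standard rescoring trick: dividing a score by
    ligand size removes the bias of additive scoring functions toward large
    molecules.  Raw columns are retained.
    """
    modes = list(modes)
    for mode in modes:
        if mode not in (PER_HEAVY_ATOM, PER_WEIGHT):
            raise ValueError(f"unknown normalization mode {mode!r}")
    lig = table.ligands
    if PER_HEAVY_ATOM in modes:
        if "heavy_atoms" not in lig.columns:
            raise ValueError("per_heavy_atom normalization needs heavy_atoms")
        bad = lig.index[(lig["heavy_atoms"].isna()) | (lig["heavy_atoms"] < 1)]
        if len(bad):
            raise ValueError(f"invalid heavy_atoms for ligand {bad[0]!r}")
    if PER_WEIGHT in modes:
        if "mol_weight" not in lig.columns:
            raise ValueError("per_weight normalization needs mol_weight")
        bad = lig.index[(lig["mol_weight"].isna()) | (lig["mol_weight"] <= 0)]
        if len(bad):
            raise ValueError(f"invalid mol_weight for ligand {bad[0]!r}")
    metas = list(table.columns)
    values = table.values.copy()
    for m in table.columns:
        if m.normalization != RAW:
            continue
        for mode in modes:
            new = replace(m, normalization=mode)
            denom = lig["heavy_atoms"] if mode == PER_HEAVY_ATOM else lig["mol_weight"]
            values[new.key] = table.values[m.key] / denom.astype(float)
            metas.append(new)
    return ScoreTable(table.ligands.copy(), metas, values[[m.key for m in metas]])


def merge_tables(tables: Sequence[ScoreTable]) -> ScoreTable:
    """Column-wise union of score tables over one identical ligand set."""
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    ref_ids = set(first.ligands.index)
    for t in tables[1:]:
        ids = set(t.ligands.index)
        if ids != ref_ids:
            diff = sorted(ids.symmetric_difference(ref_ids))
            raise ValueError(f"ligand sets differ; symmetric difference: {diff[:10]}")
        if not t.ligands["label"].reindex(first.ligands.index).equals(
            first.ligands["label"]
        ):
            raise ValueError("ligand labels differ between tables")
    metas: list[ScoreColumnMeta] = []
    frames: list[pd.DataFrame] = []
    for t in tables:
        metas.extend(t.columns)
        frames.append(t.values.reindex(first.ligands.index))
    values = pd.concat(frames, axis=1)
    return ScoreTable(first.ligands.copy(), metas, values)
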