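"""Shared helpers: tiny in-memory score tables built from raw arrays."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vsensemble.score_data import HIGHER, ScoreColumnMeta, ScoreTable


def make_table(
    X: np.ndarray,
    labels: np.ndarray,
    chains: list[str] | None = None,
    frames: list[str] | None = None,
    direction: str = HIGHER,
    heavy_atoms: np.ndarray | None = None,
    mol_weight: np.ndarray | None = None,
) -> ScoreTable:
    """Score table from a raw (N, k) matrix; columns named F0..Fk-1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == len(labels) and X.ndim == 2 and X.shape[1] != len(labels):
        pass
    n, k = X.shape
    ids = np.array([f"lig{i:04d}" for i in range(n)])
    data = {"label": np.asarray(labels, dtype=int)}
    if heavy_atoms is not None:
        data["heavy_atoms"] = heavy_atoms
    if mol_weight is not None:
        data["mol_weight"] = mol_weight
    ligands = pd.DataFrame(data, index=pd.Index(ids, name="ligand_id"))
    metas = [
        ScoreColumnMeta(
            f"F{j}",
            chains[j] if chains else None,
            frames[j] if frames else None,
            direction,
        )
        for j in range(k)
    ]
    values = pd.DataFrame(
        {m.key: X[:, j] for j, m in enumerate(metas)}, index=ligands.index
    )
    return ScoreTable(ligands, metas, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
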