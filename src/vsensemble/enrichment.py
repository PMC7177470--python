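"""Ranking and enrichment-factor (EF) statistics.

The EF at fraction f is the ratio of the active rate among the top-ranked
``ceil(f*N)`` molecules to the active rate of the whole library:

    EF_f = (a_s / top_size) / (A / N)

with ``a_s`` actives found in the top set, ``A`` total actives and ``N``
library size.  A perfect ranking of the 53-active / 5300-molecule library
at f = 0.01 gives EF = 100; a random ranking averages EF = 1.

Ties are always resolved *pessimistically*: at equal consensus value,
inactive molecules are ranked ahead of actives (then lexicographically by
ligand id), so a reported EF is a lower bound over all tie resolutions.
Ligands missing any score used by a model get consensus -inf and are ranked
last, again inactives first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .score_data import HIGHER, ScoreTable

__all__ = [
    "Ranking",
    "EnrichmentResult",
    "rank_ligands",
    "enrichment_factor",
    "actives_in_top",
    "mean_reciprocal_rank",
]


@dataclass(frozen=True)
class Ranking:
    """Ligands ordered best-first by consensus value (pessimistic ties)."""

    ligand_ids: tuple[str, ...]
    consensus_values: np.ndarray  # non-increasing, -inf for missing
    labels: np.ndarray  # activity labels in ranked order
    tie_policy: str = "pessimistic"

    def __post_init__(self) -> None:
        v = self.consensus_values
        if len(v) != len(self.ligand_ids) or len(self.labels) != len(v):
            raise ValueError("ranking fields have mismatched lengths")
        if np.any(np.diff(v) > 0):
            raise ValueError("consensus values are not non-increasing")

    def __len__(self) -> int:
        return len(self.ligand_ids)


@dataclass(frozen=True)
class EnrichmentResult:
    """EF at one fraction, with the counts behind it."""

    fraction: float
    top_size: int
    actives_in_top: int
    ef: float
    n_ligands: int
    n_actives: int


# -- core counting kernel ------------------------------------------------


def _with_missing_last(values: np.ndarray) -> np.ndarray:
    return np.where(np.isnan(values), -np.inf, values)


def actives_in_top(values: np.ndarray, labels: np.ndarray, top_size: int) -> np.ndarray:
    """Pessimistic count of actives among the ``top_size`` best values.

    ``values`` may be one column ``(N,)`` or a candidate batch ``(N, C)``;
    a count per column is returned.  NaN values rank last.  At the cut-off
    value, inactive ties fill the remaining slots before active ties —
    the pessimistic convention, counted here without an explicit sort.
    """
    V = _with_missing_last(np.asarray(values, dtype=float))
    squeeze = V.ndim == 1
    if squeeze:
        V = V[:, None]
    n = V.shape[0]
    if not 1 <= top_size <= n:
        raise ValueError(f"top_size {top_size} outside 1..{n}")
    act = np.asarray(labels, dtype=bool)[:, None]
    thr = np.partition(V, n - top_size, axis=0)[n - top_size]
    above = V > thr
    a_above = (above & act).sum(axis=0)
    n_above = above.sum(axis=0)
    at = V == thr
    inact_at = (at & ~act).sum(axis=0)
    slots = top_size - n_above
    counts = a_above + np.maximum(0, slots - inact_at)
    return counts[0] if squeeze else counts


def _pessimistic_order(
    values: np.ndarray, labels: np.ndarray, ligand_ids: np.ndarray
) -> np.ndarray:
    """Indices sorting by value desc, then inactives first, then ligand id."""
    v = _with_missing_last(np.asarray(values, dtype=float))
    return np.lexsort((np.asarray(ligand_ids), np.asarray(labels), -v))


def mean_reciprocal_rank(
    values: np.ndarray, labels: np.ndarray, ligand_ids: np.ndarray | None = None
) -> float:
    """Mean of 1/rank over actives under the pessimistic ranking.

    Used as a deterministic secondary criterion on EF plateaus: among
    rankings with equal EF, the one pushing actives higher overall wins.
    """
    labels = np.asarray(labels)
    if ligand_ids is None:
        ligand_ids = np.arange(len(labels))
    order = _pessimistic_order(values, labels, ligand_ids)
    ranks = np.empty(len(order), dtype=float)
    ranks[order] = np.arange(1, len(order) + 1)
    active_ranks = ranks[labels.astype(bool)]
    if len(active_ranks) == 0:
        raise ValueError("no actives: mean reciprocal rank undefined")
    return float(np.mean(1.0 / active_ranks))


# -- public operations ---------------------------------------------------


def consensus_values(
    table: ScoreTable, weights: Mapping[str, float]
) -> np.ndarray:
    """Weighted sum of oriented score columns; NaN where any score missing."""
    if not weights:
        raise ValueError("no weights given")
    keys = list(weights)
    for key in keys:
        meta = table.meta(key)  # raises KeyError on unknown column
        if meta.direction != HIGHER:
            raise ValueError(
                f"column {key!r} is not oriented higher_better; orient first"
            )
    X = table.matrix(keys)
    w = np.array([weights[k] for k in keys], dtype=float)
    return X @ w


def rank_ligands(table: ScoreTable, weights: Mapping[str, float]) -> Ranking:
    """Rank ligands by the linear consensus Σ w_j s_j (pessimistic ties)."""
    values = consensus_values(table, weights)
    labels = table.labels
    ids = table.ligand_ids
    order = _pessimistic_order(values, labels, ids)
    sorted_vals = _with_missing_last(values)[order]
    return Ranking(
        ligand_ids=tuple(ids[order]),
        consensus_values=sorted_vals,
        labels=labels[order],
    )


def enrichment_factor(
    ranking: Ranking,
    labels: Mapping[str, int] | None = None,
    fraction: float = 0.01,
) -> EnrichmentResult:
    """EF at ``fraction`` (default 1%) for an existing ranking.

    ``labels`` may override the activity labels carried by the ranking
    (keyed by ligand id); by default the ranking's own labels are used.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if labels is not None:
        lab = np.array([labels[i] for i in ranking.ligand_ids], dtype=int)
    else:
        lab = np.asarray(ranking.labels, dtype=int)
    n = len(ranking)
    n_act = int(lab.sum())
    if n_act == 0:
        raise ValueError("no actives in the library: EF undefined")
    top = math.ceil(fraction * n)
    a_s = int(lab[:top].sum())
    ef = (a_s / top) / (n_act / n)
    return EnrichmentResult(
        fraction=fraction,
        top_size=top,
        actives_in_top=a_s,
        ef=ef,
        n_ligands=n,
        n_actives=n_act,
    )


def ef_from_counts(a_top: float | np.ndarray, top: int, n_act: int, n: int):
    """EF from counts; vectorized over ``a_top``."""
    return (np.asarray(a_top, dtype=float) / top) / (n_act / n)


def ef_of_values(
    values: np.ndarray, labels: np.ndarray, fraction: float = 0.01
) -> np.ndarray | float:
    """EF of one value column or a batch of candidate columns at once.

    This is the vectorized engine behind the EFO coefficient scans: a
    ``(N, C)`` batch gives C enrichment factors in one pass.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    n_act = int(labels.sum())
    if n_act == 0:
        raise ValueError("no actives in the library: EF undefined")
    top = math.ceil(fraction * n)
    counts = actives_in_top(values, labels, top)
    out = ef_from_counts(counts, top, n_act, n)
    return float(out) if np.isscalar(counts) or counts.ndim == 0 else out
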