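"""Enrichment-factor optimization (EFO): linear consensus models over
docking-score columns with coefficients chosen to maximize EF 1%.

A consensus model is ``s_lead + w_2 s_2 + ... + w_k s_k`` over 1-4 oriented
score columns, the leading coefficient fixed at +1 (orientation absorbs the
sign).  EF is piecewise constant in the coefficients, so the fit is a
gradient-free cyclic coordinate search: each free coefficient is scanned
over tan(theta) on a 1-degree grid in (-88, 88) degrees, scaled by the ratio
of column standard deviations so theta = 45 deg means "equal contribution".
On small tables the scan additionally evaluates every pairwise crossing
coefficient (the breakpoints of the piecewise-constant objective), which
makes each coordinate scan exact.  Sweeps repeat until EF stops improving;
five multi-starts guard against bad basins.  EF plateaus are broken
deterministically: within a scan the plateau mid-point is taken, and among
finished candidates the higher mean reciprocal rank of actives wins, then
the smaller coefficient L1 norm.

Subset search enumerates sizes 1-2 exhaustively and grows sizes 3-4 by beam
search; admissibility constraints (spanning at least two monomer chains or
two MD frames) are enforced as hard filters on the emitted models.
"""

from __future__ import annotations

import itertools
import json
import math
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .enrichment import (
    Ranking,
    actives_in_top,
    ef_from_counts,
    ef_of_values,
    mean_reciprocal_rank,
    rank_ligands,
)
from .score_data import HIGHER, ScoreColumnMeta, ScoreTable

__all__ = [
    "ConsensusModel",
    "ValidationReport",
    "SearchConstraint",
    "optimize_coefficients",
    "search_combinations",
    "validate_model",
    "score_with_model",
    "best_per_size",
]

GRID_POINTS = 177  # 1-degree steps over (-88, 88) inclusive
MAX_SWEEPS = 10
N_RANDOM_STARTS = 3
EXACT_BREAKPOINT_LIMIT = 400  # below this N, coordinate scans are exact
_SEED_MOD = 2**31


@dataclass
class ValidationReport:
    """Repeated stratified 70/30 split validation of one model."""

    n_repeats: int
    train_fraction: float
    test_efs: list[float]
    mean_test_ef: float
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ConsensusModel:
    """Fitted linear consensus over 1-4 score columns (leading coeff +1)."""

    variables: list[ScoreColumnMeta]
    coefficients: list[float]
    ef_train: float
    ef_full: float | None = None
    mrr: float | None = None
    seed: int = 0
    validation: ValidationReport | None = None

    def __post_init__(self) -> None:
        if len(self.variables) != len(self.coefficients):
            raise ValueError("variables and coefficients differ in length")
        if not self.coefficients or self.coefficients[0] != 1.0:
            raise ValueError("leading coefficient must be fixed at 1.0")
        keys = [v.key for v in self.variables]
        if len(set(keys)) != len(keys):
            raise ValueError("model variables must be distinct")

    @property
    def weights(self) -> dict[str, float]:
        return {v.key: c for v, c in zip(self.variables, self.coefficients)}

    @property
    def l1_norm(self) -> float:
        return float(np.sum(np.abs(self.coefficients)))

    def distinct_chains(self) -> int:
        return len({v.chain for v in self.variables if v.chain is not None})

    def distinct_frames(self) -> int:
        return len({v.frame for v in self.variables if v.frame is not None})

    def equation(self) -> str:
        """Human-readable form, e.g. ``1.00 PS__D__562 + 0.46 Contacts...``."""
        terms = []
        for i, (v, c) in enumerate(zip(self.variables, self.coefficients)):
            if i == 0:
                terms.append(f"{c:.2f} {v.key}")
            else:
                sign = "+" if c >= 0 else "-"
                terms.append(f"{sign} {abs(c):.3g} {v.key}")
        return " ".join(terms)

    def to_dict(self) -> dict:
        return {
            "variables": [asdict(v) for v in self.variables],
            "coefficients": list(map(float, self.coefficients)),
            "ef_train": self.ef_train,
            "ef_full": self.ef_full,
            "mrr": self.mrr,
            "seed": self.seed,
            "validation": self.validation.to_dict() if self.validation else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConsensusModel":
        val = d.get("validation")
        return cls(
            variables=[ScoreColumnMeta(**v) for v in d["variables"]],
            coefficients=list(d["coefficients"]),
            ef_train=d["ef_train"],
            ef_full=d.get("ef_full"),
            mrr=d.get("mrr"),
            seed=d.get("seed", 0),
            validation=ValidationReport(**val) if val else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ConsensusModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SearchConstraint:
    """Admissibility rules for consensus-model subsets."""

    max_vars: int = 4
    min_distinct_chains: int = 1
    min_distinct_frames: int = 1
    allowed_columns: list[str] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.max_vars <= 4:
            raise ValueError("max_vars must be between 1 and 4")

    def admissible(self, metas: Sequence[ScoreColumnMeta]) -> bool:
        chains = {m.chain for m in metas if m.chain is not None}
        frames = {m.frame for m in metas if m.frame is not None}
        return (
            len(metas) <= self.max_vars
            and len(chains) >= self.min_distinct_chains
            and len(frames) >= self.min_distinct_frames
        )

    def extensible(self, metas: Sequence[ScoreColumnMeta]) -> bool:
        """Could a superset within max_vars still satisfy the constraint?"""
        chains = {m.chain for m in metas if m.chain is not None}
        frames = {m.frame for m in metas if m.frame is not None}
        room = self.max_vars - len(metas)
        return (
            room >= 0
            and len(chains) + room >= self.min_distinct_chains
            and len(frames) + room >= self.min_distinct_frames
        )


def _derive_seed(seed: int, *tokens: str) -> int:
    crc = zlib.crc32("|".join(tokens).encode())
    return (seed * 1_000_003 + crc) % _SEED_MOD


def _check_oriented(table: ScoreTable, keys: Sequence[str]) -> None:
    for k in keys:
        if table.meta(k).direction != HIGHER:
            raise ValueError(f"column {k!r} is not oriented higher_better")


# -- coefficient fitting -------------------------------------------------


def _grid_tangents() -> np.ndarray:
    theta = np.deg2rad(np.linspace(-88.0, 88.0, GRID_POINTS))
    return np.tan(theta)


_TAN_GRID = _grid_tangents()


def _breakpoints(base: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Coefficients where the ranking by ``base + w*x`` changes.

    For ligand pair (i, j): w = (base_j - base_i) / (x_i - x_j).  Evaluating
    mid-points between consecutive crossings covers every attainable ranking,
    making a 1-D scan exact.  O(N^2); used only for small tables.
    """
    finite = np.isfinite(base) & np.isfinite(x)
    b, xx = base[finite], x[finite]
    db = b[None, :] - b[:, None]
    dx = xx[:, None] - xx[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = db / dx
    iu = np.triu_indices(len(b), k=1)
    w = w[iu]
    w = np.unique(w[np.isfinite(w)])
    if len(w) == 0:
        return np.array([0.0])
    mids = (w[:-1] + w[1:]) / 2.0
    span = max(1.0, abs(w[0]), abs(w[-1]))
    return np.concatenate(([w[0] - span], w, mids, [w[-1] + span]))


def _plateau_choice(cands: np.ndarray, counts: np.ndarray, current: float) -> float:
    """Deterministic pick on an EF plateau.

    EF is piecewise constant, so the scan's optimum is a set of tied
    candidates.  The widest contiguous tied run is the most robust
    optimum; its (evaluated) mid-point is returned.  If the current value
    already sits inside that run it is kept, which lets sweeps converge.
    """
    best = counts.max()
    tied = counts == best
    # contiguous runs of tied candidates
    edges = np.flatnonzero(np.diff(np.concatenate(([0], tied.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]  # runs are [start, end)
    widths = cands[ends - 1] - cands[starts]
    k = int(np.argmax(widths))
    lo, hi = starts[k], ends[k] - 1
    if cands[lo] <= current <= cands[hi]:
        idx = np.searchsorted(cands, current)
        if idx < len(cands) and cands[idx] == current and tied[idx]:
            return current
    mid = (cands[lo] + cands[hi]) / 2.0
    return float(cands[lo + int(np.argmin(np.abs(cands[lo : hi + 1] - mid)))])


def _auc_batch(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC AUC per column via the rank-sum identity (NaN ranks last)."""
    V = np.where(np.isnan(values), -np.inf, values)
    if V.ndim == 1:
        V = V[:, None]
    n = V.shape[0]
    act = np.asarray(labels, dtype=bool)
    a = int(act.sum())
    order = np.argsort(V, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, n + 1)[:, None], axis=0)
    rank_sum = ranks[act].sum(axis=0)
    return (rank_sum - a * (a + 1) / 2.0) / (a * (n - a))


def _batched_counts(
    base: np.ndarray, x: np.ndarray, cands: np.ndarray, labels: np.ndarray, top: int
) -> np.ndarray:
    """Actives-in-top for ``base + w*x`` over all candidate w, chunked."""
    out = np.empty(len(cands), dtype=int)
    # keep the candidate matrix under ~40 MB
    chunk = max(1, int(5_000_000 / max(1, len(base))))
    for lo in range(0, len(cands), chunk):
        hi = min(lo + chunk, len(cands))
        V = base[:, None] + np.outer(x, cands[lo:hi])
        out[lo:hi] = actives_in_top(V, labels, top)
    return out


def optimize_coefficients(
    table: ScoreTable,
    subset: Sequence[str],
    fraction: float = 0.01,
    seed: int = 0,
    max_sweeps: int = MAX_SWEEPS,
    exact_breakpoint_limit: int = EXACT_BREAKPOINT_LIMIT,
) -> ConsensusModel:
    """Fit coefficients maximizing EF at ``fraction`` for an ordered subset.

    The first column of ``subset`` is the leading variable (coefficient
    fixed at +1.0).  Deterministic given ``seed``.
    """
    keys = list(subset)
    if not 1 <= len(keys) <= 4:
        raise ValueError("subset must contain 1 to 4 columns")
    _check_oriented(table, keys)
    X = table.matrix(keys)
    labels = table.labels
    n = len(labels)
    n_act = int(labels.sum())
    if n_act == 0:
        raise ValueError("no actives: EF undefined")
    top = math.ceil(fraction * n)
    sds = np.nanstd(X, axis=0)
    for k_i, sd in zip(keys, sds):
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"constant (or all-missing) score column: {k_i!r}")

    ids = table.ligand_ids

    def evaluate(w_free: np.ndarray) -> tuple[float, float, float]:
        vals = X[:, 0] + X[:, 1:] @ w_free if len(keys) > 1 else X[:, 0]
        a = actives_in_top(vals, labels, top)
        ef = float(ef_from_counts(a, top, n_act, n))
        mrr = mean_reciprocal_rank(vals, labels, ids)
        return ef, mrr, float(1.0 + np.abs(w_free).sum())

    if len(keys) == 1:
        ef, mrr, _ = evaluate(np.empty(0))
        return ConsensusModel([table.meta(keys[0])], [1.0], ef, ef, mrr, seed)

    scale = sds[0] / sds[1:]
    rng = np.random.default_rng(seed % _SEED_MOD)
    if len(keys) == 2:
        # one free coefficient: the scan is global, multi-starts are redundant
        starts = [np.zeros(1)]
    else:
        starts = [np.zeros(len(keys) - 1), scale.copy()]
        for _ in range(N_RANDOM_STARTS):
            theta = rng.uniform(-88.0, 88.0, size=len(keys) - 1)
            starts.append(np.tan(np.deg2rad(theta)) * scale)

    exact = n <= exact_breakpoint_limit
    finished: list[tuple[float, float, float, np.ndarray]] = []
    for w0 in starts:
        w = w0.copy()
        prev_ef = -np.inf
        for _ in range(max_sweeps):
            for j in range(len(w)):
                others = np.delete(np.arange(len(w)), j)
                base = X[:, 0] + X[:, 1 + others] @ w[others]
                x = X[:, 1 + j]
                cands = _TAN_GRID * scale[j]
                if exact:
                    cands = np.concatenate([cands, _breakpoints(base, x)])
                cands = np.unique(np.append(cands, w[j]))
                counts = _batched_counts(base, x, cands, labels, top)
                w[j] = _plateau_choice(cands, counts, w[j])
            ef = float(
                ef_from_counts(
                    actives_in_top(X[:, 0] + X[:, 1:] @ w, labels, top),
                    top,
                    n_act,
                    n,
                )
            )
            if ef <= prev_ef or len(w) == 1:
                break  # a single-coefficient scan is already global
            prev_ef = ef
        finished.append((*evaluate(w), w))

    # best by EF, then mean reciprocal rank, then parsimony (L1), then order
    best_ef, best_mrr, best_l1, best_w = finished[0]
    for ef, mrr, l1, w in finished[1:]:
        if (ef, mrr, -l1) > (best_ef, best_mrr, -best_l1):
            best_ef, best_mrr, best_l1, best_w = ef, mrr, l1, w

    # Final pass over the winner: EF plateaus are wide, so among the
    # candidates tied at the optimal count pick the one maximizing AUC —
    # a smooth surrogate that peaks where nuisance noise cancels.
    w = best_w.copy()
    for j in range(len(w)):
        others = np.delete(np.arange(len(w)), j)
        base = X[:, 0] + X[:, 1 + others] @ w[others]
        x = X[:, 1 + j]
        cands = _TAN_GRID * scale[j]
        if exact:
            cands = np.concatenate([cands, _breakpoints(base, x)])
        cands = np.unique(np.append(cands, w[j]))
        counts = _batched_counts(base, x, cands, labels, top)
        tied = np.flatnonzero(counts == counts.max())
        if len(tied) > 1:
            chunk = max(1, int(5_000_000 / max(1, n)))
            aucs = np.empty(len(tied))
            for lo in range(0, len(tied), chunk):
                sel = tied[lo : lo + chunk]
                aucs[lo : lo + len(sel)] = _auc_batch(
                    base[:, None] + np.outer(x, cands[sel]), labels
                )
            w[j] = float(cands[tied[int(np.argmax(aucs))]])
        else:
            w[j] = float(cands[tied[0]])
    best_w = w
    best_ef, best_mrr, best_l1 = evaluate(best_w)
    metas = [table.meta(k) for k in keys]
    coeffs = [1.0] + [float(c) for c in best_w]
    return ConsensusModel(metas, coeffs, best_ef, best_ef, best_mrr, seed)


# -- subset search -------------------------------------------------------


def _rank_key(model: ConsensusModel) -> tuple:
    return (
        model.ef_train,
        model.mrr if model.mrr is not None else 0.0,
        -model.l1_norm,
        tuple(sorted(v.key for v in model.variables)),
    )


def _fit_best_ordering(
    table: ScoreTable,
    orderings: Sequence[Sequence[str]],
    fraction: float,
    seed: int,
    **opt_kw,
) -> ConsensusModel:
    best: ConsensusModel | None = None
    for ordered in orderings:
        sub_seed = _derive_seed(seed, *ordered)
        m = optimize_coefficients(table, ordered, fraction, sub_seed, **opt_kw)
        # Orderings of one subset are reparametrizations of the same model
        # class: equal (EF, MRR) means equivalent rankings, so the first
        # (canonical) ordering is kept rather than tie-breaking on L1,
        # which would merely prefer the smaller-coefficient parametrization.
        if best is None or (m.ef_train, m.mrr) > (best.ef_train, best.mrr):
            best = m
    assert best is not None
    return best


def search_combinations(
    table: ScoreTable,
    constraint: SearchConstraint,
    fraction: float = 0.01,
    seed: int = 0,
    beam_width: int = 50,
    **opt_kw,
) -> list[ConsensusModel]:
    """Search score-column subsets for the best EF consensus models.

    Sizes 1 and 2 are enumerated exhaustively; sizes 3-4 extend the top
    ``beam_width`` smaller models with each remaining column.  Each subset
    is fitted once per choice of leading variable.  Only models satisfying
    the constraint are returned, sorted best-first.
    """
    pool = list(constraint.allowed_columns or table.column_keys)
    _check_oriented(table, pool)
    X = table.matrix(pool)
    sds = np.nanstd(X, axis=0)
    pool = [k for k, sd in zip(pool, sds) if np.isfinite(sd) and sd > 0]
    if not pool:
        raise ValueError("no usable (non-constant) score columns in pool")
    metas = {k: table.meta(k) for k in pool}
    pool_chains = {m.chain for m in metas.values() if m.chain is not None}
    pool_frames = {m.frame for m in metas.values() if m.frame is not None}
    if len(pool_chains) < constraint.min_distinct_chains:
        raise ValueError(
            f"constraint unsatisfiable: pool spans {len(pool_chains)} chain(s), "
            f"needs {constraint.min_distinct_chains}"
        )
    if len(pool_frames) < constraint.min_distinct_frames:
        raise ValueError(
            f"constraint unsatisfiable: pool spans {len(pool_frames)} frame(s), "
            f"needs {constraint.min_distinct_frames}"
        )
    if constraint.max_vars < max(
        constraint.min_distinct_chains, constraint.min_distinct_frames
    ):
        raise ValueError("constraint unsatisfiable: max_vars too small")

    emitted: list[ConsensusModel] = []
    level: list[ConsensusModel] = []  # fitted models of the current size

    # size 1
    for key in pool:
        m = _fit_best_ordering(table, [[key]], fraction, seed, **opt_kw)
        level.append(m)
        if constraint.admissible(m.variables):
            emitted.append(m)

    # size 2: exhaustive over unordered pairs, both leading choices
    if constraint.max_vars >= 2:
        nxt: list[ConsensusModel] = []
        for a, b in itertools.combinations(pool, 2):
            if not constraint.extensible([metas[a], metas[b]]):
                continue
            m = _fit_best_ordering(table, [[a, b], [b, a]], fraction, seed, **opt_kw)
            nxt.append(m)
            if constraint.admissible(m.variables):
                emitted.append(m)
        level = nxt

    # sizes 3..max_vars: beam extension
    for _size in range(3, constraint.max_vars + 1):
        beam = sorted(level, key=_rank_key, reverse=True)[:beam_width]
        seen: set[frozenset[str]] = set()
        nxt = []
        for parent in beam:
            pkeys = [v.key for v in parent.variables]
            for new in pool:
                if new in pkeys:
                    continue
                subset = frozenset(pkeys + [new])
                if subset in seen:
                    continue
                seen.add(subset)
                if not constraint.extensible([metas[k] for k in subset]):
                    continue
                m = _fit_best_ordering(
                    table, [pkeys + [new], [new] + pkeys], fraction, seed, **opt_kw
                )
                nxt.append(m)
                if constraint.admissible(m.variables):
                    emitted.append(m)
        level = nxt

    return sorted(emitted, key=_rank_key, reverse=True)


def best_per_size(models: Sequence[ConsensusModel]) -> dict[int, ConsensusModel]:
    """Best model for each subset size, preserving the search's ordering."""
    out: dict[int, ConsensusModel] = {}
    for m in models:
        size = len(m.variables)
        if size not in out or _rank_key(m) > _rank_key(out[size]):
            out[size] = m
    return dict(sorted(out.items()))


# -- validation and application -----------------------------------------


def validate_model(
    table: ScoreTable,
    model: ConsensusModel,
    seed: int = 0,
    n_repeats: int = 5,
    train_fraction: float = 0.7,
    fraction: float = 0.01,
    **opt_kw,
) -> ValidationReport:
    """Repeated stratified 70/30 validation of a consensus model.

    Each repeat refits the coefficients (same column subset) on the training
    split and records EF at ``fraction`` on the held-out split.  Stratified
    splitting preserves the ~1% active rate, without which a 30% test set of
    a 53-active library often contains too few actives for EF 1% to mean
    anything.  A test split with zero actives is re-drawn with the next seed.
    """
    keys = [v.key for v in model.variables]
    labels = table.labels
    ids = table.ligand_ids
    test_efs: list[float] = []
    draw_seed = seed % _SEED_MOD
    repeats_done = 0
    while repeats_done < n_repeats:
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=train_fraction, random_state=draw_seed
        )
        (train_idx, test_idx), = splitter.split(np.zeros(len(labels)), labels)
        draw_seed = (draw_seed + 1) % _SEED_MOD
        if labels[test_idx].sum() == 0:
            continue  # EF undefined on this draw: re-draw with next seed
        train = table.subset_ligands(ids[train_idx])
        test = table.subset_ligands(ids[test_idx])
        refit = optimize_coefficients(
            train, keys, fraction, _derive_seed(seed, "val", str(repeats_done)),
            **opt_kw,
        )
        test_ef = float(
            ef_of_values(
                test.matrix(keys) @ np.asarray(refit.coefficients),
                test.labels,
                fraction,
            )
        )
        test_efs.append(test_ef)
        repeats_done += 1
    return ValidationReport(
        n_repeats=n_repeats,
        train_fraction=train_fraction,
        test_efs=test_efs,
        mean_test_ef=float(np.mean(test_efs)),
        seed=seed,
    )


def score_with_model(table: ScoreTable, model: ConsensusModel) -> Ranking:
    """Apply a fitted model to a (possibly new) score table."""
    missing = [v.key for v in model.variables if v.key not in table.column_keys]
    if missing:
        raise KeyError(f"table lacks model column(s): {missing}")
    return rank_ligands(table, model.weights)
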