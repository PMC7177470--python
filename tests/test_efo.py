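"""EFO optimizer: coefficient fitting, subset search, validation."""

import numpy as np
import pytest

from vsensemble import efo
from vsensemble import synthetic as syn
from vsensemble.enrichment import ef_of_values
from .conftest import make_table


def test_single_column_model_has_that_columns_ef(rng):
    values = rng.normal(size=100) + 2.0 * (rng.random(100) < 0.1)
    labels = (rng.random(100) < 0.1).astype(int)
    labels[0] = 1
    t = make_table(values[:, None], labels)
    m = efo.optimize_coefficients(t, t.column_keys, fraction=0.05)
    assert m.coefficients == [1.0]
    assert m.ef_train == pytest.approx(ef_of_values(values, labels, 0.05))


def test_complementary_toy_instance_needs_both_columns():
    """Active (1,1) vs inactives (1.6,0), (0,1.6), (0.5,0.5): only the sum
    puts the active first (any w in (0.6, 2.5) works); each single column
    ranks an inactive on top."""
    X = np.array([[1.0, 1.0], [1.6, 0.0], [0.0, 1.6], [0.5, 0.5]])
    labels = np.array([1, 0, 0, 0])
    t = make_table(X, labels)
    for j in range(2):
        assert ef_of_values(X[:, j], labels, 0.25) == 0.0
    m = efo.optimize_coefficients(t, t.column_keys, fraction=0.25)
    assert m.ef_train == pytest.approx(4.0)
    assert 0.6 < m.coefficients[1] < 2.5


def test_constant_column_rejected():
    t = make_table(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]), [1, 0, 0])
    with pytest.raises(ValueError, match="constant"):
        efo.optimize_coefficients(t, t.column_keys, fraction=0.5)


def test_optimizer_deterministic(rng):
    X = rng.normal(size=(300, 3)) + 1.5 * (rng.random((300, 1)) < 0.05)
    labels = (rng.random(300) < 0.05).astype(int)
    labels[:3] = 1
    t = make_table(X, labels)
    m1 = efo.optimize_coefficients(t, t.column_keys, 0.02, seed=11)
    m2 = efo.optimize_coefficients(t, t.column_keys, 0.02, seed=11)
    assert m1.coefficients == m2.coefficients
    assert m1.ef_train == m2.ef_train


def test_leading_coefficient_fixed_and_validated():
    with pytest.raises(ValueError, match="leading"):
        efo.ConsensusModel(
            [efo.ScoreColumnMeta("PS", "A", "1")], [2.0], ef_train=1.0
        )


def test_planted_pair_coefficient_recovery():
    """With (u+v, u-v) planted, the fitted ratio concentrates near 1
    (exact cancellation of the nuisance v)."""
    table, pair = syn.complementary_pair_campaign(seed=3)
    m = efo.optimize_coefficients(t := table, list(pair), 0.01, seed=3)
    assert m.ef_train > ef_of_values(t.matrix([pair[0]])[:, 0], t.labels, 0.01)
    assert abs(m.coefficients[1]) == pytest.approx(1.0, abs=0.15)


def test_search_size1_equals_argmax_single_ef(rng):
    X = rng.normal(size=(200, 5)) + rng.uniform(0, 2, 5) * (
        rng.random((200, 1)) < 0.05
    )
    labels = (rng.random(200) < 0.05).astype(int)
    labels[:2] = 1
    t = make_table(X, labels, chains=list("ABCDA"), frames=["1"] * 5)
    models = efo.search_combinations(
        t, efo.SearchConstraint(max_vars=1), 0.02, seed=0
    )
    singles = [ef_of_values(X[:, j], labels, 0.02) for j in range(5)]
    assert models[0].ef_train == pytest.approx(max(singles))


def test_search_candidate_counting(rng):
    """6 columns, max_vars=2: exactly C(6,1) + C(6,2) subsets considered."""
    X = rng.normal(size=(60, 6))
    labels = np.zeros(60, dtype=int)
    labels[:3] = 1
    t = make_table(X, labels, chains=list("ABCDAB"), frames=["1"] * 6)
    models = efo.search_combinations(
        t, efo.SearchConstraint(max_vars=2), 0.05, seed=0
    )
    assert len(models) == 6 + 15
    sizes = sorted(len(m.variables) for m in models)
    assert sizes == [1] * 6 + [2] * 15


def test_search_unsatisfiable_constraint_errors(rng):
    X = rng.normal(size=(30, 3))
    labels = np.array([1] + [0] * 29)
    t = make_table(X, labels, chains=["A", "A", "A"], frames=["1"] * 3)
    with pytest.raises(ValueError, match="unsatisfiable"):
        efo.search_combinations(
            t, efo.SearchConstraint(min_distinct_chains=2), 0.1, seed=0
        )


def test_search_constraint_enforced_on_outputs():
    table, pair = syn.complementary_pair_campaign(seed=5)
    models = efo.search_combinations(
        table, efo.SearchConstraint(max_vars=2, min_distinct_chains=2), 0.01, seed=5
    )
    assert models and all(m.distinct_chains() >= 2 for m in models)
    # the planted cross-chain pair is the best model
    assert sorted(v.key for v in models[0].variables) == sorted(pair)


def test_best_training_ef_non_decreasing_with_max_vars(rng):
    X = rng.normal(size=(120, 4)) + np.array([1.2, 0.8, 0.5, 0.3]) * (
        rng.random((120, 1)) < 0.05
    )
    labels = (rng.random(120) < 0.05).astype(int)
    labels[:2] = 1
    t = make_table(X, labels, chains=list("ABCD"), frames=["1"] * 4)
    best = []
    for max_vars in (1, 2, 3):
        models = efo.search_combinations(
            t, efo.SearchConstraint(max_vars=max_vars), 0.05, seed=1, beam_width=20
        )
        best.append(models[0].ef_train)
    assert best[0] <= best[1] <= best[2]


def test_validation_deterministic_and_separable(rng):
    # perfectly separable synthetic table: every test EF is the maximum
    # attainable for the test-set size
    n = 400
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, 8, replace=False)] = 1
    values = labels * 100.0 + rng.normal(0, 1, n)
    t = make_table(values[:, None], labels)
    m = efo.optimize_coefficients(t, t.column_keys, 0.02, seed=0)
    rep = efo.validate_model(t, m, seed=9, fraction=0.02)
    rep2 = efo.validate_model(t, m, seed=9, fraction=0.02)
    assert rep == rep2
    assert rep.n_repeats == 5 and len(rep.test_efs) == 5
    # perfect separation: every held-out top slot is an active, so each
    # test EF sits at the maximum attainable for its split's active count
    assert all(ef >= 20.0 for ef in rep.test_efs)
    assert rep.mean_test_ef == pytest.approx(np.mean(rep.test_efs))


def test_score_with_model_consistency_and_errors(rng):
    X = rng.normal(size=(200, 2)) + 1.5 * (rng.random((200, 1)) < 0.05)
    labels = (rng.random(200) < 0.05).astype(int)
    labels[:2] = 1
    t = make_table(X, labels)
    m = efo.optimize_coefficients(t, t.column_keys, 0.02, seed=2)
    # model over the table it was fitted on reproduces ef_train
    from vsensemble.enrichment import enrichment_factor

    r = efo.score_with_model(t, m)
    assert enrichment_factor(r, fraction=0.02).ef == pytest.approx(m.ef_train)
    # permuted row order -> identical ranking
    perm = rng.permutation(t.n_ligands)
    t_perm = t.subset_ligands(t.ligand_ids[perm])
    r_perm = efo.score_with_model(t_perm, m)
    assert r_perm.ligand_ids == r.ligand_ids
    # missing column named in the error
    t_missing = t.subset_columns(t.column_keys[:1])
    with pytest.raises(KeyError, match=t.column_keys[1]):
        efo.score_with_model(t_missing, m)


def test_zero_coefficient_equals_reduced_model(rng):
    X = rng.normal(size=(100, 2))
    labels = (rng.random(100) < 0.1).astype(int)
    labels[0] = 1
    t = make_table(X, labels)
    full = efo.ConsensusModel(
        [t.meta(k) for k in t.column_keys], [1.0, 0.0], ef_train=0.0
    )
    reduced = efo.ConsensusModel([t.meta(t.column_keys[0])], [1.0], ef_train=0.0)
    assert (
        efo.score_with_model(t, full).ligand_ids
        == efo.score_with_model(t, reduced).ligand_ids
    )


def test_model_json_round_trip(tmp_path, rng):
    X = rng.normal(size=(100, 2)) + (rng.random((100, 1)) < 0.05)
    labels = (rng.random(100) < 0.05).astype(int)
    labels[0] = 1
    t = make_table(X, labels, chains=["A", "C"], frames=["990", "990"])
    m = efo.optimize_coefficients(t, t.column_keys, 0.05, seed=4)
    m.validation = efo.validate_model(t, m, seed=4, fraction=0.05)
    p = tmp_path / "model.json"
    m.save(p)
    again = efo.ConsensusModel.load(p)
    assert again == m
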