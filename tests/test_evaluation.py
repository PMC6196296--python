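import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gismma import (
    AssociationMatrix,
    global_loocv,
    kfold_cv,
    local_loocv_fixed_mirna,
    local_loocv_fixed_sm,
    roc_auc,
    toy_fixture,
)
from gismma import evaluation, model, predict
from gismma.errors import ValidationError
from gismma.graphlets import counted_and_normalized

from oracles import mann_whitney_auc


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([3, 4], [1, 2])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([5.0, 5.0, 5.0], [5.0, 5.0])
        assert auc == 0.5

    def test_partial_ties_hand_count(self):
        # pairs: (2>1), (2==3 -> 0.5... no: 2<3 -> 0), (3>1), (3==3 -> 0.5)
        _, auc = roc_auc([2, 3], [1, 3])
        assert auc == (1 + 0 + 1 + 0.5) / 4

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([], [1.0])

    def test_curve_monotone_from_origin_to_corner(self, rng):
        pos = rng.normal(1, 1, 40)
        neg = rng.normal(0, 1, 60)
        points, _ = roc_auc(pos, neg)
        assert tuple(points[0]) == (0.0, 0.0)
        assert tuple(points[-1]) == (1.0, 1.0)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sweep_equals_mann_whitney_exactly(self, data):
        """Dual computation: trapezoidal threshold-sweep area is bitwise
        identical to the pair-ordering statistic, ties counted half."""
        grid = st.integers(min_value=0, max_value=4)  # coarse -> many ties
        pos = data.draw(st.lists(grid, min_size=1, max_size=12))
        neg = data.draw(st.lists(grid, min_size=1, max_size=12))
        _, auc = roc_auc(pos, neg)
        assert auc == mann_whitney_auc(pos, neg)


@pytest.fixture(scope="module")
def toy():
    fx = toy_fixture()
    tensors = (
        counted_and_normalized(fx.sm_similarity),
        counted_and_normalized(fx.mirna_similarity),
    )
    return fx, tensors


def _perfect_scorer(associations_full):
    """Stand-in scorer that always reproduces the *full* adjacency, so every
    held-out known pair outscores every unknown pair by construction."""
    full = associations_full.values.astype(float)

    def scorer(tensor_sm, tensor_mirna, train):
        return full

    return scorer


class TestLoocvSchemes:
    @pytest.mark.parametrize(
        "scheme_fn",
        [global_loocv, local_loocv_fixed_mirna, local_loocv_fixed_sm],
    )
    def test_perfect_separation_gives_auc_one(self, scheme_fn, toy, monkeypatch):
        fx, tensors = toy
        monkeypatch.setattr(
            model, "fit_predict_from_tensors", _perfect_scorer(fx.associations)
        )
        result = scheme_fn(
            fx.sm_similarity, fx.mirna_similarity, fx.associations, tensors=tensors
        )
        assert result.auc == 1.0
        assert result.n_test == fx.associations.n_known

    def test_random_scores_give_chance_auc(self, monkeypatch):
        """Scores independent of the labels must land near AUC 0.5."""
        rng = np.random.default_rng(42)
        n_sm, n_mi = 20, 40
        a = np.zeros((n_sm, n_mi), dtype=int)
        idx = rng.choice(n_sm * n_mi, 60, replace=False)
        a.flat[idx] = 1
        assoc = AssociationMatrix(
            tuple(f"s{i}" for i in range(n_sm)),
            tuple(f"m{j}" for j in range(n_mi)),
            a,
        )
        fixed_scores = rng.normal(size=(n_sm, n_mi))
        monkeypatch.setattr(
            model, "fit_predict_from_tensors", lambda *args: fixed_scores
        )
        result = global_loocv(None, None, assoc, tensors=(None, None))
        assert abs(result.auc - 0.5) < 0.05

    def test_toy_ranks_match_hand_enumeration(self, toy):
        """Naive re-ranking: score each holdout with predict() and count the
        candidates above it, independent of the evaluation internals."""
        fx, tensors = toy
        result = global_loocv(
            fx.sm_similarity, fx.mirna_similarity, fx.associations, tensors=tensors
        )
        a = fx.associations.values
        by_pair = {pair: (rank, n) for pair, rank, n in result.per_test_ranks}
        for i, j in np.argwhere(a == 1):
            train = fx.associations.with_pairs_removed([(i, j)])
            scores = predict(fx.sm_similarity, fx.mirna_similarity, train).values
            cand = scores[a == 0]
            expected_rank = 1 + (cand > scores[i, j]).sum() + 0.5 * (cand == scores[i, j]).sum()
            pair = (fx.associations.sm_ids[i], fx.associations.mirna_ids[j])
            rank, n = by_pair[pair]
            assert n == int((a == 0).sum())
            assert rank == pytest.approx(expected_rank)

    def test_single_candidate_column_handled(self, toy, monkeypatch):
        """A miRNA associated with all but one small molecule leaves one
        candidate in the fixed-miRNA ranking; no division error."""
        fx, tensors = toy
        a = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], dtype=int)
        assoc = AssociationMatrix(
            fx.associations.sm_ids, fx.associations.mirna_ids, a
        )
        result = local_loocv_fixed_mirna(
            fx.sm_similarity, fx.mirna_similarity, assoc, tensors=tensors
        )
        for (_, rank, n_cand) in result.per_test_ranks:
            assert n_cand == 1
            assert rank in (1.0, 1.5, 2.0)

    def test_anti_leakage_holdout_absent_from_training(self, toy, monkeypatch):
        """Within every LOOCV iteration the held-out pair must be zero in the
        association matrix the model trains on."""
        fx, tensors = toy
        original = model.fit_predict_from_tensors
        seen_train = []

        def spy(tensor_sm, tensor_mirna, train):
            seen_train.append(train.values.copy())
            return original(tensor_sm, tensor_mirna, train)

        monkeypatch.setattr(model, "fit_predict_from_tensors", spy)
        global_loocv(
            fx.sm_similarity, fx.mirna_similarity, fx.associations, tensors=tensors
        )
        known = np.argwhere(fx.associations.values == 1)
        assert len(seen_train) == len(known)
        for (i, j), train in zip(known, seen_train):
            assert train[i, j] == 0
            # exactly one pair removed per iteration
            assert train.sum() == fx.associations.n_known - 1

    def test_empty_associations_rejected(self, toy):
        fx, tensors = toy
        empty = AssociationMatrix(
            fx.associations.sm_ids, fx.associations.mirna_ids, np.zeros((3, 3), int)
        )
        with pytest.raises(ValidationError):
            global_loocv(fx.sm_similarity, fx.mirna_similarity, empty, tensors=tensors)


class TestKfold:
    def test_same_seed_identical_results(self, toy):
        fx, tensors = toy
        r1 = kfold_cv(fx.sm_similarity, fx.mirna_similarity, fx.associations,
                      k=3, replicates=2, seed=7, tensors=tensors)
        r2 = kfold_cv(fx.sm_similarity, fx.mirna_similarity, fx.associations,
                      k=3, replicates=2, seed=7, tensors=tensors)
        assert r1.auc == r2.auc
        assert r1.per_test_ranks == r2.per_test_ranks

    def test_perfect_separation_mean_one_sd_zero(self, toy, monkeypatch):
        fx, tensors = toy
        monkeypatch.setattr(
            model, "fit_predict_from_tensors", _perfect_scorer(fx.associations)
        )
        r = kfold_cv(fx.sm_similarity, fx.mirna_similarity, fx.associations,
                     k=3, replicates=3, seed=1, tensors=tensors)
        mean, sd = r.replicate_stats
        assert mean == 1.0
        assert sd == 0.0

    def test_folds_partition_known_pairs(self, toy):
        fx, tensors = toy
        r = kfold_cv(fx.sm_similarity, fx.mirna_similarity, fx.associations,
                     k=3, replicates=1, seed=5, tensors=tensors)
        pairs = [p for p, _, _ in r.per_test_ranks]
        assert sorted(pairs) == sorted(
            (s, m) for s, m in fx.associations.known_pairs()
        )

    def test_too_many_folds_rejected(self, toy):
        fx, tensors = toy
        with pytest.raises(ValidationError):
            kfold_cv(fx.sm_similarity, fx.mirna_similarity, fx.associations,
                     k=10, replicates=1, seed=1, tensors=tensors)

    def test_seed_required(self, toy):
        fx, tensors = toy
        with pytest.raises(ValidationError, match="seed"):
            kfold_cv(fx.sm_similarity, fx.mirna_similarity, fx.associations,
                     k=3, replicates=1, tensors=tensors)


class TestDispatchAndReport:
    def test_unknown_scheme_rejected(self, toy):
        fx, tensors = toy
        with pytest.raises(ValidationError, match="scheme"):
            evaluation.evaluate(
                fx.sm_similarity, fx.mirna_similarity, fx.associations, "bogus"
            )

    def test_report_is_json_serializable(self, toy):
        fx, tensors = toy
        r = kfold_cv(fx.sm_similarity, fx.mirna_similarity, fx.associations,
                     k=3, replicates=2, seed=3, tensors=tensors)
        report = evaluation.result_report(r, seed=3, config={"k": 3})
        text = json.dumps(report)
        assert json.loads(text)["scheme"] == "kfold"
        assert "auc_sd" in report
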