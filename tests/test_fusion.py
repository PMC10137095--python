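import numpy as np
import pytest

from ststp.fusion import (build_ststp, guided_select, redundancy_matrix,
                          relevance, selection_criterion)


# ---------------------------------------------------------------------------
# independent oracles: literal restatements of the merit and the search
# ---------------------------------------------------------------------------

def merit_oracle(subset, X, y):
    """J = sum(rel) / sqrt(k + sum_{l != u} red), evaluated naively."""
    def r2(a, b):
        c = np.corrcoef(a, b)[0, 1]
        return 0.0 if np.isnan(c) else c * c

    rel = sum(r2(X[:, j], y) for j in subset)
    red = sum(r2(X[:, l], X[:, u])
              for l in subset for u in subset if l != u)
    return rel / np.sqrt(len(subset) + red)


def stepwise_oracle(X, y, tol=1e-4):
    """Exhaustive add/drop stepwise search mirroring the stated policy."""
    pool = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    selected, steps, j_cur = [], [], -np.inf
    while True:
        cands = [c for c in pool if c not in selected]
        if not cands:
            break
        scored = [(merit_oracle(selected + [c], X, y), c) for c in cands]
        best_j = max(s for s, _ in scored)
        best_c = min(c for s, c in scored if s >= best_j - 1e-15)
        if best_j <= j_cur + tol and selected:
            break
        selected.append(best_c)
        j_cur = best_j
        steps.append(("add", best_c))
        while len(selected) > 2:
            scored = [(merit_oracle([s for s in selected if s != d], X, y), d)
                      for d in selected[:-1]]
            best_jd = max(s for s, _ in scored)
            if best_jd <= j_cur + tol:
                break
            best_d = min(d for s, d in scored if s >= best_jd - 1e-15)
            selected = [s for s in selected if s != best_d]
            j_cur = best_jd
            steps.append(("drop", best_d))
    return selected, steps


def _dataset(rng, n=60, p=6, informative=0):
    y = rng.integers(0, 2, n).astype(float)
    while len(set(y)) < 2:
        y = rng.integers(0, 2, n).astype(float)
    X = rng.normal(size=(n, p))
    X[:, informative] += 2.0 * y
    return X, y


class TestBuild:
    def test_lengths_are_additive(self):
        rng = np.random.default_rng(0)
        v = build_ststp(rng.normal(size=(4, 8)), rng.normal(size=(4, 6)),
                        rng.normal(size=(4, 10)), rng.normal(size=(4, 4)))
        assert v.matrix.shape == (4, 28)
        assert v.slices == {"CNN": (0, 8), "OF": (8, 6), "PCA": (14, 10),
                            "EAR": (24, 4)}

    def test_absent_modality_slice_stays_zero(self):
        rng = np.random.default_rng(1)
        blocks = dict(cnn_emb=rng.normal(size=(3, 5)),
                      of_vec=rng.normal(size=(3, 6)),
                      pca_vec=np.zeros((3, 10)),
                      ear_vec=rng.normal(size=(3, 5)))
        v = build_ststp(**blocks)
        assert np.all(v.block("PCA") == 0.0)
        assert np.array_equal(v.block("CNN"), blocks["cnn_emb"])

    def test_deconcatenation_recovers_inputs(self):
        rng = np.random.default_rng(2)
        blocks = [rng.normal(size=(5, d)) for d in (3, 6, 2, 5)]
        v = build_ststp(*blocks)
        for name, arr in zip(("CNN", "OF", "PCA", "EAR"), blocks):
            assert np.array_equal(v.block(name), arr)

    def test_row_count_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="keyframe count"):
            build_ststp(rng.normal(size=(3, 2)), rng.normal(size=(4, 2)),
                        rng.normal(size=(3, 2)), rng.normal(size=(3, 2)))


class TestCriterion:
    def test_matches_literal_formula_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X, y = _dataset(rng, n=40, p=5)
            subset = sorted(rng.choice(5, rng.integers(1, 5), replace=False))
            assert selection_criterion(subset, X, y) == pytest.approx(
                merit_oracle(subset, X, y), abs=1e-10)

    def test_dominant_singleton_wins(self):
        rng = np.random.default_rng(5)
        X, y = _dataset(rng, n=80, p=4, informative=2)
        X[:, 2] = y  # perfect predictor
        scores = [selection_criterion([j], X, y) for j in range(4)]
        assert np.argmax(scores) == 2

    def test_duplicate_feature_never_raises_merit(self):
        rng = np.random.default_rng(6)
        X, y = _dataset(rng, n=60, p=3, informative=0)
        X[:, 1] = X[:, 0]  # exact duplicate
        j_single = selection_criterion([0], X, y)
        j_dup = selection_criterion([0, 1], X, y)
        assert j_dup <= j_single + 1e-12

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            selection_criterion([], np.zeros((3, 2)), np.array([0, 1, 0]))


class TestGuidedSelect:
    def test_path_matches_exhaustive_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            p = int(rng.integers(4, 9))
            X, y = _dataset(rng, p=p, informative=int(rng.integers(0, p)))
            state = guided_select(X, y)
            sel_oracle, steps_oracle = stepwise_oracle(X, y)
            assert state.steps == steps_oracle
            assert state.selected == sel_oracle

    def test_planted_informative_feature_found_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            X, y = _dataset(rng, n=60, p=5, informative=3)
            state = guided_select(X, y)
            hits += state.steps[0] == ("add", 3)
        assert hits >= 19

    def test_exact_duplicates_never_co_selected(self):
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            X, y = _dataset(rng, n=60, p=6, informative=1)
            X[:, 4] = X[:, 1]
            state = guided_select(X, y)
            assert not {1, 4} <= set(state.selected)

    def test_accepted_merit_history_non_decreasing(self):
        rng = np.random.default_rng(7)
        X, y = _dataset(rng, n=80, p=8, informative=2)
        state = guided_select(X, y)
        assert np.all(np.diff(state.j_history) >= -1e-12)

    def test_final_subset_stable_under_column_permutation(self):
        rng = np.random.default_rng(8)
        X, y = _dataset(rng, n=80, p=6, informative=2)
        perm = rng.permutation(6)
        state = guided_select(X, y)
        state_p = guided_select(X[:, perm], y)
        assert sorted(perm[state_p.selected]) == sorted(state.selected)

    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="class"):
            guided_select(rng.normal(size=(10, 3)), np.zeros(10))

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(10)
        X, y = _dataset(rng, n=40, p=4, informative=0)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            state = guided_select(X, y)
        assert 2 not in state.pool


class TestSupport:
    def test_relevance_and_redundancy_shapes(self):
        rng = np.random.default_rng(11)
        X, y = _dataset(rng, n=30, p=4)
        rel = relevance(X, y)
        red = redundancy_matrix(X)
        assert rel.shape == (4,) and red.shape == (4, 4)
        assert np.allclose(red, red.T)
        assert np.allclose(np.diag(red), 1.0)
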