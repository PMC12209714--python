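"""Tests of covariate adjustment, the polytope fit, the adjusted Rand index
(against a brute-force pair-counting oracle), label alignment/consensus and
the stability-based selection of K."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from neurosubtype.subtyping import (
    Assignment,
    PolytopeModel,
    SubtypingConfig,
    adjusted_rand_index,
    align_labels,
    assign,
    consensus_assignment,
    fit_polytope,
    relabel,
    residualize_covariates,
    stability_profile,
    subtype_cohort,
)


def ari_pair_counting(a, b):
    """Brute-force oracle: count agreeing/disagreeing subject pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        n11 += same_a and same_b
        n00 += (not same_a) and (not same_b)
        n10 += same_a and (not same_b)
        n01 += (not same_a) and same_b
    total = n11 + n00 + n10 + n01
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


class TestResidualization:
    def test_control_residuals_standardized(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        Xc = feats.X_controls
        np.testing.assert_allclose(Xc.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Xc.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_planted_betas_recovered(self, default_cohort):
        cfg, table, _ = default_cohort
        feats = residualize_covariates(table)
        # betas rows: intercept, age, tiv
        assert feats.betas.shape == (3, table.n_regions)
        assert feats.betas[1].mean() == pytest.approx(cfg.beta_age, abs=5e-4)
        assert feats.betas[2].mean() == pytest.approx(cfg.beta_tiv, abs=5e-4)

    def test_fit_on_controls_only_preserves_disease_effect(self, small_cohort):
        cfg, table, truth = small_cohort
        feats = residualize_covariates(table)
        is_s1 = (truth["true_subtype"] == "subtype1").to_numpy()
        affected0 = cfg.affected_regions - 1
        gap = feats.X[is_s1][:, affected0].mean() - feats.X_controls[:, affected0].mean()
        # planted effect is effect_size in control-SD units
        assert gap == pytest.approx(cfg.effect_size, abs=0.35)

    def test_labels_and_ids(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        assert set(feats.labels.tolist()) == {-1, 1}
        assert (feats.labels == 1).sum() == table.is_patient.sum()
        np.testing.assert_array_equal(feats.patient_ids, table.subject_ids[table.is_patient])

    def test_constant_covariate_rejected(self, small_cohort):
        _, table, _ = small_cohort
        bad = table.data.copy()
        bad["age"] = 45.0
        from neurosubtype.io import MorphometryTable

        with pytest.raises(ValueError, match="constant among controls"):
            residualize_covariates(MorphometryTable(data=bad))

    def test_too_few_controls_rejected(self, small_cohort):
        _, table, _ = small_cohort
        from neurosubtype.io import MorphometryTable

        few = table.data.copy()
        keep = (few["group"] == "patient") | (few.index < 3)
        with pytest.raises(ValueError, match="at least 4 controls"):
            residualize_covariates(MorphometryTable(data=few[keep].reset_index(drop=True)))


class TestAdjustedRandIndex:
    def test_exhaustive_small_partitions_match_oracle(self):
        """Every pair of partitions of up to 6 elements into up to 3 labels."""
        n = 6
        parts = list(itertools.product(range(3), repeat=n))[:150]
        rng = np.random.default_rng(0)
        picks = rng.choice(len(parts), size=(60, 2))
        for i, j in picks:
            a, b = np.array(parts[i]), np.array(parts[j])
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_pair_counting(a, b), abs=1e-12
            )

    def test_matches_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(2, 40)
            a = rng.integers(0, rng.integers(1, 6), n)
            b = rng.integers(0, rng.integers(1, 6), n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_degenerate_single_cluster(self):
        assert adjusted_rand_index([1, 1, 1], [2, 2, 2]) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            adjusted_rand_index([], [])
        with pytest.raises(ValueError, match="mismatch"):
            adjusted_rand_index([1, 2], [1, 2, 3])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=30),
        st.permutations(range(5)),
    )
    def test_relabeling_invariance(self, labels, perm):
        a = np.array(labels)
        b = np.array([perm[v] for v in labels])
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)
        assert adjusted_rand_index(a, a) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_symmetry_and_bounds(self, data):
        n = data.draw(st.integers(2, 25))
        a = np.array(data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n)))
        b = np.array(data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n)))
        ab = adjusted_rand_index(a, b)
        assert ab == pytest.approx(adjusted_rand_index(b, a), abs=1e-12)
        assert ab <= 1.0 + 1e-12


class TestAlignmentAndConsensus:
    def test_align_known_permutation(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([3, 3, 1, 1, 2, 2])
        mapping = align_labels(a, b)
        np.testing.assert_array_equal(relabel(b, mapping), a)

    def test_align_with_noise(self):
        a = np.array([1, 1, 1, 2, 2, 2])
        b = np.array([2, 2, 1, 1, 1, 1])  # best map: 2->1, 1->2
        aligned = relabel(b, align_labels(a, b))
        assert (aligned == a).sum() == 5

    def test_consensus_majority_and_tiebreak(self):
        ids = np.array(["p1", "p2", "p3"])
        mk = lambda lab: Assignment(
            labels=np.array(lab), scores=np.zeros((3, 2)), subject_ids=ids
        )
        # third patient: votes 1, 2, 2 after alignment -> 2; first two stable
        cons = consensus_assignment([mk([1, 2, 1]), mk([1, 2, 2]), mk([2, 1, 1])])
        np.testing.assert_array_equal(cons[:2], [1, 2])
        # even split 1/2 on every patient -> lowest label wins
        cons = consensus_assignment([mk([1, 2, 1]), mk([1, 2, 1])])
        np.testing.assert_array_equal(cons, [1, 2, 1])

    def test_consensus_requires_consistent_subjects(self):
        a = Assignment(np.array([1, 2]), np.zeros((2, 2)), np.array(["p1", "p2"]))
        b = Assignment(np.array([1, 2]), np.zeros((2, 2)), np.array(["p1", "p9"]))
        with pytest.raises(ValueError, match="inconsistent"):
            consensus_assignment([a, b])
        with pytest.raises(ValueError, match="at least one"):
            consensus_assignment([])


class TestPolytopeFit:
    def test_manual_model_scores_are_distances(self):
        W = np.array([[3.0, 0.0], [0.0, 4.0]])
        b = np.array([3.0, -8.0])
        model = PolytopeModel(K=2, W=W, b=b, C=1.0, seed=0, n_restarts=1,
                              objective=0.0, converged=True, n_iter=1)
        S = model.scores(np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(S[0], [(3 + 3) / 3, (4 - 8) / 4])
        a = assign(model, np.array([[1.0, 1.0]]))
        assert a.labels[0] == 1

    def test_assign_tie_goes_to_lowest_face(self):
        W = np.array([[1.0, 0.0], [1.0, 0.0]])
        b = np.array([0.0, 0.0])
        model = PolytopeModel(K=2, W=W, b=b, C=1.0, seed=0, n_restarts=1,
                              objective=0.0, converged=True, n_iter=1)
        assert assign(model, np.array([[2.0, 5.0]])).labels[0] == 1

    def test_dimension_mismatch_rejected(self):
        model = PolytopeModel(K=1, W=np.ones((1, 3)), b=np.zeros(1), C=1.0,
                              seed=0, n_restarts=1, objective=0.0,
                              converged=True, n_iter=1)
        with pytest.raises(ValueError, match="dimension"):
            model.scores(np.ones((2, 4)))

    def test_invalid_inputs(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        with pytest.raises(ValueError, match="K must be >= 1"):
            fit_polytope(feats, 0)
        with pytest.raises(ValueError, match="exceeds the number of patients"):
            fit_polytope(feats, 31)
        bad = residualize_covariates(table)
        bad.X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_polytope(bad, 2)

    def test_fit_recovers_planted_subtypes(self, small_cohort):
        _, table, truth = small_cohort
        feats = residualize_covariates(table)
        _, assignment = fit_polytope(feats, 2, seed=0, n_restarts=6)
        true_pat = truth.loc[truth["true_subtype"] != "control", "true_subtype"]
        ari = adjusted_rand_index(assignment.labels, true_pat.to_numpy())
        assert ari >= 0.8

    def test_controls_inside_polytope(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        model, _ = fit_polytope(feats, 2, seed=0, n_restarts=6)
        S = model.scores(feats.X_controls)
        # most controls sit on the negative side of every face
        assert (S.max(axis=1) < 0).mean() >= 0.8

    def test_objective_history_non_increasing(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        model, _ = fit_polytope(feats, 2, seed=0, n_restarts=1, max_iter=30)
        h = np.array(model.objective_history)
        assert len(h) >= 1
        assert (np.diff(h) <= 1e-8 * np.abs(h[:-1]) + 1e-8).all()
        assert model.converged

    def test_deterministic_given_seed(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        m1, a1 = fit_polytope(feats, 2, seed=3, n_restarts=4)
        m2, a2 = fit_polytope(feats, 2, seed=3, n_restarts=4)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        np.testing.assert_allclose(m1.W, m2.W)
        assert m1.objective == m2.objective

    def test_all_faces_populated(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        for K in (2, 3):
            _, a = fit_polytope(feats, K, seed=1, n_restarts=4, max_iter=20)
            assert set(a.labels.tolist()) == set(range(1, K + 1))


class TestStabilityAndCohort:
    def test_k2_most_stable_on_planted_cohort(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        prof = stability_profile(feats, K_range=(2, 3), n_folds=3, seed=0,
                                 n_restarts=2, max_iter=20)
        assert prof.selected_K == 2
        assert prof.mean_ari[0] > prof.mean_ari[1]
        assert prof.ks == [2, 3]
        assert set(prof.fold_assignments) == {2, 3}
        assert len(prof.fold_assignments[2]) == 3

    def test_profile_input_validation(self, small_cohort):
        _, table, _ = small_cohort
        feats = residualize_covariates(table)
        with pytest.raises(ValueError, match="K_range is empty"):
            stability_profile(feats, K_range=())
        with pytest.raises(ValueError, match="n_folds"):
            stability_profile(feats, K_range=(2,), n_folds=1)

    def test_subtype_cohort_end_to_end(self, small_cohort):
        _, table, truth = small_cohort
        cfg = SubtypingConfig(k_range=(2, 3), n_folds=3, n_restarts=4,
                              cv_restarts=2, max_iter=20, seed=0)
        result = subtype_cohort(table, cfg)
        assert result.profile.selected_K == 2
        assert len(result.consensus_labels) == 30
        true_pat = truth.loc[truth["true_subtype"] != "control", "true_subtype"]
        ari = adjusted_rand_index(result.consensus_labels, true_pat.to_numpy())
        assert ari >= 0.8
        np.testing.assert_array_equal(
            result.patient_ids, table.subject_ids[table.is_patient]
        )
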