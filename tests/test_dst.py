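"""Evidence classifier: mass construction, Dempster fusion, training, ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gait_evidence.dst import (
    OA,
    NP_GROUP,
    UNCLASSIFIED,
    VACUOUS,
    BodyOfEvidence,
    FeatureEvidenceParams,
    TotalConflictError,
    _single_feature_loo_correct,
    boe_from_feature,
    classify,
    combine,
    combine_all,
    confidence_factor,
    fit,
    loo_accuracy,
    rank_features,
    simplex_coords,
)


def combine_oracle(b1: BodyOfEvidence, b2: BodyOfEvidence) -> BodyOfEvidence:
    """Brute-force Dempster combination: enumerate all 9 set-product terms."""
    focal1 = [(frozenset({"OA"}), b1.m_oa), (frozenset({"NP"}), b1.m_np), (frozenset({"OA", "NP"}), b1.m_u)]
    focal2 = [(frozenset({"OA"}), b2.m_oa), (frozenset({"NP"}), b2.m_np), (frozenset({"OA", "NP"}), b2.m_u)]
    masses: dict[frozenset, float] = {}
    conflict = 0.0
    for (s1, m1), (s2, m2) in itertools.product(focal1, focal2):
        inter = s1 & s2
        if inter:
            masses[inter] = masses.get(inter, 0.0) + m1 * m2
        else:
            conflict += m1 * m2
    z = 1.0 - conflict
    return BodyOfEvidence(
        masses.get(frozenset({"OA"}), 0.0) / z,
        masses.get(frozenset({"NP"}), 0.0) / z,
        masses.get(frozenset({"OA", "NP"}), 0.0) / z,
    )


class TestConfidenceFactor:
    def test_midpoint_is_half(self):
        p = FeatureEvidenceParams(k=2.5, theta=1.3)
        assert confidence_factor(1.3, p) == pytest.approx(0.5)

    def test_known_value(self):
        p = FeatureEvidenceParams(k=1.0, theta=0.0)
        assert confidence_factor(math.log(3), p) == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("k", [2.0, -2.0])
    def test_strictly_monotone_with_sign_of_k(self, k):
        p = FeatureEvidenceParams(k=k, theta=0.0)
        values = np.linspace(-3, 3, 25)
        cfs = [confidence_factor(v, p) for v in values]
        diffs = np.diff(cfs)
        assert np.all(diffs > 0) if k > 0 else np.all(diffs < 0)


class TestMassConstruction:
    def test_full_confidence_commits_b(self):
        p = FeatureEvidenceParams(k=1.0, theta=0.0, A=0.2, B=0.8)
        b = boe_from_feature(1e3, p)  # cf -> 1
        assert b.m_oa == pytest.approx(0.8, abs=1e-6)
        assert b.m_np == pytest.approx(0.0, abs=1e-12)
        assert b.m_u == pytest.approx(0.2, abs=1e-6)

    def test_zero_crossing_at_cf_equal_a(self):
        p = FeatureEvidenceParams(k=1.0, theta=0.0, A=0.2, B=0.8)
        value = math.log(0.2 / 0.8)  # cf = 0.2 = A exactly
        b = boe_from_feature(value, p)
        assert b.m_oa == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_at_theta(self):
        p = FeatureEvidenceParams(k=-1.7, theta=0.4, A=0.1, B=0.9)
        b = boe_from_feature(0.4, p)
        assert b.m_oa == pytest.approx(b.m_np, abs=1e-12)

    @given(
        value=st.floats(-50, 50),
        theta=st.floats(-10, 10),
        k=st.floats(-5, 5).filter(lambda x: abs(x) > 1e-3),
        a=st.floats(0, 0.49),
        b=st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_masses_valid_and_committed_mass_capped(self, value, theta, k, a, b):
        boe = boe_from_feature(value, FeatureEvidenceParams(k=k, theta=theta, A=a, B=b))
        assert min(boe.m_oa, boe.m_np, boe.m_u) >= -1e-12
        assert boe.m_oa + boe.m_np + boe.m_u == pytest.approx(1.0, abs=1e-10)
        assert max(boe.m_oa, boe.m_np) <= b + 1e-10
        assert boe.m_u >= 1.0 - b - 1e-10

    @given(v1=st.floats(-30, 30), delta=st.floats(0.0, 30))
    @settings(max_examples=200, deadline=None)
    def test_lower_value_never_decreases_oa_mass_when_k_negative(self, v1, delta):
        p = FeatureEvidenceParams(k=-0.8, theta=1.0)
        low, high = v1 - delta, v1
        assert boe_from_feature(low, p).m_oa >= boe_from_feature(high, p).m_oa - 1e-12


class TestDempsterCombination:
    def test_worked_example(self):
        b = combine(BodyOfEvidence(0.6, 0.2, 0.2), BodyOfEvidence(0.5, 0.3, 0.2))
        assert b.m_oa == pytest.approx(0.7222, abs=5e-5)
        assert b.m_np == pytest.approx(0.2222, abs=5e-5)
        assert b.m_u == pytest.approx(0.0556, abs=5e-5)

    def test_vacuous_is_identity(self):
        b = BodyOfEvidence(0.55, 0.15, 0.3)
        out = combine(b, VACUOUS)
        assert out.as_array() == pytest.approx(b.as_array(), abs=1e-12)

    def test_total_conflict_raises(self):
        with pytest.raises(TotalConflictError):
            combine(BodyOfEvidence(1.0, 0.0, 0.0), BodyOfEvidence(0.0, 1.0, 0.0))

    def test_matches_enumeration_oracle_on_random_pairs(self, random_boe_triples):
        triples = random_boe_triples
        for i in range(0, len(triples) - 1, 2):
            b1 = BodyOfEvidence(*triples[i])
            b2 = BodyOfEvidence(*triples[i + 1])
            got = combine(b1, b2).as_array()
            want = combine_oracle(b1, b2).as_array()
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_combine_all_permutation_invariant(self, random_boe_triples):
        rng = np.random.default_rng(7)
        boes = [BodyOfEvidence(*t) for t in random_boe_triples[:5]]
        base = combine_all(boes).as_array()
        for _ in range(10):
            perm = [boes[i] for i in rng.permutation(5)]
            np.testing.assert_allclose(combine_all(perm).as_array(), base, atol=1e-10)

    def test_combine_all_singleton(self):
        b = BodyOfEvidence(0.3, 0.3, 0.4)
        assert combine_all([b]) is b

    def test_repeated_reinforcement_drives_belief_up(self):
        b = combine_all([BodyOfEvidence(0.6, 0.2, 0.2)] * 18)
        # cross-check against the iterated oracle
        acc = BodyOfEvidence(0.6, 0.2, 0.2)
        for _ in range(17):
            acc = combine_oracle(acc, BodyOfEvidence(0.6, 0.2, 0.2))
        np.testing.assert_allclose(b.as_array(), acc.as_array(), atol=1e-10)
        assert b.m_oa > 0.99


class TestClassifyAndSimplex:
    @pytest.mark.parametrize(
        "triple,expected",
        [((0.7, 0.2, 0.1), OA), ((0.2, 0.7, 0.1), NP_GROUP), ((0.4, 0.4, 0.2), UNCLASSIFIED)],
    )
    def test_decision_rule(self, triple, expected):
        assert classify(BodyOfEvidence(*triple)) == expected

    def test_vertices_map_exactly(self):
        assert simplex_coords(BodyOfEvidence(1, 0, 0)) == (1.0, 0.0)
        assert simplex_coords(BodyOfEvidence(0, 1, 0)) == (0.0, 0.0)
        x, y = simplex_coords(BodyOfEvidence(0, 0, 1))
        assert (x, y) == pytest.approx((0.5, np.sqrt(3) / 2))

    def test_centroid(self):
        x, y = simplex_coords(BodyOfEvidence(1 / 3, 1 / 3, 1 / 3))
        assert (x, y) == pytest.approx((0.5, np.sqrt(3) / 6))

    def test_belief_ties_land_on_the_median(self, random_boe_triples):
        for t in random_boe_triples[:50]:
            m = (t[0] + t[1]) / 2
            x, _ = simplex_coords(BodyOfEvidence(m, m, 1 - 2 * m))
            assert x == pytest.approx(0.5, abs=1e-12)


class TestTraining:
    def test_theta_is_class_mean_midpoint(self):
        scores = pd.DataFrame(
            {"Vertical force_PC1": [-6.54, -6.54, 7.16, 7.16]},
            index=["a", "b", "c", "d"],
        )
        labels = pd.Series(["OA", "OA", "NP", "NP"], index=scores.index)
        model = fit(scores, labels)
        p = model.params["Vertical force_PC1"]
        assert p.theta == pytest.approx(0.31, abs=1e-12)
        assert p.k < 0  # OA-low convention: negative slope
        # cf ~ 0.88 at each class mean
        assert confidence_factor(-6.54, p) == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-10)

    def test_symmetric_point_gives_equal_masses(self, tiny_scores):
        scores, labels = tiny_scores
        model = fit(scores, labels)
        f = model.features[0]
        b = boe_from_feature(model.params[f].theta, model.params[f])
        assert b.m_oa == pytest.approx(b.m_np, abs=1e-12)

    def test_training_is_deterministic(self, tiny_scores):
        scores, labels = tiny_scores
        assert fit(scores, labels).to_json() == fit(scores, labels).to_json()

    def test_zero_separation_everywhere_raises(self):
        scores = pd.DataFrame({"f_PC1": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        labels = pd.Series(["OA", "OA", "NP", "NP"], index=scores.index)
        with pytest.raises(ValueError, match="zero class-mean separation"):
            fit(scores, labels)

    def test_refinement_keeps_training_separable_data_correct(self, tiny_scores):
        scores, labels = tiny_scores
        model = fit(scores, labels, refine=True)
        preds = [classify(model.combined(scores.loc[s])) for s in scores.index]
        assert preds == list(labels)


class TestLeaveOneOut:
    def test_perfectly_separated_single_feature(self):
        scores = pd.DataFrame({"f_PC1": [-5.0] * 5 + [5.0] * 5}, index=[f"s{i}" for i in range(10)])
        labels = pd.Series(["OA"] * 5 + ["NP"] * 5, index=scores.index)
        acc, beliefs = loo_accuracy(scores, labels)
        assert acc == 1.0
        assert (beliefs["predicted"] == beliefs["true"]).all()

    def test_fast_single_feature_path_matches_general_loo(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 24)
        labels = pd.Series(["OA"] * 12 + ["NP"] * 12, index=[f"s{i}" for i in range(24)])
        scores = pd.DataFrame({"f_PC1": x}, index=labels.index)
        acc, _ = loo_accuracy(scores, labels)
        fast = _single_feature_loo_correct(x, (labels == "OA").to_numpy())
        assert fast == pytest.approx(acc)

    def test_chance_level_on_pure_noise(self):
        rng = np.random.default_rng(12)
        accs = []
        is_oa = np.array([True] * 30 + [False] * 30)
        for _ in range(200):
            accs.append(_single_feature_loo_correct(rng.normal(0, 1, 60), is_oa))
        assert abs(np.mean(accs) - 0.5) < 0.1


class TestRanking:
    def _noise_scores(self, rng, n=32, p=10):
        subjects = [f"OA{i}" for i in range(n // 2)] + [f"NP{i}" for i in range(n // 2)]
        scores = pd.DataFrame(
            rng.normal(0, 1, (n, p)), index=subjects, columns=[f"c{j}_PC1" for j in range(p)]
        )
        labels = pd.Series(["OA"] * (n // 2) + ["NP"] * (n // 2), index=subjects)
        return scores, labels

    def test_separating_feature_ranks_first_in_both_halves(self):
        scores, labels = self._noise_scores(np.random.default_rng(0))
        scores["signal_PC1"] = np.where(labels == "OA", -5.0, 5.0)
        result = rank_features(scores, labels, seed=1, top_n=3)
        assert "signal_PC1" in result.retained
        assert result.accuracy.loc["signal_PC1", "half1"] == 1.0
        assert result.accuracy.loc["signal_PC1", "half2"] == 1.0

    def test_noise_features_near_chance(self):
        scores, labels = self._noise_scores(np.random.default_rng(1), n=60, p=20)
        result = rank_features(scores, labels, seed=2, top_n=5)
        assert abs(result.accuracy.to_numpy().mean() - 0.5) < 0.12

    def test_retained_invariant_to_column_order(self):
        scores, labels = self._noise_scores(np.random.default_rng(2))
        scores["signal_PC1"] = np.where(labels == "OA", -4.0, 4.0)
        r1 = rank_features(scores, labels, seed=9, top_n=4)
        shuffled = scores[list(reversed(scores.columns))]
        r2 = rank_features(shuffled, labels, seed=9, top_n=4)
        assert set(r1.retained) == set(r2.retained)
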