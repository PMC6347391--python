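"""Per-channel waveform PCA: oracle equivalence, sign convention, round trips."""

import numpy as np
import pandas as pd
import pytest

from gait_evidence.channels import DEFAULT_CHANNELS
from gait_evidence.pca_features import (
    apply_sign_convention,
    feature_label,
    fit_pca,
    load_models,
    parse_feature_label,
    project,
    reconstruct_single_component,
    representative_extremes,
    save_models,
)
from gait_evidence.synthetic import CohortSpec, EffectSpec, cosine_modes, generate_cohort
from gait_evidence.waveform_io import WaveformSet


def _toy_set(n=6, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 1, (n, 1, 101)).cumsum(axis=2)  # smooth-ish random walks
    subjects = [f"s{i}" for i in range(n)]
    ws = WaveformSet(subjects=subjects, channels=["Vertical force"], data=data)
    labels = pd.Series(["OA"] * (n // 2) + ["NP"] * (n - n // 2), index=subjects)
    return ws, labels


class TestFitAgainstCovarianceOracle:
    def test_scores_match_explicit_eigendecomposition(self):
        ws, labels = _toy_set()
        models, scores = fit_pca(ws, labels)
        x = ws.data[:, 0, :]
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (len(ws.subjects) - 1)  # explicit 101x101 covariance
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(models[0].eigenvalues, evals[:3], atol=1e-8)
        oracle_scores = xc @ evecs[:, :3]
        # eigenvector signs are arbitrary in the oracle: compare magnitudes
        np.testing.assert_allclose(
            np.abs(scores.to_numpy()), np.abs(oracle_scores), atol=1e-8
        )

    def test_variance_fractions_are_shares(self):
        ws, labels = _toy_set(seed=1)
        models, _ = fit_pca(ws, labels)
        vf = models[0].variance_fraction
        assert np.all((vf >= 0) & (vf <= 1))
        assert np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() <= 1 + 1e-12

    def test_training_scores_are_centered(self):
        ws, labels = _toy_set(seed=2)
        _, scores = fit_pca(ws, labels)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-8)

    def test_identical_curves_give_zero_scores(self):
        data = np.tile(np.sin(np.linspace(0, 3, 101)), (5, 1, 1))
        ws = WaveformSet(subjects=[f"s{i}" for i in range(5)], channels=["Vertical force"],
                         data=data)
        labels = pd.Series(["OA", "OA", "NP", "NP", "NP"], index=ws.subjects)
        models, scores = fit_pca(ws, labels)
        np.testing.assert_allclose(models[0].eigenvalues, 0.0, atol=1e-10)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-8)
        np.testing.assert_allclose(models[0].variance_fraction, 0.0)

    def test_too_few_subjects_rejected(self):
        ws, labels = _toy_set(n=3)
        with pytest.raises(ValueError, match="training subjects"):
            fit_pca(ws, labels)


class TestProjection:
    def test_mean_curve_projects_to_zero(self):
        ws, labels = _toy_set(seed=3)
        models, _ = fit_pca(ws, labels)
        m = models[0]
        probe = WaveformSet(subjects=["m"], channels=["Vertical force"],
                            data=m.mean_curve[None, None, :])
        np.testing.assert_allclose(project(models, probe).to_numpy(), 0.0, atol=1e-10)

    def test_unit_displacement_along_eigenvector(self):
        ws, labels = _toy_set(seed=4)
        models, _ = fit_pca(ws, labels)
        m = models[0]
        probe = WaveformSet(
            subjects=["m"], channels=["Vertical force"],
            data=(m.mean_curve + 2.0 * m.eigenvectors[0])[None, None, :],
        )
        got = project(models, probe).to_numpy().ravel()
        np.testing.assert_allclose(got, [2.0, 0.0, 0.0], atol=1e-8)

    def test_projection_reproduces_training_scores(self):
        ws, labels = _toy_set(seed=5)
        models, scores = fit_pca(ws, labels)
        np.testing.assert_allclose(project(models, ws).to_numpy(), scores.to_numpy(), atol=1e-9)

    def test_missing_channel_rejected(self):
        ws, labels = _toy_set(seed=6)
        models, _ = fit_pca(ws, labels)
        other = WaveformSet(subjects=["a"], channels=["Mediolateral force"],
                            data=np.zeros((1, 1, 101)))
        with pytest.raises(ValueError, match="missing channels"):
            project(models, other)


class TestSignConvention:
    def test_flip_only_where_oa_mean_exceeds_np_mean(self):
        ws, labels = _toy_set(seed=7)
        models, scores = fit_pca(ws, labels)
        oa = scores.loc[labels == "OA"].mean()
        np_means = scores.loc[labels == "NP"].mean()
        assert np.all(np_means - oa >= -1e-12)

    def test_idempotent(self):
        ws, labels = _toy_set(seed=8)
        models, scores = fit_pca(ws, labels)
        models2, scores2 = apply_sign_convention(models, scores, labels)
        np.testing.assert_array_equal(scores.to_numpy(), scores2.to_numpy())
        for m1, m2 in zip(models, models2):
            np.testing.assert_array_equal(m1.eigenvectors, m2.eigenvectors)
            np.testing.assert_array_equal(m1.sign_flipped, m2.sign_flipped)

    def test_forced_flip_case(self):
        # one synthetic column with OA mean +2, NP mean -3 must be negated
        ws, labels = _toy_set(seed=9)
        models, scores = fit_pca(ws, labels)
        col = scores.columns[0]
        scores[col] = np.where(labels == "OA", 2.0, -3.0)
        flipped_models, flipped = apply_sign_convention(models, scores, labels)
        assert flipped.loc[labels == "OA", col].mean() == pytest.approx(-2.0)
        channel, pc = parse_feature_label(col)
        m0 = [m for m in flipped_models if m.channel == channel][0]
        assert m0.sign_flipped[pc - 1]


class TestReconstruction:
    def test_zero_score_returns_mean_curve(self):
        ws, labels = _toy_set(seed=10)
        models, _ = fit_pca(ws, labels)
        np.testing.assert_array_equal(
            reconstruct_single_component(models[0], 1, 0.0), models[0].mean_curve
        )

    def test_project_round_trip_recovers_score(self):
        ws, labels = _toy_set(seed=11)
        models, _ = fit_pca(ws, labels)
        for pc in (1, 2, 3):
            curve = reconstruct_single_component(models[0], pc, -3.7)
            score = (curve - models[0].mean_curve) @ models[0].eigenvectors[pc - 1]
            assert score == pytest.approx(-3.7, abs=1e-10)

    def test_pc_index_out_of_range(self):
        ws, labels = _toy_set(seed=12)
        models, _ = fit_pca(ws, labels)
        with pytest.raises(ValueError):
            reconstruct_single_component(models[0], 4, 1.0)

    def test_representative_extremes_bracket_the_mean(self):
        ws, labels = _toy_set(seed=13)
        models, scores = fit_pca(ws, labels)
        lo, hi = representative_extremes(models[0], 1, scores.iloc[:, 0])
        v = models[0].eigenvectors[0]
        assert (lo - models[0].mean_curve) @ v < (hi - models[0].mean_curve) @ v


class TestSerializationAndRecovery:
    def test_model_json_round_trip(self, tmp_path):
        ws, labels = _toy_set(seed=14)
        models, _ = fit_pca(ws, labels)
        path = tmp_path / "models.json"
        save_models(models, path)
        loaded = load_models(path)
        np.testing.assert_array_equal(loaded[0].eigenvectors, models[0].eigenvectors)
        np.testing.assert_array_equal(loaded[0].sign_flipped, models[0].sign_flipped)

    def test_group_mean_reconstruction_matches_generator_offset(self):
        # zero-noise cohort with well-separated mode variances: the group-mean
        # reconstruction along the first mode reproduces the generator's
        # mode x group-mean-score offset (sign flips cancel: both the
        # eigenvector and the score means flip together)
        channel = "Vertical force"
        spec = CohortSpec(
            n_oa=20, n_np=20, channels=[channel], seed=21, trial_noise_sd=0.0,
            effect_specs=[EffectSpec((channel, 1), -8.0, 1.0, -4.0, 1.0, 8.0, 1.0)],
            noise_score_sds=(9.0, 2.0, 0.5),
        )
        cohort = generate_cohort(spec)
        labels = cohort.labels
        models, scores = fit_pca(cohort.waveforms, labels)
        col = feature_label(channel, 1)
        m = models[0]
        fitted_gap = (
            scores.loc[labels == "NP", col].mean() - scores.loc[labels == "OA", col].mean()
        )
        recon_gap = (
            reconstruct_single_component(m, 1, fitted_gap)
            - reconstruct_single_component(m, 1, 0.0)
        )
        true_gap = (
            cohort.true_scores.loc[labels == "NP", col].mean()
            - cohort.true_scores.loc[labels == "OA", col].mean()
        )
        np.testing.assert_allclose(recon_gap, true_gap * cosine_modes(3)[0], atol=0.15)
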