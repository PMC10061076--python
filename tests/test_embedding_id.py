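import numpy as np
import pandas as pd
import pytest

from ecoglearn.embedding_id import (
    EmbeddingReport,
    correlate_id_performance,
    ess_local_id,
    fit_embedding,
    session_separability,
    subsample_for_embedding,
    twonn_global_id,
)
from ecoglearn.features import FeatureEpoch


def _epochs(n, shape=(4, 5, 6)):
    rng = np.random.default_rng(0)
    return [FeatureEpoch(x=rng.random(shape).astype(np.float32),
                         y=np.array([0.0, 0.0, 1.0]), state=i % 2,
                         session_index=i // 10, t_start=0.1 * i,
                         gate_match=True)
            for i in range(n)]


class TestSubsample:
    def test_stride_one_keeps_all(self):
        feats, meta = subsample_for_embedding(_epochs(30), stride=1)
        assert feats.shape == (30, 4 * 5 * 6)

    def test_stride_ten_keeps_every_tenth(self):
        feats, meta = subsample_for_embedding(_epochs(100), stride=10)
        assert feats.shape[0] == 10
        assert list(meta["session"]) == [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]

    def test_default_tensor_flattens_to_9600(self):
        feats, _ = subsample_for_embedding(_epochs(3, shape=(64, 15, 10)),
                                           stride=1)
        assert feats.shape[1] == 9600

    def test_per_hand_scope_keeps_one_state(self):
        feats, meta = subsample_for_embedding(_epochs(40), stride=1, state=1)
        assert set(meta["state"]) == {1}
        assert feats.shape[0] == 20


class TestEmbedding:
    def test_planted_clusters_stay_separated(self, rng):
        """Two well-separated Gaussian clusters in high dimension must remain
        separated in the 2D embedding (silhouette above 0.5)."""
        from sklearn.metrics import silhouette_score

        a = rng.normal(size=(100, 200))
        b = rng.normal(size=(100, 200)) + 12.0 / np.sqrt(200)
        feats = np.vstack([a, b])
        labels = np.repeat([0, 1], 100)
        report = fit_embedding(feats, seed=0)
        assert silhouette_score(report.coords, labels) > 0.5

    def test_seeded_rerun_is_identical(self, rng):
        feats = rng.normal(size=(80, 30))
        c1 = fit_embedding(feats, seed=5).coords
        c2 = fit_embedding(feats, seed=5).coords
        assert np.array_equal(c1, c2)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_embedding(rng.normal(size=(20, 10)))


class TestSessionSeparability:
    @staticmethod
    def _report(coords, sessions, states):
        meta = pd.DataFrame({"session": sessions, "state": states})
        return EmbeddingReport(coords=coords, meta=meta, scope="both_hands")

    def test_linearly_separated_session_scores_one(self, rng):
        coords = np.vstack([rng.normal(size=(30, 2)),
                            rng.normal(size=(30, 2)) + 20.0])
        rep = self._report(coords, [0] * 60, [0] * 30 + [1] * 30)
        sep = session_separability(rep)
        assert sep.per_session["accuracy"].iloc[0] == 1.0

    def test_identical_clouds_score_near_chance(self, rng):
        pts = rng.normal(size=(40, 2))
        coords = np.vstack([pts, pts])
        rep = self._report(coords, [0] * 80, [0] * 40 + [1] * 40)
        sep = session_separability(rep)
        assert abs(sep.per_session["accuracy"].iloc[0] - 0.5) <= 0.1

    def test_single_state_session_flagged(self, rng):
        coords = rng.normal(size=(20, 2))
        rep = self._report(coords, [0] * 20, [0] * 20)
        sep = session_separability(rep)
        assert sep.per_session["flagged"].iloc[0]
        assert np.isnan(sep.per_session["accuracy"].iloc[0])

    def test_accuracy_invariant_to_rigid_transform(self, rng):
        coords = np.vstack([rng.normal(size=(25, 2)),
                            rng.normal(size=(25, 2)) + [3.0, 0.0]])
        states = [0] * 25 + [1] * 25
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        acc1 = session_separability(
            self._report(coords, [0] * 50, states)).per_session["accuracy"][0]
        acc2 = session_separability(
            self._report(coords @ rot.T + 7.0, [0] * 50, states)
        ).per_session["accuracy"][0]
        assert acc1 == pytest.approx(acc2, abs=0.05)

    def test_ramped_separability_study_has_significant_trend(self):
        """A study whose planted left/right pattern distance ramps up across
        sessions shows a significantly positive separability trend."""
        from ecoglearn.features import FeatureConfig, featurize_study
        from ecoglearn.synthgen import StudyParams, generate_study

        n = 12
        params = StudyParams(n_sessions=n, trials_per_session=8,
                             trial_duration=4.0, n_channels=16,
                             sampling_rate=150.0, band_centers=(10, 20, 30, 40),
                             noise_scale=3.0,
                             snr_schedule=np.full(n, 0.6),
                             separability_schedule=np.linspace(0.05, 2.5, n),
                             diversity_schedule=np.full(n, 2, dtype=int),
                             seed=21)
        sessions, _ = generate_study(params)
        cfg = FeatureConfig(band_centers=params.band_centers)
        epochs = featurize_study(sessions, cfg)
        feats, meta = subsample_for_embedding(epochs, stride=3)
        emb = fit_embedding(feats, meta, seed=4)
        sep = session_separability(emb)
        slope, _, _, p = sep.trend
        assert slope > 0
        assert p < 0.05


class TestEssLocalId:
    def test_hypercube_dimension_recovered(self, rng):
        """Uniform 5-D hypercube embedded in 50-D by rotation: mean local ID
        lands in the known-manifold band [4, 6]."""
        cube = rng.random((2000, 5))
        basis = np.linalg.qr(rng.normal(size=(50, 5)))[0]
        _, mean_id = ess_local_id(cube @ basis.T, k=100)
        assert 4.0 <= mean_id <= 6.0

    def test_noisy_line_is_one_dimensional(self, rng):
        line = np.linspace(0, 1, 1500)[:, None] * np.ones((1, 10))
        line += 1e-4 * rng.normal(size=line.shape)
        _, mean_id = ess_local_id(line, k=100)
        assert mean_id < 2.0

    def test_isotropic_gaussian_matches_ambient_dimension(self, rng):
        for d in (3, 8):
            pts = rng.normal(size=(1200, d))
            _, mean_id = ess_local_id(pts, k=100)
            assert abs(mean_id - d) <= 1.0

    def test_duplicate_points_skipped_with_flag(self, rng):
        pts = np.zeros((150, 4))  # every neighborhood fully degenerate
        ids, mean_id = ess_local_id(pts, k=100)
        assert np.all(np.isnan(ids)) and np.isnan(mean_id)

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError):
            ess_local_id(rng.normal(size=(50, 3)), k=100)

    def test_diversity_knob_raises_local_id(self):
        """The generator's pattern-diversity schedule measurably controls the
        ESS local ID (monotone across five levels)."""
        from scipy.stats import spearmanr

        from ecoglearn.features import FeatureConfig, extract_features
        from ecoglearn.synthgen import StudyParams, generate_session, make_ground_truth

        cfg = FeatureConfig(band_centers=(10, 20, 30, 40))
        means = []
        levels = (1, 2, 4, 8, 16)
        for k_level in levels:
            params = StudyParams(n_sessions=1, trials_per_session=30,
                                 trial_duration=2.0, n_channels=16,
                                 sampling_rate=150.0,
                                 band_centers=(10, 20, 30, 40),
                                 noise_scale=1.0,
                                 snr_schedule=np.array([0.8]),
                                 separability_schedule=np.array([0.5]),
                                 diversity_schedule=np.array([k_level]),
                                 artifact_rate=np.zeros(1), seed=33)
            truth = make_ground_truth(params)
            sess = generate_session(params, 0, truth)
            feats = np.stack([e.x.ravel()
                              for e in extract_features(sess, cfg)])
            _, mean_id = ess_local_id(feats, k=100)
            means.append(mean_id)
        assert spearmanr(levels, means).statistic > 0.8


class TestTwoNN:
    def test_uniform_disk_is_two_dimensional(self, rng):
        pts = rng.normal(size=(5000, 2))
        pts *= (np.sqrt(rng.random(5000)) / np.linalg.norm(pts, axis=1))[:, None]
        assert 1.8 <= twonn_global_id(pts) <= 2.2

    def test_uniform_10_ball_recovered_with_known_bias(self, rng):
        pts = rng.normal(size=(5000, 10))
        r = rng.random(5000) ** (1 / 10)
        pts *= (r / np.linalg.norm(pts, axis=1))[:, None]
        assert 8.5 <= twonn_global_id(pts) <= 11.5

    def test_duplicates_are_removed_before_estimation(self, rng):
        pts = rng.normal(size=(300, 3))
        doubled = np.vstack([pts, pts])
        est = twonn_global_id(doubled)
        assert np.isfinite(est) and 2.0 <= est <= 4.5

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError):
            twonn_global_id(rng.normal(size=(50, 3)))


class TestIdPerformanceCorrelation:
    def test_perfectly_ordered_vectors(self):
        ids = np.arange(10.0)
        r, p = correlate_id_performance(ids, ids * 2 + 1)
        assert r == pytest.approx(1.0)
        r, p = correlate_id_performance(ids, -ids)
        assert r == pytest.approx(-1.0)

    def test_too_few_windows_raises(self):
        with pytest.raises(ValueError):
            correlate_id_performance([1.0, 2.0], [0.1, 0.2])

    def test_planted_linear_link_recovered_in_simulation(self):
        """32 windows with a planted linear ID-performance link plus noise:
        the mean estimated correlation matches the population value."""
        rho = 0.8
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(500):
            x = rng.normal(size=32)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=32)
            rs.append(correlate_id_performance(x, y)[0])
        assert abs(np.mean(rs) - rho) <= 0.05
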