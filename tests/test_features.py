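import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecoglearn.features import (
    FeatureConfig,
    FeatureEpoch,
    detect_artifacts,
    extract_features,
    filter_gate_mismatch,
    interpolate_artifacts,
    make_direction_label,
    morlet_atom,
)
from ecoglearn.synthgen import RawSession


def _session_from_signal(signal, fs=150.0, state=None):
    signal = np.atleast_2d(signal)
    n = signal.shape[1]
    hand = np.zeros((n, 3))
    target = np.tile([0.0, 0.0, 1.0], (n, 1))
    st_ = np.zeros(n, dtype=np.int8) if state is None else state
    return RawSession(0, signal, hand, target, st_, st_.copy(), [], fs)


# ---------------------------------------------------------------------------
# Morlet feature extraction
# ---------------------------------------------------------------------------

class TestExtractFeatures:
    def test_default_tensor_flattens_to_9600(self):
        """64 channels x 15 bands x 10 steps = 9,600 model inputs."""
        fs = 586.0
        rng = np.random.default_rng(0)
        sess = _session_from_signal(rng.normal(size=(64, int(2 * fs))), fs=fs)
        cfg = FeatureConfig()
        epochs = extract_features(sess, cfg)
        assert epochs[0].x.shape == (64, 15, 10)
        assert epochs[0].x.ravel().shape == (9600,)

    def test_band_argmax_identifies_pure_tone(self):
        """A unit 100 Hz sinusoid concentrates modulus in the 100 Hz band.

        Oracle: the numerically evaluated Morlet frequency response peaks at
        the band whose center matches the tone.
        """
        fs = 586.0
        t = np.arange(int(3 * fs)) / fs
        sig = np.sin(2 * np.pi * 100.0 * t)
        sess = _session_from_signal(sig, fs=fs)
        epochs = extract_features(sess, FeatureConfig())
        x = np.stack([e.x for e in epochs]).mean(axis=0)  # (1, 15, 10)
        band = int(np.argmax(x.mean(axis=2)))
        centers = FeatureConfig().band_centers
        assert centers[band] == 100
        # numerical frequency-response oracle: inner product of each atom
        # with the tone must also peak at 100 Hz
        resp = []
        for nu in centers:
            atom = morlet_atom(nu, fs, 7.0)
            k = np.arange(atom.size) / fs
            resp.append(abs(np.sum(atom * np.exp(-2j * np.pi * 100.0 * k))))
        assert centers[int(np.argmax(resp))] == 100

    def test_exactly_one_window_signal_gives_one_epoch(self):
        fs = 150.0
        sess = _session_from_signal(np.ones((2, int(fs))), fs=fs)
        epochs = extract_features(sess, FeatureConfig(band_centers=(10, 20)))
        assert len(epochs) == 1

    def test_short_signal_warns_and_returns_empty(self):
        sess = _session_from_signal(np.ones((2, 10)), fs=150.0)
        with pytest.warns(UserWarning):
            epochs = extract_features(sess, FeatureConfig(band_centers=(10,)))
        assert epochs == []

    def test_nan_signal_raises_with_sample_range(self):
        sig = np.ones((1, 400))
        sig[0, 203] = np.nan
        sess = _session_from_signal(sig, fs=150.0)
        with pytest.raises(ValueError, match="203"):
            extract_features(sess, FeatureConfig(band_centers=(10,)))

    def test_hop_consistency_and_positivity(self, rng):
        fs = 150.0
        sess = _session_from_signal(rng.normal(size=(3, int(4 * fs))), fs=fs)
        cfg = FeatureConfig(band_centers=(10, 30))
        epochs = extract_features(sess, cfg)
        starts = np.array([e.t_start for e in epochs])
        assert np.allclose(np.diff(starts), cfg.hop)
        assert all(np.all(e.x >= 0) for e in epochs)

    def test_amplitude_equivariance(self, rng):
        """Scaling the raw signal by s > 0 scales every feature by s."""
        fs = 150.0
        sig = rng.normal(size=(2, int(2 * fs)))
        cfg = FeatureConfig(band_centers=(10, 40))
        base = extract_features(_session_from_signal(sig, fs=fs), cfg)
        scaled = extract_features(_session_from_signal(3.5 * sig, fs=fs), cfg)
        for a, b in zip(base, scaled):
            assert np.allclose(b.x, 3.5 * a.x, rtol=1e-5)


# ---------------------------------------------------------------------------
# Direction labels
# ---------------------------------------------------------------------------

class TestDirectionLabel:
    @pytest.mark.parametrize("hand,target,expected", [
        ((0, 0, 0), (0, 0, 2), (0, 0, 1)),
        ((1, 0, 0), (0, 0, 0), (-1, 0, 0)),
        ((1, 1, 0), (2, 2, 0), (np.sqrt(0.5), np.sqrt(0.5), 0)),
    ])
    def test_known_directions(self, hand, target, expected):
        assert np.allclose(make_direction_label(hand, target), expected)

    def test_degenerate_pair_is_dropped_not_fabricated(self):
        assert make_direction_label((1, 1, 1), (1, 1, 1)) is None

    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_labels_are_unit_norm(self, vals):
        hand, target = np.array(vals[:3]), np.array(vals[3:])
        label = make_direction_label(hand, target)
        if label is not None:
            assert abs(np.linalg.norm(label) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

class TestArtifacts:
    def test_clean_noise_session_is_empty(self, rng):
        sess = _session_from_signal(rng.normal(size=(3, 600)), fs=150.0)
        assert detect_artifacts(sess) == []

    def test_injected_flatline_is_detected(self, rng):
        sig = rng.normal(size=(3, 900))
        sig[:, 300:375] = sig[:, 299:300]  # 0.5 s connection loss at 150 Hz
        sess = _session_from_signal(sig, fs=150.0)
        segs = detect_artifacts(sess)
        assert len(segs) == 1
        start, end = segs[0]
        assert start < 375 and end > 300  # overlaps the injected segment

    def test_all_zero_session_is_one_segment(self):
        sess = _session_from_signal(np.zeros((2, 500)), fs=150.0)
        segs = detect_artifacts(sess)
        assert len(segs) == 1
        assert segs[0][0] == 0 and segs[0][1] >= 499

    def test_detection_matches_truth_on_synthetic_study(self, tiny_study):
        sessions, _ = tiny_study
        hits = total = 0
        for sess in sessions:
            segs = detect_artifacts(sess)
            for t0, t1 in sess.artifact_truth:
                total += 1
                if any(s < t1 and e > t0 for s, e in segs):
                    hits += 1
        assert total > 0 and hits / total >= 0.8

    def test_interpolation_identity_on_empty_segments(self, rng):
        sess = _session_from_signal(rng.normal(size=(2, 300)), fs=150.0)
        out = interpolate_artifacts(sess, [])
        assert np.array_equal(out.signal, sess.signal)

    def test_interpolation_restores_linear_ramp(self):
        sig = np.arange(100.0)[None, :].copy()
        corrupted = sig.copy()
        corrupted[0, 10:13] = 99.0
        sess = _session_from_signal(corrupted, fs=150.0)
        out = interpolate_artifacts(sess, [(10, 13)])
        assert np.allclose(out.signal, sig)

    def test_three_sample_gap_hand_checked(self):
        sig = np.array([[1.0, 0.0, 0.0, 0.0, 4.0, 4.0]])
        sess = _session_from_signal(sig, fs=150.0)
        out = interpolate_artifacts(sess, [(1, 4)])
        assert np.allclose(out.signal[0, 1:4], [1.75, 2.5, 3.25])

    def test_boundary_segment_holds_nearest_value(self):
        sig = np.array([[9.0, 9.0, 5.0, 6.0]])
        sess = _session_from_signal(sig, fs=150.0)
        out = interpolate_artifacts(sess, [(0, 2)])
        assert np.allclose(out.signal[0, :2], 5.0)

    def test_out_of_bounds_segment_raises(self):
        sess = _session_from_signal(np.zeros((1, 10)), fs=150.0)
        with pytest.raises(ValueError):
            interpolate_artifacts(sess, [(5, 20)])


# ---------------------------------------------------------------------------
# Gate filtering
# ---------------------------------------------------------------------------

def _epoch(gate_match, i=0):
    return FeatureEpoch(x=np.zeros((1, 1, 1)), y=np.array([0.0, 0.0, 1.0]),
                        state=0, session_index=0, t_start=0.1 * i,
                        gate_match=gate_match)


def test_outlier_session_exclusion_is_explicit(tiny_study):
    from ecoglearn.features import FeatureConfig, featurize_study

    sessions, _ = tiny_study
    cfg = FeatureConfig(band_centers=(10, 20, 40))
    all_epochs = featurize_study(sessions, cfg, gate_filter=False)
    kept = featurize_study(sessions, cfg, gate_filter=False,
                           exclude_sessions=(1,))
    assert {e.session_index for e in kept} == {0, 2}
    assert len(kept) < len(all_epochs)


@pytest.mark.parametrize("n_total,n_bad", [(10, 0), (100, 5), (0, 0)])
def test_gate_filter_counts_and_order(n_total, n_bad):
    epochs = [_epoch(i >= n_bad, i) for i in range(n_total)]
    kept = filter_gate_mismatch(epochs)
    assert len(kept) == n_total - n_bad
    assert [e.t_start for e in kept] == sorted(e.t_start for e in kept)
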