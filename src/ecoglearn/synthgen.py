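"""Synthetic long-term ECoG study generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: cosine
directional tuning of band-limited amplitude, a left/right state pattern
offset, session-indexed adaptation (rising tuning gain and state
separability), a session-dependent number of pattern prototypes (a knob for
local intrinsic dimensionality), gate-prediction errors and connection-loss
artifacts.  Every quantity that the analysis later tries to recover is stored
as ground truth.

The signal model for channel ``c`` at time ``t`` is a sum of band-limited
carriers plus 1/f background noise::

    s_c(t) = sum_f A_cf(t) * cos(2*pi*nu_f*t + phi_cf) + noise_c(t)
    A_cf(t) = baseline
              + snr(sess)   * (p_c . d(t)) * g_cf          # directional tuning
              + sep(sess)   * state_offset_cf(state(t))    # left/right pattern
              + proto_cf(k(trial))                         # diversity mixture

where ``p_c`` is the channel's preferred direction, ``d(t)`` the unit
hand-to-target direction, ``g_cf`` the per-band tuning gain and ``nu_f`` the
band-center frequencies.  Amplitudes are rectified at zero so band power is
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATE_LEFT = 0
STATE_RIGHT = 1


@dataclass
class StudyParams:
    """Configuration of a synthetic study.

    Schedules are arrays indexed by session; ``None`` selects the default
    ramps that emulate long-term adaptation (tuning gain and state
    separability rising with session index, gate-error rate falling).
    """

    n_sessions: int = 43
    trials_per_session: int = 19
    trial_duration: float = 20.0
    n_channels: int = 64
    sampling_rate: float = 586.0
    band_centers: tuple = tuple(range(10, 151, 10))
    snr_schedule: np.ndarray | None = None
    separability_schedule: np.ndarray | None = None
    diversity_schedule: np.ndarray | None = None
    gate_error_rate: np.ndarray | None = None
    artifact_rate: np.ndarray | None = None
    baseline_amplitude: float = 1.0
    noise_scale: float = 0.5
    motor_noise_deg: float = 10.0
    target_distance: float = 1.0
    hand_speed: float = 0.2
    seed: int = 0

    def __post_init__(self):
        n = self.n_sessions
        if self.snr_schedule is None:
            self.snr_schedule = np.linspace(0.5, 1.5, n)
        if self.separability_schedule is None:
            self.separability_schedule = np.linspace(0.4, 1.2, n)
        if self.diversity_schedule is None:
            self.diversity_schedule = np.rint(np.linspace(2, 6, n)).astype(int)
        if self.gate_error_rate is None:
            self.gate_error_rate = np.linspace(0.08, 0.02, n)
        if self.artifact_rate is None:
            self.artifact_rate = np.ones(n)
        for name in ("snr_schedule", "separability_schedule", "diversity_schedule",
                     "gate_error_rate", "artifact_rate"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per session, got {arr.shape}")
            setattr(self, name, arr)
        if self.sampling_rate <= 2 * max(self.band_centers):
            raise ValueError("sampling_rate must exceed twice the highest band center")
        if np.any(self.gate_error_rate < 0) or np.any(self.gate_error_rate > 1):
            raise ValueError("gate_error_rate entries must lie in [0, 1]")

    @property
    def n_bands(self) -> int:
        return len(self.band_centers)


@dataclass
class GroundTruth:
    """Planted encoding shared by all sessions of one study."""

    preferred_directions: np.ndarray  # (n_channels, 3), unit rows
    band_gains: np.ndarray            # (n_channels, n_bands), non-negative
    state_offsets: np.ndarray         # (2, n_channels, n_bands)
    prototypes: np.ndarray            # (K_max, n_channels, n_bands)
    carrier_phases: np.ndarray        # (n_channels, n_bands)
    params: StudyParams | None = None


@dataclass
class RawSession:
    """One recording session: raw signal plus aligned kinematic/state streams."""

    session_index: int
    signal: np.ndarray        # (n_channels, n_samples)
    hand_pos: np.ndarray      # (n_samples, 3)
    target_pos: np.ndarray    # (n_samples, 3)
    state: np.ndarray         # (n_samples,) int, STATE_LEFT/STATE_RIGHT
    gate_pred: np.ndarray     # (n_samples,) int
    artifact_truth: list = field(default_factory=list)  # [(start, end)] sample index, end exclusive
    sampling_rate: float = 586.0

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


def desk_scale_params(seed: int = 7, n_sessions: int = 14) -> StudyParams:
    """Desk-scale study preset used by the qualitative end-to-end analyses.

    A reduced study (one 8x4 implant, six 10-60 Hz bands at 150 Hz, fourteen
    sessions of six 5 s trials) whose ramped tuning-gain and separability
    schedules emulate long-term adaptation, with background noise set so that
    decoding quality spans the range observed in practice rather than
    saturating at the metric ceiling.
    """
    return StudyParams(
        n_sessions=n_sessions,
        trials_per_session=6,
        trial_duration=5.0,
        n_channels=32,
        sampling_rate=150.0,
        band_centers=(10, 20, 30, 40, 50, 60),
        noise_scale=6.0,
        snr_schedule=np.linspace(0.3, 1.8, n_sessions),
        separability_schedule=np.linspace(0.1, 1.6, n_sessions),
        seed=seed,
    )


def _truth_rng(params: StudyParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(0xEC06,)))


def _session_rng(params: StudyParams, session_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(session_index,)))


def make_ground_truth(params: StudyParams) -> GroundTruth:
    """Draw the planted encoding (preferred directions, gains, prototypes)."""
    rng = _truth_rng(params)
    nc, nb = params.n_channels, params.n_bands
    pd = rng.normal(size=(nc, 3))
    pd /= np.linalg.norm(pd, axis=1, keepdims=True)
    # band gains concentrated on a per-channel favourite band, never all-zero
    gains = 0.1 + rng.random(size=(nc, nb))
    fav = rng.integers(0, nb, size=nc)
    gains[np.arange(nc), fav] += 1.0
    state_offsets = rng.normal(scale=0.3, size=(2, nc, nb))
    k_max = int(np.max(params.diversity_schedule))
    prototypes = rng.normal(scale=0.25, size=(k_max, nc, nb))
    phases = rng.uniform(0, 2 * np.pi, size=(nc, nb))
    return GroundTruth(pd, gains, state_offsets, prototypes, phases, params)


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, scale: float) -> np.ndarray:
    """Background noise with ~1/f amplitude spectrum, unit-ish variance, scaled."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= shaping
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    std = pink.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return scale * pink / std


def _smooth_noise(rng: np.random.Generator, k: int, n: int, fs: float,
                  cutoff_hz: float = 1.0) -> np.ndarray:
    """K unit-variance Gaussian processes low-passed below ``cutoff_hz``."""
    white = rng.standard_normal((k, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[:, freqs > cutoff_hz] = 0.0
    smooth = np.fft.irfft(spec, n=n, axis=1)
    std = smooth.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return smooth / std


def _simulate_kinematics(params: StudyParams, rng: np.random.Generator, n_trials: int):
    """Constant-speed pursuit of uniformly directed targets with angular jitter."""
    fs = params.sampling_rate
    dt = 1.0 / fs
    samples_per_trial = int(round(params.trial_duration * fs))
    n = n_trials * samples_per_trial
    hand = np.zeros((n, 3))
    target = np.zeros((n, 3))
    state = np.zeros(n, dtype=np.int8)
    pos = np.zeros(3)
    jitter = np.deg2rad(params.motor_noise_deg)
    i = 0
    for trial in range(n_trials):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        tgt = pos + params.target_distance * direction
        st = STATE_LEFT if trial % 2 == 0 else STATE_RIGHT
        for _ in range(samples_per_trial):
            to_tgt = tgt - pos
            dist = np.linalg.norm(to_tgt)
            if dist > 1e-6:
                step_dir = to_tgt / dist
                noise = rng.normal(scale=jitter, size=3)
                step_dir = step_dir + noise
                step_dir /= np.linalg.norm(step_dir)
                step = min(params.hand_speed * dt, dist)
                pos = pos + step * step_dir
            hand[i] = pos
            target[i] = tgt
            state[i] = st
            i += 1
    return hand, target, state


def generate_session(params: StudyParams, session_index: int,
                     truth: GroundTruth) -> RawSession:
    """Generate one session of raw signal with planted directional encoding."""
    if not 0 <= session_index < params.n_sessions:
        raise ValueError(f"session_index {session_index} outside schedule range "
                         f"[0, {params.n_sessions})")
    rng = _session_rng(params, session_index)
    fs = params.sampling_rate
    n_trials = int(np.clip(rng.integers(params.trials_per_session - 1,
                                        params.trials_per_session + 2), 1, None))
    hand, target, state = _simulate_kinematics(params, rng, n_trials)
    n = hand.shape[0]
    nc, nb = params.n_channels, params.n_bands

    # unit hand->target direction per sample (piecewise smooth)
    diff = target - hand
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    d = diff / norms  # (n, 3)

    snr = params.snr_schedule[session_index]
    sep = params.separability_schedule[session_index]
    k_sess = int(params.diversity_schedule[session_index])

    tuning = truth.preferred_directions @ d.T                     # (nc, n)
    # diversity: a smooth K-dimensional mixture trajectory over pattern
    # prototypes; larger K spreads the session over a higher-dimensional
    # submanifold (the local-ID control knob) at constant per-sample variance
    alpha = _smooth_noise(rng, k_sess, n, fs) / np.sqrt(k_sess)

    t = np.arange(n) / fs
    signal = np.zeros((nc, n))
    for f, nu in enumerate(params.band_centers):
        proto_contrib = truth.prototypes[:k_sess, :, f].T @ alpha  # (nc, n)
        amp = (params.baseline_amplitude
               + snr * tuning * truth.band_gains[:, f][:, None]
               + sep * truth.state_offsets[state, :, f].T
               + proto_contrib)
        np.clip(amp, 0.0, None, out=amp)
        carrier = np.cos(2 * np.pi * nu * t[None, :] + truth.carrier_phases[:, f][:, None])
        signal += amp * carrier
    signal += _one_over_f_noise(rng, nc, n, fs, params.noise_scale)

    # gate predictions: correct except blocks flipped at the session's error rate
    gate = state.copy()
    block = max(1, int(round(0.1 * fs)))
    n_blocks = int(np.ceil(n / block))
    flips = rng.random(n_blocks) < params.gate_error_rate[session_index]
    for bi in np.nonzero(flips)[0]:
        sl = slice(bi * block, min((bi + 1) * block, n))
        gate[sl] = 1 - gate[sl]

    # connection-loss artifacts: all channels flatline at the last valid value
    artifacts = []
    n_events = rng.poisson(params.artifact_rate[session_index])
    for _ in range(int(n_events)):
        dur = int(rng.uniform(0.2, 0.6) * fs)
        if dur >= n - 2:
            continue
        start = int(rng.integers(1, n - dur))
        end = start + dur
        signal[:, start:end] = signal[:, start - 1][:, None]
        artifacts.append((start, end))
    artifacts.sort()

    return RawSession(session_index, signal, hand, target, state, gate,
                      artifacts, sampling_rate=fs)


def generate_study(params: StudyParams):
    """Generate all sessions of a study sharing one planted ground truth."""
    truth = make_ground_truth(params)
    sessions = [generate_session(params, s, truth) for s in range(params.n_sessions)]
    return sessions, truth


# ---------------------------------------------------------------------------
# HDF5 study container
# ---------------------------------------------------------------------------

def save_study(path, sessions, truth: GroundTruth) -> None:
    """Write a study to an HDF5 container, one group per session."""
    import h5py

    with h5py.File(path, "w") as h5:
        p = truth.params
        if p is not None:
            h5.attrs["seed"] = p.seed
            h5.attrs["sampling_rate"] = p.sampling_rate
            h5.attrs["band_centers"] = np.asarray(p.band_centers)
        g = h5.create_group("ground_truth")
        g.create_dataset("preferred_directions", data=truth.preferred_directions)
        g.create_dataset("band_gains", data=truth.band_gains)
        g.create_dataset("state_offsets", data=truth.state_offsets)
        g.create_dataset("prototypes", data=truth.prototypes)
        g.create_dataset("carrier_phases", data=truth.carrier_phases)
        for sess in sessions:
            grp = h5.create_group(f"session_{sess.session_index:03d}")
            grp.attrs["session_index"] = sess.session_index
            grp.attrs["sampling_rate"] = sess.sampling_rate
            grp.create_dataset("signal", data=sess.signal, compression="gzip")
            grp.create_dataset("hand_pos", data=sess.hand_pos)
            grp.create_dataset("target_pos", data=sess.target_pos)
            grp.create_dataset("state", data=sess.state)
            grp.create_dataset("gate_pred", data=sess.gate_pred)
            art = np.asarray(sess.artifact_truth, dtype=np.int64).reshape(-1, 2)
            grp.create_dataset("artifact_truth", data=art)


def load_study(path):
    """Read a study container written by :func:`save_study`."""
    import h5py

    sessions = []
    with h5py.File(path, "r") as h5:
        g = h5["ground_truth"]
        truth = GroundTruth(
            preferred_directions=g["preferred_directions"][...],
            band_gains=g["band_gains"][...],
            state_offsets=g["state_offsets"][...],
            prototypes=g["prototypes"][...],
            carrier_phases=g["carrier_phases"][...],
        )
        for name in sorted(k for k in h5 if k.startswith("session_")):
            grp = h5[name]
            sessions.append(RawSession(
                session_index=int(grp.attrs["session_index"]),
                signal=grp["signal"][...],
                hand_pos=grp["hand_pos"][...],
                target_pos=grp["target_pos"][...],
                state=grp["state"][...],
                gate_pred=grp["gate_pred"][...],
                artifact_truth=[tuple(r) for r in grp["artifact_truth"][...]],
                sampling_rate=float(grp.attrs["sampling_rate"]),
            ))
    return sessions, truth
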