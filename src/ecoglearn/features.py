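"""Time-frequency feature extraction, artifact repair and sample filtering.

Raw multichannel signal is convolved with a bank of complex Morlet wavelets
(one per band center), the modulus is averaged over short fragments, and each
sliding window becomes a ``channels x bands x steps`` tensor paired with the
unit hand-to-target direction at the window end.  With the defaults (64
channels, 15 bands from 10 to 150 Hz, 1 s windows stepped every 100 ms and
averaged over 100 ms fragments) each epoch is a 64x15x10 tensor, i.e., 9,600
features when flattened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve


@dataclass
class FeatureConfig:
    window: float = 1.0           # seconds of signal per epoch
    hop: float = 0.1              # seconds between consecutive epochs
    band_centers: tuple = tuple(range(10, 151, 10))
    avg_fragment: float = 0.1     # seconds averaged into one time step
    morlet_cycles: float = 7.0    # time/frequency resolution trade-off
    label_tolerance: float = 1e-9  # min hand-target distance for a valid label

    def __post_init__(self):
        steps = self.window / self.avg_fragment
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("window must be an integer multiple of avg_fragment")
        if self.hop > self.window:
            raise ValueError("hop must not exceed window")

    @property
    def n_steps(self) -> int:
        return int(round(self.window / self.avg_fragment))

    @property
    def n_bands(self) -> int:
        return len(self.band_centers)


@dataclass
class FeatureEpoch:
    """One analysis window: feature tensor, direction label and bookkeeping."""

    x: np.ndarray          # (channels, bands, steps)
    y: np.ndarray          # unit 3-vector, hand-to-target direction
    state: int
    session_index: int
    t_start: float         # seconds within session
    gate_match: bool


def morlet_atom(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet atom at ``freq`` Hz, L1-normalized modulus envelope.

    sigma_t = n_cycles / (2*pi*f); the atom is truncated at +-4 sigma_t.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = max(1, int(np.ceil(4.0 * sigma_t * fs)))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    atom = envelope * np.exp(2j * np.pi * freq * t)
    return atom / envelope.sum()


def make_direction_label(hand, target, tolerance: float = 1e-9):
    """Unit vector from hand to target, or ``None`` when they coincide.

    A degenerate pair (distance below tolerance) signals that the epoch must
    be dropped rather than given a fabricated label.
    """
    diff = np.asarray(target, dtype=float) - np.asarray(hand, dtype=float)
    norm = np.linalg.norm(diff)
    if norm < tolerance:
        return None
    return diff / norm


def wavelet_power(signal: np.ndarray, fs: float, cfg: FeatureConfig) -> np.ndarray:
    """Modulus of the complex Morlet transform, (channels, bands, samples)."""
    signal = np.atleast_2d(signal)
    out = np.empty((signal.shape[0], cfg.n_bands, signal.shape[1]))
    for f, nu in enumerate(cfg.band_centers):
        atom = morlet_atom(nu, fs, cfg.morlet_cycles)
        for c in range(signal.shape[0]):
            out[c, f] = np.abs(fftconvolve(signal[c], atom, mode="same"))
    return out


def extract_features(session, cfg: FeatureConfig | None = None) -> list[FeatureEpoch]:
    """Slide a window over one session and emit feature epochs.

    Windows requiring samples beyond the session are not emitted.  Epochs
    whose hand and target coincide are dropped.  ``gate_match`` compares the
    gate prediction with the true state at the window end.
    """
    if cfg is None:
        cfg = FeatureConfig()
    fs = session.sampling_rate
    n = session.n_samples
    win = int(round(cfg.window * fs))
    hop = int(round(cfg.hop * fs))
    frag = int(round(cfg.avg_fragment * fs))
    if n < win:
        import warnings
        warnings.warn("session shorter than one window; no epochs emitted", stacklevel=2)
        return []
    if not np.all(np.isfinite(session.signal)):
        bad = np.nonzero(~np.isfinite(session.signal).all(axis=0))[0]
        raise ValueError(f"non-finite signal in samples [{bad[0]}, {bad[-1]}]")

    power = wavelet_power(session.signal, fs, cfg)  # (C, B, n)
    epochs: list[FeatureEpoch] = []
    start = 0
    while start + win <= n:
        end = start + win
        # mean modulus over n_steps fragments; trailing samples (win not an
        # exact multiple of frag) are folded into the last fragment
        x = np.empty((power.shape[0], cfg.n_bands, cfg.n_steps), dtype=np.float32)
        for s in range(cfg.n_steps):
            f0 = start + s * frag
            f1 = end if s == cfg.n_steps - 1 else f0 + frag
            x[:, :, s] = power[:, :, f0:f1].mean(axis=2)
        last = end - 1
        y = make_direction_label(session.hand_pos[last], session.target_pos[last],
                                 cfg.label_tolerance)
        if y is not None:
            epochs.append(FeatureEpoch(
                x=x,
                y=y,
                state=int(session.state[last]),
                session_index=session.session_index,
                t_start=start / fs,
                gate_match=bool(session.gate_pred[last] == session.state[last]),
            ))
        start += hop
    return epochs


# ---------------------------------------------------------------------------
# Artifact handling
# ---------------------------------------------------------------------------

def detect_artifacts(session, min_flat: float = 0.05, mad_k: float = 8.0,
                     merge_gap: float = 0.05) -> list[tuple[int, int]]:
    """Locate connection-loss segments: flatlines or extreme amplitudes.

    A sample is suspect when any channel's derivative is exactly zero over at
    least ``min_flat`` seconds, or its amplitude deviates from the channel
    median by more than ``mad_k`` robust standard deviations.  Overlapping or
    near-adjacent suspect runs are merged.
    """
    sig = session.signal
    fs = session.sampling_rate
    n = sig.shape[1]
    if n < 2:
        return []
    suspect = np.zeros(n, dtype=bool)

    # amplitude outliers (robust per-channel threshold)
    med = np.median(sig, axis=1, keepdims=True)
    mad = np.median(np.abs(sig - med), axis=1, keepdims=True) * 1.4826
    mad[mad == 0] = np.inf
    suspect |= np.any(np.abs(sig - med) > mad_k * mad, axis=0)

    # flatline runs: zero first difference on any channel for >= min_flat s
    min_len = max(2, int(round(min_flat * fs)))
    flat = (np.diff(sig, axis=1) == 0)
    any_flat = np.any(flat, axis=0)
    run_start = None
    for i in range(any_flat.size + 1):
        active = i < any_flat.size and any_flat[i]
        if active and run_start is None:
            run_start = i
        elif not active and run_start is not None:
            if i - run_start + 1 >= min_len:
                suspect[run_start:i + 1] = True
            run_start = None

    # collect merged segments
    gap = int(round(merge_gap * fs))
    segments: list[tuple[int, int]] = []
    idx = np.nonzero(suspect)[0]
    if idx.size == 0:
        return segments
    s0, prev = idx[0], idx[0]
    for i in idx[1:]:
        if i - prev > gap:
            segments.append((int(s0), int(prev + 1)))
            s0 = i
        prev = i
    segments.append((int(s0), int(prev + 1)))
    return segments


def interpolate_artifacts(session, segments):
    """Repair segments by per-channel linear interpolation in the raw domain.

    Segments touching a session boundary hold the nearest valid value.
    Returns a new session; all samples outside the segments are unchanged.
    """
    from dataclasses import replace

    sig = session.signal.copy()
    n = sig.shape[1]
    for start, end in segments:
        if not (0 <= start < end <= n):
            raise ValueError(f"segment ({start}, {end}) outside session bounds")
        left = start - 1
        right = end
        for c in range(sig.shape[0]):
            if left < 0 and right >= n:
                sig[c, start:end] = 0.0
            elif left < 0:
                sig[c, start:end] = sig[c, right]
            elif right >= n:
                sig[c, start:end] = sig[c, left]
            else:
                sig[c, start:end] = np.interp(
                    np.arange(start, end), [left, right], [sig[c, left], sig[c, right]])
    return replace(session, signal=sig)


def filter_gate_mismatch(epochs: list[FeatureEpoch]) -> list[FeatureEpoch]:
    """Drop epochs whose gate prediction disagreed with the true state."""
    return [e for e in epochs if e.gate_match]


def featurize_study(sessions, cfg: FeatureConfig | None = None,
                    repair_artifacts: bool = True,
                    gate_filter: bool = True,
                    exclude_sessions: tuple = ()) -> list[FeatureEpoch]:
    """Full preprocessing chain for a list of sessions.

    Detects and interpolates connection-loss artifacts, extracts Morlet
    feature epochs and removes gate-mismatched samples.  Outlier sessions
    are excluded by explicit index (``exclude_sessions``), not by an
    automatic rule: which sessions count as outliers is a judgement made
    from the recording context.
    """
    epochs: list[FeatureEpoch] = []
    for sess in sessions:
        if sess.session_index in exclude_sessions:
            continue
        if repair_artifacts:
            sess = interpolate_artifacts(sess, detect_artifacts(sess))
        epochs.extend(extract_features(sess, cfg))
    if gate_filter:
        epochs = filter_gate_mismatch(epochs)
    return epochs


# ---------------------------------------------------------------------------
# Feature container I/O
# ---------------------------------------------------------------------------

def save_features(path, epochs: list[FeatureEpoch], cfg: FeatureConfig) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["window"] = cfg.window
        h5.attrs["hop"] = cfg.hop
        h5.attrs["band_centers"] = np.asarray(cfg.band_centers)
        h5.create_dataset("epochs/x", data=np.stack([e.x for e in epochs]),
                          compression="gzip")
        h5.create_dataset("epochs/y", data=np.stack([e.y for e in epochs]))
        meta = np.array([(e.state, e.session_index, e.t_start, e.gate_match)
                         for e in epochs],
                        dtype=[("state", "i4"), ("session_index", "i4"),
                               ("t_start", "f8"), ("gate_match", "?")])
        h5.create_dataset("epochs/meta", data=meta)


def load_features(path) -> list[FeatureEpoch]:
    import h5py

    with h5py.File(path, "r") as h5:
        xs = h5["epochs/x"][...]
        ys = h5["epochs/y"][...]
        meta = h5["epochs/meta"][...]
    return [FeatureEpoch(x=xs[i], y=ys[i], state=int(meta["state"][i]),
                         session_index=int(meta["session_index"][i]),
                         t_start=float(meta["t_start"][i]),
                         gate_match=bool(meta["gate_match"][i]))
            for i in range(len(xs))]
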