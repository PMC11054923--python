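"""Synthetic two-electrode sEMG session generation.

A *session* is one continuous two-channel recording (medial electrode over
the flexor carpi radialis, lateral electrode over the extensor carpi
radialis) during which a participant holds one hand action for 1 s, ten
times, with 4 s of rest in between and ~8 s of rest at the start.  Six hand
actions are modelled: hand open (HO), hand close (HC), wrist extension
(WE), wrist flexion (WF), wrist pronation (WP) and wrist supination (WS).

The raw signal is emulated as zero-mean Gaussian noise band-pass shaped to
the 20-450 Hz surface-EMG band, amplitude-modulated during each hold by a
unimodal burst profile scaled to a per-action, per-channel RMS gain.  The
per-action gain asymmetries (e.g. wrist extension activating the lateral
extensor far more than the medial flexor) are encoded in
:class:`ActionSignature` objects, calibrated so that envelope features
extracted downstream reproduce the direction and rough magnitude of
activation patterns seen in real two-electrode recordings.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import signal as sps

__all__ = [
    "ACTIONS",
    "RecordingProtocol",
    "ActionSignature",
    "RawRecording",
    "ProtocolConfigError",
    "build_protocol",
    "default_signatures",
    "simulate_session",
    "simulate_participant",
    "write_session_csv",
    "read_session_csv",
]

#: Canonical ordered action labels.
ACTIONS: tuple[str, ...] = ("HO", "HC", "WE", "WF", "WP", "WS")

#: Surface-EMG carrier band (Hz) used to shape the raw noise.
_EMG_BAND_HZ = (20.0, 450.0)

#: Cosine-ramp fraction at the feet of each burst (of the hold duration).
_RAMP_FRAC = 0.1

#: Relative amplitude of the slow stochastic burst modulation.
_MOD_DEPTH = 0.10

#: Exponent sharpening the triangular burst profile around its maximum,
#: keeping the instant of peak activity well defined under modulation.
_PEAK_SHARPNESS = 1.5

#: Relative amplitude of the faster within-burst modulation applied when
#: the two channels are weakly coupled; vanishes as |cross_corr| -> 1.
_FAST_MOD_DEPTH = 0.30

#: Maximum per-channel burst-onset jitter (s) applied when the two
#: channels are weakly coupled; vanishes as |cross_corr| -> 1.
_MAX_ONSET_JITTER_S = 0.03

#: Maximum antisymmetric medial/lateral burst-centre offset (s): weakly
#: coupled muscle pairs peak at slightly different times, which is what
#: drives their envelope correlation down.
_MAX_CHANNEL_LAG_S = 0.12


class ProtocolConfigError(ValueError):
    """Raised when a protocol configuration value violates an invariant."""


@dataclass(frozen=True)
class RecordingProtocol:
    """Timing and structure of one acquisition session.

    Defaults reproduce the cued protocol: ~8 s initial rest, 1 s holds,
    4 s inter-rest, 10 repetitions per session, 5 sessions per action,
    sampled at 1111 Hz.  ``trailing_rest_s`` (2 s) pads the recording after
    the final repetition so a 2 s analysis window centred on the last burst
    never runs off the end.
    """

    sampling_rate_hz: float = 1111.0
    initial_rest_s: float = 8.0
    action_hold_s: float = 1.0
    inter_rest_s: float = 4.0
    trailing_rest_s: float = 2.0
    reps_per_session: int = 10
    sessions_per_action: int = 5
    actions: tuple[str, ...] = ACTIONS

    def __post_init__(self) -> None:
        for key in ("sampling_rate_hz", "initial_rest_s", "action_hold_s",
                    "inter_rest_s", "trailing_rest_s"):
            if not getattr(self, key) > 0:
                raise ProtocolConfigError(f"{key} must be positive, got {getattr(self, key)}")
        for key in ("reps_per_session", "sessions_per_action"):
            if int(getattr(self, key)) < 1:
                raise ProtocolConfigError(f"{key} must be >= 1, got {getattr(self, key)}")
        if len(set(self.actions)) != len(self.actions) or not self.actions:
            raise ProtocolConfigError("actions must be a non-empty set of unique labels")
        if self.trailing_rest_s < 1.0:
            raise ProtocolConfigError("trailing_rest_s must be >= 1 s")

    @property
    def session_duration_s(self) -> float:
        """Closed-form total duration of one session in seconds."""
        r = self.reps_per_session
        return (self.initial_rest_s + r * self.action_hold_s
                + (r - 1) * self.inter_rest_s + self.trailing_rest_s)

    @property
    def n_samples(self) -> int:
        return round(self.session_duration_s * self.sampling_rate_hz)

    def cue_times_s(self) -> np.ndarray:
        """Onset time of each repetition's hold, in seconds from start."""
        period = self.action_hold_s + self.inter_rest_s
        return self.initial_rest_s + period * np.arange(self.reps_per_session)


def build_protocol(config: Mapping[str, object] | None = None) -> RecordingProtocol:
    """Build a :class:`RecordingProtocol`, filling unset keys with defaults.

    Parameters
    ----------
    config
        Mapping of field overrides (``sampling_rate_hz``, ``reps_per_session``,
        ...).  Unknown keys raise :class:`ProtocolConfigError`.
    """
    config = dict(config or {})
    valid = set(RecordingProtocol.__dataclass_fields__)
    unknown = set(config) - valid
    if unknown:
        raise ProtocolConfigError(f"unknown protocol keys: {sorted(unknown)}")
    if "actions" in config:
        config["actions"] = tuple(config["actions"])  # type: ignore[arg-type]
    return RecordingProtocol(**config)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ActionSignature:
    """Per-action activation pattern of the two electrodes.

    ``medial_gain_uV`` / ``lateral_gain_uV`` are the RMS amplitudes (µV) the
    carrier noise reaches at the peak of a hold on each channel;
    ``baseline_uV`` is the resting-noise RMS common to both channels.
    ``cross_corr`` in [-1, 1] sets how strongly the two channels' burst
    fluctuations co-vary (synergist pairs near +1, antagonists negative).
    """

    action: str
    medial_gain_uV: float
    lateral_gain_uV: float
    baseline_uV: float
    cross_corr: float

    def __post_init__(self) -> None:
        if not (self.baseline_uV > 0):
            raise ValueError("baseline_uV must be > 0")
        if not (self.medial_gain_uV > self.baseline_uV
                and self.lateral_gain_uV > self.baseline_uV):
            raise ValueError("channel gains must exceed the baseline")
        if not (-1.0 <= self.cross_corr <= 1.0):
            raise ValueError("cross_corr must lie in [-1, 1]")


def default_signatures() -> dict[str, ActionSignature]:
    """Default per-action signatures for the six hand actions.

    Gains are calibrated so the 5 Hz envelope's per-channel mean and peak
    land near the activation levels seen in real recordings: wrist
    extension drives the lateral (extensor) channel far harder than the
    medial, wrist flexion the reverse; hand open/close activate both
    forearm channels at comparable levels.  Cross-channel coupling is high
    for hand open, near zero for hand close, and mildly negative for the
    wrist rotations/flexion.
    """
    base = 12.0
    table = {
        # action: (medial gain, lateral gain, cross correlation)
        "HO": (130.0, 152.0, 0.95),
        "HC": (194.0, 191.0, 0.05),
        "WE": (102.0, 256.0, 0.25),
        "WF": (214.0, 128.0, -0.45),
        "WP": (152.0, 137.0, -0.05),
        "WS": (78.0, 104.0, -0.35),
    }
    return {
        a: ActionSignature(action=a, medial_gain_uV=m, lateral_gain_uV=l,
                           baseline_uV=base, cross_corr=c)
        for a, (m, l, c) in table.items()
    }


@dataclass(frozen=True)
class RawRecording:
    """One session's two-channel raw µV time series plus cue metadata."""

    medial_uV: np.ndarray
    lateral_uV: np.ndarray
    sampling_rate_hz: float
    action: str
    cue_times_s: np.ndarray
    participant_id: str
    session_id: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.medial_uV) != len(self.lateral_uV):
            raise ValueError("channel lengths differ")
        cues = np.asarray(self.cue_times_s, dtype=float)
        if len(cues) and not np.all(np.diff(cues) > 0):
            raise ValueError("cue times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.medial_uV)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-pass shaped to the sEMG carrier band."""
    lo, hi = _EMG_BAND_HZ
    hi = min(hi, 0.45 * fs)  # keep the band below Nyquist for low fs
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _slow_modulation(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance slow (<2 Hz) stochastic amplitude fluctuation."""
    sos = sps.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _fast_modulation(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 2-5 Hz within-burst amplitude fluctuation."""
    sos = sps.butter(2, [2.0, 5.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _coupled_pair(rng: np.random.Generator, n: int, fs: float, c: float,
                  maker) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance processes with correlation ``c`` (sign included)."""
    a = np.sqrt(abs(c))
    b = np.sqrt(max(0.0, 1.0 - a * a))
    common, ind1, ind2 = (maker(rng, n, fs) for _ in range(3))
    return a * common + b * ind1, np.sign(c) * a * common + b * ind2


def _burst_shape(t: np.ndarray, onset: float, hold: float) -> np.ndarray:
    """Unimodal activation profile over one hold: a triangular peak at the
    hold midpoint with short cosine-smoothed feet.

    The sharp (non-flat) maximum makes the instant of peak activity well
    defined, which downstream peak-centred segmentation relies on.
    """
    tau = (t - onset) / hold
    inside = (tau >= 0) & (tau <= 1)
    s = np.zeros_like(t)
    tri = 1.0 - np.abs(2.0 * tau[inside] - 1.0)
    s[inside] = tri ** _PEAK_SHARPNESS
    # cosine-smooth the feet so activation switches on/off without a corner
    ramp = _RAMP_FRAC
    feet = inside & ((tau < ramp) | (tau > 1 - ramp))
    edge = np.minimum(tau[feet], 1 - tau[feet]) / ramp
    s[feet] *= 0.5 * (1 - np.cos(np.pi * edge))
    return s


def simulate_session(protocol: RecordingProtocol, action: str,
                     signature: ActionSignature, seed: int) -> RawRecording:
    """Simulate one session of ``action`` under ``protocol``.

    Each channel is unit-RMS band-limited carrier noise multiplied by a
    time-varying amplitude: the resting baseline plus, over each cued hold,
    the burst profile scaled to the channel gain and perturbed by a slow
    stochastic modulation.  The two channels' modulations (and, when the
    coupling is weak, their burst onsets) are mixed to realise the
    signature's ``cross_corr``.  Identical seeds give bit-identical output.
    """
    if action not in protocol.actions:
        raise ValueError(f"unknown action label: {action!r}")
    if signature.action != action:
        raise ValueError(
            f"signature is for {signature.action!r}, not {action!r}")

    fs = protocol.sampling_rate_hz
    n = protocol.n_samples
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    carriers = [_bandlimited_noise(rng, n, fs) for _ in range(2)]

    # slow and fast modulations share a common component weighted so the
    # two channels' fluctuations correlate at cross_corr (sign included)
    c = signature.cross_corr
    slow = _coupled_pair(rng, n, fs, c, _slow_modulation)
    fast = _coupled_pair(rng, n, fs, c, _fast_modulation)
    decouple = 1.0 - min(1.0, abs(c))
    fast_depth = _FAST_MOD_DEPTH * decouple
    jitter_amp = _MAX_ONSET_JITTER_S * decouple
    # antisymmetric burst-centre lag: medial early, lateral late
    lag = _MAX_CHANNEL_LAG_S * (1.0 - min(1.0, max(0.0, c)))
    lags = (-lag / 2.0, +lag / 2.0)
    cues = protocol.cue_times_s()
    hold = protocol.action_hold_s

    channels = []
    gains = (signature.medial_gain_uV, signature.lateral_gain_uV)
    for carrier, gain, f_slow, f_fast, ch_lag in zip(
            carriers, gains, slow, fast, lags):
        burst = np.zeros(n)
        for cue in cues:
            onset = cue + ch_lag + rng.uniform(-jitter_amp, jitter_amp)
            burst += _burst_shape(t, onset, hold)
        mod = np.clip(1.0 + _MOD_DEPTH * f_slow + fast_depth * f_fast,
                      0.75, 1.25)
        amplitude = signature.baseline_uV + (gain - signature.baseline_uV) * burst * mod
        channels.append(carrier * amplitude)

    return RawRecording(
        medial_uV=channels[0], lateral_uV=channels[1],
        sampling_rate_hz=fs, action=action, cue_times_s=cues,
        participant_id="", session_id="", seed=int(seed),
    )


def derive_session_seed(master_seed: int, participant_id: str,
                        action: str, session_index: int) -> int:
    """Deterministic per-session seed.

    The rule is fixed: a :class:`numpy.random.SeedSequence` keyed on the
    master seed, a CRC-32 of the participant id, the action's index in the
    canonical order, and the session index; the first generated 32-bit word
    is the seed.
    """
    pid_key = zlib.crc32(str(participant_id).encode())
    action_key = zlib.crc32(str(action).encode())
    ss = np.random.SeedSequence(
        [int(master_seed), pid_key, action_key, int(session_index)])
    return int(ss.generate_state(1)[0])


def simulate_participant(protocol: RecordingProtocol,
                         signatures: Mapping[str, ActionSignature],
                         participant_id: str,
                         master_seed: int) -> list[RawRecording]:
    """Simulate all sessions for one participant.

    Returns ``sessions_per_action`` recordings for each action in protocol
    order (30 with defaults: 6 actions x 5 sessions, i.e. 50 repetitions
    per action).  Per-session seeds derive deterministically from
    ``(master_seed, participant_id, action, session_index)``.
    """
    missing = [a for a in protocol.actions if a not in signatures]
    if missing:
        raise ValueError(f"missing signatures for actions: {missing}")
    recordings = []
    for action in protocol.actions:
        for s_idx in range(protocol.sessions_per_action):
            seed = derive_session_seed(master_seed, participant_id, action, s_idx)
            rec = simulate_session(protocol, action, signatures[action], seed)
            recordings.append(replace(
                rec, participant_id=str(participant_id),
                session_id=f"{action}-s{s_idx}"))
    return recordings


def write_session_csv(rec: RawRecording, out_dir: str | Path,
                      precision: int = 9) -> tuple[Path, Path]:
    """Write one session as ``time_s,medial_uV,lateral_uV`` CSV plus a JSON
    metadata sidecar; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.participant_id or 'anon'}_{rec.session_id or 'session'}"
    csv_path = out_dir / f"{stem}.csv"
    t = np.arange(rec.n_samples) / rec.sampling_rate_hz
    fmt = f"%.{precision}g"
    with open(csv_path, "w") as fh:
        fh.write("time_s,medial_uV,lateral_uV\n")
        np.savetxt(fh, np.column_stack([t, rec.medial_uV, rec.lateral_uV]),
                   fmt=fmt, delimiter=",")
    meta_path = out_dir / f"{stem}.json"
    meta = {
        "participant_id": rec.participant_id,
        "session_id": rec.session_id,
        "action": rec.action,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "cue_times_s": [float(c) for c in rec.cue_times_s],
        "seed": rec.seed,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return csv_path, meta_path


def read_session_csv(csv_path: str | Path,
                     meta_path: str | Path | None = None) -> RawRecording:
    """Read a session written by :func:`write_session_csv` (or any export
    mapped to the same three-column dialect plus JSON sidecar)."""
    csv_path = Path(csv_path)
    if meta_path is None:
        meta_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    return RawRecording(
        medial_uV=data[:, 1], lateral_uV=data[:, 2],
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        action=meta["action"],
        cue_times_s=np.asarray(meta["cue_times_s"], dtype=float),
        participant_id=str(meta["participant_id"]),
        session_id=str(meta["session_id"]),
        seed=int(meta["seed"]),
    )
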