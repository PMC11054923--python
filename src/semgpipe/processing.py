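"""Envelope extraction and peak-centred segmentation.

The processing chain per repetition is: cut a window around the cued hold,
full-wave rectify both channels, smooth with a 3rd-order 5 Hz low-pass
Butterworth filter, and emit a 2 s segment positioned so that the instant
of peak summed two-channel activity sits at its centre.  Zero-phase
(forward-backward) filtering is the default so envelope peaks are not
lagged; causal single-pass filtering is available for real-time emulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy import stats

from .protocol import RawRecording, RecordingProtocol

__all__ = [
    "FilterSpec",
    "EnvelopeSegment",
    "ChannelCorrelation",
    "rectify",
    "lowpass_envelope",
    "segment_recording",
    "channel_correlation",
    "SEGMENT_DURATION_S",
]

log = logging.getLogger(__name__)

#: Analysis-window length in seconds (fully encloses a 1 s hold).
SEGMENT_DURATION_S = 2.0

#: Threshold below which inter-electrode correlation counts as "low".
LOW_CORRELATION_THRESHOLD = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth envelope filter (default 3rd order, 5 Hz)."""

    order: int = 3
    cutoff_hz: float = 5.0
    phase_mode: Literal["zero", "causal"] = "zero"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not self.cutoff_hz > 0:
            raise ValueError("cutoff_hz must be positive")
        if self.phase_mode not in ("zero", "causal"):
            raise ValueError("phase_mode must be 'zero' or 'causal'")


@dataclass(frozen=True)
class EnvelopeSegment:
    """One 2 s rectified-and-filtered two-channel window."""

    medial_env_uV: np.ndarray
    lateral_env_uV: np.ndarray
    sampling_rate_hz: float
    action: str
    participant_id: str
    session_id: str
    rep_index: int
    center_time_s: float

    def __post_init__(self) -> None:
        if len(self.medial_env_uV) != len(self.lateral_env_uV):
            raise ValueError("channel lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.medial_env_uV)


@dataclass(frozen=True)
class ChannelCorrelation:
    """Pearson correlation between the two electrodes' envelopes."""

    r: float
    is_low: bool


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rectify an empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return np.abs(x)


def _design(spec: FilterSpec, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if spec.cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    return sps.butter(spec.order, spec.cutoff_hz, btype="lowpass",
                      fs=fs, output="sos")


def lowpass_envelope(signal: np.ndarray, sampling_rate_hz: float,
                     spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Low-pass filter a (rectified) signal into a smooth envelope.

    Zero-phase mode filters forward and backward (squaring the magnitude
    response, zero lag); causal mode is a single forward pass.  DC gain is
    exactly 1 in both modes.
    """
    x = np.asarray(signal, dtype=float)
    sos = _design(spec, sampling_rate_hz)
    if spec.phase_mode == "zero":
        return sps.sosfiltfilt(sos, x)
    # start the causal filter from the signal's initial level to avoid a
    # spurious turn-on transient
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def segment_recording(rec: RawRecording, protocol: RecordingProtocol,
                      spec: FilterSpec = FilterSpec()) -> list[EnvelopeSegment]:
    """Cut one peak-centred 2 s envelope segment per repetition.

    For each cue, peak activity is located as the argmax (earliest sample
    on ties) of the summed two-channel rectified-filtered envelope within
    ``[cue - 0.5 s, cue + hold + 1 s]``; the emitted window is peak ± 1 s,
    rectified and filtered per channel within the window.  Windows that
    would overrun the recording are shifted inward (with a warning) rather
    than padded.
    """
    if len(rec.cue_times_s) != protocol.reps_per_session:
        raise ValueError(
            f"recording has {len(rec.cue_times_s)} cues, protocol expects "
            f"{protocol.reps_per_session}")
    fs = rec.sampling_rate_hz
    n = rec.n_samples
    seg_len = round(SEGMENT_DURATION_S * fs)
    if n < seg_len:
        raise ValueError("recording shorter than one segment window")

    # whole-recording envelopes, used only to locate peak activity
    env_sum = (lowpass_envelope(rectify(rec.medial_uV), fs, spec)
               + lowpass_envelope(rectify(rec.lateral_uV), fs, spec))

    half = seg_len // 2
    segments = []
    for rep, cue in enumerate(rec.cue_times_s):
        lo = max(0, round((cue - 0.5) * fs))
        hi = min(n, round((cue + protocol.action_hold_s + 1.0) * fs))
        peak = lo + int(np.argmax(env_sum[lo:hi]))
        start = peak - half
        if start < 0 or start + seg_len > n:
            shifted = min(max(start, 0), n - seg_len)
            log.warning(
                "segment window for rep %d clamped from sample %d to %d",
                rep, start, shifted)
            start = shifted
        sl = slice(start, start + seg_len)
        # clip the tiny negative undershoot the Butterworth filter can
        # introduce on rectified input, keeping envelopes non-negative
        med = np.maximum(lowpass_envelope(rectify(rec.medial_uV[sl]), fs, spec), 0.0)
        lat = np.maximum(lowpass_envelope(rectify(rec.lateral_uV[sl]), fs, spec), 0.0)
        segments.append(EnvelopeSegment(
            medial_env_uV=med,
            lateral_env_uV=lat,
            sampling_rate_hz=fs, action=rec.action,
            participant_id=rec.participant_id, session_id=rec.session_id,
            rep_index=rep, center_time_s=peak / fs,
        ))
    return segments


def channel_correlation(seg: EnvelopeSegment) -> ChannelCorrelation:
    """Pearson correlation between the two filtered channels; ``is_low``
    flags coefficients at or below 0.5."""
    m, l = seg.medial_env_uV, seg.lateral_env_uV
    if np.ptp(m) == 0 or np.ptp(l) == 0:
        raise ValueError("correlation undefined for a zero-variance channel")
    r = float(stats.pearsonr(m, l).statistic)
    return ChannelCorrelation(r=r, is_low=r <= LOW_CORRELATION_THRESHOLD)
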