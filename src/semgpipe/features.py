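"""Time-domain feature extraction from envelope segments.

Six statistics are computed per channel from the rectified-and-filtered
samples V_i of a 2 s segment, giving 12 features per segment:

    V_mean = (1/n) Σ|V_i|                 mean absolute voltage (µV)
    V_max  = max|V_i|, V_min = min|V_i|   extreme absolute voltages (µV)
    V_SD   = sqrt( Σ(V_i - V_mean)² / (n-1) )   sample SD (µV)
    skew   = m3 / m2^(3/2)                population-moment skewness (g1)
    kurt   = m4 / m2²                     Pearson (non-excess) kurtosis

with m_k = (1/n) Σ (V_i - V_mean)^k.  A Gaussian sample has kurt ≈ 3.
Features feed the classifiers raw — no calibration or standardization is
applied anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .processing import EnvelopeSegment

__all__ = [
    "CHANNEL_NAMES",
    "BASE_FEATURES",
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureTable",
    "extract_features",
    "build_feature_table",
]

log = logging.getLogger(__name__)

CHANNEL_NAMES: tuple[str, str] = ("medial", "lateral")
BASE_FEATURES: tuple[str, ...] = ("v_mean", "v_max", "v_min", "v_sd", "skew", "kurt")
#: Canonical column order: channel-major, e.g. medial_v_mean ... lateral_kurt.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{f}" for ch in CHANNEL_NAMES for f in BASE_FEATURES)

_META_COLUMNS = ("participant", "session", "rep", "action")


@dataclass(frozen=True)
class FeatureVector:
    """The 12 named features of one segment plus its labels."""

    values: dict[str, float]
    action: str
    participant_id: str
    session_id: str
    rep_index: int

    def __post_init__(self) -> None:
        if set(self.values) != set(FEATURE_NAMES):
            raise ValueError("feature vector must contain exactly the 12 "
                             "canonical features")


def _channel_features(v: np.ndarray) -> dict[str, float]:
    v = np.abs(np.asarray(v, dtype=float))  # no-op post-rectification
    n = v.size
    out = {
        "v_mean": float(v.mean()),
        "v_max": float(v.max()),
        "v_min": float(v.min()),
        "v_sd": float(v.std(ddof=1)) if n > 1 else 0.0,
    }
    m2 = float(((v - v.mean()) ** 2).mean())
    if m2 > 0.0:
        with np.errstate(all="ignore"):
            out["skew"] = float(stats.skew(v, bias=True))
            out["kurt"] = float(stats.kurtosis(v, fisher=False, bias=True))
    # (near-)zero variance: moment ratios are 0/0; report 0 by convention
    if m2 == 0.0 or not np.isfinite(out.get("skew", np.nan)) \
            or not np.isfinite(out.get("kurt", np.nan)):
        log.warning("zero-variance channel: skew/kurt reported as 0")
        out["skew"] = 0.0
        out["kurt"] = 0.0
    return out


def extract_features(seg: EnvelopeSegment) -> FeatureVector:
    """Compute the 12 per-segment features (6 per channel).

    Zero-variance channels get skew = kurt = 0 with a logged warning
    rather than NaN, so degenerate synthetic inputs do not abort sweeps.
    """
    if seg.n_samples == 0:
        raise ValueError("empty segment")
    values: dict[str, float] = {}
    for ch, samples in zip(CHANNEL_NAMES, (seg.medial_env_uV, seg.lateral_env_uV)):
        for name, val in _channel_features(samples).items():
            values[f"{ch}_{name}"] = val
    return FeatureVector(values=values, action=seg.action,
                         participant_id=seg.participant_id,
                         session_id=seg.session_id, rep_index=seg.rep_index)


class FeatureTable:
    """Labelled per-segment feature rows (one row per 2 s segment).

    Thin wrapper around a :class:`pandas.DataFrame` with metadata columns
    (participant, session, rep, action) followed by the 12 feature
    columns in canonical order.
    """

    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in (*_META_COLUMNS, *FEATURE_NAMES)
                   if c not in frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if frame[list(FEATURE_NAMES)].isna().any().any():
            raise ValueError("feature table contains missing values")
        self.frame = frame.reset_index(drop=True)[
            list(_META_COLUMNS) + list(FEATURE_NAMES)]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["action"].to_numpy()

    @property
    def classification_eligible(self) -> bool:
        """True when at least two distinct action labels are present."""
        return self.frame["action"].nunique() >= 2

    def matrix(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Raw (unscaled) feature matrix restricted to ``subset``."""
        cols = list(subset) if subset is not None else list(FEATURE_NAMES)
        unknown = [c for c in cols if c not in FEATURE_NAMES]
        if unknown:
            raise KeyError(f"unknown feature names: {unknown}")
        return self.frame[cols].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        # repr-precision floats so a read-back round-trips exactly
        self.frame.to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        # round_trip parser so written values read back bit-exact
        return cls(pd.read_csv(path, float_precision="round_trip"))


def build_feature_table(segments: Iterable[EnvelopeSegment]) -> FeatureTable:
    """Assemble one feature row per segment into a :class:`FeatureTable`."""
    rows = []
    segments = list(segments)
    if not segments:
        raise ValueError("no segments given")
    n0 = segments[0].n_samples
    for seg in segments:
        if seg.n_samples != n0:
            raise ValueError("segments have mismatched lengths")
        fv = extract_features(seg)
        rows.append({
            "participant": fv.participant_id, "session": fv.session_id,
            "rep": fv.rep_index, "action": fv.action, **fv.values,
        })
    return FeatureTable(pd.DataFrame(rows))
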