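"""Swimming-speed and fin-beat estimation from keypoint track tables.

Markerless pose-estimation tools export per-frame keypoint tables
(frame, x, y, likelihood per body part).  This module turns such tracks
— typically 60 fps video of a 45-57 mm fish — into a swimming-speed
series in body lengths per second, a fin-beat frequency, and the
frequency-speed regression that characterises how undulation frequency
sets swimming speed.

Two CSV dialects are read: the pose-estimation export layout (three
header rows: scorer / bodyparts / coords, with x, y, likelihood columns
per body part) and a plain ``frame,x,y,confidence`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "TrackSeries",
    "load_tracks",
    "write_tracks",
    "estimate_speed",
    "fin_frequency",
    "correlate_f_u",
    "SpeedEstimate",
]


class TrackFormatError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class TrackSeries:
    """A single keypoint's track.

    positions are in pixels unless ``scale`` (m/px) has been applied by
    the caller; ``body_length`` is in metres.
    """

    frames: np.ndarray        # strictly increasing frame indices
    x: np.ndarray             # px (or m)
    y: np.ndarray
    confidence: np.ndarray    # in [0, 1]
    fps: float = 60.0
    scale: float = 1.0        # metres per pixel
    body_length: float = 0.057  # m
    keypoint: str = "mouth"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.confidence = np.asarray(self.confidence, float)
        if len(self.frames) and (np.diff(self.frames) <= 0).any():
            raise TrackFormatError("frame indices must be strictly increasing")
        if self.fps <= 0:
            raise TrackFormatError("fps must be positive")
        if ((self.confidence < 0) | (self.confidence > 1)).any():
            raise TrackFormatError("confidences must lie in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.fps

    def __len__(self):
        return len(self.frames)


def load_tracks(path_or_buf, dialect: str = "plain", keypoint: str = None,
                fps: float = 60.0, scale: float = 1.0,
                body_length: float = 0.057) -> TrackSeries:
    """Read a keypoint track table.

    ``dialect='plain'``: columns frame, x, y, confidence.
    ``dialect='pose_export'``: three header rows naming body parts with
    x/y/likelihood triples; ``keypoint`` picks the body part (default:
    the first one).
    """
    if dialect == "plain":
        df = pd.read_csv(path_or_buf)
        missing = [c for c in ("frame", "x", "y", "confidence") if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing columns: {', '.join(missing)}")
        return TrackSeries(frames=df["frame"].to_numpy(), x=df["x"].to_numpy(),
                           y=df["y"].to_numpy(),
                           confidence=df["confidence"].to_numpy(),
                           fps=fps, scale=scale, body_length=body_length,
                           keypoint=keypoint or "keypoint")
    if dialect == "pose_export":
        df = pd.read_csv(path_or_buf, header=[0, 1, 2], index_col=0)
        parts = list(dict.fromkeys(c[1] for c in df.columns))
        part = keypoint or parts[0]
        if part not in parts:
            raise TrackFormatError(f"body part {part!r} not in file (has {parts})")
        sub = df.xs(part, axis=1, level=1)
        sub.columns = [c[-1] for c in sub.columns]
        for c in ("x", "y", "likelihood"):
            if c not in sub.columns:
                raise TrackFormatError(f"missing column {c!r} for body part {part!r}")
        return TrackSeries(frames=df.index.to_numpy(), x=sub["x"].to_numpy(),
                           y=sub["y"].to_numpy(),
                           confidence=sub["likelihood"].to_numpy(),
                           fps=fps, scale=scale, body_length=body_length,
                           keypoint=part)
    raise TrackFormatError(f"unknown dialect {dialect!r}")


def write_tracks(track: TrackSeries, path_or_buf) -> None:
    """Write a track in the plain dialect (round-trips with load_tracks)."""
    pd.DataFrame({"frame": track.frames, "x": track.x, "y": track.y,
                  "confidence": track.confidence}).to_csv(path_or_buf, index=False)


@dataclass
class SpeedEstimate:
    times: np.ndarray      # s
    speed: np.ndarray      # BL/s
    plateau: float         # BL/s: mean of the top-decile smoothed speeds
    n_used: int
    n_flagged: int


def estimate_speed(track: TrackSeries, half_width: int = 5,
                   conf_threshold: float = 0.9) -> SpeedEstimate:
    """Swimming-speed series (BL/s) from a keypoint track.

    Frames below the confidence threshold are dropped and linearly
    interpolated; positions are smoothed with a local least-squares
    quadratic (Savitzky-Golay window ``2*half_width + 1``) and
    differentiated centrally.  The plateau speed is the mean of the
    top-decile smoothed speeds — the operational definition of the
    measured swimming speed u_e.
    """
    ok = track.confidence >= conf_threshold
    if ok.sum() < 5:
        raise InsufficientDataError(
            f"only {int(ok.sum())} samples above confidence {conf_threshold}")
    t = track.times
    x = np.interp(t, t[ok], track.x[ok])
    y = np.interp(t, t[ok], track.y[ok])
    window = 2 * half_width + 1
    if window >= len(t):
        window = len(t) - 1 if (len(t) - 1) % 2 else len(t) - 2
    if window >= 3:
        x = signal.savgol_filter(x, window, polyorder=2)
        y = signal.savgol_filter(y, window, polyorder=2)
    dt = 1.0 / track.fps
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    speed = np.hypot(vx, vy) * track.scale / track.body_length
    top = np.sort(speed)[-max(1, len(speed) // 10):]
    return SpeedEstimate(times=t, speed=speed, plateau=float(top.mean()),
                         n_used=int(ok.sum()), n_flagged=int((~ok).sum()))


def fin_frequency(track: TrackSeries, method: str = "zero_crossings") -> float:
    """Fin-beat frequency (Hz) from a fin-tip track's lateral signal.

    ``zero_crossings``: sign changes of the mean-subtracted lateral
    coordinate divided by twice the window length (resolution: one
    crossing quantum = 1/(2*duration)).  ``periodogram``: location of
    the periodogram peak.  Requires at least three oscillation periods.
    """
    sig = track.y - track.y.mean()
    if np.allclose(sig, 0.0):
        raise InsufficientDataError("no oscillation in the lateral signal")
    duration = (track.frames[-1] - track.frames[0]) / track.fps
    crossings = int(np.count_nonzero(np.diff(np.signbit(sig))))
    f_zc = crossings / (2.0 * duration)
    if f_zc * duration < 3:
        raise InsufficientDataError("fewer than three oscillation periods in window")
    if method == "zero_crossings":
        return float(f_zc)
    if method == "periodogram":
        freqs, power = signal.periodogram(sig, fs=track.fps)
        return float(freqs[np.argmax(power)])
    raise ValueError(f"unknown method {method!r}")


def correlate_f_u(f: np.ndarray, u_e: np.ndarray):
    """OLS line and Pearson r for the fin-frequency / speed relation.

    Returns ``(slope, intercept, r)``; slope in (BL/s)/Hz.
    """
    f = np.asarray(f, float)
    u_e = np.asarray(u_e, float)
    if len(f) < 3:
        raise InsufficientDataError("need at least 3 (f, u_e) pairs")
    if np.allclose(f, f[0]):
        raise ValueError("zero variance in f: fit undefined")
    res = stats.linregress(f, u_e)
    return float(res.slope), float(res.intercept), float(res.rvalue)
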