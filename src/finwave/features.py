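"""Kinematic and positional features of swimming behaviour.

Covers the quantities reported for cruising and escape behaviour:
tortuosity of the body curve, thrust (along-heading) velocity, bending
angle between rostral and caudal body chords, arena occupancy heat maps,
time spent in the centre band of the current, and stimulus-aligned
escape time series with bootstrap confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bootstrap_median_band
from .synthetic import ArenaSpec, Trajectory
from .wave_model import BendingField, Midline, MidlineSequence

__all__ = [
    "OccupancyMap",
    "tortuosity",
    "tortuosity_series",
    "velocity_series",
    "max_bending_angle",
    "bending_angle_series",
    "occupancy_map",
    "centre_occupancy",
    "escape_timeseries",
    "bending_series",
]


@dataclass
class OccupancyMap:
    """2D position histogram normalised to percentages summing to 100."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    percent: np.ndarray  # (nx, ny)

    def __post_init__(self) -> None:
        if np.any(self.percent < 0):
            raise ValueError("percentages must be >= 0")
        if abs(float(self.percent.sum()) - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")


def tortuosity(midline: Midline) -> float:
    """Body-curve tortuosity in [0, 1].

    Defined as the difference between the body length and the
    head-to-tail distance, normalised to the body length:
    0 means the animal is entirely straight; 1 means head and tail touch.
    """
    arc = midline.arc_length
    if arc <= 0:
        raise ValueError("midline arc length must be > 0")
    chord = float(np.linalg.norm(midline.tail - midline.head))
    return float(np.clip((arc - chord) / arc, 0.0, 1.0))


def tortuosity_series(seq: MidlineSequence) -> np.ndarray:
    return np.array([tortuosity(m) for m in seq.midlines])


def velocity_series(traj: Trajectory) -> pd.DataFrame:
    """Speed and thrust velocity over time.

    Speed is the centred-difference displacement rate; thrust velocity is
    the velocity component projected on the smoothed heading direction,
    i.e. progress along the direction of travel. Returns a tidy frame
    with columns ``time_s``, ``speed``, ``thrust_velocity``.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples")
    t = traj.times_s
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    vx = np.gradient(traj.x_mm, t)
    vy = np.gradient(traj.y_mm, t)
    speed = np.hypot(vx, vy)
    # smoothed heading from a moving average of velocity
    win = max(3, min(int(traj.fps // 10) | 1, len(t) // 2 * 2 - 1))
    kernel = np.ones(win) / win
    hx = np.convolve(vx, kernel, mode="same")
    hy = np.convolve(vy, kernel, mode="same")
    norm = np.hypot(hx, hy)
    ok = norm > 1e-12
    thrust = np.zeros_like(speed)
    thrust[ok] = (vx[ok] * hx[ok] + vy[ok] * hy[ok]) / norm[ok]
    return pd.DataFrame({"time_s": t, "speed": speed, "thrust_velocity": thrust})


def _chord_angle(midline: Midline, rostral_window=(0.0, 1 / 3),
                 caudal_window=(2 / 3, 1.0)) -> float:
    pts = midline.points
    n = pts.shape[0]

    def chord(window):
        i0 = int(round(window[0] * (n - 1)))
        i1 = int(round(window[1] * (n - 1)))
        return pts[i1] - pts[i0]

    a, b = chord(rostral_window), chord(caudal_window)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        return np.nan  # degenerate chord; caller flags the frame
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosang))


def max_bending_angle(midline: Midline, rostral_window=(0.0, 1 / 3),
                      caudal_window=(2 / 3, 1.0)) -> float:
    """Angle (rad) between the rostral-third and caudal-third body chords."""
    if midline.points.shape[0] < 3:
        raise ValueError("need at least 3 midline points")
    return _chord_angle(midline, rostral_window, caudal_window)


def bending_angle_series(seq: MidlineSequence, **windows) -> pd.DataFrame:
    """Per-frame chord bending angle with per-trial max and median attached."""
    ang = np.array([_chord_angle(m, **windows) if m.points.shape[0] >= 3 else np.nan
                    for m in seq.midlines])
    df = pd.DataFrame({"time_s": seq.times_s, "bending_angle_rad": ang})
    df.attrs["max"] = float(np.nanmax(ang))
    df.attrs["median"] = float(np.nanmedian(ang))
    return df


def occupancy_map(traj: Trajectory, arena: ArenaSpec, n_bins: int = 20) -> OccupancyMap:
    """2D occupancy histogram over the arena, normalised to 100%."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    x, y = traj.x_mm, traj.y_mm
    out = (x < 0) | (x > arena.width_mm) | (y < 0) | (y > arena.height_mm)
    if np.any(out):
        warnings.warn(f"{int(out.sum())} samples outside arena were clipped",
                      RuntimeWarning)
        x = np.clip(x, 0, arena.width_mm)
        y = np.clip(y, 0, arena.height_mm)
    hist, xe, ye = np.histogram2d(
        x, y, bins=n_bins, range=[[0, arena.width_mm], [0, arena.height_mm]]
    )
    percent = hist / hist.sum() * 100.0
    # enforce exact mass conservation against accumulated rounding
    percent *= 100.0 / percent.sum()
    return OccupancyMap(x_edges=xe, y_edges=ye, percent=percent)


def centre_occupancy(traj: Trajectory, arena: ArenaSpec) -> float:
    """Fraction of samples whose lateral (cross-stream) coordinate lies
    within the central band of width ``centre_band_frac`` of the channel."""
    half_band = arena.centre_band_frac * arena.height_mm / 2.0
    centre = arena.height_mm / 2.0
    return float(np.mean(np.abs(traj.y_mm - centre) <= half_band))


def escape_timeseries(
    sequences: list[MidlineSequence],
    trajectories: list[Trajectory] | None = None,
    stim_times_s: list[float] | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Stimulus-aligned escape kinematics across individuals.

    Per individual, tortuosity (and speed when trajectories are given)
    is computed per frame and the time axis re-zeroed at that
    individual's stimulus. Individuals are resampled onto the common
    time grid of the first individual if frame rates differ (logged via
    a warning). Returns a tidy frame with the cross-individual median
    and a 95% bootstrap confidence band per time point.
    """
    if not sequences:
        raise ValueError("need at least one individual")
    stim_times_s = stim_times_s or [0.0] * len(sequences)
    fps0 = sequences[0].fps
    if any(abs(s.fps - fps0) > 1e-9 for s in sequences):
        warnings.warn("frame rates differ across individuals; resampling to "
                      "the first individual's grid", RuntimeWarning)
    # common grid: relative times of the first individual
    rel0 = sequences[0].times_s - stim_times_s[0]
    tort_rows = []
    speed_rows = []
    for k, seq in enumerate(sequences):
        rel = seq.times_s - stim_times_s[k]
        tor = tortuosity_series(seq)
        tort_rows.append(np.interp(rel0, rel, tor))
        if trajectories is not None:
            v = velocity_series(trajectories[k])
            speed_rows.append(np.interp(rel0, rel, v["speed"].to_numpy()))
    tort = np.vstack(tort_rows)
    med, lo, hi = bootstrap_median_band(tort, n_boot=n_boot, seed=seed)
    out = pd.DataFrame({"time_s": rel0, "median_tortuosity": med,
                        "tortuosity_lo": lo, "tortuosity_hi": hi})
    if speed_rows:
        sp = np.vstack(speed_rows)
        meds, los, his = bootstrap_median_band(sp, n_boot=n_boot, seed=seed)
        out["median_speed"] = meds
        out["speed_lo"] = los
        out["speed_hi"] = his
    return out


def pectoral_peak_from_sequence(
    seq: MidlineSequence,
    rostral_window: tuple[float, float] = (0.08, 0.5),
    trim_segments: int = 3,
    smooth_window: int = 9,
) -> float:
    """Pectoral bending-peak position (body-length fraction) from a
    midline sequence.

    Fits the single-frequency bending amplitude envelope and locates its
    rostral-window maximum. Tracked midlines carry pixel-level jitter
    concentrated at the skeleton endpoints, so the bending field is
    smoothed along arc length (Savitzky-Golay) and ``trim_segments``
    end segments are excluded before the envelope is evaluated.
    """
    from scipy.signal import savgol_filter

    from .wave_model import fit_single_frequency, pectoral_peak_position

    bf = bending_series(seq)
    theta = bf.theta
    if smooth_window >= 5 and theta.shape[1] > smooth_window:
        theta = savgol_filter(theta, smooth_window, 2, axis=1)
    k = trim_segments
    sl = slice(k, theta.shape[1] - k) if k > 0 else slice(None)
    trimmed = BendingField(theta=theta[:, sl], times_s=bf.times_s, s_frac=bf.s_frac[sl])
    fit = fit_single_frequency(trimmed)
    return pectoral_peak_position(fit.amplitude, fit.s_frac, rostral_window)


def bending_series(seq: MidlineSequence) -> BendingField:
    """Per-segment local bending angles from a midline sequence.

    The inverse of midline reconstruction: per frame, bending of segment
    j is the turning angle between segments j-1 and j (the first
    segment's absolute heading is dropped, matching a body-frame model
    whose initial heading is arbitrary... the first bending entry is the
    heading change at the first joint relative to heading 0, so a
    sequence generated in the body frame round-trips exactly).
    """
    pts = seq.points_array()
    d = np.diff(pts, axis=1)  # (T, n_seg, 2)
    heading = np.unwrap(np.arctan2(d[..., 1], d[..., 0]), axis=1)
    theta = np.concatenate([heading[:, :1], np.diff(heading, axis=1)], axis=1)
    n_seg = theta.shape[1]
    s = (np.arange(n_seg) + 0.5) / n_seg
    return BendingField(theta=theta, times_s=seq.times_s, s_frac=s)
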